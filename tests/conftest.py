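"""Shared fixtures: small geometries for unit tests and the seeded
20-eye recovery cohorts used by the parameter-recovery checks."""

from __future__ import annotations

import logging

import numpy as np
import pytest
from dataclasses import replace

from retipulse.simulate import PRESETS, SimulationConfig, amplitude_field, make_vessel_tree
from retipulse.pipeline import run_group

logging.getLogger("retipulse").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Coarser scale (12 um/px) so the 1 mm annulus fits a 200 px frame."""
    return SimulationConfig(image_size=200, microns_per_pixel=12.0)


@pytest.fixture(scope="session")
def small_tree(small_config):
    return make_vessel_tree(small_config, seed=7)


@pytest.fixture(scope="session")
def frozen_preset():
    """N1_N1 preset with every dispersion and noise source switched off."""
    return replace(
        PRESETS["N1_N1"],
        between_eye_sd=0.0,
        arterial_between_eye_sd=0.0,
        venous_slope_sd=0.0,
        arterial_slope_sd=0.0,
        noise_sd=0.0,
        drift_magnitude=0.0,
    )


@pytest.fixture(scope="session")
def small_truth(frozen_preset, small_tree, small_config):
    return amplitude_field(frozen_preset, small_tree, small_config.geometry)


@pytest.fixture(scope="session")
def recovery_cohorts():
    """Full-pipeline observation tables for 20-eye seed-1 cohorts of the
    normal (N1_N1) and CRVO study groups — the parameter-recovery basis."""
    return {
        gid: run_group(gid, n_eyes=20, seed=1)
        for gid in ("N1_N1", "CRVO_CRVO")
    }
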