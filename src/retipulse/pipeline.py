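"""End-to-end analysis: video + segmentation + timing -> observations.

Ties the modules together in the order the method prescribes: trim to
three cardiac cycles, tile the vessel mask into 5x5-pixel loci, fit the
harmonic regression per locus, map loci into disc-centred polar
coordinates, restrict to the 0.25-1 mm annulus, split hemifields, and
reduce each vessel x force level to mean/max log amplitude and the
amplitude slope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .harmonic import HarmonicModelSpec, assemble_loci, fit_harmonic
from .io import CardiacTiming, SegmentationMap, VideoSequence, estimate_period, trim_cycles
from .mapping import DiscGeometry, annulus_filter, build_amplitude_map, split_hemifield
from .summary import ODFRecord, summarize_map

__all__ = [
    "analyze_recording",
    "analyze_eye",
    "run_cohort",
    "run_group",
    "cohort_summary",
]


def analyze_recording(
    seq: VideoSequence,
    seg: SegmentationMap,
    timing: CardiacTiming,
    odf_record: ODFRecord,
    n_cycles: int = 3,
    eye_id: str = "",
    participant_id: str = "",
    group_id: str = "",
    group_by_hemifield: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Run the locus-to-vessel pipeline on one recording at one ODF."""
    period = estimate_period(timing)
    seq = trim_cycles(seq, timing, n=n_cycles)
    spec = HarmonicModelSpec.for_record(
        period, float(seq.timestamps[0]), float(seq.timestamps[0]) + n_cycles * period
    )
    loci = assemble_loci(seq, seg)
    fits = [fit_harmonic(s, spec) for s in loci if s.valid]
    geometry = DiscGeometry(seg.disc_center, seg.microns_per_pixel)
    amp_map = build_amplitude_map(fits, geometry)
    amp_map = annulus_filter(amp_map)
    amp_map = split_hemifield(amp_map)
    return summarize_map(
        amp_map,
        odf_record,
        eye_id=eye_id,
        participant_id=participant_id,
        group_id=group_id,
        group_by_hemifield=group_by_hemifield,
    )


def analyze_eye(eye) -> pd.DataFrame:
    """Observations for every force level of one synthetic eye,
    joined with the eye's covariates (the cohort-table contract)."""
    frames_tables = []
    for rec in eye.odf_records:
        seq, timing = eye.render(rec.odf)
        obs = analyze_recording(
            seq,
            eye.tree,
            timing,
            rec,
            n_cycles=eye.config.n_cycles,
            eye_id=eye.eye_id,
            participant_id=eye.participant_id,
            group_id=eye.group_id,
            group_by_hemifield=eye.group_by_hemifield,
        )
        frames_tables.append(obs)
    table = pd.concat(frames_tables, ignore_index=True)
    table["age"] = eye.age
    table["sex"] = eye.sex
    table["poag"] = eye.poag
    table["laterality"] = eye.laterality
    return table


def run_cohort(eyes) -> pd.DataFrame:
    """Analyse an iterable of synthetic eyes into one cohort table."""
    tables = [analyze_eye(eye) for eye in eyes]
    return pd.concat(tables, ignore_index=True)


def run_group(
    group_id: str,
    n_eyes: int,
    seed: int,
    config=None,
    presets=None,
) -> pd.DataFrame:
    """Generate and analyse a single-group synthetic cohort end to end."""
    from .simulate import PRESETS, SimulationConfig, generate_cohort

    config = config if config is not None else SimulationConfig(seed=seed)
    presets = presets if presets is not None else PRESETS
    eyes = generate_cohort(presets, n_eyes, config, seed, groups=(group_id,))
    return run_cohort(eyes)


def cohort_summary(
    table: pd.DataFrame, vessel_label: str, column: str, group_id: str | None = None
) -> tuple[float, float, int]:
    """Cohort mean of a per-eye summary with its simulation standard error.

    Observations are first averaged within each eye (over vessels and
    force levels), then across eyes; the SE is the between-eye standard
    deviation over sqrt(n_eyes).
    """
    sub = table[table["vessel_label"] == vessel_label]
    if group_id is not None:
        sub = sub[sub["group_id"] == group_id]
    sub = sub.dropna(subset=[column])
    per_eye = sub.groupby("eye_id")[column].mean()
    n = len(per_eye)
    mean = float(per_eye.mean())
    se = float(per_eye.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return mean, se, n
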