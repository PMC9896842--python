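"""Synthetic-data generator: geometry, truth calibration, rendering."""

from dataclasses import replace

import numpy as np
import pytest

from retipulse.io import LABELS
from retipulse.mapping import DiscGeometry, to_polar
from retipulse.simulate import (
    GROUP_IDS,
    PRESETS,
    SimulationConfig,
    amplitude_field,
    generate_cohort,
    make_vessel_tree,
    render_frames,
    sample_observation_table,
)


class TestVesselTree:
    def test_annulus_that_cannot_fit_is_rejected(self):
        # disc-to-edge extent well under 1 mm at 6 um/px
        cfg = SimulationConfig(image_size=56)
        with pytest.raises(ValueError, match="1 mm"):
            make_vessel_tree(cfg, seed=0)

    def test_deterministic_under_fixed_seed(self, small_config):
        t1 = make_vessel_tree(small_config, seed=1)
        t2 = make_vessel_tree(small_config, seed=1)
        assert np.array_equal(t1.labels, t2.labels)
        assert np.array_equal(t1.vessel_ids, t2.vessel_ids)

    def test_every_vein_spans_the_full_annulus(self, default_config):
        """Brute-force polar scan: each vein's pixels reach past 1.0 mm."""
        tree = make_vessel_tree(default_config, seed=2)
        geom = DiscGeometry(tree.disc_center, tree.microns_per_pixel)
        veins = tree.vessel_meta[tree.vessel_meta.vessel_label == "vein"]
        assert len(veins) >= 2
        for vid in veins.vessel_id:
            px = np.argwhere(tree.vessel_ids == vid)
            radii = [to_polar((r, c), geom)[0] for r, c in px]
            assert max(radii) >= 1.0
            assert min(radii) < 0.25  # emerges inside the annulus

    def test_each_hemifield_has_artery_and_vein(self, small_tree):
        meta = small_tree.vessel_meta
        for hemi in ("superior", "inferior"):
            sub = meta[meta.hemifield == hemi]
            assert set(sub.vessel_label) == {"artery", "vein"}


class TestAmplitudeField:
    def test_zero_slope_gives_constant_field(self, small_tree, small_config, frozen_preset):
        preset = replace(
            frozen_preset,
            venous_mean_logamp=2.0, venous_slope=0.0,
            arterial_mean_logamp=2.0, arterial_slope=0.0,
        )
        truth = amplitude_field(preset, small_tree, small_config.geometry)
        vessel = (small_tree.labels == LABELS["vein"]) | (small_tree.labels == LABELS["artery"])
        assert np.allclose(np.log(truth.amplitude[vessel]), 2.0, atol=1e-12)

    def test_log_amplitude_is_linear_in_distance(self, small_truth, small_tree, small_config):
        """With venous slope -0.80, log amplitude drops by 0.60 over 0.75 mm."""
        geom = small_config.geometry
        params = small_truth.scope_params[("vein", "both")]
        assert params["slope"] == pytest.approx(-0.80)
        mask = small_tree.labels == LABELS["vein"]
        px = np.argwhere(mask)
        d = np.array([to_polar(tuple(p), geom)[0] for p in px])
        la = np.log(small_truth.amplitude[mask])
        pred = params["intercept"] + params["slope"] * d
        assert np.allclose(la, pred, atol=1e-9)
        # the stated attenuation arithmetic: d=0.25 vs d=1.0 differ by -0.80 * 0.75 = -0.60
        at = lambda dist: params["intercept"] + params["slope"] * dist
        assert at(1.0) - at(0.25) == pytest.approx(-0.60)

    def test_annulus_mean_matches_preset_exactly(self, small_truth, small_tree, small_config):
        """Conservation: zero between-eye SD pins the annulus mean to 2.08."""
        geom = small_config.geometry
        mask = small_tree.labels == LABELS["vein"]
        px = np.argwhere(mask)
        d = np.array([to_polar(tuple(p), geom)[0] for p in px])
        ann = (d >= 0.25) & (d <= 1.0)
        mean = np.log(small_truth.amplitude[mask][ann]).mean()
        assert mean == pytest.approx(PRESETS["N1_N1"].venous_mean_logamp, abs=1e-9)

    def test_per_vessel_truth_table_is_complete(self, small_truth, small_tree):
        tt = small_truth.vessel_truth
        assert set(tt.vessel_id) == set(small_tree.vessel_meta.vessel_id)
        assert (tt.true_max_logamp >= tt.true_mean_logamp - 1e-12).all()


class TestRenderFrames:
    def test_beeps_mark_every_cycle_boundary(self, small_tree, small_truth, small_config):
        _, timing = render_frames(small_truth, small_tree, small_config, seed=0)
        assert np.allclose(np.diff(timing.beep_times), small_config.cardiac_period)
        assert timing.beep_times[0] == 0.0

    def test_deterministic_frames(self, small_tree, small_truth, small_config):
        s1, _ = render_frames(small_truth, small_tree, small_config, seed=9)
        s2, _ = render_frames(small_truth, small_tree, small_config, seed=9)
        assert s1.frames.tobytes() == s2.frames.tobytes()

    def test_noiseless_peak_to_trough_equals_truth(self, small_config, frozen_preset):
        """Single-harmonic waveform sampled through its extremes: the
        rendered range over one cycle equals the truth amplitude."""
        cfg = replace(small_config, frame_rate=24.0)  # extremes at t=0, 0.5 on-grid
        tree = make_vessel_tree(cfg, seed=7)
        preset = replace(frozen_preset, harmonic2_fraction=0.0)
        truth = amplitude_field(preset, tree, cfg.geometry)
        seq, _ = render_frames(truth, tree, cfg, seed=0)
        r, c = np.argwhere(tree.labels == LABELS["vein"])[0]
        cycle = seq.frames[:24, r, c]
        assert np.ptp(cycle) == pytest.approx(truth.amplitude[r, c], rel=1e-12)

    def test_spectrum_contains_only_drift_and_two_harmonics(
        self, small_tree, small_config, frozen_preset
    ):
        """Noise off: vessel-pixel energy sits at DC, the drift bin and
        the first two cardiac harmonics (bins 3 and 6 of a 3-cycle record)."""
        preset = replace(frozen_preset, drift_magnitude=3.0)
        truth = amplitude_field(preset, small_tree, small_config.geometry)
        seq, _ = render_frames(truth, small_tree, small_config, seed=1)
        r, c = np.argwhere(small_tree.labels == LABELS["vein"])[0]
        power = np.abs(np.fft.rfft(seq.frames[:, r, c])) ** 2
        allowed = {0, 1, 3, 6}
        leak = sum(p for k, p in enumerate(power) if k not in allowed)
        assert leak < 1e-12 * power.sum()

    def test_ar1_noise_lag1_autocorrelation(self, frozen_preset):
        """Pooled over >1000 samples the lag-1 autocorrelation of the
        rendered noise matches the AR coefficient within 3 SE."""
        phi = 0.5
        preset = replace(frozen_preset, noise_sd=2.0, ar_coefficient=phi)
        cfg = SimulationConfig(image_size=200, microns_per_pixel=12.0, n_cycles=3)
        tree = make_vessel_tree(cfg, seed=7)
        truth = amplitude_field(preset, tree, cfg.geometry)
        seq, _ = render_frames(truth, tree, cfg, seed=11)
        bg = np.argwhere(tree.labels == LABELS["background"])[:100]
        x = seq.frames[:, bg[:, 0], bg[:, 1]]
        x = x - x.mean(axis=0)  # remove per-pixel baseline
        n_pairs = (x.shape[0] - 1) * x.shape[1]
        r1 = float((x[1:] * x[:-1]).sum() / (x[:-1] ** 2).sum())
        se = (1 - phi**2) ** 0.5 / np.sqrt(n_pairs)
        # mean-correction biases r1 down by ~(1 + 3 phi) / T per series
        bias = (1 + 3 * phi) / x.shape[0]
        assert abs(r1 - phi + bias) < 3 * se + 0.01


class TestCohort:
    def test_hvo_hemifields_share_one_physical_eye(self, small_config):
        eyes = list(generate_cohort(PRESETS, 1, small_config, seed=3))
        assert len(eyes) == 5  # 6 groups, HVO_HVO + N2_HVO merged
        hvo = [e for e in eyes if e.group_id == "HVO_HVO"]
        assert len(hvo) == 1
        assert hvo[0].group_by_hemifield == {
            "superior": "HVO_HVO", "inferior": "N2_HVO",
        }

    def test_fellow_eyes_share_participant_and_age(self, small_config):
        eyes = {e.group_id: e for e in generate_cohort(PRESETS, 1, small_config, seed=3)}
        assert eyes["N1_CRVO"].participant_id == eyes["CRVO_CRVO"].participant_id
        assert eyes["N1_CRVO"].age == eyes["CRVO_CRVO"].age

    def test_cohort_reproducible_from_seed(self, small_config):
        e1 = next(generate_cohort(PRESETS, 1, small_config, seed=5, groups=("N1_N1",)))
        e2 = next(generate_cohort(PRESETS, 1, small_config, seed=5, groups=("N1_N1",)))
        assert e1.truth.amplitude.tobytes() == e2.truth.amplitude.tobytes()
        s1, _ = e1.render(0.0)
        s2, _ = e2.render(0.0)
        assert s1.frames.tobytes() == s2.frames.tobytes()

    def test_unknown_group_rejected(self, small_config):
        with pytest.raises(KeyError):
            list(generate_cohort(PRESETS, 1, small_config, seed=0, groups=("BRVO",)))

    def test_between_eye_dispersion_is_realised(self, small_config):
        """Empirical SD of per-eye venous targets tracks the preset SD."""
        targets = [
            e.truth.scope_params[("vein", "both")]["annulus_mean"]
            for e in generate_cohort(PRESETS, 20, small_config, seed=1, groups=("N1_N1",))
        ]
        sd = np.std(targets, ddof=1)
        truth_sd = PRESETS["N1_N1"].between_eye_sd
        # sampling SD of a 20-draw sample SD is ~ sd / sqrt(2*(n-1))
        assert abs(sd - truth_sd) < 3 * truth_sd / np.sqrt(2 * 19)

    def test_group_ids_cover_the_six_study_groups(self):
        assert set(PRESETS) == set(GROUP_IDS)
        eyes = sample_observation_table(PRESETS, 2, seed=0)
        assert set(eyes.group_id) == set(GROUP_IDS)
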