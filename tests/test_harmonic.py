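"""Harmonic regression core: locus assembly, AR(1) fitting, amplitudes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retipulse.harmonic import (
    AMPLITUDE_FLOOR,
    HarmonicFit,
    HarmonicModelSpec,
    LocusSeries,
    amplitude_from_fit,
    assemble_loci,
    design_matrix,
    fit_harmonic,
    log_amplitude,
    periodic_component,
)
from retipulse.io import LABELS, SegmentationMap, VideoSequence


def _spec(period=1.0, t_end=3.0):
    return HarmonicModelSpec.for_record(period, 0.0, t_end)


def _series(y, fps=25.0, label="vein"):
    y = np.asarray(y, dtype=float)
    return LocusSeries((0, 0), y, np.arange(y.size) / fps, label)


def _fit_with(a1=0.0, b1=0.0, a2=0.0, b2=0.0):
    return HarmonicFit(
        center_pixel=(0, 0), vessel_label="vein", vessel_id=1,
        trend_coefficients=np.zeros(2), a1=a1, b1=b1, a2=a2, b2=b2,
        phi=0.0, sigma=0.0, amplitude=0.0, log_amplitude=0.0,
        floored=False, converged=True,
    )


class TestAssembleLoci:
    def _video(self, h, w, value=5.0, n_frames=3):
        return VideoSequence(np.full((n_frames, h, w), value), np.arange(n_frames) / 25.0)

    def test_vessel_patch_tiles_on_cluster_stride(self):
        labels = np.zeros((10, 10), dtype=np.uint8)
        labels[:, :] = LABELS["vein"]
        seg = SegmentationMap(labels, (5, 5))
        loci = assemble_loci(self._video(10, 10), seg, cluster=5)
        assert len(loci) == 4  # 2 x 2 grid
        assert all(l.valid for l in loci)
        assert {l.center_pixel for l in loci} == {(2, 2), (2, 7), (7, 2), (7, 7)}

    def test_cluster_below_label_fraction_is_invalid(self):
        labels = np.zeros((5, 5), dtype=np.uint8)
        labels.flat[:10] = LABELS["vein"]  # 10/25 = 40% < 60%
        seg = SegmentationMap(labels, (2, 2))
        loci = assemble_loci(self._video(5, 5), seg, cluster=5)
        assert len(loci) == 1 and not loci[0].valid

    def test_constant_image_gives_constant_series(self):
        labels = np.full((5, 5), LABELS["artery"], dtype=np.uint8)
        seg = SegmentationMap(labels, (2, 2))
        (locus,) = assemble_loci(self._video(5, 5, value=9.0), seg)
        assert np.all(locus.values == 9.0)

    def test_dimension_mismatch_rejected(self):
        seg = SegmentationMap(np.zeros((6, 6), dtype=np.uint8), (3, 3))
        with pytest.raises(ValueError, match="dimensions"):
            assemble_loci(self._video(5, 5), seg)


class TestFitHarmonic:
    def test_noiseless_single_harmonic_recovered_exactly(self):
        t = np.arange(75) / 25.0
        y = 10.0 * np.cos(2 * np.pi * t / 1.0)
        fit = fit_harmonic(_series(y), _spec())
        assert fit.converged
        assert fit.a1 == pytest.approx(10.0, abs=1e-8)
        assert abs(fit.b1) < 1e-8 and abs(fit.a2) < 1e-8 and abs(fit.b2) < 1e-8
        assert fit.phi == 0.0
        assert fit.amplitude == pytest.approx(20.0, abs=1e-6)

    def test_constant_series_floors_the_amplitude(self):
        fit = fit_harmonic(_series(np.full(75, 3.0)), _spec())
        assert fit.floored
        assert fit.log_amplitude == pytest.approx(math.log(AMPLITUDE_FLOOR))

    def test_noiseless_two_harmonics_with_spline_drift_exact(self):
        """Exactness: spline-representable drift plus two harmonics are
        recovered to 1e-6 relative amplitude error."""
        t = np.arange(75) / 25.0
        spec = _spec()
        drift = 2.0 + 0.5 * t - 1.5 * np.maximum(t - 1.0, 0) + 0.8 * np.maximum(t - 2.0, 0)
        omega = 2 * np.pi
        y = drift + 6 * np.cos(omega * t) + 8 * np.sin(omega * t) + 2 * np.cos(2 * omega * t)
        fit = fit_harmonic(_series(y), spec)
        truth = _fit_with(a1=6, b1=8, a2=2)
        expected = amplitude_from_fit(truth, spec)
        assert fit.amplitude == pytest.approx(expected, rel=1e-6)

    def test_rank_deficient_design_rejected(self):
        # duplicated knot -> identical spline columns
        spec = HarmonicModelSpec(1.0, spline_knots=[1.0, 1.0])
        with pytest.raises(ValueError, match="rank"):
            fit_harmonic(_series(np.zeros(75)), spec)
        # more parameters than observations
        dense = HarmonicModelSpec(1.0, spline_knots=np.linspace(0.01, 2.9, 200))
        with pytest.raises(ValueError, match="cannot support"):
            fit_harmonic(_series(np.zeros(75)), dense)

    def test_gls_oracle_equivalence_with_known_phi(self):
        """Prais-Winsten whitening at fixed phi equals exact GLS with the
        analytic AR(1) covariance, inverted directly (n = 40)."""
        rng = np.random.default_rng(5)
        n, phi = 40, 0.6
        t = np.arange(n) / 25.0
        spec = HarmonicModelSpec.for_record(1.0, 0.0, t[-1] + 0.04)
        X = design_matrix(t, spec)
        y = X @ rng.normal(size=X.shape[1]) + rng.normal(size=n)
        fit = fit_harmonic(_series(y), spec, phi=phi)
        idx = np.arange(n)
        sigma = phi ** np.abs(idx[:, None] - idx[None, :]) / (1 - phi**2)
        si = np.linalg.inv(sigma)
        beta = np.linalg.solve(X.T @ si @ X, X.T @ si @ y)
        ours = np.concatenate([fit.trend_coefficients, fit.harmonic_coefficients])
        assert np.abs(ours - beta).max() < 1e-8

    def test_coefficients_within_three_se_of_truth(self):
        """Monte-Carlo recovery on an AR(1) series of n = 300."""
        rng = np.random.default_rng(12)
        n, phi, sig = 300, 0.5, 1.0
        t = np.arange(n) / 25.0
        spec = HarmonicModelSpec.for_record(1.0, 0.0, n / 25.0)
        truth = {"a1": 6.0, "b1": 8.0, "a2": 2.0, "b2": 0.0}
        omega = 2 * np.pi
        signal = (
            truth["a1"] * np.cos(omega * t) + truth["b1"] * np.sin(omega * t)
            + truth["a2"] * np.cos(2 * omega * t)
        )
        eps = np.empty(n)
        eps[0] = rng.normal(0, sig / math.sqrt(1 - phi**2))
        for k in range(1, n):
            eps[k] = phi * eps[k - 1] + rng.normal(0, sig)
        fit = fit_harmonic(_series(signal + eps), spec)
        se = fit.coef_se[-4:]
        for i, key in enumerate(("a1", "b1", "a2", "b2")):
            assert abs(fit.harmonic_coefficients[i] - truth[key]) < 3 * se[i]
        assert abs(fit.phi - phi) < 0.2

    def test_bias_and_coverage_over_replicates(self):
        """Across 150 replicates: coefficient bias within Monte-Carlo error
        of zero, and 95% interval coverage for a1 inside [90%, 99%]."""
        rng = np.random.default_rng(99)
        n, phi, sig, reps = 300, 0.5, 1.0, 150
        t = np.arange(n) / 25.0
        spec = HarmonicModelSpec.for_record(1.0, 0.0, n / 25.0)
        a1 = 6.0
        omega = 2 * np.pi
        signal = a1 * np.cos(omega * t) + 8.0 * np.sin(omega * t)
        errs, cover = [], 0
        for _ in range(reps):
            eps = np.empty(n)
            eps[0] = rng.normal(0, sig / math.sqrt(1 - phi**2))
            for k in range(1, n):
                eps[k] = phi * eps[k - 1] + rng.normal(0, sig)
            fit = fit_harmonic(_series(signal + eps), spec)
            errs.append(fit.a1 - a1)
            if abs(fit.a1 - a1) < 1.96 * fit.coef_se[-4]:
                cover += 1
        errs = np.asarray(errs)
        assert abs(errs.mean()) < 3 * errs.std(ddof=1) / math.sqrt(reps)
        assert 0.90 * reps <= cover + 0.5 and cover <= 0.99 * reps + 1


class TestAmplitude:
    def test_pure_first_harmonic_range(self):
        assert amplitude_from_fit(_fit_with(a1=10), _spec()) == pytest.approx(20.0, abs=1e-9)

    def test_pure_second_harmonic_range(self):
        # 3 cos(2wt) + 4 sin(2wt) = 5 cos(2wt - psi): range 10
        assert amplitude_from_fit(_fit_with(a2=3, b2=4), _spec()) == pytest.approx(10.0, abs=1e-8)

    def test_mixed_harmonics_match_dense_grid_oracle(self):
        fit = _fit_with(a1=6, b1=8, a2=2)
        spec = _spec()
        grid = np.linspace(0, spec.fundamental_period, 10_000, endpoint=False)
        vals = periodic_component(fit, spec, grid)
        oracle = float(vals.max() - vals.min())
        assert amplitude_from_fit(fit, spec) == pytest.approx(oracle, rel=1e-6)
        # the refined optimum can only widen the grid estimate
        assert amplitude_from_fit(fit, spec) >= oracle - 1e-12

    def test_first_harmonic_definition_switch(self):
        fit = _fit_with(a1=3, b1=4, a2=50)
        assert amplitude_from_fit(fit, _spec(), method="first_harmonic") == pytest.approx(10.0)


class TestLogAmplitude:
    @pytest.mark.parametrize(
        "amp,expected", [(1.0, 0.0), (math.e**2, 2.0), (math.e, 1.0)]
    )
    def test_known_values(self, amp, expected):
        value, floored = log_amplitude(amp)
        assert value == pytest.approx(expected)
        assert not floored

    def test_zero_amplitude_floors(self):
        value, floored = log_amplitude(0.0, floor=1e-3)
        assert value == pytest.approx(math.log(1e-3))
        assert floored

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            log_amplitude(-0.1)

    @given(
        a=st.floats(min_value=1e-2, max_value=1e3),
        factor=st.floats(min_value=1.0001, max_value=10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_above_floor(self, a, factor):
        assert log_amplitude(a * factor)[0] > log_amplitude(a)[0]
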