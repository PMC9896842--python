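"""Harmonic regression of locus time series against the cardiac cycle.

Each 5x5-pixel locus (a 30 x 30 micron cluster at 6 um/px) yields one
green-intensity time series. The model fitted to it is

    y(t) = S(t) + sum_{k=1,2} [a_k cos(2 pi k t / T) + b_k sin(2 pi k t / T)] + e(t)
    e_t = phi * e_{t-1} + eta_t,      eta_t ~ iid N(0, sigma^2)

with S a linear spline (trend) whose knots default to the cardiac-cycle
boundaries, T the oximeter-derived cardiac period, and an AR(1) error.
The pulse amplitude is the peak-to-trough range of the fitted
two-harmonic waveform over one period; a log transform of that amplitude
("log u") is the quantity carried into all downstream statistics.

Estimation is iterated Cochrane-Orcutt with a Prais-Winsten first
observation, which at convergence (or with the AR coefficient held
fixed) coincides exactly with generalised least squares under the
analytic AR(1) covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .io import LABELS, SegmentationMap, VideoSequence

__all__ = [
    "LocusSeries",
    "HarmonicModelSpec",
    "HarmonicFit",
    "assemble_loci",
    "fit_harmonic",
    "amplitude_from_fit",
    "log_amplitude",
    "fits_to_table",
]

#: Minimum fraction of cluster pixels that must carry the vessel label.
LABEL_FRACTION = 0.60

#: Amplitudes below this floor (arbitrary intensity units) are clamped
#: before the log transform.
AMPLITUDE_FLOOR = 1e-3


@dataclass
class LocusSeries:
    """Mean green intensity of one pixel cluster per frame."""

    center_pixel: tuple[int, int]
    values: np.ndarray
    timestamps: np.ndarray
    vessel_label: str
    vessel_id: int = 0
    valid: bool = True
    label_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.values.shape != self.timestamps.shape:
            raise ValueError("values and timestamps must have equal length")


@dataclass
class HarmonicModelSpec:
    """Structure of the locus regression model.

    ``spline_knots`` are the interior knots of the linear-spline trend;
    by default one knot per cardiac-cycle boundary (two interior knots
    for a three-cycle record).
    """

    fundamental_period: float
    spline_knots: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_harmonics: int = 2
    ar_order: int = 1

    def __post_init__(self) -> None:
        if self.fundamental_period <= 0:
            raise ValueError("fundamental period must be positive")
        self.spline_knots = np.sort(np.asarray(self.spline_knots, dtype=float))

    @classmethod
    def for_record(
        cls, period: float, t_start: float, t_end: float
    ) -> "HarmonicModelSpec":
        """Spec with interior knots at each cycle boundary within (t_start, t_end)."""
        knots = np.arange(t_start + period, t_end, period)
        knots = knots[knots < t_end - 1e-9]
        return cls(fundamental_period=period, spline_knots=knots)


@dataclass
class HarmonicFit:
    """Per-locus estimates from the harmonic regression."""

    center_pixel: tuple[int, int]
    vessel_label: str
    vessel_id: int
    trend_coefficients: np.ndarray
    a1: float
    b1: float
    a2: float
    b2: float
    phi: float
    sigma: float
    amplitude: float
    log_amplitude: float
    floored: bool
    converged: bool
    n_iter: int = 0
    coef_se: np.ndarray | None = None
    coef_cov: np.ndarray | None = None

    @property
    def harmonic_coefficients(self) -> np.ndarray:
        return np.array([self.a1, self.b1, self.a2, self.b2])


# ---------------------------------------------------------------------------
# locus assembly


def _block_stats(values: np.ndarray, mask: np.ndarray, cluster: int):
    """Per-block sums of ``values`` over ``mask`` pixels and block counts.

    ``values`` may be (H, W) or (T, H, W); blocks tile the image on a
    stride equal to the cluster size (partial edge blocks dropped).
    """
    h, w = mask.shape
    hb, wb = h // cluster, w // cluster
    m = mask[: hb * cluster, : wb * cluster]
    counts = m.reshape(hb, cluster, wb, cluster).sum(axis=(1, 3))
    if values.ndim == 2:
        v = np.where(m, values[: hb * cluster, : wb * cluster], 0.0)
        sums = v.reshape(hb, cluster, wb, cluster).sum(axis=(1, 3))
    else:
        v = np.where(m, values[:, : hb * cluster, : wb * cluster], 0.0)
        t = v.shape[0]
        sums = v.reshape(t, hb, cluster, wb, cluster).sum(axis=(2, 4))
    return sums, counts


def assemble_loci(
    seq: VideoSequence,
    seg: SegmentationMap,
    cluster: int = 5,
    labels: tuple[str, ...] = ("artery", "vein"),
    min_label_fraction: float = LABEL_FRACTION,
) -> list[LocusSeries]:
    """Tile the vessel mask into cluster-sized loci and extract their series.

    Clusters tile the image on a stride equal to the cluster size; a
    cluster is a valid locus for a vessel class when at least
    ``min_label_fraction`` of its pixels carry that label. The series is
    the per-frame mean over the labelled pixels only. Invalid clusters
    are returned flagged so the caller can count exclusions.
    """
    if seq.image_shape != seg.labels.shape:
        raise ValueError(
            f"video {seq.image_shape} and segmentation {seg.labels.shape} "
            "dimensions differ"
        )
    frames = np.asarray(seq.frames, dtype=float)
    vessel_ids = seg.vessel_ids
    loci: list[LocusSeries] = []
    min_count = min_label_fraction * cluster * cluster
    for label in labels:
        code = LABELS[label]
        mask = seg.labels == code
        if not mask.any():
            continue
        sums, counts = _block_stats(frames, mask, cluster)
        occupied = counts > 0
        for bi, bj in zip(*np.nonzero(occupied)):
            n_px = counts[bi, bj]
            valid = n_px >= min_count
            center = (bi * cluster + cluster // 2, bj * cluster + cluster // 2)
            series = sums[:, bi, bj] / n_px
            vid = 0
            if vessel_ids is not None:
                block = vessel_ids[
                    bi * cluster : (bi + 1) * cluster, bj * cluster : (bj + 1) * cluster
                ]
                ids = block[
                    mask[bi * cluster : (bi + 1) * cluster, bj * cluster : (bj + 1) * cluster]
                ]
                if ids.size:
                    uniq, cnt = np.unique(ids, return_counts=True)
                    vid = int(uniq[np.argmax(cnt)])
            loci.append(
                LocusSeries(
                    center_pixel=center,
                    values=series,
                    timestamps=seq.timestamps,
                    vessel_label=label,
                    vessel_id=vid,
                    valid=bool(valid),
                    label_fraction=float(n_px) / (cluster * cluster),
                )
            )
    return loci


# ---------------------------------------------------------------------------
# model fitting


def design_matrix(t: np.ndarray, spec: HarmonicModelSpec) -> np.ndarray:
    """Columns: intercept, t, hinge(t - knot_i)..., cos/sin at k = 1..n_harmonics."""
    cols = [np.ones_like(t), t]
    cols += [np.maximum(t - k, 0.0) for k in spec.spline_knots]
    omega = 2.0 * np.pi / spec.fundamental_period
    for k in range(1, spec.n_harmonics + 1):
        cols.append(np.cos(k * omega * t))
        cols.append(np.sin(k * omega * t))
    return np.column_stack(cols)


def _prais_winsten(X: np.ndarray, y: np.ndarray, phi: float):
    """AR(1)-whitened design and response (exact GLS transform)."""
    s = math.sqrt(1.0 - phi * phi)
    Xw = np.empty_like(X)
    yw = np.empty_like(y)
    Xw[0] = s * X[0]
    yw[0] = s * y[0]
    Xw[1:] = X[1:] - phi * X[:-1]
    yw[1:] = y[1:] - phi * y[:-1]
    return Xw, yw


def fit_harmonic(
    series: LocusSeries,
    spec: HarmonicModelSpec,
    phi: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
    amplitude_method: str = "peak_to_trough",
    floor: float = AMPLITUDE_FLOOR,
) -> HarmonicFit:
    """Fit the spline + two-harmonic + AR(1) model to one locus.

    Parameters
    ----------
    series : LocusSeries
        The locus time series (must be flagged valid).
    spec : HarmonicModelSpec
        Model structure; the fundamental period comes from the oximeter
        timing, never re-estimated from the pixel signal.
    phi : float, optional
        Hold the AR(1) coefficient fixed at this value (then the solve is
        a single exact GLS step). By default ``phi`` is estimated by
        iterated Cochrane-Orcutt: whiten with the current value, refit,
        re-estimate from the residual lag-1 autocorrelation, to ``tol``.
    amplitude_method : {"peak_to_trough", "first_harmonic"}
        Definition of the pulse amplitude; ``peak_to_trough`` (default)
        is the range of the fitted two-harmonic waveform over one period,
        ``first_harmonic`` is ``2 * sqrt(a1^2 + b1^2)``.

    Raises
    ------
    ValueError
        If the design is rank deficient (knots too dense for the record)
        or the series is too short to resolve two harmonics.
    """
    t = series.timestamps
    y = series.values
    n = y.size
    X = design_matrix(t, spec)
    p = X.shape[1]
    if n < p:
        raise ValueError(f"series of length {n} cannot support {p} parameters")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design: spline knots too dense for the record")

    n_harm_cols = 2 * spec.n_harmonics
    fixed_phi = phi is not None
    cur_phi = float(phi) if fixed_phi else 0.0
    y_var = float(np.var(y))

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    converged = False
    it = 0
    if fixed_phi:
        Xw, yw = _prais_winsten(X, y, cur_phi)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = y - X @ beta
        converged = True
    else:
        for it in range(1, max_iter + 1):
            denom = float(resid[:-1] @ resid[:-1])
            if denom <= 1e-12 * max(y_var, 1.0) * n or float(resid @ resid) <= 1e-20 * n:
                # numerically perfect fit: no error process to estimate
                cur_phi = 0.0
                converged = True
                break
            new_phi = float(resid[1:] @ resid[:-1]) / denom
            new_phi = float(np.clip(new_phi, -0.99, 0.99))
            Xw, yw = _prais_winsten(X, y, new_phi)
            beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
            resid = y - X @ beta
            if abs(new_phi - cur_phi) < tol:
                cur_phi = new_phi
                converged = True
                break
            cur_phi = new_phi

    Xw, yw = _prais_winsten(X, y, cur_phi)
    rw = yw - Xw @ beta
    dof = max(n - p, 1)
    sigma = float(np.sqrt(rw @ rw / dof))
    XtX = Xw.T @ Xw
    try:
        cov = sigma**2 * np.linalg.inv(XtX)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:  # pragma: no cover - rank guard above
        cov = None
        se = None

    a1, b1, a2, b2 = beta[-n_harm_cols:][:4] if spec.n_harmonics >= 2 else (
        *beta[-n_harm_cols:], 0.0, 0.0
    )
    fit = HarmonicFit(
        center_pixel=series.center_pixel,
        vessel_label=series.vessel_label,
        vessel_id=series.vessel_id,
        trend_coefficients=beta[: p - n_harm_cols],
        a1=float(a1),
        b1=float(b1),
        a2=float(a2),
        b2=float(b2),
        phi=cur_phi,
        sigma=sigma,
        amplitude=0.0,
        log_amplitude=0.0,
        floored=False,
        converged=bool(converged),
        n_iter=it,
        coef_se=se,
        coef_cov=cov,
    )
    fit.amplitude = amplitude_from_fit(fit, spec, method=amplitude_method)
    fit.log_amplitude, fit.floored = log_amplitude(fit.amplitude, floor=floor)
    return fit


def periodic_component(fit: HarmonicFit, spec: HarmonicModelSpec, t: np.ndarray):
    omega = 2.0 * np.pi / spec.fundamental_period
    return (
        fit.a1 * np.cos(omega * t)
        + fit.b1 * np.sin(omega * t)
        + fit.a2 * np.cos(2 * omega * t)
        + fit.b2 * np.sin(2 * omega * t)
    )


def amplitude_from_fit(
    fit: HarmonicFit,
    spec: HarmonicModelSpec,
    method: str = "peak_to_trough",
    n_grid: int = 4096,
) -> float:
    """Pulse amplitude of the fitted periodic component.

    ``peak_to_trough`` evaluates the two-harmonic waveform on a dense
    grid over one period (two-harmonic ranges have no simple closed
    form) and polishes the extremes by bounded scalar optimisation;
    ``first_harmonic`` returns ``2 * sqrt(a1^2 + b1^2)``.
    """
    if method == "first_harmonic":
        return 2.0 * math.hypot(fit.a1, fit.b1)
    if method != "peak_to_trough":
        raise ValueError(f"unknown amplitude method: {method!r}")
    T = spec.fundamental_period
    grid = np.linspace(0.0, T, n_grid, endpoint=False)
    vals = periodic_component(fit, spec, grid)
    step = T / n_grid

    def refine(i: int, sign: float) -> float:
        t0 = grid[i]
        res = minimize_scalar(
            lambda t: sign * periodic_component(fit, spec, np.array([t]))[0],
            bounds=(t0 - step, t0 + step),
            method="bounded",
            options={"xatol": 1e-12},
        )
        return sign * res.fun

    hi = max(float(vals.max()), refine(int(np.argmax(vals)), -1.0))
    lo = min(float(vals.min()), refine(int(np.argmin(vals)), 1.0))
    return hi - lo


def log_amplitude(amplitude: float, floor: float = AMPLITUDE_FLOOR) -> tuple[float, bool]:
    """Natural log of the amplitude, clamped at a small positive floor.

    Returns ``(log u, floored)`` where ``floored`` marks amplitudes at or
    below the floor (e.g. a constant series).
    """
    if amplitude < 0:
        raise ValueError("amplitude cannot be negative")
    if amplitude <= floor:
        return math.log(floor), True
    return math.log(amplitude), False


def fits_to_table(fits: list[HarmonicFit]) -> pd.DataFrame:
    """Flatten fits to the per-locus CSV contract."""
    rows = [
        {
            "center_row": f.center_pixel[0],
            "center_col": f.center_pixel[1],
            "vessel_label": f.vessel_label,
            "vessel_id": f.vessel_id,
            "a1": f.a1,
            "b1": f.b1,
            "a2": f.a2,
            "b2": f.b2,
            "phi": f.phi,
            "sigma": f.sigma,
            "amplitude": f.amplitude,
            "log_amplitude": f.log_amplitude,
            "floored": f.floored,
            "converged": f.converged,
        }
        for f in fits
    ]
    return pd.DataFrame(rows)
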