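"""Disc-centred polar mapping of locus amplitudes and heat-map export.

The optic-disc centre is the polar origin. Radial distance ``d`` is in
millimetres (pixel distance x microns-per-pixel / 1000); the angle is
measured from the horizontal image axis, counter-clockwise, in
(-180, 180] degrees, so positive angles (smaller row indices, the image
top) are the superior hemifield in standard fundus-photo orientation.
Analysis is restricted to the 0.25-1 mm annulus: the innermost zone is
dropped to exclude the rising phase of pulsation near the vessel origin.
Annulus bounds are treated as closed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .harmonic import HarmonicFit  # noqa: E402

__all__ = [
    "DiscGeometry",
    "to_polar",
    "build_amplitude_map",
    "annulus_filter",
    "detection_filter",
    "split_hemifield",
    "render_heatmap",
    "ANNULUS_INNER_MM",
    "ANNULUS_OUTER_MM",
]

ANNULUS_INNER_MM = 0.25
ANNULUS_OUTER_MM = 1.0


@dataclass(frozen=True)
class DiscGeometry:
    """Disc centre (row, col) and image scale."""

    disc_center: tuple[float, float]
    microns_per_pixel: float = 6.0  # 30 um locus = 5 px cluster

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")


def to_polar(
    center_pixel: tuple[float, float], geometry: DiscGeometry
) -> tuple[float, float]:
    """Polar coordinates (d in mm, angle in degrees) of a locus centre.

    The angle is measured counter-clockwise from the horizontal axis;
    loci above the disc centre (smaller rows) have positive angles.
    """
    dy = geometry.disc_center[0] - center_pixel[0]  # positive = image up
    dx = center_pixel[1] - geometry.disc_center[1]
    d_px = math.hypot(dy, dx)
    d_mm = d_px * geometry.microns_per_pixel / 1000.0
    angle = math.degrees(math.atan2(dy, dx))
    if angle <= -180.0:  # atan2 returns (-180, 180]; keep that convention
        angle += 360.0
    return d_mm, angle


def build_amplitude_map(
    fits: list[HarmonicFit], geometry: DiscGeometry
) -> pd.DataFrame:
    """One row per converged locus with polar fields attached.

    Columns: ``center_row, center_col, vessel_label, vessel_id,
    amplitude, log_amplitude, floored, d_mm, angle_deg``.
    """
    rows = []
    for f in fits:
        if not f.converged:
            continue
        d_mm, angle = to_polar(f.center_pixel, geometry)
        rows.append(
            {
                "center_row": f.center_pixel[0],
                "center_col": f.center_pixel[1],
                "vessel_label": f.vessel_label,
                "vessel_id": f.vessel_id,
                "amplitude": f.amplitude,
                "log_amplitude": f.log_amplitude,
                "floored": f.floored,
                "d_mm": d_mm,
                "angle_deg": angle,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "center_row",
            "center_col",
            "vessel_label",
            "vessel_id",
            "amplitude",
            "log_amplitude",
            "floored",
            "d_mm",
            "angle_deg",
        ],
    )


def annulus_filter(
    amp_map: pd.DataFrame,
    inner: float = ANNULUS_INNER_MM,
    outer: float = ANNULUS_OUTER_MM,
) -> pd.DataFrame:
    """Keep loci with ``inner <= d <= outer`` (closed bounds).

    The number of removed loci is recorded in ``DataFrame.attrs`` under
    ``"n_removed"``. Idempotent by construction.
    """
    if inner >= outer:
        raise ValueError(f"inner bound {inner} must be below outer bound {outer}")
    keep = (amp_map["d_mm"] >= inner) & (amp_map["d_mm"] <= outer)
    out = amp_map.loc[keep].reset_index(drop=True)
    out.attrs["n_removed"] = int((~keep).sum())
    return out


def detection_filter(amp_map: pd.DataFrame, min_amplitude: float = 5.0) -> pd.DataFrame:
    """Optionally drop loci below a raw-amplitude detection threshold.

    Five arbitrary units is the sensitivity/specificity optimum for
    visible pulsation detection; the filter is off by default in the
    pipeline because group summaries average amplitudes rather than make
    detection calls.
    """
    keep = amp_map["amplitude"] >= min_amplitude
    out = amp_map.loc[keep].reset_index(drop=True)
    out.attrs["n_removed"] = int((~keep).sum())
    return out


def split_hemifield(amp_map: pd.DataFrame) -> pd.DataFrame:
    """Tag each locus superior (angle in (0, 180)) or inferior.

    Loci exactly on the horizontal axis (angle 0 or 180) inherit the
    hemifield of their vessel's circular-mean angle, so a vessel
    straddling the axis stays in one hemifield.
    """
    out = amp_map.copy()
    angle = out["angle_deg"].to_numpy(float)
    on_axis = (angle == 0.0) | (angle == 180.0)
    hemi = np.where(angle > 0, "superior", "inferior")
    hemi[(angle == 180.0)] = "inferior"  # provisional; fixed below by vessel rule
    out["hemifield"] = hemi
    if on_axis.any():
        rad = np.radians(angle)
        for vid, grp in out.groupby("vessel_id"):
            idx = grp.index[on_axis[grp.index]]
            if len(idx) == 0:
                continue
            mean_angle = math.degrees(
                math.atan2(
                    float(np.mean(np.sin(rad[grp.index]))),
                    float(np.mean(np.cos(rad[grp.index]))),
                )
            )
            out.loc[idx, "hemifield"] = "superior" if mean_angle > 0 else "inferior"
    return out


def render_heatmap(
    amp_map: pd.DataFrame,
    background: np.ndarray,
    path,
    scale: tuple[float, float] = (0.0, 40.0),
    cmap: str = "inferno",
    marker_size: float = 12.0,
):
    """Composite a pulse-amplitude heat map over a background frame.

    Loci are coloured by raw (pre-log) amplitude clipped to ``scale``
    (default 0-40 arbitrary units) on the given colour ramp, with an
    embedded legend. Raw amplitude is used for display; statistics run
    on log amplitude.
    """
    if len(amp_map) == 0:
        raise ValueError("cannot render a heat map from an empty amplitude map")
    lo, hi = scale
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(np.asarray(background), cmap="gray", interpolation="nearest")
    sc = ax.scatter(
        amp_map["center_col"],
        amp_map["center_row"],
        c=np.clip(amp_map["amplitude"], lo, hi),
        cmap=cmap,
        vmin=lo,
        vmax=hi,
        s=marker_size,
        marker="s",
        linewidths=0,
    )
    fig.colorbar(sc, ax=ax, label="pulse amplitude (arbitrary units)")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
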