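"""Per-vessel, per-force summaries: mean/max log amplitude and slope.

Ophthalmodynamometric force (ODF, Meditron units; 1 mu = 3.33 g) raises
the intraocular pressure as ``induced IOP = 0.89 x ODF + baseline IOP``
(mm Hg). Each vessel at each force level is reduced to its annulus-locus
mean and maximum log amplitude plus the amplitude slope: the unweighted
OLS slope of locus log amplitude against radial distance (log u/mm),
negative values indicating attenuation of the pulse wave along the
vessel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ODFRecord",
    "VesselObservation",
    "induced_iop",
    "summarize_vessel",
    "amplitude_slope",
    "summarize_map",
    "MIN_SLOPE_LOCI",
    "MIN_SLOPE_SPAN_MM",
]

IOP_PER_MU = 0.89  # mm Hg per Meditron unit
GRAMS_PER_MU = 3.33

#: Minimum loci, spanning at least this radial extent, for a slope fit.
MIN_SLOPE_LOCI = 5
MIN_SLOPE_SPAN_MM = 0.2


def induced_iop(odf: float, baseline: float) -> float:
    """IOP (mm Hg) induced by an ophthalmodynamometric force.

    ``induced IOP = 0.89 x ODF + baseline IOP``, with ODF in Meditron
    units and the baseline in mm Hg.
    """
    if odf < 0:
        raise ValueError("ophthalmodynamometric force cannot be negative")
    return IOP_PER_MU * odf + baseline


@dataclass(frozen=True)
class ODFRecord:
    """One force application: ODF level plus derived pressures."""

    odf: float
    baseline_iop: float
    induced_iop: float = field(init=False)
    grams_force: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "induced_iop", induced_iop(self.odf, self.baseline_iop))
        object.__setattr__(self, "grams_force", GRAMS_PER_MU * self.odf)


@dataclass
class VesselObservation:
    """Summary of one vessel at one force level."""

    eye_id: str
    participant_id: str
    vessel_id: int
    vessel_label: str
    hemifield: str
    group_id: str
    odf: float
    induced_iop: float
    mean_logamp: float
    max_logamp: float
    slope: float  # NaN when the design is degenerate
    slope_se: float
    n_loci: int


def amplitude_slope(
    amp_map: pd.DataFrame,
    vessel_id: int,
    min_loci: int = MIN_SLOPE_LOCI,
    min_span: float = MIN_SLOPE_SPAN_MM,
) -> tuple[float, float, float]:
    """OLS slope of log amplitude on radial distance for one vessel.

    Returns ``(slope, se, intercept)`` in log u/mm; all NaN when the
    vessel has fewer than ``min_loci`` annulus loci or they span less
    than ``min_span`` mm of radial distance (degenerate design).
    """
    sub = amp_map[amp_map["vessel_id"] == vessel_id]
    d = sub["d_mm"].to_numpy(float)
    y = sub["log_amplitude"].to_numpy(float)
    if d.size < min_loci or (d.max() - d.min() if d.size else 0.0) < min_span:
        return float("nan"), float("nan"), float("nan")
    n = d.size
    dbar, ybar = d.mean(), y.mean()
    sxx = float(((d - dbar) ** 2).sum())
    slope = float(((d - dbar) * (y - ybar)).sum()) / sxx
    intercept = ybar - slope * dbar
    resid = y - intercept - slope * d
    se = float(np.sqrt((resid @ resid) / max(n - 2, 1) / sxx))
    return slope, se, intercept


def summarize_vessel(
    amp_map: pd.DataFrame,
    vessel_id: int,
    odf_record: ODFRecord,
    eye_id: str = "",
    participant_id: str = "",
    group_id: str = "",
) -> VesselObservation | None:
    """Reduce one vessel's annulus loci at one ODF to an observation.

    Returns ``None`` (with a log entry) when the vessel has no retained
    loci at this force level.
    """
    sub = amp_map[amp_map["vessel_id"] == vessel_id]
    if len(sub) == 0:
        logger.info("vessel %s has no retained loci at ODF %s; skipped",
                    vessel_id, odf_record.odf)
        return None
    logamp = sub["log_amplitude"].to_numpy(float)
    slope, se, _ = amplitude_slope(amp_map, vessel_id)
    label = sub["vessel_label"].mode().iat[0]
    hemi = sub["hemifield"].mode().iat[0] if "hemifield" in sub else ""
    return VesselObservation(
        eye_id=eye_id,
        participant_id=participant_id,
        vessel_id=int(vessel_id),
        vessel_label=str(label),
        hemifield=str(hemi),
        group_id=group_id,
        odf=odf_record.odf,
        induced_iop=odf_record.induced_iop,
        mean_logamp=float(logamp.mean()),
        max_logamp=float(logamp.max()),
        slope=slope,
        slope_se=se,
        n_loci=int(len(sub)),
    )


def summarize_map(
    amp_map: pd.DataFrame,
    odf_record: ODFRecord,
    eye_id: str = "",
    participant_id: str = "",
    group_id: str = "",
    group_by_hemifield: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Observations for every vessel present in an annulus-filtered map.

    ``group_by_hemifield`` optionally maps hemifield -> group_id for eyes
    whose superior and inferior hemivessels belong to different study
    groups (hemiretinal occlusion).
    """
    rows = []
    for vid in sorted(amp_map["vessel_id"].unique()):
        obs = summarize_vessel(
            amp_map, vid, odf_record,
            eye_id=eye_id, participant_id=participant_id, group_id=group_id,
        )
        if obs is None:
            continue
        if group_by_hemifield:
            obs.group_id = group_by_hemifield.get(obs.hemifield, obs.group_id)
        rows.append(vars(obs))
    return pd.DataFrame(rows)
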