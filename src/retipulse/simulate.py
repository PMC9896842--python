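"""Synthetic pulsatile fundus video with known ground truth.

The generator emulates the statistical structure the analysis assumes:
vessels radiating from the optic disc, cardiac-locked periodic darkening
of the green channel on vessel pixels (two harmonics), a slow global
intensity drift, first-order autoregressive pixel noise, and a pulse
amplitude whose logarithm varies linearly with radial distance from the
disc centre. Six study-group presets encode cohort-level venous and
arterial mean log amplitudes and attenuation slopes (with between-eye
dispersions) for: normal eyes (N1_N1), unaffected fellow eyes of CRVO
and HVO patients (N1_CRVO, N1_HVO), unaffected and affected hemivessels
of hemiretinal-vein-occlusion eyes (N2_HVO, HVO_HVO), and eyes with
central retinal vein occlusion (CRVO_CRVO).

Pulsation is rendered as an intensity *decrease* (more haemoglobin
absorbs more green light); the analysis is polarity-free because
amplitude is defined peak-to-trough.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from skimage.draw import disk

from .harmonic import LABEL_FRACTION, _block_stats
from .io import (
    LABELS,
    CardiacTiming,
    SegmentationMap,
    VideoSequence,
    write_segmentation,
    write_stack,
    write_timing,
)
from .mapping import ANNULUS_INNER_MM, ANNULUS_OUTER_MM, DiscGeometry, to_polar
from .summary import ODFRecord

__all__ = [
    "GroupPreset",
    "PRESETS",
    "GROUP_COVARIATES",
    "SimulationConfig",
    "GroundTruth",
    "SyntheticEye",
    "make_vessel_tree",
    "amplitude_field",
    "render_frames",
    "generate_cohort",
    "sample_observation_table",
    "write_cohort",
]

GROUP_IDS = ("N1_N1", "N1_CRVO", "N1_HVO", "N2_HVO", "HVO_HVO", "CRVO_CRVO")

#: Intensity baselines by label (arbitrary units on a 16-bit scale).
BASE_LEVELS = {
    "background": 120.0,
    "artery": 95.0,
    "vein": 80.0,
    "other_vessel": 100.0,
    "disc": 170.0,
    "cup": 190.0,
}


@dataclass(frozen=True)
class GroupPreset:
    """Cohort-level truth for one study group.

    Mean log amplitudes and slopes are the group centres; the ``*_sd``
    fields are between-eye dispersions. ``harmonic2_fraction`` is the
    share of periodic energy in the second cardiac harmonic;
    ``ar_coefficient`` and ``noise_sd`` parameterise the AR(1) pixel
    noise (marginal SD, intensity units); ``drift_magnitude`` bounds the
    slow non-periodic drift (intensity units).
    """

    group_id: str
    venous_mean_logamp: float
    venous_slope: float
    arterial_mean_logamp: float
    arterial_slope: float
    between_eye_sd: float
    arterial_between_eye_sd: float = 0.4
    venous_slope_sd: float = 0.6
    arterial_slope_sd: float = 0.55
    harmonic2_fraction: float = 0.2
    ar_coefficient: float = 0.4
    noise_sd: float = 2.0
    drift_magnitude: float = 3.0

    def __post_init__(self) -> None:
        if not -1.0 < self.ar_coefficient < 1.0:
            raise ValueError("AR coefficient must lie in (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise SD cannot be negative")
        if not 0.0 <= self.harmonic2_fraction <= 1.0:
            raise ValueError("second-harmonic fraction must lie in [0, 1]")

    def mean_logamp(self, vessel_label: str) -> float:
        return self.venous_mean_logamp if vessel_label == "vein" else self.arterial_mean_logamp

    def slope(self, vessel_label: str) -> float:
        return self.venous_slope if vessel_label == "vein" else self.arterial_slope


#: Study-group centres: cohort mean log amplitudes (log u) and amplitude
#: slopes (log u/mm) with between-eye SDs, venous and arterial.
PRESETS: dict[str, GroupPreset] = {
    p.group_id: p
    for p in [
        GroupPreset("N1_N1", 2.08, -0.80, 1.56, -0.44, 0.48, 0.39, 1.03, 0.54),
        GroupPreset("N1_CRVO", 1.76, -0.54, 1.23, -0.30, 0.34, 0.30, 0.76, 0.55),
        GroupPreset("N1_HVO", 1.33, -0.63, 1.09, -0.35, 0.37, 0.37, 0.55, 0.55),
        GroupPreset("N2_HVO", 1.30, -0.005, 1.23, -0.10, 0.59, 0.51, 0.64, 0.55),
        GroupPreset("HVO_HVO", 1.23, 0.000, 1.15, -0.05, 0.46, 0.49, 0.51, 0.55),
        GroupPreset("CRVO_CRVO", 0.99, 0.35, 0.91, 0.26, 0.45, 0.44, 0.60, 0.70),
    ]
}

#: Per-group covariate distributions: age (years, Gaussian), POAG prevalence.
GROUP_COVARIATES = {
    "N1_N1": {"age_mean": 59.52, "age_sd": 19.4, "poag_prev": 0.0},
    "N1_CRVO": {"age_mean": 57.25, "age_sd": 16.8, "poag_prev": 1.0},
    "N1_HVO": {"age_mean": 73.20, "age_sd": 5.9, "poag_prev": 1.0},
    "N2_HVO": {"age_mean": 74.38, "age_sd": 5.9, "poag_prev": 0.875},
    "HVO_HVO": {"age_mean": 74.38, "age_sd": 5.9, "poag_prev": 0.875},
    "CRVO_CRVO": {"age_mean": 70.24, "age_sd": 13.5, "poag_prev": 0.381},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry and acquisition parameters of a synthetic recording."""

    frame_rate: float = 25.0
    cardiac_period: float = 1.0
    n_cycles: int = 3
    image_size: int = 384
    microns_per_pixel: float = 6.0
    disc_center: tuple[float, float] | None = None
    disc_radius_mm: float = 0.75
    n_vessels_per_type: int = 2
    vessel_width_px: int = 7
    odf_levels: tuple[float, ...] = (0.0, 20.0, 40.0)
    baseline_iop: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("need at least one cardiac cycle")
        if self.frame_rate * self.cardiac_period < 8:
            raise ValueError(
                "fewer than 8 samples per cycle cannot resolve two harmonics"
            )
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")

    @property
    def center(self) -> tuple[float, float]:
        if self.disc_center is not None:
            return self.disc_center
        return (self.image_size / 2.0, self.image_size / 2.0)

    @property
    def geometry(self) -> DiscGeometry:
        return DiscGeometry(self.center, self.microns_per_pixel)

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate * self.cardiac_period * self.n_cycles))


@dataclass
class GroundTruth:
    """True amplitude field plus per-vessel summaries and waveform parameters."""

    amplitude: np.ndarray  # (H, W), intensity units; 0 off-vessel
    vessel_truth: pd.DataFrame  # vessel_id, label, hemifield, true mean/max/slope
    scope_params: dict  # (label, hemifield-scope) -> {intercept, slope, mean}
    harmonic2_fraction: float
    ar_coefficient: float
    noise_sd: float
    drift_magnitude: float

    def log_amplitude_at(self, mask: np.ndarray) -> np.ndarray:
        return np.log(self.amplitude[mask])


# ---------------------------------------------------------------------------
# vessel tree


def _hemifield_angles(rng, n_vessels: int, superior: bool):
    """Well-separated vessel angles (degrees) within one hemifield."""
    lo, hi = (25.0, 155.0) if superior else (-155.0, -25.0)
    width = (hi - lo) / n_vessels
    centers = lo + width * (np.arange(n_vessels) + 0.5)
    jitter = rng.uniform(-0.25, 0.25, size=n_vessels) * width
    return centers + jitter


def make_vessel_tree(config: SimulationConfig, seed: int) -> SegmentationMap:
    """Draw a labelled image: disc, cup and vessels radiating past 1 mm.

    Each hemifield (superior/inferior) receives at least one artery and
    one vein, drawn as gently wiggling radial paths of constant width
    from the cup margin out beyond the 1 mm annulus. Vessel labels
    overwrite disc/cup labels where vessels cross the disc surface.

    Raises ``ValueError`` when the frame cannot contain the 1 mm annulus
    at the configured scale.
    """
    if config.n_vessels_per_type < 2:
        raise ValueError("need at least one vessel per type per hemifield")
    s = config.image_size
    mpp = config.microns_per_pixel
    cr, cc = config.center
    outer_px = ANNULUS_OUTER_MM * 1000.0 / mpp
    reach_px = outer_px * 1.1 + config.vessel_width_px
    edge = min(cr, cc, s - 1 - cr, s - 1 - cc)
    if edge < reach_px:
        raise ValueError(
            f"vessels cannot reach 1 mm: frame allows {edge * mpp / 1000.0:.3f} mm "
            f"from the disc centre, {reach_px * mpp / 1000.0:.3f} mm needed"
        )

    rng = np.random.default_rng(seed)
    labels = np.zeros((s, s), dtype=np.uint8)
    vessel_ids = np.zeros((s, s), dtype=np.int32)

    # disc and cup
    disc_px = config.disc_radius_mm * 1000.0 / mpp
    rr, cc_idx = disk((cr, cc), disc_px, shape=(s, s))
    labels[rr, cc_idx] = LABELS["disc"]
    rr, cc_idx = disk((cr, cc), 0.3 * disc_px, shape=(s, s))
    labels[rr, cc_idx] = LABELS["cup"]

    r0 = max(0.3 * disc_px * 0.9, 2.0)  # vessels emerge at the cup margin
    r1 = reach_px
    half_w = config.vessel_width_px / 2.0

    n_per_hemi = config.n_vessels_per_type  # arteries + veins per hemifield
    meta = []
    vid = 0
    for superior in (True, False):
        angles = _hemifield_angles(rng, n_per_hemi, superior)
        types = ["artery", "vein"] * (n_per_hemi // 2 + 1)
        types = types[:n_per_hemi]
        order = rng.permutation(n_per_hemi)
        for slot, k in enumerate(order):
            vtype = types[k]
            theta = math.radians(angles[slot])
            u = np.array([-math.sin(theta), math.cos(theta)])  # (row, col), up = -row
            perp = np.array([-u[1], u[0]])
            wig_amp = rng.uniform(1.0, 3.0)
            wig_len = rng.uniform(80.0, 140.0)
            wig_phase = rng.uniform(0.0, 2.0 * math.pi)
            vid += 1
            for r in np.arange(r0, r1, 0.5):
                off = wig_amp * math.sin(2.0 * math.pi * (r - r0) / wig_len + wig_phase)
                pos = np.array([cr, cc]) + r * u + off * perp
                prr, pcc = disk((pos[0], pos[1]), half_w, shape=(s, s))
                labels[prr, pcc] = LABELS[vtype]
                vessel_ids[prr, pcc] = vid
            meta.append(
                {
                    "vessel_id": vid,
                    "vessel_label": vtype,
                    "hemifield": "superior" if superior else "inferior",
                    "angle_deg": angles[slot],
                }
            )

    return SegmentationMap(
        labels=labels,
        disc_center=(cr, cc),
        vessel_ids=vessel_ids,
        vessel_meta=pd.DataFrame(meta),
        microns_per_pixel=mpp,
    )


# ---------------------------------------------------------------------------
# truth amplitude field


def _distance_map(shape, geometry: DiscGeometry) -> np.ndarray:
    rows, cols = np.indices(shape)
    d_px = np.hypot(rows - geometry.disc_center[0], cols - geometry.disc_center[1])
    return d_px * geometry.microns_per_pixel / 1000.0


def _locus_truth(
    amplitude: np.ndarray,
    tree: SegmentationMap,
    geometry: DiscGeometry,
    cluster: int = 5,
) -> pd.DataFrame:
    """Per-vessel truth summaries over the same loci the pipeline uses."""
    records = []
    for _, v in tree.vessel_meta.iterrows():
        vid = int(v["vessel_id"])
        label_code = LABELS[v["vessel_label"]]
        mask = (tree.vessel_ids == vid) & (tree.labels == label_code)
        sums, counts = _block_stats(amplitude, mask, cluster)
        min_count = LABEL_FRACTION * cluster * cluster
        valid = counts >= min_count
        d_list, logamp = [], []
        for bi, bj in zip(*np.nonzero(valid)):
            center = (bi * cluster + cluster // 2, bj * cluster + cluster // 2)
            d_mm, _ = to_polar(center, geometry)
            if ANNULUS_INNER_MM <= d_mm <= ANNULUS_OUTER_MM:
                d_list.append(d_mm)
                logamp.append(math.log(sums[bi, bj] / counts[bi, bj]))
        d_arr = np.array(d_list)
        y = np.array(logamp)
        if y.size >= 5 and np.ptp(d_arr) >= 0.2:
            slope = float(np.polyfit(d_arr, y, 1)[0])
        else:
            slope = float("nan")
        records.append(
            {
                "vessel_id": vid,
                "vessel_label": v["vessel_label"],
                "hemifield": v["hemifield"],
                "true_mean_logamp": float(y.mean()) if y.size else float("nan"),
                "true_max_logamp": float(y.max()) if y.size else float("nan"),
                "true_slope": slope,
                "n_loci": int(y.size),
            }
        )
    return pd.DataFrame(records)


def amplitude_field(
    preset: GroupPreset,
    tree: SegmentationMap,
    geometry: DiscGeometry,
    preset_inferior: GroupPreset | None = None,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Lay a log-linear amplitude field over the vessel pixels.

    For each vessel pixel at radial distance ``d`` (mm), the true log
    amplitude is ``intercept + slope * d``, with the intercept calibrated
    so the mean over that vessel class's 0.25-1 mm annulus pixels equals
    the preset mean (plus a per-eye offset drawn from the between-eye SD
    when ``rng`` is given; with no ``rng`` all dispersions are zero).
    ``preset_inferior`` assigns a different preset to the inferior
    hemifield (hemiretinal occlusion: one eye, two hemifield presets;
    ``preset`` then governs the superior hemifield).
    """
    d_map = _distance_map(tree.labels.shape, geometry)
    annulus = (d_map >= ANNULUS_INNER_MM) & (d_map <= ANNULUS_OUTER_MM)
    rows = np.indices(tree.labels.shape)[0]
    superior_px = rows < geometry.disc_center[0]

    amplitude = np.zeros_like(d_map)
    scope_params: dict = {}
    scopes = (
        [("superior", preset), ("inferior", preset_inferior)]
        if preset_inferior is not None
        else [("both", preset)]
    )
    for hemi, pre in scopes:
        if hemi == "both":
            hemi_mask = np.ones_like(superior_px)
        elif hemi == "superior":
            hemi_mask = superior_px
        else:
            hemi_mask = ~superior_px
        for label, mean_sd, slope_sd in [
            ("vein", pre.between_eye_sd, pre.venous_slope_sd),
            ("artery", pre.arterial_between_eye_sd, pre.arterial_slope_sd),
        ]:
            mask = (tree.labels == LABELS[label]) & hemi_mask
            if not mask.any():
                continue
            mean_off = float(rng.normal(0.0, mean_sd)) if rng is not None else 0.0
            slope_off = float(rng.normal(0.0, slope_sd)) if rng is not None else 0.0
            slope = pre.slope(label) + slope_off
            target = pre.mean_logamp(label) + mean_off
            cal = mask & annulus
            d_bar = float(d_map[cal].mean()) if cal.any() else float(d_map[mask].mean())
            intercept = target - slope * d_bar
            amplitude[mask] = np.exp(intercept + slope * d_map[mask])
            scope_params[(label, hemi)] = {
                "intercept": intercept,
                "slope": slope,
                "annulus_mean": target,
                "group_id": pre.group_id,
            }

    vessel_truth = _locus_truth(amplitude, tree, geometry)
    return GroundTruth(
        amplitude=amplitude,
        vessel_truth=vessel_truth,
        scope_params=scope_params,
        harmonic2_fraction=preset.harmonic2_fraction,
        ar_coefficient=preset.ar_coefficient,
        noise_sd=preset.noise_sd,
        drift_magnitude=preset.drift_magnitude,
    )


# ---------------------------------------------------------------------------
# rendering


def _unit_waveform(t: np.ndarray, period: float, h2_fraction: float) -> np.ndarray:
    """Two-harmonic waveform normalised to range [0, 1] (unit peak-to-trough)."""
    omega = 2.0 * math.pi / period
    a1 = math.sqrt(max(1.0 - h2_fraction, 0.0))
    a2 = math.sqrt(h2_fraction)
    dense = np.linspace(0.0, period, 8192, endpoint=False)
    u_dense = a1 * np.cos(omega * dense) + a2 * np.cos(2 * omega * dense)
    lo, hi = float(u_dense.min()), float(u_dense.max())
    u = a1 * np.cos(omega * t) + a2 * np.cos(2 * omega * t)
    return (u - lo) / (hi - lo)


def render_frames(
    truth: GroundTruth,
    tree: SegmentationMap,
    config: SimulationConfig,
    seed: int,
) -> tuple[VideoSequence, CardiacTiming]:
    """Render the frame stack plus pulse-oximeter beep timestamps.

    Per-pixel intensity: a label-dependent baseline, plus a slow global
    sinusoidal drift (one cycle over the record, bounded by the drift
    magnitude), minus the cardiac waveform scaled to the pixel's true
    peak-to-trough amplitude, plus stationary AR(1) noise. Non-vessel
    pixels carry baseline, drift and noise only. Beeps mark every cycle
    boundary, including the start and end of the record.
    """
    rng = np.random.default_rng(seed)
    n = config.n_frames
    t = np.arange(n) / config.frame_rate
    duration = n / config.frame_rate

    base = np.zeros_like(truth.amplitude)
    for name, level in BASE_LEVELS.items():
        base[tree.labels == LABELS[name]] = level

    w = _unit_waveform(t, config.cardiac_period, truth.harmonic2_fraction)
    frames = base[None, :, :] - truth.amplitude[None, :, :] * w[:, None, None]

    if truth.drift_magnitude > 0:
        phase = rng.uniform(0.0, 2.0 * math.pi)
        drift = truth.drift_magnitude * np.sin(2.0 * math.pi * t / duration + phase)
        frames = frames + drift[:, None, None]

    if truth.noise_sd > 0:
        phi = truth.ar_coefficient
        sd_inn = truth.noise_sd * math.sqrt(1.0 - phi * phi)
        shape = truth.amplitude.shape
        eps = rng.normal(0.0, truth.noise_sd, size=shape)  # stationary start
        noise = np.empty((n, *shape))
        noise[0] = eps
        innov = rng.normal(0.0, sd_inn, size=(n - 1, *shape))
        for k in range(1, n):
            eps = phi * eps + innov[k - 1]
            noise[k] = eps
        frames = frames + noise

    beeps = np.arange(config.n_cycles + 1) * config.cardiac_period
    seq = VideoSequence(frames=frames, timestamps=t, channel="green")
    timing = CardiacTiming(beep_times=beeps, period_estimate=config.cardiac_period)
    return seq, timing


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class SyntheticEye:
    """One synthetic eye: geometry, truth, covariates and lazy renders."""

    eye_id: str
    participant_id: str
    laterality: str
    group_id: str
    group_by_hemifield: dict[str, str]
    age: float
    sex: str
    poag: bool
    tree: SegmentationMap
    truth: GroundTruth
    odf_records: list[ODFRecord]
    config: SimulationConfig
    render_seeds: dict[float, int] = field(default_factory=dict)

    @property
    def geometry(self) -> DiscGeometry:
        return DiscGeometry(self.tree.disc_center, self.tree.microns_per_pixel)

    def render(self, odf: float) -> tuple[VideoSequence, CardiacTiming]:
        """Render the recording at one force level (fresh noise per level)."""
        return render_frames(self.truth, self.tree, self.config, self.render_seeds[odf])


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def generate_cohort(
    presets: dict[str, GroupPreset],
    n_eyes_per_group: int,
    config: SimulationConfig,
    seed: int,
    groups: tuple[str, ...] | None = None,
):
    """Yield synthetic eyes for the requested study groups.

    ``HVO_HVO`` and ``N2_HVO`` describe the two hemifields of the same
    physical eye: when both groups are requested, each draw yields one
    eye carrying the affected (``HVO_HVO``) preset on the superior
    hemifield and the unaffected (``N2_HVO``) preset on the inferior.
    Fellow-eye groups (``N1_CRVO`` with ``CRVO_CRVO``, ``N1_HVO`` with
    the HVO eye) share a participant and age where counts allow.
    Fully reproducible from ``seed``.
    """
    if n_eyes_per_group < 1:
        raise ValueError("need at least one eye per group")
    groups = tuple(groups) if groups is not None else GROUP_IDS
    unknown = set(groups) - set(GROUP_IDS)
    if unknown:
        raise KeyError(f"unknown group_id(s): {sorted(unknown)}")
    for g in groups:
        if g not in presets:
            raise KeyError(f"no preset supplied for group {g!r}")

    hvo_merged = "HVO_HVO" in groups and "N2_HVO" in groups
    emit: list[tuple[str, GroupPreset, GroupPreset | None]] = []
    for g in groups:
        if hvo_merged and g == "N2_HVO":
            continue  # folded into the HVO_HVO eye
        inferior = presets["N2_HVO"] if (hvo_merged and g == "HVO_HVO") else None
        emit.append((g, presets[g], inferior))

    participants: dict[tuple[str, int], tuple[str, float]] = {}

    for g, preset, preset_inferior in emit:
        gidx = GROUP_IDS.index(g)
        for i in range(n_eyes_per_group):
            eye_rng = np.random.default_rng(np.random.SeedSequence([seed, gidx, i]))
            tree = make_vessel_tree(config, _derived_seed(seed, gidx, i, 1))
            truth = amplitude_field(
                preset, tree, config.geometry,
                preset_inferior=preset_inferior, rng=eye_rng,
            )
            cov = GROUP_COVARIATES[g]
            age = float(eye_rng.normal(cov["age_mean"], cov["age_sd"]))
            sex = "male" if eye_rng.random() < 0.5 else "female"
            poag = bool(eye_rng.random() < cov["poag_prev"])
            laterality = "right" if eye_rng.random() < 0.5 else "left"

            # fellow-eye pairing: unaffected contralateral eyes share the
            # participant (and age) of their diseased counterpart
            pair_key = None
            if g in ("N1_CRVO", "CRVO_CRVO"):
                pair_key = ("crvo", i)
            elif g in ("N1_HVO", "HVO_HVO", "N2_HVO"):
                pair_key = ("hvo", i)
            participant_id = f"P_{g}_{i:03d}"
            if pair_key is not None:
                if pair_key in participants:
                    participant_id, age = participants[pair_key]
                    laterality = "left" if laterality == "right" else laterality
                else:
                    participant_id = f"P_{pair_key[0]}_{i:03d}"
                    participants[pair_key] = (participant_id, age)

            odf_records = [ODFRecord(o, config.baseline_iop) for o in config.odf_levels]
            render_seeds = {
                o: _derived_seed(seed, gidx, i, 2, k)
                for k, o in enumerate(config.odf_levels)
            }
            group_by_hemifield = (
                {"superior": "HVO_HVO", "inferior": "N2_HVO"}
                if preset_inferior is not None
                else {"superior": g, "inferior": g}
            )
            yield SyntheticEye(
                eye_id=f"E_{g}_{i:03d}",
                participant_id=participant_id,
                laterality=laterality,
                group_id=g,
                group_by_hemifield=group_by_hemifield,
                age=age,
                sex=sex,
                poag=poag,
                tree=tree,
                truth=truth,
                odf_records=odf_records,
                config=config,
                render_seeds=render_seeds,
            )


# ---------------------------------------------------------------------------
# summary-level generator (statistical calibration)


def sample_observation_table(
    presets: dict[str, GroupPreset],
    n_eyes_per_group: int,
    seed: int,
    odf_levels: tuple[float, ...] = (0.0, 20.0, 40.0),
    n_vessels_per_type: int = 2,
    obs_sd: float = 0.15,
    max_gap: float = 0.6,
    baseline_iop: float = 15.0,
    groups: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Draw a vessel-observation table directly from the group presets.

    This bypasses video rendering: per-eye effects come from the preset
    between-eye SDs and each vessel x ODF observation adds independent
    measurement noise (``obs_sd``, log u). It exists for statistical
    calibration of the mixed-model layer (null-calibration and recovery
    checks over many replicates), where rendering thousands of videos
    would add nothing but runtime.
    """
    rng = np.random.default_rng(seed)
    groups = tuple(groups) if groups is not None else tuple(presets)
    rows = []
    for g in groups:
        preset = presets[g]
        cov = GROUP_COVARIATES.get(g, {"age_mean": 65.0, "age_sd": 12.0, "poag_prev": 0.2})
        for i in range(n_eyes_per_group):
            age = float(rng.normal(cov["age_mean"], cov["age_sd"]))
            sex = "male" if rng.random() < 0.5 else "female"
            poag = bool(rng.random() < cov["poag_prev"])
            laterality = "right" if rng.random() < 0.5 else "left"
            eye_off = {
                "vein": rng.normal(0.0, preset.between_eye_sd),
                "artery": rng.normal(0.0, preset.arterial_between_eye_sd),
            }
            slope_off = {
                "vein": rng.normal(0.0, preset.venous_slope_sd),
                "artery": rng.normal(0.0, preset.arterial_slope_sd),
            }
            for label in ("vein", "artery"):
                for v in range(n_vessels_per_type):
                    for odf in odf_levels:
                        mean = preset.mean_logamp(label) + eye_off[label] + rng.normal(0, obs_sd)
                        rows.append(
                            {
                                "eye_id": f"E_{g}_{i:03d}",
                                "participant_id": f"P_{g}_{i:03d}",
                                "vessel_id": v + 1,
                                "vessel_label": label,
                                "hemifield": "superior" if v % 2 == 0 else "inferior",
                                "group_id": g,
                                "odf": odf,
                                "induced_iop": 0.89 * odf + baseline_iop,
                                "mean_logamp": mean,
                                "max_logamp": mean + abs(max_gap + rng.normal(0, obs_sd)),
                                "slope": preset.slope(label) + slope_off[label]
                                + rng.normal(0, obs_sd),
                                "slope_se": obs_sd,
                                "n_loci": 25,
                                "age": age,
                                "sex": sex,
                                "poag": poag,
                                "laterality": laterality,
                            }
                        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk cohort


def write_cohort(eyes, outdir, fmt: str = "png") -> None:
    """Write a cohort directory: per-eye stacks, segmentation, timing,
    ODF records, truth tables and a YAML manifest."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"eyes": []}
    for eye in eyes:
        eyedir = outdir / eye.eye_id
        eyedir.mkdir(parents=True, exist_ok=True)
        write_segmentation(eye.tree, eyedir / "segmentation.png")
        truth_df = eye.truth.vessel_truth
        truth_df.to_csv(eyedir / "vessel_truth.csv", index=False)
        pd.DataFrame(
            {
                "odf": [r.odf for r in eye.odf_records],
                "baseline_iop": [r.baseline_iop for r in eye.odf_records],
                "induced_iop": [r.induced_iop for r in eye.odf_records],
                "grams_force": [r.grams_force for r in eye.odf_records],
            }
        ).to_csv(eyedir / "odf.csv", index=False)
        for rec in eye.odf_records:
            seq, timing = eye.render(rec.odf)
            tag = f"odf_{rec.odf:g}"
            if fmt == "tiff":
                write_stack(seq, eyedir / f"{tag}.tiff", fmt="tiff")
            else:
                write_stack(seq, eyedir / tag, fmt="png")
            write_timing(timing, eyedir / f"{tag}_beeps.csv")
        manifest["eyes"].append(
            {
                "eye_id": eye.eye_id,
                "participant_id": eye.participant_id,
                "group_id": eye.group_id,
                "group_by_hemifield": eye.group_by_hemifield,
                "laterality": eye.laterality,
                "age": round(eye.age, 2),
                "sex": eye.sex,
                "poag": eye.poag,
                "odf_levels": [r.odf for r in eye.odf_records],
            }
        )
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
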