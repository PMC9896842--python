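"""Reading, writing and preparing fundus video for densitometry.

Conventions used throughout the package:

* frames are ``(T, H, W)`` arrays, 0-indexed in time;
* pixel coordinates are ``(row, col)``, 0-based, origin at the image
  top-left;
* timestamps are seconds from the start of the recording.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "LABELS",
    "LABEL_NAMES",
    "VideoSequence",
    "CardiacTiming",
    "SegmentationMap",
    "read_stack",
    "write_stack",
    "read_segmentation",
    "write_segmentation",
    "read_timing",
    "write_timing",
    "extract_green",
    "align_frames",
    "estimate_period",
    "trim_cycles",
]

#: Integer codes of the segmentation classes.
LABELS = {
    "background": 0,
    "artery": 1,
    "vein": 2,
    "other_vessel": 3,
    "disc": 4,
    "cup": 5,
}
LABEL_NAMES = {v: k for k, v in LABELS.items()}


@dataclass
class VideoSequence:
    """A timestamped single-channel frame stack.

    Attributes
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity values in acquisition order (float or integer).
    timestamps : ndarray, shape (T,)
        Seconds per frame, strictly increasing.
    channel : str
        Channel label; ``"green"`` after extraction.
    valid_mask : ndarray of bool, shape (H, W), optional
        Pixels valid in every frame (False where alignment shifted in
        border values).
    """

    frames: np.ndarray
    timestamps: np.ndarray
    channel: str = "green"
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.shape[0] != self.timestamps.shape[0]:
            raise ValueError("one timestamp per frame required")
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class CardiacTiming:
    """Cardiac-cycle timing derived from pulse-oximeter beeps."""

    beep_times: np.ndarray
    period_estimate: float | None = None
    cycle_bounds: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beep_times = np.asarray(self.beep_times, dtype=float)
        if self.beep_times.size > 1 and not np.all(np.diff(self.beep_times) > 0):
            raise ValueError("beep times must be strictly increasing")


@dataclass
class SegmentationMap:
    """Pixel labels with the optic-disc centre.

    ``labels`` holds the integer codes of :data:`LABELS`; ``vessel_ids``
    (optional) gives a positive id per segmented vessel, 0 elsewhere.
    """

    labels: np.ndarray
    disc_center: tuple[float, float]
    vessel_ids: np.ndarray | None = None
    vessel_meta: pd.DataFrame | None = None
    microns_per_pixel: float = 6.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        r, c = self.disc_center
        h, w = self.labels.shape
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError("disc centre must lie within the label image")
        unknown = set(np.unique(self.labels)) - set(LABEL_NAMES)
        if unknown:
            raise ValueError(f"unknown label codes present: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# stack I/O


def write_stack(seq: VideoSequence, path: str | Path, fmt: str = "png") -> Path:
    """Write a frame stack as numbered 16-bit PNGs or a multi-page TIFF.

    Float frames are rounded and clipped into the uint16 range. A
    ``timestamps.csv`` sidecar records the frame times.
    """
    path = Path(path)
    frames = np.clip(np.rint(seq.frames), 0, 65535).astype(np.uint16)
    if fmt == "tiff":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, frames, photometric="minisblack")
        sidecar = path.with_suffix(".timestamps.csv")
    elif fmt == "png":
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(frames):
            iio.imwrite(path / f"frame_{i:05d}.png", frame)
        sidecar = path / "timestamps.csv"
    else:
        raise ValueError(f"unknown stack format: {fmt!r}")
    pd.DataFrame({"time_s": seq.timestamps}).to_csv(sidecar, index=False)
    return path


def read_stack(path: str | Path, fps: float | None = None) -> VideoSequence:
    """Read a numbered PNG sequence or multi-page TIFF as a video.

    Timestamps come from the ``timestamps.csv`` sidecar when present,
    otherwise from ``fps``. All frames must share dimensions.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in {".png", ".tif", ".tiff"}
            and re.search(r"\d+", p.stem)
        )
        if not files:
            raise FileNotFoundError(f"no numbered frames under {path}")
        frames = [np.asarray(iio.imread(p)) for p in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"frames have mixed dimensions: {sorted(shapes)}")
        stack = np.stack(frames)
        sidecar = path / "timestamps.csv"
    elif path.suffix.lower() in {".tif", ".tiff"}:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        sidecar = path.with_suffix(".timestamps.csv")
    else:
        raise ValueError(f"cannot read a frame stack from {path}")
    if sidecar.exists():
        timestamps = pd.read_csv(sidecar)["time_s"].to_numpy(float)
    elif fps is not None:
        timestamps = np.arange(stack.shape[0]) / float(fps)
    else:
        raise ValueError(
            "no timing sidecar found; pass fps= (CLI: --fps) to set frame times"
        )
    return VideoSequence(frames=stack, timestamps=timestamps, channel="unknown")


def write_segmentation(seg: SegmentationMap, path: str | Path) -> Path:
    """Write an indexed-label PNG plus a JSON sidecar (legend, disc centre, scale)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, seg.labels.astype(np.uint8))
    meta = {
        "legend": LABELS,
        "disc_center": [float(seg.disc_center[0]), float(seg.disc_center[1])],
        "microns_per_pixel": seg.microns_per_pixel,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    if seg.vessel_ids is not None:
        iio.imwrite(path.with_suffix(".vessel_ids.png"), seg.vessel_ids.astype(np.uint8))
    if seg.vessel_meta is not None:
        seg.vessel_meta.to_csv(path.with_suffix(".vessels.csv"), index=False)
    return path


def read_segmentation(path: str | Path) -> SegmentationMap:
    path = Path(path)
    labels = np.asarray(iio.imread(path))
    meta = json.loads(path.with_suffix(".json").read_text())
    vid_path = path.with_suffix(".vessel_ids.png")
    vessel_ids = np.asarray(iio.imread(vid_path)).astype(int) if vid_path.exists() else None
    meta_path = path.with_suffix(".vessels.csv")
    vessel_meta = pd.read_csv(meta_path) if meta_path.exists() else None
    return SegmentationMap(
        labels=labels.astype(np.uint8),
        disc_center=tuple(meta["disc_center"]),
        vessel_ids=vessel_ids,
        vessel_meta=vessel_meta,
        microns_per_pixel=float(meta["microns_per_pixel"]),
    )


def write_timing(timing: CardiacTiming, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"beep_time_s": timing.beep_times}).to_csv(path, index=False)
    return path


def read_timing(path: str | Path) -> CardiacTiming:
    beeps = pd.read_csv(path)["beep_time_s"].to_numpy(float)
    return CardiacTiming(beep_times=beeps)


# ---------------------------------------------------------------------------
# preparation


def extract_green(seq: VideoSequence) -> VideoSequence:
    """Project an RGB(A) stack onto its green plane.

    Green-channel densitometry tracks haemoglobin, which absorbs green
    light far more strongly than red or blue. Single-channel input passes
    through unchanged (the operation is idempotent).
    """
    frames = seq.frames
    if frames.ndim == 3:
        return replace(seq, channel="green")
    if frames.ndim == 4:
        n_chan = frames.shape[-1]
        if n_chan < 3:
            raise ValueError(f"cannot identify a green plane in {n_chan}-channel input")
        return replace(seq, frames=frames[..., 1], channel="green")
    raise ValueError("expected a (T, H, W) or (T, H, W, C) stack")


def align_frames(
    seq: VideoSequence,
    reference: int = 0,
    max_shift: int = 20,
) -> tuple[VideoSequence, pd.DataFrame]:
    """Rigidly align frames to a reference by integer-pixel translation.

    Each frame is shifted by the integer translation maximising its
    cross-correlation with the reference frame; raw intensity values are
    preserved (no interpolation). Border pixels rolled in by any shift
    are marked invalid in ``valid_mask``; frames requiring a shift larger
    than ``max_shift`` are flagged ``excluded`` and left untouched.

    Returns the aligned sequence and a per-frame report with columns
    ``frame, shift_row, shift_col, excluded``.
    """
    if seq.n_frames < 2:
        raise ValueError("alignment needs at least two frames")
    frames = np.asarray(seq.frames, dtype=float)
    ref = frames[reference]
    ref_f = np.fft.rfft2(ref - ref.mean())
    h, w = ref.shape

    aligned = frames.copy()
    valid = np.ones((h, w), dtype=bool)
    records = []
    for i, frame in enumerate(frames):
        if i == reference:
            records.append((i, 0, 0, False))
            continue
        xc = np.fft.irfft2(ref_f * np.conj(np.fft.rfft2(frame - frame.mean())), s=ref.shape)
        peak = np.unravel_index(np.argmax(xc), xc.shape)
        dr = int(peak[0]) if peak[0] <= h // 2 else int(peak[0]) - h
        dc = int(peak[1]) if peak[1] <= w // 2 else int(peak[1]) - w
        excluded = max(abs(dr), abs(dc)) > max_shift
        if not excluded and (dr or dc):
            aligned[i] = np.roll(frame, (dr, dc), axis=(0, 1))
            row_sl = slice(0, dr) if dr > 0 else slice(h + dr, h)
            col_sl = slice(0, dc) if dc > 0 else slice(w + dc, w)
            if dr:
                valid[row_sl, :] = False
            if dc:
                valid[:, col_sl] = False
        records.append((i, dr, dc, excluded))
    report = pd.DataFrame(records, columns=["frame", "shift_row", "shift_col", "excluded"])
    out = replace(seq, frames=aligned, valid_mask=valid)
    return out, report


def estimate_period(timing: CardiacTiming) -> float:
    """Mean inter-beep interval (s); also fills cycle bounds on the timing."""
    beeps = timing.beep_times
    if beeps.size < 2:
        raise ValueError("period estimation needs at least two beeps")
    period = float(np.mean(np.diff(beeps)))
    timing.period_estimate = period
    timing.cycle_bounds = [
        (float(beeps[i]), float(beeps[i + 1])) for i in range(beeps.size - 1)
    ]
    return period


def trim_cycles(seq: VideoSequence, timing: CardiacTiming, n: int = 3) -> VideoSequence:
    """Restrict the video to the first ``n`` complete cardiac cycles.

    Frames with ``first_beep <= t < first_beep + n * period`` are kept,
    so the output spans ``n`` cycles to within one frame interval.
    """
    beeps = timing.beep_times
    available = beeps.size - 1
    if available < n:
        raise ValueError(
            f"recording holds only {max(available, 0)} complete cycles; {n} requested"
        )
    period = timing.period_estimate or estimate_period(timing)
    t0 = beeps[0]
    keep = (seq.timestamps >= t0) & (seq.timestamps < t0 + n * period)
    return replace(seq, frames=seq.frames[keep], timestamps=seq.timestamps[keep])
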