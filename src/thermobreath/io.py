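"""Readers/writers and nostril-temperature extraction from frame + mask pairs.

A recording is a stack of thermal frames (small matrices of surface
temperature in degrees Celsius) with a binary nostril mask per frame.  The
mask may be produced at the RGB camera's resolution (e.g. 1080x1440) while
the thermal grid is much coarser (e.g. 120x160); :func:`downscale_mask`
bridges the two by nearest-neighbour block mapping.  Reducing each masked
frame with a pixel statistic yields the nostril temperature time series that
all downstream breathing analysis consumes.

All matrices are row-major with the origin at the top-left; timestamps are
seconds from the start of the recording.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FrameStack",
    "TemperatureSeries",
    "RegurgitationAnnotation",
    "STATISTICS",
    "extract_nostril_temperature",
    "downscale_mask",
    "series_from_frames",
    "read_series_csv",
    "write_series_csv",
    "read_annotation_csv",
    "write_annotation_csv",
    "read_frame_manifest",
    "write_frame_stack",
    "write_events_csv",
    "read_events_csv",
]

#: Supported per-frame pixel reductions.  ``p10`` is the 10th percentile,
#: offered because inspired-air cooling is strongest at the naris rim.
STATISTICS = ("mean", "median", "min", "p10")


class ValidationError(ValueError):
    """A structurally invalid input (shapes, ranges, ordering)."""


@dataclass
class FrameStack:
    """Per-frame thermal matrices plus binary nostril masks.

    Masks may have a different (finer) resolution than the thermal frames.
    """

    timestamps_s: np.ndarray
    thermal: list[np.ndarray]
    masks: list[np.ndarray]

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if not (len(self.timestamps_s) == len(self.thermal) == len(self.masks)):
            raise ValidationError("timestamps, thermal frames and masks must have equal length")
        if len(self.timestamps_s) >= 2 and not np.all(np.diff(self.timestamps_s) > 0):
            raise ValidationError("timestamps must be strictly increasing")
        for f in self.thermal:
            if not np.all(np.isfinite(f)):
                raise ValidationError("thermal frames must be finite")

    def __len__(self) -> int:
        return len(self.timestamps_s)


@dataclass
class TemperatureSeries:
    """Uniformly sampled nostril temperature with per-sample missing flags."""

    recording_id: str
    times_s: np.ndarray
    values_C: np.ndarray
    fs: float
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values_C = np.asarray(self.values_C, dtype=float)
        if self.missing is None:
            self.missing = ~np.isfinite(self.values_C)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not (len(self.times_s) == len(self.values_C) == len(self.missing)):
            raise ValidationError("times, values and missing flags must have equal length")
        if not self.fs > 0:
            raise ValidationError("fs must be positive")
        if np.any(~np.isfinite(self.values_C[~self.missing])):
            raise ValidationError("non-missing samples must be finite")

    def __len__(self) -> int:
        return len(self.values_C)

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0]) if len(self) else 0.0


@dataclass
class RegurgitationAnnotation:
    """Visually annotated regurgitation onsets for one recording."""

    recording_id: str
    regurg_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.regurg_times_s = np.asarray(self.regurg_times_s, dtype=float)
        if np.any(self.regurg_times_s < 0):
            raise ValidationError("regurgitation times must be non-negative")
        if len(self.regurg_times_s) >= 2 and not np.all(np.diff(self.regurg_times_s) > 0):
            raise ValidationError("regurgitation times must be strictly increasing")


def extract_nostril_temperature(
    thermal: np.ndarray, mask: np.ndarray, statistic: str = "mean"
) -> float:
    """Reduce the mask-selected thermal pixels of one frame to a single value.

    Returns ``nan`` (the missing sentinel) when the mask selects no pixel,
    e.g. when nostril segmentation failed for that frame.
    """
    if statistic not in STATISTICS:
        raise ValidationError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
    thermal = np.asarray(thermal, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if thermal.shape != mask.shape:
        raise ValidationError(
            f"thermal shape {thermal.shape} != mask shape {mask.shape}; "
            "downscale the mask to the thermal grid first"
        )
    vals = thermal[mask]
    if vals.size == 0:
        return float("nan")
    if statistic == "mean":
        return float(np.mean(vals))
    if statistic == "median":
        return float(np.median(vals))
    if statistic == "min":
        return float(np.min(vals))
    return float(np.percentile(vals, 10))


def downscale_mask(mask: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Downscale a binary mask by nearest-neighbour block mapping.

    A target pixel is true iff at least one source pixel whose centre maps
    into it is true.  Identity when the shapes already match; upscaling is
    not supported.
    """
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    h, w = target
    if h > H or w > W:
        raise ValidationError(f"cannot upscale mask from {(H, W)} to {(h, w)}")
    if (H, W) == (h, w):
        return mask.copy()
    # centre of source pixel r is r + 0.5; it lands in target row
    # floor((r + 0.5) * h / H)
    row_map = np.minimum(((np.arange(H) + 0.5) * h / H).astype(int), h - 1)
    col_map = np.minimum(((np.arange(W) + 0.5) * w / W).astype(int), w - 1)
    out = np.zeros((h, w), dtype=bool)
    rr, cc = np.nonzero(mask)
    out[row_map[rr], col_map[cc]] = True
    return out


def series_from_frames(
    stack: FrameStack, statistic: str = "mean", recording_id: str = "recording"
) -> TemperatureSeries:
    """Assemble the nostril temperature time series from a frame stack.

    One sample per frame; frames with an empty mask yield a missing sample.
    The sampling rate is estimated as ``(n - 1) / (t_last - t_first)``;
    if the timestamp jitter exceeds 1 % the median frame interval is used
    instead and a warning is emitted.
    """
    n = len(stack)
    if n < 2:
        raise ValidationError("need at least 2 frames to form a time series")
    tshape = stack.thermal[0].shape
    values = np.empty(n)
    for i in range(n):
        mask = stack.masks[i]
        if mask.shape != tshape:
            mask = downscale_mask(mask, tshape)
        values[i] = extract_nostril_temperature(stack.thermal[i], mask, statistic)
    dt = np.diff(stack.timestamps_s)
    fs = (n - 1) / (stack.timestamps_s[-1] - stack.timestamps_s[0])
    if np.max(np.abs(dt * fs - 1.0)) > 0.01:
        warnings.warn(
            "frame interval jitter exceeds 1%; using median frame interval",
            stacklevel=2,
        )
        fs = 1.0 / float(np.median(dt))
    return TemperatureSeries(
        recording_id=recording_id,
        times_s=stack.timestamps_s.copy(),
        values_C=values,
        fs=float(fs),
    )


# ---------------------------------------------------------------------------
# CSV I/O.  Dialect: comma-separated, '.' decimal, required header, UTF-8.
# Numeric columns are written with 6 decimals; a missing temperature sample
# is an empty cell.

def write_series_csv(series: TemperatureSeries, path: str | Path, header_comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(["time_s", "temp_C"])
        for t, v, m in zip(series.times_s, series.values_C, series.missing):
            writer.writerow([f"{t:.6f}", "" if m else f"{v:.6f}"])


def read_series_csv(path: str | Path, recording_id: str | None = None, fs: float | None = None) -> TemperatureSeries:
    path = Path(path)
    times, values = [], []
    with path.open("r", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    if not rows or rows[0][:2] != ["time_s", "temp_C"]:
        raise ValidationError(f"{path}: expected header 'time_s,temp_C'")
    for row in rows[1:]:
        times.append(float(row[0]))
        values.append(float(row[1]) if row[1] != "" else float("nan"))
    times_arr = np.asarray(times)
    if fs is None:
        if len(times_arr) < 2:
            raise ValidationError(f"{path}: need >= 2 samples to estimate fs")
        fs = (len(times_arr) - 1) / (times_arr[-1] - times_arr[0])
    return TemperatureSeries(
        recording_id=recording_id or path.stem,
        times_s=times_arr,
        values_C=np.asarray(values),
        fs=float(fs),
    )


def write_annotation_csv(annotations: Iterable[RegurgitationAnnotation], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["recording_id", "regurg_time_s"])
        for ann in annotations:
            for t in ann.regurg_times_s:
                writer.writerow([ann.recording_id, f"{t:.6f}"])


def read_annotation_csv(path: str | Path) -> list[RegurgitationAnnotation]:
    with Path(path).open("r", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    if not rows or rows[0][:2] != ["recording_id", "regurg_time_s"]:
        raise ValidationError(f"{path}: expected header 'recording_id,regurg_time_s'")
    by_id: dict[str, list[float]] = {}
    for rid, t in (r[:2] for r in rows[1:]):
        by_id.setdefault(rid, []).append(float(t))
    return [
        RegurgitationAnnotation(recording_id=rid, regurg_times_s=np.sort(ts))
        for rid, ts in by_id.items()
    ]


def write_events_csv(rows: Sequence[dict], path: str | Path, header_comment: str | None = None) -> None:
    """Write labeled breath events; columns fixed by the event contract."""
    cols = ["recording_id", "event_time_s", "depth_z", "label", "predicted"]
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(cols)
        for row in rows:
            writer.writerow(
                [
                    row["recording_id"],
                    f"{row['event_time_s']:.6f}",
                    f"{row['depth_z']:.6f}",
                    row["label"],
                    row.get("predicted") or "",
                ]
            )


def read_events_csv(path: str | Path) -> list[dict]:
    with Path(path).open("r", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    if not rows or rows[0][0] != "recording_id":
        raise ValidationError(f"{path}: expected events header")
    out = []
    for rid, t, d, label, predicted in (r[:5] for r in rows[1:]):
        out.append(
            {
                "recording_id": rid,
                "event_time_s": float(t),
                "depth_z": float(d),
                "label": label,
                "predicted": predicted or None,
            }
        )
    return out


# ---------------------------------------------------------------------------
# Frame-stack persistence: per-frame CSV matrices for thermal data, one
# single-channel 0/255 PNG per mask, and a manifest listing paths and
# timestamps.

def write_frame_stack(stack: FrameStack, out_dir: str | Path) -> Path:
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    (out_dir / "thermal").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with manifest.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "time_s", "thermal_path", "mask_path"])
        for i in range(len(stack)):
            tpath = Path("thermal") / f"frame_{i:05d}.csv"
            mpath = Path("masks") / f"frame_{i:05d}.png"
            np.savetxt(out_dir / tpath, stack.thermal[i], fmt="%.6f", delimiter=",")
            iio.imwrite(out_dir / mpath, (stack.masks[i].astype(np.uint8) * 255))
            writer.writerow([i, f"{stack.timestamps_s[i]:.6f}", tpath.as_posix(), mpath.as_posix()])
    return manifest


def read_frame_manifest(manifest_path: str | Path) -> FrameStack:
    import imageio.v3 as iio

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    with manifest_path.open("r", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0][0] != "frame":
        raise ValidationError(f"{manifest_path}: expected manifest header")
    times, thermal, masks = [], [], []
    for _, t, tpath, mpath in (r[:4] for r in rows[1:]):
        times.append(float(t))
        thermal.append(np.loadtxt(base / tpath, delimiter=",", ndmin=2))
        masks.append(np.asarray(iio.imread(base / mpath)) > 127)
    return FrameStack(timestamps_s=np.asarray(times), thermal=thermal, masks=masks)
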