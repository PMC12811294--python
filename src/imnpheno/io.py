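"""Calibrated image and table I/O, run configuration, and stage running.

Images travel as multi-page TIFF with (time, channel, y, x) axes and
pixel-size metadata in the resolution tags; tables as CSV with a stable
column order and >= 9 significant digits on floats; configuration as a
single YAML per run; logs as JSON lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import tifffile
import yaml

from .frames import Frame, PIXEL_SIZE_BY_MAGNIFICATION


class CalibrationError(ValueError):
    """Pixel size neither present in the file metadata nor overridden."""


class SchemaError(ValueError):
    """Records do not share a schema."""


class StageError(ValueError):
    """Unknown stage or a violated stage contract."""


# --------------------------------------------------------------------------
# image stacks
# --------------------------------------------------------------------------

def write_image_stack(
    frames: list[Frame] | dict[str, Frame] | Frame,
    path: str | Path,
    channels: list[str] | None = None,
) -> None:
    """Write frames to a TIFF stack with TCYX axes and resolution tags.

    Accepts a single frame, a time-ordered list, or a channel dict (one
    timepoint). Pixel size is stored in the X/Y resolution tags as
    pixels per µm.
    """
    if isinstance(frames, Frame):
        frames = [frames]
    if isinstance(frames, dict):
        channels = list(frames)
        frames = list(frames.values())
    px = frames[0].pixel_size_um
    chans = channels or sorted({f.channel for f in frames})
    times = sorted({f.timepoint for f in frames})
    arr = np.zeros((len(times), len(chans), *frames[0].shape), dtype=np.float32)
    for f in frames:
        arr[times.index(f.timepoint), chans.index(f.channel)] = f.data
    tifffile.imwrite(
        str(path),
        arr,
        resolution=(1.0 / px, 1.0 / px),
        metadata={
            "axes": "TCYX",
            "channels": chans,
            "timepoints": [float(t) for t in times],
            "time_unit": frames[0].time_unit,
        },
    )


def read_image_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
) -> list[Frame]:
    """Read a TIFF/OME-TIFF into a time-ordered list of frames.

    Axes are normalized to (time, channel, y, x); single-plane files are
    promoted to one timepoint, one channel. Pixel size comes from the
    resolution tags unless ``pixel_size_um`` overrides them; with
    neither, a :class:`CalibrationError` is raised.
    """
    try:
        with tifffile.TiffFile(str(path)) as tf:
            series = tf.series[0]
            arr = series.asarray()
            axes = series.axes
            page = tf.pages[0]
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
            px = None
            if pixel_size_um is not None:
                px = float(pixel_size_um)
            elif "XResolution" in page.tags:
                num, den = page.tags["XResolution"].value
                # (1, 1) is the writer default for uncalibrated files
                if num and (num, den) != (1, 1):
                    px = den / num
            if px is None or px <= 0:
                raise CalibrationError(
                    f"{path}: no pixel size in metadata and no override given"
                )
    except tifffile.TiffFileError as exc:
        raise OSError(f"{path}: not a readable TIFF file: {exc}") from exc

    # normalize to TCYX
    arr = np.asarray(arr)
    axes = axes.replace("S", "C").replace("Z", "T").replace("Q", "T").replace("I", "T")
    while arr.ndim < 4:
        arr = arr[np.newaxis]
        axes = ("C" if "C" not in axes else "T") + axes
    if axes != "TCYX":
        order = [axes.index(a) for a in "TCYX" if a in axes]
        arr = np.transpose(arr, order)
    chans = list(meta.get("channels", [f"ch{i}" for i in range(arr.shape[1])]))
    times = list(meta.get("timepoints", list(range(arr.shape[0]))))
    unit = meta.get("time_unit", "days")
    frames = []
    for ti in range(arr.shape[0]):
        for ci in range(arr.shape[1]):
            frames.append(
                Frame(np.clip(arr[ti, ci].astype(float), 0, None), px,
                      channel=chans[ci], timepoint=float(times[ti]), time_unit=unit)
            )
    return frames


# --------------------------------------------------------------------------
# record tables
# --------------------------------------------------------------------------

def write_records(records: pd.DataFrame | list[dict], path: str | Path) -> None:
    """Write records to CSV with a header, stable column order and >= 9
    significant digits on floats (round-trip within 1e-9 relative)."""
    if isinstance(records, list):
        if records:
            keys = set(records[0])
            for r in records:
                if set(r) != keys:
                    raise SchemaError("records do not share a schema")
        records = pd.DataFrame(records)
    df = records
    df.to_csv(str(path), index=False, float_format="%.12g")


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path))


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One run's tunable parameters, loadable from a single YAML file."""

    magnification_pixel_size: dict[int, float] = field(
        default_factory=lambda: dict(PIXEL_SIZE_BY_MAGNIFICATION)
    )
    #: Gaussian sigma (µm) and object-area bounds (µm²) for soma detection
    detection_sigma_um: float = 2.0
    min_area_um2: float = 20.0
    max_area_um2: float = 400.0
    min_roundness: float = 0.5
    #: motility rule: cumulative movement threshold over the experiment
    motility_threshold_um: float = 12.5
    motility_duration_min: float = 10.0
    #: longitudinal imaging schedule (first day, last day, interval)
    schedule: tuple[float, float, float] = (12.0, 46.0, 2.0)
    #: tracker parameters
    association_iou: float = 0.3
    merge_iou: float = 0.5
    max_gap: int = 1
    min_track_length: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise StageError(f"unknown config keys: {sorted(unknown)}")
        if "schedule" in raw:
            raw["schedule"] = tuple(raw["schedule"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


# --------------------------------------------------------------------------
# stage running
# --------------------------------------------------------------------------

_STAGES: dict[str, Callable] = {}


def register_stage(name: str):
    def deco(fn):
        _STAGES[name] = fn
        return fn
    return deco


def run_stage(
    name: str,
    config: RunConfig,
    inputs: dict[str, Any],
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Run a registered stage and append a JSON-lines log entry.

    The log records the stage name, config hash, seed, and per-output
    row/frame counts; outputs that are DataFrames are written to CSV in
    ``out_dir`` when given.
    """
    from . import stages as _builtin_stages  # noqa: F401  (registers stages)

    if name not in _STAGES:
        raise StageError(f"unknown stage {name!r}; known: {sorted(_STAGES)}")
    outputs = _STAGES[name](config, inputs)
    entry = {
        "stage": name,
        "config_hash": config.digest(),
        "seed": config.seed,
        "time": time.time(),
        "counts": {
            k: (len(v) if hasattr(v, "__len__") else 1) for k, v in outputs.items()
        },
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for key, val in outputs.items():
            if isinstance(val, pd.DataFrame):
                write_records(val, out_dir / f"{key}.csv")
        with open(out_dir / "log.jsonl", "a") as fh:
            fh.write(json.dumps(entry) + "\n")
    outputs["_log"] = entry
    return outputs
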