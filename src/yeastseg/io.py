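"""File formats and run configuration.

Stacks are multi-page TIFFs or directories of lexicographically ordered
single-page TIFFs; label stacks are written as 16-bit multi-page TIFF,
track tables as CSV, and the run configuration round-trips losslessly
through YAML with unknown keys rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imageprep import PrepParams
from .seeding import SeedingParams
from .subroutine import SubroutineParams
from .tracker import TrackerParams

TRACK_COLUMNS = ["frame", "label", "area", "centroid_row", "centroid_col",
                 "status"]


def read_stack(path: str | Path) -> list[np.ndarray]:
    """Read a time-lapse stack: frames in acquisition order, float64.

    ``path`` may be a multi-page TIFF or a directory of single-page TIFFs
    ordered lexicographically.  Mixed frame shapes abort with the
    offending page index.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise ValueError(f"no TIFF files in directory {path}")
        for i, f in enumerate(files):
            try:
                frames.append(np.asarray(tifffile.imread(f), dtype=np.float64))
            except Exception as exc:
                raise ValueError(f"unreadable page {i} ({f.name})") from exc
    else:
        data = tifffile.imread(path)
        arr = np.asarray(data)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"expected 2-D frames, got shape {arr.shape}")
        frames = [np.asarray(f, dtype=np.float64) for f in arr]
    for i, f in enumerate(frames):
        if f.shape != frames[0].shape:
            raise ValueError(f"frame {i} shape {f.shape} != {frames[0].shape}")
    return frames


def write_stack(stack, path: str | Path, dtype=np.float32) -> None:
    """Write frames as a multi-page TIFF."""
    arr = np.stack([np.asarray(f) for f in stack]).astype(dtype)
    tifffile.imwrite(Path(path), arr, photometric="minisblack")


def write_labels(labels, path: str | Path) -> None:
    """Write a label stack as 16-bit multi-page TIFF (background 0)."""
    arr = np.stack([np.asarray(f) for f in labels])
    if arr.min() < 0:
        raise ValueError("negative labels")
    if arr.max() > 65535:
        raise ValueError("labels exceed the 16-bit range")
    tifffile.imwrite(Path(path), arr.astype(np.uint16),
                     photometric="minisblack")


def read_labels(path: str | Path) -> np.ndarray:
    arr = np.asarray(tifffile.imread(Path(path)))
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(np.int32)


def write_tracks(table: pd.DataFrame, path: str | Path) -> None:
    """Write a track table as CSV, one row per (frame, cell), ordered by
    frame then label; byte-deterministic for a fixed table."""
    cols = [c for c in table.columns if c in TRACK_COLUMNS or
            c == "birth_frame"]
    out = table[cols].sort_values(["frame", "label"], kind="stable")
    out.to_csv(Path(path), index=False, lineterminator="\n",
               float_format="%.3f")


def read_tracks(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


@dataclass
class RunConfig:
    """Every tunable of a run, round-trippable through YAML."""

    modality: str = "phase"
    prep: PrepParams = field(default_factory=PrepParams)
    subroutine: SubroutineParams = field(default_factory=SubroutineParams)
    seeding: SeedingParams = field(default_factory=SeedingParams)
    tracker: TrackerParams = field(default_factory=TrackerParams)
    worker_count: int = 1
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seeding"]["vote_thresholds"] = list(
            d["seeding"]["vote_thresholds"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for name, sub_cls in (("prep", PrepParams),
                              ("subroutine", SubroutineParams),
                              ("seeding", SeedingParams),
                              ("tracker", TrackerParams)):
            if name in data and isinstance(data[name], dict):
                sub_known = {f.name for f in fields(sub_cls)}
                sub_unknown = set(data[name]) - sub_known
                if sub_unknown:
                    raise ValueError(
                        f"unknown {name} keys: {sorted(sub_unknown)}")
                data[name] = sub_cls(**data[name])
        cfg = cls(**data)
        if isinstance(cfg.seeding.vote_thresholds, list):
            cfg.seeding.vote_thresholds = tuple(cfg.seeding.vote_thresholds)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
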