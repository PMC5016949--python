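"""Tracking-table I/O and the shared data model.

The package works on *tracking tables*: delimited-text exports of spot
coordinates from two-colour 3D live-cell videos, one green and one red
fluorescent spot per cell per frame.  All coordinates are in nanometres
with z along the optical axis; times are seconds from video start.

Two dialects are supported:

* the *wide* dialect (the package's native format) has one row per
  (video, frame) with both channels' coordinates side by side;
* the *long* dialect, typical of spot-tracking software exports, has one
  row per spot and is paired by (video_id, nearest time).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

GREEN = "green"
RED = "red"
CHANNELS = (GREEN, RED)

#: frame-level columns of the wide tracking-table dialect, in canonical order
FRAME_COLUMNS = [
    "time_s",
    "x_nm_green", "y_nm_green", "z_nm_green",
    "intensity_green", "contrast_green",
    "x_nm_red", "y_nm_red", "z_nm_red",
    "intensity_red", "contrast_red",
]

#: video-level metadata columns of the wide dialect
META_COLUMNS = ["video_id", "cell_id", "strain_id", "role", "pair_id"]

#: optional columns carrying per-video acquisition metadata
OPTIONAL_COLUMNS = ["frame_interval_s", "stack_z_min_nm", "stack_z_max_nm"]

MANDATORY_COLUMNS = META_COLUMNS + FRAME_COLUMNS

ROLES = ("mother", "daughter", "unpaired")


class SchemaError(ValueError):
    """A tracking table does not match the expected column schema."""


class ValidationError(ValueError):
    """A tracking table parses but violates a data-model invariant."""


@dataclass(frozen=True)
class SpotObservation:
    """One fluorescent spot in one frame."""

    time: float          # seconds from video start
    channel: str         # "green" or "red"
    x: float             # nm
    y: float             # nm
    z: float             # nm, along the optical axis
    max_intensity: float  # arbitrary camera units
    contrast: float      # arbitrary units

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValidationError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.time < 0:
            raise ValidationError(f"time must be >= 0, got {self.time}")
        for name in ("x", "y", "z"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"coordinate {name} is not finite")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class StrainSpec:
    """Operator-array geometry of one reporter strain.

    The fluorescence of each spot centres on the midpoint of its operator
    array, so the effective genomic separation of the two spots is the
    intragenic spacer plus half of each flanking array.
    """

    strain_id: str
    a_bp: float      # intragenic spacer length (bp)
    x_p_bp: float    # first operator array length (bp)
    x_q_bp: float    # second operator array length (bp)

    def __post_init__(self) -> None:
        for name in ("a_bp", "x_p_bp", "x_q_bp"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")

    @property
    def z_effective_bp(self) -> float:
        """Effective genomic separation: a + 0.5*x_p + 0.5*x_q (bp)."""
        return self.a_bp + 0.5 * self.x_p_bp + 0.5 * self.x_q_bp


@dataclass
class CellVideo:
    """A time series of paired green/red spot observations for one cell.

    ``frames`` is a DataFrame with (at least) the columns in
    :data:`FRAME_COLUMNS`; extra columns are preserved as opaque metadata.
    Missing frames are allowed: all downstream statistics use the actual
    ``time_s`` stamps, never frame indices.
    """

    video_id: str
    cell_id: str
    strain_id: str
    frames: pd.DataFrame
    role: str = "unpaired"
    pair_id: str | None = None
    frame_interval: float = 1.0          # s, nominal time between Z-stacks
    stack_range: tuple[float, float] = (0.0, 5000.0)  # nm, axial imaging bounds

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"role must be one of {ROLES}, got {self.role!r}")
        if (self.role == "unpaired") != (self.pair_id is None):
            raise ValidationError(
                f"video {self.video_id}: role 'unpaired' if and only if pair_id is absent "
                f"(role={self.role!r}, pair_id={self.pair_id!r})"
            )
        missing = [c for c in FRAME_COLUMNS if c not in self.frames.columns]
        if missing:
            raise SchemaError(f"video {self.video_id}: frames missing column(s) {missing}")
        if self.stack_range[1] <= self.stack_range[0]:
            raise ValidationError(f"video {self.video_id}: empty stack_range {self.stack_range}")
        t = self.frames["time_s"].to_numpy(dtype=float)
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValidationError(f"video {self.video_id}: times are not strictly increasing")
        coords = self.frames[[f"{ax}_nm_{ch}" for ch in CHANNELS for ax in "xyz"]]
        if len(coords) and not np.isfinite(coords.to_numpy(dtype=float)).all():
            raise ValidationError(f"video {self.video_id}: non-finite coordinates")
        self.frames = self.frames.reset_index(drop=True)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return self.frames["time_s"].to_numpy(dtype=float)

    def positions(self, channel: str) -> np.ndarray:
        """(n_frames, 3) array of x/y/z coordinates (nm) for one channel."""
        if channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        cols = [f"{ax}_nm_{channel}" for ax in "xyz"]
        return self.frames[cols].to_numpy(dtype=float)

    def replace(self, **changes) -> "CellVideo":
        """Return a copy with the given fields replaced (frames are copied)."""
        if "frames" not in changes:
            changes["frames"] = self.frames.copy()
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# wide-dialect read/write

def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _video_from_group(group: pd.DataFrame, video_id: str) -> CellVideo:
    first = group.iloc[0]
    pair_id = first["pair_id"]
    if pd.isna(pair_id) or pair_id == "":
        pair_id = None
    frame_interval = float(first["frame_interval_s"]) if "frame_interval_s" in group.columns else 1.0
    if "stack_z_min_nm" in group.columns and "stack_z_max_nm" in group.columns:
        stack_range = (float(first["stack_z_min_nm"]), float(first["stack_z_max_nm"]))
    else:
        stack_range = (0.0, 5000.0)
    frame_cols = [c for c in group.columns if c not in META_COLUMNS + OPTIONAL_COLUMNS]
    return CellVideo(
        video_id=str(video_id),
        cell_id=str(first["cell_id"]),
        strain_id=str(first["strain_id"]),
        role=str(first["role"]),
        pair_id=None if pair_id is None else str(pair_id),
        frame_interval=frame_interval,
        stack_range=stack_range,
        frames=group[frame_cols].reset_index(drop=True),
    )


def read_tracking_table(path: str | Path) -> list[CellVideo]:
    """Read a wide-dialect tracking table (comma or tab, autodetected).

    Returns videos grouped by ``video_id`` in order of first appearance.
    Unknown extra columns are preserved in each video's ``frames``.

    Raises
    ------
    SchemaError
        if a mandatory column is missing (the error names the column).
    ValidationError
        if times within a video are not strictly increasing.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), float_precision="round_trip")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    videos = []
    for vid, group in df.groupby("video_id", sort=False):
        videos.append(_video_from_group(group, vid))
    return videos


def write_tracking_table(videos: Iterable[CellVideo], path: str | Path) -> None:
    """Write videos as a wide-dialect tracking table (inverse of read).

    Column order is deterministic; ``.tsv`` paths are tab-delimited,
    anything else comma-delimited.  An empty collection yields a
    header-only file.
    """
    path = Path(path)
    rows = []
    extra_cols: list[str] = []
    for v in videos:
        extras = [c for c in v.frames.columns if c not in FRAME_COLUMNS]
        for c in extras:
            if c not in extra_cols:
                extra_cols.append(c)
        block = v.frames.copy()
        block.insert(0, "video_id", v.video_id)
        block.insert(1, "cell_id", v.cell_id)
        block.insert(2, "strain_id", v.strain_id)
        block.insert(3, "role", v.role)
        block.insert(4, "pair_id", "" if v.pair_id is None else v.pair_id)
        block["frame_interval_s"] = v.frame_interval
        block["stack_z_min_nm"] = v.stack_range[0]
        block["stack_z_max_nm"] = v.stack_range[1]
        rows.append(block)
    columns = MANDATORY_COLUMNS + OPTIONAL_COLUMNS + extra_cols
    if rows:
        out = pd.concat(rows, ignore_index=True)
        out = out[[c for c in columns if c in out.columns]]
    else:
        out = pd.DataFrame(columns=columns)
    sep = "\t" if path.suffix == ".tsv" else ","
    out.to_csv(path, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# long (per-spot) dialect

LONG_COLUMNS = ["video_id", "time_s", "channel", "x_nm", "y_nm", "z_nm",
                "intensity", "contrast"]


def read_long_table(path: str | Path, frame_interval: float = 1.0,
                    stack_range: tuple[float, float] = (0.0, 5000.0)) -> list[CellVideo]:
    """Read a long per-spot tracking export (one row per spot).

    Green and red observations are paired by (video_id, nearest time);
    the pairing tolerance is ``frame_interval / 2``.  Spots with no
    partner within tolerance are dropped.  Optional ``cell_id``,
    ``strain_id``, ``role`` and ``pair_id`` columns are honoured.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), float_precision="round_trip")
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    tol = frame_interval / 2.0
    videos = []
    for vid, group in df.groupby("video_id", sort=False):
        green = group[group["channel"] == GREEN].sort_values("time_s")
        red = group[group["channel"] == RED].sort_values("time_s")
        if green.empty or red.empty:
            continue
        rt = red["time_s"].to_numpy(dtype=float)
        rows = []
        used: set[int] = set()
        for _, g in green.iterrows():
            i = int(np.argmin(np.abs(rt - g["time_s"])))
            if abs(rt[i] - g["time_s"]) > tol or i in used:
                continue
            used.add(i)
            r = red.iloc[i]
            rows.append({
                "time_s": float(g["time_s"]),
                "x_nm_green": g["x_nm"], "y_nm_green": g["y_nm"], "z_nm_green": g["z_nm"],
                "intensity_green": g["intensity"], "contrast_green": g["contrast"],
                "x_nm_red": r["x_nm"], "y_nm_red": r["y_nm"], "z_nm_red": r["z_nm"],
                "intensity_red": r["intensity"], "contrast_red": r["contrast"],
            })
        if not rows:
            continue
        frames = pd.DataFrame(rows).sort_values("time_s").reset_index(drop=True)
        first = group.iloc[0]
        pair_id = first.get("pair_id", None)
        if pair_id is not None and (pd.isna(pair_id) or pair_id == ""):
            pair_id = None
        videos.append(CellVideo(
            video_id=str(vid),
            cell_id=str(first.get("cell_id", vid)),
            strain_id=str(first.get("strain_id", "unknown")),
            role=str(first.get("role", "unpaired")),
            pair_id=None if pair_id is None else str(pair_id),
            frame_interval=frame_interval,
            stack_range=stack_range,
            frames=frames,
        ))
    return videos


# ---------------------------------------------------------------------------
# strain-spec tables, config, reports

def read_strain_table(path: str | Path) -> list[StrainSpec]:
    """Read a strain-spec table (TSV/CSV: strain_id, a_bp, x_p_bp, x_q_bp)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), float_precision="round_trip")
    missing = [c for c in ("strain_id", "a_bp", "x_p_bp", "x_q_bp") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    return [StrainSpec(str(r.strain_id), float(r.a_bp), float(r.x_p_bp), float(r.x_q_bp))
            for r in df.itertuples()]


def default_config() -> dict:
    """Default pipeline configuration (see docs/methods.md for rationale)."""
    from .simulate import SimulationConfig  # deferred: avoids import cycle
    sim = dataclasses.asdict(SimulationConfig())
    return {
        "simulation": sim,
        "population": {
            "n_cells": 30,
            "fraction_paired": 0.6,
            "n_colocalising_videos": 10,
        },
        "strains": [
            {"strain_id": "71kb", "a_bp": 60600.0, "x_p_bp": 10400.0, "x_q_bp": 10400.0},
        ],
        "qc": {
            "enabled": True,
            "contrast_min_green": 12.0,
            "contrast_min_red": 12.0,
            "intensity_min_red": 25.0,
            "intensity_min_green": 16.0,
            "z_margin": 1000.0,
        },
        "dynamics": {
            "bin_width_s": 6.0,
            "plateau_t_min_s": 150.0,
            "n_boot": 2000,
            "exclude_videos": [],
        },
        "inheritance": {
            "n_unrelated": None,
        },
        "geometry": {
            "bin_width_nm": 63.0,
        },
    }


def _merge(defaults: dict, overrides: dict, context: str = "") -> dict:
    out = dict(defaults)
    for key, value in overrides.items():
        where = f"{context}.{key}" if context else key
        if key not in defaults:
            raise ValidationError(f"unknown config key {where!r}")
        if isinstance(defaults[key], dict) and key != "strains":
            if not isinstance(value, dict):
                raise ValidationError(f"config section {where!r} must be a mapping")
            out[key] = _merge(defaults[key], value, where)
        else:
            out[key] = value
    return out


_NUMERIC_KEYS = {
    ("qc", "contrast_min_green"), ("qc", "contrast_min_red"),
    ("qc", "intensity_min_red"), ("qc", "intensity_min_green"),
    ("qc", "z_margin"),
    ("dynamics", "bin_width_s"), ("dynamics", "plateau_t_min_s"),
    ("geometry", "bin_width_nm"),
    ("population", "n_cells"), ("population", "fraction_paired"),
    ("population", "n_colocalising_videos"),
    ("dynamics", "n_boot"),
}


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML pipeline config; unset keys are filled with defaults.

    Raises :class:`ValidationError` on unknown keys or non-numeric values
    for numeric thresholds.
    """
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        if not isinstance(overrides, dict):
            raise ValidationError(f"{path}: config root must be a mapping")
        cfg = _merge(cfg, overrides)
    for section, key in _NUMERIC_KEYS:
        value = cfg[section][key]
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ValidationError(f"config {section}.{key} must be numeric, got {value!r}")
    # simulation sub-config is validated by SimulationConfig itself
    from .simulate import SimulationConfig
    cfg["simulation"] = dataclasses.asdict(SimulationConfig(**cfg["simulation"]))
    return cfg


def write_report(results: dict | pd.DataFrame, path: str | Path) -> None:
    """Write an analysis report: dict → JSON, DataFrame → TSV.

    Output is deterministic for fixed inputs (sorted JSON keys, fixed
    column order).
    """
    path = Path(path)
    if isinstance(results, pd.DataFrame):
        results.to_csv(path, sep="\t", index=False)
        return

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
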