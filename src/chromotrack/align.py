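"""Channel alignment and quality control.

Two-colour systems image the green and red fluorophores on separate
cameras, so red coordinates must be mapped into the green frame before
inter-locus distances mean anything.  Alignment is two-stage:

1. *coarse*: an affine map (translation + rotation + magnification)
   derived from a calibration target, applied here to coordinates with
   externally supplied parameters;
2. *fine*: a constant translation equal to the mean red-minus-green
   offset measured on a colocalising control strain, in which a single
   spot carries both fluorophores so the true separation is zero.

After fine alignment the residual mean 3D red-green distance on the
control strain is the *measurement error* of the whole workflow.

Quality control removes frames in which either spot drifted within
``z_margin`` of the stack boundary or fell below contrast/intensity
thresholds, in the fixed precedence order z-margin → contrast →
intensity (the first failing rule claims the frame).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import CellVideo, GREEN, RED, ValidationError

_ROT_TOL = 1e-9


@dataclass(frozen=True)
class AffineTransform:
    """Coarse channel-alignment map: p -> magnification * R @ p + translation."""

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    magnification: float = 1.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValidationError("rotation must be a 3x3 matrix")
        if not np.allclose(R.T @ R, np.eye(3), atol=_ROT_TOL):
            raise ValidationError("rotation matrix is not orthonormal (tolerance 1e-9)")
        if self.magnification <= 0:
            raise ValidationError("magnification must be > 0")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        return self.magnification * points @ R.T + t

    def inverse(self) -> "AffineTransform":
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        R_inv = R.T
        m_inv = 1.0 / self.magnification
        t_inv = -m_inv * R_inv @ t
        return AffineTransform(tuple(t_inv), tuple(map(tuple, R_inv)), m_inv)


@dataclass(frozen=True)
class FineOffsets:
    """Per-axis mean red-minus-green offsets (nm) from a colocalising set."""

    dx: float
    dy: float
    dz: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValidationError("n_points must be >= 1")
        if not np.all(np.isfinite([self.dx, self.dy, self.dz])):
            raise ValidationError("offsets must be finite")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.dz])


@dataclass(frozen=True)
class QCThresholds:
    """Quality-control thresholds (defaults as used throughout the package)."""

    contrast_min_green: float = 12.0
    contrast_min_red: float = 12.0
    intensity_min_red: float = 25.0
    intensity_min_green: float = 16.0
    z_margin: float = 1000.0  # nm from either stack boundary

    def __post_init__(self) -> None:
        for name in ("contrast_min_green", "contrast_min_red", "intensity_min_red",
                     "intensity_min_green", "z_margin"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class QCReport:
    """Frame bookkeeping for one video's QC pass."""

    video_id: str
    total: int
    kept: int
    removed_z_margin: int
    removed_contrast: int
    removed_intensity: int

    def __post_init__(self) -> None:
        if self.kept + self.removed_z_margin + self.removed_contrast + \
                self.removed_intensity != self.total:
            raise ValidationError("QC counts do not sum to total frames")


def apply_affine(video: CellVideo, transform: AffineTransform,
                 channel: str) -> CellVideo:
    """Map one channel's coordinates through an affine transform."""
    if channel not in (GREEN, RED):
        raise ValueError(f"channel must be '{GREEN}' or '{RED}'")
    out = video.replace()
    cols = [f"{ax}_nm_{channel}" for ax in "xyz"]
    if len(out.frames):
        out.frames[cols] = transform.apply(out.frames[cols].to_numpy(dtype=float))
    return out


def _stack_offsets(videos: Iterable[CellVideo]) -> np.ndarray:
    deltas = [v.positions(RED) - v.positions(GREEN) for v in videos if v.n_frames]
    if not deltas:
        raise ValidationError("no usable frames to estimate offsets from")
    return np.vstack(deltas)


def estimate_fine_offsets(colocalising_videos: Sequence[CellVideo]) -> FineOffsets:
    """Per-axis arithmetic mean of (red - green) over all supplied frames.

    The input should be the colocalising control strain after coarse
    alignment and QC, so the means isolate the residual chromatic offset.
    """
    deltas = _stack_offsets(colocalising_videos)
    mean = deltas.mean(axis=0)
    return FineOffsets(float(mean[0]), float(mean[1]), float(mean[2]), len(deltas))


def apply_fine_offsets(videos: Sequence[CellVideo],
                       offsets: FineOffsets) -> list[CellVideo]:
    """Subtract the mean offsets from every red-channel coordinate."""
    out = []
    for video in videos:
        v = video.replace()
        if len(v.frames):
            cols = [f"{ax}_nm_{RED}" for ax in "xyz"]
            v.frames[cols] = v.frames[cols].to_numpy(dtype=float) - offsets.vector
        out.append(v)
    return out


def measurement_error(colocalising_videos: Sequence[CellVideo]) -> tuple[float, float, int]:
    """Mean and SD of the 3D red-green distance over all frames.

    On a fine-aligned colocalising set this is the residual measurement
    error of the workflow.  Returns ``(mean_nm, sd_nm, n_frames)``; the
    SD uses the n-1 denominator (0.0 for a single frame).
    """
    deltas = _stack_offsets(colocalising_videos)
    dist = np.linalg.norm(deltas, axis=1)
    sd = float(dist.std(ddof=1)) if len(dist) > 1 else 0.0
    return float(dist.mean()), sd, len(dist)


def qc_filter(video: CellVideo,
              thresholds: QCThresholds = QCThresholds()) -> tuple[CellVideo, QCReport]:
    """Remove low-quality frames; attribute each removal to one rule.

    A frame fails if either spot's z is within ``z_margin`` of a stack
    boundary, or either channel's contrast is below its contrast
    threshold, or either channel's intensity is below its intensity
    threshold.  Removals are attributed in the precedence order
    z-margin → contrast → intensity, so the counts are unambiguous even
    when a frame violates several rules.  Empty output is allowed.
    """
    f = video.frames
    n = len(f)
    if n == 0:
        return video.replace(), QCReport(video.video_id, 0, 0, 0, 0, 0)
    z_lo, z_hi = video.stack_range
    z_green = f["z_nm_green"].to_numpy(dtype=float)
    z_red = f["z_nm_red"].to_numpy(dtype=float)
    margin = thresholds.z_margin
    fail_z = np.zeros(n, dtype=bool)
    for z in (z_green, z_red):
        fail_z |= (z < z_lo + margin) | (z > z_hi - margin)
    fail_contrast = (
        (f["contrast_green"].to_numpy(dtype=float) < thresholds.contrast_min_green)
        | (f["contrast_red"].to_numpy(dtype=float) < thresholds.contrast_min_red)
    )
    fail_intensity = (
        (f["intensity_green"].to_numpy(dtype=float) < thresholds.intensity_min_green)
        | (f["intensity_red"].to_numpy(dtype=float) < thresholds.intensity_min_red)
    )
    removed_z = int(fail_z.sum())
    removed_contrast = int((fail_contrast & ~fail_z).sum())
    removed_intensity = int((fail_intensity & ~fail_z & ~fail_contrast).sum())
    keep = ~(fail_z | fail_contrast | fail_intensity)
    filtered = video.replace(frames=f[keep].reset_index(drop=True))
    report = QCReport(video.video_id, n, int(keep.sum()),
                      removed_z, removed_contrast, removed_intensity)
    return filtered, report


def qc_filter_all(videos: Sequence[CellVideo],
                  thresholds: QCThresholds = QCThresholds(),
                  drop_empty: bool = True) -> tuple[list[CellVideo], list[QCReport]]:
    """Apply :func:`qc_filter` to a collection, optionally dropping
    videos left with no frames."""
    kept, reports = [], []
    for video in videos:
        filtered, report = qc_filter(video, thresholds)
        reports.append(report)
        if filtered.n_frames or not drop_empty:
            kept.append(filtered)
    return kept, reports
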