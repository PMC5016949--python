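"""Dynamics statistics for paired-locus trajectories.

Four statistics characterise how a tethered locus pair moves:

* **Anisotropy D** — the inter-locus vector of each frame is mapped to
  the unit square by an area-preserving transform (azimuth → u, polar
  cosine → v); if the vectors are isotropic the (u, v) points are
  uniform on [0,1]^2, so the one-sample two-dimensional
  Kolmogorov-Smirnov statistic D against uniformity measures how
  strongly the pair maintains a preferred relative orientation.
* **RV coefficient** — a multivariate generalisation of the squared
  Pearson correlation between the two loci's 3D motion; 1 means the
  loci track together rigidly, near 0 means independent motion.
* **MSCD** — the mean square change in inter-locus distance,
  ``mean (d(t+tau) - d(t))^2`` over all within-video ordered time-point
  pairs at lag tau, pooled across videos and binned; a one-dimensional
  MSD applied to the separation distance.  For confined motion the
  curve rises and plateaus at twice the stationary variance of d.
  A bootstrap *between-cell baseline* — the expected squared distance
  difference between random time points of different videos — marks
  where the plateau would sit if within-cell variability explained all
  between-cell variability.
* **MSD** — the ordinary per-locus mean square displacement, same
  binning machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import CellVideo, GREEN, RED, ValidationError
from .geometry import DistanceSeries, distance_series

TWO_PI = 2.0 * math.pi


# ---------------------------------------------------------------------------
# UV mapping and the 2D Kolmogorov-Smirnov anisotropy statistic

def uv_map(vector_3d) -> tuple[float, float]:
    """Map a nonzero 3D vector to the unit square (area-preserving).

    ``u`` is the full-circle azimuth, ``(atan2(y, x) + pi) / (2*pi)``,
    wrapped to [0, 1); ``v = (|r| - z) / (2 |r|)`` is the affinely
    rescaled polar cosine in [0, 1].  Isotropic vectors give (u, v)
    uniform on the unit square.  A vector with x = y = 0 gets u = 0.5;
    a zero vector is rejected (v is undefined).
    """
    x, y, z = (float(c) for c in vector_3d)
    r = math.sqrt(x * x + y * y + z * z)
    if r == 0.0:
        raise ValidationError("uv_map is undefined for the zero vector")
    u = (math.atan2(y, x) + math.pi) / TWO_PI
    if u >= 1.0:
        u = 0.0
    v = (r - z) / (2.0 * r)
    return u, v


def uv_map_many(vectors: np.ndarray) -> np.ndarray:
    """Vectorised :func:`uv_map`; zero-length rows are dropped."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[1] != 3:
        raise ValueError("vectors must be an (n, 3) array")
    r = np.linalg.norm(vectors, axis=1)
    keep = r > 0
    vectors, r = vectors[keep], r[keep]
    u = (np.arctan2(vectors[:, 1], vectors[:, 0]) + math.pi) / TWO_PI
    u[u >= 1.0] = 0.0
    v = (r - vectors[:, 2]) / (2.0 * r)
    return np.column_stack([u, v])


@dataclass(frozen=True)
class AnisotropyResult:
    """2D KS anisotropy statistic for one set of inter-locus vectors."""

    D: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.D <= 1.0:
            raise ValidationError("D must be in [0, 1]")


def ks2d_uniform(points: np.ndarray, chunk: int = 512) -> float:
    """One-sample 2D Kolmogorov-Smirnov statistic vs uniform on [0,1]^2.

    Evaluated at the data points only: for each point and each of the
    four quadrant orientations, D is the largest absolute difference
    between the empirical fraction in the quadrant and its area.  The
    lower quadrants are closed (``<=``), their complements open — the
    convention pinned by the brute-force oracle in the test suite.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n == 0:
        raise ValidationError("no points for the 2D KS statistic")
    u, v = pts[:, 0], pts[:, 1]
    best = 0.0
    for start in range(0, n, chunk):
        cu = u[start:start + chunk][:, None]
        cv = v[start:start + chunk][:, None]
        le_u = u[None, :] <= cu
        le_v = v[None, :] <= cv
        n_ll = (le_u & le_v).sum(axis=1) / n
        n_lu = (le_u & ~le_v).sum(axis=1) / n
        n_rl = (~le_u & le_v).sum(axis=1) / n
        n_rr = 1.0 - n_ll - n_lu - n_rl
        cu, cv = cu[:, 0], cv[:, 0]
        diffs = np.abs(np.stack([
            n_ll - cu * cv,
            n_lu - cu * (1.0 - cv),
            n_rl - (1.0 - cu) * cv,
            n_rr - (1.0 - cu) * (1.0 - cv),
        ]))
        best = max(best, float(diffs.max()))
    return best


def anisotropy_D(vectors: np.ndarray) -> AnisotropyResult:
    """Anisotropy statistic D of a set of 3D inter-locus vectors.

    Zero-length vectors are skipped; at least one nonzero vector is
    required.  D near 0 means isotropic relative orientation; large D
    means the pair holds a preferred orientation.
    """
    uv = uv_map_many(vectors)
    if len(uv) == 0:
        raise ValidationError("no nonzero vectors for anisotropy_D")
    return AnisotropyResult(ks2d_uniform(uv), len(uv))


def pair_vectors(video: CellVideo) -> np.ndarray:
    """Per-frame inter-locus vectors, red minus green (the pinned sign)."""
    return video.positions(RED) - video.positions(GREEN)


def anisotropy_for_video(video: CellVideo) -> AnisotropyResult:
    return anisotropy_D(pair_vectors(video))


# ---------------------------------------------------------------------------
# RV coefficient

def rv_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    """RV coefficient between two T x 3 multivariate series.

    With column-centred matrices and cross-covariance blocks
    ``S_ab = A' B``, RV = trace(Sxy Syx) / sqrt(trace(Sxx^2) trace(Syy^2)),
    equivalently the cosine similarity of the configuration matrices
    XX' and YY'.  RV is in [0, 1], symmetric, and invariant to a rigid
    rotation applied to either series alone.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2:
        raise ValueError("X and Y must be equal-shape (T, k) arrays")
    if len(X) < 3:
        raise ValidationError("RV requires at least 3 time points")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = np.linalg.norm(Xc.T @ Xc)
    syy = np.linalg.norm(Yc.T @ Yc)
    if sxx == 0.0 or syy == 0.0:
        raise ValidationError("RV undefined: an input has zero total variance")
    sxy = float(np.sum((Xc.T @ Yc) ** 2))
    return sxy / (sxx * syy)


def rv_for_video(video: CellVideo, mode: str = "displacement") -> float:
    """RV coefficient between the green and red locus trajectories.

    ``mode='displacement'`` (default) compares per-frame displacement
    vectors of consecutive retained frames — the motion of each locus;
    ``mode='position'`` compares the raw position series.
    """
    G = video.positions(GREEN)
    R = video.positions(RED)
    if mode == "displacement":
        G, R = np.diff(G, axis=0), np.diff(R, axis=0)
    elif mode != "position":
        raise ValueError("mode must be 'displacement' or 'position'")
    return rv_coefficient(G, R)


# ---------------------------------------------------------------------------
# lag-binned curves: MSCD and MSD

@dataclass
class MSCDCurve:
    """Lag-binned mean square change in distance (or displacement).

    ``bin_centres`` are the centres of half-open [k*w, (k+1)*w) lag
    bins; only bins with at least one pair are reported.  ``se`` treats
    pairs as independent (overlapping pairs are autocorrelated, so it
    understates the true error; see the methods note).
    """

    bin_centres: np.ndarray  # s
    mscd: np.ndarray         # nm^2
    n_pairs: np.ndarray
    se: np.ndarray           # nm^2
    baseline: float | None = None     # bootstrap between-cell value, nm^2
    baseline_se: float | None = None

    def __post_init__(self) -> None:
        if np.any(self.mscd < 0) or np.any(self.n_pairs < 1):
            raise ValidationError("invalid MSCD curve contents")


def _binned_lag_curve(lags: np.ndarray, sq_values: np.ndarray,
                      bin_width_s: float) -> MSCDCurve:
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be > 0")
    idx = np.floor(lags / bin_width_s).astype(int)
    n = np.bincount(idx)
    sums = np.bincount(idx, weights=sq_values)
    sums2 = np.bincount(idx, weights=sq_values ** 2)
    keep = n > 0
    bins = np.nonzero(keep)[0]
    counts = n[keep]
    means = sums[keep] / counts
    var = np.maximum(sums2[keep] / counts - means ** 2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(counts > 1, np.sqrt(var / np.maximum(counts - 1, 1)), 0.0)
    centres = (bins + 0.5) * bin_width_s
    return MSCDCurve(centres, means, counts, se)


def _all_pair_lags(times: np.ndarray, values: np.ndarray):
    """Lags and squared differences over all ordered pairs of one series."""
    i, j = np.triu_indices(len(times), k=1)
    lags = times[j] - times[i]
    if values.ndim == 1:
        sq = (values[j] - values[i]) ** 2
    else:
        sq = np.sum((values[j] - values[i]) ** 2, axis=1)
    return lags, sq


def mscd_curve(series_collection: Sequence[DistanceSeries],
               bin_width_s: float = 6.0) -> MSCDCurve:
    """Mean square change in distance vs time interval.

    Every ordered within-video pair (t, t+tau) contributes
    ``(d(t+tau) - d(t))^2``; pairs are pooled across videos (normally
    the videos of one strain) before binning into ``bin_width_s`` bins.
    Lags use actual time stamps, so sparse or irregular sampling is
    handled naturally.  Each series needs at least 2 points.
    """
    series_collection = list(series_collection)
    if not series_collection:
        raise ValidationError("empty distance-series collection")
    lags, sqs = [], []
    for s in series_collection:
        if len(s) < 2:
            raise ValidationError(f"series {s.video_id!r} has fewer than 2 points")
        lg, sq = _all_pair_lags(s.times, s.distances)
        lags.append(lg)
        sqs.append(sq)
    return _binned_lag_curve(np.concatenate(lags), np.concatenate(sqs), bin_width_s)


def mscd_for_videos(videos: Sequence[CellVideo],
                    bin_width_s: float = 6.0) -> MSCDCurve:
    return mscd_curve([distance_series(v) for v in videos], bin_width_s)


def bootstrap_baseline(series_collection: Sequence[DistanceSeries],
                       n_boot: int = 10000, seed: int = 0,
                       exclude_videos: Sequence[str] = ()) -> tuple[float, float]:
    """Between-cell MSCD baseline by bootstrap.

    Each draw picks a video uniformly, a random time point within it,
    then a *different* video uniformly and a random time point within
    that, and records the squared distance difference.  The mean over
    ``n_boot`` draws estimates the time-independent, cell-independent
    MSCD; the SE is the bootstrap standard error of that mean.
    ``exclude_videos`` removes named videos first (e.g. outlier cells
    with unusually large distances).
    """
    excluded = set(exclude_videos)
    series = [s for s in series_collection if s.video_id not in excluded and len(s)]
    if len(series) < 2:
        raise ValidationError("bootstrap baseline needs >= 2 non-empty videos")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    n_videos = len(series)
    vi = rng.integers(0, n_videos, size=n_boot)
    vj = rng.integers(0, n_videos - 1, size=n_boot)
    vj[vj >= vi] += 1  # uniform over videos different from vi
    draws = np.empty(n_boot)
    for k in range(n_boot):
        a = series[vi[k]].distances
        b = series[vj[k]].distances
        draws[k] = a[rng.integers(0, len(a))] - b[rng.integers(0, len(b))]
    sq = draws ** 2
    se = float(sq.std(ddof=1) / math.sqrt(n_boot)) if n_boot > 1 else 0.0
    return float(sq.mean()), se


def plateau_estimate(curve: MSCDCurve, t_min_s: float = 150.0) -> float:
    """Count-weighted mean of MSCD bins with centre >= ``t_min_s``."""
    keep = curve.bin_centres >= t_min_s
    if not np.any(keep):
        raise ValidationError(f"no MSCD bins with centre >= {t_min_s} s")
    w = curve.n_pairs[keep]
    return float(np.sum(curve.mscd[keep] * w) / np.sum(w))


def msd_curve(position_series: Sequence[tuple[np.ndarray, np.ndarray]],
              bin_width_s: float = 6.0) -> MSCDCurve:
    """Per-locus mean square displacement vs time interval.

    ``position_series`` is a sequence of ``(times, positions)`` pairs
    with positions of shape (T, 3); MSD(tau) = mean |p(t+tau) - p(t)|^2
    over all within-video ordered pairs, binned as in
    :func:`mscd_curve`.
    """
    position_series = list(position_series)
    if not position_series:
        raise ValidationError("empty position-series collection")
    lags, sqs = [], []
    for times, pos in position_series:
        times = np.asarray(times, dtype=float)
        pos = np.asarray(pos, dtype=float)
        if len(times) < 2:
            raise ValidationError("each position series needs >= 2 points")
        lg, sq = _all_pair_lags(times, pos)
        lags.append(lg)
        sqs.append(sq)
    return _binned_lag_curve(np.concatenate(lags), np.concatenate(sqs), bin_width_s)


def msd_for_videos(videos: Sequence[CellVideo], channel: str,
                   bin_width_s: float = 6.0) -> MSCDCurve:
    return msd_curve([(v.times, v.positions(channel)) for v in videos], bin_width_s)
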