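"""Mother/daughter chromatin-configuration inheritance test.

In budding yeast, mother and daughter cells stay attached after
division, so related pairs can be identified directly.  If chromatin
configuration were inherited, the compaction of a locus in a daughter
would resemble its own mother's more than a random mother's.  The test
compares log2 compaction ratios of related mother/daughter pairs
against randomly drawn unrelated pairs with a Mann-Whitney rank-sum
test: inheritance would make the *magnitudes* of the related ratios
stochastically smaller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .io import CellVideo, StrainSpec, ValidationError
from .geometry import compaction_ratio, distance_series

PAIR_MODES = ("mother-daughter", "mother-mother", "daughter-daughter")


def _strain_map(strain_specs) -> dict[str, StrainSpec]:
    if isinstance(strain_specs, dict):
        return strain_specs
    return {s.strain_id: s for s in strain_specs}


def video_compaction(video: CellVideo, strain_specs, stat: str = "mean") -> float:
    """Per-video compaction: mean (or median) of per-frame ratios 0.34*z/d."""
    spec = _strain_map(strain_specs).get(video.strain_id)
    if spec is None:
        raise ValidationError(f"no strain spec for {video.strain_id!r}")
    d = distance_series(video).distances
    if d.size == 0:
        raise ValidationError(f"video {video.video_id!r} has no retained frames")
    if np.any(d <= 0):
        raise ValidationError(f"video {video.video_id!r} has zero distances")
    ratios = compaction_ratio(spec.z_effective_bp, d)
    if stat == "mean":
        return float(np.mean(ratios))
    if stat == "median":
        return float(np.median(ratios))
    raise ValueError("stat must be 'mean' or 'median'")


def log2_compaction_ratios(pairs: Sequence[tuple[CellVideo, CellVideo]],
                           strain_specs, stat: str = "mean") -> list[float]:
    """log2(compaction_A / compaction_B) for each (A, B) video pair.

    The first element of each pair (the mother, for related pairs) goes
    in the numerator.  Both videos of a pair must be from the same
    strain, so the genomic separation cancels and the ratio compares
    measured distances only.
    """
    out = []
    for a, b in pairs:
        if a.strain_id != b.strain_id:
            raise ValidationError(
                f"pair ({a.video_id}, {b.video_id}) mixes strains "
                f"{a.strain_id!r} and {b.strain_id!r}")
        ca = video_compaction(a, strain_specs, stat)
        cb = video_compaction(b, strain_specs, stat)
        out.append(math.log2(ca / cb))
    return out


def related_pairs(videos: Sequence[CellVideo]) -> list[tuple[CellVideo, CellVideo]]:
    """(mother, daughter) video pairs from lineage metadata."""
    by_pair: dict[str, dict[str, CellVideo]] = {}
    for v in videos:
        if v.pair_id is not None:
            by_pair.setdefault(v.pair_id, {})[v.role] = v
    pairs = []
    for pair_id in sorted(by_pair):
        members = by_pair[pair_id]
        if "mother" in members and "daughter" in members:
            pairs.append((members["mother"], members["daughter"]))
    return pairs


def random_unrelated_pairs(mothers: Sequence[CellVideo],
                           daughters: Sequence[CellVideo],
                           n_pairs: int, seed: int,
                           mode: str = "mother-daughter"
                           ) -> list[tuple[CellVideo, CellVideo]]:
    """Seeded random unrelated pairs, drawn with replacement.

    ``mode='mother-daughter'`` draws mother x daughter pairs excluding
    true lineage pairs; the same-role modes draw mother/mother or
    daughter/daughter pairs of distinct cells.  Raises if no valid
    combination exists (e.g. a single related mother/daughter couple).
    """
    if mode not in PAIR_MODES:
        raise ValueError(f"mode must be one of {PAIR_MODES}")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if mode == "mother-daughter":
        pool_a, pool_b = list(mothers), list(daughters)
        valid = [(i, j) for i in range(len(pool_a)) for j in range(len(pool_b))
                 if pool_a[i].pair_id is None
                 or pool_a[i].pair_id != pool_b[j].pair_id]
    else:
        pool = list(mothers) if mode == "mother-mother" else list(daughters)
        pool_a = pool_b = pool
        valid = [(i, j) for i, j in combinations(range(len(pool)), 2)]
    if not valid:
        raise ValidationError(f"no unrelated {mode} combinations available")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(valid), size=n_pairs)
    return [(pool_a[valid[k][0]], pool_b[valid[k][1]]) for k in picks]


# ---------------------------------------------------------------------------
# Mann-Whitney rank-sum test

_EXACT_LIMIT = 12  # combined sample size up to which the exact branch runs


def _u_statistic(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(U_a, U_b): number of wins of each sample, ties counting half."""
    n_a, n_b = len(a), len(b)
    ranks = rankdata(np.concatenate([a, b]))
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2.0
    return u_a, n_a * n_b - u_a


def mann_whitney_exact(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test.

    Returns ``(U, p)`` with U the smaller of the two U statistics.  The
    p-value is computed by exact enumeration of all rank arrangements
    when the combined sample size is at most 12 and there are no ties;
    otherwise by the normal approximation with tie correction and
    continuity correction.  Degenerate inputs with zero rank variance
    (e.g. two identical constant samples) return p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    n_a, n_b = len(a), len(b)
    u_a, u_b = _u_statistic(a, b)
    u = min(u_a, u_b)
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    if n_a + n_b <= _EXACT_LIMIT and not has_ties:
        # exact null distribution of U_a over all C(n_a+n_b, n_a)
        # equally likely rank assignments
        mid = n_a * n_b / 2.0
        observed_dev = abs(u_a - mid)
        total = hits = 0
        values = np.sort(combined)
        for idx in combinations(range(n_a + n_b), n_a):
            perm_a = values[list(idx)]
            perm_u, _ = _u_statistic(perm_a, np.delete(values, list(idx)))
            total += 1
            if abs(perm_u - mid) >= observed_dev - 1e-12:
                hits += 1
        return u, hits / total
    # normal approximation with tie correction
    n = n_a + n_b
    _, counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 1.0
    z = (abs(u_a - n_a * n_b / 2.0) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * float(norm.sf(z))
    return u, min(p, 1.0)


@dataclass
class InheritanceResult:
    """Related vs unrelated mother/daughter compaction comparison."""

    related_log2_ratios: list[float]
    unrelated_log2_ratios: list[float]
    U_abs: float          # Mann-Whitney U on |log2 ratios| (primary)
    p_abs: float
    U_signed: float       # Mann-Whitney U on signed log2 ratios
    p_signed: float
    n_related: int
    n_unrelated: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p_abs <= 1.0 and 0.0 < self.p_signed <= 1.0):
            raise ValidationError("p-values must be in (0, 1]")
        if self.n_related != len(self.related_log2_ratios) or \
                self.n_unrelated != len(self.unrelated_log2_ratios):
            raise ValidationError("counts do not match ratio lists")


def inheritance_test(population_videos: Sequence[CellVideo], strain_specs,
                     n_unrelated: int | None = None, seed: int = 0,
                     stat: str = "mean") -> InheritanceResult:
    """Test whether related mother/daughter pairs share compaction.

    Related pairs come from lineage metadata; unrelated mother x
    daughter pairs are drawn at random (count matched to the related
    pairs unless ``n_unrelated`` is given).  The Mann-Whitney test is
    run on the |log2 ratio| magnitudes (primary: inheritance shrinks
    the magnitude of the related ratios) and on the signed ratios; both
    results are reported.
    """
    videos = [v for v in population_videos if v.n_frames > 0]
    rel = related_pairs(videos)
    if not rel:
        raise ValidationError("no related mother/daughter pairs in population")
    mothers = [v for v in videos if v.role == "mother"]
    daughters = [v for v in videos if v.role == "daughter"]
    n_unrel = len(rel) if n_unrelated is None else n_unrelated
    unrel = random_unrelated_pairs(mothers, daughters, n_unrel, seed)
    related_ratios = log2_compaction_ratios(rel, strain_specs, stat)
    unrelated_ratios = log2_compaction_ratios(unrel, strain_specs, stat)
    u_abs, p_abs = mann_whitney_exact(np.abs(related_ratios), np.abs(unrelated_ratios))
    u_signed, p_signed = mann_whitney_exact(related_ratios, unrelated_ratios)
    return InheritanceResult(
        related_log2_ratios=list(related_ratios),
        unrelated_log2_ratios=list(unrelated_ratios),
        U_abs=u_abs, p_abs=p_abs, U_signed=u_signed, p_signed=p_signed,
        n_related=len(related_ratios), n_unrelated=len(unrelated_ratios),
        seed=seed)
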