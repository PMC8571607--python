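"""Within-community sequence-similarity test against a database null.

If endosymbionts spread mostly by horizontal transfer inside one
ecological community, the strains sampled there should be more similar to
each other than a random draw of equally many strains from the global
pool.  The test: compute the community's mean pairwise corrected
distance over its m strain pairs, then build a null by repeatedly
drawing m pairwise distances at random from the full database pool
(10,000 iterations by default) and recording each draw's mean.  The
empirical lower-tail probability uses the add-one rule and a Wilcoxon
rank-sum comparison (normal approximation with continuity correction) of
the community distances against the null means is reported alongside.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .seqdist import DistanceMatrix, distance_matrix, mean_pairwise

__all__ = [
    "DistancePool",
    "SimilarityResult",
    "resample_null",
    "similarity_test",
    "wilcoxon_rank_sum",
]


@dataclass
class DistancePool:
    """Flat pool of pairwise distances with pair provenance."""

    distances: np.ndarray
    pairs: list[tuple[str, str]]
    source: str = "database"

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.ndim != 1:
            raise ValueError("distance pool must be one-dimensional")
        if not np.all(np.isfinite(self.distances)):
            raise ValueError("distance pool contains non-finite entries")
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")

    @classmethod
    def from_matrix(cls, matrix: DistanceMatrix, source: str = "database",
                    exclude_invalid: bool = True) -> "DistancePool":
        pairs, dists = [], []
        for i in range(matrix.n):
            for j in range(i + 1, matrix.n):
                v = matrix.values[i, j]
                if math.isnan(v):
                    if not exclude_invalid:
                        raise ValueError("saturated pair in pool input")
                    continue
                pairs.append((matrix.labels[i], matrix.labels[j]))
                dists.append(v)
        return cls(np.array(dists), pairs, source)

    def __len__(self) -> int:
        return int(self.distances.size)


def resample_null(
    pool: DistancePool,
    m: int,
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
    replace: bool = False,
) -> np.ndarray:
    """Null distribution of means of m distances drawn from the pool.

    Each of the B iterations draws m distances uniformly without
    replacement (within the iteration) and records their mean.  Drawing
    with replacement is only available behind the explicit ``replace``
    flag and is logged.
    """
    M = len(pool)
    if not 1 <= m:
        raise ValueError("m must be >= 1")
    if m > M and not replace:
        raise ValueError(
            f"cannot draw {m} distances from a pool of {M} without replacement"
        )
    if replace:
        warnings.warn("resampling with replacement (explicit override)",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    means = np.empty(B)
    for b in range(B):
        idx = rng.choice(M, size=m, replace=replace)
        means[b] = pool.distances[idx].mean()
    return means


def wilcoxon_rank_sum(
    x, y, continuity: bool = True
) -> tuple[float, float, float]:
    """Two-sided rank-sum test via the normal approximation.

    Returns ``(W, z, p)`` where W is the rank sum of ``x`` (average ranks
    for ties), z uses the tie-corrected variance and a 0.5 continuity
    correction, and p is two-sided.  Degenerate input (all values equal
    across both samples) yields p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    W = float(ranks[:n1].sum())
    mu = n1 * (n1 + n2 + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    N = n1 + n2
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        warnings.warn("degenerate rank-sum input (all values tied)",
                      stacklevel=2)
        return W, 0.0, 1.0
    diff = W - mu
    if continuity:
        diff -= 0.5 * np.sign(diff)
    z = diff / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return W, float(z), float(min(p, 1.0))


@dataclass
class SimilarityResult:
    """Community mean, resampled null, and the associated probabilities."""

    community_mean: float
    m: int
    B: int
    null_means: np.ndarray
    p_lower: float
    p_upper: float
    W: float
    z: float
    p_ranksum: float
    alpha: float
    verdict: str
    community_pairs: DistancePool | None = field(default=None, repr=False)

    @property
    def expected_mean(self) -> float:
        return float(self.null_means.mean())

    def as_dict(self) -> dict:
        return {
            "community_mean": self.community_mean,
            "expected_mean": self.expected_mean,
            "m": self.m,
            "B": self.B,
            "p_lower": self.p_lower,
            "p_upper": self.p_upper,
            "W": self.W,
            "z": self.z,
            "p_ranksum": self.p_ranksum,
            "alpha": self.alpha,
            "verdict": self.verdict,
        }


def similarity_test(
    community: dict[str, str],
    database: dict[str, str],
    B: int = 10_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    model: str = "jc",
) -> SimilarityResult:
    """Test whether community strains are unusually similar to each other.

    ``community`` and ``database`` map strain ids to aligned sequences of
    one marker (or a concatenation).  Database strains whose sequence
    exactly matches a community strain are removed from the database pool
    before resampling.  Primary inference is the empirical lower/upper
    tail probability of the community mean under the resampled null
    (add-one rule); the rank-sum of the m community distances against the
    B null means is reported alongside.
    """
    if len(community) < 2:
        raise ValueError("need at least two community strains")
    community_seqs = set(community.values())
    db = {k: v for k, v in database.items() if v not in community_seqs}
    n_dropped = len(database) - len(db)
    if n_dropped:
        warnings.warn(
            f"removed {n_dropped} database strain(s) identical to community "
            "strains before building the null pool",
            stacklevel=2,
        )
    if len(db) <= len(community):
        raise ValueError("database must be strictly larger than the community")

    cm = distance_matrix(community, model=model)
    community_pool = DistancePool.from_matrix(cm, source="community")
    if cm.invalid_pairs:
        warnings.warn(
            f"excluded {len(cm.invalid_pairs)} saturated community pair(s)",
            stacklevel=2,
        )
    community_mean = mean_pairwise(cm, exclude_invalid=bool(cm.invalid_pairs))
    m = len(community_pool)

    dbm = distance_matrix(db, model=model)
    db_pool = DistancePool.from_matrix(dbm, source="database")
    null_means = resample_null(db_pool, m=m, B=B, seed=seed)

    p_lower = (1 + int((null_means <= community_mean).sum())) / (1 + B)
    p_upper = (1 + int((null_means >= community_mean).sum())) / (1 + B)
    W, z, p_rs = wilcoxon_rank_sum(community_pool.distances, null_means)

    if p_lower <= alpha:
        verdict = "lower"
    elif p_upper <= alpha:
        verdict = "higher"
    else:
        verdict = "indistinct"
    return SimilarityResult(
        community_mean=float(community_mean),
        m=m,
        B=B,
        null_means=null_means,
        p_lower=p_lower,
        p_upper=p_upper,
        W=W,
        z=z,
        p_ranksum=p_rs,
        alpha=alpha,
        verdict=verdict,
        community_pairs=community_pool,
    )
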