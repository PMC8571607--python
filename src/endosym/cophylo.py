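"""Host-symbiont phylogenetic congruence statistics.

Three complementary tests of whether symbiont relatedness tracks host
relatedness, all operating on labelled distance matrices and a binary
host x symbiont link matrix (one-to-one here, single infections):

* Mantel correlation (Spearman by default) between the two distance
  matrices, permutation p-value, one-sided upper tail by default
  (directional hypothesis of positive association);
* the ParaFit global fourth-corner statistic with per-link tests;
* a Procrustes superimposition of the symbiont principal-coordinate
  configuration onto the host configuration, whose residual sum of
  squares m2_xy is small when the two phylogenies are congruent.

The three statistics answer subtly different questions and can disagree;
all are reported, none is reconciled against the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .seqdist import DistanceMatrix

__all__ = [
    "LinkSet",
    "CongruenceResult",
    "mantel",
    "pcoa",
    "parafit",
    "paco",
]

_EPS = 1e-8


@dataclass
class LinkSet:
    """Binary host x symbiont association matrix."""

    hosts: list[str]
    symbionts: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        if self.matrix.shape != (len(self.hosts), len(self.symbionts)):
            raise ValueError("link matrix shape does not match labels")
        if not set(np.unique(self.matrix)) <= {0, 1}:
            raise ValueError("link matrix must be binary")
        if np.any(self.matrix.sum(axis=0) == 0):
            raise ValueError("every symbiont must link to at least one host")

    @classmethod
    def one_to_one(cls, pairs: list[tuple[str, str]]) -> "LinkSet":
        hosts = [h for h, _ in pairs]
        symbs = [s for _, s in pairs]
        return cls(hosts, symbs, np.eye(len(pairs), dtype=int))

    @property
    def links(self) -> list[tuple[str, str]]:
        hs, ss = np.nonzero(self.matrix)
        return [(self.hosts[i], self.symbionts[j]) for i, j in zip(hs, ss)]


@dataclass
class CongruenceResult:
    method: str
    statistic: float
    p: float
    n_perm: int
    per_link: list[dict] = field(default_factory=list)
    extra: dict = field(default_factory=dict)


def _check_aligned(dx: DistanceMatrix, dy: DistanceMatrix) -> None:
    if dx.labels != dy.labels:
        raise ValueError("distance matrices must carry identical label order")


def mantel(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
    alternative: str = "greater",
) -> CongruenceResult:
    """Matrix correlation with a permutation test.

    The statistic is the (Spearman or Pearson) correlation of the strict
    upper triangles; the null permutes rows and columns of ``dy``
    jointly.  ``alternative`` is ``"greater"`` (default, positive
    association) or ``"two-sided"``.
    """
    _check_aligned(dx, dy)
    n = dx.n
    if n < 3:
        raise ValueError("Mantel test needs >= 3 labels")
    corr = {"spearman": stats.spearmanr, "pearson": stats.pearsonr}[method]
    iu = np.triu_indices(n, k=1)
    vx = dx.values[iu]

    def _stat(mat: np.ndarray) -> float:
        return float(corr(vx, mat[iu])[0])

    r_obs = _stat(dy.values)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = _stat(dy.values[np.ix_(perm, perm)])
        if alternative == "greater":
            hits += r_p >= r_obs
        else:
            hits += abs(r_p) >= abs(r_obs)
    p = (1 + hits) / (1 + n_perm)
    return CongruenceResult("mantel", r_obs, p, n_perm)


def pcoa(
    d: DistanceMatrix | np.ndarray, correction: str = "cailliez"
) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinates embedding of a distance matrix.

    Returns ``(coordinates, eigenvalues)`` keeping axes with positive
    eigenvalues.  For non-Euclidean input (smallest eigenvalue below
    -1e-8) the Cailliez constant is added to all off-diagonal distances
    first, making the matrix embeddable.
    """
    D = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("input must be a symmetric square matrix")
    n = D.shape[0]

    def _center(dist: np.ndarray) -> np.ndarray:
        A = -0.5 * dist**2
        J = np.eye(n) - np.ones((n, n)) / n
        return J @ A @ J

    G = _center(D)
    eigvals = np.linalg.eigvalsh(G)
    if correction == "cailliez" and eigvals.min() < -_EPS:
        D = D + _cailliez_constant(D) * (1 - np.eye(n))
        G = _center(D)
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > _EPS
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    return coords, vals[keep]


def _cailliez_constant(D: np.ndarray) -> float:
    """Smallest additive constant making D (off-diagonal) Euclidean."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    d1 = J @ (-0.5 * D**2) @ J
    d2 = J @ (-0.5 * D) @ J
    special = np.block([
        [np.zeros((n, n)), 2.0 * d1],
        [-np.eye(n), -4.0 * d2],
    ])
    eig = np.linalg.eigvals(special)
    c = float(np.max(eig.real))
    return max(c, 0.0)


def _pcoa_for_tests(d: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    coords, vals = pcoa(d)
    if coords.size == 0 or np.allclose(coords, 0):
        raise ValueError("degenerate principal-coordinate configuration")
    return coords, vals


def parafit(
    dh: DistanceMatrix,
    dp: DistanceMatrix,
    links: LinkSet,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    test_links: bool = False,
) -> CongruenceResult:
    """Global fourth-corner test of host-symbiont association.

    The statistic is the sum of squares of B^T.HP.C where B and C are the
    principal coordinates of hosts and symbionts and HP the binary link
    matrix; the null shuffles each symbiont's host assignments (within
    each HP column).  Per-link statistics (optional) are the drop in the
    global statistic when a link is removed (link-1) and that drop scaled
    by ``tracemax - global`` (link-2).
    """
    if links.hosts != dh.labels or links.symbionts != dp.labels:
        raise ValueError("link labels must match distance-matrix labels")
    B, lh = _pcoa_for_tests(dh)
    C, lp = _pcoa_for_tests(dp)
    tracemax = max(float((lh**2).sum()), float((lp**2).sum()))
    HP = links.matrix

    def _global(hp: np.ndarray) -> float:
        return float(((B.T @ hp @ C) ** 2).sum())

    g_obs = _global(HP)
    rng = np.random.default_rng(seed)

    def _perm_columns(hp: np.ndarray, r: np.random.Generator) -> np.ndarray:
        out = hp.copy()
        for j in range(out.shape[1]):
            out[:, j] = out[r.permutation(out.shape[0]), j]
        return out

    hits = 0
    perm_rngs_state = rng.bit_generator.state
    for _ in range(n_perm):
        hits += _global(_perm_columns(HP, rng)) >= g_obs
    p = (1 + hits) / (1 + n_perm)

    per_link: list[dict] = []
    if test_links:
        den = tracemax - g_obs
        for (i, j) in zip(*np.nonzero(HP)):
            hp_k = HP.copy()
            hp_k[i, j] = 0
            g_k = _global(hp_k)
            stat1 = g_obs - g_k
            stat2 = stat1 / den if den > _EPS else np.nan
            r = np.random.default_rng()
            r.bit_generator.state = perm_rngs_state
            hits1 = 0
            for _ in range(n_perm):
                hp_kp = _perm_columns(hp_k, r)
                g_kp = _global(hp_kp)
                hits1 += (g_obs - g_kp) >= stat1  # larger drop => link matters
            per_link.append({
                "host": links.hosts[i],
                "symbiont": links.symbionts[j],
                "link1": stat1,
                "link2": stat2,
                "p_link1": (1 + hits1) / (1 + n_perm),
            })
    return CongruenceResult(
        "parafit", g_obs, p, n_perm, per_link=per_link,
        extra={"tracemax": tracemax},
    )


def _procrustes_residual(X: np.ndarray, Y: np.ndarray) -> float:
    """Least-squares residual of fitting Y onto X (rotation + scaling).

    Both configurations are column-centred; Y is rotated and scaled to
    minimise the sum of squared differences from X (host-dependent
    orientation, not the symmetric variant).
    """
    k = max(X.shape[1], Y.shape[1])
    Xp = np.pad(X, ((0, 0), (0, k - X.shape[1])))
    Yp = np.pad(Y, ((0, 0), (0, k - Y.shape[1])))
    Xc = Xp - Xp.mean(axis=0)
    Yc = Yp - Yp.mean(axis=0)
    ss_x = float((Xc**2).sum())
    ss_y = float((Yc**2).sum())
    if ss_y < _EPS:
        return ss_x
    sv = np.linalg.svd(Yc.T @ Xc, compute_uv=False)
    return ss_x - float(sv.sum()) ** 2 / ss_y


def paco(
    dh: DistanceMatrix,
    dp: DistanceMatrix,
    links: LinkSet,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> CongruenceResult:
    """Procrustes test of cophylogeny (residual m2_xy).

    Host and symbiont distance matrices are embedded by principal
    coordinates, expanded to one row per host-symbiont link, and the
    symbiont configuration is superimposed onto the host configuration by
    least squares.  The residual sum of squares m2_xy measures
    incongruence; the permutation null shuffles which symbiont occupies
    each link, and p counts permuted residuals <= the observed one.
    """
    if links.hosts != dh.labels or links.symbionts != dp.labels:
        raise ValueError("link labels must match distance-matrix labels")
    H, _ = _pcoa_for_tests(dh)
    P, _ = _pcoa_for_tests(dp)
    hi, pi = np.nonzero(links.matrix)
    X = H[hi]
    m2_obs = _procrustes_residual(X, P[pi])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += _procrustes_residual(X, P[rng.permutation(pi)]) <= m2_obs
    p = (1 + hits) / (1 + n_perm)
    return CongruenceResult("paco", m2_obs, p, n_perm)
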