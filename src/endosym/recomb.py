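"""Recombination screens for multilocus strain data.

Four complementary detectors:

* the pairwise homoplasy index (PHI): mean refined incompatibility of
  nearby parsimony-informative sites, significant (low) values meaning
  nearby sites are more compatible than expected under free shuffling of
  site order — the signature of recombination;
* a MaxChi-style scan: per sequence pair, a sliding window over variable
  sites maximising the 2x2 chi-square of match/mismatch counts left vs
  right of a candidate breakpoint, with a permutation null of the
  maximum (columns shuffled) controlling multiplicity across positions;
* a supergroup-conflict screen: a strain whose concatenated-level clade
  assignment disagrees with one locus's assignment (both confidently)
  carries a between-clade recombinant segment;
* a shared-ST screen flagging identical sequence types carried by hosts
  from divergent taxa — whole-strain horizontal transfer.

Breakpoints are reported in the 1-based concatenated coordinate frame
and mapped to loci when a concatenation map is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .mlst import ReferenceStrain, StrainProfile, assign_supergroup
from .seqdist import ConcatenationMap

__all__ = [
    "PhiResult",
    "RecombinationEvent",
    "ConflictRecord",
    "phi_test",
    "maxchi_scan",
    "supergroup_conflict_screen",
    "shared_st_screen",
]


@dataclass(frozen=True)
class PhiResult:
    phi: float
    p: float
    n_informative: int
    testable: bool


def _alignment_array(alignment: dict[str, str]) -> tuple[list[str], np.ndarray]:
    labels = list(alignment)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment sequences differ in length")
    arr = np.array(
        [np.frombuffer(alignment[l].upper().encode(), dtype="S1") for l in labels]
    )
    return labels, arr


def _informative_columns(arr: np.ndarray) -> np.ndarray:
    """Indices of parsimony-informative columns (>=2 states, each >=2 seqs),
    ignoring non-ACGT symbols."""
    cols = []
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype="S1"))
    for j in range(arr.shape[1]):
        col = arr[valid[:, j], j]
        if col.size < 4:
            continue
        _, counts = np.unique(col, return_counts=True)
        if (counts >= 2).sum() >= 2:
            cols.append(j)
    return np.array(cols, dtype=int)


def _incompatibility(col_i: np.ndarray, col_j: np.ndarray) -> int:
    """Refined incompatibility score between two sites.

    Build the bipartite graph whose vertices are the observed states at
    each site and whose edges are the observed joint state pairs; the
    score is the graph's cycle count e - v + c, zero iff the two sites
    are compatible on a single tree without homoplasy.
    """
    ok = np.isin(col_i, np.frombuffer(b"ACGT", dtype="S1")) & np.isin(
        col_j, np.frombuffer(b"ACGT", dtype="S1")
    )
    pairs = {(a, b) for a, b in zip(col_i[ok], col_j[ok])}
    verts: dict[tuple[int, bytes], int] = {}
    parent: list[int] = []

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def vert(key: tuple[int, bytes]) -> int:
        if key not in verts:
            verts[key] = len(parent)
            parent.append(len(parent))
        return verts[key]

    e = 0
    for a, b in pairs:
        u, v = vert((0, a)), vert((1, b))
        e += 1
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    c = len({find(i) for i in range(len(parent))})
    return e - len(parent) + c


def phi_test(
    alignment: dict[str, str],
    window: int = 100,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> PhiResult:
    """Pairwise homoplasy index over informative-site pairs within a window.

    The statistic is the mean refined incompatibility over pairs of
    parsimony-informative sites at most ``window`` apart in
    informative-site order.  The null permutes informative-site order;
    p counts permuted means <= the observed one (add-one rule).  With
    fewer than two informative sites the data are not testable.
    """
    if len(alignment) < 4:
        raise ValueError("PHI needs at least four sequences")
    _, arr = _alignment_array(alignment)
    info = _informative_columns(arr)
    k = info.size
    if k < 2:
        return PhiResult(float("nan"), float("nan"), int(k), False)
    cols = [arr[:, j] for j in info]
    # incompatibility is symmetric in the two columns; cache all pairs once
    score = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            score[i, j] = score[j, i] = _incompatibility(cols[i], cols[j])

    def mean_nearby(order: np.ndarray) -> float:
        total = 0.0
        count = 0
        for a in range(k):
            upper = min(a + window, k - 1)
            for b in range(a + 1, upper + 1):
                total += score[order[a], order[b]]
                count += 1
        return total / count if count else 0.0

    identity = np.arange(k)
    phi_obs = mean_nearby(identity)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += mean_nearby(rng.permutation(k)) <= phi_obs
    p = (1 + hits) / (1 + n_perm)
    return PhiResult(float(phi_obs), float(p), int(k), True)


@dataclass
class RecombinationEvent:
    """One detected breakpoint region in the concatenated frame."""

    pair: tuple[str, str]
    start: int  # 1-based inclusive, concatenated coordinates
    end: int
    breakpoint: int  # best single position
    loci: list[str] = field(default_factory=list)
    methods: list[str] = field(default_factory=lambda: ["maxchi"])
    p: float = float("nan")
    chi2: float = float("nan")


def _max_chi2(diff: np.ndarray, w: int) -> tuple[float, int]:
    """Maximum 2x2 chi-square over breakpoints of a 2w sliding window.

    ``diff`` is the boolean mismatch vector over the scanned sites; the
    window spans w sites either side of each candidate breakpoint.
    Returns (max chi2, index of the site right of the best breakpoint).
    """
    n = diff.size
    best, best_at = 0.0, w
    cum = np.concatenate([[0], np.cumsum(diff)])
    for cut in range(w, n - w + 1):
        l_mis = cum[cut] - cum[cut - w]
        r_mis = cum[cut + w] - cum[cut]
        # 2x2 table: rows left/right, cols mismatch/match
        a, b = l_mis, w - l_mis
        c, d = r_mis, w - r_mis
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        if denom == 0:
            continue
        chi2 = 2 * w * (a * d - b * c) ** 2 / denom
        if chi2 > best:
            best, best_at = chi2, cut
    return best, best_at


def maxchi_scan(
    alignment: dict[str, str],
    concat_map: ConcatenationMap | None = None,
    half_window: int = 100,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> list[RecombinationEvent]:
    """Sliding-window chi-square breakpoint scan over all sequence pairs.

    For each pair the scan runs over the alignment's variable sites; the
    observed maximum chi-square is compared against a permutation null
    built by shuffling site order (the null of the *maximum*, so the
    family-wise error across candidate positions is controlled).  Pairs
    whose maximum exceeds the null at ``alpha`` yield one event, with the
    breakpoint mapped back to 1-based alignment coordinates and to loci
    when a concatenation map is given.
    """
    if len(alignment) < 3:
        raise ValueError("breakpoint scan needs >= 3 sequences")
    labels, arr = _alignment_array(alignment)
    variable = np.array(
        [len(set(arr[:, j])) > 1 for j in range(arr.shape[1])], dtype=bool
    )
    var_idx = np.nonzero(variable)[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events: list[RecombinationEvent] = []
    for (ia, a), (ib, b) in combinations(enumerate(labels), 2):
        diff = (arr[ia, var_idx] != arr[ib, var_idx]).astype(int)
        n = diff.size
        w = half_window
        if n < 2 * w:
            w = max(n // 2, 2)
        if n < 2 * w or diff.sum() == 0:
            continue
        chi2_obs, cut = _max_chi2(diff, w)
        if chi2_obs == 0:
            continue
        hits = 0
        for _ in range(n_perm):
            chi2_p, _ = _max_chi2(rng.permutation(diff), w)
            hits += chi2_p >= chi2_obs
        p = (1 + hits) / (1 + n_perm)
        if p > alpha:
            continue
        # breakpoint lies between variable sites cut-1 and cut
        left = int(var_idx[cut - 1]) + 1
        right = int(var_idx[cut]) + 1 if cut < n else int(var_idx[-1]) + 1
        bp = (left + right) // 2
        loci: list[str] = []
        if concat_map is not None:
            loci = sorted(
                {concat_map.locus_of(pos)[0] for pos in (left, right)},
                key=lambda l: concat_map.spans[l][0],
            )
        events.append(
            RecombinationEvent(
                pair=(a, b), start=left, end=right, breakpoint=bp,
                loci=loci, methods=["maxchi"], p=p, chi2=float(chi2_obs),
            )
        )
    return events


@dataclass
class ConflictRecord:
    strain: str
    concatenated_label: str
    per_locus_labels: dict[str, str]
    conflicting_loci: list[str]


def supergroup_conflict_screen(
    strain_seqs: dict[str, dict[str, str]],
    references: list[ReferenceStrain],
    threshold: float = 0.005,
) -> list[ConflictRecord]:
    """Flag strains whose per-locus clade assignment contradicts the
    concatenated-level one.

    A locus is conflicting only when both assignments are confident
    (margin >= ``threshold``); ambiguous calls at either level never
    create a conflict.  References must span >= 2 supergroups at every
    locus.
    """
    records: list[ConflictRecord] = []
    for strain, seqs in sorted(strain_seqs.items()):
        concat_label, concat_margin = assign_supergroup(
            seqs, references, level="concatenated", threshold=threshold
        )
        per_locus: dict[str, str] = {}
        conflicts: list[str] = []
        for locus in seqs:
            label, margin = assign_supergroup(
                seqs, references, level="per-locus", locus=locus,
                threshold=threshold,
            )
            per_locus[locus] = label
            if (
                label not in ("ambiguous", concat_label)
                and concat_label != "ambiguous"
            ):
                conflicts.append(locus)
        if conflicts:
            records.append(
                ConflictRecord(strain, concat_label, per_locus, sorted(conflicts))
            )
    return records


_RANKS = ["class", "order", "family", "genus"]
_UNKNOWN = {"", "-", "na", "NA", None}


def _divergence_rank(tax_a: dict[str, str], tax_b: dict[str, str]) -> int | None:
    """Index of the highest rank at which two taxonomies demonstrably
    differ (0 = class); None when they never demonstrably differ."""
    for i, rank in enumerate(_RANKS):
        a, b = tax_a.get(rank), tax_b.get(rank)
        if a in _UNKNOWN or b in _UNKNOWN:
            continue
        if a != b:
            return i
    return None


def shared_st_screen(
    profiles: dict[str, StrainProfile],
    min_rank_distance: str = "order",
) -> list[tuple[str, list[str]]]:
    """Sequence types carried by hosts from divergent taxa.

    Returns ``(st_label, sorted host sample ids)`` for every ST found in
    >= 2 hosts for which some host pair diverges at or above
    ``min_rank_distance`` (class > order > family > genus).
    """
    if min_rank_distance not in _RANKS:
        raise ValueError(f"unknown rank {min_rank_distance!r}")
    rank_idx = _RANKS.index(min_rank_distance)
    by_st: dict[str, list[StrainProfile]] = {}
    for prof in profiles.values():
        if prof.st_label:
            by_st.setdefault(prof.st_label, []).append(prof)
    out: list[tuple[str, list[str]]] = []
    for st, members in sorted(by_st.items()):
        if len(members) < 2:
            continue
        for pa, pb in combinations(members, 2):
            d = _divergence_rank(pa.taxonomy, pb.taxonomy)
            if d is not None and d <= rank_idx:
                out.append((st, sorted(m.sample_id for m in members)))
                break
    return out
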