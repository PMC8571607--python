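"""Pairwise nucleotide distances and distance-matrix utilities.

Distances are computed from aligned sequences with *pairwise deletion*:
for each pair, any site where either sequence carries a gap or an IUPAC
ambiguity code is dropped before counting differences.  The observed
proportion of differing sites (p-distance) can be corrected to an
expected number of substitutions per site under the one-parameter
equal-rates substitution model, d = -(3/4) ln(1 - 4p/3).  The correction
diverges as p approaches 3/4; saturated pairs are flagged rather than
capped and are excluded from mean summaries with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

__all__ = [
    "SaturationError",
    "PairwiseDistance",
    "DistanceMatrix",
    "ConcatenationMap",
    "p_distance",
    "jc_correct",
    "jc_distance",
    "concatenate",
    "distance_matrix",
    "mean_pairwise",
    "nj_tree",
]

VALID_BASES = frozenset("ACGT")


class SaturationError(ValueError):
    """Observed divergence too high for the one-parameter correction (p >= 0.75)."""


@dataclass(frozen=True)
class PairwiseDistance:
    """Observed proportion of differing sites and the count of compared sites."""

    p: float
    valid_sites: int

    @property
    def d(self) -> float:
        """Model-corrected distance in substitutions/site."""
        return jc_correct(self.p)


def _encode(seq: str) -> np.ndarray:
    """Uppercase sequence to a byte array; caller guarantees nothing else."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype="S1")


_VALID_SET = np.frombuffer(b"ACGT", dtype="S1")


def p_distance(seq_a: str, seq_b: str) -> PairwiseDistance:
    """Proportion of differing sites among jointly unambiguous sites.

    Sites where either sequence has a gap ('-') or any non-ACGT symbol are
    excluded (pairwise deletion).  Raises ``ValueError`` on unequal lengths
    or when no valid site remains.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequences differ in length: {len(seq_a)} vs {len(seq_b)}"
        )
    a = _encode(seq_a)
    b = _encode(seq_b)
    valid = np.isin(a, _VALID_SET) & np.isin(b, _VALID_SET)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no jointly valid sites; distance undefined")
    mismatches = int((a[valid] != b[valid]).sum())
    return PairwiseDistance(p=mismatches / n_valid, valid_sites=n_valid)


def jc_correct(p: float) -> float:
    """Correct an observed p-distance to substitutions/site.

    d = -(3/4) ln(1 - 4p/3); defined for 0 <= p < 0.75.
    """
    if p < 0:
        raise ValueError(f"p-distance must be non-negative, got {p}")
    if p >= 0.75:
        raise SaturationError(
            f"p = {p} >= 0.75: divergence saturated, correction undefined"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_distance(seq_a: str, seq_b: str) -> float:
    """Model-corrected distance between two aligned sequences."""
    return jc_correct(p_distance(seq_a, seq_b).p)


@dataclass(frozen=True)
class ConcatenationMap:
    """Locus spans in concatenated coordinates, 1-based inclusive."""

    spans: dict[str, tuple[int, int]]

    @property
    def total_length(self) -> int:
        return max(end for _, end in self.spans.values())

    def locus_of(self, position: int) -> tuple[str, int]:
        """Map a 1-based concatenated position to (locus, 1-based offset)."""
        for locus, (start, end) in self.spans.items():
            if start <= position <= end:
                return locus, position - start + 1
        raise ValueError(f"position {position} outside concatenated frame")

    def to_concat(self, locus: str, offset: int) -> int:
        """Map a 1-based locus offset back to the concatenated frame."""
        start, end = self.spans[locus]
        pos = start + offset - 1
        if not start <= pos <= end:
            raise ValueError(f"offset {offset} outside locus {locus!r}")
        return pos


def concatenate(
    per_locus: dict[str, dict[str, str]],
    locus_order: list[tuple[str, int]],
) -> tuple[dict[str, str], ConcatenationMap]:
    """Concatenate per-locus alignments in scheme order.

    Parameters
    ----------
    per_locus
        Mapping locus name -> {sample id -> sequence}.
    locus_order
        Ordered ``(locus_name, expected_length)`` pairs defining the frame.

    Returns the concatenated sequences (samples present at *all* loci are
    required) and the locus->span map in 1-based inclusive coordinates.
    """
    spans: dict[str, tuple[int, int]] = {}
    cursor = 1
    for name, length in locus_order:
        if name not in per_locus:
            raise ValueError(f"missing locus {name!r} in input")
        spans[name] = (cursor, cursor + length - 1)
        cursor += length
    samples = set(per_locus[locus_order[0][0]])
    for name, _ in locus_order[1:]:
        samples &= set(per_locus[name])
    concat: dict[str, str] = {}
    for sid in sorted(samples):
        parts = []
        for name, length in locus_order:
            seq = per_locus[name][sid]
            if len(seq) != length:
                raise ValueError(
                    f"sample {sid!r} locus {name!r}: length {len(seq)} != {length}"
                )
            parts.append(seq)
        concat[sid] = "".join(parts)
    return concat, ConcatenationMap(spans)


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix with per-pair valid-site counts.

    Saturated pairs (under the corrected model) hold ``nan`` and are listed
    in ``invalid_pairs``.
    """

    labels: list[str]
    values: np.ndarray
    valid_sites: np.ndarray | None = None
    invalid_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.nan_to_num(self.values),
                           np.nan_to_num(self.values.T)):
            raise ValueError("matrix is not symmetric")
        if not np.all(np.diag(self.values) == 0):
            raise ValueError("diagonal must be exactly zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def pair(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        """Strict upper triangle, row-major."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        vs = None if self.valid_sites is None else self.valid_sites[np.ix_(idx, idx)]
        keep = set(labels)
        inv = [p for p in self.invalid_pairs if p[0] in keep and p[1] in keep]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], vs, inv)


def distance_matrix(
    sequences: dict[str, str], model: str = "jc"
) -> DistanceMatrix:
    """All-pairs distance matrix under ``model`` ('p' or 'jc').

    Under 'jc', pairs at or beyond saturation are flagged invalid (nan)
    rather than raising; callers decide how to treat them.
    """
    if model not in {"p", "jc"}:
        raise ValueError(f"unknown model {model!r}")
    labels = list(sequences)
    if len(labels) < 2:
        raise ValueError("need at least two sequences")
    n = len(labels)
    values = np.zeros((n, n))
    valid = np.zeros((n, n), dtype=int)
    invalid_pairs: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            pd = p_distance(sequences[labels[i]], sequences[labels[j]])
            valid[i, j] = valid[j, i] = pd.valid_sites
            if model == "p":
                d = pd.p
            else:
                try:
                    d = jc_correct(pd.p)
                except SaturationError:
                    d = math.nan
                    invalid_pairs.append((labels[i], labels[j]))
    # keep the matrix symmetric whatever happened above
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values, valid, invalid_pairs)


def mean_pairwise(matrix: DistanceMatrix, exclude_invalid: bool = False) -> float:
    """Arithmetic mean over the strict upper triangle.

    Saturation-flagged entries raise unless ``exclude_invalid`` is set, in
    which case they are dropped with a warning.
    """
    if matrix.n < 2:
        raise ValueError("mean pairwise distance needs >= 2 labels")
    tri = matrix.condensed()
    bad = np.isnan(tri)
    if bad.any():
        if not exclude_invalid:
            raise ValueError(
                f"{int(bad.sum())} saturated pair(s) present; pass "
                "exclude_invalid=True to drop them"
            )
        warnings.warn(
            f"excluding {int(bad.sum())} saturated pair(s) from the mean",
            stacklevel=2,
        )
        tri = tri[~bad]
    if tri.size == 0:
        raise ValueError("no valid pairs to average")
    return float(tri.mean())


def nj_tree(matrix: DistanceMatrix):
    """Neighbor-joining tree (unrooted) from a distance matrix.

    Returns a ``skbio.TreeNode``; additive inputs are recovered exactly up
    to the usual NJ conventions.
    """
    if matrix.n < 3:
        raise ValueError("neighbor joining needs >= 3 labels")
    if np.isnan(matrix.values).any():
        raise ValueError("matrix contains invalid (saturated) entries")
    dm = _SkbioDM(matrix.values, ids=matrix.labels)
    return _skbio_nj(dm)
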