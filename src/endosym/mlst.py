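"""Multilocus sequence typing (MLST) bookkeeping.

Strains are characterised by exact-identity alleles at five housekeeping
loci; a sequence type (ST) is a unique five-allele combination.  Alleles
are numbered: two sequences share a number iff they are identical strings
(the MLST convention — no similarity thresholds).  Loci containing any
ambiguity code are marked missing rather than guessed at; profiles with
missing loci receive manual-style labels (``ST-N1``, ``ST-N2``, ...)
instead of an ST.

Supergroups (deep clades, here A/B/F) are assigned by nearest mean
model-corrected distance to labelled reference strains, either on the
concatenated alignment or per locus; disagreement between the two levels
is the recombination signal screened in :mod:`endosym.recomb`.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

from .seqdist import SaturationError, jc_distance

__all__ = [
    "LocusDef",
    "WOLBACHIA_SCHEME",
    "AlleleCatalog",
    "StrainProfile",
    "ReferenceStrain",
    "DiversitySummary",
    "ScreeningSummary",
    "MISSING",
    "assign_alleles",
    "assign_sts",
    "assign_supergroup",
    "diversity_summary",
    "incidence_summary",
    "detect_novel",
]

MISSING = None  # sentinel for an untypable locus


def _is_number(allele: object) -> bool:
    """Definite allele numbers are integral (python or numpy)."""
    return isinstance(allele, numbers.Integral) and not isinstance(allele, bool)

AMBIGUOUS = set("RYSWKMBDHVN-.")


@dataclass(frozen=True)
class LocusDef:
    name: str
    length: int
    order_index: int


#: Five-locus typing scheme for Wolbachia, in concatenation order.
WOLBACHIA_SCHEME: list[LocusDef] = [
    LocusDef("gatB", 369, 0),
    LocusDef("coxA", 402, 1),
    LocusDef("hcpA", 444, 2),
    LocusDef("ftsZ", 435, 3),
    LocusDef("fbpA", 429, 4),
]


class AlleleCatalog:
    """Per-locus bidirectional map between allele numbers and sequences.

    Allele numbers are unique within a locus; every allele carries a
    provenance flag (``reference`` for catalogued alleles, ``novel`` for
    alleles first seen in a query dataset).
    """

    def __init__(self, loci: list[str]) -> None:
        self._by_seq: dict[str, dict[str, int]] = {l: {} for l in loci}
        self._by_num: dict[str, dict[int, str]] = {l: {} for l in loci}
        self.provenance: dict[str, dict[int, str]] = {l: {} for l in loci}

    @property
    def loci(self) -> list[str]:
        return list(self._by_seq)

    def add(self, locus: str, seq: str, number: int | None = None,
            provenance: str = "reference") -> int:
        seq = seq.upper()
        if seq in self._by_seq[locus]:
            return self._by_seq[locus][seq]
        if number is None:
            number = max(self._by_num[locus], default=0) + 1
        if number in self._by_num[locus]:
            raise ValueError(f"allele {locus}_{number} already catalogued")
        self._by_seq[locus][seq] = number
        self._by_num[locus][number] = seq
        self.provenance[locus][number] = provenance
        return number

    def lookup(self, locus: str, seq: str) -> int | None:
        return self._by_seq[locus].get(seq.upper())

    def sequence(self, locus: str, number: int) -> str:
        return self._by_num[locus][number]

    def numbers(self, locus: str) -> list[int]:
        return sorted(self._by_num[locus])


@dataclass
class StrainProfile:
    """One typed strain: per-locus allele labels plus host taxonomy."""

    sample_id: str
    alleles: dict[str, object]  # locus -> int | "near X" str | MISSING
    st_label: str | None = None
    supergroup: str | None = None
    taxonomy: dict[str, str] = field(default_factory=dict)

    @property
    def is_complete(self) -> bool:
        """True when every locus carries a definite (integer) allele."""
        return all(_is_number(a) for a in self.alleles.values())

    @property
    def has_all_labels(self) -> bool:
        """True when every locus carries some label, partial ones included."""
        return all(a is not MISSING for a in self.alleles.values())

    def allele_tuple(self, locus_order: list[str]) -> tuple | None:
        if not self.is_complete:
            return None
        return tuple(self.alleles[l] for l in locus_order)


@dataclass(frozen=True)
class ReferenceStrain:
    """Labelled reference strain used for supergroup assignment."""

    strain_id: str
    supergroup: str
    sequences: dict[str, str]  # locus -> aligned sequence


def _is_clean(seq: str) -> bool:
    return not (set(seq.upper()) & AMBIGUOUS) and set(seq.upper()) <= set("ACGT")


def assign_alleles(
    locus_sequences: dict[str, dict[str, str]],
    catalog: AlleleCatalog,
    scheme: list[LocusDef] = WOLBACHIA_SCHEME,
) -> dict[str, StrainProfile]:
    """Assign allele numbers for every sample at every locus.

    Identical strings receive identical numbers; unseen clean sequences are
    added to the catalog with the next free number and flagged ``novel``;
    sequences containing ambiguity codes mark the locus missing.  A clean
    sequence of the wrong length is an error naming sample and locus.
    """
    defs = {d.name: d for d in scheme}
    samples: set[str] = set()
    for locus in locus_sequences:
        samples.update(locus_sequences[locus])
    profiles: dict[str, StrainProfile] = {}
    for sid in sorted(samples):
        alleles: dict[str, object] = {}
        for d in scheme:
            seq = locus_sequences.get(d.name, {}).get(sid)
            if seq is None:
                alleles[d.name] = MISSING
                continue
            seq = seq.upper()
            if not _is_clean(seq):
                alleles[d.name] = MISSING
                continue
            if len(seq) != defs[d.name].length:
                raise ValueError(
                    f"sample {sid!r}, locus {d.name!r}: sequence length "
                    f"{len(seq)} != expected {defs[d.name].length}"
                )
            num = catalog.lookup(d.name, seq)
            if num is None:
                num = catalog.add(d.name, seq, provenance="novel")
            alleles[d.name] = num
        profiles[sid] = StrainProfile(sample_id=sid, alleles=alleles)
    return profiles


def assign_sts(
    profiles: dict[str, StrainProfile],
    reference_sts: dict[tuple, str] | None = None,
    scheme: list[LocusDef] = WOLBACHIA_SCHEME,
) -> dict[str, StrainProfile]:
    """Label sequence types from complete five-allele tuples.

    Tuples present in ``reference_sts`` keep their catalogued label; new
    tuples get sequential labels above the largest reference id, ordered
    by first occurrence in canonical sample-id sort.  Profiles with any
    missing locus get manual-style labels ``ST-N1``, ``ST-N2``, ...
    """
    reference_sts = dict(reference_sts or {})
    locus_order = [d.name for d in sorted(scheme, key=lambda d: d.order_index)]

    def _st_num(label: str) -> int | None:
        tail = label.rsplit("-", 1)[-1]
        return int(tail) if tail.isdigit() else None

    next_new = 1 + max(
        (n for lbl in reference_sts.values() if (n := _st_num(lbl)) is not None),
        default=0,
    )
    seen_new: dict[tuple, str] = {}
    n_partial = 0
    for sid in sorted(profiles):
        prof = profiles[sid]
        tup = prof.allele_tuple(locus_order)
        if tup is None:
            n_partial += 1
            prof.st_label = f"ST-N{n_partial}"
            continue
        if tup in reference_sts:
            prof.st_label = reference_sts[tup]
        elif tup in seen_new:
            prof.st_label = seen_new[tup]
        else:
            prof.st_label = f"ST-{next_new}"
            seen_new[tup] = prof.st_label
            next_new += 1
    return profiles


def assign_supergroup(
    query: dict[str, str],
    references: list[ReferenceStrain],
    level: str = "concatenated",
    locus: str | None = None,
    threshold: float = 0.005,
) -> tuple[str, float]:
    """Assign a supergroup by minimal mean corrected distance to references.

    ``level`` is ``"concatenated"`` (all loci shared between the query and
    every reference) or ``"per-locus"`` (requires ``locus``).  Returns
    ``(label, margin)`` where margin is the gap between the best and
    second-best group means; the label is ``"ambiguous"`` when the margin
    falls below ``threshold`` substitutions/site.
    """
    if not references:
        raise ValueError("no reference strains supplied")
    labels = {r.supergroup for r in references}
    if len(labels) < 2:
        raise ValueError("need references from at least two supergroups")
    if level == "per-locus":
        if locus is None:
            raise ValueError("per-locus assignment requires a locus name")
        loci = [locus]
    elif level == "concatenated":
        loci = sorted(
            set(query) & set.intersection(*(set(r.sequences) for r in references))
        )
        if not loci:
            raise ValueError("query and references share no loci")
    else:
        raise ValueError(f"unknown level {level!r}")

    group_means: dict[str, float] = {}
    for label in labels:
        dists = []
        for ref in references:
            if ref.supergroup != label:
                continue
            try:
                q = "".join(query[l] for l in loci)
                r = "".join(ref.sequences[l] for l in loci)
            except KeyError:
                continue
            try:
                dists.append(jc_distance(q, r))
            except SaturationError:
                continue
        if dists:
            group_means[label] = sum(dists) / len(dists)
    if len(group_means) < 2:
        raise ValueError("fewer than two supergroups comparable to the query")
    ranked = sorted(group_means.items(), key=lambda kv: kv[1])
    best_label, best = ranked[0]
    margin = ranked[1][1] - best
    if margin < threshold:
        return "ambiguous", margin
    return best_label, margin


@dataclass(frozen=True)
class DiversitySummary:
    unique_alleles_total: int
    max_allele_slots: int
    unique_st_count: int
    per_supergroup_st_counts: dict[str, int]
    per_locus_unique_alleles: dict[str, int]


def diversity_summary(
    profiles: dict[str, StrainProfile],
    scheme: list[LocusDef] = WOLBACHIA_SCHEME,
) -> DiversitySummary:
    """Allele and ST diversity bookkeeping over fully labelled profiles.

    Partial labels ("near X") count as distinct from X — they are distinct
    observed sequences.  Profiles missing any locus label are excluded.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    locus_order = [d.name for d in sorted(scheme, key=lambda d: d.order_index)]
    full = [p for p in profiles.values() if p.has_all_labels]
    per_locus = {
        locus: len({p.alleles[locus] for p in full}) for locus in locus_order
    }
    sts = {p.st_label for p in full if p.st_label is not None}
    by_group: dict[str, set[str]] = {}
    for p in full:
        if p.st_label is not None and p.supergroup is not None:
            by_group.setdefault(p.supergroup, set()).add(p.st_label)
    return DiversitySummary(
        unique_alleles_total=sum(per_locus.values()),
        max_allele_slots=len(locus_order) * len(full),
        unique_st_count=len(sts),
        per_supergroup_st_counts={g: len(s) for g, s in sorted(by_group.items())},
        per_locus_unique_alleles=per_locus,
    )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (47/390 -> 12.05)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ScreeningSummary:
    n_screened: int
    infected_counts: dict[str, int]
    incidence_percent: dict[str, float]
    coinfection_pairs: dict[tuple[str, str], list[str]]


def incidence_summary(screen_table) -> ScreeningSummary:
    """Infection incidence from a per-morphospecies screening table.

    ``screen_table`` is a pandas DataFrame with a ``sample_id`` column and
    one boolean column per symbiont.  Incidence is 100 x infected/screened,
    rounded half-up to two decimals.
    """
    if len(screen_table) == 0:
        raise ValueError("empty screening table")
    symbionts = [c for c in screen_table.columns if c != "sample_id"]
    n = len(screen_table)
    counts = {s: int(screen_table[s].sum()) for s in symbionts}
    incidence = {s: round_half_up(100.0 * counts[s] / n) for s in symbionts}
    pairs: dict[tuple[str, str], list[str]] = {}
    for a, b in combinations(symbionts, 2):
        both = screen_table.loc[
            screen_table[a].astype(bool) & screen_table[b].astype(bool),
            "sample_id",
        ].tolist()
        if both:
            pairs[(a, b)] = both
    return ScreeningSummary(n, counts, incidence, pairs)


def detect_novel(
    profiles: dict[str, StrainProfile],
    catalog: AlleleCatalog,
    reference_sts: dict[tuple, str] | None = None,
    scheme: list[LocusDef] = WOLBACHIA_SCHEME,
) -> dict[str, object]:
    """Count alleles and STs absent from the reference catalog.

    An allele is novel iff its exact sequence was not in the reference
    catalog (``provenance == "novel"``); an ST is novel iff its complete
    five-allele tuple is absent from ``reference_sts``.  Profiles with
    missing loci are excluded from novel-ST counting.
    """
    reference_sts = reference_sts or {}
    locus_order = [d.name for d in sorted(scheme, key=lambda d: d.order_index)]
    novel_alleles = {
        locus: sorted(
            n for n, prov in catalog.provenance[locus].items() if prov == "novel"
        )
        for locus in locus_order
    }
    used: dict[str, set] = {l: set() for l in locus_order}
    novel_tuples = set()
    for prof in profiles.values():
        for locus in locus_order:
            a = prof.alleles[locus]
            if _is_number(a):
                used[locus].add(int(a))
        tup = prof.allele_tuple(locus_order)
        if tup is not None and tup not in reference_sts:
            novel_tuples.add(tup)
    per_locus = {
        l: len(set(novel_alleles[l]) & used[l]) for l in locus_order
    }
    return {
        "per_locus_novel_alleles": per_locus,
        "novel_allele_total": sum(per_locus.values()),
        "novel_st_count": len(novel_tuples),
    }
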