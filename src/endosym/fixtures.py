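"""Packaged survey tables: strain profiles, screening counts, locus registry.

The package ships a transcription of the published community survey of a
soil-arthropod site: 36 unique host-Wolbachia combinations with their
five-locus allele profiles, ST labels and supergroups; per-symbiont
screening counts over 390 morphospecies; and the five-locus amplicon
registry.  Loading is read-only and checksum-pinned.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .mlst import MISSING, LocusDef, StrainProfile

__all__ = ["SurveyTables", "load_fixtures", "load_screening_table"]

_CHECKSUMS = {
    "loci.tsv": "249dda3d5ac1c96993dd9ebb21f14a123812230a341d8229a5a339468eab7d8f",
    "wolbachia_profiles.tsv": "9f81c318bcd276bd8c6b8b5f763c6d7cb1ad04fa64f165813ce8c3723ddf56a2",
    "screening.json": "9d5f16c94e3e58049bd6c4dfb8409ce13932524e097ba48c4f5b310c03d177cc",
}


class FixtureCorruptionError(RuntimeError):
    pass


def _read_bytes(name: str) -> bytes:
    data = resources.files("endosym.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureCorruptionError(
            f"fixture {name!r} checksum mismatch: {digest}"
        )
    return data


@dataclass(frozen=True)
class SurveyTables:
    """Read-only bundle of the packaged survey tables."""

    loci: list[LocusDef]
    profiles: dict[str, StrainProfile]
    profile_table: pd.DataFrame
    screening: dict

    @property
    def locus_order(self) -> list[tuple[str, int]]:
        return [(d.name, d.length) for d in
                sorted(self.loci, key=lambda d: d.order_index)]


def _parse_allele(raw: str):
    raw = raw.strip()
    if raw in {"", "-", "missing"}:
        return MISSING
    return int(raw) if raw.isdigit() else raw  # "near X" labels stay verbatim


def load_fixtures() -> SurveyTables:
    """Load and validate the packaged tables."""
    loci_df = pd.read_csv(_io_str("loci.tsv"), sep="\t")
    loci = [
        LocusDef(r["name"], int(r["length"]), int(r["order_index"]))
        for _, r in loci_df.iterrows()
    ]
    table = pd.read_csv(
        _io_str("wolbachia_profiles.tsv"), sep="\t", dtype=str
    ).fillna("")
    if len(table) != 36:
        raise FixtureCorruptionError(f"expected 36 profile rows, got {len(table)}")
    locus_names = [d.name for d in sorted(loci, key=lambda d: d.order_index)]
    profiles: dict[str, StrainProfile] = {}
    for _, row in table.iterrows():
        alleles = {l: _parse_allele(row[l]) for l in locus_names}
        if sum(a is not MISSING for a in alleles.values()) != 5:
            raise FixtureCorruptionError(
                f"profile {row['sample_id']} lacks five allele labels"
            )
        profiles[row["sample_id"]] = StrainProfile(
            sample_id=row["sample_id"],
            alleles=alleles,
            st_label=row["st"],
            supergroup=row["supergroup"],
            taxonomy={
                "class": row["class"],
                "order": row["order"],
                "family": row["family"],
                "genus": row["genus"],
            },
        )
    screening = json.loads(_read_bytes("screening.json"))
    return SurveyTables(
        loci=loci, profiles=profiles, profile_table=table, screening=screening
    )


def _io_str(name: str):
    import io

    return io.StringIO(_read_bytes(name).decode("utf-8"))


def load_screening_table() -> pd.DataFrame:
    """Expand the screening counts into a per-morphospecies boolean table.

    The published record gives per-symbiont totals and the named
    co-infected morphospecies; the remaining infected rows are filled with
    anonymous ids.  Row identity beyond the named co-infections is
    arbitrary, but every marginal count is exact, so incidence and
    co-infection summaries are faithful.
    """
    screening = json.loads(_read_bytes("screening.json"))
    n = screening["n_screened"]
    symbionts = list(screening["infected"])
    flags: dict[str, dict[str, bool]] = {}

    def _row(sid: str) -> dict[str, bool]:
        return flags.setdefault(sid, {s: False for s in symbionts})

    for co in screening["coinfections"]:
        for sid in co["samples"]:
            for s in co["symbionts"]:
                _row(sid)[s] = True
    counter = 0
    for s in symbionts:
        have = sum(r[s] for r in flags.values())
        for _ in range(screening["infected"][s] - have):
            counter += 1
            _row(f"uninvolved{counter:04d}")[s] = True
    while len(flags) < n:
        counter += 1
        _row(f"clean{counter:04d}")
    rows = [{"sample_id": sid, **vals} for sid, vals in sorted(flags.items())]
    df = pd.DataFrame(rows)
    assert len(df) == n
    return df
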