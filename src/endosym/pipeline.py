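"""End-to-end pipeline: simulate -> type -> dist -> tests -> report.

Runs the stages in dependency order on a simulated community, records
every stage's seed and parameters, and writes a machine-readable JSON
report plus per-stage artifacts.  All randomness flows from one master
seed so a re-run with the same config reproduces the report exactly
(timestamps excluded by construction: none are recorded).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cophylo, recomb, richness, seqdist, similarity
from .fixtures import load_fixtures
from .mlst import (
    AlleleCatalog,
    assign_alleles,
    assign_sts,
    diversity_summary,
)
from .simulate import SimulationConfig, emit_dataset, simulate_transmission

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ["simulate", "type", "dist", "similarity", "congruence", "recomb"]


@dataclass
class PipelineConfig:
    out_dir: str
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    similarity_iterations: int = 10_000
    alpha: float = 0.05
    mantel_perms: int = 999
    cophylo_perms: int = 499
    recomb_perms: int = 500

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the JSON-ready report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "master_seed": config.simulation.seed,
        "stages": {},
    }
    dataset = None
    if "simulate" in config.stages:
        dataset = simulate_transmission(config.simulation)
        data_dir = emit_dataset(dataset, out / "data")
        report["stages"]["simulate"] = {
            "parameters": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in config.simulation.__dict__.items()
            },
            "n_hosts": config.simulation.n_hosts,
            "n_strains": len(set(dataset.truth.assignments.values())),
            "n_transfer_events": len(dataset.truth.transfer_log),
            "n_recomb_events": len(dataset.truth.recomb_log),
            "checksums": {
                p.name: _checksum(p) for p in sorted(data_dir.glob("*.tsv"))
            },
        }
    remaining = [s for s in config.stages if s != "simulate"]
    if remaining and dataset is None:
        raise RuntimeError("downstream stages require the simulate stage")
    if dataset is None:
        _write_report(out, report)
        return report

    loci = dataset.loci
    per_locus = {
        locus: dataset.host_locus_seqs(locus) for locus, _ in loci
    }
    concat, cmap = seqdist.concatenate(per_locus, loci)

    if "type" in config.stages:
        catalog = AlleleCatalog([l for l, _ in loci])
        from .mlst import LocusDef

        scheme = [LocusDef(l, L, i) for i, (l, L) in enumerate(loci)]
        profiles = assign_alleles(per_locus, catalog, scheme)
        profiles = assign_sts(profiles, scheme=scheme)
        div = diversity_summary(profiles, scheme)
        report["stages"]["type"] = {
            "unique_alleles_total": div.unique_alleles_total,
            "max_allele_slots": div.max_allele_slots,
            "unique_st_count": div.unique_st_count,
            "per_locus_unique_alleles": div.per_locus_unique_alleles,
        }

    host_dm = seqdist.distance_matrix(dataset.host_marker, model="jc")
    symb_by_host = {h: concat[h] for h in host_dm.labels}
    symb_dm = seqdist.distance_matrix(symb_by_host, model="jc")

    if "dist" in config.stages:
        from .io import write_phylip_dm

        write_phylip_dm(out / "host_jc.phylip", host_dm)
        write_phylip_dm(out / "symbiont_jc.phylip", symb_dm)
        report["stages"]["dist"] = {
            "model": "jc",
            "concatenated_length": cmap.total_length,
            "host_mean_pairwise": seqdist.mean_pairwise(host_dm),
            "symbiont_mean_pairwise": seqdist.mean_pairwise(
                symb_dm, exclude_invalid=True
            ),
            "spans": {l: list(s) for l, s in cmap.spans.items()},
        }

    if "similarity" in config.stages:
        pool_concat = {
            pid: "".join(dataset.pool_seqs[l][pid] for l, _ in loci)
            for pid in dataset.pool_supergroups
        }
        community = {
            s: "".join(dataset.community_seqs[l][s] for l, _ in loci)
            for s in set(dataset.truth.assignments.values())
        }
        res = similarity.similarity_test(
            community,
            pool_concat,
            B=config.similarity_iterations,
            alpha=config.alpha,
            seed=np.random.default_rng(
                np.random.SeedSequence([config.simulation.seed, 101])
            ),
        )
        np.savetxt(
            out / "null_means.tsv", res.null_means, header="null_mean",
            comments="",
        )
        report["stages"]["similarity"] = res.as_dict()

    if "congruence" in config.stages:
        rng = np.random.SeedSequence([config.simulation.seed, 102])
        seeds = rng.spawn(3)
        links = cophylo.LinkSet(
            host_dm.labels, symb_dm.labels,
            np.eye(host_dm.n, dtype=int),
        )
        man = cophylo.mantel(
            host_dm, symb_dm, n_perm=config.mantel_perms,
            seed=np.random.default_rng(seeds[0]),
        )
        par = cophylo.parafit(
            host_dm, symb_dm, links, n_perm=config.cophylo_perms,
            seed=np.random.default_rng(seeds[1]),
        )
        pac = cophylo.paco(
            host_dm, symb_dm, links, n_perm=config.cophylo_perms,
            seed=np.random.default_rng(seeds[2]),
        )
        report["stages"]["congruence"] = {
            "mantel_r": man.statistic, "mantel_p": man.p,
            "parafit_global": par.statistic, "parafit_p": par.p,
            "paco_m2xy": pac.statistic, "paco_p": pac.p,
        }

    if "recomb" in config.stages:
        strains = {
            s: concat_seq
            for s, concat_seq in (
                (sid, "".join(dataset.community_seqs[l][sid] for l, _ in loci))
                for sid in sorted(set(dataset.truth.assignments.values()))
            )
        }
        phi = recomb.phi_test(
            strains, n_perm=config.recomb_perms,
            seed=np.random.default_rng(
                np.random.SeedSequence([config.simulation.seed, 103])
            ),
        )
        report["stages"]["recomb"] = {
            "phi": phi.phi,
            "phi_p": phi.p,
            "n_informative": phi.n_informative,
            "testable": phi.testable,
            "true_recomb_events": len(dataset.truth.recomb_log),
        }

    _write_report(out, report)
    return report


def _write_report(out: Path, report: dict) -> None:
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")


def fixture_summary() -> dict:
    """Diversity and screening numbers recomputed from the packaged tables."""
    from .fixtures import load_screening_table
    from .mlst import incidence_summary

    fx = load_fixtures()
    div = diversity_summary(fx.profiles)
    scr = incidence_summary(load_screening_table())
    spans = seqdist.concatenate(
        {name: {"x": "A" * length} for name, length in fx.locus_order},
        fx.locus_order,
    )[1]
    return {
        "unique_alleles_total": div.unique_alleles_total,
        "max_allele_slots": div.max_allele_slots,
        "unique_st_count": div.unique_st_count,
        "per_supergroup_st_counts": div.per_supergroup_st_counts,
        "per_locus_unique_alleles": div.per_locus_unique_alleles,
        "n_screened": scr.n_screened,
        "incidence_percent": scr.incidence_percent,
        "concatenated_length": spans.total_length,
        "spans": {l: list(s) for l, s in spans.spans.items()},
    }
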