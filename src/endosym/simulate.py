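"""Forward simulator for host communities and their endosymbionts.

The generator produces a ground-truthed community for every downstream
stage: an ultrametric Yule host tree; a background "database" pool of
symbiont strains structured into deep labelled clades (supergroups); one
symbiont strain per host (single infections), inherited vertically along
the host tree and optionally displaced by horizontal acquisition either
from another community host (``h_within``) or from the background pool
(``g_global``); and optional recombination on acquisition, transferring
one contiguous segment of a single locus from the displaced resident
strain into the acquired one (``rho``).  Sequences evolve under the
one-parameter equal-rates substitution model, gap-free, no indels.

Every event is logged (``transfer_log``, ``recomb_log``), so tests can
audit detector output against the truth.  All randomness derives from
one master seed; each stage uses an independent stream keyed by a fixed
label, so stages are individually reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mlst import WOLBACHIA_SCHEME

__all__ = [
    "SimulationConfig",
    "Tree",
    "CommunityTruth",
    "SimulatedDataset",
    "simulate_host_tree",
    "evolve_sequences",
    "simulate_transmission",
    "emit_dataset",
    "load_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: expected-substitution multiplier on the branches separating supergroup
#: ancestors, relative to ``subst_rate`` (deep clades vs within-clade depth)
DEEP_CLADE_FACTOR = 2.0
#: depth of each within-supergroup pool genealogy relative to the host tree
POOL_CLADE_DEPTH = 1.0

_SUPERGROUP_LABELS = ["A", "B", "F", "C", "D", "E", "G", "H"]

# fixed stream labels (master seed spawns one child stream per stage)
_STREAMS = {
    "host_tree": 1,
    "host_marker": 2,
    "pool": 3,
    "vertical": 4,
    "transfer": 5,
    "recombination": 6,
}


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the community generator (defaults give a mid-sized,
    fully vertical community)."""

    n_hosts: int = 25
    birth_rate: float = 1.0
    locus_lengths: tuple[int, ...] = tuple(d.length for d in WOLBACHIA_SCHEME)
    locus_names: tuple[str, ...] = tuple(d.name for d in WOLBACHIA_SCHEME)
    host_marker_length: int = 600
    subst_rate: float = 0.05
    #: mitochondrial markers evolve much faster than bacterial
    #: housekeeping loci; the host marker gets its own rate
    host_subst_rate: float = 0.25
    pool_size: int = 60
    n_supergroups: int = 3
    h_within: float = 0.0
    g_global: float = 0.0
    rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hosts < 3:
            raise InvalidConfigError("n_hosts must be >= 3")
        for name in ("h_within", "g_global", "rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.h_within + self.g_global > 1.0 + 1e-12:
            raise InvalidConfigError("h_within + g_global must be <= 1")
        if any(l <= 0 for l in self.locus_lengths):
            raise InvalidConfigError("locus lengths must be positive")
        if len(self.locus_lengths) != len(self.locus_names):
            raise InvalidConfigError("locus names and lengths must pair up")
        if self.pool_size < self.n_supergroups:
            raise InvalidConfigError("pool_size must cover every supergroup")
        if self.birth_rate <= 0 or self.subst_rate < 0:
            raise InvalidConfigError("rates must be positive")

    def stream(self, label: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAMS[label]])
        )


@dataclass
class Tree:
    """Minimal rooted tree with branch lengths (sufficient for the
    simulator; analyses convert to richer libraries when needed)."""

    name: str | None
    length: float = 0.0
    children: list["Tree"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Tree"]:
        if self.is_leaf:
            return [self]
        out: list[Tree] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def n_internal(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + sum(c.n_internal() for c in self.children)

    def n_cherries(self) -> int:
        """Internal nodes whose children are both leaves."""
        if self.is_leaf:
            return 0
        own = int(len(self.children) == 2
                  and all(c.is_leaf for c in self.children))
        return own + sum(c.n_cherries() for c in self.children)

    def depth(self) -> float:
        if self.is_leaf:
            return 0.0
        return max(c.length + c.depth() for c in self.children)

    def scale(self, factor: float) -> None:
        for c in self.children:
            c.length *= factor
            c.scale(factor)

    def newick(self) -> str:
        return self._newick_node() + ";"

    def _newick_node(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick_node() for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{self.length:.10g}"

    def tip_distances(self) -> tuple[list[str], np.ndarray]:
        """Patristic (path-length) distances between all leaf pairs."""
        names = self.leaf_names()
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        dist = np.zeros((n, n))

        def walk(node: Tree) -> dict[int, float]:
            if node.is_leaf:
                return {idx[node.name]: 0.0}
            below: list[dict[int, float]] = []
            for c in walk_children(node):
                below.append(c)
            merged: dict[int, float] = {}
            for k, sub in enumerate(below):
                for other in below[k + 1:]:
                    for i, di in sub.items():
                        for j, dj in other.items():
                            d = di + dj
                            dist[i, j] = dist[j, i] = d
                merged.update(sub)
            return merged

        def walk_children(node: Tree) -> list[dict[int, float]]:
            out = []
            for c in node.children:
                sub = walk(c)
                out.append({i: d + c.length for i, d in sub.items()})
            return out

        walk(self)
        return names, dist


def simulate_host_tree(
    n_hosts: int, birth_rate: float = 1.0, seed: int | np.random.Generator = 0
) -> Tree:
    """Ultrametric Yule (pure-birth) tree with ``n_hosts`` labelled tips.

    Lineages split at rate ``birth_rate`` each; simulation stops when
    ``n_hosts`` tips exist and all pending branches are extended to the
    stopping time.  Depth is rescaled to 1 so that substitution rates read
    as expected substitutions/site over the tree depth.
    """
    if n_hosts < 3:
        raise InvalidConfigError("n_hosts must be >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = Tree(name=None, length=0.0)
    active: list[Tree] = [root]
    birth_times: dict[int, float] = {id(root): 0.0}
    t = 0.0
    while len(active) < n_hosts:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        node = active.pop(rng.integers(k))
        node.length = t - birth_times.pop(id(node))
        for _ in range(2):
            child = Tree(name=None, length=0.0)
            birth_times[id(child)] = t
            node.children.append(child)
            active.append(child)
    # close all open branches at the final splitting time (ultrametric)
    for leaf in active:
        leaf.length = t - birth_times.pop(id(leaf))
    width = len(str(n_hosts))
    for i, leaf in enumerate(root.leaves()):
        leaf.name = f"H{i + 1:0{width}d}"
    depth = root.depth()
    if depth > 0:
        root.scale(1.0 / depth)
    return root


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def evolve_sequences(
    tree: Tree,
    root_sequence: str,
    subst_rate: float,
    seed: int | np.random.Generator = 0,
) -> dict[str, str]:
    """Evolve a root sequence to every tip under the equal-rates model.

    A branch of length b carries an expected ``b * subst_rate``
    substitutions/site; per site, the exact transition is applied: the
    site differs from its parent with probability
    (3/4)(1 - exp(-4/3 b r)), and a differing site takes one of the three
    other bases uniformly.
    """
    seq = root_sequence.upper()
    if set(seq) - {"A", "C", "G", "T"}:
        bad = sorted(set(seq) - {"A", "C", "G", "T"})
        raise ValueError(f"root sequence contains non-ACGT symbols: {bad}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root_arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    out: dict[str, str] = {}

    def walk(node: Tree, arr: np.ndarray) -> None:
        for child in node.children:
            t = child.length * subst_rate
            p_diff = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
            child_arr = arr.copy()
            hit = np.nonzero(rng.random(arr.size) < p_diff)[0]
            if hit.size:
                # uniform choice among the three non-parent bases
                cur = child_arr[hit]
                shift = rng.integers(1, 4, size=hit.size)
                base_idx = np.searchsorted(_BASES, cur)
                child_arr[hit] = _BASES[(base_idx + shift) % 4]
            if child.is_leaf:
                out[child.name] = child_arr.tobytes().decode()
            else:
                walk(child, child_arr)

    if tree.is_leaf:
        out[tree.name] = seq
    else:
        walk(tree, root_arr)
    return out


@dataclass
class TransferEvent:
    recipient: str
    donor: str  # host id, or "pool", or "parent" for vertical
    event: str  # vertical | within | global


@dataclass
class RecombinationRecord:
    strain_id: str
    locus: str
    start: int  # 1-based inclusive, locus frame
    end: int
    donor_strain: str


@dataclass
class CommunityTruth:
    """Ground truth of one simulated community."""

    host_tree: Tree
    assignments: dict[str, str]  # host -> strain id
    transfer_log: list[TransferEvent]
    recomb_log: list[RecombinationRecord]

    def validate(self, locus_lengths: dict[str, int]) -> None:
        hosts = set(self.host_tree.leaf_names())
        if set(self.assignments) != hosts:
            raise ValueError("every host must carry exactly one assignment")
        for rec in self.recomb_log:
            if not 1 <= rec.start <= rec.end <= locus_lengths[rec.locus]:
                raise ValueError(
                    f"recombination segment {rec} outside locus frame"
                )


@dataclass
class SimulatedDataset:
    """Truth plus all sequence data emitted by the generator."""

    config: SimulationConfig
    truth: CommunityTruth
    host_marker: dict[str, str]  # host -> marker sequence
    community_seqs: dict[str, dict[str, str]]  # locus -> strain id -> seq
    pool_seqs: dict[str, dict[str, str]]  # locus -> pool strain id -> seq
    pool_supergroups: dict[str, str]  # pool strain id -> clade label

    @property
    def loci(self) -> list[tuple[str, int]]:
        return list(zip(self.config.locus_names, self.config.locus_lengths))

    def host_locus_seqs(self, locus: str) -> dict[str, str]:
        """Per-host symbiont sequences at one locus."""
        return {
            h: self.community_seqs[locus][s]
            for h, s in self.truth.assignments.items()
        }


def _simulate_pool(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, dict[str, str]], dict[str, str]]:
    """Background database pool: deep labelled clades, shallow within."""
    n_groups = config.n_supergroups
    labels = _SUPERGROUP_LABELS[:n_groups]
    per_group = [config.pool_size // n_groups] * n_groups
    for i in range(config.pool_size % n_groups):
        per_group[i] += 1
    pool_seqs: dict[str, dict[str, str]] = {n: {} for n in config.locus_names}
    pool_supergroups: dict[str, str] = {}
    counter = 0
    roots = {
        name: _random_sequence(length, rng)
        for name, length in zip(config.locus_names, config.locus_lengths)
    }
    for label, size in zip(labels, per_group):
        # deep branch from the shared ancestor to this clade's ancestor
        deep = Tree(name=None)
        tip = Tree(name="anc", length=DEEP_CLADE_FACTOR)
        deep.children = [tip, Tree(name="unused", length=DEEP_CLADE_FACTOR)]
        ancestors = {
            locus: evolve_sequences(deep, roots[locus], config.subst_rate, rng)["anc"]
            for locus in config.locus_names
        }
        if size >= 3:
            clade = simulate_host_tree(size, config.birth_rate, rng)
            clade.scale(POOL_CLADE_DEPTH)
            tips = clade.leaf_names()
            per_locus = {
                locus: evolve_sequences(clade, ancestors[locus],
                                        config.subst_rate, rng)
                for locus in config.locus_names
            }
        else:
            tips = [f"H{i + 1}" for i in range(size)]
            per_locus = {
                locus: {t: ancestors[locus] for t in tips}
                for locus in config.locus_names
            }
        for t in tips:
            counter += 1
            pid = f"P{counter:03d}"
            pool_supergroups[pid] = label
            for locus in config.locus_names:
                pool_seqs[locus][pid] = per_locus[locus][t]
    return pool_seqs, pool_supergroups


def simulate_transmission(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: tree, pool, inheritance, transfer, recombination.

    Each host first inherits the strain evolved along its own lineage of
    the host tree; independently per host, with probability ``h_within``
    that strain is replaced by the strain currently carried by another
    community host, else with probability ``g_global`` by a random
    background-pool strain.  With probability ``rho`` an acquired strain
    recombines: one contiguous segment of one locus is copied in from the
    displaced resident strain.  Every decision is logged.
    """
    host_tree = simulate_host_tree(
        config.n_hosts, config.birth_rate, config.stream("host_tree")
    )
    hosts = host_tree.leaf_names()

    marker_rng = config.stream("host_marker")
    marker_root = _random_sequence(config.host_marker_length, marker_rng)
    host_marker = evolve_sequences(
        host_tree, marker_root, config.host_subst_rate, marker_rng
    )

    pool_seqs, pool_supergroups = _simulate_pool(config, config.stream("pool"))
    pool_ids = sorted(pool_supergroups)

    # vertical inheritance: the symbiont evolves along the host tree from
    # an ancestral strain drawn from the pool
    vert_rng = config.stream("vertical")
    root_strain = pool_ids[int(vert_rng.integers(len(pool_ids)))]
    vertical_seqs = {
        locus: evolve_sequences(
            host_tree, pool_seqs[locus][root_strain], config.subst_rate, vert_rng
        )
        for locus in config.locus_names
    }

    strain_of: dict[str, str] = {}
    strain_seqs: dict[str, dict[str, str]] = {}  # strain id -> locus -> seq
    for h in hosts:
        sid = f"V_{h}"
        strain_of[h] = sid
        strain_seqs[sid] = {l: vertical_seqs[l][h] for l in config.locus_names}

    transfer_log: list[TransferEvent] = []
    recomb_log: list[RecombinationRecord] = []
    t_rng = config.stream("transfer")
    r_rng = config.stream("recombination")
    lengths = dict(zip(config.locus_names, config.locus_lengths))
    n_recomb = 0

    order = [hosts[i] for i in t_rng.permutation(len(hosts))]
    for h in order:
        u = t_rng.random()
        if u < config.h_within:
            others = [x for x in hosts if x != h]
            donor = others[int(t_rng.integers(len(others)))]
            acquired_id = strain_of[donor]
            event = TransferEvent(h, donor, "within")
        elif u < config.h_within + config.g_global:
            acquired_id = pool_ids[int(t_rng.integers(len(pool_ids)))]
            if acquired_id not in strain_seqs:
                strain_seqs[acquired_id] = {
                    l: pool_seqs[l][acquired_id] for l in config.locus_names
                }
            event = TransferEvent(h, "pool", "global")
        else:
            transfer_log.append(TransferEvent(h, "parent", "vertical"))
            continue

        resident_id = strain_of[h]
        if r_rng.random() < config.rho:
            n_recomb += 1
            new_id = f"R{n_recomb:03d}"
            locus = config.locus_names[int(r_rng.integers(len(config.locus_names)))]
            L = lengths[locus]
            a, b = sorted(int(x) for x in r_rng.integers(1, L + 1, size=2))
            seqs = dict(strain_seqs[acquired_id])
            donor_seq = strain_seqs[resident_id][locus]
            acq = seqs[locus]
            seqs[locus] = acq[: a - 1] + donor_seq[a - 1 : b] + acq[b:]
            strain_seqs[new_id] = seqs
            recomb_log.append(
                RecombinationRecord(new_id, locus, a, b, resident_id)
            )
            strain_of[h] = new_id
        else:
            strain_of[h] = acquired_id
        transfer_log.append(event)

    live = sorted(set(strain_of.values()))
    community_seqs = {
        locus: {sid: strain_seqs[sid][locus] for sid in live}
        for locus in config.locus_names
    }
    truth = CommunityTruth(host_tree, dict(strain_of), transfer_log, recomb_log)
    truth.validate(lengths)
    return SimulatedDataset(
        config=config,
        truth=truth,
        host_marker=host_marker,
        community_seqs=community_seqs,
        pool_seqs=pool_seqs,
        pool_supergroups=pool_supergroups,
    )


HEADER_DELIM = "|"


def emit_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> Path:
    """Write the simulated dataset to plain-text files.

    Layout: ``hosts_CO1.fasta`` (host marker), ``community_<locus>.fasta``
    (one record per host, header ``host|strain``), ``pool_<locus>.fasta``
    (header ``pool_id|supergroup``), ``metadata.tsv``,
    ``transfer_log.tsv``, ``recomb_log.tsv``, ``host_tree.nwk`` and
    ``config.json``.  ``load_dataset`` reproduces the in-memory objects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def write_fasta(path: Path, records: dict[str, str]) -> None:
        with path.open("w") as fh:
            for rid, seq in records.items():
                fh.write(f">{rid}\n{seq}\n")

    write_fasta(out / "hosts_CO1.fasta", dataset.host_marker)
    for locus, _ in dataset.loci:
        write_fasta(
            out / f"community_{locus}.fasta",
            {
                f"{h}{HEADER_DELIM}{s}": dataset.community_seqs[locus][s]
                for h, s in sorted(dataset.truth.assignments.items())
            },
        )
        write_fasta(
            out / f"pool_{locus}.fasta",
            {
                f"{pid}{HEADER_DELIM}{dataset.pool_supergroups[pid]}": seq
                for pid, seq in sorted(dataset.pool_seqs[locus].items())
            },
        )
    with (out / "metadata.tsv").open("w") as fh:
        fh.write("host_id\tstrain_id\n")
        for h, s in sorted(dataset.truth.assignments.items()):
            fh.write(f"{h}\t{s}\n")
    with (out / "transfer_log.tsv").open("w") as fh:
        fh.write("recipient\tdonor\tevent\n")
        for ev in dataset.truth.transfer_log:
            fh.write(f"{ev.recipient}\t{ev.donor}\t{ev.event}\n")
    with (out / "recomb_log.tsv").open("w") as fh:
        fh.write("strain_id\tlocus\tstart\tend\tdonor_strain\n")
        for rec in dataset.truth.recomb_log:
            fh.write(
                f"{rec.strain_id}\t{rec.locus}\t{rec.start}\t{rec.end}\t"
                f"{rec.donor_strain}\n"
            )
    (out / "host_tree.nwk").write_text(dataset.truth.host_tree.newick() + "\n")
    cfg = dataset.config.__dict__.copy()
    (out / "config.json").write_text(json.dumps(cfg, indent=2) + "\n")
    return out


def _read_fasta(path: Path) -> dict[str, str]:
    records: dict[str, str] = {}
    rid = None
    chunks: list[str] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if rid is not None:
                    records[rid] = "".join(chunks)
                rid = line[1:]
                chunks = []
            else:
                chunks.append(line)
    if rid is not None:
        records[rid] = "".join(chunks)
    return records


def _parse_newick(text: str) -> Tree:
    text = text.strip().rstrip(";")
    pos = 0

    def parse_node() -> Tree:
        nonlocal pos
        node = Tree(name=None)
        if text[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while text[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            assert text[pos] == ")"
            pos += 1
        start = pos
        while pos < len(text) and text[pos] not in ":,()":
            pos += 1
        name = text[start:pos]
        node.name = name or None
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",()":
                pos += 1
            node.length = float(text[start:pos])
        return node

    return parse_node()


def load_dataset(out_dir: str | Path) -> SimulatedDataset:
    """Read back a dataset written by :func:`emit_dataset`."""
    out = Path(out_dir)
    cfg = json.loads((out / "config.json").read_text())
    cfg["locus_lengths"] = tuple(cfg["locus_lengths"])
    cfg["locus_names"] = tuple(cfg["locus_names"])
    config = SimulationConfig(**cfg)
    host_marker = _read_fasta(out / "hosts_CO1.fasta")
    assignments: dict[str, str] = {}
    with (out / "metadata.tsv").open() as fh:
        next(fh)
        for line in fh:
            h, s = line.rstrip("\n").split("\t")
            assignments[h] = s
    community_seqs: dict[str, dict[str, str]] = {}
    pool_seqs: dict[str, dict[str, str]] = {}
    pool_supergroups: dict[str, str] = {}
    for locus in config.locus_names:
        community_seqs[locus] = {}
        for header, seq in _read_fasta(out / f"community_{locus}.fasta").items():
            _, strain = header.split(HEADER_DELIM)
            community_seqs[locus][strain] = seq
        pool_seqs[locus] = {}
        for header, seq in _read_fasta(out / f"pool_{locus}.fasta").items():
            pid, label = header.split(HEADER_DELIM)
            pool_seqs[locus][pid] = seq
            pool_supergroups[pid] = label
    transfer_log: list[TransferEvent] = []
    with (out / "transfer_log.tsv").open() as fh:
        next(fh)
        for line in fh:
            r, d, e = line.rstrip("\n").split("\t")
            transfer_log.append(TransferEvent(r, d, e))
    recomb_log: list[RecombinationRecord] = []
    with (out / "recomb_log.tsv").open() as fh:
        next(fh)
        for line in fh:
            sid, locus, a, b, donor = line.rstrip("\n").split("\t")
            recomb_log.append(
                RecombinationRecord(sid, locus, int(a), int(b), donor)
            )
    host_tree = _parse_newick((out / "host_tree.nwk").read_text())
    truth = CommunityTruth(host_tree, assignments, transfer_log, recomb_log)
    return SimulatedDataset(
        config=config,
        truth=truth,
        host_marker=host_marker,
        community_seqs=community_seqs,
        pool_seqs=pool_seqs,
        pool_supergroups=pool_supergroups,
    )
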