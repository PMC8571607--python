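"""File-format helpers: FASTA, PHYLIP distance matrices, link tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .seqdist import DistanceMatrix

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_phylip_dm",
    "read_phylip_dm",
    "write_long_distances",
    "read_links",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file to an ordered id -> sequence mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.description] = str(rec.seq).upper()
    return records


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    with Path(path).open("w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n{seq}\n")


def write_phylip_dm(path: str | Path, matrix: DistanceMatrix) -> None:
    """Square PHYLIP distance matrix (relaxed names, tab-separated)."""
    with Path(path).open("w") as fh:
        fh.write(f"{matrix.n}\n")
        for i, label in enumerate(matrix.labels):
            row = "\t".join(f"{v:.8f}" for v in matrix.values[i])
            fh.write(f"{label}\t{row}\n")


def read_phylip_dm(path: str | Path) -> DistanceMatrix:
    lines = Path(path).read_text().strip().splitlines()
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for line in lines[1 : n + 1]:
        parts = line.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1 : n + 1]])
    return DistanceMatrix(labels, np.array(rows))


def write_long_distances(path: str | Path, matrix: DistanceMatrix) -> None:
    """TSV of all unordered pairs: label_i, label_j, distance."""
    with Path(path).open("w") as fh:
        fh.write("label_i\tlabel_j\tdistance\n")
        for i in range(matrix.n):
            for j in range(i + 1, matrix.n):
                fh.write(
                    f"{matrix.labels[i]}\t{matrix.labels[j]}\t"
                    f"{matrix.values[i, j]:.8f}\n"
                )


def read_links(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV (host, symbiont) to a list of link pairs."""
    df = pd.read_csv(path, sep="\t")
    return list(df.itertuples(index=False, name=None))
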