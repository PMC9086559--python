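"""Readers and writers for the on-disk formats the pipeline consumes.

TSV count matrices (feature ids in column 1, sample ids in the header),
FASTA sequence sets (normalized to the RNA alphabet on read), PPI /
interaction edge lists (two-or-three-column TSV or SIF), GraphML and SIF
network exports, and GMT gene-set files.  circRNA identifiers follow the
circBase convention ``chrN:start-end`` with 1-based, fully-closed
coordinates.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, NamedTuple

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError
from .expression import ExprMatrix

_CIRC_ID = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


class CircSpan(NamedTuple):
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive


def parse_circ_id(circ_id: str) -> CircSpan:
    """Parse a circBase-style id like ``chr8:71244603-71271897``."""
    m = _CIRC_ID.match(circ_id)
    if not m:
        raise FormatError(f"not a chr:start-end circRNA id: {circ_id!r}")
    start, end = int(m["start"]), int(m["end"])
    if start > end:
        raise FormatError(f"circRNA id has start > end: {circ_id!r}")
    return CircSpan(m["chrom"], start, end)


def format_circ_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


# ---------------------------------------------------------------- matrices

def read_counts(path: str | Path, kind: str = "count",
                lib_sizes: pd.Series | None = None,
                require_integer: bool | None = None) -> ExprMatrix:
    """Read a TSV matrix (feature ids in column 1, samples in the header).

    Count matrices must hold integers; duplicate feature or sample ids are
    format errors naming the offender.  ``lib_sizes`` defaults to column
    sums for counts.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate feature id in {path}: {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"duplicate sample id in {path}: {dup!r}")
    if require_integer is None:
        require_integer = kind == "count"
    if require_integer:
        num = df.apply(pd.to_numeric, errors="coerce")
        bad = num.isna() | (num != num.round())
        if bad.to_numpy().any():
            i, j = next(zip(*bad.to_numpy().nonzero()))
            raise FormatError(
                f"non-integer count at feature {df.index[i]!r}, sample {df.columns[j]!r}")
        df = num.astype(int)
    if kind == "count" and lib_sizes is None:
        lib_sizes = df.sum(axis=0)
    return ExprMatrix(df, kind=kind, lib_sizes=lib_sizes)


def write_counts(mat: ExprMatrix, path: str | Path) -> None:
    mat.values.to_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


# ---------------------------------------------------------------- sequences

def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA-style T to U."""
    return seq.upper().replace("T", "U")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA records into an id -> RNA-sequence mapping.

    DNA input (T) is normalized to the RNA alphabet (U); duplicate ids are
    format errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate sequence id in {path}: {rec.id!r}")
        records[rec.id] = normalize_rna(str(rec.seq))
    return records


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path), "fasta")


# ---------------------------------------------------------------- networks

def read_edges(path: str | Path) -> list[tuple[str, str]]:
    """Read an undirected edge list from 2-column TSV or 3-column SIF.

    SIF lines are ``source<tab>relation<tab>target``; a 2-column line is
    taken as a plain edge.  Self-loops are rejected; duplicates collapse.
    """
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1 and parts[0] == "":
                continue
            if len(parts) == 2:
                a, b = parts
            elif len(parts) >= 3:
                a, b = parts[0], parts[2]
            else:
                raise FormatError(f"{path} line {ln}: expected 2 or 3 columns")
            if a == b:
                raise FormatError(f"{path} line {ln}: self-loop on {a!r}")
            edges.add((min(a, b), max(a, b)))
    return sorted(edges)


def write_edges(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def write_sif(graph: nx.Graph, path: str | Path, default_relation: str = "pp") -> None:
    """Write a graph as SIF; the edge attribute ``relation`` names the type."""
    with open(path, "w") as fh:
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{data.get('relation', default_relation)}\t{b}\n")


def read_sif(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1 and parts[0] == "":
                continue
            if len(parts) != 3:
                raise FormatError(f"{path} line {ln}: SIF needs 3 columns")
            a, rel, b = parts
            g.add_edge(a, b, relation=rel)
    return g


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


# ---------------------------------------------------------------- gene sets

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: name<tab>description<tab>gene1<tab>gene2..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1 and parts[0] == "":
                continue
            if len(parts) < 3:
                raise FormatError(f"{path} line {ln}: GMT needs >= 3 columns")
            name = parts[0]
            if name in sets:
                raise FormatError(f"duplicate gene set {name!r} in {path}")
            sets[name] = set(p for p in parts[2:] if p)
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")
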