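"""Reading and writing expression matrices and gene networks.

Expression data arrive as a genes × time-points TSV: first column gene id,
remaining columns expression values at equally spaced time points (1-based
in all lag arithmetic).  Empty cells or ``NA`` (case-insensitive) mark
missing values.  Networks are directed edge lists, either plain
``regulator<TAB>target`` or Cytoscape SIF (``regulator<TAB>regulates<TAB>target``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

from .errors import ParseError, ValidationError

_MISSING_TOKENS = {"", "na"}

__all__ = [
    "ExpressionMatrix",
    "GeneNetwork",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_network",
    "write_network",
]


@dataclass
class ExpressionMatrix:
    """Continuous genes × time-points expression values.

    Parameters
    ----------
    gene_ids
        Unique gene labels, one per row.
    values
        Float array of shape ``(n_genes, n_timepoints)``.  Cells flagged in
        ``mask`` hold ``nan``.
    mask
        Boolean array, ``True`` where the measurement is missing.
    """

    gene_ids: list[str]
    values: np.ndarray
    mask: np.ndarray = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D grid")
        n, m = self.values.shape
        if n < 2:
            raise ValidationError(f"need at least 2 genes, got {n}")
        if m < 2:
            raise ValidationError(f"need at least 2 time points, got {m}")
        if len(self.gene_ids) != n:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n} rows of values"
            )
        dupes = {g for g in self.gene_ids if self.gene_ids.count(g) > 1}
        if dupes:
            raise ValidationError(f"duplicate gene id(s): {sorted(dupes)}")
        if self.mask is None:
            self.mask = np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValidationError("missing mask shape differs from values shape")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GeneNetwork:
    """Directed regulatory network: gene labels plus regulator→target edges."""

    gene_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "edges", frozenset(self.edges))
        known = set(self.gene_ids)
        if len(known) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in network")
        for src, dst in self.edges:
            if src not in known or dst not in known:
                raise ValidationError(f"edge {src}->{dst} references unknown gene")
            if src == dst:
                raise ValidationError(f"self-loop {src}->{dst} not allowed")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.gene_ids)
        g.add_edges_from(self.edges)
        return g


def read_expression_tsv(path: str | Path, has_header: bool = True) -> ExpressionMatrix:
    """Parse a genes × time-points TSV into an :class:`ExpressionMatrix`.

    Empty cells and ``NA`` (any case) become masked missing values; any other
    non-numeric cell is a :class:`ParseError` naming the line.
    """
    path = Path(path)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    mask_rows: list[list[bool]] = []
    width: int | None = None
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, record in enumerate(reader, start=1):
            if lineno == 1 and has_header:
                continue
            if not record or (len(record) == 1 and not record[0].strip()):
                continue  # blank line
            if len(record) < 2:
                raise ParseError(f"{path}:{lineno}: expected gene id plus values")
            if width is None:
                width = len(record)
            elif len(record) != width:
                raise ParseError(
                    f"{path}:{lineno}: ragged row ({len(record)} fields, expected {width})"
                )
            gene_ids.append(record[0].strip())
            vals, miss = [], []
            for col, cell in enumerate(record[1:], start=2):
                token = cell.strip()
                if token.lower() in _MISSING_TOKENS:
                    vals.append(np.nan)
                    miss.append(True)
                    continue
                try:
                    vals.append(float(token))
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric value {token!r} in column {col}"
                    ) from None
                miss.append(False)
            rows.append(vals)
            mask_rows.append(miss)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return ExpressionMatrix(gene_ids, np.array(rows), np.array(mask_rows))


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path, header: bool = True) -> None:
    """Write an expression matrix back to TSV (missing cells as ``NA``)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if header:
            writer.writerow(["gene"] + [f"t{j + 1}" for j in range(expr.n_timepoints)])
        for i, gid in enumerate(expr.gene_ids):
            cells = [
                "NA" if expr.mask[i, j] else repr(float(expr.values[i, j]))
                for j in range(expr.n_timepoints)
            ]
            writer.writerow([gid] + cells)


def write_network(net: GeneNetwork, path: str | Path, format: str = "edgelist") -> None:
    """Write a network as a 2-column edge list or 3-column SIF file.

    Edges are sorted lexicographically by (regulator, target) so output is
    deterministic; an empty network yields an empty (header-free) file.
    """
    if format not in ("edgelist", "sif"):
        raise ValidationError(f"unsupported network format {format!r}")
    path = Path(path)
    with path.open("w", newline="") as fh:
        for src, dst in sorted(net.edges):
            if format == "edgelist":
                fh.write(f"{src}\t{dst}\n")
            else:
                fh.write(f"{src}\tregulates\t{dst}\n")


def read_network(path: str | Path, gene_ids: Iterable[str] | None = None) -> GeneNetwork:
    """Read an edge-list or SIF file; dialect detected per line by column count.

    ``gene_ids``, when given, fixes the gene universe (edges must fall inside
    it); otherwise the universe is the union of edge endpoints.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) == 2:
                src, dst = fields
            elif len(fields) == 3:
                src, _, dst = fields
            else:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 (edgelist) or 3 (SIF) columns, "
                    f"got {len(fields)}"
                )
            if not src or not dst:
                raise ParseError(f"{path}:{lineno}: empty gene id")
            edges.add((src, dst))
    if gene_ids is None:
        universe: list[str] = sorted({g for e in edges for g in e})
    else:
        universe = list(gene_ids)
    return GeneNetwork(tuple(universe), frozenset(edges))
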