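"""Tab-delimited I/O for expression matrices, gene lists, networks and topologies.

The expression dialect is: a header row of sample identifiers, then one row
per gene, each row a gene identifier followed by one numeric field per
sample.  Values are assumed to be normalized upstream (log-scale or not; the
package treats them as-is).  Matrices with missing or non-finite cells are
rejected rather than imputed, because every downstream association estimator
assumes complete profiles.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "EdgeList",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_list",
    "read_edge_list",
    "write_edge_list",
]


@dataclass
class ExpressionMatrix:
    """A genes × samples real-valued expression matrix.

    Attributes
    ----------
    gene_ids : list of str
        Unique, non-empty row identifiers (opaque, case-sensitive).
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray of shape (n_genes, n_samples)
        Finite float64 expression values.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, m = self.values.shape
        if len(self.gene_ids) != n:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n} rows of values"
            )
        if len(self.sample_ids) != m:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {m} columns of values"
            )
        if any(g == "" for g in self.gene_ids):
            raise ValueError("empty gene identifier")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value for gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass
class EdgeList:
    """An undirected scored network as canonical (a, b, score) triples.

    Edges are stored with ``a < b`` lexicographically, sorted, with no
    self-loops and no duplicate pairs.  ``cutoff`` records the score
    threshold that produced the list (``None`` when unknown, e.g. after
    reading from a file without provenance).
    """

    edges: list[tuple[str, str, float]]
    cutoff: float | None = None

    def __post_init__(self) -> None:
        canon = []
        for a, b, s in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if b < a:
                a, b = b, a
            canon.append((a, b, float(s)))
        canon.sort()
        pairs = [(a, b) for a, b, _ in canon]
        if len(set(pairs)) != len(pairs):
            dup = next(p for i, p in enumerate(pairs) if p in pairs[:i])
            raise ValueError(f"duplicate edge {dup[0]!r}--{dup[1]!r}")
        self.edges = canon

    @property
    def nodes(self) -> set[str]:
        return {g for a, b, _ in self.edges for g in (a, b)}

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)


def _check_unique(ids: list[str], kind: str) -> None:
    seen: set[str] = set()
    for g in ids:
        if g in seen:
            raise ValueError(f"duplicate {kind} identifier {g!r}")
        seen.add(g)


def _load_text(source) -> str:
    """Return text content from a path, file-like object, or raw string.

    A string containing a tab or newline is treated as inline content;
    anything else is treated as a filesystem path.
    """
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, os.PathLike):
        with open(source, "r", encoding="utf-8") as fh:
            return fh.read()
    if isinstance(source, str):
        if "\t" in source or "\n" in source:
            return source
        with open(source, "r", encoding="utf-8") as fh:
            return fh.read()
    raise TypeError(f"cannot read from {type(source).__name__}")


def read_expression_matrix(source) -> ExpressionMatrix:
    """Parse a tab-delimited expression matrix.

    Parameters
    ----------
    source : path, file-like, or str
        First row holds sample identifiers (with or without a leading
        corner label); each subsequent row holds a gene identifier followed
        by one numeric field per sample.  LF and CRLF line endings are both
        accepted.

    Raises
    ------
    ValueError
        On duplicate gene identifiers (naming the identifier), non-numeric
        cells (naming row and column), ragged rows, or an empty file.
    """
    lines = [ln for ln in _load_text(source).splitlines() if ln.strip() != ""]
    if len(lines) < 2:
        raise ValueError("expression matrix needs a header row and at least one gene row")
    header = lines[0].split("\t")
    first_row_width = len(lines[1].split("\t"))
    if len(header) == first_row_width:
        # corner label present above the gene-id column
        sample_ids = header[1:]
    elif len(header) == first_row_width - 1:
        sample_ids = header
    else:
        raise ValueError(
            f"header has {len(header)} fields but first gene row has "
            f"{first_row_width}"
        )
    m = len(sample_ids)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != m + 1:
            raise ValueError(
                f"ragged row at line {lineno}: expected {m + 1} fields, "
                f"found {len(fields)}"
            )
        gid = fields[0]
        vals = []
        for j, cell in enumerate(fields[1:]):
            try:
                v = float(cell)
            except ValueError:
                v = math.nan
            if not math.isfinite(v):
                raise ValueError(
                    f"non-numeric value {cell!r} at line {lineno} "
                    f"(gene {gid!r}, sample {sample_ids[j]!r})"
                )
            vals.append(v)
        gene_ids.append(gid)
        rows.append(vals)
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows))


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix in the input dialect at full (round-trip) precision."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(matrix.sample_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_gene_list(source) -> list[str]:
    """Read a plain-text gene list, one identifier per line.

    Blank lines are ignored; duplicates are dropped (keeping first
    occurrence) with a warning; an empty result is an error.
    """
    text = _load_text(source)
    ids: list[str] = []
    seen: set[str] = set()
    dropped = 0
    for ln in text.splitlines():
        g = ln.strip()
        if not g:
            continue
        if g in seen:
            dropped += 1
            continue
        seen.add(g)
        ids.append(g)
    if dropped:
        warnings.warn(f"dropped {dropped} duplicate gene id(s)", stacklevel=2)
    if not ids:
        raise ValueError("gene list is empty")
    return ids


def write_edge_list(
    edge_list: EdgeList,
    path,
    interaction_label: str | None = None,
    header_lines: list[str] | None = None,
) -> None:
    """Write a network as Cytoscape-importable tab text.

    Default layout is ``geneA<TAB>score<TAB>geneB``; with
    ``interaction_label`` set, the score column is replaced by the constant
    label (SIF-style).  ``header_lines`` are emitted first as ``#`` comments
    (provenance: method, cutoff, seed, ...).
    """
    with open(path, "w", encoding="utf-8") as fh:
        for ln in header_lines or []:
            fh.write(f"# {ln}\n")
        for a, b, s in edge_list.edges:
            mid = interaction_label if interaction_label is not None else repr(s)
            fh.write(f"{a}\t{mid}\t{b}\n")


def read_edge_list(source) -> EdgeList:
    """Read a ``geneA<TAB>score<TAB>geneB`` network file; ``#`` lines skipped."""
    edges = []
    for lineno, ln in enumerate(_load_text(source).splitlines(), start=1):
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        fields = ln.split("\t")
        if len(fields) != 3:
            raise ValueError(f"line {lineno}: expected 3 tab-separated fields")
        a, mid, b = fields
        try:
            s = float(mid)
        except ValueError:
            raise ValueError(f"line {lineno}: score {mid!r} is not numeric") from None
        edges.append((a, b, s))
    return EdgeList(edges)
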