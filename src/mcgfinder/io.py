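"""Readers and writers for mutation matrices, gene networks and result tables.

The canonical on-disk formats are plain TSV:

* mutation matrix — header row ``sample<TAB>gene1<TAB>...``, one row per
  sample, cells strictly 0/1;
* edge list — ``geneA<TAB>geneB[<TAB>weight]``, ``#`` comment lines allowed,
  undirected (reciprocal duplicates are collapsed, keeping the max weight);
* result table — one row per gene, sorted by aggregated min-q.

A minimal MAF-like reader is provided for per-mutation record files: any
record for (sample, gene) sets the corresponding cell to 1, so repeated
mutations of one gene in one sample collapse to a single entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MutationMatrix",
    "EdgeList",
    "read_mutation_tsv",
    "write_mutation_tsv",
    "read_maf_lite",
    "read_edge_list",
    "write_edge_list",
    "write_results",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True)
class MutationMatrix:
    """Binary samples x genes somatic-mutation matrix.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers (length n, unique).
    genes : list of str
        Ordered gene symbols (length p, unique).
    X : ndarray of shape (n, p)
        Entries strictly in {0, 1}; ``X[i, j] == 1`` means sample i carries
        a somatic mutation of gene j.
    """

    samples: tuple[str, ...]
    genes: tuple[str, ...]
    X: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(map(str, self.samples)))
        object.__setattr__(self, "genes", tuple(map(str, self.genes)))
        X = np.asarray(self.X)
        if X.ndim != 2:
            raise FormatError("mutation matrix must be 2-dimensional")
        n, p = X.shape
        if n < 1 or p < 1:
            raise FormatError("mutation matrix must have at least one sample and one gene")
        if len(self.samples) != n or len(self.genes) != p:
            raise FormatError("label lengths do not match matrix shape")
        if len(set(self.samples)) != n:
            raise FormatError("duplicate sample IDs")
        if len(set(self.genes)) != p:
            raise FormatError("duplicate gene symbols")
        bad = (X != 0) & (X != 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"non-binary value at sample {self.samples[i]}, gene {self.genes[j]}"
            )
        object.__setattr__(self, "X", X.astype(np.uint8))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def restrict_genes(self, genes: Sequence[str]) -> "MutationMatrix":
        """Return a copy restricted to ``genes`` (order taken from ``genes``).

        Samples are never dropped: all-zero rows still carry information for
        the sample-indicator update (they belong in some component).
        """
        index = {g: j for j, g in enumerate(self.genes)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        cols = [index[g] for g in genes]
        return MutationMatrix(self.samples, tuple(genes), self.X[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=list(self.samples), columns=list(self.genes))


@dataclass(frozen=True)
class EdgeList:
    """Canonical undirected weighted edge list over gene symbols.

    Invariants: no self-loops; each unordered pair appears once; weights are
    nonnegative (duplicates collapse to the max weight).
    """

    edges: tuple[tuple[str, str, float], ...] = field(default_factory=tuple)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str] | tuple[str, str, float]]
    ) -> "EdgeList":
        """Canonicalize an iterable of (a, b[, w]) records into an EdgeList."""
        best: dict[tuple[str, str], float] = {}
        n_loops = 0
        for rec in pairs:
            a, b = str(rec[0]), str(rec[1])
            w = float(rec[2]) if len(rec) > 2 else 1.0
            if w < 0:
                raise FormatError(f"negative edge weight {w} on edge ({a}, {b})")
            if a == b:
                n_loops += 1
                continue
            key = (a, b) if a < b else (b, a)
            if w > best.get(key, -1.0):
                best[key] = w
        if n_loops:
            logger.warning("dropped %d self-loop edge(s)", n_loops)
        edges = tuple((a, b, w) for (a, b), w in sorted(best.items()))
        return cls(edges)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b, _ in self.edges:
            out.add(a)
            out.add(b)
        return out


def read_mutation_tsv(path: str | Path) -> MutationMatrix:
    """Read a binary mutation matrix from TSV.

    The header row names the genes; the first column holds sample IDs.
    Any cell that does not parse as 0 or 1 is a format error naming the
    offending sample and gene.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: no gene columns")
    samples = tuple(map(str, df.index))
    genes = tuple(map(str, df.columns))
    raw = np.char.strip(df.to_numpy(dtype=str))
    bad = ~np.isin(raw, ("0", "1"))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"non-binary value at sample {samples[i]}, gene {genes[j]}: {raw[i, j]!r}"
        )
    return MutationMatrix(samples, genes, (raw == "1").astype(np.uint8))


def write_mutation_tsv(path: str | Path, matrix: MutationMatrix) -> None:
    """Write a mutation matrix in the TSV format ``read_mutation_tsv`` reads."""
    df = matrix.to_frame()
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def read_maf_lite(
    path: str | Path, samples: Sequence[str] | None = None
) -> MutationMatrix:
    """Collapse per-mutation records into a binary mutation matrix.

    Requires columns ``Hugo_Symbol`` and ``Tumor_Sample_Barcode``; every
    record counts as a mutation regardless of variant classification.
    An explicit ``samples`` list fixes the row universe and order (samples
    without records get all-zero rows).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("Hugo_Symbol", "Tumor_Sample_Barcode"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col}")
    genes = tuple(pd.unique(df["Hugo_Symbol"].astype(str)))
    if len(genes) == 0:
        raise FormatError(f"{path}: no genes found")
    if samples is None:
        sample_list = tuple(pd.unique(df["Tumor_Sample_Barcode"].astype(str)))
    else:
        sample_list = tuple(map(str, samples))
    srow = {s: i for i, s in enumerate(sample_list)}
    gcol = {g: j for j, g in enumerate(genes)}
    X = np.zeros((len(sample_list), len(genes)), dtype=np.uint8)
    for s, g in zip(df["Tumor_Sample_Barcode"].astype(str), df["Hugo_Symbol"].astype(str)):
        if s in srow:
            X[srow[s], gcol[g]] = 1
    return MutationMatrix(sample_list, genes, X)


def read_edge_list(path: str | Path) -> EdgeList:
    """Read a 2-3 column undirected edge-list TSV into canonical form."""
    records: list[tuple[str, str, float]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:  # tolerate whitespace-delimited files
                parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: fewer than 2 columns")
            a, b = parts[0], parts[1]
            if len(parts) >= 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric weight {parts[2]!r}"
                    ) from exc
                records.append((a, b, w))
            else:
                records.append((a, b, 1.0))
    return EdgeList.from_pairs(records)


def write_edge_list(path: str | Path, edges: EdgeList) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#geneA\tgeneB\tweight\n")
        for a, b, w in edges.edges:
            fh.write(f"{a}\t{b}\t{w:g}\n")


def write_results(path: str | Path, table: "pd.DataFrame | object") -> None:
    """Write the per-gene result table as TSV.

    Accepts a :class:`~mcgfinder.significance.GeneSignificance` or its
    per-gene DataFrame. Columns: gene, component, score, p_value, q_value,
    min_q, candidate; sorted ascending by min_q, ties broken by descending
    score then lexical gene symbol.
    """
    df = getattr(table, "per_gene", table)
    cols = ["gene", "component", "score", "p_value", "q_value", "min_q", "candidate"]
    df = pd.DataFrame(df, columns=cols).copy()
    df = df.sort_values(
        by=["min_q", "score", "gene"], ascending=[True, False, True], kind="mergesort"
    )
    out = df.copy()
    for c in ("score", "p_value", "q_value", "min_q"):
        out[c] = out[c].map(lambda v: format(float(v), ".6g"))
    out["candidate"] = df["candidate"].map(lambda v: "true" if bool(v) else "false")
    out.to_csv(path, sep="\t", index=False)
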