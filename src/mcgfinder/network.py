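"""Normalized adjacency and graph Laplacian of the gene-interaction network.

The raw symmetric weight matrix W built from the edge list is degree
normalized as ``A = Dg^{-1/2} W Dg^{-1/2}`` (Dg = diagonal of row sums of W),
so entries lie in [0, 1] and isolated genes get all-zero rows and columns.
The graph Laplacian is ``L = D - A`` with D the diagonal of column sums of A;
its quadratic form ``g^T L g = 1/2 * sum_ij A_ij (g_i - g_j)^2`` penalizes
score differences between interacting genes, which is how network context
enters the decomposition objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .io import EdgeList

logger = logging.getLogger(__name__)

__all__ = ["GeneNetwork", "normalize_adjacency", "laplacian"]


def normalize_adjacency(edges: EdgeList, genes: Sequence[str]) -> sp.csr_matrix:
    """Build the symmetric normalized adjacency matrix over ``genes``.

    Edges whose endpoints fall outside ``genes`` are dropped with a warning;
    isolated genes keep zero rows/columns (their Laplacian penalty is zero,
    so their scores are driven purely by their own mutation columns).
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list must be nonempty")
    index = {g: j for j, g in enumerate(genes)}
    p = len(genes)
    rows, cols, vals = [], [], []
    n_dropped = 0
    for a, b, w in edges.edges:
        ia, ib = index.get(a), index.get(b)
        if ia is None or ib is None:
            n_dropped += 1
            continue
        rows += [ia, ib]
        cols += [ib, ia]
        vals += [w, w]
    if n_dropped:
        logger.warning("dropped %d edge(s) outside the gene universe", n_dropped)
    W = sp.csr_matrix((vals, (rows, cols)), shape=(p, p))
    deg = np.asarray(W.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    Dinv = sp.diags(inv_sqrt)
    A = (Dinv @ W @ Dinv).tocsr()
    A.eliminate_zeros()
    return A


def laplacian(A: sp.spmatrix | np.ndarray) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Return (D, L) with D = diag(column sums of A) and L = D - A.

    ``A`` must be symmetric with zero diagonal; L is then symmetric PSD.
    """
    A = sp.csr_matrix(A)
    if A.nnz and abs(A - A.T).max() > 1e-12:
        raise ValueError("adjacency matrix must be symmetric")
    colsum = np.asarray(A.sum(axis=0)).ravel()
    D = sp.diags(colsum, format="csr")
    L = (D - A).tocsr()
    return D, L


@dataclass(frozen=True)
class GeneNetwork:
    """Gene-interaction network aligned with a mutation matrix's columns.

    Attributes
    ----------
    genes : tuple of str
        Ordered gene symbols, aligned with the mutation-matrix columns.
    A : csr_matrix, shape (p, p)
        Symmetric normalized adjacency; entries in [0, 1], zero diagonal.
    D : csr_matrix
        Diagonal matrix of column sums of A.
    L : csr_matrix
        Graph Laplacian D - A (symmetric positive semidefinite).
    """

    genes: tuple[str, ...]
    A: sp.csr_matrix
    D: sp.csr_matrix
    L: sp.csr_matrix

    @classmethod
    def from_edges(cls, edges: EdgeList, genes: Sequence[str]) -> "GeneNetwork":
        A = normalize_adjacency(edges, genes)
        D, L = laplacian(A)
        return cls(tuple(map(str, genes)), A, D, L)

    @property
    def p(self) -> int:
        return len(self.genes)
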