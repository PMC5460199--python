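"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: the global-optimum
oracle enumerates every indicator vector, the permutation oracle enumerates
every combination of row permutations, and the quadratic-form oracle sums
the pairwise formula term by term.
"""

from __future__ import annotations

import itertools

import numpy as np

from mcgfinder.decomposition import objective, update_gene_scores


def brute_force_minimum(X: np.ndarray, L, lambda_L: float) -> tuple[float, np.ndarray]:
    """Global minimum of the regularized objective over all 2^n indicators.

    For each nonzero s the optimal g is the closed-form solve; for s = 0 the
    optimal g is 0 and the objective is ||X||_F^2.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    best_obj = float((X * X).sum())
    best_s = np.zeros(n)
    for bits in itertools.product((0, 1), repeat=n):
        s = np.asarray(bits, dtype=float)
        if s.sum() == 0:
            continue
        g = update_gene_scores(X, s, L, lambda_L)
        obj = objective(X, s, g, L, lambda_L)
        if obj < best_obj:
            best_obj, best_s = obj, s
    return best_obj, best_s


def enumerate_null_scores(rows: np.ndarray) -> np.ndarray:
    """All null gene-score vectors over every combination of row permutations.

    Feasible only for tiny fixtures: the output has prod_i (p!) rows.
    """
    rows = np.asarray(rows, dtype=float)
    k, p = rows.shape
    perms = list(itertools.permutations(range(p)))
    out = []
    for combo in itertools.product(perms, repeat=k):
        out.append(sum(rows[i][list(perm)] for i, perm in enumerate(combo)))
    return np.asarray(out)


def pairwise_quadratic_form(g: np.ndarray, A: np.ndarray) -> float:
    """Direct evaluation of 1/2 * sum_ij A_ij (g_i - g_j)^2."""
    g = np.asarray(g, dtype=float)
    A = np.asarray(A, dtype=float)
    total = 0.0
    p = len(g)
    for i in range(p):
        for j in range(p):
            total += A[i, j] * (g[i] - g[j]) ** 2
    return 0.5 * total


def normalize_adjacency_reference(W: np.ndarray) -> np.ndarray:
    """Entry-wise W_ij / sqrt(d_i d_j) with zero rows left at zero."""
    W = np.asarray(W, dtype=float)
    d = W.sum(axis=1)
    A = np.zeros_like(W)
    for i in range(W.shape[0]):
        for j in range(W.shape[1]):
            if W[i, j] != 0 and d[i] > 0 and d[j] > 0:
                A[i, j] = W[i, j] / np.sqrt(d[i] * d[j])
    return A
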