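"""Rank-one Boolean-constrained decomposition of the mutation matrix.

The mutation matrix ``X`` (samples x genes) is approximated by a sum of
components ``s_r g_r^T`` where ``s_r`` is a binary sample-indicator vector
and ``g_r`` a real gene-score vector. Each component minimizes

    ||X - s g^T||_F^2 + lambda_L * g^T L g,   s in {0,1}^n,

with ``L`` the graph Laplacian of the gene-interaction network. Both
coordinate updates are closed-form KKT minimizers:

* ``g = (||s||^2 I + lambda_L L)^{-1} X^T s``  (a ridge-like smoothed
  column mean over the active samples);
* ``s_i = 1  iff  2 (X g)_i >= ||g||^2``  (inclusive tie rule).

Alternation starts from the all-ones indicator and, because ``s`` is binary
and ``g`` is a deterministic function of ``s``, converges exactly when ``s``
stops changing. Components are extracted one at a time: samples with
``s = 1`` are assigned to the current component and the procedure repeats on
the remaining samples until every sample is assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import cho_factor, cho_solve

from .io import MutationMatrix
from .network import GeneNetwork

__all__ = [
    "Component",
    "DecompositionResult",
    "objective",
    "update_gene_scores",
    "update_sample_indicator",
    "fit_component",
    "decompose",
]

# above this dimension the regularized solve uses a sparse LU factorization
_DENSE_SOLVE_MAX_P = 600


def _solve_regularized(
    L: sp.spmatrix, lambda_L: float, c: float, B: np.ndarray
) -> np.ndarray:
    """Solve (c * I + lambda_L * L) Y = B for one or many right-hand sides."""
    p = L.shape[0]
    M = (c * sp.identity(p, format="csc")) + lambda_L * sp.csc_matrix(L)
    if p <= _DENSE_SOLVE_MAX_P:
        return cho_solve(cho_factor(M.toarray()), B)
    return spla.splu(M.tocsc()).solve(np.asarray(B, dtype=float))


def objective(
    X_active: np.ndarray,
    s: np.ndarray,
    g: np.ndarray,
    L: sp.spmatrix,
    lambda_L: float,
) -> float:
    """Regularized residual ``||X - s g^T||_F^2 + lambda_L g^T L g``."""
    X = np.asarray(X_active, dtype=float)
    s = np.asarray(s, dtype=float)
    g = np.asarray(g, dtype=float)
    fit = float(X.sum()) - 2.0 * float(s @ (X @ g)) + float(s @ s) * float(g @ g)
    penalty = float(g @ (L @ g)) if lambda_L != 0 else 0.0
    return fit + lambda_L * penalty


def update_gene_scores(
    X_active: np.ndarray,
    s: np.ndarray,
    L: sp.spmatrix,
    lambda_L: float,
) -> np.ndarray:
    """Closed-form gene-score update given a fixed sample indicator.

    Solves ``(||s||^2 I_p + lambda_L L) g = X_active^T s``. With
    ``lambda_L = 0`` this is exactly the per-gene mutation frequency within
    the active samples; the Laplacian term shrinks neighbours' scores toward
    each other.
    """
    s = np.asarray(s, dtype=float)
    ssq = float(s @ s)
    if ssq == 0.0:
        raise ValueError("empty sample set: ||s||^2 must be positive")
    if lambda_L < 0:
        raise ValueError("lambda_L must be nonnegative")
    b = np.asarray(X_active, dtype=float).T @ s
    if lambda_L == 0.0:
        return b / ssq
    return np.asarray(_solve_regularized(L, lambda_L, ssq, b), dtype=float)


def update_sample_indicator(X_active: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Closed-form indicator update: ``s_i = 1 iff 2 (X g)_i >= ||g||^2``.

    The inequality is inclusive, so a zero gene-score vector assigns every
    sample (0 >= 0), which is what makes the all-zero matrix terminate with
    a single all-sample component.
    """
    g = np.asarray(g, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("gene scores must be finite")
    margin = 2.0 * (np.asarray(X_active, dtype=float) @ g) - float(g @ g)
    return (margin >= 0.0).astype(np.uint8)


@dataclass
class Component:
    """One (sample indicator, gene score) pair with fit diagnostics.

    ``s`` and ``sample_ids`` cover the samples that were still unassigned
    when this component was extracted; ``members`` are those with ``s = 1``.
    """

    index: int
    sample_ids: tuple[str, ...]
    s: np.ndarray
    g: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = True
    warning: str | None = None

    @property
    def n_active(self) -> int:
        return int(self.s.sum())

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(sid for sid, si in zip(self.sample_ids, self.s) if si)

    def residual_norm(self, X_active: np.ndarray) -> float:
        R = np.asarray(X_active, dtype=float) - np.outer(self.s, self.g)
        return float((R * R).sum())


def fit_component(
    X_active: np.ndarray,
    L: sp.spmatrix,
    lambda_L: float = 0.1,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> Component:
    """Alternate the two KKT updates from the all-ones initialization.

    Stops when ``s`` repeats between consecutive iterations (exact
    convergence for a binary state with deterministic ``g(s)``). Two guards
    handle cases the update rules leave open:

    * if the indicator update empties the sample set, the component reverts
      to the previous iterate and stops;
    * if the indicator revisits any earlier state (a cycle), the iterate
      with the lowest objective seen so far is returned.

    ``tol`` is the slack used when checking objective monotonicity for the
    non-convergence warning; it does not affect the iterates.
    """
    X = np.asarray(X_active)
    m, p = X.shape
    if m < 1 or p < 1:
        raise ValueError("X_active must be nonempty")

    s = np.ones(m, dtype=np.uint8)
    visited = {s.tobytes()}
    trace: list[float] = []
    best_obj = np.inf
    best_state: tuple[np.ndarray, np.ndarray] | None = None
    warning = None
    converged = False
    g = update_gene_scores(X, s, L, lambda_L)  # all-ones initialization solve

    for _ in range(max_iter):
        trace.append(objective(X, s, g, L, lambda_L))
        if trace[-1] < best_obj:
            best_obj, best_state = trace[-1], (s.copy(), g.copy())
        s_new = update_sample_indicator(X, g)
        if s_new.sum() == 0:
            warning = "indicator update emptied the sample set; reverted to previous iterate"
            converged = True
            break
        trace.append(objective(X, s_new, g, L, lambda_L))
        if np.array_equal(s_new, s):
            converged = True
            break
        key = s_new.tobytes()
        if key in visited:
            warning = "indicator cycle detected; returning lowest-objective iterate"
            g_cycle = update_gene_scores(X, s_new, L, lambda_L)
            obj_cycle = objective(X, s_new, g_cycle, L, lambda_L)
            if obj_cycle < best_obj:
                best_obj, best_state = obj_cycle, (s_new, g_cycle)
            s, g = best_state
            converged = True
            break
        visited.add(key)
        s = s_new
        g = update_gene_scores(X, s, L, lambda_L)
    else:
        warning = f"sample indicator did not stabilize within max_iter={max_iter}"
        trace.append(objective(X, s, g, L, lambda_L))

    sample_ids = tuple(str(i) for i in range(m))
    return Component(
        index=0,
        sample_ids=sample_ids,
        s=np.asarray(s, dtype=np.uint8),
        g=np.asarray(g, dtype=float),
        objective_trace=trace,
        converged=converged,
        warning=warning,
    )


@dataclass
class DecompositionResult:
    """Ordered components partitioning the samples, plus the fit settings."""

    components: list[Component]
    sample_assignment: dict[str, int]
    lambda_L: float

    @property
    def R(self) -> int:
        return len(self.components)


def decompose(
    X: MutationMatrix,
    net: GeneNetwork,
    lambda_L: float = 0.1,
    max_components: int = 20,
    max_iter: int = 100,
) -> DecompositionResult:
    """Extract components until every sample is assigned.

    Each round fits one component on the rows not yet assigned; rows with
    ``s = 1`` join that component. The network, Laplacian and ``lambda_L``
    are shared across components. If ``max_components`` rounds leave samples
    unassigned, one flagged catch-all component absorbs the remainder.
    """
    if tuple(net.genes) != tuple(X.genes):
        raise ValueError("gene universes of the matrix and network are not aligned")
    n = X.n
    remaining = np.arange(n)
    components: list[Component] = []
    assignment: dict[str, int] = {}
    Xf = X.X.astype(float)

    while remaining.size > 0 and len(components) < max_components:
        comp = fit_component(Xf[remaining], net.L, lambda_L, max_iter=max_iter)
        comp.index = len(components) + 1
        comp.sample_ids = tuple(X.samples[i] for i in remaining)
        for sid in comp.members:
            assignment[sid] = comp.index
        components.append(comp)
        remaining = remaining[comp.s == 0]

    if remaining.size > 0:
        # max_components exhausted: force the remainder into one catch-all
        s = np.ones(remaining.size, dtype=np.uint8)
        g = update_gene_scores(Xf[remaining], s, net.L, lambda_L)
        comp = Component(
            index=len(components) + 1,
            sample_ids=tuple(X.samples[i] for i in remaining),
            s=s,
            g=g,
            objective_trace=[objective(Xf[remaining], s, g, net.L, lambda_L)],
            converged=True,
            warning="catch-all component: max_components exhausted with samples unassigned",
        )
        for sid in comp.members:
            assignment[sid] = comp.index
        components.append(comp)

    return DecompositionResult(components, assignment, lambda_L)
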