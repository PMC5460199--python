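"""Seeded synthetic fixtures with planted components and matched networks.

A scenario plants one or more blocks — a subset of samples with an elevated
per-cell Bernoulli mutation rate on a subset of genes — on top of a uniform
Bernoulli background, emulating sample subsets whose tumours share a
perturbed pathway. The gene network is an independent-edge random graph in
which pairs of genes inside the same planted set are connected with a
higher probability than background pairs, so planted genes are
preferentially interconnected. Sample sets are pairwise disjoint (matching
the strict partition of the decomposition); gene sets may overlap.

Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import EdgeList, MutationMatrix

__all__ = ["PlantedScenario", "GroundTruth", "generate", "default_scenario", "background_scenario"]

# study-condition defaults: one planted 30-sample x 10-gene block at per-cell
# rate 0.6 over a 0.02 background in a 200 x 100 matrix
_DEFAULT_N = 200
_DEFAULT_P = 100
_DEFAULT_BLOCK = ((tuple(range(30)), tuple(range(10)), 0.6),)
_DEFAULT_BACKGROUND = 0.02
_DEFAULT_MODULE_EDGE_P = 0.5
_DEFAULT_BACKGROUND_EDGE_P = 0.05


@dataclass(frozen=True)
class PlantedScenario:
    """Generative settings for one synthetic mutation study.

    ``components`` is a tuple of ``(sample_indices, gene_indices, rate)``
    triples; cells inside a block mutate at ``rate``, all other cells at
    ``background_rate``. ``module_edge_prob`` / ``background_edge_prob``
    control network density inside planted gene sets versus elsewhere.
    """

    n: int = _DEFAULT_N
    p: int = _DEFAULT_P
    components: tuple[tuple[tuple[int, ...], tuple[int, ...], float], ...] = _DEFAULT_BLOCK
    background_rate: float = _DEFAULT_BACKGROUND
    module_edge_prob: float = _DEFAULT_MODULE_EDGE_P
    background_edge_prob: float = _DEFAULT_BACKGROUND_EDGE_P
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.p < 1:
            raise ValueError("n and p must be positive")
        for rate in (
            self.background_rate,
            self.module_edge_prob,
            self.background_edge_prob,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        seen: set[int] = set()
        for samples, genes, rate in self.components:
            if not 0.0 <= rate <= 1.0:
                raise ValueError("planted per-cell rate must lie in [0, 1]")
            if rate <= self.background_rate:
                raise ValueError("planted per-cell rate must exceed the background rate")
            if any(i < 0 or i >= self.n for i in samples):
                raise ValueError("planted sample index out of range")
            if any(j < 0 or j >= self.p for j in genes):
                raise ValueError("planted gene index out of range")
            if seen.intersection(samples):
                raise ValueError("planted sample sets must be pairwise disjoint")
            seen.update(samples)


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a generated fixture, in label space."""

    sample_sets: tuple[tuple[str, ...], ...]
    gene_sets: tuple[tuple[str, ...], ...]
    scenario: PlantedScenario = field(repr=False, default=None)


def _labels(prefix: str, count: int) -> tuple[str, ...]:
    width = max(3, len(str(count)))
    return tuple(f"{prefix}{i:0{width}d}" for i in range(count))


def generate(scenario: PlantedScenario) -> tuple[MutationMatrix, EdgeList, GroundTruth]:
    """Draw one mutation matrix + network fixture from a scenario.

    Cells are sampled independently (background first, planted blocks
    overwritten with their own draws), so fixtures carry the sampling noise
    the method is meant to tolerate rather than copied deterministic
    patterns. Returns the matrix, the canonical edge list, and the planted
    ground truth.
    """
    rng = np.random.default_rng(scenario.seed)
    n, p = scenario.n, scenario.p
    samples = _labels("S", n)
    genes = _labels("G", p)

    X = (rng.random((n, p)) < scenario.background_rate).astype(np.uint8)
    for sample_idx, gene_idx, rate in scenario.components:
        block = (rng.random((len(sample_idx), len(gene_idx))) < rate).astype(np.uint8)
        X[np.ix_(list(sample_idx), list(gene_idx))] = block

    iu, ju = np.triu_indices(p, k=1)
    probs = np.full(iu.size, scenario.background_edge_prob)
    for _, gene_idx, _ in scenario.components:
        members = np.zeros(p, dtype=bool)
        members[list(gene_idx)] = True
        probs[members[iu] & members[ju]] = scenario.module_edge_prob
    drawn = rng.random(iu.size) < probs
    pairs = [(genes[i], genes[j]) for i, j in zip(iu[drawn], ju[drawn])]
    edges = EdgeList.from_pairs(pairs)

    truth = GroundTruth(
        sample_sets=tuple(
            tuple(samples[i] for i in s_idx) for s_idx, _, _ in scenario.components
        ),
        gene_sets=tuple(
            tuple(genes[j] for j in g_idx) for _, g_idx, _ in scenario.components
        ),
        scenario=scenario,
    )
    return MutationMatrix(samples, genes, X), edges, truth


def default_scenario(seed: int = 0) -> PlantedScenario:
    """The standard planted-block recovery scenario (see module docstring)."""
    return PlantedScenario(seed=seed)


def background_scenario(
    n: int = 100,
    p: int = 200,
    rate: float = 0.05,
    edge_prob: float = 0.05,
    seed: int = 0,
) -> PlantedScenario:
    """Pure-background scenario (no planted component) for null calibration."""
    return PlantedScenario(
        n=n,
        p=p,
        components=(),
        background_rate=rate,
        module_edge_prob=edge_prob,
        background_edge_prob=edge_prob,
        seed=seed,
    )
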