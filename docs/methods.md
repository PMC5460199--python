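# Methods

## Problem and model

Tumour cohorts are heterogeneous: a driver gene may be recurrently mutated
only within the subset of samples whose tumours share a perturbed pathway.
`mcgfinder` therefore scores mutational recurrence within automatically
selected sample subsets rather than across the whole cohort, and borrows
strength across a gene-interaction network so that genes whose neighbours
are recurrently mutated are not overlooked.

The binary mutation matrix `X` (n samples × p genes) is approximated by a
sum of rank-one components `s_r g_rᵀ`, each fitted by minimizing

    ‖X − s gᵀ‖²_F + λ_L gᵀ L g ,   s ∈ {0,1}ⁿ,

with `L = D − A` the graph Laplacian of the symmetric normalized adjacency
`A = Dg^{-1/2} W Dg^{-1/2}` (`Dg` = raw degree matrix of the weight matrix
`W`; `D` = diagonal of column sums of `A`). The quadratic form satisfies
`gᵀLg = ½ Σ_ij A_ij (g_i − g_j)²`, so the penalty is a smoothness prior on
scores of interacting genes. Modelling assumptions worth keeping in mind:

* mutations are binarized — multiplicity, variant class and allele
  fraction are ignored;
* each sample belongs to exactly one component (a strict partition);
* the network is undirected and its edge weights are trusted as given;
* gene scores may go negative (no nonnegativity constraint exists in the
  gene-score solve); the significance test is one-sided on high scores.

## Fitting

Both coordinate updates are exact minimizers (KKT conditions):
`g = (‖s‖²I + λ_L L)^{-1} Xᵀ s`, and `s_i = 1` iff `2(Xg)_i ≥ ‖g‖²` with an
*inclusive* inequality — a zero score vector therefore assigns every
sample, which terminates degenerate inputs (all-zero matrices) gracefully.
Alternation starts from `s = 1_n`. Because `s` is binary and `g` is a
deterministic function of `s`, convergence is declared exactly when `s`
repeats between consecutive iterations; each update weakly decreases the
objective, so the objective trace is non-increasing. The alternation
reaches a fixed point that is a local optimum; on exhaustively enumerable
instances (n = 8) it attains the brute-force global optimum in roughly 90%
of planted draws and can never go below it.

Two guards cover situations the update rules leave open. If the indicator
update empties the sample set (possible with one dominant gene score and
sparse rows), the component reverts to the previous iterate and stops.
Because the indicator state space is finite, alternation either converges
or cycles; visited indicators are hashed and on a repeat the
lowest-objective iterate seen is returned. Components are extracted one at
a time on the rows still unassigned, with the network, `L` and `λ_L`
unchanged; if `max_components` rounds leave samples over, one flagged
catch-all component absorbs them.

The regularized solve uses a dense Cholesky factorization up to p = 600
and a sparse LU factorization beyond, giving relative residuals near
machine precision in both regimes.

## Significance

For component r, `Xnet = X(‖s_r‖²I + λ_L L)^{-1}` satisfies
`g_r = Xnetᵀ s_r`, so each gene's score is a sum over the component's
member rows of one `Xnet` entry per row. The null model permutes the
entries of each member row independently (entries within a row are
exchangeable when background mutations carry no gene identity). The
semi-exact estimator computes the null mean (sum of row means) and
variance (sum of per-row population variances) exactly — they are shared
by all genes — and evaluates a Gaussian upper tail, justified by the CLT
across independently permuted rows. The Monte-Carlo mode draws explicit
row permutations with the add-one estimator `p = (1+k)/(n_perm+1)`; it is
the reference the semi-exact mode is validated against (maximum
|Δp| a few thousandths at 20 active rows and 100,000 draws) and is
exposed as a run mode for users who prefer the nonparametric tail.

Degenerate cases: zero-variance nulls give p = 1 unless the observed score
exceeds the null mean (then p = 0), and genes whose member-row `Xnet`
columns are structurally zero get p = 1. BH q-values are computed within
each component (statsmodels' step-up implementation); a gene's overall
significance is the minimum q across components (ties to the smallest
component index) and the candidate call is strict: `min_q < 0.05`.

With few member rows the scores are nearly lattice-valued and the Gaussian
tail is only approximate; the acceptance checks show the net effect is
conservative (the fraction of background genes called at q < 0.05 stays
at or below 0.05 on pure-noise cohorts). The min-q aggregation performs no
cross-component correction beyond BH within components, mirroring the
selection rule the decomposition defines.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `lambda_L` | 0.1 | weight of the Laplacian smoothness penalty (unitless); 0 reduces gene scores to within-component mutation frequencies |
| `q_threshold` | 0.05 | strict FDR cut for candidate calls |
| `max_components` | 20 | cap on extracted components before the catch-all |
| `max_iter` | 100 | alternation cap per component (convergence is typically < 10 iterations) |
| `significance_mode` | `semi_exact` | or `monte_carlo` |
| `n_perm` | 10000 | draws in `monte_carlo` mode (minimum 100) |

The gene universe is the intersection of matrix and network genes: genes
without any interaction cannot receive or give network influence, and the
dropped set is reported so users can audit the coverage limitation this
implies. Samples are never dropped — all-zero rows inform the indicator
update — and no hypermutator filter is applied.

## Synthetic studies

The generator plants one or more blocks (a sample subset × gene subset
with elevated per-cell Bernoulli rate) over a uniform Bernoulli
background, and draws an independent-edge network that connects genes
within a planted set with probability 0.5 versus 0.05 elsewhere, so
planted genes are preferentially interconnected. Default study
conditions: n = 200 samples, p = 100 genes, one 30 × 10 block at rate 0.6
over background 0.02. Blocks are sampled cell-wise (not copied patterns),
so fixtures carry sampling noise; sample sets are disjoint to match the
strict partition, gene sets may overlap.

What passing these studies shows — and does not. They demonstrate that the
alternation recovers a planted sample subset (mean Jaccard ≈ 0.97) and
that its genes reach significance (recall 100% over 50 replicates), and
that false-discovery control holds under a homogeneous background. Real
cohorts violate the generator's assumptions in known ways: background
mutation rates vary by gene length and genomic context, hypermutated
samples exist, networks are biased toward well-studied genes, and
intra-tumour heterogeneity is not represented. Results on the synthetic
conditions bound none of those effects.

Scale choices for the routine checks: null calibration uses 100 × 200
background cohorts (50 seeds); the p-value uniformity check uses a
1000-sample cohort, the regime where the Gaussian tail approximation is
designed to operate (small cohorts give lattice-valued scores whose
discrete p-values are conservative rather than uniform); the brute-force
optimality ensemble uses n = 8, p = 8 instances whose planted block (4 × 4
at rate 0.75) preserves the per-sample separation of the default study
conditions (three of four planted genes hit per planted sample, matching
six of ten at full scale).

## Known limitations

* Rank-one components cannot represent overlapping sample subsets; a
  sample whose tumour carries two pathway hits is assigned to one.
* `λ_L` is fixed, not tuned; the decomposition is insensitive over a wide
  range but extreme values flatten scores toward the component mean.
* The Gaussian tail understates extreme-tail discreteness for very small
  components; the Monte-Carlo mode is the fallback when exact tail mass
  matters.
* Genes outside the interaction network are not scored at all.
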