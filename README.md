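# mcgfinder

Detection of mutated cancer gene candidates from binary somatic-mutation
matrices, for cancer genomics analysts working with cohorts that show
inter-patient heterogeneity: driver genes that recur only within a subset
of tumours, not across the whole cohort, and that may be hit at low
frequency individually while their network neighbours carry the remaining
mutations of the same perturbed pathway.

## Model

The input is a binary matrix **X** (n samples × p genes, `X_ij = 1` if
sample *i* carries a somatic mutation of gene *j*) and an undirected
gene-interaction network with symmetric normalized adjacency **A**
(`A = Dg^{-1/2} W Dg^{-1/2}`) and graph Laplacian `L = D − A`, where `D` is
the diagonal of column sums of `A`. The matrix is decomposed into rank-one
components, each the outer product of a binary sample-indicator vector
`s ∈ {0,1}^n` and a real gene-score vector `g ∈ R^p`, by minimizing

    min_{s,g}  ‖X − s gᵀ‖²_F + λ_L gᵀ L g ,    s ∈ {0,1}^n ,

where `gᵀ L g = ½ Σ_ij A_ij (g_i − g_j)²` penalizes score differences
between interacting genes (default `λ_L = 0.1`). Both coordinate updates
are closed-form KKT minimizers,

    g = (‖s‖² I_p + λ_L L)^{-1} Xᵀ s ,
    s_i = 1  iff  2 (X g)_i ≥ ‖g‖² ,

alternated from the all-ones indicator until `s` stabilizes. Samples with
`s = 1` are assigned to the component and the procedure repeats on the
remaining samples until every sample is assigned.

Significance uses the identity `g = Xnetᵀ s` with the network-influenced
matrix `Xnet = X (‖s‖² I + λ_L L)^{-1}`: under the null that background
mutations carry no gene identity, the entries within each member row of
`Xnet` are exchangeable, so the null score of a gene is a sum of one
uniformly drawn entry per row. Its mean and variance are computed exactly
and a Gaussian upper tail gives the semi-exact p-value (an explicit
permutation mode is available as `--mode monte_carlo`). Benjamini–Hochberg
q-values are computed within each component; a gene's significance is its
smallest q across components and candidates are genes with `min_q < 0.05`.

## Worked example

`examples/01_end_to_end.py` plants one component — 30 of 200 samples
mutating 10 interconnected genes of 100 at per-cell rate 0.6 over a 0.02
background — and runs the full pipeline. Its output:

```
components: 5  sizes: [29, 100, 26, 23, 22]
candidates at q < 0.05: 23
planted genes recovered: 10/10
gene  component    score      p_value      q_value        min_q  candidate
G000          1 0.516178 6.537407e-20 7.466888e-19 7.466888e-19       True
G001          1 0.481751 3.341352e-17 3.341352e-16 3.341352e-16       True
...
```

Component 1 (29 samples) is the recovered planted subset; all 10 planted
genes (G000–G009) head the table with extreme min-q values. The `score`
column is the gene's entry in that component's score vector — roughly the
smoothed mutation frequency within the component's samples — and
`p_value`/`q_value` refer to the component in which the gene was most
significant. The remaining candidates are background genes picked up by
the small noise components.

The other examples isolate single stages: `02_decomposition.py` shows one
alternation converging and the Laplacian penalty lending a positive score
to an unmutated network neighbour; `03_significance_modes.py` compares
semi-exact against 100,000-permutation p-values (max |Δp| ≈ 0.004).

## Command line

```sh
mcgfinder --mutations cohort.tsv --network interactions.tsv --out results.tsv \
          --lambda 0.1 --q-threshold 0.05 --seed 1
```

Inputs are plain TSV (mutation matrix with a gene-symbol header and sample
IDs in the first column; 2–3 column edge list). A minimal MAF-like reader
(`read_maf_lite`) collapses per-mutation records to the binary matrix.
Genes absent from the network are dropped (reported in a sidecar file) and
a JSON run report is written next to the output table.

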