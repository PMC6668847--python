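# gemthresh

Benchmarking the preprocessing decisions made when overlaying transcriptomic
data on genome-scale metabolic networks (GEMs).

## The problem

Context-specific metabolic models start from a deceptively simple step:
given a gene × tissue expression matrix and a GEM whose reactions carry
gene-protein-reaction (GPR) boolean rules — AND for the subunits of an
enzyme complex, OR for isoenzymes — decide which reactions are *active* in
each tissue.  Three decisions hide in that step, and the literature makes
them inconsistently:

1. **Gene mapping** — how a GPR combines gene values into one reaction value:

   | | AND (complex) | OR (isoenzymes) |
   |---|---|---|
   | **GM1** | min | max |
   | **GM2** | min | sum |

2. **Thresholding** — when a value counts as expressed.  *Global* schemes
   apply one pooled-percentile cutoff to everything (`global50`,
   `global75`).  *Local* schemes give gene *g* its own threshold
   `t_g = clamp(mean_g, lower, upper)`, with bounds from the pooled
   expression distribution: `local25` (lower bound only, two states
   OFF / MAYBE-ON) and `local25-75` / `local25-90` (lower and upper bound,
   three states OFF / MAYBE-ON / ON — genes always under the lower bound
   are never ON, genes always over the upper bound always are).

3. **Order** — map genes to reactions then threshold reaction expression
   (Order 1), or threshold gene expression then map (Order 2).

That makes 2 × 2 × 5 = 20 combinations (global schemes are single-threshold
by construction).  `gemthresh` runs all of them and quantifies their impact
three ways: a PCA of the binary (configuration, tissue) × reaction activity
table with per-factor variance attribution (100·R² of the ordering-maximized
Pearson correlation between component scores and factor categories); a
permutation test on the mean within-organ-system Euclidean distance between
tissue activity vectors; and hypergeometric pathway enrichment
(P(X ≥ x) with population M, pathway size K, active set N, overlap x) scored
against curated pathway–tissue pairs as false-negative counts.

Everything runs on self-contained synthetic fixtures: networks with
specialist / isoenzymatic / multimeric / promiscuous GPR mixes, and
expression matrices with planted organ-system groups, housekeeping genes,
always-low genes and pathway–tissue ground truth.  Real inputs (SBML L3 +
fbc models, gene × sample TSV/CSV) are supported through the same API.

## Worked example

```python
from gemthresh import (FixtureSpec, generate_fixture, run_all, run_pca,
                       factor_attribution)
from gemthresh.preprocess import factor_labels

network, expr, truth, known = generate_fixture(FixtureSpec(seed=0))
table = run_all(network, expr)          # 640 rows: 20 configs x 32 tissues
pca = run_pca(table)
print(factor_attribution(pca, factor_labels(table)).round(1))
```

prints

```
     gene_mapping  order  scheme_approach  scheme  tissue
PC1           0.0    0.3             55.6    84.5     3.2
PC2           0.0    0.0             31.2    39.5    30.2
PC3           0.0    0.3              6.7    23.5    54.0
```

PC1 — the dominant axis of variation in active-reaction content — is driven
by thresholding (the global-vs-local choice explains 55.6% of it, the full
scheme identity 84.5%), not by gene mapping (0.0%), step order (0.3%) or
tissue identity (3.2%): the preprocessing decision matters more than the
biology unless it is made carefully.  The scripts in `examples/` walk
through each capability (GPR evaluation, the sweep, the PCA, the
organ-system permutation test, pathway enrichment) with commentary.

A thin CLI mirrors the library: `gemthresh synth | run | pca | grouping |
enrich` (see `--help`).

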