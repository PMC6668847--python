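# Methods

## Scope and model

`gemthresh` implements the preprocessing step that turns a gene × sample
expression matrix plus a GPR-annotated metabolic network into per-sample
binary active-reaction calls, across the full decision space of gene
mapping (GM1/GM2), thresholding scheme (global50, global75, local25,
local25-75, local25-90) and step order (map→threshold vs threshold→map),
together with three analyses that quantify what those decisions do.  It
does not extract flux-consistent models (GIMME/iMAT-style methods),
simulate flux, normalize expression data, or model enzyme promiscuity
kinetically.

## GPR grammar and evaluation

Rules are n-ary AND/OR trees over opaque gene identifier strings.  Mixing
`and` and `or` at one parenthesis level is a syntax error rather than a
precedence guess; Recon-style rules are fully parenthesized so this
rejects only genuinely ambiguous strings.  Serialization re-parses to a
structurally equal tree.

Evaluation: AND = min of children under both mappings; OR = max (GM1) or
sum (GM2).  For non-negative inputs this gives GM1 ≤ GM2 pointwise, and
both results lie between the smallest leaf value and the sum of leaf
values (counted with multiplicity).  *Missing-gene policy*: an unmeasured
gene is never imputed.  A missing child is dropped from an OR (the
remaining isoenzymes still carry the reaction); an AND with any missing
subunit is missing (complex abundance unknown); a rule missing everywhere
makes its reaction "no data", a state kept distinct from "inactive" and
excluded from all active-set denominators, enrichment populations and
distance computations.  Determinant-gene sets follow the arithmetic:
argmin leaves for AND, the argmax branch for GM1-OR, all non-missing
branches for GM2-OR, with ties keeping every tied branch (deterministic
and order-independent).

## Thresholding

Percentile bounds are computed on the pooled distribution of *all* matrix
entries, zeros included, with the linear interpolation convention
(index h = (n−1)·p/100).  Excluding zeros or switching convention would
silently shift every preset, so the convention is fixed and documented
here rather than configurable.  Local thresholds clamp the per-gene mean
across all samples (not non-zero samples) into [lower, upper]; T1 schemes
have no upper clamp.  A value is active when it is ≥ its threshold *and*
strictly positive; the ≥ tie rule keeps the three-state guarantee exact
when a value equals the upper bound.  Activity values retain their
magnitude (they are not binarized at this stage) so that Order 1 can
threshold genuine reaction-expression magnitudes; binarization happens
once, at the end of a pipeline run.

Scale equivariance (multiplying the matrix by c > 0 scales bounds and
thresholds by c and preserves every state) holds exactly in real
arithmetic; in floating point a gene sitting *exactly* on its own
threshold — e.g. a constant row under local T1 — can flip by one ulp.

## Step orders

Order 2 thresholds gene expression and maps the thresholded values; a
reaction is active where its mapped value is positive.  (Under Order 2
the two gene mappings give identical *binary* calls, since a sum of
non-negatives is positive exactly when their max is: gene mapping can only
matter through Order 1 thresholds or downstream magnitudes.)

Order 1 maps raw expression first and thresholds at the reaction level:

* global schemes: every reaction is cut at the pooled *gene*-expression
  percentile bound — global bounds are defined once, on the gene
  distribution, under both orders;
* local + GM1: t_r = clamp(mean over samples of reaction expression),
  since GM1 reaction expression is a single dominating gene value per
  sample and the gene-level rule transfers directly;
* local + GM2: several genes contribute to a reaction, so
  t_r = Σ over top-level OR alternatives of clamp(mean over samples of
  that alternative's GM2-evaluated value); a rule whose root is not OR is
  a single alternative.  When an alternative is itself an AND complex its
  contribution is the clamped mean of the complex's min — the aggregation
  at complex granularity is this package's design choice among the
  readings the reaction-level rule admits; alternatives missing in all
  samples are skipped.

## Decision-impact PCA

The binary (config, sample) × reaction table drops no-data columns and
columns constant across all rows, then centers each *row* to zero mean —
row centering is the documented procedure for this analysis (each profile
is centered on its own activity rate); conventional column centering is
available as an option for sensitivity checks.  Scores come from the SVD.
Factor attribution codes a factor's k categories as integers 1..k and
reports 100·R² for the maximal |Pearson R| over category orderings:
exhaustive for k ≤ 6, and for larger k (e.g. 32 tissues, where 32!
orderings are unsearchable) the mean-score ordering, which attains the
maximum for balanced designs; the path taken is logged.  Using |R| makes
the search symmetric under order reversal.

## Tissue similarity

Euclidean distances between per-sample binary activity vectors (no-data
columns dropped consistently; for binary vectors distance = √Hamming).
Organ systems with fewer than three tissues are excluded.  The permutation
p-value draws `n_perm` (default 10000) groups of the observed size
uniformly without replacement from all samples — the observed group may
recur, matching uniform subset sampling — and reports the fraction of
random mean distances *strictly* below the observed mean.  The strict
definition can return exactly 0; a `(r+1)/(n+1)` estimator is available by
flag.  Each preprocessing configuration is analyzed separately.  PCoA is
classical double-centered eigendecomposition; negative-eigenvalue mass is
reported, never clipped silently.

## Pathway enrichment

Population M = gene-associated reactions with data carrying a subsystem
label — enrichment is only meaningful where activity is observable, so
rule-less and no-data reactions are excluded (configurable in principle by
supplying a different pathway map).  p = P(X ≥ x) = 1 − CDF(x−1) for
X ~ Hypergeom(M, K, N); significance at p < 0.05 without multiple-testing
correction, matching common practice for this analysis (a
Benjamini–Hochberg option exists, off by default).  Ubiquity is the
tissue-dimension row sum of each method's binary enrichment matrix;
pathways are clustered on their ubiquity profiles by complete-linkage
Euclidean hierarchical clustering cut into 5 clusters (scipy's
deterministic lowest-index tie-break).  False negatives count known
pathway–tissue pairs without an enrichment call, aggregated per method and
per cluster or per known ubiquity category (1–2 tissues = tissue-specific,
3–10 = group-specific, more = ubiquitous).

## Synthetic fixtures

The generator emulates the statistical structure of a tissue atlas overlaid
on a human-scale GEM, at desk scale.  Defaults (all in `FixtureSpec`,
deterministic per seed):

* 300 genes, 200 reactions, 32 samples; GPR mix 35% specialist, 25%
  isoenzymatic, 20% multimeric, 10% mixed, 10% rule-less — isoenzymes and
  complexes each near the ~20% reported for human reconstructions, with
  promiscuity arising from within-pool gene reuse;
* three organ-system groups of 6/5/4 samples (organ systems worth testing
  have >2 tissues; the rest of the atlas is ungrouped);
* seven planted pathways of 15 reactions each, drawing genes from disjoint
  pools: 2 tissue-specific (elevated in 1–2 ungrouped samples), 3
  group-specific (one per group), 2 ubiquitous;
* abundances in FPKM-like units: baseline log-normal(meanlog 1, sdlog 1)
  per gene with log-normal(0, 0.4) per-sample noise — a heavy-tailed
  distribution whose pooled lower quartile lands near the ~1 FPKM
  detection level; planted genes ×8 in their target samples; housekeeping
  (ubiquitous-pathway) genes at log-normal(3.5, 0.2), which places them
  between the pooled 75th and 90th percentiles so the local25-75 upper
  clamp holds them ON while local25 and local25-90 lose them in low-noise
  samples; always-low genes (10% of the gene budget, from the background
  pool) at log-normal(−3, 0.3), far below the pooled 25th percentile in
  every sample.

Ground truth (group membership, gene classes, pathway–tissue pairs with
ubiquity categories) is emitted alongside the data so tests never
re-derive it.  Setting `effect_size = 1` ablates the planted structure and
is the negative control.  What the fixtures do *not* emulate: realistic
gene–gene correlation beyond the planted blocks, between-sample library
effects, compartment structure, or Recon-scale sparsity — so passing tests
show the pipeline recovers structure of this planted kind, not that any
scheme is optimal for a particular real atlas.  Problem sizes throughout
(200-reaction networks, 10000 permutations, 1000-instance oracle sweeps)
are the package's chosen desk-scale defaults.

The packaged file `src/gemthresh/data/known_pairs_synthetic.tsv` is a
*synthetic* curated-pair table: 154 pathway–tissue pairs over 32 human
tissue names in the proportions of the curation it mirrors (3 ubiquitous,
6 group-specific, 20 tissue-specific pathways), for exercising the loader
and the false-negative bookkeeping at realistic scale.

## Numerical and degenerate-input choices

* Percentiles: numpy `method="linear"`; all entries pooled.
* Active tie rule: value ≥ threshold ⇒ active, but activity must be > 0.
* PCA requires ≥ 2 rows and ≥ 1 varying column; all-constant input is an
  error ("no variation"), not a silent zero.
* Permutation p with identical group members is exactly 0 under the strict
  definition; use the plus-one estimator when downstream code cannot
  accept 0.
* Hierarchical clustering ties: lowest-index merge (scipy default).
* Single-leaf GPRs whose gene occurs in several reactions are labelled
  `promiscuous`, a sixth pattern label alongside no-rule / specialist /
  isoenzymatic / multimeric / isoenzymatic-multimeric, so the taxonomy
  stays exhaustive.

## Known limitations

* Order 1 + local + GM2 thresholds aggregate at OR-alternative
  granularity; other readings of the reaction-level sum rule exist (see
  above) and would change Order 1 calls for nested complex-isoenzyme
  rules.
* The 58–90% "fraction of model genes mapped" style summaries depend on an
  aggregation (union of determinant genes over reactions and samples) that
  callers assemble from `determinant_genes`; no single canonical formula
  is imposed.
* Enrichment populations, alpha, and the correction switch materially
  change false-negative counts; defaults mirror the analysis this package
  benchmarks, not a recommendation.
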