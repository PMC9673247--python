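# Methods

This note records the statistical model, the defaults and the reasoning
behind the design choices in `fruitcore`, in the spirit of a package
methods appendix.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Count model and nested tests

Gene-level counts are modelled as NB2: `y ~ NB(mu, alpha)` with
`Var = mu + alpha mu^2`, log link and a per-sample offset `log s_j`.
Model fitting is iteratively reweighted least squares on the exact NB
log-likelihood (Gamma terms included), with step-halving whenever a step
would reduce the likelihood, convergence at `max |d beta| < 1e-8`, and at
most 100 iterations.  An all-zero response returns a flagged degenerate fit
with the intercept at its lower bound.

Developmental time enters through a natural cubic spline basis built by the
truncated-power construction: boundary knots at the extreme stage
coordinates, interior knots at quantiles, affine extrapolation beyond the
boundary.  Stage labels are mapped to consecutive integers in developmental
order (stage 2 → 2, stage 3 → 3, transition → 4).  With stages shared
across species, any monotone coding spans the same model space up to
reparameterization, so the choice does not affect likelihoods or tests.
The default spline dimension is `df = min(#stages − 1, 3)`; with the three
shared stages of the flagship design this gives `df = 2`, the saturated
stage-means space, which is the richest trajectory the data can identify.
`df` is configurable everywhere.

Three designs are nested per gene: intercept only (M0), intercept + spline
(M1), and intercept + group + spline + group:spline (M2), the group being
fruit type (or species, for within-family comparisons).  Likelihood-ratio
statistics are referred to upper-tail chi-square with `p_full − p_reduced`
degrees of freedom.  Two safeguards make the statistic non-negative in
floating point: the same per-gene dispersion (estimated once under the
fullest design of a comparison) is used in both fits, and the reduced fit
is warm-started from the least-squares projection of the full fit's linear
predictor (with a symmetric retry if the full fit ever lands below the
reduced one); the statistic is finally clipped at zero.

The divergence test compares M2 against M1 *without* a group main effect in
the reduced model, so a pure magnitude shift between fruit types counts as
divergence.  This is the literal reading of "better explained by
group-specific trajectories"; a `shape_only` flag moves the group main
effect into the reduced model for users who want shape-only divergence.

### Classification rule

At BH-adjusted `padj < alpha` (default 0.01):

- `divergent_de` iff `padj(M2 vs M0) < alpha` **and** `padj(M2 vs M1) < alpha`
  — the gene must both change between at least two stages under the
  group-aware model and genuinely require group-specific trajectories;
- `conserved_de` iff not divergent and `padj(M1 vs M0) < alpha`;
- `non_de` otherwise.

Genes with total count below 10 across the comparison (configurable) are
excluded from testing and reported as `untested`; no further independent
filtering is applied.

## Dispersion estimation

1. **Gene-wise**: the Cox-Reid-adjusted profile likelihood
   (`ll(alpha) − 0.5 log det(X' W X)`) is maximized over `log alpha` in
   `[log 1e-8, log 100]` by bounded scalar search, alternating twice with
   re-fitting the means at the current dispersion.  The CR term corrects
   the downward bias from estimating the mean coefficients.  For Poisson
   data the estimate is a boundary MLE: roughly half the genes land on the
   floor and the rest at O(1/n) positive values, so "no overdispersion"
   should be read as `alpha * mu << 1`, not literal floor equality.
2. **Trend**: `alpha(mu) = a0 + a1/mu` fitted across genes by
   gamma-weighted IRLS (weights `1/fit^2`) on the mean normalized count,
   excluding floor-hugging genes and genes more than four decades from the
   current fit.
3. **Shrinkage**: the final value is the posterior mode under a log-normal
   prior centred on the trend.  The prior variance is the MAD-based spread
   of log residuals minus the expected sampling variance of a log
   dispersion estimate (`trigamma((n − p)/2)`), floored at 0.25 to guard a
   degenerate prior.  Genes whose gene-wise estimate sits more than two
   spread-SDs *above* the trend keep their gene-wise value, so genuinely
   noisy genes are not shrunk into false positives.  Non-convergent genes
   are flagged and assigned the trended value.

No exact numerical agreement with any external package's dispersion
estimates is attempted; only the statistical recipe is shared.

## Normalization

Size factors are median-of-ratios: reference = per-gene geometric mean over
samples (genes with any zero excluded), factor = median ratio per sample,
rescaled to geometric mean 1.  On cross-species orthogene matrices the
factors are computed on the joint matrix by default (the data are treated
as one dataset); a per-species flag exists.  No transcript-length
correction is applied across species: with one gene per species per
orthogene, length is a gene-level constant absorbed by the size factor and
the intercept.

Median-of-ratios assumes most genes are unchanged.  When a large fraction
of genes shares stage-dependent trajectories, the reference tilts
stage-dependently by a few percent, which is enough to inflate the
false-positive rate of the M1-vs-M0 test at 45 samples.  The comparison
runner therefore runs **two passes** by default (`refine_sf=True`): size
factors are re-estimated on the genes the first pass called non-DE, and
the tests repeated.  The refinement is skipped when fewer than
`max(50, 20%)` of genes look stable, and it is a no-op on near-null data.

## Profile clustering

DE cohorts are summarized per gene as mean normalized counts per
(group, stage) cell, `log2(x + 1)`-transformed and z-scored per gene with
the sample SD.  Whether to cluster normalized or variance-stabilized values
is an open choice; `log2(x+1)` z-scores are the declared stand-in and are
what the clustering consumes.  Constant genes get an all-zero flagged row
and are excluded from dissimilarities (their correlation is undefined);
they are reported unclustered.

Dissimilarity defaults to `(1 − Pearson r)/2` between z-scored profiles —
profile-shape clustering should be scale-free — with Euclidean available.
The divisive hierarchy is the Kaufman–Rousseeuw DIANA procedure: always
split the cluster of largest diameter; seed the splinter group with the
object of maximal average dissimilarity to the rest; move objects while
the gap (average dissimilarity to own side minus to the splinter) is
maximal and strictly positive; the split height is the parent diameter.
All ties break on the lowest object index, which makes the tree fully
deterministic.  Flat clusters come from cutting the first `k − 1` splits
or all splits above a height; clusters below `min_size` (default 15) are
reported unassigned.  Cluster counts are an *output* of the cut, never a
target.  PCA summaries are centered SVD with percent variance per
component.

## GO enrichment

The ontology is read from OBO 1.2 via `obonet`; obsolete terms are
dropped, `alt_id`s resolve to canonical terms, `is_a` and (by default)
`part_of` edges are followed.  Annotations from one or more TSV sources are
unioned per gene and closed under the true-path rule.  Terms with fewer
than 3 annotated universe genes are skipped (configurable).  The universe
is configurable between a whole-genome annotation set and the orthogene
set.

Two testing modes: *classic* (independent one-sided hypergeometric tests)
and *elim*, which processes terms deepest-level first and, when a term's p
falls below the elimination cutoff (default 0.01), removes its genes from
all strict ancestors before they are tested.  Elim is the documented,
fully specifiable decorrelation half of the hybrid weight01 scheme; the
weighting half is not reproduced, and outputs are labelled by algorithm so
a weight01 mode could be added without interface changes.  Raw p-values
are reported sorted, without multiple-testing correction across terms.

## Synthetic data generator

The generator emulates the structure of a five-species pericarp study:
five species (2 dry-, 3 fleshy-fruited), three shared stages at times
(2, 3, 4), 3 replicates per stage (~45 samples), NB counts with trend
`alpha = 0.01 + 2/mu` jittered log-normally (SD 0.3) — typical bulk
RNA-seq magnitudes — baselines log2-uniform in [4, 10], and per-sample
depth factors log-uniform in [0.5, 2].  Planted classes: null (flat),
core (one trajectory shared by all species, range = the configured log2
amplitude, default 2), divergent (fruit-type trajectories differing by the
amplitude in max-norm), and optionally species-specific.  Trajectories are
drawn in the same natural-spline basis used for fitting (the
well-specified case); a sinusoidal option probes basis misspecification.
Orthogroup tables carry the single-copy groups plus paralogous and
missing-species decoys; GO annotations plant one deep term at 80%
frequency in one class versus 10% background.  All draws come from a
counter-based Philox generator keyed by the config seed, so datasets are
bit-reproducible across platforms.

What the generator does **not** emulate: species-level baseline offsets,
batch effects, GC/length bias, outlier samples, correlated genes, or
read-level artifacts.  Passing recovery tests therefore demonstrates the
statistical machinery under its own assumptions plus realistic depth and
dispersion heterogeneity — not robustness to every failure mode of real
cross-species data.

## Numerical choices

Dispersion floor 1e-8 and ceiling 100; IRLS tolerance 1e-8, max 100
iterations; linear predictors clipped at ±500; chi-square tails via
`scipy.stats.chi2.sf`, which is accurate far below the smallest p-values
these designs can produce; BH adjustment excludes NaN inputs from the test
count and propagates them.  All simulations take explicit seeds; there is
no global random state.

## Problem sizes

The test suite and acceptance script run at desk scale by design: 2,000
genes for null calibration, 1,000 orthogenes (600 null / 200 core / 200
divergent) for the five-species recovery run, 100 random instances for the
Poisson-limit and DIANA oracles, 1,000 for the Fisher oracle.  The full
suite completes in a few minutes on one CPU; the pipeline scales linearly
in genes.

## Known limitations

- The chi-square reference for the LRT is asymptotic; at 3 replicates per
  stage the test is slightly conservative (measured rejection ≈ 0.04 at
  nominal 0.05 in the null-calibration run).
- The conserved class absorbs the BH-level false positives of the
  M1-vs-M0 test; its empirical FDR tracks `alpha` times the M1 discovery
  count divided by the class size.
- Only strict single-copy orthogroups are analyzed; many-to-one orthology
  is out of scope.
- weight01-style blended decorrelation is not implemented (classic and
  elim are).
- Stage-subset harmonization across species with unequal stage sets is
  config-driven; the package does not guess which stages to drop.
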