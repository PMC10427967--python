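# Methods

`mscpotency` implements a consensus machine-learning workflow for finding
metabolite panels that predict the immunomodulatory potency of mesenchymal
stromal cell (MSC) lines from untargeted metabolomics: intracellular MS
feature tables collected at the end of expansion (lipids and small polar
analytes) and NMR spectral features of conditioned media sampled over the
first culture days. This note records the model assumptions, the defaults
and why they were chosen, what the synthetic studies do and do not emulate,
and the numerical decisions a maintainer would want written down.

## Composite potency score

Five functional readouts per cell line — CD4+ and CD8+ %CFSE dilution for
two PBMC donors, and IDO activity (pg L-kynurenine/cell/day, computed as
`mass / (cells x days)`) — are autoscaled (z-scored across lines, ddof=1)
and decomposed by PCA. Each line's PC1 coordinate is its composite score.
Autoscaling before PCA is essential: the assay units differ by orders of
magnitude, and an unscaled PC1 would simply be IDO.

The sign of PC1 is arbitrary in any PCA, so the score is oriented
deterministically: if the mean PC1 loading over the four proliferation
variables is negative, the component is flipped. Higher score therefore
always means more residual T-cell proliferation, i.e. *lower* potency.
The score is invariant to affine rescaling of any assay column and errors
out on a zero-variance column rather than silently producing a degenerate
axis.

## Preprocessing

**MS route** (per platform): blank/QC filter -> RSD filter -> median
normalization -> ComBat -> autoscaling, then replicate means per line.

- *Blank/QC filter*: keep a feature iff its mean over experimental samples
  is at least `blank_ratio` (default 5) times its mean over blank samples,
  and it is nonzero in at least `qc_presence` (default 0.5) of pooled-QC
  injections. Means (not maxima) are used on both sides. Blank and QC
  samples stay in the table for audit.
- *RSD filter*: RSD = sd/|mean| over experimental samples. The default
  mode removes features with RSD *below* the threshold (default 0.25),
  i.e. near-constant features that cannot carry line-level signal; the
  conventional QC-repeatability reading (remove above) is available via
  `mode="remove_above"`. Zero-mean features have undefined RSD and are
  removed in either mode, with a log message.
- *Median normalization*: each sample is scaled so every sample median
  equals the global median of sample medians; a zero sample median is an
  error (it would demand infinite scaling).
- *Autoscaling*: per-feature z-score using experimental-sample statistics,
  applied to all samples; constant features become 0 with a warning. The
  operation is idempotent to 1e-12.

Zeros are passed through to the filters untouched; missing values are
rejected at read time rather than imputed, because the upstream tools this
package expects produce complete matrices.

**ComBat.** Batch correction is the parametric empirical-Bayes
location/scale model: features are standardized against the grand mean and
pooled (batch-mean-removed) variance; per-batch per-feature location
(gamma) and scale (delta^2) estimates are shrunk toward batch-level
hyperpriors — normal for gamma, inverse-gamma (method-of-moments
hyperparameters) for delta^2 — by iterating the estimating equations to a
relative tolerance of 1e-4; batch effects are removed on the standardized
axis and the grand location/scale restored. A single batch is returned
unchanged; a batch with fewer than two samples is an error; features with
zero within-batch variance are skipped with a warning. The implementation
agrees with scanpy's ComBat to ~1e-3 on shared instances (verified in the
test suite). One property worth knowing: EB shrinkage leaves a residual
between-batch mean difference of order half the batch-mean sampling noise,
so percentage-reduction statements only make sense for shifts that clearly
dominate that noise.

Whether ComBat ran before or after normalization/autoscaling is not
dictated by the data; the pipeline default is filter -> median normalize ->
ComBat -> autoscale, and the stages are callable in any order.

**NMR route**: ComBat at the sample level, then per-flask day-differencing
(`value(day d) - value(day 1)` for the same line and replicate flask; an
unmatched flask is an error naming it), then replicate means per line, then
a PLSR-guided variance filter: for each fraction p in a grid (default 0.05
to 1.00 in steps of 0.05), the top-p features by across-line variance are
fed to a PLSR with min(2, n_lines - 2) components and scored by
leave-one-out R^2; the subset with the best LOO-R^2 wins, ties going to
the smaller fraction. A validated rather than training R^2 is used because
training R^2 is maximized trivially at p = 1. Day-differencing commutes
with line aggregation on balanced designs (tested to 1e-9).

## Regression suite

Six scikit-learn families — PLSR, linear SVR, random forest (RF),
gradient-boosted regression (GBR), decision tree (DT), LASSO — are each:

1. **Tuned** by exhaustive grid search with seeded, shuffled k-fold CV
   (default 5 folds; 10 lines means folds of 2) scored by R^2; ties go to
   the earlier grid point. Default grids: LASSO alpha in 7 log-spaced
   points over [1e-3, 10]; PLSR components 1-4; SVR C in {0.1, 1, 10} x
   epsilon in {0.01, 0.1}; RF/GBR trees in {100, 500} x depth in
   {2, 3, None}; DT depth in {2, 3, 5, None}. All grids are configurable.
2. **Feature-selected with the same family**: LASSO keeps nonzero
   coefficients; PLSR keeps VIP >= 1 (the standard variable importance in
   projection); SVR keeps the largest coefficients that together cover 50%
   of the absolute-coefficient mass; RF/GBR/DT keep features above the mean
   impurity importance — scikit-learn's `SelectFromModel` default. The
   literal "any nonzero importance" rule is available
   (`tree_selection="nonzero"`) but is nearly vacuous for ensembles at ten
   samples, where almost every feature receives a tiny importance. An empty
   selection falls back to the full set with a warning. Selection is one
   pass (threshold + refit), not recursive elimination — the simplest
   stable procedure at this sample size.
3. **Re-tuned** on the selected subset (can be disabled).
4. **Scored by leave-one-out R^2**: each line is held out, the model is
   refit with the chosen hyperparameters on the fixed selected features,
   and `1 - SSE/SST` is computed over the pooled held-out predictions
   (SST about the full-sample mean). The value is bounded above by 1 and
   unbounded below. Hyperparameters and the feature subset are *not*
   re-chosen inside the loop; the resulting optimism is a property of the
   evaluation design and is stated here deliberately.

Importances are |coefficients| on the standardized feature axis for LASSO
and SVR, VIP for PLSR, impurity importances for the tree families, each
normalized to sum to one. Feature columns are standardized on entry to the
suite. Class-level summaries (`importance_by_class`) add the normalized
importances within each chemical class, so each family's class profile
also sums to one.

RF and GBR leave-one-out values are systematically lower than the linear
families on strongly informative synthetic data (often 0.0-0.5 versus
0.8-1.0): tree ensembles cannot extrapolate beyond the training range, and
with ten lines the held-out line is frequently outside it. This is a
documented small-sample property, not a defect; tests assert it only where
the behavior is stable.

## Symbolic regression

A genetic-programming engine searches expression trees over
{+, -, x, protected /, square} with feature and constant leaves. Protected
division floors the denominator magnitude at 1e-6 (sign preserved).
Complexity is the node count. Fitness is the training R^2 of the best
affine rescaling a + b*f(x) of the tree output — evolution searches for
structure while the two outer constants come free — minus a parsimony
penalty of 1e-3 per node. Each restart runs ramped half-and-half
initialization (depths 1-4), tournament selection (k=3), subtree crossover
(p=0.7) and subtree mutation (p=0.25) with a 60-node cap, and archives the
complexity/accuracy Pareto front of everything it evaluated. Defaults: 30
restarts of 200 individuals for 50 generations; the bundled pipeline uses
smaller settings (5 restarts, 100 x 20) that recover planted laws on
ten-line studies in seconds.

*Variable presence*: among archived expressions with training R^2 >= 0.90
and complexity <= 300, the presence of a feature is the fraction of
qualifying expressions containing it; features at or above a 0.10 presence
cutoff are the SR family's important set. The 300-node ceiling is far
above what the parsimony pressure permits in practice, so the R^2 floor
does the filtering; the ceiling is kept for interface fidelity. With an
empty qualifying set all presences are zero and a warning is logged. For a
consensus-model LOO-R^2, the best qualifying expression's structure is
frozen and only the affine constants are refit per leave-one-out fold.

## Consensus, ablation

For each non-SR family, the top `ceil(fraction x n)` features of its
*final* (post-selection) model by importance are flagged (default fraction
0.20; ties break by stable feature order). The 0.10 variant is supported
via the same parameter, since both conventions appear in practice. SR
flags its presence-based set. Features flagged by at least `min_models`
families (default 2) form the consensus panel, with the flagging families
recorded per feature. MS lipid and small-polar panels are built separately
and their union feeds one consensus model over the concatenated line
matrices; NMR day-2 and day-3 difference panels stay separate, and
features consensual in both are reported.

Consensus models re-tune each family on the panel-restricted matrix with
no further selection. The ablation refit drops one user-named line (the
intended use: a single non-bone-marrow-derived outlier line), keeps the
panel fixed, re-tunes with 3-fold CV (for the nine remaining lines), and
recomputes LOO-R^2 on the remaining lines. An exclusion leaving fewer than
four lines is an error.

## Over-representation analysis

Pathways come from user-supplied GMT files; no pathway content ships with
the package. For a query of n mapped metabolites against a background of
N identifiers containing K pathway members, the enrichment p-value is the
hypergeometric upper tail P(X >= k), matched against exhaustive
enumeration in the tests; Benjamini-Hochberg correction runs across
pathways. The background defaults to the union of all set members and is
overridable — with a dataset-specific background recommended — and a
user-editable id-mapping table supports collapsing lipid species to class
identifiers before mapping. Query ids outside the background must be
removed by `map_query` first; `ora` refuses them.

## Synthetic studies

The generator emulates the study design the analysis assumes: n_lines
(default 10) cell lines in two batches, one MS sample per line per
platform (matching an end-of-expansion pellet), and n_replicates_nmr
(default 10) flasks per line sampled on days 1-3. A single latent potency
factor per line drives everything: the four proliferation assays are
affine in it (slope 10-12%, noise SD 3%), IDO runs opposite with extra
noise (slope -14, noise SD 8) so that IDO rank can disagree with T-cell
rank for some lines, and each platform has n_informative (default 5 of
200) features whose log-scale line means move `effect_size` (default 3)
noise-SD units per latent-SD, with random signs. Noise: donor-level SD 0.3
shared across a line's samples, replicate-level SD 0.3 per sample. Batch
effects are a location shift (0.75) and scale factor (1.4) on the log
axis; intensities are exponentiated so raw tables are positive. NMR
features follow linear, saturating, or non-monotonic (rise-then-fall-
below-baseline) day trajectories with the informative signal carried in
the day-differences, growing with the day gap. Blank samples (2% of the
experimental mean; 50% for designated blank-dominated features) and pooled
QCs (experimental mean with 5% noise, with configurable per-feature
dropout) can be appended to exercise the filters deterministically.

What the generator does *not* emulate: correlated feature blocks (real
lipid classes co-vary strongly), heavy-tailed and missing intensities,
drift within batches, annotation ambiguity, and multiplicative
(log-scale) batch structure interacting with the linear-scale ComBat.
Passing recovery tests on this generator therefore demonstrates that the
machinery is wired correctly and recovers planted signal at realistic
sample sizes — not that the workflow's error rates transfer to any real
study.

A note on what recovery looks like at ten lines: among ~200 independent
noise features the best spurious univariate |r| against any response is
typically 0.7-0.8, so every model family ranks a handful of the same
spuriously correlated noise features highly and the >=2-family consensus
panel inherits some of them. Median panel recall on default studies is
1.0; median precision sits near 0.5. That is the honest operating point of
the consensus rule at this sample size, and the main reason the ablation
and FDR checks exist.

## Numerical choices and degenerate inputs

- All randomness flows from explicit integer seeds through numpy PCG64
  (`SeedSequence.spawn` for SR restarts); there is no global RNG state, and
  reruns are bit-identical (the pipeline manifest records SHA-256 digests
  of every artifact to make this checkable).
- Standard deviations use ddof=1 throughout scaling and RSD computation.
- Ties: grid search takes the earliest grid point; the variance filter
  takes the smaller fraction; top-fraction importance ranking breaks ties
  by stable feature order.
- Zero-variance responses raise; zero-variance features are zeroed
  (autoscale), skipped (ComBat) or reported with R^2 0 / p 1 (screen).
- The univariate screen computes R^2 as the squared Pearson correlation
  (identical to OLS R^2 for simple regression), a two-sided t-test on the
  slope with n-2 df, and BH q-values across features.
- Problem sizes in the test suite (20-seed recovery runs, 500-replicate
  FDR calibration, 4-restart SR settings) are chosen so the full suite
  completes on a single CPU in well under half an hour while keeping every
  statistical check at its stated tolerance.

## Known limitations

- Feature standardization and the composite score are computed on the full
  line set before leave-one-out evaluation, mirroring the workflow this
  package reproduces; the optimism is shared by all families equally but
  LOO-R^2 values should not be read as unbiased generalization estimates.
- Grid-tuned models at n=10 are noisy: 2-sample CV folds make PLSR
  component choice and LASSO alpha choice unstable seed to seed. The
  consensus construction is the mitigation, not a cure.
- The SR engine is a generic GP implementation; it makes no attempt to
  reproduce any proprietary SR tool's model forms, complexity metric, or
  presence plots beyond the counting semantics defined above.
- ORA p-values depend entirely on the user's pathway sets and background;
  without the original curated databases, published enrichment p-values
  are not comparable quantities.
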