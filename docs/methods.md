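# Methods

## Problem and setting

The package implements a biomarker-discovery analysis for peripheral-blood
DNA methylation in ulcerative colitis patients starting JAK-inhibitor
(tofacitinib) treatment.  Inputs are a probe x sample matrix of beta
values (methylation fractions in [0, 1]) at baseline, clinical scores at
baseline (T1) and week 8 (T2), and optionally later timepoints (T3) for a
subset.  The analysis labels each subject responder (R) or non-responder
(NR) by a composite endpoint, selects a panel of predictor CpGs by
stability-selected gradient boosting against a shadow-variable null,
evaluates a recalibrated classifier ensemble, and characterises the panel
(longitudinal ICC stability, delta-methylation persistence, blood
cell-composition confounding, covariate association, gene-set
over-representation).

Because the motivating cohort is controlled-access, the package ships a
synthetic-data module that reproduces the cohort's statistical structure
(31 subjects, 16 R / 15 NR, beta-distributed probe noise, planted group
effects, ICC-controlled longitudinal replicates, convex cell mixtures,
clinical trajectories consistent with the labels).  All calibration and
recovery claims below are statements about those synthetic conditions.

## Composite response endpoint

A subject is a responder iff endoscopic response AND (clinical OR
biochemical) response:

* endoscopic: EMS decrease >= 1 or UCEIS decrease >= 2 vs baseline;
* biochemical: >= 50% decrease in both CRP and faecal calprotectin, or
  CRP <= 5.0 mg/L and calprotectin <= 250 ug/g at week 8;
* clinical: total Mayo decrease >= 3 points and >= 30% with the
  rectal-bleeding subscore decreasing >= 1 or ending <= 1, or SCCAI
  dropping by at least half.

Percent criteria are evaluated with exact arithmetic; a drop of exactly
30% (or 50%) counts as a response — no rounding rule is applied.  The
"50% SCCAI drop" is read as `sccai_t2 <= 0.5 * sccai_t1`.  The AND/OR
precedence follows the conventional Mayo-response reading: the Mayo chain
binds its RBS clause, and the SCCAI clause is the alternative.

## Probe filtering

Gap signals (multi-modal beta distributions typical of probes overlapping
genetic variants) are detected by sorting each probe's betas and cutting
where consecutive values differ by more than 0.1 (the gap threshold).  A
probe is flagged when at least two groups emerge and every group holds at
least `ceil(0.01 * n)` samples, mirroring the published gap-hunting
semantics (threshold and outlier cutoff both exposed).  Known
variant-binding probes are removed through a user-supplied drop-list;
no annotation database is bundled.

## Selection: stability-selected gradient boosting

1. **Repeats.** `n_outer_repeats` times (default 100): a stratified
   70/30 train/test split; an xgboost binary classifier (200 trees,
   depth 3, learning rate 0.1, row subsample 0.8, per-tree feature
   subsample 0.3) fit on the train portion with the number of boosting
   rounds chosen by stratified 10-fold cross-validated early stopping;
   the held-out AUROC recorded.  Per-repeat probe importance is
   total-gain importance normalised by the fit's maximum.
2. **Aggregation.** A probe's aggregated importance is the mean of its
   normalised importances across repeats; ties break by probe ID.
3. **Shadow threshold.** Shadow variables — label-independent
   permutations of real probes — are refit under the same conditions as
   a repeat (fresh stratified split, same booster, rounds fixed to the
   repeats' median chosen rounds, no cross-validation) and their
   normalised importances are aggregated across refits.  The selection
   bar is the maximum of the shadow aggregates; probes above the bar form
   the predictor panel.

Two design points deserve explanation:

* **Feature subsampling (`colsample_bytree = 0.3`).**  With p >> n,
  greedy boosting exhibits masking: one strong probe can absorb every
  split, leaving correlated or weaker true probes with zero importance in
  every repeat.  Per-tree feature subsampling forces split diversity and
  is applied identically to shadows, so the null calibration is
  unaffected while recovery improves substantially.
* **Shadow protocol.**  The default `complement` protocol appends one
  fixed permuted copy of every real probe and performs
  `shadow_fits` refits (default: as many as the outer repeats), dropping
  one random real probe per refit.  Keeping each shadow fixed across
  refits matters: a signal-free variable that is correlated with the
  labels by chance stays "lucky" across overlapping resampling splits,
  exactly as a real noise probe does, so the per-shadow aggregate — not
  the single-fit importance — is the correct null statistic.  Appending a
  full complement resolves that null at the same multiplicity as the real
  feature set.  A literal protocol that appends a single shadow per refit
  (`shadow_protocol="single"`, grouped into fixed shadows) is provided
  for comparison, but a lone shadow competing with thousands of real
  probes is granted a split so rarely that its null tail cannot be
  resolved with an affordable refit budget; it is not the default.
* Beta values are used directly as features (an M-value transform is a
  one-liner upstream and does not change tree models' splits order within
  a probe).  Probes with any missing value are excluded from selection
  (complete-case features); pairwise imputation is not supported.

Determinism: all repeat, shadow and ensemble seeds are spawned from the
master seed by counter (`numpy.random.SeedSequence`), and probes are
processed in lexicographic order, so results are independent of input row
order and bit-reproducible.

## Recalibration ensemble

A single stratified 20% holdout is withheld once (the definite "the 20%
withheld test set"); 50 boosters are trained on stratified bootstrap
resamples of the remaining 80%, restricted to the predictor panel, and
each is evaluated on the holdout.  The mean ROC curve is the vertical
average of per-model curves on a 101-point FPR grid; mean AUROC,
precision, recall and F1 are arithmetic means over models.  The decision
threshold for the threshold metrics is 0.5 predicted probability.
Per-model re-splitting is available behind the config.  The diagnostic
summary computes LR+ = sens/(1 - spec) and the post-test probability by
Bayes' odds update; at sensitivity = specificity = 0.70 and a pre-test
probability of 0.53 this yields LR+ = 2.33 and 72.5% post-test
probability.

## Longitudinal stability

Per probe, the ICC is estimated from two-way ANOVA mean squares in the
two-way mixed, absolute-agreement, single-measurement form (ICC(A,1));
the consistency form ICC(C,1) is selectable.  The absolute-agreement form
is the appropriate test–retest choice when the occasions themselves are
fixed (T1/T2/T3).  Subjects with missing timepoints are dropped per probe
(listwise).  Bands: poor < 0.5 <= moderate < 0.75 <= good < 0.9 <=
excellent, with boundary values going to the higher band.  Persistence of
the group difference is summarised by the Spearman correlation, across
probes, of delta = mean(R) - mean(NR) at T1 versus T2, with each probe
assigned to a sign quadrant (delta is R minus NR, so positive means
hypermethylated in responders).

## Cell-type deconvolution

Proportions of CD8+ T, CD4+ T, NK, B cells, monocytes and neutrophils are
estimated per sample by constrained projection onto a reference signature
F (cell type x probe): minimise ||beta - F^T w||^2 subject to w >= 0 and
sum(w) <= 1 (equality selectable), solved by SLSQP; the solution matches
a dense simplex grid search on toy problems to <= 1.5e-2 and is exact on
noiseless mixtures.  No real sorted-cell reference is shipped; the
bundled reference generator is synthetic (50 discriminating probes per
cell type) and a user reference can be supplied as TSV.  Group
comparisons per cell type use Mann–Whitney (Welch's t selectable) with BH
adjustment across the six tests.

## Covariates and enrichment

Each predictor probe's methylation is regressed marginally on SCCAI
(continuous) and corticosteroid use (binary) by OLS with a two-sided
t-test on the slope and BH adjustment within each covariate family; the
binary case is algebraically the pooled two-sample t-test.  No
empirical-Bayes moderation is applied — defensible at n = 31, and noted
as an extension.  Over-representation uses the one-sided hypergeometric
upper tail per gene set with BH across sets; the default universe is the
genes annotated to probes surviving filtering (a whole-GMT universe is
selectable).  GO-graph-based redundancy removal is out of scope.

## Synthetic data: what it does and does not emulate

Probe-level noise is Beta(m*k, (1-m)*k) with concentration k = 50
(between-subject SD ~0.07 at beta 0.5 — realistic for between-subject
blood methylation variation).  Informative probes shift the responder
mean by +/-delta (sign random per probe, mirroring the near-even
hyper/hypo split).  Longitudinal replicates are built on the logit scale,
where the realised between-subject variance per probe is taken as the
subject-effect variance and occasion noise is added with
sigma_w^2 = sigma_b^2 (1 - ICC)/ICC, so the target ICC is analytic;
values are squashed back through the logistic.  Cell mixtures are
Dirichlet-weighted combinations of the reference plus clipped Gaussian
noise.  Clinical records are drawn in plausible score ranges conditional
on the assigned label.

Not emulated: array chemistry (probe type chemistry, detection
p-values), genomic autocorrelation between neighbouring probes,
beta-value bimodality across the genome, batch effects, correlated probe
blocks, internal consistency between the total Mayo score and its
subscores, and RNA-seq counts.  Passing tests therefore demonstrate
statistical correctness and calibration of the machinery under the
assumed generative structure, not performance on real arrays.

## Problem sizes and numerical choices

Desk-scale experiments (tests and the acceptance script) run the
selection with 15 outer repeats and 15 complement shadow refits at 2,000
probes x 31 subjects — enough to stabilise aggregated importances at
these dimensions; 20 pure-noise replicates and an effect-size grid
{0.05, 0.10, 0.15} x {5, 5, 10} replicates complete in minutes on one
CPU.  The full-scale defaults (100 repeats) remain the config defaults.
Other numerics: SLSQP ftol 1e-12; chi-square without continuity
correction (reproduces the cohort's printed baseline p-values; the
Yates-corrected values do not); Mann–Whitney exact for tie-free groups of
<= 8, tie-corrected normal approximation otherwise, with the method
recorded in the output; BH via the standard step-up; p-values reported to
4 significant digits in CSV summaries and at full precision in JSON.

## Known limitations

* The shadow bar controls the family of chance-correlated noise probes
  empirically, not a formal FWER/FDR level; with ~2,000 probes the
  max-of-shadow-aggregates bar admitted 0-0.3% of probes under the global
  null in our replicates.
* Selection and recalibration reuse the same cohort (as the analysis
  design prescribes); the holdout guards the ensemble metrics against
  training optimism but not against selection optimism.
* The ICC generator targets the logit scale; squashing to (0, 1)
  attenuates the beta-scale ICC slightly (well within +/-0.05 at the
  simulated variances).
* Mann–Whitney p-values for tied small samples use the asymptotic
  approximation; exact-with-ties enumeration is not implemented.
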