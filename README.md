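# methylboost

Peripheral-blood DNA-methylation biomarker discovery for treatment
response, built around **stability-selected gradient boosting with a
shadow-variable selection threshold**.  The package implements the full
analysis chain used to ask: *can baseline blood methylation predict which
ulcerative-colitis patients will respond to a JAK inhibitor?* — and makes
every stage testable on synthetic cohorts with known ground truth, since
real patient methylomes of this kind are controlled-access.

It is aimed at epigenetics/biostatistics practitioners who work with
Illumina-array beta values (methylation fractions in [0, 1]) and small,
deeply phenotyped cohorts (n ≈ 30, p ≈ 10^5..10^6).

## The method

Subjects are labelled responder (R) / non-responder (NR) by a strict
composite endpoint: endoscopic response (ΔEMS ≥ 1 or ΔUCEIS ≥ 2) **and**
(clinical **or** biochemical) response at week 8.  After gap-signal probe
filtering, predictor CpGs are selected as follows:

1. repeat 100×: stratified 70/30 split; gradient-boosted trees fit on the
   train set with 10-fold cross-validated early stopping; per-probe
   total-gain importance normalised per fit;
2. aggregate importances as the mean over repeats:
   `I_j = (1/R) Σ_r gain_jr / max_j gain_jr`;
3. build a null from *shadow probes* — label-independent permutations of
   real probes refit under identical conditions and aggregated the same
   way — and keep probes with `I_j > max(shadow aggregates)`.

The panel is then *recalibrated*: one stratified 20% holdout is withheld,
50 boosters are trained on bootstrap resamples of the remaining 80%
restricted to the panel, and the mean ROC / AUROC / precision / recall /
F1 over the 50 models is reported, together with the diagnostic summary
LR+ = sens/(1−spec) and the Bayes post-test probability.  Panel follow-up
includes per-probe ICC (two-way mixed, absolute agreement, single
measurement; bands poor < 0.5 ≤ moderate < 0.75 ≤ good < 0.9 ≤
excellent), the T1-vs-T2 Spearman correlation of per-probe group deltas,
Houseman-style cell-type deconvolution (w ≥ 0, Σw ≤ 1 quadratic
program over a six-cell-type blood reference), covariate regressions
(SCCAI, steroid use) and hypergeometric gene-set over-representation.

See `docs/methods.md` for assumptions, parameter defaults and design
rationale.

## Worked example

Run the whole pipeline on a synthetic cohort (2,000 probes, 31 subjects,
16 responders, 20 planted probes with a 0.15 beta shift):

```sh
methylboost run-all --out demo --seed 5 --repeats 15 --n-models 20
```

prints

```json
{
  "composite_responders": 16,
  "n_predictors": 24,
  "mean_auroc": 0.9917,
  "median_icc": 0.8942,
  "delta_spearman_rho": 0.8875,
  "deconvolution_mae": 0.0029
}
```

Reading: the endpoint module re-derives exactly the 16 responders the
generator planted; selection admits 24 probes past the shadow bar (most
of them from the 20-probe truth set — the truth list is in
`demo/inputs/truth.json`, the ranked panel in `demo/ranking.csv`); the
recalibrated 20-model ensemble separates R from NR on the holdout with
mean AUROC 0.99 (the planted effect is strong at these settings); the
longitudinal generator targeted ICC 0.9 and the stability stage estimates
a median of 0.894; group methylation differences at T1 correlate with
those at T2 at Spearman ρ = 0.89; and cell-type proportions are recovered
from noisy mixtures with a mean absolute error of 0.003.  Stage reports
(JSON/CSV) and a manifest with seeds and input hashes land in `demo/`.

Each stage is also a subcommand over files (`simulate`, `classify`,
`filter`, `select`, `evaluate`, `stability`, `deconvolve`, `covariates`,
`enrich`) — `methylboost --help` lists them; beta matrices are TSV
(probes × samples, `NA` for missing), sample sheets CSV, gene sets GMT.

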