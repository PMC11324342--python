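"""Model recalibration ensemble and classification metrics.

After the predictor panel is fixed, the model is recalibrated: a single
stratified 20% holdout is withheld once, 50 boosters are trained on
resampled versions of the remaining 80% using only the predictor probes,
and each is evaluated on the holdout.  The final ROC curve is the
vertical average of the 50 per-model curves on a common false-positive
grid; the reported AUROC / precision / recall / F1 are arithmetic means
over models.

Also here: the diagnostic likelihood-ratio summary (LR+ and the
post-test probability obtained by updating pre-test odds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import train_test_split

from .core_io import BetaMatrix
from .selection import SelectionConfig, _booster_params, _cv_best_rounds, _seed_for

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class Metrics:
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    f1: float
    auroc: float
    auroc_defined: bool = True


def classification_metrics(scores, labels, threshold: float = 0.5) -> Metrics:
    """Standard threshold metrics plus trapezoidal AUROC.

    Recall is sensitivity by definition.  With single-class labels the
    AUROC is undefined and flagged via ``auroc_defined=False`` (NaN value).
    Empty cells yield 0.0 for the affected ratio rather than an error.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    if np.unique(y).size < 2:
        return Metrics(sens, spec, prec, sens, f1, float("nan"),
                       auroc_defined=False)
    return Metrics(sens, spec, prec, sens, f1,
                   float(roc_auc_score(y, s)))


@dataclass
class LikelihoodSummary:
    """Positive/negative likelihood ratios and the Bayes post-test update."""

    lr_plus: float
    lr_minus: float
    pretest_probability: float
    posttest_probability: float


def likelihood_summary(sensitivity: float, specificity: float,
                       pretest_probability: float) -> LikelihoodSummary:
    """LR+ = sens/(1-spec); post-test probability from pre-test odds.

    At specificity 1 the LR+ is infinite (perfect rule-in) and the
    post-test probability is 1.
    """
    if not 0 < pretest_probability < 1:
        raise ValueError("pretest probability must lie in (0, 1)")
    if specificity >= 1.0:
        lr_plus = math.inf
        posttest = 1.0
    else:
        lr_plus = sensitivity / (1.0 - specificity)
        odds = pretest_probability / (1.0 - pretest_probability)
        post_odds = lr_plus * odds
        posttest = post_odds / (1.0 + post_odds)
    lr_minus = ((1.0 - sensitivity) / specificity
                if specificity > 0 else math.inf)
    return LikelihoodSummary(lr_plus=lr_plus, lr_minus=lr_minus,
                             pretest_probability=pretest_probability,
                             posttest_probability=posttest)


@dataclass
class EnsembleReport:
    """Per-model and mean performance of the recalibration ensemble."""

    per_model: pd.DataFrame          # model_id + threshold & rank metrics
    fpr_grid: np.ndarray
    tpr_mean: np.ndarray
    tpr_sd: np.ndarray
    mean_auroc: float
    mean_metrics: dict[str, float]
    confusion: dict[str, int]        # summed over models at the threshold
    holdout_samples: list[str] = field(default_factory=list)


def _stratified_bootstrap(rng: np.random.Generator, y: np.ndarray
                          ) -> np.ndarray:
    """Bootstrap indices resampled within class (class sizes preserved)."""
    idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        idx.append(rng.choice(members, size=members.size, replace=True))
    return np.concatenate(idx)


def recalibrate(beta: BetaMatrix, labels: np.ndarray,
                config: SelectionConfig | None = None,
                n_models: int = 50, holdout_fraction: float = 0.20,
                threshold: float = 0.5,
                resplit_per_model: bool = False) -> EnsembleReport:
    """Recalibration ensemble on the predictor probes.

    One stratified holdout of ``holdout_fraction`` is withheld once and
    shared by all models (``resplit_per_model=True`` draws a fresh
    holdout per model instead).  Each of the ``n_models`` boosters trains
    on a stratified bootstrap resample of the remaining data (the "80%"),
    with the number of boosting rounds chosen by cross-validated early
    stopping when the config requests it.
    """
    if config is None:
        config = SelectionConfig()
    if beta.shape[0] == 0:
        raise ValueError("predictor set is empty")
    data = beta.drop_incomplete_probes().data.sort_index()
    X = data.to_numpy().T
    y = np.asarray(labels, dtype=int)
    sample_ids = list(data.columns)

    idx = np.arange(X.shape[0])

    def split(seed: int):
        tr, ho = train_test_split(idx, test_size=holdout_fraction,
                                  stratify=y, random_state=seed % (2**31))
        if np.unique(y[ho]).size < 2:
            raise ValueError("holdout lacks one of the classes")
        return X[tr], y[tr], X[ho], y[ho], ho

    X_tr_full, y_tr_full, X_ho, y_ho, ho_idx = split(
        _seed_for(config.seed, 3))

    rows = []
    tprs = np.empty((n_models, FPR_GRID.size))
    confusion = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for m in range(n_models):
        seed_m = _seed_for(config.seed, 4, m)
        rng = np.random.default_rng(seed_m)
        if resplit_per_model:
            X_tr_full, y_tr_full, X_ho, y_ho, _ = split(seed_m)
        boot = _stratified_bootstrap(rng, y_tr_full)
        X_m, y_m = X_tr_full[boot], y_tr_full[boot]
        rounds = (config.n_trees if not config.use_cv_early_stopping
                  else _cv_best_rounds(X_m, y_m, config, seed_m))
        booster = xgb.train(_booster_params(config, seed_m),
                            xgb.DMatrix(X_m, label=y_m),
                            num_boost_round=rounds)
        scores = booster.predict(xgb.DMatrix(X_ho))
        met = classification_metrics(scores, y_ho, threshold=threshold)
        fpr, tpr, _ = roc_curve(y_ho, scores)
        tprs[m] = np.interp(FPR_GRID, fpr, tpr)
        pred = (scores >= threshold).astype(int)
        confusion["tp"] += int(np.sum((pred == 1) & (y_ho == 1)))
        confusion["tn"] += int(np.sum((pred == 0) & (y_ho == 0)))
        confusion["fp"] += int(np.sum((pred == 1) & (y_ho == 0)))
        confusion["fn"] += int(np.sum((pred == 0) & (y_ho == 1)))
        rows.append({"model_id": m, "auroc": met.auroc,
                     "precision": met.precision, "recall": met.recall,
                     "f1": met.f1, "sensitivity": met.sensitivity,
                     "specificity": met.specificity})
    per_model = pd.DataFrame(rows)
    mean_metrics = per_model.drop(columns="model_id").mean().to_dict()
    return EnsembleReport(
        per_model=per_model,
        fpr_grid=FPR_GRID.copy(),
        tpr_mean=tprs.mean(axis=0),
        tpr_sd=tprs.std(axis=0, ddof=1) if n_models > 1
        else np.zeros(FPR_GRID.size),
        mean_auroc=float(per_model["auroc"].mean()),
        mean_metrics={k: float(v) for k, v in mean_metrics.items()},
        confusion=confusion,
        holdout_samples=[sample_ids[i] for i in ho_idx])
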