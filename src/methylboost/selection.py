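"""Stability-selected gradient boosting with a shadow-variable threshold.

The selection procedure, step by step:

1. Repeat ``n_outer_repeats`` times: draw a stratified 70/30 train/test
   split, fit a gradient-boosted tree classifier on the train portion
   (number of boosting rounds chosen by stratified k-fold cross-validated
   early stopping), record each probe's total-gain importance normalised
   by the fit's maximum, and the held-out AUROC.
2. Aggregate: each probe's importance is the mean of its normalised
   importances across repeats; probes are ranked by this aggregate.
3. Shadow threshold: permutation refits in which real probes are dropped
   and *shadow* probes — label-independent permutations of real probes —
   are appended; each refit mirrors an outer repeat (fresh stratified
   split, same booster, rounds fixed to the repeats' median chosen
   rounds) but skips the cross-validation.  Shadow variables stay fixed
   across refits and their normalised importances are averaged, so each
   shadow yields one draw of the *aggregated* importance a signal-free
   variable attains — including the persistence a variable that is
   correlated with the labels by chance alone shows across overlapping
   resampling splits.  Under the default ``complement`` protocol every
   real probe contributes one shadow copy, so the null is resolved at the
   same multiplicity as the real feature set; the literal one-shadow-
   per-refit protocol (``single``) is available but needs an enormous
   refit budget to resolve the tail, because a lone shadow among
   thousands of real probes is almost never granted a split.  The
   selection bar is the maximum (or a quantile) of the shadow aggregates;
   probes whose aggregated importance exceeds the bar are the predictor
   panel.

Everything is deterministic given (data, master seed): per-repeat and
shadow seeds are spawned from the master seed by counter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .core_io import BetaMatrix


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the stability-selection run.

    Booster defaults (200 trees, depth 3, learning rate 0.1, subsample
    0.8) are sized for ~30 samples with thousands of features.  The
    shadow refits use ``shadow_trees`` rounds without cross-validation,
    keeping the permutation loop affordable.
    """

    n_outer_repeats: int = 100
    train_fraction: float = 0.70
    n_cv_folds: int = 10
    n_permutations: int = 1000
    n_trees: int = 200
    learning_rate: float = 0.1
    max_depth: int = 3
    subsample: float = 0.8
    colsample_bytree: float = 0.3  # counters masking when p >> n
    shadow_trees: int | None = None  # None: match the repeats' median rounds
    shadow_protocol: str = "complement"  # or "single" (one shadow per refit)
    shadow_fits: int | None = None   # complement refits; None: n_outer_repeats
    shadow_groups: int = 50          # distinct shadows in "single" protocol
    shadow_quantile: float = 1.0     # 1.0: bar = max of the null aggregates
    shadow_mode: str = "permute"  # "permute" a real probe, or iid "noise"
    use_cv_early_stopping: bool = True
    feature_scale: str = "beta"   # or "m" for M-values log2(b/(1-b))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_cv_folds < 2:
            raise ValueError("need at least 2 CV folds")
        if self.n_outer_repeats < 1:
            raise ValueError("need at least 1 repeat")
        if self.shadow_mode not in ("permute", "noise"):
            raise ValueError("shadow_mode must be 'permute' or 'noise'")
        if self.shadow_protocol not in ("complement", "single"):
            raise ValueError(
                "shadow_protocol must be 'complement' or 'single'")
        if self.feature_scale not in ("beta", "m"):
            raise ValueError("feature_scale must be 'beta' or 'm'")


@dataclass
class SelectionResult:
    """Ranked probes, the shadow bar that admitted them, and diagnostics."""

    ranking: pd.DataFrame           # probe_id, importance (sorted)
    shadow_bar: float
    shadow_importances: np.ndarray  # one per permutation iteration
    predictor_set: list[str]
    per_repeat_importances: pd.DataFrame  # repeats x probes (normalised)
    test_aurocs: np.ndarray
    notes: list[str] = field(default_factory=list)


def _seed_for(master: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def _booster_params(config: SelectionConfig, seed: int) -> dict:
    return {
        "objective": "binary:logistic",
        "eval_metric": "logloss",
        "tree_method": "hist",
        "max_depth": config.max_depth,
        "eta": config.learning_rate,
        "subsample": config.subsample,
        "colsample_bytree": config.colsample_bytree,
        "nthread": 1,
        "seed": seed,
        "verbosity": 0,
    }


def _normalised_gain(booster: xgb.Booster, n_features: int) -> np.ndarray:
    """Total-gain importances divided by their maximum (zeros if unused)."""
    gains = np.zeros(n_features)
    for name, gain in booster.get_score(importance_type="total_gain").items():
        gains[int(name[1:])] = gain
    top = gains.max()
    return gains / top if top > 0 else gains


def _cv_best_rounds(X: np.ndarray, y: np.ndarray, config: SelectionConfig,
                    seed: int) -> int:
    """Stratified k-fold CV early stopping for the number of rounds."""
    n_min = int(np.bincount(y).min())
    folds = min(config.n_cv_folds, n_min)
    if folds < 2:
        return config.n_trees
    cv = xgb.cv(_booster_params(config, seed), xgb.DMatrix(X, label=y),
                num_boost_round=config.n_trees, nfold=folds,
                stratified=True, early_stopping_rounds=10, seed=seed,
                verbose_eval=False)
    return max(1, len(cv))


def single_repeat(X: np.ndarray, y: np.ndarray, config: SelectionConfig,
                  repeat_seed: int) -> tuple[np.ndarray, float, int]:
    """One stability-selection repeat: split, fit, rank, evaluate.

    Returns (normalised importances over all features, held-out AUROC,
    boosting rounds used).
    """
    if np.bincount(y, minlength=2).min() < 2:
        raise ValueError("need at least 2 samples per class")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=config.train_fraction, stratify=y,
        random_state=repeat_seed % (2**31))
    rounds = (config.n_trees if not config.use_cv_early_stopping
              else _cv_best_rounds(X_tr, y_tr, config, repeat_seed))
    booster = xgb.train(_booster_params(config, repeat_seed),
                        xgb.DMatrix(X_tr, label=y_tr),
                        num_boost_round=rounds)
    imp = _normalised_gain(booster, X.shape[1])
    scores = booster.predict(xgb.DMatrix(X_te))
    auroc = float(roc_auc_score(y_te, scores))
    return imp, auroc, rounds


def _shadow_fit(Xb: np.ndarray, y: np.ndarray, config: SelectionConfig,
                rounds: int, fit_seed: int) -> np.ndarray:
    """One permutation refit: fresh stratified split, reduced booster."""
    X_tr, _, y_tr, _ = train_test_split(
        Xb, y, train_size=config.train_fraction, stratify=y,
        random_state=fit_seed % (2**31))
    booster = xgb.train(_booster_params(config, fit_seed),
                        xgb.DMatrix(X_tr, label=y_tr),
                        num_boost_round=rounds)
    return _normalised_gain(booster, Xb.shape[1])


def shadow_threshold(X: np.ndarray, y: np.ndarray, config: SelectionConfig,
                     rounds: int | None = None) -> np.ndarray:
    """Null aggregated-importance distribution from shadow-variable refits.

    Shadow features are label-independent permutations of real features
    (or i.i.d. uniform noise under ``shadow_mode='noise'``).  Each refit
    mirrors an outer repeat — fresh stratified train split, same booster —
    but skips cross-validation; the number of boosting rounds comes from
    ``rounds`` (typically the median rounds the outer repeats chose) or
    ``config.shadow_trees``, so a shadow's opportunity to earn gain
    matches a real feature's.  Shadows stay fixed across refits and their
    normalised total-gain importances are averaged per shadow: a
    signal-free variable can correlate with the labels by chance, and that
    luck persists across overlapping splits exactly as it does for a real
    probe, so the aggregate — not the single-fit importance — is the null
    statistic.

    Protocols: ``complement`` (default) appends one fixed shadow copy of
    every real feature and drops one random real feature per refit, over
    ``shadow_fits`` refits (default: as many as the outer repeats); this
    resolves the null at the same multiplicity as the real feature set.
    ``single`` appends a lone shadow per refit, ``n_permutations`` refits
    grouped into ``shadow_groups`` fixed shadows; note a lone shadow among
    thousands of real probes is rarely granted a split, so this protocol
    needs a very large refit budget.

    Returns an array of shape (n_shadows, n_refits) of normalised shadow
    importances; row means are the null aggregates.
    """
    if rounds is None:
        rounds = config.shadow_trees or config.n_trees
    rng = np.random.default_rng(_seed_for(config.seed, 1))
    n_samples, n_features = X.shape

    if config.shadow_protocol == "complement":
        n_fits = config.shadow_fits or config.n_outer_repeats
        if config.shadow_mode == "permute":
            shadows = np.column_stack(
                [rng.permutation(X[:, j]) for j in range(n_features)])
        else:
            shadows = rng.uniform(0, 1, size=(n_samples, n_features))
        out = np.empty((n_features, n_fits))
        for r in range(n_fits):
            drop = int(rng.integers(n_features))
            Xb = np.column_stack([np.delete(X, drop, axis=1), shadows])
            imp = _shadow_fit(Xb, y, config, rounds,
                              _seed_for(config.seed, 1, r + 1))
            out[:, r] = imp[n_features - 1:]
        return out

    if config.n_permutations < 50:
        import warnings
        warnings.warn("fewer than 50 permutations gives an unstable "
                      "shadow threshold", stacklevel=2)
    groups = max(1, min(config.shadow_groups, config.n_permutations))
    # a shadow hit must not be diluted over more fits than a real probe's
    # hit is diluted over repeats, or the bar drops below one-hit aggregates
    per_group = max(1, min(config.n_permutations // groups,
                           config.n_outer_repeats))
    out = np.empty((groups, per_group))
    b = 0
    for g in range(groups):
        drop = int(rng.integers(n_features))
        if config.shadow_mode == "permute":
            src = int(rng.integers(n_features))
            shadow = rng.permutation(X[:, src])
        else:
            shadow = rng.uniform(0, 1, size=n_samples)
        Xb = np.column_stack([np.delete(X, drop, axis=1), shadow])
        for r in range(per_group):
            b += 1
            imp = _shadow_fit(Xb, y, config, rounds,
                              _seed_for(config.seed, 1, b))
            out[g, r] = imp[-1]
    return out


def aggregate_and_select(probe_ids: Sequence[str],
                         per_repeat: np.ndarray,
                         shadow_importances: np.ndarray,
                         test_aurocs: np.ndarray,
                         config: SelectionConfig) -> SelectionResult:
    """Mean-aggregate repeat importances and cut at the shadow bar.

    ``shadow_importances`` has one row per shadow group; each row mean is
    one draw of the aggregated importance a signal-free variable attains.
    The bar is the ``shadow_quantile`` quantile of those draws (1.0 = the
    maximum).  Ties in the ranking are broken by probe ID.
    """
    aggregated = per_repeat.mean(axis=0)
    group_means = np.atleast_2d(shadow_importances).mean(axis=1)
    bar = float(np.quantile(group_means, config.shadow_quantile))

    order = sorted(range(len(probe_ids)),
                   key=lambda i: (-aggregated[i], probe_ids[i]))
    ranking = pd.DataFrame({
        "probe_id": [probe_ids[i] for i in order],
        "importance": aggregated[order],
    })
    predictors = ranking.loc[ranking["importance"] > bar,
                             "probe_id"].tolist()
    return SelectionResult(
        ranking=ranking, shadow_bar=bar,
        shadow_importances=shadow_importances,
        predictor_set=predictors,
        per_repeat_importances=pd.DataFrame(
            per_repeat, columns=list(probe_ids)),
        test_aurocs=test_aurocs)


def stability_select(beta: BetaMatrix, labels: np.ndarray,
                     config: SelectionConfig) -> SelectionResult:
    """Full selection: repeats, shadow refits, aggregation.

    ``beta`` is probes x samples; ``labels`` is the binary response vector
    aligned with the samples (responder = 1).  Probes with any missing
    value are excluded (complete-case features); probes are processed in
    lexicographic order so the result does not depend on input row order.
    """
    complete = beta.drop_incomplete_probes()
    data = complete.data.sort_index()
    probe_ids = list(data.index)
    X = data.to_numpy().T  # samples x features
    if config.feature_scale == "m":
        clipped = np.clip(X, 1e-6, 1 - 1e-6)
        X = np.log2(clipped / (1 - clipped))
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.size:
        raise ValueError("labels do not match the number of samples")

    per_repeat = np.empty((config.n_outer_repeats, len(probe_ids)))
    aurocs = np.empty(config.n_outer_repeats)
    rounds_used = np.empty(config.n_outer_repeats, dtype=int)
    for r in range(config.n_outer_repeats):
        per_repeat[r], aurocs[r], rounds_used[r] = single_repeat(
            X, y, config, _seed_for(config.seed, 0, r))
    rounds = (config.shadow_trees if config.shadow_trees is not None
              else int(np.median(rounds_used)))
    shadows = shadow_threshold(X, y, config, rounds=rounds)
    return aggregate_and_select(probe_ids, per_repeat, shadows, aurocs,
                                config)
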