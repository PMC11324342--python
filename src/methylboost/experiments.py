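"""Reproducible desk-scale calibration and recovery experiments.

These drivers run the pipeline's statistical checks on synthetic cohorts
at the study's dimensions (2,000 probes, 31 subjects, 16 responders):
type-I control of the shadow-variable selection bar on pure-noise data,
recovery of planted response-associated probes across effect sizes,
ICC parameter recovery, and cell-mixture deconvolution error.

The selection runs use a reduced resampling budget (15 outer repeats, 15
complement shadow refits) — enough to stabilise the aggregated
importances at these dimensions while keeping a 20-replicate experiment
in the minutes range on one CPU; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from .core_io import BetaMatrix
from .deconvolution import ReferenceSignature, deconvolve_matrix, estimate_proportions
from .evaluation import recalibrate
from .selection import SelectionConfig, stability_select
from .stability import icc_report
from .synthetic_data import (SimulationConfig, gen_cell_mixture,
                             gen_cohort_betas, gen_longitudinal,
                             make_reference)

#: resampling budget used by the desk-scale experiments
DESK_REPEATS = 15


def _sub_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def desk_selection_config(seed: int) -> SelectionConfig:
    return SelectionConfig(seed=seed, n_outer_repeats=DESK_REPEATS,
                           shadow_fits=DESK_REPEATS)


def null_calibration(seed: int, n_replicates: int = 20,
                     n_probes: int = 2000, n_models: int = 10) -> dict:
    """Selection and evaluation on pure-noise cohorts (no planted effect).

    Per replicate: fraction of probes the shadow bar admits, and the
    recalibrated mean AUROC of an ensemble on a label-independent
    20-probe panel.  Returns medians/means plus the per-replicate values.
    """
    fractions, aurocs = [], []
    for r in range(n_replicates):
        cfg = SimulationConfig(seed=_sub_seed(seed, 0, r), n_probes=n_probes,
                               n_informative=0, effect_delta=0.0)
        beta, sheet, _ = gen_cohort_betas(cfg)
        y = sheet.labels_for(beta.sample_ids)
        res = stability_select(beta, y, desk_selection_config(
            _sub_seed(seed, 1, r)))
        fractions.append(len(res.predictor_set) / n_probes)

        rng = np.random.default_rng(_sub_seed(seed, 2, r))
        panel = list(rng.choice(beta.probe_ids, size=20, replace=False))
        rep = recalibrate(beta.subset_probes(panel), y,
                          config=desk_selection_config(_sub_seed(seed, 3, r)),
                          n_models=n_models)
        aurocs.append(rep.mean_auroc)
    return {
        "median_selected_fraction": float(np.median(fractions)),
        "selected_fractions": fractions,
        "mean_auroc": float(np.mean(aurocs)),
        "auroc_se": float(np.std(aurocs, ddof=1) / np.sqrt(len(aurocs))),
        "aurocs": aurocs,
        "n_replicates": n_replicates,
        "n_probes": n_probes,
    }


def signal_recovery(seed: int, delta: float, n_replicates: int = 10,
                    n_probes: int = 2000, n_informative: int = 20) -> dict:
    """Recovery of planted probes by the full selection procedure."""
    recoveries, n_selected = [], []
    for r in range(n_replicates):
        cfg = SimulationConfig(seed=_sub_seed(seed, 10, r),
                               n_probes=n_probes,
                               n_informative=n_informative,
                               effect_delta=delta)
        beta, sheet, truth = gen_cohort_betas(cfg)
        y = sheet.labels_for(beta.sample_ids)
        res = stability_select(beta, y, desk_selection_config(
            _sub_seed(seed, 11, r)))
        selected = set(res.predictor_set)
        recoveries.append(len(selected & truth) / len(truth))
        n_selected.append(len(selected))
    return {
        "delta": delta,
        "median_recovery": float(np.median(recoveries)),
        "recoveries": recoveries,
        "median_n_selected": float(np.median(n_selected)),
        "n_replicates": n_replicates,
    }


def planted_signal_auroc(seed: int, n_replicates: int = 10,
                         n_models: int = 10) -> dict:
    """Recalibrated ensemble AUROC when a true signal is present."""
    aurocs = []
    for r in range(n_replicates):
        cfg = SimulationConfig(seed=_sub_seed(seed, 20, r))
        beta, sheet, truth = gen_cohort_betas(cfg)
        y = sheet.labels_for(beta.sample_ids)
        rep = recalibrate(beta.subset_probes(sorted(truth)), y,
                          config=desk_selection_config(
                              _sub_seed(seed, 21, r)),
                          n_models=n_models)
        aurocs.append(rep.mean_auroc)
    return {
        "mean_auroc": float(np.mean(aurocs)),
        "auroc_se": float(np.std(aurocs, ddof=1) / np.sqrt(len(aurocs))),
        "aurocs": aurocs,
        "n_replicates": n_replicates,
    }


def icc_recovery(seed: int, targets=(0.0, 0.5, 0.9),
                 n_probes: int = 200) -> dict:
    """Median estimated ICC per generator target, with banding check."""
    out = {}
    for target in targets:
        cfg = SimulationConfig(seed=_sub_seed(seed, 30, int(target * 10)),
                               n_probes=n_probes, n_informative=0,
                               icc_target=target, n_timepoints=3)
        beta, _, _ = gen_cohort_betas(cfg)
        rep = icc_report(gen_longitudinal(cfg, beta))
        from .stability import koo_li_classify
        banding_ok = all(row["koo_li_class"] == koo_li_classify(row["icc"])
                         for _, row in rep.iterrows())
        out[target] = {"median_icc": float(rep["icc"].median()),
                       "banding_consistent": banding_ok,
                       "n_probes": n_probes}
    return out


def deconvolution_recovery(seed: int, n_samples: int = 100,
                           noise_sd: float = 0.02) -> dict:
    """Noiseless exactness and noisy mean absolute error of the QP."""
    ref = ReferenceSignature(make_reference(seed=_sub_seed(seed, 40)))
    rng = np.random.default_rng(_sub_seed(seed, 41))
    w_true = rng.dirichlet(np.ones(6))
    beta = ref.data.to_numpy().T @ w_true
    est = estimate_proportions(beta, ref)
    noiseless_err = float(np.abs(est.w.to_numpy() - w_true).max())

    m, truth = gen_cell_mixture(ref.data, n_samples=n_samples,
                                dirichlet_alpha=1.0, noise_sd=noise_sd,
                                seed=_sub_seed(seed, 42))
    props = deconvolve_matrix(m, ref)
    mae = (props - truth).abs().mean()
    return {"noiseless_max_error": noiseless_err,
            "noisy_mae_per_cell_type": {k: float(v) for k, v in mae.items()},
            "noisy_mae_max": float(mae.max()),
            "noisy_mae_mean": float(mae.mean()),
            "n_samples": n_samples, "noise_sd": noise_sd}


def stability_rho(seed: int, n_probes: int = 500,
                  n_informative: int = 50) -> dict:
    """Delta-methylation persistence (Spearman rho T1 vs T2)."""
    from .stability import delta_correlation
    cfg = SimulationConfig(seed=_sub_seed(seed, 50), n_probes=n_probes,
                           n_informative=n_informative, effect_delta=0.15,
                           icc_target=0.95)
    beta, sheet, _ = gen_cohort_betas(cfg)
    m = gen_longitudinal(cfg, beta)
    t1 = [c for c in m.sample_ids if c.endswith("_T1")]
    t2 = [c for c in m.sample_ids if c.endswith("_T2")]
    y = sheet.labels_for([c.replace("_T1", "") + "_T1" for c in t1])
    rho, _ = delta_correlation(m.subset_samples(t1), m.subset_samples(t2),
                               y, y)
    return {"rho": float(rho), "n_probes": n_probes}
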