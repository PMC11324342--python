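"""Synthetic cohort generators.

The real cohort behind this pipeline (31 ulcerative-colitis patients, 16
responders / 15 non-responders, EPIC-array peripheral-blood methylation at
up to three timepoints) is controlled-access, so every stage is exercised
on synthetic data that reproduces the statistical structure the analysis
assumes:

* beta-distributed methylation with planted response-associated mean
  shifts (sign randomised per probe, so hyper- and hypo-methylated
  effects both occur, mirroring the near-even split seen in practice);
* longitudinal replicates with a controlled intraclass correlation,
  built on the logit scale where the subject/occasion variance split is
  analytic;
* convex cell-type mixtures of a reference signature matrix;
* clinical score trajectories consistent with each subject's assigned
  response label under the composite endpoint;
* gap-signal probes for the probe filter.

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core_io import BetaMatrix, ClinicalRecord, SampleSheet

CELL_TYPES = ("CD8T", "CD4T", "NK", "B", "Mono", "Neu")

_EPS = 1e-6


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults emulate the cohort: 31 subjects (16 responders), 2,000
    probes of which 20 carry a mean beta shift of 0.15 between response
    groups, beta noise with concentration 50 (between-subject SD ~0.07
    at beta 0.5), three timepoints with target ICC 0.9.
    """

    n_subjects: int = 31
    n_responders: int = 16
    n_probes: int = 2000
    n_informative: int = 20
    effect_delta: float = 0.15
    beta_precision: float = 50.0
    icc_target: float = 0.9
    n_timepoints: int = 3
    dirichlet_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_responders <= self.n_subjects:
            raise ValueError("n_responders must be <= n_subjects")
        if not 0 <= self.n_informative <= self.n_probes:
            raise ValueError("n_informative must be <= n_probes")
        if self.effect_delta < 0 or self.effect_delta >= 0.45:
            raise ValueError(
                "effect_delta must keep group means inside (0, 1)")
        if not 0 <= self.icc_target <= 1:
            raise ValueError("icc_target must lie in [0, 1]")


def _probe_ids(n: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(n)]


def gen_clinical(labels: Sequence[str],
                 rng: np.random.Generator) -> list[ClinicalRecord]:
    """Clinical records whose composite endpoint matches the given labels.

    Responders satisfy the endoscopic criterion plus at least one of the
    clinical/biochemical criteria.  Non-responders either fail endoscopy
    outright or (adversarially) respond endoscopically while failing both
    the clinical and the biochemical criterion.  Scores are drawn in
    clinically plausible ranges for an active moderate-to-severe cohort;
    internal consistency between the total Mayo score and its subscores
    is not enforced.
    """
    records = []
    for i, label in enumerate(labels):
        sid = f"sub{i + 1:02d}"
        ems_t1 = int(rng.integers(2, 4))
        uceis_t1 = int(rng.integers(4, 9))
        mayo_t1 = int(rng.integers(8, 13))
        rbs_t1 = int(rng.integers(2, 4))
        sccai_t1 = int(rng.integers(6, 13))
        crp_t1 = float(rng.uniform(10, 40))
        fcal_t1 = float(rng.uniform(600, 3000))

        if label == "R":
            endo = True
            which = rng.integers(0, 3)  # 0 clinical, 1 biochem, 2 both
            clin = which in (0, 2)
            bio = which in (1, 2)
        else:
            if rng.random() < 0.5:
                endo = False
                clin = bool(rng.random() < 0.5)
                bio = bool(rng.random() < 0.5)
            else:  # adversarial: endoscopic responder, nothing else
                endo, clin, bio = True, False, False

        if endo:
            ems_t2 = ems_t1 - int(rng.integers(1, ems_t1 + 1))
            uceis_t2 = max(0, uceis_t1 - int(rng.integers(0, 4)))
        else:
            ems_t2 = ems_t1
            uceis_t2 = max(0, uceis_t1 - int(rng.integers(0, 2)))

        if bio:
            crp_t2 = crp_t1 * float(rng.uniform(0.1, 0.5))
            fcal_t2 = fcal_t1 * float(rng.uniform(0.1, 0.5))
        else:
            crp_t2 = max(5.5, crp_t1 * float(rng.uniform(0.6, 1.0)))
            fcal_t2 = max(260.0, fcal_t1 * float(rng.uniform(0.6, 1.0)))

        if clin:
            drop = max(3, int(np.ceil(0.30 * mayo_t1)))
            mayo_t2 = mayo_t1 - drop - int(rng.integers(0, 2))
            mayo_t2 = max(0, mayo_t2)
            rbs_t2 = int(rng.integers(0, 2))
            sccai_t2 = int(rng.integers(0, sccai_t1 // 2 + 1))
        else:
            mayo_t2 = mayo_t1 - int(rng.integers(0, 3))
            rbs_t2 = rbs_t1
            lo = sccai_t1 // 2 + 1
            sccai_t2 = int(rng.integers(lo, sccai_t1 + 1))

        records.append(ClinicalRecord(
            subject_id=sid,
            ems_t1=ems_t1, ems_t2=ems_t2,
            uceis_t1=uceis_t1, uceis_t2=uceis_t2,
            mayo_t1=mayo_t1, mayo_t2=mayo_t2,
            rbs_t1=rbs_t1, rbs_t2=rbs_t2,
            sccai_t1=sccai_t1, sccai_t2=sccai_t2,
            crp_t1=crp_t1, crp_t2=crp_t2,
            fcal_t1=fcal_t1, fcal_t2=fcal_t2))
    return records


def gen_cohort_betas(config: SimulationConfig
                     ) -> tuple[BetaMatrix, SampleSheet, set[str]]:
    """Baseline (T1) beta matrix, sample sheet and informative-probe truth.

    Per probe j a non-responder mean m_j is drawn uniformly; informative
    probes add a shift of ±effect_delta (sign random per probe) to the
    responder mean.  Values are Beta(m*k, (1-m)*k) with k the
    beta_precision concentration.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    probes = _probe_ids(cfg.n_probes)

    labels = np.array(["R"] * cfg.n_responders
                      + ["NR"] * (cfg.n_subjects - cfg.n_responders))
    rng.shuffle(labels)

    means_nr = rng.uniform(0.1, 0.9, size=cfg.n_probes)
    informative = rng.choice(cfg.n_probes, size=cfg.n_informative,
                             replace=False)
    # informative probe means re-drawn so the shifted mean stays in (0, 1)
    lo, hi = 0.05 + cfg.effect_delta, 0.95 - cfg.effect_delta
    if lo >= hi:
        raise ValueError("effect_delta leaves no feasible probe mean")
    means_nr[informative] = rng.uniform(lo, hi, size=cfg.n_informative)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_informative)

    means = np.tile(means_nr[:, None], (1, cfg.n_subjects))
    is_r = labels == "R"
    for idx, sign in zip(informative, signs):
        means[idx, is_r] = means_nr[idx] + sign * cfg.effect_delta

    k = cfg.beta_precision
    values = rng.beta(means * k, (1.0 - means) * k)

    subject_ids = [f"sub{i + 1:02d}" for i in range(cfg.n_subjects)]
    sample_ids = [f"{s}_T1" for s in subject_ids]
    beta = BetaMatrix(pd.DataFrame(values, index=probes, columns=sample_ids))

    records = gen_clinical(labels, rng)
    rows = []
    for rec, label, sid, samp in zip(records, labels, subject_ids,
                                     sample_ids):
        row = {"sample_id": samp, "subject_id": sid, "timepoint": "T1",
               "response": label, "steroid": int(rng.random() < 0.5),
               "sccai": rec.sccai_t1}
        row.update({f: getattr(rec, f) for f in (
            "ems_t1", "ems_t2", "uceis_t1", "uceis_t2", "mayo_t1",
            "mayo_t2", "rbs_t1", "rbs_t2", "sccai_t1", "sccai_t2",
            "crp_t1", "crp_t2", "fcal_t1", "fcal_t2")})
        rows.append(row)
    sheet = SampleSheet(pd.DataFrame(rows))
    truth = {probes[i] for i in informative}
    return beta, sheet, truth


def gen_longitudinal(config: SimulationConfig, base: BetaMatrix,
                     occasion_sd: float | None = None) -> BetaMatrix:
    """Longitudinal replicates (T1..Tk) with a target intraclass correlation.

    The baseline values are taken to the logit scale, where each subject's
    value acts as the subject-level latent mean; per probe, occasion noise
    with variance sigma_w^2 = sigma_b^2 * (1 - ICC) / ICC is added at every
    timepoint (sigma_b^2 being the realised between-subject variance of
    the latents), then values are squashed back to (0, 1).  With
    icc_target = 0 the subject effect is removed entirely and
    ``occasion_sd`` supplies the noise scale; with icc_target = 1 the
    replicates are exact copies.
    """
    cfg = config
    icc = cfg.icc_target
    if icc == 1 and occasion_sd is not None and occasion_sd > 0:
        raise ValueError("ICC 1 is incompatible with occasion noise > 0")
    if occasion_sd is None:
        occasion_sd = 0.3
    rng = np.random.default_rng(cfg.seed + 1)
    latent = logit(np.clip(base.values, _EPS, 1 - _EPS))
    n_probes, n_subjects = latent.shape

    if icc == 0:
        centre = np.tile(latent.mean(axis=1, keepdims=True),
                         (1, n_subjects))
        sigma_w = np.full(n_probes, occasion_sd)
    elif icc == 1:
        centre = latent
        sigma_w = np.zeros(n_probes)
    else:
        centre = latent
        sigma_b2 = latent.var(axis=1, ddof=1)
        sigma_w = np.sqrt(sigma_b2 * (1 - icc) / icc)

    tps = [f"T{t + 1}" for t in range(cfg.n_timepoints)]
    subjects = [s.rsplit("_", 1)[0] for s in base.sample_ids]
    blocks = []
    columns = []
    for t in tps:
        noise = rng.normal(size=latent.shape) * sigma_w[:, None]
        blocks.append(expit(centre + noise))
        columns.extend(f"{s}_{t}" for s in subjects)
    values = np.concatenate(blocks, axis=1)
    return BetaMatrix(pd.DataFrame(values, index=base.probe_ids,
                                   columns=columns))


def make_reference(n_discriminating: int = 50, background: int = 100,
                   seed: int = 0) -> pd.DataFrame:
    """Synthetic six-cell-type reference signature (cell type x probe).

    Each cell type receives ``n_discriminating`` probes that are highly
    methylated in that type (0.85) and lowly methylated elsewhere (0.10),
    plus shared background probes with a common random mean — the
    structure a sorted-blood reference panel provides.  This is a
    synthetic stand-in; a real (e.g. IDOL-derived) reference can be
    supplied as TSV instead.
    """
    rng = np.random.default_rng(seed)
    k = len(CELL_TYPES)
    n_probes = k * n_discriminating + background
    probes = _probe_ids(n_probes)
    F = np.full((k, n_probes), 0.10)
    for t in range(k):
        F[t, t * n_discriminating:(t + 1) * n_discriminating] = 0.85
    shared = rng.uniform(0.2, 0.8, size=background)
    F[:, k * n_discriminating:] = np.tile(shared, (k, 1))
    return pd.DataFrame(F, index=list(CELL_TYPES), columns=probes)


def gen_cell_mixture(reference: pd.DataFrame, n_samples: int,
                     dirichlet_alpha: float | Sequence[float] = 1.0,
                     noise_sd: float = 0.0, seed: int = 0
                     ) -> tuple[BetaMatrix, pd.DataFrame]:
    """Convex mixtures of the reference plus Gaussian noise.

    Returns the mixed beta matrix and the true mixing proportions
    (samples x cell types, rows summing to 1).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    k = reference.shape[0]
    alpha = np.broadcast_to(np.asarray(dirichlet_alpha, dtype=float), (k,))
    W = rng.dirichlet(alpha, size=n_samples)  # samples x cell types
    beta = reference.to_numpy().T @ W.T  # probes x samples
    if noise_sd > 0:
        beta = beta + rng.normal(scale=noise_sd, size=beta.shape)
    beta = np.clip(beta, 0.0, 1.0)
    sample_ids = [f"mix{i + 1:03d}" for i in range(n_samples)]
    m = BetaMatrix(pd.DataFrame(beta, index=list(reference.columns),
                                columns=sample_ids))
    truth = pd.DataFrame(W, index=sample_ids, columns=list(reference.index))
    return m, truth


def gen_gap_probes(n_probes: int, gap_fraction: float = 0.1,
                   gap_size: float = 0.5, n_samples: int = 31,
                   seed: int = 0) -> tuple[BetaMatrix, set[str]]:
    """Beta matrix where a fraction of probes carry a bimodal gap signal.

    Gap probes split the samples into two clusters whose centres differ by
    ``gap_size``; within-cluster spread is kept below 0.04 so a cluster
    never fragments at the 0.1 gap threshold.  The remaining probes are
    unimodal with spread < 0.08 and are never gap-called.
    """
    rng = np.random.default_rng(seed)
    probes = _probe_ids(n_probes)
    n_gap = int(round(gap_fraction * n_probes))
    gap_idx = set(rng.choice(n_probes, size=n_gap, replace=False).tolist())
    values = np.empty((n_probes, n_samples))
    for j in range(n_probes):
        if j in gap_idx:
            centre = rng.uniform(0.05, 0.95 - gap_size)
            split = int(rng.integers(2, n_samples - 1))
            assign = np.zeros(n_samples)
            assign[split:] = 1.0
            rng.shuffle(assign)
            v = centre + assign * gap_size + rng.uniform(
                -0.02, 0.02, size=n_samples)
        else:
            centre = rng.uniform(0.1, 0.9)
            v = centre + rng.uniform(-0.04, 0.04, size=n_samples)
        values[j] = np.clip(v, 0.0, 1.0)
    truth = {probes[j] for j in gap_idx}
    return BetaMatrix(pd.DataFrame(values, index=probes,
                                   columns=[f"S{i + 1:02d}"
                                            for i in range(n_samples)])), truth


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of the config with a different seed."""
    return replace(config, seed=seed)
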