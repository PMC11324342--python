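"""Reference-based blood cell-type deconvolution.

Whole-blood methylation is a mixture of cell-type-specific profiles, so a
group difference can reflect shifting cell composition rather than
within-cell methylation change.  Proportions of the six major leukocyte
populations (CD8+ T, CD4+ T, NK, B, monocytes, neutrophils) are estimated
per sample by constrained projection onto a reference signature matrix:

    w* = argmin ||beta - F^T w||^2   s.t.  w >= 0,  sum(w) <= 1

solved as a small quadratic program (the sum constraint can be switched
to equality).  Estimated proportions are then compared between response
groups per cell type with a Mann–Whitney test and FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .core_io import BetaMatrix, benjamini_hochberg, mann_whitney


@dataclass
class ReferenceSignature:
    """Cell-type x probe beta means of sorted reference populations."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("reference betas must lie in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ProportionEstimate:
    sample_id: str
    w: pd.Series           # indexed by cell type
    residual_norm: float


def _check_rank(F: np.ndarray, cell_types: list[str]) -> None:
    if np.linalg.matrix_rank(F) < F.shape[0]:
        # name the culprits: cell types whose profile is (nearly) a
        # combination of the others
        corr = np.corrcoef(F)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
        raise ValueError(
            f"reference signature is rank-deficient; cell types "
            f"{cell_types[i]!r} and {cell_types[j]!r} are collinear")


def _solve_qp(F: np.ndarray, beta: np.ndarray,
              sum_to_one: bool) -> np.ndarray:
    """min ||beta - F^T w||^2 with w >= 0 and sum(w) <= 1 (or = 1)."""
    k = F.shape[0]
    w0 = np.full(k, 1.0 / k)

    def objective(w):
        r = F.T @ w - beta
        return float(r @ r)

    def grad(w):
        return 2.0 * (F @ (F.T @ w - beta))

    kind = "eq" if sum_to_one else "ineq"
    constraints = [{"type": kind,
                    "fun": (lambda w: np.sum(w) - 1.0) if sum_to_one
                    else (lambda w: 1.0 - np.sum(w)),
                    "jac": (lambda w: np.ones(k)) if sum_to_one
                    else (lambda w: -np.ones(k))}]
    res = optimize.minimize(objective, w0, jac=grad, method="SLSQP",
                            bounds=[(0.0, 1.0)] * k,
                            constraints=constraints,
                            options={"maxiter": 200, "ftol": 1e-12})
    return np.clip(res.x, 0.0, None)


def estimate_proportions(sample_betas: pd.Series | np.ndarray,
                         ref: ReferenceSignature,
                         sample_id: str = "",
                         sum_to_one: bool = False) -> ProportionEstimate:
    """Constrained projection of one sample onto the reference."""
    F = ref.data.to_numpy(dtype=float)
    if F.shape[1] < F.shape[0]:
        raise ValueError("need at least as many probes as cell types")
    _check_rank(F, ref.cell_types)
    beta = np.asarray(sample_betas, dtype=float)
    w = _solve_qp(F, beta, sum_to_one)
    resid = float(np.linalg.norm(F.T @ w - beta))
    return ProportionEstimate(
        sample_id=sample_id,
        w=pd.Series(w, index=ref.cell_types),
        residual_norm=resid)


def deconvolve_matrix(m: BetaMatrix, ref: ReferenceSignature,
                      sum_to_one: bool = False) -> pd.DataFrame:
    """Per-sample proportions (samples x cell types) over shared probes."""
    shared = [p for p in ref.probe_ids if p in set(m.probe_ids)]
    if len(shared) < len(ref.cell_types):
        raise ValueError("too few shared probes for deconvolution")
    sub_ref = ReferenceSignature(ref.data[shared])
    sub = m.subset_probes(shared)
    rows = {}
    for sid in sub.sample_ids:
        est = estimate_proportions(sub.data[sid].to_numpy(), sub_ref,
                                   sample_id=sid, sum_to_one=sum_to_one)
        rows[sid] = est.w
    return pd.DataFrame(rows).T


def compare_groups(proportions: pd.DataFrame, labels: np.ndarray,
                   test: str = "mannwhitney") -> pd.DataFrame:
    """Per-cell-type two-group comparison with BH adjustment.

    ``labels`` is the binary response vector aligned with the proportion
    rows.  Default test is Mann–Whitney (robust at ~15 per group); Welch's
    t is available via ``test='welch'``.
    """
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("both groups required")
    rows = []
    for cell in proportions.columns:
        a = proportions.loc[y == 1, cell].to_numpy()
        b = proportions.loc[y == 0, cell].to_numpy()
        if test == "mannwhitney":
            stat, p, method = mann_whitney(a, b)
        elif test == "welch":
            from scipy import stats as _st
            r = _st.ttest_ind(a, b, equal_var=False)
            stat, p, method = float(r.statistic), float(r.pvalue), "welch"
        else:
            raise ValueError("test must be 'mannwhitney' or 'welch'")
        rows.append({"cell_type": cell, "statistic": stat, "p": p,
                     "method": method})
    out = pd.DataFrame(rows)
    out["p_bh"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["p_bh"] < 0.05
    return out
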