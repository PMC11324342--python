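"""Longitudinal biomarker stability.

Two complementary views of whether a candidate CpG's signal survives
time and treatment:

* the intraclass correlation coefficient (ICC) of each probe's beta
  values across timepoints — between-subject variance over total
  variance, estimated from two-way ANOVA mean squares and interpreted
  with the conventional bands: poor < 0.5 <= moderate < 0.75 <= good
  < 0.9 <= excellent;
* the correlation, across probes, of the responder-minus-non-responder
  methylation difference at baseline with the same difference after
  treatment, with each probe assigned to a sign quadrant (a probe
  hypermethylated in responders at both timepoints sits in the
  hyper-hyper quadrant, etc.).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import BetaMatrix, spearman

KOO_LI_BANDS = ("poor", "moderate", "good", "excellent")


@dataclass
class ICCEstimate:
    probe_id: str
    icc: float
    n_subjects: int
    n_timepoints: int
    form: str
    koo_li_class: str


def koo_li_classify(icc: float) -> str:
    """Interpretation band; boundary values go to the higher band."""
    if icc >= 0.9:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.5:
        return "moderate"
    return "poor"


def icc(values: np.ndarray, probe_id: str = "",
        form: str = "A-1") -> ICCEstimate:
    """Single-measurement ICC from a subjects x timepoints matrix.

    ``form`` selects the two-way model: "A-1" (mixed, absolute agreement —
    the default, appropriate for test–retest over fixed occasions) or
    "C-1" (consistency).  Rows containing missing values are dropped
    (listwise deletion).  A matrix with zero total variance has no defined
    ICC and raises.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValueError("expected a subjects x timepoints matrix")
    v = v[~np.isnan(v).any(axis=1)]
    n, k = v.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 timepoints")
    grand = v.mean()
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((v - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if ss_total == 0:
        raise ValueError(f"zero total variance: ICC undefined for "
                         f"{probe_id!r}")
    if form == "A-1":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    elif form == "C-1":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError("form must be 'A-1' or 'C-1'")
    est = (msr - mse) / denom if denom != 0 else 1.0
    return ICCEstimate(probe_id=probe_id, icc=float(est), n_subjects=n,
                       n_timepoints=k, form=form,
                       koo_li_class=koo_li_classify(float(est)))


def _split_longitudinal(m: BetaMatrix) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Parse 'subject_Tk' sample IDs into (frame, subjects, timepoints)."""
    cols = pd.DataFrame(
        [sid.rsplit("_", 1) for sid in m.sample_ids],
        columns=["subject", "timepoint"])
    subjects = sorted(cols["subject"].unique())
    tps = sorted(cols["timepoint"].unique())
    return cols, subjects, tps


def icc_report(m: BetaMatrix, form: str = "A-1") -> pd.DataFrame:
    """Per-probe ICC over the timepoints encoded in 'subject_Tk' columns.

    Subjects missing any timepoint are dropped per probe (listwise).
    Returns a frame with icc, koo_li_class, n_subjects, n_timepoints.
    """
    cols, subjects, tps = _split_longitudinal(m)
    if len(tps) < 2:
        raise ValueError("need at least two timepoints")
    # sample order: subjects x timepoints index grid
    order = np.full((len(subjects), len(tps)), -1)
    for i, (subj, tp) in enumerate(zip(cols["subject"], cols["timepoint"])):
        order[subjects.index(subj), tps.index(tp)] = i
    values = m.values
    rows = []
    for p, probe in enumerate(m.probe_ids):
        grid = np.where(order >= 0, values[p, order.clip(min=0)], np.nan)
        est = icc(grid, probe_id=probe, form=form)
        rows.append({"probe_id": probe, "icc": est.icc,
                     "koo_li_class": est.koo_li_class,
                     "n_subjects": est.n_subjects,
                     "n_timepoints": est.n_timepoints, "form": est.form})
    return pd.DataFrame(rows)


def band_counts(report: pd.DataFrame) -> dict[str, int]:
    counts = report["koo_li_class"].value_counts().to_dict()
    return {band: int(counts.get(band, 0)) for band in KOO_LI_BANDS}


@dataclass
class QuadrantAssignment:
    probe_id: str
    delta_t1: float
    delta_t2: float
    quadrant: str


def _quadrant(d1: float, d2: float) -> str:
    first = "hyper" if d1 >= 0 else "hypo"
    second = "hyper" if d2 >= 0 else "hypo"
    return f"{first}-{second}"


def delta_correlation(m_t1: BetaMatrix, m_t2: BetaMatrix,
                      labels_t1: np.ndarray, labels_t2: np.ndarray
                      ) -> tuple[float, list[QuadrantAssignment]]:
    """Cross-timepoint correlation of group methylation differences.

    Per probe, delta = mean(responders) - mean(non-responders), so a
    positive delta means hypermethylation in responders.  Returns the
    Spearman rho of (delta at T1, delta at T2) across the shared probes
    and a quadrant assignment per probe.
    """
    shared = [p for p in m_t1.probe_ids if p in set(m_t2.probe_ids)]
    if not shared:
        raise ValueError("no shared probes between timepoints")
    y1 = np.asarray(labels_t1, dtype=int)
    y2 = np.asarray(labels_t2, dtype=int)
    for y, name in ((y1, "T1"), (y2, "T2")):
        if np.unique(y).size < 2:
            raise ValueError(f"both response classes required at {name}")
    v1 = m_t1.subset_probes(shared).values
    v2 = m_t2.subset_probes(shared).values
    d1 = v1[:, y1 == 1].mean(axis=1) - v1[:, y1 == 0].mean(axis=1)
    d2 = v2[:, y2 == 1].mean(axis=1) - v2[:, y2 == 0].mean(axis=1)
    rho = spearman(d1, d2)
    quads = [QuadrantAssignment(p, float(a), float(b), _quadrant(a, b))
             for p, a, b in zip(shared, d1, d2)]
    return rho, quads
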