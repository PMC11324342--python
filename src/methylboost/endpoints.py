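"""Composite treatment-response endpoint.

Response after 8 weeks of treatment is a strict composite: an endoscopic
response (decrease in endoscopic Mayo score >= 1 or UCEIS >= 2 versus
baseline) combined with a clinical and/or biochemical response.  The three
component criteria:

* endoscopic: EMS drop >= 1 or UCEIS drop >= 2;
* biochemical: >= 50% decrease in both CRP and faecal calprotectin, or
  CRP <= 5.0 mg/L and faecal calprotectin <= 250 ug/g at week 8;
* clinical: total Mayo drop >= 3 points and >= 30% with rectal-bleeding
  subscore dropping >= 1 or ending <= 1, or a >= 50% drop in SCCAI.

Ties at exactly 30% / 50% count as a response (no rounding rule applied).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .core_io import ClinicalRecord


@dataclass
class ResponseCall:
    """Component and composite response decisions for one subject."""

    subject_id: str
    endoscopic: bool
    biochemical: bool
    clinical: bool
    composite: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.composite == (
            self.endoscopic and (self.clinical or self.biochemical))


def _require(r: ClinicalRecord, names: Sequence[str]) -> None:
    for name in names:
        v = getattr(r, name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"missing {name} for subject {r.subject_id}")


def endoscopic_response(r: ClinicalRecord) -> bool:
    """EMS decreased by >= 1 or UCEIS decreased by >= 2 versus baseline."""
    _require(r, ["ems_t1", "ems_t2", "uceis_t1", "uceis_t2"])
    return (r.ems_t1 - r.ems_t2) >= 1 or (r.uceis_t1 - r.uceis_t2) >= 2


def biochemical_response(r: ClinicalRecord) -> bool:
    """Halved CRP and calprotectin, or both below absolute cutoffs."""
    _require(r, ["crp_t1", "crp_t2", "fcal_t1", "fcal_t2"])
    halved = r.crp_t2 <= 0.5 * r.crp_t1 and r.fcal_t2 <= 0.5 * r.fcal_t1
    absolute = r.crp_t2 <= 5.0 and r.fcal_t2 <= 250.0
    return halved or absolute


def clinical_response(r: ClinicalRecord) -> bool:
    """Mayo-based response (with the RBS clause) or a 50% SCCAI drop."""
    _require(r, ["mayo_t1", "mayo_t2", "rbs_t1", "rbs_t2",
                 "sccai_t1", "sccai_t2"])
    d_mayo = r.mayo_t1 - r.mayo_t2
    mayo_ok = (d_mayo >= 3 and d_mayo >= 0.30 * r.mayo_t1
               and ((r.rbs_t1 - r.rbs_t2) >= 1 or r.rbs_t2 <= 1))
    sccai_ok = r.sccai_t2 <= 0.5 * r.sccai_t1
    return mayo_ok or sccai_ok


def composite_response(r: ClinicalRecord) -> ResponseCall:
    """Endoscopic response AND (clinical OR biochemical) response."""
    endo = endoscopic_response(r)
    bio = biochemical_response(r)
    clin = clinical_response(r)
    reasons = [name for name, ok in
               (("endoscopic", endo), ("biochemical", bio),
                ("clinical", clin)) if ok]
    return ResponseCall(
        subject_id=r.subject_id,
        endoscopic=endo, biochemical=bio, clinical=clin,
        composite=endo and (clin or bio), reasons=reasons)


def tally_responses(records: Sequence[ClinicalRecord]) -> dict:
    """Counts and percentages of each criterion across a cohort."""
    calls = [composite_response(r) for r in records]
    n = len(calls)
    out: dict = {"n": n}
    for crit in ("endoscopic", "biochemical", "clinical", "composite"):
        count = sum(getattr(c, crit) for c in calls)
        out[crit] = {"count": count,
                     "percent": round(100.0 * count / n, 1) if n else 0.0}
    return out
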