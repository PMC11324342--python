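"""Pre-selection probe exclusion.

Probes whose beta distribution splits into well-separated clusters ("gap
signals") usually reflect an underlying genetic variant rather than a
methylation difference, so they are removed before biomarker selection.
The detector mirrors the gap-hunting rule: sort the per-probe betas, cut
wherever two consecutive sorted values differ by more than ``threshold``
(default 0.1), and call a gap when at least two groups emerge and every
group holds at least ``ceil(out_cutoff * n)`` samples.

Known variant-binding probes are handled through a user-supplied drop-list
(one probe ID per line); no annotation database is consulted here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core_io import BetaMatrix


@dataclass
class GapCall:
    probe_id: str
    has_gap: bool
    n_groups: int
    largest_gap: float

    def __post_init__(self) -> None:
        assert self.has_gap == (self.n_groups >= 2) or not self.has_gap


def gap_call(betas: Sequence[float], probe_id: str = "",
             threshold: float = 0.1, out_cutoff: float = 0.01) -> GapCall:
    """Detect a gap signal in one probe's beta values.

    Groups are maximal runs of sorted values with consecutive differences
    <= threshold.  A gap is called when >= 2 groups exist and the smallest
    group still holds max(1, ceil(out_cutoff * n)) samples, so single
    outliers do not trigger a call at the default cutoff.
    """
    v = np.asarray(betas, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError(f"all values missing for probe {probe_id!r}")
    if v.size < 3:
        raise ValueError(f"need >= 3 non-missing values for {probe_id!r}")
    s = np.sort(v)
    diffs = np.diff(s)
    cut = diffs > threshold
    group_sizes = np.diff(np.concatenate(
        [[0], np.flatnonzero(cut) + 1, [s.size]]))
    n_groups = group_sizes.size
    largest_gap = float(diffs.max()) if diffs.size else 0.0
    min_size = max(1, math.ceil(out_cutoff * v.size))
    has_gap = n_groups >= 2 and bool((group_sizes >= min_size).all())
    # a veto by the group-size rule reports the probe as unimodal
    return GapCall(probe_id=probe_id, has_gap=has_gap,
                   n_groups=n_groups if has_gap else 1,
                   largest_gap=largest_gap)


def filter_matrix(m: BetaMatrix, threshold: float = 0.1,
                  out_cutoff: float = 0.01,
                  drop_list: Iterable[str] = ()) -> tuple[BetaMatrix, list[str]]:
    """Remove gap probes and drop-listed probes from a beta matrix.

    Returns the filtered matrix and the removed probe IDs (gap calls first,
    then drop-list hits, each sorted, without duplicates).
    """
    drop = set(drop_list)
    gap_hits = []
    for probe in m.probe_ids:
        if probe in drop:
            continue
        call = gap_call(m.data.loc[probe].to_numpy(), probe_id=probe,
                        threshold=threshold, out_cutoff=out_cutoff)
        if call.has_gap:
            gap_hits.append(probe)
    removed = sorted(gap_hits) + sorted(drop & set(m.probe_ids))
    kept = [p for p in m.probe_ids if p not in set(removed)]
    if not kept:
        import warnings
        warnings.warn("all probes removed by filtering", stacklevel=2)
    return BetaMatrix(m.data.loc[kept]), removed


def read_drop_list(path: str | Path) -> list[str]:
    """One probe ID per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
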