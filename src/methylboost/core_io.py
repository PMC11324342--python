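"""Domain containers, file I/O and shared statistics.

The central container is :class:`BetaMatrix`, a probes x samples matrix of
methylation beta values (methylated / (methylated + unmethylated) intensity,
in [0, 1]).  Everything downstream — probe filtering, feature selection,
stability and deconvolution — consumes this container together with a
:class:`SampleSheet` describing subjects, timepoints and response labels.

Also hosted here are the small statistical routines shared by several
stages: Benjamini–Hochberg adjustment, the 2x2 Pearson chi-square,
Mann–Whitney U and Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

TIMEPOINTS = ("T1", "T2", "T3")
RESPONSE_LABELS = ("R", "NR", "unknown")

#: clinical score columns required for endpoint classification
CLINICAL_COLUMNS = (
    "ems_t1", "ems_t2", "uceis_t1", "uceis_t2", "mayo_t1", "mayo_t2",
    "rbs_t1", "rbs_t2", "sccai_t1", "sccai_t2", "crp_t1", "crp_t2",
    "fcal_t1", "fcal_t2",
)


class BetaMatrixError(ValueError):
    """Raised when a beta matrix violates its invariants."""


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation fractions in [0, 1].

    Missing values are allowed as NaN.  Probe and sample identifiers must
    be unique; all non-missing values must lie in [0, 1].
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise BetaMatrixError(f"duplicate probe IDs: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise BetaMatrixError(f"duplicate sample IDs: {dups[:5]}")
        values = df.to_numpy(dtype=float)
        bad = (values < 0) | (values > 1)
        if np.any(bad & ~np.isnan(values)):
            i, j = np.argwhere(bad & ~np.isnan(values))[0]
            raise BetaMatrixError(
                f"beta value {values[i, j]!r} out of [0, 1] at probe "
                f"{df.index[i]!r}, sample {df.columns[j]!r}"
            )
        self.data = df.astype(float)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.data.loc[list(probes)])

    def subset_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.data[list(samples)])

    def drop_incomplete_probes(self) -> "BetaMatrix":
        """Remove probes with any missing value (complete-case features)."""
        return BetaMatrix(self.data.dropna(axis=0, how="any"))


def read_beta_matrix(path: str | Path, dialect: str = "tsv") -> BetaMatrix:
    """Read a beta matrix: first column probe IDs, header row sample IDs.

    Non-numeric cells and values outside [0, 1] are hard errors naming the
    offending probe and sample; "NA" encodes a missing value.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"],
                     keep_default_na=False, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for probe, row in df.iterrows():
            for sample, cell in row.items():
                if pd.isna(cell):
                    continue
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise BetaMatrixError(
                        f"non-numeric cell {cell!r} at probe {probe!r}, "
                        f"sample {sample!r} in {path}"
                    ) from None
        raise
    return BetaMatrix(numeric)


def write_beta_matrix(m: BetaMatrix, path: str | Path,
                      precision: int = 6) -> None:
    """Write TSV with probes as rows; NA for missing; fixed precision."""
    m.data.to_csv(path, sep="\t", na_rep="NA",
                  float_format=f"%.{precision}f", index_label="probe_id")


@dataclass
class SampleSheet:
    """Per-sample metadata: subject, timepoint, response label, covariates.

    One row per (subject, timepoint); the response label of a subject must
    not change across timepoints.  Clinical score columns (see
    ``CLINICAL_COLUMNS``) travel with the sheet so the endpoint module can
    re-derive labels.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("sample_id", "subject_id", "timepoint", "response"):
            if col not in df.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
        bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")
        bad_resp = set(df["response"]) - set(RESPONSE_LABELS)
        if bad_resp:
            raise ValueError(f"unknown response labels: {sorted(bad_resp)}")
        key = df[["subject_id", "timepoint"]]
        if key.duplicated().any():
            raise ValueError("duplicate (subject_id, timepoint) rows")
        per_subject = df.groupby("subject_id")["response"].nunique()
        if (per_subject > 1).any():
            bad = per_subject[per_subject > 1].index.tolist()
            raise ValueError(
                f"response label changes across timepoints for {bad}")
        self.data = df.reset_index(drop=True)

    def at_timepoint(self, timepoint: str) -> pd.DataFrame:
        return self.data[self.data["timepoint"] == timepoint]

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Binary response vector (R=1, NR=0) aligned with sample_ids."""
        lookup = self.data.set_index("sample_id")["response"]
        labels = lookup.reindex(list(sample_ids))
        if labels.isna().any():
            missing = labels[labels.isna()].index.tolist()
            raise KeyError(f"samples absent from sheet: {missing[:5]}")
        if (labels == "unknown").any():
            raise ValueError("cannot binarise 'unknown' response labels")
        return (labels == "R").to_numpy().astype(int)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, index=False)


@dataclass
class ClinicalRecord:
    """Clinical scores of one subject at baseline (T1) and week 8 (T2).

    EMS: endoscopic Mayo subscore 0-3. UCEIS: 0-8. Total Mayo: 0-12.
    RBS: rectal-bleeding subscore 0-3. SCCAI: clinical activity index.
    CRP in mg/L; faecal calprotectin in ug/g.
    """

    subject_id: str
    ems_t1: float
    ems_t2: float
    uceis_t1: float
    uceis_t2: float
    mayo_t1: float
    mayo_t2: float
    rbs_t1: float
    rbs_t2: float
    sccai_t1: float
    sccai_t2: float
    crp_t1: float
    crp_t2: float
    fcal_t1: float
    fcal_t2: float

    _RANGES = {
        "ems": (0, 3), "uceis": (0, 8), "mayo": (0, 12),
        "rbs": (0, 3), "sccai": (0, 19),
    }

    def __post_init__(self) -> None:
        for score, (lo, hi) in self._RANGES.items():
            for tp in ("t1", "t2"):
                v = getattr(self, f"{score}_{tp}")
                if not (lo <= v <= hi):
                    raise ValueError(
                        f"{score}_{tp}={v} outside [{lo}, {hi}] for "
                        f"subject {self.subject_id}")
        for name in ("crp_t1", "crp_t2", "fcal_t1", "fcal_t2"):
            if getattr(self, name) < 0:
                raise ValueError(
                    f"{name} negative for subject {self.subject_id}")


def records_from_sheet(sheet: SampleSheet) -> list[ClinicalRecord]:
    """Extract one ClinicalRecord per subject from T1 rows of the sheet."""
    t1 = sheet.at_timepoint("T1")
    records = []
    for _, row in t1.iterrows():
        records.append(ClinicalRecord(
            subject_id=row["subject_id"],
            **{c: float(row[c]) for c in CLINICAL_COLUMNS}))
    return records


@dataclass
class GeneSetCollection:
    """Named gene sets plus the gene universe they are tested against."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect all sets with a new universe; drop emptied sets."""
        uni = frozenset(universe)
        kept = {name: genes & uni for name, genes in self.sets.items()}
        kept = {n: g for n, g in kept.items() if g}
        return GeneSetCollection(sets=kept, universe=uni)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read the standard GMT format: name, description, member genes."""
    sets: dict[str, frozenset[str]] = {}
    universe: set[str] = set()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            sets[name] = frozenset(genes)
            universe.update(genes)
    return GeneSetCollection(sets=sets, universe=frozenset(universe))


@dataclass
class AnnotationMap:
    """probe_id -> gene symbols (possibly none for intergenic probes)."""

    mapping: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def genes_for(self, probe_id: str) -> tuple[str, ...]:
        return tuple(self.mapping.get(probe_id, ()))


def read_annotation(path: str | Path) -> AnnotationMap:
    """Read a 2-column TSV (probe_id, gene); multiple rows per probe OK."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    mapping: dict[str, tuple[str, ...]] = {}
    for probe, group in df.groupby(df.columns[0]):
        genes = tuple(sorted(set(group.iloc[:, 1].dropna())))
        mapping[str(probe)] = genes
    return AnnotationMap(mapping)


# ---------------------------------------------------------------------------
# shared statistics


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Step-up FDR adjustment; order-preserving, clipped to 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chisq_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table, no continuity correction.

    This is the test behind the cohort's categorical baseline comparisons
    (e.g. sex and prior-vedolizumab distribution in responders vs
    non-responders).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: zero margin")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(x: Sequence[float], y: Sequence[float]
                 ) -> tuple[float, float, str]:
    """Two-sided Mann–Whitney U.

    Uses the exact null distribution when both groups are small (n <= 8)
    and tie-free, otherwise the tie-corrected normal approximation.
    Returns (U, p, method) so reports can state which was used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and max(x.size, y.size) <= 8) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with mid-ranked ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("Spearman correlation undefined for constant input")
    return float(stats.spearmanr(x, y).statistic)
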