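"""Post-hoc covariate regressions and gene-set over-representation.

Two follow-up questions about a selected predictor panel:

* is a probe's methylation merely tracking disease activity (SCCAI) or
  corticosteroid use?  Per probe and covariate, an ordinary least-squares
  regression of beta on the covariate with a two-sided t-test on the
  slope, BH-adjusted within each covariate family;
* do the genes annotated to the panel cluster in known gene sets?  A
  one-sided hypergeometric over-representation test per set, BH-adjusted
  across sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (AnnotationMap, BetaMatrix, GeneSetCollection,
                      SampleSheet, benjamini_hochberg)


def covariate_regression(m: BetaMatrix, sheet: SampleSheet,
                         covariates: tuple[str, ...] = ("sccai", "steroid"),
                         ) -> pd.DataFrame:
    """Marginal OLS of each probe's beta on each covariate.

    Returns one row per (probe, covariate) with slope (beta units per
    covariate unit), two-sided p and BH-adjusted p within the covariate's
    family.  Covariates must vary across samples.
    """
    meta = sheet.data.set_index("sample_id").loc[m.sample_ids]
    rows = []
    for cov in covariates:
        x = meta[cov].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            raise ValueError(f"covariate {cov!r} is constant")
        block = []
        for probe in m.probe_ids:
            yv = m.data.loc[probe].to_numpy()
            fit = stats.linregress(x, yv)
            block.append({"probe_id": probe, "covariate": cov,
                          "slope": float(fit.slope),
                          "p": float(fit.pvalue)})
        frame = pd.DataFrame(block)
        frame["p_bh"] = benjamini_hochberg(frame["p"].to_numpy())
        rows.append(frame)
    out = pd.concat(rows, ignore_index=True)
    out["significant"] = out["p_bh"] < 0.05
    return out


def map_probes_to_genes(probes, ann: AnnotationMap
                        ) -> tuple[list[str], list[str]]:
    """Deduplicated gene symbols for a probe list, plus unannotated probes."""
    genes: set[str] = set()
    unannotated = []
    for probe in probes:
        hits = ann.genes_for(probe)
        if hits:
            genes.update(hits)
        else:
            unannotated.append(probe)
    return sorted(genes), unannotated


def overrepresentation(predictor_genes, sets: GeneSetCollection
                       ) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per gene set.

    With N the universe size, K the set size, n the number of predictor
    genes and k their overlap with the set, p = P(X >= k) for
    X ~ Hypergeom(N, K, n); BH adjustment across sets.  Sets with
    adjusted p < 0.05 are flagged significant.
    """
    selected = set(predictor_genes)
    if not selected <= sets.universe:
        extra = sorted(selected - sets.universe)
        raise ValueError(f"predictor genes outside universe: {extra[:5]}")
    if not selected:
        return pd.DataFrame(columns=["set_name", "k", "K", "n", "N",
                                     "p", "p_fdr", "significant"])
    N = len(sets.universe)
    n = len(selected)
    rows = []
    for name, members in sorted(sets.sets.items()):
        K = len(members)
        k = len(selected & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N,
                     "p": p})
    out = pd.DataFrame(rows)
    out["p_fdr"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["p_fdr"] < 0.05
    return out
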