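"""Differential composition analysis.

Two layers, mirroring how amplicon studies usually report composition
shifts: (1) STAMP-style group tests on per-sample relative abundances at a
chosen taxonomic rank — Kruskal-Wallis across all groups, Welch's t-test
for pairwise or one-vs-rest contrasts, BH-FDR across taxa; and (2) a
volcano-style differential-OTU screen with a fold-change > 4 and p < 0.05
decision rule.  The volcano stage deliberately replaces negative-binomial
count modelling with a pseudocount log-relative-abundance Welch test: the
decision thresholds, not the dispersion machinery, are what the screen is
about, and the test is documented and swappable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diversity import kruskal_wallis
from .tables import OTUTable, relative_abundance


@dataclass
class DifferentialResult:
    feature_id: str
    mean_ra: dict[str, float]
    log2_fold_change: float
    statistic: float
    p: float
    p_adjusted: float
    status: str  # enriched | decreased | ns


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Satterthwaite df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            warnings.warn("both groups constant and equal; p set to 1")
            return 0.0, float(len(x) + len(y) - 2), 1.0
        warnings.warn("zero variance in both groups with unequal means")
        return float(np.inf if np.mean(x) > np.mean(y) else -np.inf), \
            float(len(x) + len(y) - 2), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_fdr(pvals) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def group_test_by_taxon(
    agg: OTUTable,
    labels=None,
    mode: str = "three-group-KW",
    contrast: tuple[str, str] | None = None,
    alpha: float = 0.05,
) -> list[DifferentialResult]:
    """Test every taxon of a rank-aggregated table for group differences.

    ``mode='three-group-KW'`` runs Kruskal-Wallis across all groups;
    ``mode='pairwise-welch'`` runs Welch's t-test on the two groups named by
    ``contrast`` — a label of ``"Others"`` pools the remaining groups, which
    yields the one-vs-rest columns of STAMP-style tables.  Tests are run on
    per-sample relative abundances; BH-FDR is applied across taxa.
    """
    if mode not in {"three-group-KW", "pairwise-welch"}:
        raise ValueError(f"unknown mode {mode!r}")
    labels = np.asarray(labels if labels is not None
                        else [m.group for m in agg.metadata])
    ra = relative_abundance(agg)
    results = []
    pvals = []
    for taxon in agg.otu_ids:
        vals = ra.loc[taxon].to_numpy()
        means = {g: float(vals[labels == g].mean()) for g in np.unique(labels)}
        if mode == "three-group-KW":
            stat, p = kruskal_wallis(vals, labels)
            lfc = np.nan
        else:
            if contrast is None:
                raise ValueError("pairwise-welch needs a contrast (a, b)")
            a, b = contrast
            xa = vals[labels == a] if a != "Others" else vals[labels != b]
            xb = vals[labels == b] if b != "Others" else vals[labels != a]
            stat, _, p = welch_t(xa, xb)
            eps = _default_pseudocount(ra.to_numpy())
            lfc = float(np.log2((xb.mean() + eps) / (xa.mean() + eps)))
        pvals.append(p)
        results.append(DifferentialResult(
            feature_id=taxon, mean_ra=means, log2_fold_change=lfc,
            statistic=stat, p=p, p_adjusted=np.nan, status="ns",
        ))
    adjusted = bh_fdr(pvals)
    for r, q in zip(results, adjusted):
        r.p_adjusted = q
        if q < alpha:
            r.status = "significant"
    return results


def _default_pseudocount(ra: np.ndarray) -> float:
    nonzero = ra[ra > 0]
    return float(nonzero.min() / 2.0) if len(nonzero) else 0.5


def volcano_differential(
    table: OTUTable,
    group_a: str,
    group_b: str,
    fc_thresh: float = 4.0,
    p_thresh: float = 0.05,
    pseudocount: float | None = None,
) -> list[DifferentialResult]:
    """Volcano-style per-OTU screen between two groups.

    Fold change = (mean RA in B + ε)/(mean RA in A + ε); p from Welch's
    t-test on log(RA + ε).  Status is ``enriched`` (FC > fc_thresh,
    p < p_thresh, i.e. higher in B), ``decreased`` (FC < 1/fc_thresh,
    p < p_thresh) or ``ns``.  ε defaults to half the smallest nonzero
    relative abundance in the table.
    """
    labels = np.asarray([m.group for m in table.metadata])
    for g in (group_a, group_b):
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g} needs at least two samples")
    ra = relative_abundance(table)
    # ra columns follow counts columns; align labels to columns
    meta = table.metadata_frame()
    col_labels = meta["group"].to_numpy()
    eps = pseudocount if pseudocount is not None else _default_pseudocount(ra.to_numpy())
    a_cols = ra.columns[col_labels == group_a]
    b_cols = ra.columns[col_labels == group_b]
    log_a = np.log(ra[a_cols] + eps)
    log_b = np.log(ra[b_cols] + eps)
    results, pvals = [], []
    for otu in table.otu_ids:
        ma = float(ra.loc[otu, a_cols].mean())
        mb = float(ra.loc[otu, b_cols].mean())
        fc = (mb + eps) / (ma + eps)
        if ra.loc[otu].nunique() == 1:      # flat OTU, incl. all-zero
            t, p = 0.0, 1.0
        else:
            t, _, p = welch_t(log_a.loc[otu], log_b.loc[otu])
        pvals.append(p)
        if fc > fc_thresh and p < p_thresh:
            status = "enriched"
        elif fc < 1.0 / fc_thresh and p < p_thresh:
            status = "decreased"
        else:
            status = "ns"
        results.append(DifferentialResult(
            feature_id=otu, mean_ra={group_a: ma, group_b: mb},
            log2_fold_change=float(np.log2(fc)), statistic=t, p=p,
            p_adjusted=np.nan, status=status,
        ))
    adjusted = bh_fdr(pvals)
    for r, q in zip(results, adjusted):
        r.p_adjusted = q
    return results


def differential_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"feature_id": r.feature_id}
        row.update({f"mean_ra_{g}": v for g, v in sorted(r.mean_ra.items())})
        row.update({
            "log2_fold_change": r.log2_fold_change, "statistic": r.statistic,
            "p": r.p, "p_adjusted": r.p_adjusted, "status": r.status,
        })
        rows.append(row)
    return pd.DataFrame(rows)
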