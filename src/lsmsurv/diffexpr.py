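"""Differential expression between index-high and index-low sample groups.

Per gene: a two-sample t-test (Welch by default) on log2 values and a fold
change ``log2fc = mean(high) - mean(low)``.  A gene is called ``up`` when
log2fc > 1 and p < 0.05, ``down`` when log2fc < -1 and p < 0.05, otherwise
``ns`` — both conditions are required, and no multiple-testing correction is
applied to the calls by default (a BH column is available but off, matching
the raw-p convention of the array literature; documented caveat).

The transcriptome-shift test asks whether the fold changes of a gene list
(typically the DEGs) are centered below zero, i.e. whether the index-high
group has globally lower RNA levels: by default a one-sided (less) Wilcoxon
signed-rank of log2fc against 0, with a sign test and a mirrored two-sample
KS variant as alternatives, plus empirical-CDF points for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

__all__ = [
    "ShiftTestResult",
    "group_compare",
    "top_table",
    "shift_test",
    "ecdf_points",
    "FC_CUT",
    "P_CUT",
]

#: DEG thresholds: |log2 fold change| > 1 and p < 0.05.
FC_CUT = 1.0
P_CUT = 0.05


@dataclass(frozen=True)
class ShiftTestResult:
    statistic: float
    p_value: float
    median_log2fc: float
    test_name: str
    n: int


def group_compare(
    m: ExpressionMatrix,
    groups: Sequence[str] | np.ndarray,
    equal_var: bool = False,
    fc_cut: float = FC_CUT,
    p_cut: float = P_CUT,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-gene t-tests and fold changes between the high and low groups.

    ``groups`` holds ``"high"``/``"low"`` per sample, aligned with the matrix
    columns.  Welch's unequal-variance t-test is the default
    (``equal_var=True`` switches to the pooled-variance test).  Returns a
    DataFrame with columns gene, log2fc, p_value, direction (and fdr when
    requested); direction follows the joint threshold rule.
    """
    groups = np.asarray(groups)
    if len(groups) != m.shape[1]:
        raise ValueError("groups length does not match number of samples")
    hi = groups == "high"
    lo = groups == "low"
    if hi.sum() < 2 or lo.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    X = m.values
    xhi, xlo = X[:, hi], X[:, lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pval = stats.ttest_ind(xhi, xlo, axis=1, equal_var=equal_var)
    log2fc = xhi.mean(axis=1) - xlo.mean(axis=1)
    pval = np.where(np.isnan(pval), 1.0, pval)  # zero-variance genes: no call
    direction = np.full(len(log2fc), "ns", dtype=object)
    direction[(log2fc > fc_cut) & (pval < p_cut)] = "up"
    direction[(log2fc < -fc_cut) & (pval < p_cut)] = "down"
    out = pd.DataFrame(
        {
            "gene": m.gene_ids,
            "log2fc": log2fc,
            "p_value": pval,
            "direction": direction,
        }
    )
    if fdr:
        out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def top_table(t: pd.DataFrame, k: int = 12) -> pd.DataFrame:
    """Top ``k`` up- and top ``k`` down-regulated genes by |log2fc|.

    Only significant genes (direction up/down) are ranked; ties in |log2fc|
    break by smaller p-value, then lexicographic gene name.  Fewer rows are
    returned when fewer significant genes exist.
    """
    sig = t[t["direction"].isin(["up", "down"])].copy()
    if sig.empty:
        return sig
    sig["_absfc"] = sig["log2fc"].abs()
    sig = sig.sort_values(
        ["_absfc", "p_value", "gene"], ascending=[False, True, True]
    )
    up = sig[sig["direction"] == "up"].head(k)
    down = sig[sig["direction"] == "down"].head(k)
    return (
        pd.concat([up, down]).drop(columns="_absfc").reset_index(drop=True)
    )


def shift_test(
    t: pd.DataFrame,
    method: Literal["wilcoxon_signed", "ks_vs_zero_symmetric", "sign"] = "wilcoxon_signed",
) -> ShiftTestResult:
    """Test whether the table's log2 fold changes are centered below zero.

    One-sided (``less``) throughout: small p means the fold-change
    distribution sits below 0, i.e. globally reduced expression in the high
    group.  Callers normally pass the DEG subset of a
    :func:`group_compare` table; at least 5 rows are required.

    Methods: ``wilcoxon_signed`` (signed-rank of log2fc vs 0, default),
    ``sign`` (exact binomial on the fraction of negative fold changes), and
    ``ks_vs_zero_symmetric`` (two-sample KS of the fold changes against their
    mirror image, sensitive to any asymmetry toward negative values).
    """
    fc = np.asarray(t["log2fc"], dtype=float)
    if len(fc) < 5:
        raise ValueError(f"shift test needs >= 5 genes, got {len(fc)}")
    if method == "wilcoxon_signed":
        res = stats.wilcoxon(fc, alternative="less")
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "sign":
        nz = fc[fc != 0]
        neg = int((nz < 0).sum())
        res = stats.binomtest(neg, len(nz), 0.5, alternative="greater")
        stat, p = float(neg), float(res.pvalue)
    elif method == "ks_vs_zero_symmetric":
        res = stats.ks_2samp(fc, -fc, alternative="greater")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown shift-test method {method!r}")
    return ShiftTestResult(
        statistic=stat,
        p_value=p,
        median_log2fc=float(np.median(fc)),
        test_name=method,
        n=len(fc),
    )


def ecdf_points(t: pd.DataFrame) -> pd.DataFrame:
    """Empirical CDF of log2 fold changes, for cumulative-distribution plots."""
    fc = np.sort(np.asarray(t["log2fc"], dtype=float))
    frac = np.arange(1, len(fc) + 1) / len(fc)
    return pd.DataFrame({"log2fc": fc, "cumulative_fraction": frac})
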