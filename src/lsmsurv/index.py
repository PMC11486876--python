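"""The multiplicative survival index: ratio of harmful to favorable gene products.

For sample *j* the index is

    index_j = prod_{g in harmful} x_gj / prod_{g in favorable} x_fj

where ``x`` are the log2 expression values as stored.  The products are taken
on the log2 scale deliberately — see the methods note: the published
definition applies the ratio to expression values without any further
transform, and RMA-style log2 intensities are strictly positive, which the
code enforces (a zero or negative factor would make the ratio ill-defined).

Samples are stratified into ``high``/``low`` at the median index by default
(ties to ``low``), and the index is evaluated against survival three ways:
log-rank on the groups, Cox on the group indicator, and Cox on the
standardized continuous index (HR per SD).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SurvivalTable
from .survival import CoxResult, cox_univariate, logrank_test

__all__ = [
    "GeneSets",
    "IndexEvaluation",
    "compute_index",
    "stratify_index",
    "evaluate_index",
    "gene_sets_from_screen",
]


@dataclass(frozen=True)
class GeneSets:
    """Harmful (numerator) and favorable (denominator) gene sets; disjoint."""

    harmful: tuple[str, ...]
    favorable: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.harmful or not self.favorable:
            raise ValueError("harmful and favorable gene sets must be non-empty")
        overlap = set(self.harmful) & set(self.favorable)
        if overlap:
            raise ValueError(f"genes in both sets: {sorted(overlap)}")

    def swapped(self) -> "GeneSets":
        return GeneSets(harmful=self.favorable, favorable=self.harmful)


@dataclass(frozen=True)
class IndexEvaluation:
    logrank_chi2: float
    logrank_p: float
    cox_group: CoxResult      # high vs low indicator
    cox_continuous: CoxResult  # per-SD of the index


def compute_index(m: ExpressionMatrix, gs: GeneSets) -> pd.Series:
    """Per-sample index values (product of harmful over product of favorable).

    All involved expression values must be strictly positive; a non-positive
    value raises an error naming the gene and sample.
    """
    for gene in (*gs.harmful, *gs.favorable):
        if gene not in m.data.index:
            raise KeyError(f"index gene {gene!r} absent from expression matrix")
    sub = m.data.loc[list(gs.harmful) + list(gs.favorable)]
    nonpos = sub <= 0
    if nonpos.to_numpy().any():
        i, j = np.argwhere(nonpos.to_numpy())[0]
        raise ValueError(
            f"non-positive expression value for index gene {sub.index[i]!r} "
            f"in sample {sub.columns[j]!r}; the ratio is ill-defined"
        )
    num = m.data.loc[list(gs.harmful)].prod(axis=0)
    den = m.data.loc[list(gs.favorable)].prod(axis=0)
    out = num / den
    out.name = "index_value"
    return out


def stratify_index(
    values: pd.Series | Sequence[float],
    rule: Literal["median"] | tuple[str, float] = "median",
) -> pd.DataFrame:
    """Assign each sample to the index-high or index-low group.

    Returns a DataFrame indexed by sample with columns ``index_value``,
    ``group`` and ``cutoff``; ties at the cutoff go to ``low``.
    """
    values = pd.Series(values)
    x = values.to_numpy(dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(x) == 0:
        raise ValueError("index is constant; cannot stratify")
    if rule == "median":
        cut = float(np.median(x))
    elif isinstance(rule, tuple) and rule[0] == "quantile":
        cut = float(np.quantile(x, rule[1]))
    else:
        raise ValueError(f"unknown stratification rule {rule!r}")
    return pd.DataFrame(
        {
            "index_value": x,
            "group": np.where(x > cut, "high", "low"),
            "cutoff": cut,
        },
        index=values.index,
    )


def evaluate_index(assignments: pd.DataFrame, s: SurvivalTable) -> IndexEvaluation:
    """Survival association of the index: log-rank + group and continuous Cox.

    ``assignments`` is the output of :func:`stratify_index`, aligned to ``s``
    (same samples, same order).  The continuous index is standardized before
    the Cox fit so its hazard ratio reads per standard deviation.
    """
    if list(assignments.index) != list(s.sample_ids):
        raise ValueError("assignments and survival table are not sample-aligned")
    groups = assignments["group"].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("all samples fall in one index group")
    chi2, p = logrank_test(s, groups)
    cox_group = cox_univariate(s, (groups == "high").astype(float))
    vals = assignments["index_value"].to_numpy(dtype=float)
    z = (vals - vals.mean()) / vals.std(ddof=1)
    cox_cont = cox_univariate(s, z)
    return IndexEvaluation(
        logrank_chi2=chi2, logrank_p=p, cox_group=cox_group, cox_continuous=cox_cont
    )


def gene_sets_from_screen(screen: pd.DataFrame) -> GeneSets:
    """Build the index gene sets from a screen table's inclusion flags."""
    inc = screen[screen["included_in_index"]]
    harmful = tuple(inc.loc[inc["label"] == "harmful", "gene"])
    favorable = tuple(inc.loc[inc["label"] == "favorable", "gene"])
    if not harmful or not favorable:
        raise ValueError(
            "screen did not yield both harmful and favorable included genes "
            f"(harmful={list(harmful)}, favorable={list(favorable)})"
        )
    return GeneSets(harmful=harmful, favorable=favorable)
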