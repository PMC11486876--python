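"""Per-gene survival screening: KM curves, log-rank tests, Cox hazard ratios.

Each panel gene is dichotomized at its median (configurable), compared by
Kaplan–Meier / log-rank, and fit in a univariate Cox model (Efron ties, Wald
confidence intervals on the log scale).  A gene is labeled ``favorable`` when
its hazard ratio is below 1 and ``harmful`` otherwise; by default a gene is
flagged for index inclusion when its log-rank p-value passes ``alpha``, with
explicit override lists available for pinned gene sets.

All estimation is delegated to lifelines; this module owns the screening
conventions (cut rule, tie rule, labeling, inclusion) and the tabular result
contract.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .io import ExpressionMatrix, SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "CoxResult",
    "dichotomize",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "screen_genes",
    "multivariable_cox",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: survival probability and risk-set size over time.

    ``times`` starts at 0 with survival 1.0; censored times reduce the risk
    set without a downward step.
    """

    times: np.ndarray
    survival_prob: np.ndarray
    n_at_risk: np.ndarray


@dataclass(frozen=True)
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    beta: float
    se: float
    flagged: str | None = None  # "separation" | "non-convergence" | None


def dichotomize(
    values: Sequence[float] | np.ndarray | pd.Series,
    rule: Literal["median", "mean"] | tuple[str, float] = "median",
) -> np.ndarray:
    """Split values into ``"high"``/``"low"`` at a data-driven cutoff.

    ``rule`` is ``"median"``, ``"mean"``, or ``("quantile", q)``.  Values equal
    to the cutoff are assigned to ``"low"``; a constant vector is an error.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    if np.ptp(x) == 0:
        raise ValueError("cannot dichotomize a constant vector")
    if rule == "median":
        cut = float(np.median(x))
    elif rule == "mean":
        cut = float(np.mean(x))
    elif isinstance(rule, tuple) and rule[0] == "quantile":
        cut = float(np.quantile(x, rule[1]))
    else:
        raise ValueError(f"unknown dichotomization rule {rule!r}")
    return np.where(x > cut, "high", "low")


def km_estimate(s: SurvivalTable) -> KMCurve:
    """Kaplan–Meier product-limit estimate of the survival function."""
    if len(s) < 1:
        raise ValueError("need at least one sample")
    kmf = KaplanMeierFitter()
    kmf.fit(s.time, event_observed=s.event)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(times).to_numpy(dtype=float)
    return KMCurve(times=times, survival_prob=surv, n_at_risk=at_risk.astype(int))


def logrank_test(
    s: SurvivalTable, groups: Sequence[str] | np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank test (1 df); returns (chi2, p).

    Requires both groups non-empty and at least one event overall.
    """
    groups = np.asarray(groups)
    if len(groups) != len(s):
        raise ValueError("groups length does not match survival table")
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("log-rank test needs two non-empty groups")
    if len(labels) > 2:
        raise ValueError(f"expected two groups, got {list(labels)}")
    if s.event.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    a = groups == labels[0]
    res = _ll_logrank(
        s.time[a], s.time[~a], event_observed_A=s.event[a], event_observed_B=s.event[~a]
    )
    return float(res.test_statistic), float(res.p_value)


def _cox_fit(time: np.ndarray, event: np.ndarray, x: np.ndarray) -> CoxResult:
    df = pd.DataFrame({"time": time, "event": event, "x": x})
    cph = CoxPHFitter()  # Efron tie handling (lifelines default)
    binary = len(np.unique(x)) == 2
    if binary:
        # complete separation: all events in one group -> unbounded MLE
        hi = x == x.max()
        ev_hi, ev_lo = event[hi].sum(), event[~hi].sum()
        if (ev_hi == 0 or ev_lo == 0) and event.sum() > 0:
            inf_hr = np.inf if ev_hi > 0 else 0.0
            return CoxResult(
                hr=inf_hr,
                ci_low=0.0,
                ci_high=np.inf,
                p=np.nan,
                beta=np.sign(np.log(inf_hr) if inf_hr else -1) * np.inf,
                se=np.inf,
                flagged="separation",
            )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    return CoxResult(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p=float(cph.summary.loc["x", "p"]),
        beta=beta,
        se=se,
    )


def cox_univariate(
    s: SurvivalTable,
    x: Sequence[float] | np.ndarray,
    dichotomized: bool = False,
    rule: Literal["median", "mean"] | tuple[str, float] = "median",
) -> CoxResult:
    """Univariate Cox PH fit of survival on one covariate.

    With ``dichotomized=True`` the covariate is first median-split (per
    ``rule``) and coded 0 = low, 1 = high, so the hazard ratio compares the
    high to the low group.  CI is Wald 95% on the log-hazard scale.
    """
    x = np.asarray(x, dtype=float)
    if len(x) != len(s):
        raise ValueError("covariate length does not match survival table")
    if s.event.sum() < 2:
        raise ValueError("Cox regression needs at least 2 events")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    if dichotomized:
        x = (dichotomize(x, rule) == "high").astype(float)
    return _cox_fit(s.time, s.event, x)


def screen_genes(
    m: ExpressionMatrix,
    s: SurvivalTable,
    panel: Sequence[str],
    alpha: float = 0.05,
    cut_rule: Literal["median", "mean"] | tuple[str, float] = "median",
    cox_on_groups: bool = True,
    include_harmful: Sequence[str] | None = None,
    include_favorable: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Screen a gene panel for survival association.

    For each panel gene: median-split expression, log-rank test between the
    high and low groups, and a univariate Cox fit (on the dichotomized groups
    by default, or on the continuous log2 values with ``cox_on_groups=False``).
    Label is ``favorable`` iff HR < 1.  ``included_in_index`` defaults to
    ``p_logrank < alpha``; explicit ``include_harmful``/``include_favorable``
    lists override the automatic rule (e.g. a pinned published signature).

    Returns one row per gene with columns gene, hr, ci_low, ci_high,
    p_logrank, p_cox, n_high, n_low, label, included_in_index.
    """
    missing = [g for g in panel if g not in m.data.index]
    if missing:
        raise KeyError(f"panel genes absent from expression matrix: {missing}")
    if list(m.sample_ids) != list(s.sample_ids):
        raise ValueError("expression and survival samples not aligned; "
                         "call align_samples first")
    override = include_harmful is not None or include_favorable is not None
    include_harmful = set(include_harmful or [])
    include_favorable = set(include_favorable or [])

    rows = []
    for gene in panel:
        x = m.data.loc[gene].to_numpy(dtype=float)
        groups = dichotomize(x, cut_rule)
        chi2, p_lr = logrank_test(s, groups)
        try:
            cox = cox_univariate(
                s, x, dichotomized=cox_on_groups, rule=cut_rule
            )
        except RuntimeError as exc:
            logger.warning("gene %s: %s; excluded from index", gene, exc)
            rows.append(
                dict(
                    gene=gene, hr=np.nan, ci_low=np.nan, ci_high=np.nan,
                    p_logrank=p_lr, p_cox=np.nan,
                    n_high=int((groups == "high").sum()),
                    n_low=int((groups == "low").sum()),
                    label="unknown", included_in_index=False,
                )
            )
            continue
        label = "favorable" if cox.hr < 1 else "harmful"
        if override:
            included = gene in include_harmful or gene in include_favorable
            if gene in include_harmful:
                label = "harmful"
            elif gene in include_favorable:
                label = "favorable"
        else:
            included = bool(p_lr < alpha) and cox.flagged is None
        rows.append(
            dict(
                gene=gene,
                hr=cox.hr,
                ci_low=cox.ci_low,
                ci_high=cox.ci_high,
                p_logrank=p_lr,
                p_cox=cox.p,
                n_high=int((groups == "high").sum()),
                n_low=int((groups == "low").sum()),
                label=label,
                included_in_index=included,
            )
        )
    return pd.DataFrame(rows)


def multivariable_cox(
    s: SurvivalTable,
    covariates: pd.DataFrame,
    entry_p: float = 0.15,
    condition_threshold: float = 1e6,
) -> pd.DataFrame:
    """Univariate pass followed by a joint Cox fit of qualifying covariates.

    Covariates with a univariate Wald p-value below ``entry_p`` enter the joint
    (multivariable) model.  Output contains one ``univariate`` row per offered
    covariate and one ``multivariable`` row per entered covariate, with hr,
    ci_low, ci_high and p.  Collinear covariates (condition number of the
    standardized design above ``condition_threshold``, or exact duplicates)
    raise an error naming the offending pair.
    """
    if covariates.shape[1] < 2:
        raise ValueError("offer at least 2 covariates")
    if s.event.sum() < 2:
        raise ValueError("need at least 2 events")
    if len(covariates) != len(s):
        raise ValueError("covariate rows do not match survival table")

    X = covariates.to_numpy(dtype=float)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    for i in range(Xs.shape[1]):
        for j in range(i + 1, Xs.shape[1]):
            r = abs(np.corrcoef(Xs[:, i], Xs[:, j])[0, 1])
            if r > 0.999:
                raise ValueError(
                    f"collinear covariates: {covariates.columns[i]!r} and "
                    f"{covariates.columns[j]!r} (|r| = {r:.4f})"
                )
    if np.linalg.cond(Xs) > condition_threshold:
        raise ValueError("covariate design is ill-conditioned")

    rows = []
    entered = []
    for name in covariates.columns:
        res = cox_univariate(s, covariates[name].to_numpy())
        rows.append(
            dict(covariate=name, model="univariate", hr=res.hr,
                 ci_low=res.ci_low, ci_high=res.ci_high, p=res.p)
        )
        if res.p < entry_p:
            entered.append(name)
    if entered:
        df = pd.DataFrame(
            {"time": s.time, "event": s.event, **{c: covariates[c].to_numpy()
                                                  for c in entered}}
        )
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        for name in entered:
            beta = float(cph.params_[name])
            se = float(cph.standard_errors_[name])
            rows.append(
                dict(
                    covariate=name,
                    model="multivariable",
                    hr=float(np.exp(beta)),
                    ci_low=float(np.exp(beta - 1.959963984540054 * se)),
                    ci_high=float(np.exp(beta + 1.959963984540054 * se)),
                    p=float(cph.summary.loc[name, "p"]),
                )
            )
    return pd.DataFrame(rows)
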