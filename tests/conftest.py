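import numpy as np
import pandas as pd
import pytest

from lsmsurv import (
    ExpressionMatrix,
    SurvivalTable,
    paperlike_config,
    simulate,
)

PANEL = ["LSM1", "LSM2", "LSM3", "LSM4", "LSM5", "LSM6", "LSM7", "LSM8"]


@pytest.fixture(scope="session")
def paperlike():
    """One study-like synthetic cohort (123 samples, 8-gene panel, 500 nulls)."""
    return simulate(paperlike_config(seed=7))


@pytest.fixture(scope="session")
def small_paperlike():
    """Same structure but a tiny background, for fast pipeline runs."""
    return simulate(paperlike_config(seed=11, n_background_genes=40))


@pytest.fixture
def tiny_expression():
    data = pd.DataFrame(
        [[5.0, 6.0, 7.0], [8.0, 7.5, 6.5], [3.0, 3.5, 4.0]],
        index=["G1", "G2", "G3"],
        columns=["S1", "S2", "S3"],
    )
    return ExpressionMatrix(data)


def make_survival(times, events, ids=None):
    ids = ids or [f"S{i + 1}" for i in range(len(times))]
    return SurvivalTable(
        pd.DataFrame({"time": times, "event": events}, index=pd.Index(ids))
    )


def logrank_oracle(time, event, in_group_a):
    """Textbook two-group log-rank chi-square: sum(O-E) squared over sum(V).

    Walks the distinct event times; at each, with n at risk (n_a in group A)
    and d events (d_a in A), accumulates O-E = d_a - d*n_a/n and the
    hypergeometric variance d*(n_a/n)*(1-n_a/n)*(n-d)/(n-1).  Independent of
    the implementation under test.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    a = np.asarray(in_group_a, bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n_a = (at_risk & a).sum()
        d = ((time == t) & (event == 1)).sum()
        d_a = ((time == t) & (event == 1) & a).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:  # every event time had one group at risk: statistic undefined
        return np.nan
    return o_minus_e**2 / var
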