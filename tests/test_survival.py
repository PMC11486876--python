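import numpy as np
import pandas as pd
import pytest

from lsmsurv import (
    SignatureGene,
    SimulationConfig,
    cox_univariate,
    dichotomize,
    km_estimate,
    logrank_test,
    multivariable_cox,
    screen_genes,
    simulate,
)
from conftest import logrank_oracle, make_survival


class TestDichotomize:
    def test_median_split_balanced(self):
        assert list(dichotomize([1, 2, 3, 4])) == ["low", "low", "high", "high"]

    def test_ties_at_cutoff_go_low(self):
        # median of {1,2,2,9} is 2; both 2's equal the cutoff -> low
        assert list(dichotomize([1, 2, 2, 9])) == ["low", "low", "low", "high"]

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            dichotomize([3.0, 3.0, 3.0])


class TestKMEstimate:
    def test_two_events_closed_form(self):
        km = km_estimate(make_survival([1, 2], [1, 1]))
        assert np.allclose(km.times, [0, 1, 2])
        assert np.allclose(km.survival_prob, [1.0, 0.5, 0.0])

    def test_censoring_reduces_risk_set_without_step(self):
        # n=4: event at 1 (S=3/4), censor at 2, event at 3 with 2 at risk
        # (S=3/4 * 1/2 = 0.375), one still under follow-up
        km = km_estimate(make_survival([1, 2, 3, 4], [1, 0, 1, 0]))
        s = dict(zip(km.times, km.survival_prob))
        assert s[1] == pytest.approx(0.75)
        assert s[2] == pytest.approx(0.75)  # no step at the censored time
        assert s[3] == pytest.approx(0.375)

    def test_all_censored_stays_at_one(self):
        km = km_estimate(make_survival([1, 2, 3], [0, 0, 0]))
        assert np.all(km.survival_prob == 1.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(10, size=40).round(1)
        km = km_estimate(make_survival(times, np.ones_like(times, dtype=int)))
        for t, s in zip(km.times, km.survival_prob):
            assert s == pytest.approx(np.mean(times > t))


class TestLogrank:
    def test_matches_textbook_oracle_on_toy_data(self):
        time = [1, 2, 3, 4, 5, 6]
        event = [1, 1, 0, 1, 1, 1]
        groups = np.array(["high", "low", "high", "low", "high", "low"])
        s = make_survival(time, event)
        chi2, p = logrank_test(s, groups)
        assert chi2 == pytest.approx(
            logrank_oracle(time, event, groups == "high"), abs=1e-10
        )

    def test_label_exchange_symmetry(self):
        rng = np.random.default_rng(0)
        s = make_survival(rng.exponential(5, 20), rng.integers(0, 2, 20))
        g = np.where(rng.random(20) < 0.5, "high", "low")
        if len(np.unique(g)) < 2 or s.event.sum() == 0:  # pragma: no cover
            pytest.skip("degenerate draw")
        chi2a, pa = logrank_test(s, g)
        swapped = np.where(g == "high", "low", "high")
        chi2b, pb = logrank_test(s, swapped)
        assert chi2a == pytest.approx(chi2b)
        assert pa == pytest.approx(pb)

    def test_null_calibration_under_permutation(self):
        # identical survival randomly split: p < 0.05 in about 5% of permutations
        rng = np.random.default_rng(42)
        n = 60
        s = make_survival(rng.exponential(10, n), np.ones(n, dtype=int))
        hits = 0
        n_perm = 500
        for _ in range(n_perm):
            g = np.array(["low"] * (n // 2) + ["high"] * (n // 2))
            rng.shuffle(g)
            _, p = logrank_test(s, g)
            hits += p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_perm)
        assert abs(hits / n_perm - 0.05) < 3.5 * se

    def test_single_group_and_no_events_error(self):
        s = make_survival([1, 2, 3], [1, 1, 0])
        with pytest.raises(ValueError, match="two non-empty"):
            logrank_test(s, ["high", "high", "high"])
        s0 = make_survival([1, 2, 3], [0, 0, 0])
        with pytest.raises(ValueError, match="at least one event"):
            logrank_test(s0, ["high", "low", "high"])


class TestCoxUnivariate:
    def test_negating_covariate_inverts_hr(self):
        rng = np.random.default_rng(3)
        n = 80
        x = rng.standard_normal(n)
        s = make_survival(rng.exponential(np.exp(-0.5 * x)), np.ones(n, dtype=int))
        a = cox_univariate(s, x)
        b = cox_univariate(s, -x)
        assert b.hr == pytest.approx(1 / a.hr, rel=1e-6)
        assert b.p == pytest.approx(a.p, rel=1e-6)

    def test_null_covariate_hr_near_one(self):
        cfg = SimulationConfig(
            n_samples=1000,
            signature_genes=(SignatureGene("G", 0.0, 1),),
            n_background_genes=0,
            seed=31,
        )
        d = simulate(cfg)
        res = cox_univariate(d.survival, d.expression.values[0])
        assert 0.85 <= res.hr <= 1.18

    def test_two_group_exponential_rate_ratio(self):
        # dichotomized groups with true rate ratio 2
        rng = np.random.default_rng(8)
        n = 2000
        hi = np.arange(n) < n // 2
        times = np.where(hi, rng.exponential(0.5, n), rng.exponential(1.0, n))
        s = make_survival(times, np.ones(n, dtype=int))
        res = cox_univariate(s, hi.astype(float))
        assert 1.8 <= res.hr <= 2.2
        assert res.ci_low <= res.hr <= res.ci_high

    def test_complete_separation_flagged_unbounded(self):
        s = make_survival([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0])
        res = cox_univariate(s, [1, 1, 1, 0, 0, 0])
        assert res.flagged == "separation"
        assert not np.isfinite(res.ci_high) or res.ci_low == 0.0

    def test_constant_covariate_errors(self):
        s = make_survival([1, 2, 3], [1, 1, 0])
        with pytest.raises(ValueError, match="constant"):
            cox_univariate(s, [2.0, 2.0, 2.0])


class TestScreenGenes:
    def test_missing_panel_gene_errors(self, paperlike):
        with pytest.raises(KeyError, match="NOPE"):
            screen_genes(paperlike.expression, paperlike.survival, ["LSM1", "NOPE"])

    def test_strong_genes_labeled_by_direction(self, paperlike):
        scr = screen_genes(
            paperlike.expression,
            paperlike.survival,
            ["LSM1", "LSM2", "LSM4", "LSM8"],
        ).set_index("gene")
        assert (scr.loc[["LSM1", "LSM2", "LSM4"], "label"] == "harmful").all()
        assert scr.loc["LSM8", "label"] == "favorable"
        assert (scr["ci_low"] <= scr["hr"]).all()
        assert (scr["hr"] <= scr["ci_high"]).all()

    def test_labels_invariant_to_time_rescaling(self, small_paperlike):
        d = small_paperlike
        panel = ["LSM1", "LSM4", "LSM8"]
        a = screen_genes(d.expression, d.survival, panel)
        surv2 = make_survival(
            d.survival.time * 12.0, d.survival.event, ids=d.survival.sample_ids
        )
        b = screen_genes(d.expression, surv2, panel)
        assert list(a["label"]) == list(b["label"])
        assert np.allclose(a["p_logrank"], b["p_logrank"])

    def test_override_lists_pin_inclusion(self, paperlike):
        scr = screen_genes(
            paperlike.expression,
            paperlike.survival,
            ["LSM1", "LSM2", "LSM3", "LSM4", "LSM8"],
            include_harmful=["LSM1", "LSM2", "LSM4"],
            include_favorable=["LSM8"],
        ).set_index("gene")
        assert scr["included_in_index"].sum() == 4
        assert not scr.loc["LSM3", "included_in_index"]


class TestMultivariableCox:
    def _data(self, seed=6, n=400):
        rng = np.random.default_rng(seed)
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        times = rng.exponential(np.exp(-np.log(2) * x1))
        s = make_survival(times, np.ones(n, dtype=int))
        return s, pd.DataFrame({"signal": x1, "noise": x2})

    def test_signal_enters_and_stays_significant(self):
        s, cov = self._data()
        out = multivariable_cox(s, cov)
        multi = out[out["model"] == "multivariable"].set_index("covariate")
        assert "signal" in multi.index
        assert multi.loc["signal", "p"] < 0.05
        if "noise" in multi.index:  # noise rarely passes entry at p<0.15
            assert multi.loc["noise", "p"] > 0.05

    def test_duplicated_covariate_collinearity_error(self):
        s, cov = self._data()
        cov["dup"] = cov["signal"]
        with pytest.raises(ValueError, match="collinear.*signal.*dup"):
            multivariable_cox(s, cov)

    def test_single_entrant_matches_univariate(self):
        s, cov = self._data(seed=9)
        # make the second covariate pure noise that fails entry
        out = multivariable_cox(s, cov, entry_p=1e-6)
        uni = out[out["model"] == "univariate"].set_index("covariate")
        multi = out[out["model"] == "multivariable"].set_index("covariate")
        assert list(multi.index) == ["signal"]
        assert multi.loc["signal", "hr"] == pytest.approx(
            uni.loc["signal", "hr"], rel=1e-9
        )
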