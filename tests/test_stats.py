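"""Association and outcome statistics: odds ratios, test selection, logistic
screening and stepwise selection, Kaplan-Meier/log-rank, Cox."""

import numpy as np
import pandas as pd
import pytest

from radstrat import stats as st


class TestOddsRatioWald:
    def test_balanced_table(self):
        e = st.odds_ratio_wald(10, 10, 10, 10)
        assert e.estimate == pytest.approx(1.0)
        # CI symmetric about 1 on the log scale
        assert np.log(e.ci_low) == pytest.approx(-np.log(e.ci_high))

    def test_never_smoker_example(self):
        e = st.odds_ratio_wald(25, 22, 7, 83)
        assert round(e.estimate, 2) == 13.47
        assert round(e.ci_low, 2) == 5.15
        assert round(e.ci_high, 2) == 35.22

    def test_zero_cell_flagged(self):
        e = st.odds_ratio_wald(0, 47, 21, 153)
        assert e.undefined and e.estimate == 0.0
        e = st.odds_ratio_wald(21, 153, 0, 47)
        assert e.undefined and e.estimate == np.inf

    @pytest.mark.parametrize("seed", range(10))
    def test_exposure_flip_reciprocity(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(1, 100, 4)
        e1 = st.odds_ratio_wald(a, b, c, d)
        e2 = st.odds_ratio_wald(b, a, d, c)
        assert e1.estimate == pytest.approx(1.0 / e2.estimate)
        assert e1.ci_low == pytest.approx(1.0 / e2.ci_high)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            st.odds_ratio_wald(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            st.odds_ratio_wald(0, 0, 0, 0)


class TestGroupCompare:
    def test_identical_proportions_give_zero_statistic(self):
        g = {"a": np.array([0] * 20 + [1] * 20), "b": np.array([0] * 20 + [1] * 20)}
        r = st.group_compare(g, "categorical")
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_chi2_matches_hand_oracle(self):
        # table (20,10 / 10,20) without continuity correction:
        # expected all 15, chi2 = sum (O-E)^2/E = 4 * 25/15 = 20/3
        g = {"a": np.array([0] * 20 + [1] * 10), "b": np.array([0] * 10 + [1] * 20)}
        from scipy.stats import chi2_contingency

        chi2, _, _, _ = chi2_contingency([[20, 10], [10, 20]], correction=False)
        assert chi2 == pytest.approx(20 / 3)
        r = st.group_compare(g, "categorical")
        assert r.test == "chi2"

    def test_fisher_fallback_on_sparse_table(self):
        g = {"a": np.array([0] * 9 + [1]), "b": np.array([0] * 2 + [1] * 8)}
        r = st.group_compare(g, "categorical")
        assert r.test == "fisher"

    def test_t_test_chosen_for_shifted_normals(self):
        rng = np.random.default_rng(0)
        g = {"a": rng.normal(0, 1, 50), "b": rng.normal(2, 1, 50)}
        r = st.group_compare(g, "numeric")
        assert r.test == "t"
        assert r.p_value < 1e-3

    def test_mannwhitney_for_skewed(self):
        rng = np.random.default_rng(1)
        g = {"a": np.exp(rng.normal(0, 1, 80)), "b": np.exp(rng.normal(1, 1, 80))}
        r = st.group_compare(g, "numeric")
        assert r.test == "mannwhitney"

    def test_kruskal_for_three_groups(self):
        rng = np.random.default_rng(2)
        g = {k: rng.normal(i, 1, 30) for i, k in enumerate("abc")}
        assert st.group_compare(g, "numeric").test == "kruskal"

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            st.group_compare({"a": np.ones(5)}, "numeric")


class TestUnivariableScreen:
    @pytest.mark.parametrize("seed", range(5))
    def test_binary_covariate_equals_contingency_or(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        df = pd.DataFrame({"y": rng.random(n) < 0.4, "x": rng.random(n) < 0.5})
        a = int((df.y & df.x).sum())
        b = int((~df.y & df.x).sum())
        c = int((df.y & ~df.x).sum())
        d = int((~df.y & ~df.x).sum())
        if min(a, b, c, d) == 0:
            pytest.skip("zero cell drawn")
        table_or = st.odds_ratio_wald(a, b, c, d).estimate
        logit_or = st.univariable_screen(df, "y", ["x"])[0].estimate
        assert logit_or == pytest.approx(table_or, abs=1e-6)

    def test_categorical_levels_from_contingency_counts(self):
        """Reconstructing a three-level exposure from its published per-level
        counts reproduces the published per-level odds ratios."""
        # cases (any OA) per cluster level: M1 39, M2+M5 93, M3+M4 101
        # references (WT) per level:        M1  6, M2+M5 22, M3+M4 64
        rows = []
        for lvl, cases, refs in (("M1", 39, 6), ("M2+M5", 93, 22), ("M3+M4", 101, 64)):
            rows += [{"y": True, "cluster": lvl}] * cases
            rows += [{"y": False, "cluster": lvl}] * refs
        df = pd.DataFrame(rows)
        est = st.univariable_screen(df, "y", ["cluster"], {"cluster": "M3+M4"})
        by_level = {e.level: e for e in est}
        assert round(by_level["M1"].estimate, 2) == 4.12
        assert round(by_level["M2+M5"].estimate, 2) == 2.68

    def test_type_i_error_rate(self):
        """A pure-noise candidate is flagged at p<0.05 in about 5% of seeds."""
        flagged = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            df = pd.DataFrame(
                {"y": rng.random(300) < 0.5, "x": rng.standard_normal(300)}
            )
            e = st.univariable_screen(df, "y", ["x"])[0]
            flagged += (not e.undefined) and e.p_value < 0.05
        assert 0.02 <= flagged / n_seeds <= 0.08

    def test_perfect_separation_flagged_not_crashed(self):
        df = pd.DataFrame({"y": [0] * 20 + [1] * 20, "x": list(range(40))})
        e = st.univariable_screen(df, "y", ["x"])[0]
        assert e.undefined


class TestStepwise:
    def test_single_candidate_equals_univariable(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"x": rng.standard_normal(300)})
        df["y"] = rng.random(300) < 1 / (1 + np.exp(-df["x"]))
        uni = st.univariable_screen(df, "y", ["x"])[0]
        step = st.stepwise_logistic(df, "y", ["x"])
        assert step.retained == ["x"]
        assert step.estimates[0].estimate == pytest.approx(uni.estimate, rel=1e-6)

    def test_collinear_candidate_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"x1": rng.standard_normal(200)})
        df["x2"] = 2.0 * df["x1"]
        df["y"] = rng.random(200) < 1 / (1 + np.exp(-df["x1"]))
        import logging

        with caplog.at_level(logging.WARNING):
            res = st.stepwise_logistic(df, "y", ["x1", "x2"])
        assert any("collinear" in r.message for r in caplog.records)
        assert "x2" not in res.retained

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((400, 3))
        y = rng.random(400) < 1 / (1 + np.exp(-(X[:, 0] - 0.5 * X[:, 1])))
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["y"] = y
        r1 = st.stepwise_logistic(df, "y", ["a", "b", "c"])
        r2 = st.stepwise_logistic(df, "y", ["c", "b", "a"])
        assert sorted(r1.retained) == sorted(r2.retained)
        e1 = {(e.term, e.level): e.estimate for e in r1.estimates}
        e2 = {(e.term, e.level): e.estimate for e in r2.estimates}
        for key in e1:
            assert e1[key] == pytest.approx(e2[key], rel=1e-8)

    def test_true_predictor_recovery_small(self):
        """True logit slope 1 retained, most noise dropped (small replicate of
        the larger acceptance simulation)."""
        kept_true, dropped_noise = 0, 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(2000 + seed)
            X = rng.standard_normal((500, 5))
            y = rng.random(500) < 1 / (1 + np.exp(-X[:, 0]))
            df = pd.DataFrame(X, columns=["t", "n1", "n2", "n3", "n4"])
            df["y"] = y
            res = st.stepwise_logistic(df, "y", list("t n1 n2 n3 n4".split()))
            kept_true += "t" in res.retained
            dropped_noise += sum(n not in res.retained for n in ["n1", "n2", "n3", "n4"]) >= 3
        assert kept_true >= 18
        assert dropped_noise >= 18


class TestSurvival:
    def test_no_events_survival_is_one(self):
        r = st.km_logrank(
            np.array([3.0, 5.0, 8.0, 2.0]),
            np.zeros(4),
            np.array(["a", "a", "b", "b"]),
        )
        for curve in r.curves.values():
            assert (curve["survival"] == 1.0).all()
        assert np.isnan(r.p_value)

    def test_product_limit_single_event(self):
        r = st.km_logrank(
            np.array([5.0, 6.0, 7.0, 8.0, 9.0]),
            np.array([1, 0, 0, 0, 0]),
            np.array(["g"] * 5),
        )
        s = r.curves["g"].set_index("time")["survival"]
        assert s.loc[5.0] == pytest.approx(0.8)

    def test_logrank_matches_risk_set_oracle(self):
        """Two-group fixture with hand-enumerable risk sets: the log-rank
        statistic equals sum(O-E)^2-over-variance computed explicitly."""
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 1, 1, 1, 1])
        group = np.array(["a", "b", "a", "b", "a", "b"])

        # explicit risk-set enumeration (hypergeometric variance form)
        o_minus_e = 0.0
        var = 0.0
        for t in np.unique(time[event == 1]):
            at_risk = time >= t
            n = at_risk.sum()
            n_a = (at_risk & (group == "a")).sum()
            d = ((time == t) & (event == 1)).sum()
            d_a = ((time == t) & (event == 1) & (group == "a")).sum()
            o_minus_e += d_a - d * n_a / n
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        expected = o_minus_e**2 / var
        r = st.km_logrank(time, event, group)
        assert r.statistic == pytest.approx(expected, rel=1e-10)

    def test_positive_times_required(self):
        with pytest.raises(ValueError):
            st.km_logrank(np.array([0.0, 1.0]), np.array([1, 1]), np.array(["a", "a"]))

    def test_cox_recovers_binary_log_hr(self):
        rng = np.random.default_rng(11)
        n = 1000
        x = (rng.random(n) < 0.5).astype(float)
        hazard = 0.05 * np.exp(np.log(2.0) * x)
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.uniform(20, 80, n)
        df = pd.DataFrame(
            {
                "time": np.minimum(t_event, t_cens),
                "event": (t_event <= t_cens).astype(int),
                "x": x,
            }
        )
        est = st.cox_fit(df, "time", "event", ["x"])[0]
        assert est.estimate == pytest.approx(2.0, rel=0.10)
        assert est.ci_low < 2.0 < est.ci_high

    def test_constant_covariate_flagged(self):
        df = pd.DataFrame(
            {"time": [1.0, 2, 3, 4], "event": [1, 1, 0, 1], "x": [1.0, 1, 1, 1]}
        )
        est = st.cox_fit(df, "time", "event", ["x"])[0]
        assert est.undefined


def test_estimates_frame_layout():
    ests = [st.odds_ratio_wald(10, 20, 5, 40, term="exposure")]
    frame = st.estimates_frame(ests)
    assert list(frame.columns) == [
        "term", "level", "model", "estimate", "ci_low", "ci_high", "p_value", "undefined",
    ]
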