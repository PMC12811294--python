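"""Kaplan-Meier curves, logrank tests, Cox proportional hazards, and
ANOVA with Dunnett many-to-one comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imnpheno import survival as sv
from imnpheno import synthetic as syn


def records(durations, events, start=0.0):
    return pd.DataFrame(
        {"start": start, "end": np.asarray(durations, float) + start,
         "event": list(events)}
    )


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        c = sv.kaplan_meier(records([5, 8, 11], [0, 0, 0]))
        assert len(c.times) == 0
        assert c.at(100.0) == 1.0

    def test_hand_product_limit_all_events(self):
        c = sv.kaplan_meier(records([2, 4, 6], [1, 1, 1]))
        np.testing.assert_allclose(c.times, [2, 4, 6])
        np.testing.assert_allclose(c.survival, [2 / 3, 1 / 3, 0.0])

    def test_hand_product_limit_with_censoring(self):
        c = sv.kaplan_meier(records([2, 3, 4], [1, 0, 1]))
        np.testing.assert_allclose(c.times, [2, 4])
        np.testing.assert_allclose(c.survival, [2 / 3, 0.0])
        np.testing.assert_array_equal(c.at_risk, [3, 1])

    def test_monotone_from_one(self):
        rng = np.random.default_rng(0)
        c = sv.kaplan_meier(records(rng.exponential(10, 200),
                                    rng.integers(0, 2, 200)))
        assert c.survival[0] <= 1.0
        assert (np.diff(c.survival) <= 1e-12).all()

    def test_matches_empirical_cdf_without_censoring(self):
        rng = np.random.default_rng(1)
        dur = rng.exponential(5, 150)
        c = sv.kaplan_meier(records(dur, np.ones(150, int)))
        for t in (1.0, 3.0, 8.0):
            assert c.at(t) == pytest.approx((dur > t).mean(), abs=1e-12)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            sv.kaplan_meier(records([-1.0], [1]))


class TestPairwiseLogrank:
    def test_identical_groups_give_zero_statistic(self):
        g = records([1, 2, 3, 4], [1, 1, 1, 1])
        out = sv.pairwise_logrank({"a": g, "b": g.copy()})
        assert out["statistic"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_two_group_toy(self):
        # A events at 1, 2; B events at 3, 4: O-E form computed by hand
        # over the 2x2 table at each event time gives chi2 = 4.5333...
        a = records([1, 2], [1, 1])
        b = records([3, 4], [1, 1])
        out = sv.pairwise_logrank({"A": a, "B": b})
        # hand calculation: E_A = 1/2 + 1/3 = 5/6, O_A = 2,
        # V = sum of hypergeometric variances = 1/4 + 2/9 = 17/36
        # chi2 = (2 - 5/6)^2 / (17/36)
        expect = (2 - 5 / 6) ** 2 / (17 / 36)
        assert out["statistic"].iloc[0] == pytest.approx(expect, rel=1e-6)

    def test_monotone_time_transform_invariance(self):
        rng = np.random.default_rng(2)
        a = records(rng.exponential(5, 60), np.ones(60, int))
        b = records(rng.exponential(8, 60), np.ones(60, int))
        s1 = sv.pairwise_logrank({"a": a, "b": b})["statistic"].iloc[0]
        a2, b2 = a.copy(), b.copy()
        for df in (a2, b2):
            df["end"] = np.sqrt(df["end"])  # common monotone transform
        s2 = sv.pairwise_logrank({"a": a2, "b": b2})["statistic"].iloc[0]
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_bonferroni_adjustment_and_raw_p(self):
        rng = np.random.default_rng(3)
        groups = {
            k: records(rng.exponential(5, 40), np.ones(40, int))
            for k in ("a", "b", "c")
        }
        out = sv.pairwise_logrank(groups)
        assert len(out) == 3
        assert ((out["p_adj"] >= out["p"]) | np.isclose(out["p_adj"], out["p"])).all()
        assert (out["p_adj"] <= 1.0).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sv.pairwise_logrank({"a": records([1], [1]),
                                 "b": records([], [])})

    def test_null_type_one_error_rate(self):
        """Two identical exponential arms: rejection rate at alpha=0.05
        stays within [0.035, 0.065] over repeated simulations."""
        rej = 0
        n_sims = 400
        for i in range(n_sims):
            coh = syn.CohortSpec(
                groups=[syn.GroupSpec("a", 200), syn.GroupSpec("b", 200)],
                baseline_hazard=0.05, entry_day=0.0, final_day=46.0, seed=20000 + i,
            )
            df = syn.generate_survival_cohort(coh)
            out = sv.pairwise_logrank({g: d for g, d in df.groupby("group")},
                                      adjust=None)
            if out["p"].iloc[0] < 0.05:
                rej += 1
        assert 0.035 <= rej / n_sims <= 0.065


class TestCoxPh:
    def test_identical_groups_log_hr_zero(self):
        g = records(np.arange(1.0, 41.0), np.ones(40, int))
        df = pd.concat([g.assign(x=0.0), g.assign(x=1.0)], ignore_index=True)
        fit = sv.cox_ph(df, ["x"])
        assert fit.converged
        assert fit.log_hr[0] == pytest.approx(0.0, abs=1e-6)

    def test_minimal_single_event_closed_form(self):
        """Two subjects, one event, binary covariate: the partial
        likelihood is exp(bx1)/(exp(bx1)+exp(bx2)), monotone in b, so
        the MLE diverges (complete separation) and must be flagged."""
        df = pd.DataFrame({"start": [0.0, 0.0], "end": [1.0, 2.0],
                           "event": [1, 0], "x": [1.0, 0.0]})
        fit = sv.cox_ph(df, ["x"])
        assert not fit.converged

    def test_reference_flip_negates_log_hr(self):
        coh = syn.CohortSpec(
            groups=[syn.GroupSpec("a", 200), syn.GroupSpec("b", 200, log_hr=0.5)],
            baseline_hazard=0.05, entry_day=0.0, final_day=60.0, seed=4,
        )
        df = syn.generate_survival_cohort(coh)
        fa = sv.cox_two_group(df, reference="a")
        fb = sv.cox_two_group(df, reference="b")
        assert fa.log_hr[0] == pytest.approx(-fb.log_hr[0], rel=1e-4)

    def test_agrees_with_lifelines_oracle(self):
        """Independent cross-check of the partial-likelihood fit."""
        from lifelines import CoxPHFitter

        coh = syn.CohortSpec(
            groups=[syn.GroupSpec("a", 150), syn.GroupSpec("b", 150, log_hr=0.7)],
            baseline_hazard=0.05, entry_day=0.0, final_day=60.0, seed=5,
        )
        df = syn.generate_survival_cohort(coh)
        df["x"] = (df["group"] == "b").astype(float)
        df["duration"] = df["end"] - df["start"]
        fit = sv.cox_ph(df, ["x"])
        cph = CoxPHFitter().fit(df[["duration", "event", "x"]], "duration", "event")
        assert fit.log_hr[0] == pytest.approx(cph.params_["x"], abs=0.02)

    def test_parameter_recovery_with_coverage(self):
        """True log HR 0.693: estimates within +/-0.15 on average and
        95% CI covering truth in >= 93% of replicates."""
        true = 0.693
        n_reps = 120
        est, cover = [], 0
        for i in range(n_reps):
            coh = syn.CohortSpec(
                groups=[syn.GroupSpec("ctl", 500),
                        syn.GroupSpec("mut", 500, log_hr=true)],
                baseline_hazard=0.05, entry_day=0.0, final_day=46.0, seed=40000 + i,
            )
            df = syn.generate_survival_cohort(coh)
            fit = sv.cox_two_group(df)
            est.append(fit.log_hr[0])
            if fit.ci_low[0] <= true <= fit.ci_high[0]:
                cover += 1
        assert np.mean(est) == pytest.approx(true, abs=0.15)
        assert cover / n_reps >= 0.93

    def test_ci_width_shrinks_like_inverse_sqrt_n(self):
        widths, ns = [], (125, 250, 500, 1000, 2000)
        for n in ns:
            w = []
            for rep in range(4):
                coh = syn.CohortSpec(
                    groups=[syn.GroupSpec("a", n), syn.GroupSpec("b", n, log_hr=0.5)],
                    baseline_hazard=0.05, entry_day=0.0, final_day=80.0,
                    seed=700 + 17 * n + rep,
                )
                df = syn.generate_survival_cohort(coh)
                fit = sv.cox_two_group(df)
                w.append(fit.ci_high[0] - fit.ci_low[0])
            widths.append(np.mean(w))
        slope = np.polyfit(np.log(ns), np.log(widths), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.05)

    def test_no_events_rejected(self):
        df = records([1, 2], [0, 0]).assign(x=[0.0, 1.0])
        with pytest.raises(ValueError):
            sv.cox_ph(df, ["x"])

    def test_constant_covariate_rejected(self):
        df = records([1, 2], [1, 1]).assign(x=[1.0, 1.0])
        with pytest.raises(ValueError):
            sv.cox_ph(df, ["x"])


class TestAnovaDunnett:
    def test_null_rejection_rate_bounded(self):
        rng = np.random.default_rng(6)
        rej = total = 0
        for _ in range(200):
            groups = {k: rng.normal(0, 1, 30) for k in ("ctl", "m1", "m2")}
            _, tab = sv.anova_dunnett(groups, control="ctl", seed=0)
            rej += (tab["p_adj"] < 0.05).sum()
            total += len(tab)
        assert rej / total <= 0.07

    def test_two_groups_degenerate_to_t_test(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 50), rng.normal(0.4, 1, 50)
        _, tab = sv.anova_dunnett({"ctl": a, "mut": b}, control="ctl", seed=1)
        t_p = stats.ttest_ind(b, a).pvalue
        assert tab["p_adj"].iloc[0] == pytest.approx(t_p, abs=0.005)

    def test_power_on_two_sd_shift(self):
        rng = np.random.default_rng(8)
        groups = {"ctl": rng.normal(0, 1, 100), "m1": rng.normal(2, 1, 100),
                  "m2": rng.normal(0, 1, 100)}
        f, tab = sv.anova_dunnett(groups, control="ctl", seed=2)
        assert tab.set_index("group").loc["m1", "p_adj"] < 0.001
        assert f > 10

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError):
            sv.anova_dunnett({"a": np.ones(3), "b": np.ones(3)}, control="ctl")

    def test_dataframe_input(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({
            "group": ["ctl"] * 20 + ["mut"] * 20,
            "value": np.concatenate([rng.normal(0, 1, 20), rng.normal(1, 1, 20)]),
        })
        f, tab = sv.anova_dunnett(df, control="ctl", seed=3)
        assert len(tab) == 1 and tab["group"].iloc[0] == "mut"
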