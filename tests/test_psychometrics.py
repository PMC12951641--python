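import numpy as np
import pandas as pd
import pytest

import wmcoupling as w
from wmcoupling import psychometrics as ps


def _table(rows):
    return pd.DataFrame(
        rows, columns=["participant_id", "task", "trial", "rt_s", "correct"]
    )


class TestMakeIndicators:
    def test_forty_trials_partition_into_four_blocks_of_ten(self):
        rows = [("P1", "maintenance", t, float(t), True) for t in range(1, 41)]
        ind = ps.make_indicators(_table(rows))
        # medians of 1-10, 11-20, 21-30, 31-40
        assert ind.loc["P1", "maintenance_p1"] == 5.5
        assert ind.loc["P1", "maintenance_p2"] == 15.5
        assert ind.loc["P1", "maintenance_p3"] == 25.5
        assert ind.loc["P1", "maintenance_p4"] == 35.5

    def test_median_is_robust_to_a_lapse_trial(self):
        rows = [("P1", "maintenance", t, rt, True)
                for t, rt in enumerate([1.0, 2.0, 100.0], start=1)]
        ind = ps.make_indicators(_table(rows), partitions=1)
        assert ind.loc["P1", "maintenance_p1"] == 2.0

    def test_set_size_task_yields_one_indicator_per_size(self):
        rows = []
        for size in (3, 4, 5, 6, 7):
            for t in range(3):
                rows.append(("P1", "ospan", size * 10 + t, 1.0 + size, True, size))
        tab = pd.DataFrame(
            rows,
            columns=["participant_id", "task", "trial", "rt_s", "correct", "set_size"],
        )
        ind = ps.make_indicators(tab)
        assert list(ind.columns) == [f"ospan_s{k}" for k in (3, 4, 5, 6, 7)]
        assert ind.loc["P1", "ospan_s7"] == 8.0

    def test_participant_with_too_few_trials_dropped(self):
        rows = [("P1", "maintenance", t, 1.0, True) for t in range(1, 41)]
        rows += [("P2", "maintenance", t, 1.0, True) for t in range(1, 3)]  # only 2 trials
        ind = ps.make_indicators(_table(rows))
        assert list(ind.index) == ["P1"]


class TestExclusionFilter:
    def _two_task_table(self, acc_by_pid, rt_by_pid=None):
        rows = []
        for pid, (a1, a2) in acc_by_pid.items():
            rt = (rt_by_pid or {}).get(pid, 1.0)
            for task, acc in (("maintenance", a1), ("manipulation", a2)):
                for t in range(1, 21):
                    rows.append((pid, task, t, rt, t / 20.0 <= acc))
        return _table(rows)

    def test_low_accuracy_in_both_tasks_removes_participant(self):
        tab = self._two_task_table({"P1": (0.75, 0.75), "P2": (0.95, 0.95),
                                    "P3": (0.95, 0.95), "P4": (0.9, 0.9)})
        filtered, report = ps.exclusion_filter(tab)
        assert "P1" not in set(filtered["participant_id"])
        assert report.iloc[0]["participant_id"] == "P1"

    def test_low_accuracy_in_only_one_task_is_retained(self):
        tab = self._two_task_table({"P1": (0.75, 0.95), "P2": (0.95, 0.95),
                                    "P3": (0.9, 0.9)})
        filtered, report = ps.exclusion_filter(tab)
        assert "P1" in set(filtered["participant_id"])
        assert len(report) == 0

    def test_extreme_mean_rt_removed_by_sd_rule(self):
        rng = np.random.default_rng(0)
        acc = {f"P{k:02d}": (0.95, 0.95) for k in range(30)}
        rts = {f"P{k:02d}": 1.0 + 0.01 * rng.standard_normal() for k in range(30)}
        rts["P00"] = 50.0  # far beyond 4 SD
        tab = self._two_task_table(acc, rts)
        filtered, report = ps.exclusion_filter(tab)
        assert "P00" not in set(filtered["participant_id"])
        assert "4.0 SD" in report.iloc[0]["reason"]


class TestDescribeContrast:
    def test_identical_tasks_give_zero_d_and_unit_r(self):
        rows = [("P%d" % p, task, t, 1.0 + 0.1 * p, True)
                for p in range(10) for task in ("maintenance", "manipulation")
                for t in range(1, 5)]
        res = ps.describe_contrast(_table(rows))
        assert res.cohens_d == 0.0
        assert res.pearson_r == pytest.approx(1.0)

    def test_antithetic_task_means_give_negative_unit_r(self):
        rows = []
        for p in range(10):
            rows += [(f"P{p}", "maintenance", 1, 1.0 + 0.1 * p, True)]
            rows += [(f"P{p}", "manipulation", 1, 3.0 - 0.1 * p, True)]
        res = ps.describe_contrast(_table(rows))
        assert res.pearson_r == pytest.approx(-1.0)

    def test_recovers_known_standardized_difference(self):
        """True paired effect d = 1.0, n = 64: estimate lands within +/-0.3."""
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            base = rng.standard_normal(64) * 0.5 + 2.0
            diff = 1.0 + rng.standard_normal(64)  # sd(diff)=1, mean 1 -> d=1
            rows = []
            for p in range(64):
                rows.append((f"P{p:03d}", "maintenance", 1, base[p], True))
                rows.append((f"P{p:03d}", "manipulation", 1, base[p] + diff[p], True))
            res = ps.describe_contrast(_table(rows))
            hits += abs(res.cohens_d - 1.0) <= 0.3
        assert hits >= 18


class TestFactorModel:
    def test_model_degrees_of_freedom_pin_the_identification(self, behavior_table):
        """8 indicators: two correlated factors -> df 19; one factor -> df 20."""
        ind = ps.make_indicators(behavior_table)
        f1 = tuple(f"maintenance_p{k}" for k in range(1, 5))
        f2 = tuple(f"manipulation_p{k}" for k in range(1, 5))
        fit1, fit2, diff = ps.compare_one_vs_two_factor(ind, f1, f2)
        assert fit1.df == 20
        assert fit2.df == 19
        assert diff.delta_df == 1
        assert fit1.converged and fit2.converged

    def test_two_factor_fit_recovers_generating_parameters(self, behavior_table):
        ind = ps.make_indicators(behavior_table)
        f1 = tuple(f"maintenance_p{k}" for k in range(1, 5))
        f2 = tuple(f"manipulation_p{k}" for k in range(1, 5))
        fit = ps.fit_factor_model(ind, ps.two_factor_spec(f1, f2))
        # generator loadings 0.5, inter-factor r 0.65 (n = 200)
        assert np.all(np.abs(fit.loadings.to_numpy() - 0.5) < 0.1)
        assert fit.factor_corr[0, 1] == pytest.approx(0.65, abs=0.1)

    def test_loading_recovery_at_large_n(self):
        """Mean absolute loading error < 0.1 at n = 1000 (5 replicates)."""
        errs = []
        f1 = tuple(f"maintenance_p{k}" for k in range(1, 5))
        f2 = tuple(f"manipulation_p{k}" for k in range(1, 5))
        for rep in range(5):
            tab = w.generate_behavior(
                w.BehaviorGenSpec(n_participants=1000, inter_factor_r=0.5,
                                  loadings_task1=(0.4, 0.5, 0.6, 0.7),
                                  loadings_task2=(0.7, 0.6, 0.5, 0.4), seed=50 + rep)
            )
            fit = ps.fit_factor_model(ps.make_indicators(tab), ps.two_factor_spec(f1, f2))
            truth = np.array([0.4, 0.5, 0.6, 0.7, 0.7, 0.6, 0.5, 0.4])
            errs.append(np.abs(np.abs(fit.loadings.to_numpy()) - truth).mean())
        assert np.mean(errs) < 0.1

    def test_chi_square_calibrated_under_the_true_model(self):
        """Data simulated from the two-factor model: chi2/df near 1."""
        ratios = []
        f1 = tuple(f"maintenance_p{k}" for k in range(1, 5))
        f2 = tuple(f"manipulation_p{k}" for k in range(1, 5))
        for rep in range(8):
            tab = w.generate_behavior(
                w.BehaviorGenSpec(n_participants=500, inter_factor_r=0.65, seed=200 + rep)
            )
            fit = ps.fit_factor_model(ps.make_indicators(tab), ps.two_factor_spec(f1, f2))
            ratios.append(fit.chi_square / fit.df)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.4)

    def test_one_factor_fit_matches_statsmodels_ml_efa(self):
        """A 1-factor confirmatory fit on a correlation matrix coincides with
        statsmodels' maximum-likelihood exploratory factor model."""
        from statsmodels.multivariate.factor import Factor

        tab = w.generate_behavior(
            w.BehaviorGenSpec(n_participants=500, inter_factor_r=1.0, seed=33)
        )
        ind = ps.make_indicators(tab)
        cols = list(ind.columns)
        corr = np.corrcoef(ind.to_numpy(), rowvar=False)
        fit = ps.fit_factor_model((corr, len(ind)), ps.one_factor_spec(tuple(cols)))
        sm_fit = Factor(corr=corr, n_factor=1, method="ml").fit()
        np.testing.assert_allclose(
            np.abs(fit.loadings.to_numpy()),
            np.abs(np.asarray(sm_fit.loadings).ravel()),
            atol=0.02,
        )

    def test_nonpositive_definite_covariance_rejected(self):
        f = ("a", "b", "c")
        S = np.ones((3, 3))  # rank 1, singular
        with pytest.raises(ValueError):
            ps.fit_factor_model((S, 100), ps.one_factor_spec(f))


class TestChiSqDifference:
    def _fit(self, chi2, df):
        spec = ps.one_factor_spec(("a",))
        return ps.FactorModelFit(
            spec=spec, chi_square=chi2, df=df, p_value=np.nan, discrepancy=0.0,
            loadings=pd.Series(dtype=float), uniquenesses=pd.Series(dtype=float),
            factor_corr=np.eye(1), n=100, converged=True, heywood=False,
        )

    def test_identical_fit_statistics_give_zero_difference_and_p_one(self):
        diff = ps.chisq_difference(self._fit(20.0, 20), self._fit(20.0, 19))
        assert diff.delta_chi2 == 0.0
        assert diff.delta_df == 1
        assert diff.p == 1.0

    def test_wrong_nesting_order_rejected(self):
        with pytest.raises(ValueError):
            ps.chisq_difference(self._fit(10.0, 19), self._fit(10.0, 20))

    def test_strong_two_factor_data_reject_the_one_factor_model(self, behavior_table):
        ind = ps.make_indicators(behavior_table)
        f1 = tuple(f"maintenance_p{k}" for k in range(1, 5))
        f2 = tuple(f"manipulation_p{k}" for k in range(1, 5))
        _, _, diff = ps.compare_one_vs_two_factor(ind, f1, f2)
        assert diff.p < 0.001


class TestSplits:
    def test_median_split_is_deterministic_and_exhaustive(self):
        rng = np.random.default_rng(1)
        tab = _table([
            (f"P{p}", "maintenance", t, float(rng.random()), True)
            for p in range(4) for t in range(1, 11)
        ])
        low1, high1 = ps.split_by_median(tab, "rt_s")
        low2, high2 = ps.split_by_median(tab, "rt_s")
        pd.testing.assert_frame_equal(low1, low2)
        assert len(low1) + len(high1) == len(tab)

    def test_odd_even_split_of_duplicated_rows_gives_identical_fits(self):
        tab = w.generate_behavior(w.BehaviorGenSpec(n_participants=40, seed=12))
        ind = ps.make_indicators(tab)
        doubled = pd.concat([ind, ind.rename(index=lambda s: s + "x")]).sort_index()
        f1 = tuple(f"maintenance_p{k}" for k in range(1, 5))
        f2 = tuple(f"manipulation_p{k}" for k in range(1, 5))
        res = ps.split_half_consistency(doubled, f1, f2, split_rule="odd_even")
        # each half contains exactly one copy of every participant
        a = res["half1"]["two_factor"]
        b = res["half2"]["two_factor"]
        assert a.chi_square == pytest.approx(b.chi_square, abs=1e-6)
        assert res["consistent"]

    def test_too_few_participants_to_split_rejected(self):
        tab = w.generate_behavior(w.BehaviorGenSpec(n_participants=10, seed=13))
        ind = ps.make_indicators(tab)
        f1 = tuple(f"maintenance_p{k}" for k in range(1, 5))
        f2 = tuple(f"manipulation_p{k}" for k in range(1, 5))
        with pytest.raises(ValueError):
            ps.split_half_consistency(ind, f1, f2)
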