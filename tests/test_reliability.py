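"""Variance components, Spearman-Brown projection and absolute reliability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import accelrel as ar
from accelrel.reliability import LOA_FACTOR, EstimationError
from oracles import oneway_anova_oracle


class TestOnewayComponents:
    def test_balanced_toy_closed_form(self):
        # 3 subjects x 2 days: MSW = 2, MSB = 200, n0 = 2
        values = [10, 12, 20, 22, 30, 32]
        groups = ["a", "a", "b", "b", "c", "c"]
        vc = ar.oneway_components(values, groups)
        assert vc.sigma2_residual == pytest.approx(2.0)
        assert vc.sigma2_between == pytest.approx(99.0)
        assert vc.n0 == pytest.approx(2.0)
        assert ar.icc_single(vc) == pytest.approx(0.980, abs=5e-4)

    def test_identical_observations_flag_undefined_icc(self):
        vc = ar.oneway_components([5.0] * 6, ["a", "a", "b", "b", "c", "c"])
        assert vc.sigma2_between == 0.0 and vc.sigma2_residual == 0.0
        with pytest.raises(EstimationError):
            ar.icc_single(vc)

    def test_negative_between_estimate_truncated(self):
        # group means closer than residual noise implies -> MoM estimate < 0
        values = [0.0, 10.0, 5.0, 5.0]
        vc = ar.oneway_components(values, ["a", "a", "b", "b"])
        assert vc.sigma2_between == 0.0 and vc.truncated

    def test_matches_brute_force_oracle_on_unbalanced_data(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            k = rng.integers(3, 8)
            sizes = rng.integers(1, 9, k)
            while (sizes >= 2).sum() == 0:
                sizes = rng.integers(1, 9, k)
            groups = np.repeat([f"g{i}" for i in range(k)], sizes)
            values = rng.normal(rng.normal(0, 3, k).repeat(sizes), 1.5)
            vc = ar.oneway_components(values, groups)
            s2b, s2w = oneway_anova_oracle(values, groups)
            assert vc.sigma2_between == pytest.approx(s2b, abs=1e-9)
            assert vc.sigma2_residual == pytest.approx(s2w, abs=1e-9)

    def test_requires_two_groups_and_replication(self):
        with pytest.raises(EstimationError):
            ar.oneway_components([1, 2, 3], ["a", "a", "a"])
        with pytest.raises(EstimationError):
            ar.oneway_components([1, 2, 3], ["a", "b", "c"])

    def test_reml_agrees_with_moments_on_clean_simulation(self):
        rng = np.random.default_rng(5)
        k, m = 60, 10
        groups = np.repeat(np.arange(k), m)
        values = rng.normal(0, 2, k).repeat(m) + rng.normal(0, 1, k * m)
        mom = ar.oneway_components(values, groups)
        reml = ar.oneway_components(values, groups, method="reml")
        assert reml.sigma2_between == pytest.approx(mom.sigma2_between, rel=0.05)
        assert reml.sigma2_residual == pytest.approx(mom.sigma2_residual, rel=0.05)


class TestAdjustedComponents:
    def test_recovers_generating_variances_with_covariate(self):
        rng = np.random.default_rng(23)
        reps = []
        for _ in range(10):
            k, m = 87, 21
            b = rng.normal(0, np.sqrt(40.0), k)
            wear = rng.normal(800, 90, (k, m))
            e = rng.normal(0, np.sqrt(25.0), (k, m))
            y = (0.7 * wear + b[:, None] + e).ravel()
            groups = np.repeat(np.arange(k), m)
            vc = ar.adjusted_components(y, groups, wear.ravel())
            reps.append((vc.sigma2_between, vc.sigma2_residual, vc.beta))
        s2b, s2w, beta = np.mean(reps, axis=0)
        assert s2b == pytest.approx(40.0, rel=0.10)
        assert s2w == pytest.approx(25.0, rel=0.10)
        assert beta == pytest.approx(0.7, abs=0.01)

    def test_null_covariate_slope_leaves_components_unchanged(self):
        rng = np.random.default_rng(2)
        k, m = 80, 15
        groups = np.repeat(np.arange(k), m)
        y = rng.normal(0, 2, k).repeat(m) + rng.normal(0, 1, k * m)
        x = rng.normal(700, 80, k * m)  # unrelated covariate
        crude = ar.oneway_components(y, groups)
        adj = ar.adjusted_components(y, groups, x)
        assert adj.covariate_adjusted
        assert adj.sigma2_between == pytest.approx(crude.sigma2_between, rel=0.1, abs=0.1)
        assert adj.sigma2_residual == pytest.approx(crude.sigma2_residual, rel=0.05)

    def test_constant_covariate_falls_back_to_crude(self):
        y = [1.0, 2.0, 3.0, 4.0]
        g = ["a", "a", "b", "b"]
        vc = ar.adjusted_components(y, g, [5.0] * 4)
        assert not vc.covariate_adjusted


class TestSpearmanBrown:
    @pytest.mark.parametrize(
        "icc_s, expected_days",
        [(0.29, 9.8), (0.31, 8.9), (0.50, 4.0), (0.80, 1.0)],
    )
    def test_days_needed_examples(self, icc_s, expected_days):
        assert round(ar.spearman_brown_days(icc_s, 0.80), 1) == expected_days

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(icc=st.floats(0.01, 0.99))
    def test_identity_and_closed_form_at_default_target(self, icc):
        assert ar.spearman_brown_days(icc, icc) == pytest.approx(1.0)
        assert ar.spearman_brown_days(icc, 0.80) == pytest.approx(4 * (1 - icc) / icc)

    def test_strictly_decreasing_in_single_day_reliability(self):
        grid = np.linspace(0.05, 0.95, 50)
        days = [ar.spearman_brown_days(i, 0.8) for i in grid]
        assert all(a > b for a, b in zip(days, days[1:]))

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_degenerate_reliability_rejected(self, bad):
        with pytest.raises(ValueError):
            ar.spearman_brown_days(bad, 0.8)


class TestAbsoluteReliability:
    def test_sem_is_root_residual_variance(self):
        vc = ar.VarianceComponents(1.0, 9235.21, 10, 100, 10.0)
        assert ar.sem_from_components(vc) == pytest.approx(96.1, abs=0.005)

    @pytest.mark.parametrize("sem, loa", [(96.1, 266.4), (27.7, 76.8), (0.0, 0.0)])
    def test_loa_examples(self, sem, loa):
        assert round(ar.loa_from_sem(sem), 1) == loa

    def test_loa_sem_ratio_constant(self):
        assert LOA_FACTOR == pytest.approx(2.7719, abs=5e-5)

    @pytest.mark.parametrize(
        "sem, ref, pct", [(96.1, 486.0, 19.8), (15.9, 65.9, 24.1), (0.0, 50.0, 0.0)]
    )
    def test_typical_error_pct(self, sem, ref, pct):
        assert round(ar.typical_error_pct(sem, ref), 1) == pct

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            ar.typical_error_pct(5.0, 0.0)


class TestReliabilityTable:
    def test_recovers_configured_icc_and_days_needed(self):
        cfg = ar.SimulationConfig(seed=31)
        total = 72900.0
        cfg.sigma2_between["cpm"] = 0.5 * total
        cfg.sigma2_within["cpm"] = 0.5 * total
        cfg.weekend_effect = {k: 0.0 for k in cfg.weekend_effect}
        tab, _ = ar.simulate_day_table(cfg)
        table = ar.reliability_table(tab, hour_criteria=(10,), outcomes=("cpm",))
        cell = table.iloc[0]
        assert cell.icc_s == pytest.approx(0.5, abs=0.08)
        assert 3.0 < cell.n_days_needed < 5.5

    def test_degenerate_cohort_cells_flagged(self):
        # no within-subject variation: ICC pinned at 1, days-needed undefined
        days = pd.DataFrame(
            {
                "subject_id": np.repeat(list("abcd"), 3),
                "wear_minutes": 700,
                "cpm": np.repeat([100.0, 200.0, 300.0, 400.0], 3),
            }
        )
        table = ar.reliability_table(days, hour_criteria=(10,), outcomes=("cpm",))
        assert table.iloc[0].icc_s == pytest.approx(1.0)
        assert np.isnan(table.iloc[0].n_days_needed)

    def test_stricter_hours_do_not_degrade_reliability(self, study_day_table):
        tab, _ = study_day_table
        table = ar.reliability_table(tab, hour_criteria=(8, 12), outcomes=("sed_min",))
        loose, strict = table.icc_s.to_numpy()
        assert strict >= loose - 0.02


class TestWeeklyReliabilityTable:
    def _weeks(self, values_by_subject):
        rows = []
        for sid, vals in values_by_subject.items():
            for w, v in enumerate(vals, start=1):
                rows.append({"subject_id": sid, "week_index": w, "cpm": v, "wear_minutes": 800.0 + w})
        return pd.DataFrame(rows)

    def test_constant_weekly_values_give_perfect_reliability(self):
        weeks = self._weeks({"a": [500] * 3, "b": [300] * 3, "c": [400] * 3})
        out = ar.weekly_reliability_table(weeks, outcomes=("cpm",))
        row = out.iloc[0]
        assert row["icc_s"] == pytest.approx(1.0)
        assert row["sem"] == 0.0 and row["loa"] == 0.0

    def test_requires_repeated_weeks(self):
        weeks = self._weeks({"a": [500], "b": [300], "c": [400]})
        with pytest.raises(EstimationError):
            ar.weekly_reliability_table(weeks, outcomes=("cpm",))

    def test_adjustment_shrinks_sed_error_not_percent(self, study_day_table):
        tab, _ = study_day_table
        weeks, _ = ar.summarize_weeks(tab, ar.WearCriteria(10, 4))
        crude = ar.weekly_reliability_table(weeks, adjust=False).set_index("outcome")
        adj = ar.weekly_reliability_table(weeks, adjust=True).set_index("outcome")
        assert adj.loc["sed_min", "sem"] < crude.loc["sed_min", "sem"]
        assert adj.loc["sed_pct", "sem"] == pytest.approx(crude.loc["sed_pct", "sem"], rel=0.05)

    def test_median_reference_switch(self):
        weeks = self._weeks({"a": [510, 490, 500], "b": [300, 310, 290], "c": [400, 410, 390]})
        mean_ref = ar.weekly_reliability_table(weeks, outcomes=("cpm",), reference="mean")
        med_ref = ar.weekly_reliability_table(weeks, outcomes=("cpm",), reference="median")
        assert mean_ref.iloc[0].reference_level == pytest.approx(weeks.cpm.mean())
        assert med_ref.iloc[0].reference_level == pytest.approx(weeks.cpm.median())
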