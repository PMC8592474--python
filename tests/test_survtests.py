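"""Tests for risk tables and the two-sample survival tests."""

import math

import numpy as np
import pytest

import switchweight as sw
from conftest import simulate_one


@pytest.fixture
def medium_trial(small_scenario) -> sw.TrialData:
    return simulate_one(small_scenario)


class TestRiskTable:
    def test_hand_enumerated_counts(self, four_patient_sample):
        table = sw.build_risk_table(four_patient_sample)
        np.testing.assert_array_equal(table.time, [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(table.n0, [2, 1, 1])
        np.testing.assert_array_equal(table.n1, [2, 2, 1])
        np.testing.assert_array_equal(table.d0, [1, 0, 1])
        np.testing.assert_array_equal(table.d1, [0, 1, 0])

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="event"):
            sw.SurvivalSample(
                time=np.array([1.0, 2.0]),
                event=np.array([False, False]),
                arm=np.array([0, 1]),
            )

    def test_single_event(self):
        sample = sw.SurvivalSample(
            time=np.array([3.0, 5.0]),
            event=np.array([True, False]),
            arm=np.array([0, 1]),
        )
        table = sw.build_risk_table(sample)
        assert len(table) == 1
        assert table.n[0] == 2 and table.d0[0] == 1

    def test_censored_tie_stays_at_risk(self):
        # censored exactly at the event time counts at risk there
        sample = sw.SurvivalSample(
            time=np.array([2.0, 2.0, 3.0]),
            event=np.array([True, False, True]),
            arm=np.array([0, 1, 1]),
        )
        table = sw.build_risk_table(sample)
        assert table.n1[0] == 2

    def test_counts_are_internally_consistent(self, medium_trial):
        table = sw.build_risk_table(medium_trial.sample)
        assert np.all(np.diff(table.time) > 0)
        assert np.all(np.diff(table.n) <= 0)
        assert np.all((table.d >= 1) & (table.d <= table.n))
        assert np.all(table.d0 <= table.n0) and np.all(table.d1 <= table.n1)
        assert table.d.sum() == medium_trial.n_events


class TestLogrank:
    def test_hand_computed_fixture(self, four_patient_sample):
        result = sw.logrank(sw.build_risk_table(four_patient_sample))
        assert result.u == pytest.approx(2 / 3, rel=1e-12)
        assert result.v == pytest.approx(0.25 + 2 / 9 + 0.25, rel=1e-12)
        assert result.z == pytest.approx(0.78446, abs=1e-5)

    def test_arm_exchange_negates_statistic(self, medium_trial):
        table = sw.build_risk_table(medium_trial.sample)
        swapped = sw.SurvivalSample(
            time=medium_trial.time, event=medium_trial.event,
            arm=1 - medium_trial.arm,
        )
        direct = sw.logrank(table)
        mirrored = sw.logrank(sw.build_risk_table(swapped))
        assert mirrored.u == pytest.approx(-direct.u, rel=1e-10)
        assert mirrored.z == pytest.approx(-direct.z, rel=1e-10)

    def test_matches_lifelines(self, medium_trial):
        from lifelines.statistics import logrank_test

        table = sw.build_risk_table(medium_trial.sample)
        mine = sw.logrank(table)
        m0 = medium_trial.arm == 0
        m1 = medium_trial.arm == 1
        reference = logrank_test(
            medium_trial.time[m0], medium_trial.time[m1],
            medium_trial.event[m0], medium_trial.event[m1],
        )
        assert mine.z ** 2 == pytest.approx(reference.test_statistic, rel=1e-10)


class TestWeightedLogrank:
    def test_unit_weights_reduce_to_logrank(self, four_patient_sample):
        table = sw.build_risk_table(four_patient_sample)
        plain = sw.logrank(table)
        weighted = sw.weighted_logrank(table, np.ones(len(table)))
        assert weighted.u == plain.u and weighted.v == plain.v

    def test_constant_weights_leave_z_unchanged(self, medium_trial):
        table = sw.build_risk_table(medium_trial.sample)
        plain = sw.logrank(table)
        scaled = sw.weighted_logrank(table, np.full(len(table), 3.7))
        assert scaled.z == pytest.approx(plain.z, rel=1e-12)

    def test_hand_weights_match_direct_summation(self, four_patient_sample):
        table = sw.build_risk_table(four_patient_sample)
        weights = np.array([2.0, 1.0, 0.5])
        result = sw.weighted_logrank(table, weights)
        u = v = 0.0  # independent per-row accumulation
        for j in range(len(table)):
            n0, n1 = table.n0[j], table.n1[j]
            d0, d = table.d0[j], table.d[j]
            n = n0 + n1
            u += weights[j] * (d0 - d * n0 / n)
            if n > 1:
                v += weights[j] ** 2 * n0 * n1 * d * (n - d) / (n ** 2 * (n - 1))
        assert result.u == pytest.approx(u, rel=1e-12)
        assert result.v == pytest.approx(v, rel=1e-12)

    @pytest.mark.parametrize(
        "weights", [[-1.0, 1.0, 1.0], [0.0, 0.0, 0.0], [1.0, 1.0]]
    )
    def test_invalid_weights_rejected(self, four_patient_sample, weights):
        table = sw.build_risk_table(four_patient_sample)
        with pytest.raises(ValueError):
            sw.weighted_logrank(table, np.array(weights))


class TestFlemingHarrington:
    def test_rho_gamma_zero_is_unweighted(self, medium_trial):
        table = sw.build_risk_table(medium_trial.sample)
        np.testing.assert_array_equal(sw.fh_weights(table, 0, 0), 1.0)

    def test_left_limit_at_first_event(self, four_patient_sample):
        table = sw.build_risk_table(four_patient_sample)
        assert sw.fh_weights(table, 1, 0)[0] == 1.0

    def test_hand_computed_pooled_km_left_limits(self, four_patient_sample):
        table = sw.build_risk_table(four_patient_sample)
        # pooled KM: S(1)=3/4, S(2)=1/2 -> left limits (1, 3/4, 1/2)
        np.testing.assert_allclose(
            sw.fh_weights(table, 1, 1), [0.0, 0.1875, 0.25], rtol=1e-12
        )

    def test_matches_lifelines_fleming_harrington(self, medium_trial):
        from lifelines.statistics import logrank_test

        table = sw.build_risk_table(medium_trial.sample)
        mine = sw.weighted_logrank(table, sw.fh_weights(table, 1, 1))
        m0 = medium_trial.arm == 0
        m1 = medium_trial.arm == 1
        reference = logrank_test(
            medium_trial.time[m0], medium_trial.time[m1],
            medium_trial.event[m0], medium_trial.event[m1],
            weightings="fleming-harrington", p=1, q=1,
        )
        assert mine.z ** 2 == pytest.approx(reference.test_statistic, rel=1e-9)


class TestMWLR:
    def test_no_assumed_switching_equals_logrank(self, medium_trial):
        rates = sw.rates_from_medians(sw.ClinicalMedians(10, 15, 2, p=0.0))
        table = sw.build_risk_table(medium_trial.sample)
        assert sw.mwlr(medium_trial.sample, rates).z == sw.logrank(table).z

    def test_full_switching_weights_strictly_decrease(self, medium_trial):
        rates = sw.rates_from_medians(sw.ClinicalMedians(10, 15, 2, p=1.0))
        table = sw.build_risk_table(medium_trial.sample)
        weights = sw.weight_at(rates, table.time)
        assert np.all(np.diff(weights) < 0)
        result = sw.mwlr(medium_trial.sample, rates)
        assert result.params["p_prime"] == 1.0
        assert 0.0 < result.p_one_sided < 1.0


class TestMaxCombo:
    def test_correlation_matrix_properties(self, medium_trial):
        result = sw.maxcombo(medium_trial.sample)
        corr = result.params["correlation"]
        np.testing.assert_allclose(np.diag(corr), 1.0, rtol=1e-12)
        np.testing.assert_allclose(corr, corr.T, rtol=1e-12)
        off_diagonal = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert np.all((off_diagonal > 0) & (off_diagonal <= 1))

    def test_p_value_pays_multiplicity_penalty(self, medium_trial):
        from scipy import stats

        result = sw.maxcombo(medium_trial.sample)
        assert result.z == max(result.params["component_z"])
        assert result.p_one_sided >= stats.norm.sf(result.z) - 1e-6
        assert 0.0 < result.p_one_sided < 1.0

    def test_deterministic(self, medium_trial):
        a = sw.maxcombo(medium_trial.sample)
        b = sw.maxcombo(medium_trial.sample)
        assert a.p_one_sided == b.p_one_sided


class TestRMST:
    def test_uncensored_rmst_is_truncated_mean(self):
        rng = np.random.default_rng(4)
        time = np.concatenate([rng.exponential(10, 30), rng.exponential(15, 30)])
        sample = sw.SurvivalSample(
            time=time,
            event=np.ones(60, dtype=bool),
            arm=np.repeat([0, 1], 30),
        )
        result = sw.rmst_test(sample, truncation="minimax")
        tau = result.params["truncation"]
        assert result.params["rmst0"] == pytest.approx(
            np.minimum(time[:30], tau).mean(), rel=1e-10
        )
        assert result.params["rmst1"] == pytest.approx(
            np.minimum(time[30:], tau).mean(), rel=1e-10
        )

    def test_identical_arms_give_zero(self):
        sample = sw.SurvivalSample(
            time=np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0]),
            event=np.ones(6, dtype=bool),
            arm=np.repeat([0, 1], 3),
        )
        result = sw.rmst_test(sample)
        assert result.u == 0.0 and result.z == 0.0

    def test_hand_integrated_fixture(self, four_patient_sample):
        # tau = minimax = 3; control KM steps 1->0.5->0, experimental 1->0.5
        result = sw.rmst_test(four_patient_sample)
        assert result.params["truncation"] == 3.0
        assert result.params["rmst0"] == pytest.approx(2.0)
        assert result.params["rmst1"] == pytest.approx(2.5)
        assert result.v == pytest.approx(0.625)
        assert result.z == pytest.approx(0.5 / math.sqrt(0.625), rel=1e-12)

    def test_truncation_beyond_minimax_rejected(self, four_patient_sample):
        with pytest.raises(ValueError, match="minimax"):
            sw.rmst_test(four_patient_sample, truncation=3.5)

    def test_matches_r_survival_package(self):
        """Frozen oracle: survival::survfit, summary(..., rmean=tau) on this
        exact simulated trial (seed 5, replicate 0) gives rmean 14.90048 /
        13.71286 and se(rmean) 1.639214 / 1.294036 per arm."""
        config = sw.ScenarioConfig(
            medians=sw.ClinicalMedians(10.0, 15.0, 2.0, p=1.0),
            n0=40, n1=60, target_deaths=70, n_sims=1, seed=5,
        )
        trial = simulate_one(config)
        result = sw.rmst_test(trial.sample)
        assert result.params["rmst0"] == pytest.approx(14.900481, abs=1e-5)
        assert result.params["rmst1"] == pytest.approx(13.712865, abs=1e-5)
        assert result.v == pytest.approx(2.687022 + 1.674529, abs=1e-4)


class TestIO:
    def test_roundtrip(self, tmp_path, four_patient_sample):
        path = tmp_path / "sample.csv"
        sw.write_survival(four_patient_sample, path)
        recovered = sw.read_survival(path)
        np.testing.assert_array_equal(recovered.time, four_patient_sample.time)
        np.testing.assert_array_equal(recovered.event, four_patient_sample.event)
        np.testing.assert_array_equal(recovered.arm, four_patient_sample.arm)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time,arm\n1.0,0\n2.0,1\n")
        with pytest.raises(ValueError, match="missing"):
            sw.read_survival(path)
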