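"""Summary construction and the statistical battery, with formula oracles."""
import math

import numpy as np
import pandas as pd
import pytest

from optiongen import (
    GeneratorConfig,
    compare_correlations,
    correlate,
    paired_compare,
    partial_correlate,
    simulate_cohort,
    summarize,
    tradeoff_mixed_model,
)
from optiongen.analysis import motivation_glm
from optiongen.pipeline import path_level_table, score_cohort


def toy_metrics(uniq=(1.0, 2.0, 3.0), valid=(True, True, True)):
    return pd.DataFrame(
        {
            "participant_id": ["a"] * len(uniq),
            "session_index": [1] * len(uniq),
            "task_kind": ["option_generation"] * len(uniq),
            "path_id": [f"p{i}" for i in range(len(uniq))],
            "valid": list(valid),
            "duration_s": [2.0] * len(uniq),
            "uniqueness": list(uniq),
        }
    )


class TestSummarize:
    def test_mean_uniqueness_of_three_paths(self, small_cohort):
        metrics = score_cohort(small_cohort)
        out = summarize(small_cohort, metrics)
        assert len(out) == len(small_cohort.sessions)
        # brute-force recount for every session
        for row in out.itertuples(index=False):
            sub = metrics[
                (metrics.participant_id == row.participant_id)
                & (metrics.session_index == row.session_index)
                & metrics.valid
            ]
            assert row.fluency == len(sub)
            assert row.mean_uniqueness == pytest.approx(sub.uniqueness.mean())

    def test_simple_mean(self):
        from optiongen.model import Cohort, Session
        from conftest import make_trajectory

        sess = Session(
            "a", 1, "baseline", "option_generation",
            [make_trajectory(f"p{i}", seed=i) for i in range(3)],
        )
        cohort = Cohort(sessions=[sess])
        out = summarize(cohort, toy_metrics())
        assert out.loc[0, "fluency"] == 3
        assert out.loc[0, "mean_uniqueness"] == pytest.approx(2.0)

    def test_zero_valid_paths_flagged(self):
        from optiongen.model import Cohort, Session
        from conftest import make_trajectory

        sess = Session(
            "a", 1, "baseline", "option_generation",
            [make_trajectory(f"p{i}", seed=i) for i in range(3)],
        )
        cohort = Cohort(sessions=[sess])
        out = summarize(cohort, toy_metrics(valid=(False, False, False)))
        assert out.loc[0, "fluency"] == 0
        assert math.isnan(out.loc[0, "mean_uniqueness"])

    def test_missing_metrics_named(self, small_cohort):
        metrics = score_cohort(small_cohort)
        truncated = metrics.iloc[5:]
        with pytest.raises(ValueError, match="missing or incomplete"):
            summarize(small_cohort, truncated)


class TestCorrelate:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = correlate(x, 2 * x + 1)
        assert res.estimate == pytest.approx(1.0)

    def test_null_behaviour(self, rng):
        x = rng.normal(size=4000)
        y = rng.normal(size=4000)
        res = correlate(x, y)
        assert abs(res.estimate) < 0.05

    def test_textbook_formula_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        res = correlate(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        expected = float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
        assert res.estimate == pytest.approx(expected, rel=1e-12)
        assert 0 <= res.pvalue <= 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_spearman_is_rank_pearson(self, rng):
        x = rng.normal(size=30)
        y = x**3 + rng.normal(size=30) * 0.1
        from scipy.stats import rankdata

        res = correlate(x, y, method="spearman")
        expected = correlate(rankdata(x), rankdata(y)).estimate
        assert res.estimate == pytest.approx(expected, rel=1e-10)


class TestPartialCorrelate:
    def test_no_controls_reduces_to_plain(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        assert partial_correlate(x, y).estimate == pytest.approx(
            correlate(x, y).estimate
        )

    def test_control_equal_to_y_kills_correlation(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40) * 0.2
        res = partial_correlate(x, y, controls=y)
        assert abs(res.estimate) < 1e-8

    def test_uncorrelated_control_changes_little(self, rng):
        x = rng.normal(size=500)
        y = x + rng.normal(size=500)
        z = rng.normal(size=500)
        plain = correlate(x, y).estimate
        partial = partial_correlate(x, y, controls=z).estimate
        assert partial == pytest.approx(plain, abs=0.02)

    def test_recursive_formula_oracle(self, rng):
        x = rng.normal(size=60)
        z = rng.normal(size=60)
        y = 0.5 * x + 0.8 * z + rng.normal(size=60)
        r_xy = correlate(x, y).estimate
        r_xz = correlate(x, z).estimate
        r_yz = correlate(y, z).estimate
        expected = (r_xy - r_xz * r_yz) / math.sqrt(
            (1 - r_xz**2) * (1 - r_yz**2)
        )
        res = partial_correlate(x, y, controls=z)
        assert res.estimate == pytest.approx(expected, rel=1e-9)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(size=50)
        z = rng.normal(size=(50, 2))
        y = x + z @ [0.5, -0.7] + rng.normal(size=50)
        res = partial_correlate(x, y, controls=z)
        df = pd.DataFrame({"x": x, "y": y, "c1": z[:, 0], "c2": z[:, 1]})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert res.estimate == pytest.approx(float(ref["r"].iloc[0]), rel=1e-9)
        assert res.pvalue == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_collinear_controls_rejected(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        z = rng.normal(size=30)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlate(x, y, controls=np.column_stack([z, 2 * z]))


class TestCompareCorrelations:
    def test_equal_correlations_give_zero(self):
        res = compare_correlations(0.5, 0.5, 0.3, n=50)
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_antisymmetry(self):
        a = compare_correlations(0.6, 0.2, 0.3, n=80)
        b = compare_correlations(0.2, 0.6, 0.3, n=80)
        assert a.statistic == pytest.approx(-b.statistic)

    def test_hand_computed_formula(self):
        r_ab, r_ac, r_bc, n = 0.56, -0.38, -0.62, 96
        z1, z2 = math.atanh(r_ab), math.atanh(r_ac)
        rbar2 = (r_ab**2 + r_ac**2) / 2
        f = min(1.0, (1 - r_bc) / (2 * (1 - rbar2)))
        h = (1 - f * rbar2) / (1 - rbar2)
        expected = (z1 - z2) * math.sqrt((n - 3) / (2 * (1 - r_bc) * h))
        res = compare_correlations(r_ab, r_ac, r_bc, n=n)
        assert res.statistic == pytest.approx(expected, rel=1e-12)

    def test_naive_variant(self):
        res = compare_correlations(0.6, 0.2, 0.0, n=50, dependent=False)
        expected = (math.atanh(0.6) - math.atanh(0.2)) / math.sqrt(2 / 47)
        assert res.statistic == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compare_correlations(1.0, 0.5, 0.2, n=30)
        with pytest.raises(ValueError):
            compare_correlations(0.5, 0.5, 0.2, n=3)


class TestPairedCompare:
    @staticmethod
    def crossover_summaries(seed=3, n_agents=12):
        cohort = simulate_cohort(
            GeneratorConfig(n_agents=n_agents, master_seed=seed), "ON_OFF_crossover"
        )
        metrics = score_cohort(cohort)
        return summarize(cohort, metrics)

    def test_identical_conditions_flag_zero_variance(self):
        s = pd.DataFrame(
            {
                "participant_id": list("abcd") * 2,
                "condition": ["ON"] * 4 + ["OFF"] * 4,
                "fluency": [10, 12, 14, 16] * 2,
            }
        )
        res = paired_compare(s, "fluency", "ON", "OFF", transform="never")
        assert res.extra["zero_variance"]
        assert res.estimate == 0.0
        assert math.isnan(res.statistic)

    def test_generator_shift_sign_recovered(self):
        s = self.crossover_summaries()
        res = paired_compare(s, "fluency", "ON", "OFF", transform="never")
        assert res.estimate > 0 and res.statistic > 0
        res_u = paired_compare(s, "mean_uniqueness", "ON", "OFF", transform="never")
        assert res_u.estimate < 0

    def test_unmatched_participants_listed(self):
        s = pd.DataFrame(
            {
                "participant_id": ["a", "b", "a"],
                "condition": ["ON", "ON", "OFF"],
                "fluency": [10.0, 11.0, 9.0],
            }
        )
        with pytest.raises(ValueError, match="b"):
            paired_compare(s, "fluency", "ON", "OFF")

    def test_row_order_invariance(self):
        s = self.crossover_summaries(seed=5, n_agents=10)
        res1 = paired_compare(s, "fluency", "ON", "OFF", transform="never")
        res2 = paired_compare(
            s.sample(frac=1.0, random_state=0), "fluency", "ON", "OFF",
            transform="never",
        )
        assert res1.statistic == pytest.approx(res2.statistic, rel=1e-12)


class TestMixedModel:
    @staticmethod
    def crossover_table(seed=3, n_agents=12, effects=None):
        cfg = GeneratorConfig(
            n_agents=n_agents, master_seed=seed, condition_effects=effects
        )
        cohort = simulate_cohort(cfg, "ON_OFF_crossover")
        metrics = score_cohort(cohort)
        return path_level_table(cohort, metrics)

    def test_null_condition_effect_near_zero(self):
        from optiongen.simulate import ConditionEffect

        table = self.crossover_table(seed=11, effects={"ON": ConditionEffect()})
        res = tradeoff_mixed_model(table, condition_ref="OFF")
        ci = 2.5 * res.extra["bse"][res.extra["condition_term"]]
        assert abs(res.estimate) < ci

    def test_positive_boost_recovered(self):
        res = tradeoff_mixed_model(self.crossover_table(seed=3), condition_ref="OFF")
        assert res.estimate > 0
        assert res.pvalue < 0.05

    def test_duplicating_rows_keeps_estimates_shrinks_se(self):
        table = self.crossover_table(seed=7, n_agents=10)
        res1 = tradeoff_mixed_model(table, condition_ref="OFF")
        res2 = tradeoff_mixed_model(
            pd.concat([table, table], ignore_index=True), condition_ref="OFF"
        )
        term = res1.extra["condition_term"]
        assert res2.extra["fe_params"][term] == pytest.approx(
            res1.extra["fe_params"][term], rel=0.1
        )
        assert res2.extra["bse"][term] < res1.extra["bse"][term]

    def test_requires_two_conditions_and_enough_participants(self):
        table = self.crossover_table(seed=3)
        with pytest.raises(ValueError, match="2 conditions"):
            tradeoff_mixed_model(table[table.condition == "ON"])
        small = table[table.participant_id.isin(table.participant_id.unique()[:4])]
        with pytest.raises(ValueError, match="10 participants"):
            tradeoff_mixed_model(small)


def test_motivation_glm_smoke():
    cohort = simulate_cohort(
        GeneratorConfig(n_agents=20, master_seed=9), "single_session"
    )
    metrics = score_cohort(cohort)
    s = summarize(cohort, metrics)
    res = motivation_glm(s)
    assert res.extra["n_obs"] == 20
    assert 0 <= res.pvalue <= 1
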