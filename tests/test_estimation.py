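"""Weighted coverage, cluster bootstrap, pooling, summaries."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_women
from delivcare import (
    bootstrap_ci,
    country_summary,
    pooled_estimate,
    score_distribution,
    score_table,
    weighted_coverage,
)
from delivcare.estimation import estimate_with_ci, indicator_values, pooled_weights


def scored(rows, **kw):
    return score_table(make_women(rows, **kw))


FULL = ("hospital", "yes", "yes", "yes")
NONE = ("home", "no", "no", "no")


class TestWeightedCoverage:
    def test_equal_weights_average_rescaled_scores(self):
        df = scored([FULL, NONE])
        assert weighted_coverage(df, "delivery_care").point == pytest.approx(50.0)

    def test_unequal_weights_hand_arithmetic(self):
        df = scored([FULL, NONE])
        df.loc[0, "weight"] = 3.0
        # binary facility indicator: (3*1 + 1*0) / 4 = 75%
        assert weighted_coverage(df, "facility").point == pytest.approx(75.0)

    def test_full_coverage_is_100_regardless_of_weights(self):
        df = scored([FULL] * 4)
        df["weight"] = [0.1, 5.0, 2.3, 9.9]
        assert weighted_coverage(df, "delivery_care").point == pytest.approx(100.0)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError, match="empty"):
            weighted_coverage(scored([FULL]).iloc[:0], "facility")

    def test_zero_weight_sum_raises(self):
        df = scored([FULL])
        df["weight"] = 0.0
        with pytest.raises(ValueError, match="zero"):
            weighted_coverage(df, "facility")

    def test_unknown_indicator_raises(self):
        with pytest.raises(KeyError):
            weighted_coverage(scored([FULL]), "nonexistent")


class TestBootstrap:
    def test_degenerate_population_gives_zero_width_interval(self):
        df = scored([FULL] * 16)
        lo, hi = bootstrap_ci(df, "delivery_care", b=50, seed=0)
        assert lo == hi == pytest.approx(100.0)

    def test_same_seed_gives_identical_interval(self):
        df = scored([FULL, NONE] * 10)
        assert bootstrap_ci(df, "facility", b=100, seed=9) == bootstrap_ci(
            df, "facility", b=100, seed=9)

    def test_too_few_replicates_raises(self):
        with pytest.raises(ValueError, match="replicates"):
            bootstrap_ci(scored([FULL] * 4), "facility", b=1)

    def test_single_psu_stratum_raises(self):
        df = scored([FULL] * 4)
        df["psu"] = "P0"
        with pytest.raises(ValueError, match="single PSU"):
            bootstrap_ci(df, "facility", b=10, seed=0)

    def test_interval_brackets_the_point_estimate(self):
        df = scored([FULL, NONE, FULL, NONE, FULL] * 8)
        est = estimate_with_ci(df, "delivery_care", b=200, seed=4)
        assert est.ci_low <= est.point <= est.ci_high


class TestPooling:
    def two_countries(self, n_a=10, n_b=10):
        # country A: 40% care coverage (score 2), country B: 80% (score 4)
        a = scored([("home", "yes", "no", "yes")] * n_a, country_id="A")
        b = scored([("lower", "yes", "yes", "yes")] * n_b, country_id="B")
        return pd.concat([a, b], ignore_index=True)

    def test_pooled_is_mean_of_country_estimates(self):
        df = self.two_countries()
        assert pooled_estimate(df, "delivery_care").point == pytest.approx(60.0)

    def test_pooled_is_invariant_to_country_sample_size(self):
        df = self.two_countries(n_a=10, n_b=1000)
        assert pooled_estimate(df, "delivery_care").point == pytest.approx(60.0)

    def test_one_country_pools_to_its_own_estimate(self):
        df = scored([FULL, NONE], country_id="A")
        assert pooled_estimate(df, "delivery_care").point == pytest.approx(
            weighted_coverage(df, "delivery_care").point)

    def test_pooled_weights_sum_equally_per_country(self):
        df = self.two_countries(n_a=7, n_b=29)
        w = pooled_weights(df)
        sums = pd.Series(w).groupby(df["country_id"]).sum()
        assert np.allclose(sums, len(df))


class TestSummaries:
    def test_median_and_quartiles_linear_interpolation(self):
        med, q1, q3 = country_summary([10.0, 20.0, 30.0])
        assert (med, q1, q3) == (20.0, 15.0, 25.0)

    def test_single_estimate(self):
        assert country_summary([42.0]) == (42.0, 42.0, 42.0)

    def test_all_equal_has_zero_iqr(self):
        med, q1, q3 = country_summary([5.0] * 9)
        assert q1 == med == q3 == 5.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            country_summary([])


class TestScoreDistribution:
    def test_all_top_scores(self):
        dist = score_distribution(scored([FULL] * 3))
        assert dist.tolist() == [0, 0, 0, 0, 0, 1]

    def test_equal_weights_split(self):
        dist = score_distribution(scored([FULL, NONE]))
        assert dist.tolist() == [0.5, 0, 0, 0, 0, 0.5]

    def test_sums_to_one_on_study_data(self, study_scored):
        _, table, _ = study_scored
        assert score_distribution(table).sum() == pytest.approx(1.0, abs=1e-9)


def test_linearity_identity_between_score_and_components(study_scored):
    """Weighted mean rescaled score equals the score-weighted combination
    of component coverages, for arbitrary positive weights."""
    _, table, _ = study_scored
    rng = np.random.default_rng(1)
    table = table.copy()
    table["weight"] = rng.uniform(0.2, 5.0, len(table))
    care = weighted_coverage(table, "delivery_care").point
    parts = {ind: weighted_coverage(table, ind).point
             for ind in ("hospital", "lower", "sba", "stay24", "pnc48")}
    combo = (2 * parts["hospital"] + parts["lower"] + parts["sba"]
             + parts["stay24"] + parts["pnc48"]) / 5
    assert care == pytest.approx(combo, abs=1e-9)


def test_indicator_values_treat_missing_as_not_covered():
    df = scored([("missing", "missing", "missing", "missing")])
    for ind in ("facility", "sba", "stay24", "pnc48", "delivery_care"):
        assert indicator_values(df, ind)[0] == 0.0
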