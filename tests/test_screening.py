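"""Screening update: Monte-Carlo sampling, binning, LR and table arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from iaqscreen.core import SURROGATES
from iaqscreen.screening import (
    DEFAULT_BINS,
    DEFAULT_LR1,
    GroupDistributions,
    IndexBin,
    SamplingRanges,
    assign_bins,
    bin_percentages,
    display_round,
    empirical_likelihood_ratio_table,
    fit_index_distributions,
    likelihood_ratio,
    likelihood_ratio_table,
    model_average_predict,
    monte_carlo_sample,
    post_test_probability,
    relative_impact,
    update_screening_table,
)


class TestMonteCarloSample:
    def test_within_bounds_and_deterministic(self):
        ranges = SamplingRanges(n_samples=5000, seed=11)
        a = monte_carlo_sample(ranges)
        b = monte_carlo_sample(ranges)
        pd.testing.assert_frame_equal(a, b)
        for s in SURROGATES:
            lo, hi = getattr(ranges, s)
            assert a[s].between(lo, hi).all()

    def test_means_near_interval_midpoints(self):
        ranges = SamplingRanges(n_samples=100_000, seed=3)
        sample = monte_carlo_sample(ranges)
        for s in SURROGATES:
            lo, hi = getattr(ranges, s)
            mid = (lo + hi) / 2
            assert sample[s].mean() == pytest.approx(mid, abs=0.01 * (hi - lo))


class TestModelAveragePredict:
    class _Const:
        def __init__(self, value):
            self.value = value

        def predict(self, X):
            return np.full(len(X), self.value)

    class _IdScaler:
        n_features_in_ = 3

        def transform(self, X):
            return X

    def _triples(self, n=10):
        return monte_carlo_sample(SamplingRanges(n_samples=n, seed=0))

    def test_single_model_fraction_binary(self):
        fractions, labels = model_average_predict(
            [(self._Const(1), self._IdScaler())], self._triples()
        )
        assert set(fractions) <= {0.0, 1.0}
        assert labels.all()

    def test_tie_resolves_to_unsatisfactory(self):
        models = [(self._Const(1), self._IdScaler()), (self._Const(0), self._IdScaler())]
        fractions, labels = model_average_predict(models, self._triples())
        assert (fractions == 0.5).all()
        assert not labels.any()

    def test_fractions_bounded(self):
        models = [(self._Const(v), self._IdScaler()) for v in (1, 1, 0)]
        fractions, _ = model_average_predict(models, self._triples())
        assert ((fractions >= 0) & (fractions <= 1)).all()


class TestBins:
    def test_default_bins_partition_axis(self):
        theta = np.linspace(0, 2.5, 1001)
        idx = assign_bins(theta)
        assert (idx >= 0).all()
        # edges reproduce the printed 2-decimal labels
        assert assign_bins([0.3149])[0] == 0
        assert assign_bins([0.315])[0] == 1
        assert assign_bins([0.4249])[0] == 1
        assert assign_bins([0.425])[0] == 2
        assert assign_bins([0.645])[0] == 4

    def test_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(0)
        theta = rng.uniform(0, 1.2, 500)
        labels = rng.integers(0, 2, 500).astype(bool)
        table = bin_percentages(theta, labels)
        filled = table.dropna()
        assert (filled.pct_satisfactory + filled.pct_unsatisfactory).round(9).eq(100).all()

    def test_all_satisfactory(self):
        theta = np.linspace(0.1, 1.5, 50)
        table = bin_percentages(theta, np.ones(50, dtype=bool))
        filled = table.dropna()
        assert (filled.pct_satisfactory == 100).all()

    def test_hand_binned_fixture(self):
        theta = [0.10, 0.20, 0.35, 0.40, 0.45, 0.50, 0.60, 0.60, 0.70, 0.90]
        labels = [True, True, True, False, True, False, False, False, False, False]
        table = bin_percentages(theta, labels).set_index("bin")
        assert table.loc["<0.32", "count"] == 2
        assert table.loc["<0.32", "pct_satisfactory"] == 100
        assert table.loc["0.32-0.42", "pct_satisfactory"] == 50
        assert table.loc["0.43-0.53", "pct_satisfactory"] == 50
        assert table.loc["0.54-0.64", "pct_unsatisfactory"] == 100
        assert table.loc[">=0.65", "count"] == 2


class TestFitIndexDistributions:
    def test_two_point_group_mean(self):
        theta = np.array([0.4, 0.6, 0.3, 0.9])
        labels = np.array([True, True, False, False])
        dists = fit_index_distributions(theta, labels)
        assert dists.mean_satisfactory == pytest.approx(0.5)
        assert dists.mean_unsatisfactory == pytest.approx(0.6)

    def test_parameter_recovery_from_known_normals(self):
        rng = np.random.default_rng(8)
        sat = rng.normal(0.40, 0.11, size=10_000)
        uns = rng.normal(0.63, 0.25, size=10_000)
        theta = np.concatenate([sat, uns])
        labels = np.concatenate([np.ones(10_000, bool), np.zeros(10_000, bool)])
        dists = fit_index_distributions(theta, labels)
        assert dists.mean_satisfactory == pytest.approx(0.40, rel=0.02)
        assert dists.sd_satisfactory == pytest.approx(0.11, rel=0.02)
        assert dists.mean_unsatisfactory == pytest.approx(0.63, rel=0.02)
        assert dists.sd_unsatisfactory == pytest.approx(0.25, rel=0.02)

    def test_studentized_range_hand_value(self):
        values = np.arange(11.0)  # 0..10: range 10, sd sqrt(11)
        labels = np.ones(11, bool)
        theta = np.concatenate([values, [0.0, 1.0]])
        labels = np.concatenate([labels, [False, False]])
        dists = fit_index_distributions(theta, labels)
        assert dists.u_satisfactory == pytest.approx(10 / np.sqrt(11))

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_index_distributions([0.5, 0.5, 0.3, 0.4], [True, True, False, False])


class TestLikelihoodRatio:
    def test_identical_distributions_give_unity(self):
        dists = GroupDistributions(0.45, 0.2, 0.45, 0.2)
        for b in DEFAULT_BINS:
            assert likelihood_ratio(b, dists) == pytest.approx(1.0)

    def test_whole_axis_bin_is_unity(self):
        dists = GroupDistributions(0.40, 0.11, 0.63, 0.25)
        whole = IndexBin("all", -np.inf, np.inf)
        assert likelihood_ratio(whole, dists) == pytest.approx(1.0)

    def test_top_bin_value_against_normal_cdf(self):
        """Survey-like moments: u N(0.63, 0.25) vs s N(0.40, 0.11), θ ≥ 0.645."""
        dists = GroupDistributions(
            mean_satisfactory=0.40, sd_satisfactory=0.11,
            mean_unsatisfactory=0.63, sd_unsatisfactory=0.25,
        )
        top = DEFAULT_BINS[-1]
        expected = (1 - norm.cdf(0.645, 0.63, 0.25)) / (1 - norm.cdf(0.645, 0.40, 0.11))
        lr = likelihood_ratio(top, dists)
        assert lr == pytest.approx(expected)
        assert lr == pytest.approx(36.7, abs=0.2)

    def test_partition_masses_sum_to_one(self):
        dists = GroupDistributions(0.40, 0.11, 0.63, 0.25)
        for mean, sd in ((0.40, 0.11), (0.63, 0.25)):
            total = sum(
                norm.cdf(b.upper, mean, sd) - norm.cdf(b.lower, mean, sd)
                for b in DEFAULT_BINS
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_vanishing_denominator_flags_infinity(self):
        dists = GroupDistributions(0.1, 0.01, 2.0, 0.1)
        assert likelihood_ratio(IndexBin("hi", 1.9, 2.1), dists) == np.inf

    def test_empirical_counting_oracle_agrees(self):
        """Counting LR vs normal-CDF LR on truly normal indices, n = 10⁵."""
        rng = np.random.default_rng(21)
        n = 100_000
        sat = rng.normal(0.40, 0.11, size=n)
        uns = rng.normal(0.63, 0.25, size=n)
        theta = np.concatenate([sat, uns])
        labels = np.concatenate([np.ones(n, bool), np.zeros(n, bool)])
        dists = GroupDistributions(0.40, 0.11, 0.63, 0.25)
        analytic = likelihood_ratio_table(dists)
        empirical = empirical_likelihood_ratio_table(theta, labels)
        for label, lr in analytic.items():
            assert empirical[label] == pytest.approx(lr, rel=0.10), label


class TestScreeningTable:
    def test_published_rows_reproduced(self):
        """LR₂ = r·LR₁ with display rounding matches all five published cells."""
        impacts = {"<0.32": 1.4, "0.32-0.42": 1.2, "0.43-0.53": 1.1,
                   "0.54-0.64": 1.3, ">=0.65": 1.5}
        table = update_screening_table(DEFAULT_LR1, impacts).set_index("bin")
        assert table.loc["<0.32", "lr2"] == pytest.approx(0.14)
        assert table.loc["<0.32", "lr2_display"] == 0.1
        assert table.loc["0.32-0.42", "lr2_display"] == 0.5
        assert table.loc["0.43-0.53", "lr2_display"] == 0.9
        assert table.loc["0.54-0.64", "lr2"] == pytest.approx(2.21)
        assert table.loc["0.54-0.64", "lr2_display"] == 2.2
        assert table.loc[">=0.65", "lr2"] == pytest.approx(37.5)
        assert table.loc[">=0.65", "lr2_display"] == 38

    def test_unit_impacts_leave_lr_unchanged(self):
        impacts = {k: 1.0 for k in DEFAULT_LR1}
        table = update_screening_table(DEFAULT_LR1, impacts)
        assert table.lr2.tolist() == pytest.approx(table.lr1.tolist())

    @pytest.mark.parametrize(
        "value, expected",
        [(0.14, 0.1), (0.48, 0.5), (0.88, 0.9), (2.21, 2.2), (37.5, 38.0),
         (0.25, 0.3), (9.95, 10.0), (10.4, 10.0)],
    )
    def test_display_rounding_half_up(self, value, expected):
        assert display_round(value) == expected

    def test_relative_impact_arithmetic(self):
        r = relative_impact({"a": 2.0}, {"a": 4.0})
        assert r["a"] == 0.5

    def test_relative_impact_flags_bad_bins(self):
        r = relative_impact({"a": 0.0}, {"a": 4.0})
        assert np.isnan(r["a"])


class TestPostTestProbability:
    @pytest.mark.parametrize(
        "pre, lr, expected", [(0.3, 1.0, 0.3), (0.5, 3.0, 0.75)]
    )
    def test_odds_arithmetic(self, pre, lr, expected):
        assert post_test_probability(pre, lr) == pytest.approx(expected)

    def test_monotone_in_lr(self):
        values = [post_test_probability(0.3, lr) for lr in (0.1, 1.0, 5.0, 25.0)]
        assert values == sorted(values)

    def test_degenerate_prior_returned_with_warning(self):
        with pytest.warns(UserWarning):
            assert post_test_probability(1.0, 5.0) == 1.0
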