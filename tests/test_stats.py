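"""Group-level inference: t-tests vs chance, permutation machinery,
paired comparisons, correlation, and age regression."""

import numpy as np
import pytest
from scipy import stats as sps

from wmdecode.decode import CvScheme
from wmdecode.exceptions import ConfigurationError
from wmdecode.stats import (
    CHANCE,
    age_regression,
    paired_sensory_delay,
    permutation_test,
    sensory_delay_correlation,
    ttest_vs_chance,
)

from conftest import gaussian_epochs


class TestTtestVsChance:
    def test_matches_hand_rolled_t_formula(self):
        acc = np.array([0.35, 0.41, 0.30, 0.45, 0.38, 0.36])
        res = ttest_vs_chance(acc)
        n = len(acc)
        t_hand = (acc.mean() - CHANCE) / (acc.std(ddof=1) / np.sqrt(n))
        p_hand = sps.t.sf(t_hand, df=n - 1)
        assert res.test_statistic == pytest.approx(t_hand, abs=1e-10)
        assert res.p_raw == pytest.approx(p_hand, abs=1e-10)

    def test_exactly_at_chance_not_significant(self):
        res = ttest_vs_chance(np.full(10, CHANCE) + np.array([1e-9, -1e-9] * 5))
        assert not res.significant

    def test_bonferroni_never_decreases_and_caps(self):
        acc = np.array([0.4, 0.42, 0.39, 0.41])
        res1 = ttest_vs_chance(acc, n_tests=1)
        res66 = ttest_vs_chance(acc, n_tests=66)
        assert res66.p_adjusted >= res1.p_adjusted
        assert res66.p_adjusted <= 1.0
        assert res66.p_adjusted == pytest.approx(min(1.0, res1.p_raw * 66))

    def test_zero_variance_flagged_with_sign_decision(self):
        above = ttest_vs_chance(np.full(5, 0.5))
        below = ttest_vs_chance(np.full(5, 0.2))
        assert above.zero_variance and above.p_raw == 0.0
        assert below.zero_variance and below.p_raw == 1.0

    def test_power_at_reported_delay_moments(self):
        """Cohorts drawn at the observed Delay-period accuracy distribution
        (mean .444, sd .086, n=20) are detected after a 3-window Bonferroni
        correction in >= 95% of replicates."""
        rng = np.random.default_rng(0)
        hits = sum(
            ttest_vs_chance(rng.normal(0.444, 0.086, size=20), n_tests=3).significant
            for _ in range(100)
        )
        assert hits >= 95

    def test_familywise_error_controlled_over_66_bins(self):
        """Null accuracies tested at 66 bins with Bonferroni keep the
        family-wise error near or below alpha."""
        rng = np.random.default_rng(1)
        fwe = 0
        for _ in range(200):
            any_sig = False
            accs = rng.normal(CHANCE, 0.04, size=(66, 20))
            for row in accs:
                if ttest_vs_chance(row, n_tests=66).significant:
                    any_sig = True
                    break
            fwe += any_sig
        assert fwe / 200 <= 0.075  # alpha=.05 plus binomial slack

    def test_too_few_subjects(self):
        with pytest.raises(ConfigurationError):
            ttest_vs_chance(np.array([0.4]))


def _mean_stat(X, y, cv, seed):
    """Cheap injected statistic: separation of class means (exchangeable)."""
    classes = sorted(set(y.tolist()), key=str)
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    return float(np.linalg.norm(means - means.mean(axis=0)))


class TestPermutationTest:
    def _null_cohort(self, rng, n_subjects=3):
        return [gaussian_epochs(rng, n_per_class=10, n_channels=4, separation=0.0)
                for _ in range(n_subjects)]

    def test_p_uniform_under_null(self):
        """With exchangeable labels, permutation p-values are uniform on the
        discrete grid {1/(N+1), ..., 1} (KS test over replicates)."""
        rng = np.random.default_rng(2)
        ps = []
        for rep in range(100):
            cohort = self._null_cohort(rng)
            res = permutation_test(
                cohort, (0.0, 1000.0), n_perm=99, seed=1000 + rep,
                cv=CvScheme(n_iterations=1), decode_fn=_mean_stat,
            )
            ps.append(res.p_perm)
        ks = sps.kstest(ps, sps.uniform(loc=0.01, scale=0.99).cdf)
        assert ks.pvalue > 0.01

    def test_p_never_zero_add_one_formula(self):
        rng = np.random.default_rng(3)
        cohort = [gaussian_epochs(rng, n_per_class=12, n_channels=4, separation=5.0)]
        res = permutation_test(cohort, (0.0, 1000.0), n_perm=99, seed=0,
                               cv=CvScheme(n_iterations=1), decode_fn=_mean_stat)
        assert res.p_perm == pytest.approx(1 / 100)
        assert res.p_perm > 0

    def test_identical_seed_identical_null(self):
        rng = np.random.default_rng(4)
        cohort = self._null_cohort(rng)
        a = permutation_test(cohort, (0.0, 1000.0), n_perm=120, seed=7,
                             cv=CvScheme(n_iterations=1), decode_fn=_mean_stat)
        b = permutation_test(cohort, (0.0, 1000.0), n_perm=120, seed=7,
                             cv=CvScheme(n_iterations=1), decode_fn=_mean_stat)
        assert np.array_equal(a.null_distribution, b.null_distribution)
        assert a.p_perm == b.p_perm

    def test_small_n_perm_warns(self):
        rng = np.random.default_rng(5)
        cohort = self._null_cohort(rng, n_subjects=1)
        with pytest.warns(UserWarning, match="unstable"):
            permutation_test(cohort, (0.0, 1000.0), n_perm=20, seed=0,
                             cv=CvScheme(n_iterations=1), decode_fn=_mean_stat)

    def test_real_decoder_detects_strong_signal(self):
        """With the actual decoding pipeline as the statistic, a separable
        cohort is maximally significant."""
        rng = np.random.default_rng(6)
        cohort = [gaussian_epochs(rng, n_per_class=20, n_channels=6, separation=4.0)
                  for _ in range(2)]
        res = permutation_test(cohort, (0.0, 1000.0), n_perm=99, seed=0,
                               cv=CvScheme(n_iterations=3, group_size=2))
        assert res.p_perm == pytest.approx(1 / 100)
        assert res.cv_iterations_used == 3


class TestPairedSensoryDelay:
    def test_identical_vectors_null(self):
        s = np.array([0.5, 0.6, 0.55])
        res = paired_sensory_delay(s, s)
        assert res.test_statistic == 0.0 or res.zero_variance
        assert not res.significant

    def test_recovers_planted_gap(self):
        """A planted 13.5% Sensory-over-Delay gap is estimated within 2 SE
        (averaged over replicates to control draw noise)."""
        rng = np.random.default_rng(7)
        estimates = []
        for _ in range(10):
            sens = rng.normal(0.58, 0.11, size=20)
            delay = sens - rng.normal(0.135, 0.04, size=20)
            res = paired_sensory_delay(sens, delay)
            estimates.append(res.estimate)
            assert res.significant
        se_pooled = 0.04 / np.sqrt(20 * 10)
        assert abs(np.mean(estimates) - 0.135) < 2 * se_pooled

    def test_wrong_direction_large_p(self):
        rng = np.random.default_rng(8)
        delay = rng.normal(0.6, 0.02, size=10)
        sens = delay - 0.1
        res = paired_sensory_delay(sens, delay)
        assert res.p_raw > 0.5

    def test_length_mismatch(self):
        with pytest.raises(ConfigurationError):
            paired_sensory_delay(np.ones(3), np.ones(4))


class TestCorrelation:
    def test_exact_linear_relationship(self):
        s = np.linspace(0.4, 0.8, 10)
        r, p = sensory_delay_correlation(s, 0.5 * s + 0.1)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_independent_vectors_rarely_large_r(self):
        rng = np.random.default_rng(9)
        big = sum(
            abs(sensory_delay_correlation(rng.normal(size=20), rng.normal(size=20))[0]) >= 0.45
            for _ in range(200)
        )
        # P(|r| >= 0.45) under the null at n=20 is ~0.05 by construction;
        # allow binomial slack at 200 replicates
        assert big / 200 <= 0.08

    def test_zero_variance_errors(self):
        with pytest.raises(ConfigurationError):
            sensory_delay_correlation(np.full(5, 0.5), np.arange(5.0))


class TestAgeRegression:
    def test_exact_line_r2_one(self):
        ages = np.array([84.0, 100, 120, 140, 152])
        res = age_regression(ages, 0.3 + 0.001 * ages, window="Delay")
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(0.001)

    def test_null_false_positive_rate_near_alpha(self):
        rng = np.random.default_rng(10)
        hits = sum(
            age_regression(rng.uniform(84, 152, 20), rng.normal(0.5, 0.05, 20))["p"] < 0.05
            for _ in range(200)
        )
        assert 0.005 <= hits / 200 <= 0.11

    def test_planted_age_effect_recovered(self):
        rng = np.random.default_rng(11)
        signs = []
        for _ in range(30):
            ages = rng.uniform(84, 152, 20)
            acc = 0.4 + 0.002 * (ages - 118) + rng.normal(0, 0.03, 20)
            signs.append(age_regression(ages, acc)["slope"] > 0)
        assert np.mean(signs) >= 0.9

    def test_constant_age_errors(self):
        with pytest.raises(ConfigurationError):
            age_regression(np.full(5, 100.0), np.arange(5.0))
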