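import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from coralprev import (
    accuracy_experiment,
    cliffs_delta,
    power_experiment,
    power_two_proportions,
    smooth_power_curve,
)
from coralprev.power_eval import PowerPoint
from coralprev.survey import FIGURE_PROTOCOLS


def brute_force_delta(x, y):
    gt = sum(xi > yj for xi in x for yj in y)
    lt = sum(xi < yj for xi in x for yj in y)
    return (gt - lt) / (len(x) * len(y))


def mc_power_z_test(p1, p2, n1, n2, alpha=0.05, reps=200_000, seed=0):
    """Monte-Carlo oracle: rejection rate of the pooled two-proportion z test."""
    rng = np.random.default_rng(seed)
    x1 = rng.binomial(n1, p1, reps)
    x2 = rng.binomial(n2, p2, reps)
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = np.where(se > 0, (x1 / n1 - x2 / n2) / np.where(se > 0, se, 1.0), 0.0)
    return np.mean(np.abs(z) > stats.norm.ppf(1 - alpha / 2))


class TestPowerTwoProportions:
    def test_zero_effect_power_equals_alpha(self):
        for alpha in (0.01, 0.05, 0.1):
            assert power_two_proportions(0.2, 0.2, 50, 80, alpha) == pytest.approx(alpha)

    def test_reference_value(self):
        assert power_two_proportions(0.1, 0.3, 50, 50) == pytest.approx(0.71, abs=0.01)

    @pytest.mark.parametrize(
        "p1,p2,n1,n2",
        [
            (0.1, 0.3, 50, 50),
            (0.1, 0.2, 100, 100),
            (0.2, 0.4, 50, 50),
            (0.16, 0.16, 100, 100),
            (0.3, 0.5, 80, 80),
            (0.1, 0.25, 200, 100),
        ],
    )
    def test_agrees_with_monte_carlo_z_test(self, p1, p2, n1, n2):
        approx = power_two_proportions(p1, p2, n1, n2)
        mc = mc_power_z_test(p1, p2, n1, n2)
        assert abs(approx - mc) < 0.025

    def test_power_increases_with_sample_size(self):
        powers = [power_two_proportions(0.15, 0.25, n, n) for n in (20, 50, 100, 300, 1000)]
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            power_two_proportions(1.2, 0.3, 50, 50)
        with pytest.raises(ValueError):
            power_two_proportions(0.1, 0.3, 1, 50)


class TestCliffsDelta:
    def test_identical_samples_give_zero(self):
        assert cliffs_delta([1, 2, 3], [3, 2, 1]) == 0.0

    def test_complete_dominance_gives_one(self):
        assert cliffs_delta([4, 5, 6], [1, 2, 3]) == 1.0

    def test_hand_computed_example(self):
        assert cliffs_delta([1, 2, 3], [2, 3, 4]) == pytest.approx(-5 / 9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cliffs_delta([], [1.0])

    @given(
        st.lists(st.integers(min_value=0, max_value=8), min_size=1, max_size=50),
        st.lists(st.integers(min_value=0, max_value=8), min_size=1, max_size=50),
    )
    def test_matches_brute_force_and_antisymmetry(self, x, y):
        d = cliffs_delta(x, y)
        assert d == pytest.approx(brute_force_delta(x, y), abs=1e-12)
        assert d == pytest.approx(-cliffs_delta(y, x), abs=1e-12)
        assert -1.0 <= d <= 1.0


@pytest.fixture(scope="module")
def small_population():
    from coralprev import Frame, generate_poisson, mark_random

    pattern = generate_poisson(Frame(400.0, 200.0), 0.63, seed=21)
    return mark_random(pattern, 0.162, seed=22)


@pytest.fixture(scope="module")
def summary():
    from coralprev import Frame, generate_poisson, mark_random

    pattern = generate_poisson(Frame(400.0, 200.0), 0.63, seed=31)
    marked = mark_random(pattern, 0.162, seed=32)
    return accuracy_experiment(marked, FIGURE_PROTOCOLS["25x2"], n_surveys=60, seed=33)


class TestAccuracyExperiment:

    def test_vacuous_tolerance_always_within(self, small_population):
        acc = accuracy_experiment(
            small_population, FIGURE_PROTOCOLS["25x2"], n_surveys=20, tolerance=1.0, seed=0
        )
        assert acc.prob_within_tolerance == 1.0

    def test_relative_margin_scales_with_true_prevalence(self, small_population):
        acc = accuracy_experiment(
            small_population, FIGURE_PROTOCOLS["25x2"], n_surveys=5,
            tolerance=0.05, tolerance_mode="relative", seed=0,
        )
        assert acc.margin == pytest.approx(0.05 * small_population.prevalence)

    def test_estimates_recorded_per_survey(self, small_population):
        acc = accuracy_experiment(
            small_population, FIGURE_PROTOCOLS["50x2"], n_surveys=30, seed=1
        )
        assert acc.estimates.shape == (30,)
        assert acc.n_undefined == 0
        assert np.isfinite(acc.estimates).all()

    def test_estimate_spread_shrinks_with_transect_area(self, small_population):
        small = accuracy_experiment(small_population, FIGURE_PROTOCOLS["10x1"],
                                    n_surveys=100, seed=2)
        large = accuracy_experiment(small_population, FIGURE_PROTOCOLS["50x2"],
                                    n_surveys=100, seed=3)
        assert np.nanstd(large.estimates) < np.nanstd(small.estimates)

    def test_invalid_mode_rejected(self, small_population):
        with pytest.raises(ValueError):
            accuracy_experiment(small_population, FIGURE_PROTOCOLS["10x1"],
                                tolerance_mode="percentile", seed=0)


class TestPowerExperiment:
    def test_pairs_have_valid_ranges(self, summary):
        points = power_experiment(summary, n_pairs=50, seed=0)
        assert len(points) == 50
        for p in points:
            assert 0.0 <= p.achieved_power <= 1.0
            assert -1.0 <= p.effect_size <= 1.0
            assert p.pair[0] != p.pair[1]

    def test_self_pair_gives_zero_effect_and_alpha_power(self, summary):
        s = summary.surveys[0]
        delta = cliffs_delta(s.transect_prevalences, s.transect_prevalences)
        power = power_two_proportions(
            s.prevalence_estimate, s.prevalence_estimate, s.unique_total, s.unique_total
        )
        assert delta == 0.0
        assert power == pytest.approx(0.05)

    def test_power_increases_with_effect_size(self, summary):
        points = power_experiment(summary, n_pairs=100, seed=4)
        deltas = np.abs([p.effect_size for p in points])
        powers = np.array([p.achieved_power for p in points])
        rho = stats.spearmanr(deltas, powers).statistic
        assert rho > 0.3


class TestSmoothPowerCurve:
    def test_reproduces_monotone_line(self):
        xs = np.linspace(0, 1, 20)
        points = [PowerPoint(x, 0.1 + 0.7 * x, 50, 50, 0.1, 0.2) for x in xs]
        curve = smooth_power_curve(points)
        assert np.allclose(curve(xs), 0.1 + 0.7 * xs, atol=1e-9)

    def test_constant_points_give_constant_curve(self):
        points = [PowerPoint(x, 0.3, 50, 50, 0.1, 0.2) for x in np.linspace(0, 1, 15)]
        curve = smooth_power_curve(points)
        assert np.allclose(curve(np.linspace(0, 1, 7)), 0.3)

    def test_predictions_bounded_and_monotone(self):
        rng = np.random.default_rng(8)
        xs = rng.uniform(0, 1, 40)
        points = [
            PowerPoint(x, float(np.clip(x + rng.normal(0, 0.2), 0, 1)), 50, 50, 0.1, 0.2)
            for x in xs
        ]
        curve = smooth_power_curve(points)
        grid = np.linspace(0, 1, 50)
        preds = curve(grid)
        assert ((preds > 0) & (preds < 1)).all()
        assert (np.diff(preds) >= -1e-12).all()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            smooth_power_curve([PowerPoint(0.1, 0.2, 50, 50, 0.1, 0.2)] * 5)
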