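"""Psychometric function, QUEST machinery and pinprick statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from painlearn.errors import (
    InvalidMeasurementError,
    NoDetectionError,
    UnreachableProbabilityError,
)
from painlearn.psychophysics import (
    DEFAULT_QUEST_SHAPE,
    PinprickMeasurement,
    PsychometricCurve,
    QuestPosterior,
    StaircasePair,
    curve_from_quest,
    invert_weibull,
    make_step_observer,
    make_weibull_observer,
    method_of_limits,
    pinprick_threshold,
    quest_next,
    quest_update,
    run_dual_quest,
    staircase_convergence,
    target_offset,
    weibull_detection_prob,
)


class TestWeibull:
    def test_value_at_threshold(self):
        c = PsychometricCurve(0.0)
        assert weibull_detection_prob(c, 0.0) == pytest.approx(
            0.6295413597, abs=1e-9
        )

    def test_asymptotes(self):
        c = PsychometricCurve(0.0)
        assert weibull_detection_prob(c, -50.0) == pytest.approx(0.01, abs=1e-12)
        assert weibull_detection_prob(c, 50.0) == pytest.approx(0.9901, abs=1e-12)

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            PsychometricCurve(0.0, slope_beta_w=-1.0)
        with pytest.raises(ValueError):
            PsychometricCurve(0.0, guess_gamma_w=1.5)
        with pytest.raises(ValueError):
            weibull_detection_prob(PsychometricCurve(0.0), float("nan"))

    def test_invert_at_75(self):
        c = PsychometricCurve(0.0)
        assert invert_weibull(c, 0.75) == pytest.approx(0.0423344, abs=1e-5)

    def test_invert_round_trip_at_named_point(self):
        c = PsychometricCurve(-1.0)
        x = invert_weibull(c, 0.6295413597078694)
        assert x == pytest.approx(-1.0, abs=1e-9)

    def test_unreachable_probability(self):
        c = PsychometricCurve(0.0)
        with pytest.raises(UnreachableProbabilityError):
            invert_weibull(c, 0.009)
        with pytest.raises(UnreachableProbabilityError):
            invert_weibull(c, 0.995)

    @settings(derandomize=True, max_examples=60)
    @given(
        p=st.floats(0.011, 0.989),
        T=st.floats(-2.0, 1.0),
    )
    def test_inversion_identity_property(self, p, T):
        c = PsychometricCurve(T)
        x = invert_weibull(c, p)
        assert weibull_detection_prob(c, x) == pytest.approx(p, abs=1e-8)

    @settings(derandomize=True, max_examples=40)
    @given(
        x1=st.floats(-3.0, 3.0),
        dx=st.floats(0.0, 3.0),
    )
    def test_monotone_in_intensity(self, x1, dx):
        c = PsychometricCurve(0.0)
        assert weibull_detection_prob(c, x1 + dx) >= weibull_detection_prob(c, x1)


class TestMethodOfLimits:
    def test_deterministic_step_observer(self):
        obs = make_step_observer(0.1)
        est = method_of_limits(obs, start=0.01, step=0.01, seed=0)
        # every detection sits at 0.10 up to one step of overshoot
        assert est == pytest.approx(0.10, abs=0.011)

    def test_always_detecting_observer(self):
        calls = []

        def obs(x, rng):
            calls.append(x)
            return 1

        est = method_of_limits(obs, start=0.05, step=0.01, seed=0)
        assert len(calls) == 5  # every presentation detected
        assert est == pytest.approx(np.mean(calls[:5]))

    def test_never_detecting_observer(self):
        with pytest.raises(NoDetectionError):
            method_of_limits(lambda x, rng: 0, start=0.01, step=0.05, seed=0)


def _brute_force_posterior(grid, history, shape=DEFAULT_QUEST_SHAPE):
    """Independent batch Bayes update on the same grid (flat prior)."""
    offset = target_offset(shape)
    logd = np.zeros_like(grid)
    for x, r in history:
        curves = [
            PsychometricCurve(t - offset, shape.slope, shape.guess, shape.lapse)
            for t in grid
        ]
        p = np.array([weibull_detection_prob(c, x) for c in curves])
        logd += np.log(p) if r else np.log1p(-p)
    d = np.exp(logd - logd.max())
    return d / d.sum()


class TestQuest:
    def test_no_data_posterior_is_prior(self):
        prior = QuestPosterior.from_prior(-1.0)
        assert prior.trial_history == []
        assert prior.mean == pytest.approx(-1.0, abs=1e-9)

    def test_mass_conservation(self):
        post = QuestPosterior.from_prior(-1.0)
        for x, r in [(-1.1, 1), (-0.9, 0), (-1.0, 1), (-1.2, 0)]:
            post = quest_update(post, x, r)
            assert np.sum(post.density) == pytest.approx(1.0, abs=1e-10)

    def test_update_order_commutes(self):
        post = QuestPosterior.from_prior(-1.0)
        a = quest_update(quest_update(post, -1.0, 1), -1.0, 0)
        b = quest_update(quest_update(post, -1.0, 0), -1.0, 1)
        np.testing.assert_allclose(a.log_density, b.log_density, atol=1e-12)

    def test_yes_lowers_no_raises_posterior_mean(self):
        post = QuestPosterior.from_prior(-1.0)
        assert quest_update(post, -1.0, 1).mean <= post.mean
        assert quest_update(post, -1.0, 0).mean >= post.mean

    def test_posterior_matches_brute_force_oracle(self):
        """Sequential grid updates equal one batch Bayes update."""
        rng = np.random.default_rng(42)
        curve = PsychometricCurve(-1.0)
        target = invert_weibull(curve, 0.75)
        post = QuestPosterior.from_prior(-1.1)
        for _ in range(200):
            x = target + rng.normal(0, 0.15)
            r = int(rng.random() < weibull_detection_prob(curve, x))
            post = quest_update(post, x, r)
        # prior is Gaussian, oracle flat: compare likelihood parts
        oracle = _brute_force_posterior(post.grid, post.trial_history)
        prior = QuestPosterior.from_prior(-1.1)
        lik = post.log_density - prior.log_density
        lik = np.exp(lik - lik.max())
        lik /= lik.sum()
        np.testing.assert_allclose(lik, oracle, atol=1e-8)
        assert post.mean == pytest.approx(target, abs=0.05)

    def test_quest_next_rules(self):
        post = QuestPosterior.from_prior(-1.0)
        assert quest_next(post) == pytest.approx(post.mean)
        assert quest_next(post, rule="quantile", q=0.5) == pytest.approx(
            -1.0, abs=0.01
        )
        with pytest.raises(ValueError):
            quest_next(post, rule="mode")

    def test_yes_at_high_intensity_shifts_placement_down(self):
        post = QuestPosterior.from_prior(-1.0)
        updated = quest_update(post, -0.5, 1)
        assert quest_next(updated) < quest_next(post)


class TestDualQuest:
    def test_staircases_have_40_trials_each(self, default_curve):
        obs = make_weibull_observer(default_curve)
        pair, _, _ = run_dual_quest(obs, 0.09, seed=0)
        assert len(pair.staircase_a) == 40
        assert len(pair.staircase_b) == 40

    def test_determinism_under_seed(self, default_curve):
        obs = make_weibull_observer(default_curve)
        p1, _, _ = run_dual_quest(obs, 0.09, seed=7)
        p2, _, _ = run_dual_quest(obs, 0.09, seed=7)
        assert p1.staircase_a == p2.staircase_a
        assert p1.staircase_b == p2.staircase_b
        assert p1.final_threshold_mA == p2.final_threshold_mA

    def test_sequential_equals_batch_history_update(self, default_curve):
        obs = make_weibull_observer(default_curve)
        _, post_a, _ = run_dual_quest(obs, 0.09, seed=3)
        replay = QuestPosterior.from_prior(math.log10(0.09))
        for x, r in post_a.trial_history:
            replay = quest_update(replay, x, r)
        np.testing.assert_allclose(
            post_a.log_density, replay.log_density, atol=1e-10
        )

    def test_step_observer_convergence(self):
        """A noiseless threshold observer pins the estimate to its step."""
        obs = make_step_observer(0.1)
        pair, _, _ = run_dual_quest(obs, 0.08, seed=0)
        assert math.log10(pair.final_threshold_mA) == pytest.approx(
            math.log10(0.1), abs=0.05
        )

    def test_curve_from_quest_round_trip(self):
        curve = curve_from_quest(0.1)
        assert 10 ** invert_weibull(curve, 0.75) == pytest.approx(0.1, rel=1e-9)


class TestStaircaseConvergence:
    def test_identical_staircases_converge_at_trial_1(self):
        pair = StaircasePair((0.1,) * 40, (0.1,) * 40, 0.1)
        assert staircase_convergence(pair, 0.1) == 1

    def test_constructed_convergence_at_trial_15(self):
        # differences of 1 mA through trial 14 keep every suffix mean that
        # includes them above the 0.005 mA criterion; zero afterwards
        a = [0.10] * 40
        b = [1.10] * 14 + [0.10] * 26
        pair = StaircasePair(tuple(a), tuple(b), 0.1)
        assert staircase_convergence(pair, 0.1, frac=0.05) == 15

    def test_persistent_offset_never_converges(self):
        pair = StaircasePair((0.1,) * 40, (0.2,) * 40, 0.1)
        assert staircase_convergence(pair, 0.1) is None


class TestPinprick:
    def test_geometric_mean_of_powers_of_two(self):
        m = PinprickMeasurement((8.0, 16.0, 32.0), (64.0, 128.0))
        gm, sd = pinprick_threshold(m)
        assert gm == pytest.approx(32.0, rel=1e-12)  # fifth root of 2**25

    def test_identical_values_have_zero_sd(self):
        m = PinprickMeasurement((64.0, 64.0, 64.0), (64.0, 64.0))
        gm, sd = pinprick_threshold(m)
        assert gm == pytest.approx(64.0)
        assert sd == pytest.approx(0.0, abs=1e-14)

    def test_zero_force_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            PinprickMeasurement((0.0, 16.0, 32.0), (64.0, 128.0))

    def test_wrong_count_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            PinprickMeasurement((8.0, 16.0), (64.0, 128.0))
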