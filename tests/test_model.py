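import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from stepfall.features import FallClassFeatures, FallFeatures, StepFeatures
from stepfall.model import (
    FallClassModel,
    FallModel,
    GaussianParams,
    NullFeature,
    NullModel,
    SpeedGaussian,
    SpeedModelSet,
    classify_fall,
    default_speed_gaussians,
    fall_likelihood,
    fit_gaussian,
    fit_null,
    speed_posterior,
    step_probability,
)
from stepfall.params import FALL_CLASS, STEP_F1, STEP_F2


def brute_force_posterior(f1, f2, model):
    """Independent oracle: explicit products and normalisation with plain
    Python floats (no log-space tricks)."""
    def gauss(x, lam, sigma):
        return math.exp(-((x - lam) ** 2) / (2 * sigma**2)) / (
            sigma * math.sqrt(2 * math.pi)
        )

    weights = [model.null.f1.pdf(f1) * model.null.f2.pdf(f2) * model.prior[0]]
    for i, sg in enumerate(model.speeds, start=1):
        weights.append(
            gauss(f1, sg.f1.lam, sg.f1.sigma)
            * gauss(f2, sg.f2.lam, sg.f2.sigma)
            * model.prior[i]
        )
    total = sum(weights)
    return np.array([w / total for w in weights])


def random_model_set(rng, k=3):
    speeds = tuple(
        SpeedGaussian(
            mu_label=60.0 + 20 * i,
            f1=GaussianParams(rng.uniform(0.2, 1.0), rng.uniform(0.05, 0.5)),
            f2=GaussianParams(rng.uniform(0.02, 0.3), rng.uniform(0.01, 0.2)),
        )
        for i in range(k)
    )
    null = NullModel(
        f1=NullFeature(
            lam01=rng.uniform(1, 50),
            mu01=rng.uniform(0.05, 0.3),
            lam02=rng.uniform(1, 50),
            mu02=rng.uniform(0.0, 0.05),
        ),
        f2=NullFeature(
            lam01=rng.uniform(1, 20),
            mu01=rng.uniform(0.1, 0.6),
            lam02=rng.uniform(1, 20),
            mu02=rng.uniform(-0.6, -0.1),
        ),
    )
    prior = rng.uniform(0.1, 1.0, size=k + 1)
    prior /= prior.sum()
    return SpeedModelSet(speeds=speeds, null=null, prior=prior)


class TestFitGaussian:
    def test_constant_input_floors_sigma(self):
        g = fit_gaussian([1.0, 1.0, 1.0])
        assert g.lam == 1.0
        assert g.sigma == 1e-6

    def test_two_point_closed_form(self):
        g = fit_gaussian([0.0, 2.0])
        assert g.lam == pytest.approx(1.0)
        assert g.sigma == pytest.approx(math.sqrt(2))

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_gaussian([1.0])

    def test_recovers_trained_step_parameters(self):
        # 60 steps/min f1 parameters of the shipped calibration
        lam, sigma = 0.4846, 0.2023
        n = 10_000
        x = np.random.default_rng(7).normal(lam, sigma, n)
        g = fit_gaussian(x)
        assert abs(g.lam - lam) < 4 * sigma / math.sqrt(n)
        assert abs(g.sigma - sigma) < 4 * sigma / math.sqrt(2 * n)

    @settings(max_examples=30, deadline=None)
    @given(
        lam=st.floats(-5, 5),
        sigma=st.floats(0.01, 3.0),
        seed=st.integers(0, 10_000),
    )
    def test_property_recovery(self, lam, sigma, seed):
        n = 2000
        x = np.random.default_rng(seed).normal(lam, sigma, n)
        g = fit_gaussian(x)
        assert abs(g.lam - lam) < 4 * sigma / math.sqrt(n)
        assert abs(g.sigma - sigma) < 4 * sigma / math.sqrt(2 * n)


class TestFitNull:
    def test_symmetric_samples(self, rng):
        x = rng.normal(0, 1.0, 20_000)
        x = np.concatenate([x, -x])  # exactly symmetric
        nf = fit_null(x)
        assert nf.mu01 == pytest.approx(-nf.mu02, abs=1e-9)
        assert nf.lam01 == pytest.approx(nf.lam02, rel=1e-6)

    def test_exponential_tail_recovery(self, rng):
        # build a sample whose tails beyond the quartiles are exactly
        # exponential with known rates
        n = 10_000
        mu01, mu02 = 1.0, -1.0
        lam01, lam02 = 4.0, 2.5
        body = rng.uniform(mu02, mu01, n // 2)
        up = mu01 + rng.exponential(1 / lam01, n // 4)
        down = mu02 - rng.exponential(1 / lam02, n // 4)
        nf = fit_null(np.concatenate([body, up, down]))
        assert nf.lam01 == pytest.approx(lam01, rel=0.10)
        assert nf.lam02 == pytest.approx(lam02, rel=0.10)
        assert nf.mu01 == pytest.approx(mu01, abs=0.1)
        assert nf.mu02 == pytest.approx(mu02, abs=0.1)

    def test_density_integrates_to_one(self, rng):
        nf = fit_null(rng.normal(0.3, 0.8, 5000))
        total, _ = quad(nf.pdf, -60, 60, limit=500)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_null([1.0, 2.0, 3.0])

    def test_invariants(self):
        with pytest.raises(ValueError):
            NullFeature(lam01=-1.0, mu01=1.0, lam02=1.0, mu02=0.0)
        with pytest.raises(ValueError):
            NullFeature(lam01=1.0, mu01=0.0, lam02=1.0, mu02=1.0)


class TestSpeedPosterior:
    def test_single_speed_zero_null_prior(self, model_set):
        m = SpeedModelSet(
            speeds=model_set.speeds[:1],
            null=model_set.null,
            prior=np.array([0.0, 1.0]),
        )
        post = speed_posterior(StepFeatures(0.5, 0.14), m)
        assert np.allclose(post, [0.0, 1.0])

    def test_identical_classes_split_equally(self, model_set):
        sg = model_set.speeds[0]
        twin = SpeedGaussian(mu_label=99.0, f1=sg.f1, f2=sg.f2)
        m = SpeedModelSet(
            speeds=(sg, twin),
            null=model_set.null,
            prior=np.array([0.0, 0.5, 0.5]),
        )
        post = speed_posterior(StepFeatures(0.7, 0.1), m)
        assert post[1] == pytest.approx(post[2])

    def test_table_parameters_favour_fastest(self, model_set):
        """At the 100 steps/min feature means the posterior peaks there."""
        m = SpeedModelSet(
            speeds=default_speed_gaussians(),
            null=model_set.null,
            prior=np.full(4, 0.25),
        )
        f = StepFeatures(0.8141, 0.0688)
        post = speed_posterior(f, m)
        assert int(np.argmax(post)) == 3  # [null, 60, 80, 100]
        oracle = brute_force_posterior(f.f1, f.f2, m)
        assert np.allclose(post, oracle, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            m = random_model_set(rng)
            f = StepFeatures(rng.uniform(0, 1.2), rng.uniform(-0.5, 0.5))
            post = speed_posterior(f, m)
            assert np.allclose(post, brute_force_posterior(f.f1, f.f2, m), atol=1e-12)

    def test_sums_to_one(self, rng):
        for _ in range(100):
            m = random_model_set(rng, k=int(rng.integers(1, 5)))
            post = speed_posterior(
                StepFeatures(rng.uniform(0, 2), rng.uniform(-1, 1)), m
            )
            assert post.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(post >= 0) and np.all(post <= 1)

    def test_underflow_returns_prior(self, model_set):
        m = SpeedModelSet(
            speeds=tuple(
                SpeedGaussian(s.mu_label, GaussianParams(s.f1.lam, 1e-6), s.f2)
                for s in model_set.speeds
            ),
            null=NullModel(
                f1=NullFeature(lam01=1e3, mu01=0.0, lam02=1e3, mu02=0.0),
                f2=model_set.null.f2,
            ),
            prior=model_set.prior,
        )
        post = speed_posterior(StepFeatures(1e200, 1e200), m)
        assert np.allclose(post, m.prior)

    def test_prior_validation(self, model_set):
        with pytest.raises(ValueError, match="prior"):
            SpeedModelSet(
                speeds=model_set.speeds,
                null=model_set.null,
                prior=np.array([0.5, 0.5, 0.5, 0.5]),
            )


class TestStepProbability:
    def test_arithmetic(self):
        assert step_probability(np.array([0.2, 0.5, 0.3])) == pytest.approx(0.8)

    def test_all_null(self):
        assert step_probability(np.array([1.0, 0.0, 0.0])) == 0.0

    def test_identity(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, 4)
            p /= p.sum()
            assert step_probability(p) == pytest.approx(1.0 - p[0])

    def test_monotone_in_null_likelihood(self, model_set):
        """Scaling up the null likelihood (via prior weight) never raises
        the step probability."""
        f = StepFeatures(0.3, 0.1)
        probs = []
        for w in np.linspace(0.05, 0.95, 10):
            prior = np.concatenate([[w], np.full(3, (1 - w) / 3)])
            m = SpeedModelSet(
                speeds=model_set.speeds, null=model_set.null, prior=prior
            )
            probs.append(step_probability(speed_posterior(f, m)))
        assert np.all(np.diff(probs) <= 1e-12)


class TestFallLikelihood:
    def test_peak_score(self, fall_model):
        f = FallFeatures(fall_model.f1.lam, fall_model.f2.lam)
        score, is_fall = fall_likelihood(f, fall_model)
        assert score == pytest.approx(1.0)
        assert is_fall

    def test_decision_boundary_is_2ln10(self, fall_model):
        """score > 0.1 iff joint squared standardised distance < 2 ln 10."""
        boundary = 2 * math.log(10)
        for z1 in np.linspace(0, 2.5, 11):
            for z2 in np.linspace(0, 2.5, 11):
                f = FallFeatures(
                    fall_model.f1.lam + z1 * fall_model.f1.sigma,
                    fall_model.f2.lam + z2 * fall_model.f2.sigma,
                )
                score, is_fall = fall_likelihood(f, fall_model)
                assert is_fall == (z1**2 + z2**2 < boundary)

    def test_far_features_score_tiny(self, fall_model):
        f = FallFeatures(
            fall_model.f1.lam + 10 * fall_model.f1.sigma,
            fall_model.f2.lam + 10 * fall_model.f2.sigma,
        )
        score, is_fall = fall_likelihood(f, fall_model)
        assert score < 1e-20
        assert not is_fall

    def test_score_in_unit_interval(self, fall_model, rng):
        for _ in range(100):
            f = FallFeatures(rng.uniform(0, 20), rng.uniform(0, 500))
            score, _ = fall_likelihood(f, fall_model)
            assert 0 < score <= 1

    def test_tau2_validation(self):
        with pytest.raises(ValueError, match="tau2"):
            FallModel(tau2=1.5)


class TestClassifyFall:
    def test_class_means_score_one(self, fall_class_model):
        f = FallClassFeatures(5.2423, 1.9998, -1.8940)
        label, scores = classify_fall(f, fall_class_model)
        assert label == "c1"
        assert scores["c1"] == pytest.approx(1.0)

    def test_equidistant_tie_goes_to_earlier_class(self):
        g = GaussianParams
        m = FallClassModel(
            classes={
                "c1": (g(0.0, 1.0), g(0.0, 1.0), g(0.0, 1.0)),
                "c2": (g(2.0, 1.0), g(0.0, 1.0), g(0.0, 1.0)),
                "c3": (g(10.0, 1.0), g(10.0, 1.0), g(10.0, 1.0)),
            }
        )
        label, scores = classify_fall(FallClassFeatures(1.0, 0.0, 0.0), m)
        assert scores["c1"] == pytest.approx(scores["c2"])
        assert label == "c1"

    def test_well_separated_draws_always_correct(self, fall_class_model, rng):
        """300 synthetic falls, 100 per class, drawn within 0.5 sigma of
        the class means, are all assigned to the generating class."""
        for cls, feats in FALL_CLASS.items():
            for _ in range(100):
                values = []
                for key in ("f1", "f2", "f3"):
                    lam, sigma = feats[key]
                    x = lam + rng.uniform(-0.5, 0.5) * sigma
                    values.append(x)
                label, _ = classify_fall(FallClassFeatures(*values), fall_class_model)
                assert label == cls

    def test_thresholds_fall_back(self):
        g = GaussianParams
        m = FallClassModel(
            classes={
                "c1": (g(0.0, 1.0), g(0.0, 1.0), g(0.0, 1.0)),
                "c2": (g(5.0, 1.0), g(0.0, 1.0), g(0.0, 1.0)),
                "c3": (g(-5.0, 1.0), g(0.0, 1.0), g(0.0, 1.0)),
            },
            thresholds={"c1": 0.99, "c2": 0.99, "c3": 0.99},
        )
        label, _ = classify_fall(FallClassFeatures(2.5, 0.0, 0.0), m)
        assert label == "c3"  # nothing passes, fallback class


def test_default_speed_gaussians_match_tables():
    speeds = default_speed_gaussians()
    assert [s.mu_label for s in speeds] == [60.0, 80.0, 100.0]
    for s in speeds:
        assert (s.f1.lam, s.f1.sigma) == STEP_F1[int(s.mu_label)]
        assert (s.f2.lam, s.f2.sigma) == STEP_F2[int(s.mu_label)]
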