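"""Stochastic models: per-cadence Gaussian likelihoods, null-class
exponential-tail model, cadence posterior, step probability, and fall
detection / classification scores.

Step windows are scored with a Bayesian posterior over
``{null, cadence_1, ..., cadence_k}``: Gaussian densities for the
cadence classes, a two-sided exponential-tail density for the null
class, and a configurable prior.  Fall scores use peak-normalised
Gaussian kernels ``exp(-(x - lam)^2 / (2 sigma^2))`` so the default
detection threshold of 0.1 corresponds to a joint squared standardised
distance of ``2 ln 10``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .features import FallClassFeatures, FallFeatures, StepFeatures
from .params import (
    DEFAULT_DELTA_MAX,
    DEFAULT_TAU2,
    FALL_CLASS,
    FALL_CLASS_LABELS,
    FALL_F1,
    FALL_F2,
    STEP_F1,
    STEP_F2,
)

__all__ = [
    "GaussianParams",
    "SpeedGaussian",
    "NullFeature",
    "NullModel",
    "SpeedModelSet",
    "FallModel",
    "FallClassModel",
    "fit_gaussian",
    "fit_null",
    "speed_posterior",
    "step_probability",
    "fall_likelihood",
    "classify_fall",
]

SIGMA_FLOOR = 1e-6


@dataclass(frozen=True)
class GaussianParams:
    lam: float  # mean
    sigma: float  # standard deviation

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    def logpdf(self, x: float) -> float:
        z = (x - self.lam) / self.sigma
        return -0.5 * z * z - math.log(self.sigma * math.sqrt(2 * math.pi))

    def log_kernel(self, x: float) -> float:
        """Log of the peak-normalised kernel (1 at the mean)."""
        z = (x - self.lam) / self.sigma
        return -0.5 * z * z


@dataclass(frozen=True)
class SpeedGaussian:
    """Gaussian feature model for one cadence class."""

    mu_label: float  # steps/min
    f1: GaussianParams
    f2: GaussianParams


@dataclass(frozen=True)
class NullFeature:
    """Two-sided exponential-tail density for one feature of the null class.

    The density follows an upward exponential tail for ``f >= mu01``, a
    downward tail for ``f <= mu02`` and a flat plateau in between at the
    larger of the two tail boundary values; the whole shape is divided
    by its analytic integral so it is a proper density.
    """

    lam01: float  # upward tail rate
    mu01: float  # upward tail location (upper quartile)
    lam02: float  # downward tail rate
    mu02: float  # downward tail location (lower quartile)

    def __post_init__(self) -> None:
        if not (self.lam01 > 0 and self.lam02 > 0):
            raise ValueError("null tail rates must be positive")
        if self.mu02 > self.mu01:
            raise ValueError("mu02 must not exceed mu01")

    @property
    def _norm(self) -> float:
        plateau = 0.5 * max(self.lam01, self.lam02)
        return 1.0 + plateau * (self.mu01 - self.mu02)

    def pdf(self, f: float) -> float:
        if f >= self.mu01:
            d = 0.5 * self.lam01 * math.exp(-self.lam01 * (f - self.mu01))
        elif f <= self.mu02:
            d = 0.5 * self.lam02 * math.exp(-self.lam02 * (self.mu02 - f))
        else:
            d = 0.5 * max(self.lam01, self.lam02)
        return d / self._norm

    def logpdf(self, f: float) -> float:
        p = self.pdf(f)
        return math.log(p) if p > 0 else -math.inf


@dataclass(frozen=True)
class NullModel:
    f1: NullFeature
    f2: NullFeature


@dataclass(frozen=True)
class SpeedModelSet:
    """Cadence Gaussians + null model + prior, order: [null, speeds...]."""

    speeds: tuple[SpeedGaussian, ...]
    null: NullModel
    prior: np.ndarray  # length len(speeds) + 1, null first
    delta_max: float = DEFAULT_DELTA_MAX

    def __post_init__(self) -> None:
        prior = np.asarray(self.prior, dtype=float)
        if prior.shape != (len(self.speeds) + 1,):
            raise ValueError(
                f"prior must have {len(self.speeds) + 1} entries, got {prior.shape}"
            )
        if np.any(prior < 0) or not math.isclose(prior.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("prior entries must be >= 0 and sum to 1")
        object.__setattr__(self, "prior", prior)
        object.__setattr__(self, "speeds", tuple(self.speeds))

    @property
    def cadences(self) -> tuple[float, ...]:
        return tuple(s.mu_label for s in self.speeds)


@dataclass(frozen=True)
class FallModel:
    f1: GaussianParams = field(default_factory=lambda: GaussianParams(*FALL_F1))
    f2: GaussianParams = field(default_factory=lambda: GaussianParams(*FALL_F2))
    tau2: float = DEFAULT_TAU2

    def __post_init__(self) -> None:
        if not 0 < self.tau2 < 1:
            raise ValueError(f"tau2 must lie in (0, 1), got {self.tau2}")


def _default_class_params() -> dict[str, tuple[GaussianParams, ...]]:
    return {
        c: tuple(GaussianParams(*FALL_CLASS[c][k]) for k in ("f1", "f2", "f3"))
        for c in FALL_CLASS_LABELS
    }


@dataclass(frozen=True)
class FallClassModel:
    """Per-class Gaussian kernels over the three impact-axis features."""

    classes: dict[str, tuple[GaussianParams, ...]] = field(
        default_factory=_default_class_params
    )
    thresholds: dict[str, float] | None = None
    fallback: str = "c3"

    def __post_init__(self) -> None:
        for label, trio in self.classes.items():
            if len(trio) != 3:
                raise ValueError(f"class {label!r} must have 3 feature models")


def fit_gaussian(samples) -> GaussianParams:
    """Sample mean and (n-1)-denominator std, std floored at 1e-6."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 samples to fit, got {x.size}")
    lam = float(x.mean())
    sigma = float(x.std(ddof=1))
    return GaussianParams(lam=lam, sigma=max(sigma, SIGMA_FLOOR))


def fit_null(samples) -> NullFeature:
    """Fit the two-sided exponential-tail null density for one feature.

    Tail locations are the sample quartiles; tail rates come from the
    method of moments on the mean excess beyond each quartile.  If a
    tail holds no samples its rate falls back to 1/std of the whole
    sample.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 4:
        raise ValueError(f"need at least 4 samples to fit null model, got {x.size}")
    mu01 = float(np.quantile(x, 0.75))
    mu02 = float(np.quantile(x, 0.25))
    fallback = 1.0 / max(float(x.std(ddof=1)), SIGMA_FLOOR)

    hi = x[x > mu01]
    lam01 = 1.0 / float(np.mean(hi - mu01)) if hi.size else fallback
    lo = x[x < mu02]
    lam02 = 1.0 / float(np.mean(mu02 - lo)) if lo.size else fallback
    return NullFeature(lam01=lam01, mu01=mu01, lam02=lam02, mu02=mu02)


def posterior_from_loglik(loglik: np.ndarray, prior: np.ndarray) -> np.ndarray:
    """Combine per-class log-likelihoods with a prior in log space.

    Returns the normalised posterior; if every class underflows the
    prior itself is returned.
    """
    with np.errstate(divide="ignore"):
        logprior = np.log(prior)
    logpost = np.asarray(loglik, dtype=float) + logprior
    if not np.any(np.isfinite(logpost)):
        return np.asarray(prior, dtype=float).copy()
    total = logsumexp(logpost[np.isfinite(logpost)])
    post = np.exp(logpost - total)
    post[~np.isfinite(logpost)] = 0.0
    return post / post.sum()


def speed_posterior(f: StepFeatures, m: SpeedModelSet) -> np.ndarray:
    """Posterior over ``[null, cadence_1, ..., cadence_k]`` given a window.

    Likelihoods multiply across the two features (independence) and are
    combined with the prior in log space; if every class underflows the
    prior itself is returned.
    """
    k = len(m.speeds)
    loglik = np.empty(k + 1)
    loglik[0] = m.null.f1.logpdf(f.f1) + m.null.f2.logpdf(f.f2)
    for i, sg in enumerate(m.speeds, start=1):
        loglik[i] = sg.f1.logpdf(f.f1) + sg.f2.logpdf(f.f2)
    return posterior_from_loglik(loglik, m.prior)


def step_probability(posterior: np.ndarray) -> float:
    """Probability the window holds a step: posterior mass off the null."""
    posterior = np.asarray(posterior, dtype=float)
    return float(1.0 - posterior[0])


def fall_likelihood(f: FallFeatures, m: FallModel) -> tuple[float, bool]:
    """Kernel-product fall score and thresholded decision.

    Score is the product of peak-normalised Gaussian kernels over the
    two fall features, so it lies in (0, 1] and equals 1 at the trained
    means; a fall is flagged when it exceeds ``tau2``.
    """
    log_score = m.f1.log_kernel(f.f1) + m.f2.log_kernel(f.f2)
    score = math.exp(log_score)
    return score, score > m.tau2


def classify_fall(
    f: FallClassFeatures, m: FallClassModel
) -> tuple[str, dict[str, float]]:
    """Assign a detected fall to a class by kernel-product score.

    Returns the argmax class (ties broken by class order) and all
    per-class scores.  With thresholds set, classes scoring below their
    threshold are excluded and the fallback class is used if none pass.
    """
    values = (f.f1, f.f2, f.f3)
    scores: dict[str, float] = {}
    for label, trio in m.classes.items():
        log_score = sum(g.log_kernel(v) for g, v in zip(trio, values))
        scores[label] = math.exp(log_score)

    candidates = list(m.classes)
    if m.thresholds is not None:
        candidates = [c for c in candidates if scores[c] > m.thresholds.get(c, 0.0)]
        if not candidates:
            return m.fallback, scores
    best = candidates[0]
    for c in candidates[1:]:  # strict > keeps the earliest class on ties
        if scores[c] > scores[best]:
            best = c
    return best, scores


def default_speed_gaussians() -> tuple[SpeedGaussian, ...]:
    """The shipped per-cadence step feature Gaussians."""
    return tuple(
        SpeedGaussian(
            mu_label=float(c),
            f1=GaussianParams(*STEP_F1[c]),
            f2=GaussianParams(*STEP_F2[c]),
        )
        for c in sorted(STEP_F1)
    )
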