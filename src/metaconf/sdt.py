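"""Generative signal-detection model of choice and confidence.

An observer sees a noisy internal sample ``X_pre ~ N(d*theta_pre, 1)`` of a
two-alternative stimulus with true side ``d`` in {-1, +1}, commits to an
action by comparing the sample to a criterion ``m``, and (optionally) receives
a second, post-decision sample ``X_post ~ N(d*theta_post, 1)``.  Confidence is
the posterior probability that the action was correct, computed from the
log-likelihood ratio of the two sides under the observer's assumed evidence
distribution, and reported on a 9-point scale with Gaussian report noise.

Three variants perturb the ideal (base) computation:

``temporal_weighting``
    separate multiplicative weights on pre- and post-decision log odds.
``choice_weighting``
    separate weights on post-decision log odds depending on whether the
    post-decision sample confirms or disconfirms the chosen side.
``choice_bias``
    a fixed increment of subjective probability ``w_bias`` for the chosen
    side, applied to the direction log odds before conditioning on the
    action; it applies with or without post-decision evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

__all__ = [
    "RATING_GRID",
    "CONF_EPS",
    "EvidenceStrengthPair",
    "LikelihoodMoments",
    "InternalSample",
    "VariantParams",
    "SubjectModelParams",
    "ConfidenceComputation",
    "mixture_moments",
    "single_moments",
    "lo_direction",
    "lo_correct",
    "combine_evidence",
    "lo_correct_total",
    "confidence_from_logodds",
    "decide",
    "simulate_report",
    "snap_to_grid",
]

#: The 9 allowed confidence ratings (scale endpoints labelled 0% and 100%).
RATING_GRID = np.linspace(0.0, 1.0, 9)

#: Confidence is clamped to [CONF_EPS, 1 - CONF_EPS] so that log-odds
#: round-trips stay finite.
CONF_EPS = 1e-6

Variant = Literal["base", "temporal_weighting", "choice_weighting", "choice_bias"]
VARIANTS = ("base", "temporal_weighting", "choice_weighting", "choice_bias")


@dataclass(frozen=True)
class EvidenceStrengthPair:
    """Internal evidence strengths (units of internal-noise SD) for the low
    and high stimulus-strength conditions."""

    mu_low: float
    mu_high: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu_low) and math.isfinite(self.mu_high)):
            raise ValueError("evidence strengths must be finite")
        if self.mu_low <= 0:
            raise ValueError("mu_low must be positive")
        if self.mu_high < self.mu_low:
            raise ValueError("mu_high must be >= mu_low")

    def theta_post(self, level: str) -> float:
        if level == "low":
            return self.mu_low
        if level == "high":
            return self.mu_high
        raise ValueError(f"unknown post-decision level {level!r}")


@dataclass(frozen=True)
class LikelihoodMoments:
    """Single-Gaussian approximation N(mu, sigma2) to the observer's assumed
    evidence distribution (conditional on the true side)."""

    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu) and math.isfinite(self.sigma2)):
            raise ValueError("moments must be finite")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


@dataclass(frozen=True)
class InternalSample:
    """Internal evidence on one trial."""

    d: int
    x_pre: float
    x_post: Optional[float] = None
    post_level: str = "none"

    def __post_init__(self) -> None:
        if self.d not in (-1, 1):
            raise ValueError("true side d must be -1 or +1")
        if (self.x_post is None) != (self.post_level == "none"):
            raise ValueError("x_post must be present iff post_level != 'none'")


@dataclass(frozen=True)
class VariantParams:
    """Weights of the active model variant; only that variant's fields are set."""

    variant: Variant = "base"
    w_pre: Optional[float] = None
    w_post: Optional[float] = None
    w_confirmatory: Optional[float] = None
    w_disconfirmatory: Optional[float] = None
    w_bias: Optional[float] = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        required = {
            "base": (),
            "temporal_weighting": ("w_pre", "w_post"),
            "choice_weighting": ("w_confirmatory", "w_disconfirmatory"),
            "choice_bias": ("w_bias",),
        }[self.variant]
        for name in ("w_pre", "w_post", "w_confirmatory", "w_disconfirmatory", "w_bias"):
            value = getattr(self, name)
            if name in required:
                if value is None or not math.isfinite(value):
                    raise ValueError(f"{self.variant} requires finite {name}")
            elif value is not None:
                raise ValueError(f"{name} is not a parameter of variant {self.variant}")
        if self.variant == "choice_bias" and not (0.0 < self.w_bias < 1.0):
            raise ValueError("w_bias must lie in the open interval (0, 1)")

    @classmethod
    def base(cls) -> "VariantParams":
        return cls("base")

    @classmethod
    def temporal(cls, w_pre: float, w_post: float) -> "VariantParams":
        return cls("temporal_weighting", w_pre=w_pre, w_post=w_post)

    @classmethod
    def choice_weighting(cls, w_confirmatory: float, w_disconfirmatory: float) -> "VariantParams":
        return cls(
            "choice_weighting",
            w_confirmatory=w_confirmatory,
            w_disconfirmatory=w_disconfirmatory,
        )

    @classmethod
    def choice_bias(cls, w_bias: float) -> "VariantParams":
        return cls("choice_bias", w_bias=w_bias)


@dataclass(frozen=True)
class SubjectModelParams:
    """Full generative parameter set for one subject."""

    m: float
    strengths: EvidenceStrengthPair
    sigma_report: float
    variant_params: VariantParams = field(default_factory=VariantParams.base)

    def __post_init__(self) -> None:
        if self.sigma_report <= 0:
            raise ValueError("sigma_report must be positive")
        if not math.isfinite(self.m):
            raise ValueError("criterion m must be finite")


@dataclass(frozen=True)
class ConfidenceComputation:
    """Decomposition of a confidence judgment into log-odds components."""

    lo_dir_pre: float
    lo_dir_post: float
    lo_bias: float
    lo_correct_total: float
    confidence: float


def mixture_moments(strengths: EvidenceStrengthPair) -> LikelihoodMoments:
    """Moments of the single-Gaussian approximation to the equal-probability
    two-strength mixture.

    The mean is the average of the two strengths; by the law of total
    variance the variance is the between-strength spread plus the unit
    within-strength variance.
    """
    mu = 0.5 * (strengths.mu_low + strengths.mu_high)
    sigma2 = (0.5 * (strengths.mu_high - strengths.mu_low)) ** 2 + 1.0
    return LikelihoodMoments(mu, sigma2)


def single_moments(theta: float) -> LikelihoodMoments:
    """Moments when a single known evidence strength applies (unit variance)."""
    return LikelihoodMoments(theta, 1.0)


def lo_direction(x, moments: LikelihoodMoments):
    """Log posterior odds of the rightward side given an internal sample.

    With flat priors this is the log Gaussian likelihood ratio
    ``log[N(x; mu, sigma2) / N(x; -mu, sigma2)]`` which simplifies to
    ``2*mu*x / sigma2``.
    """
    if moments.sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    return 2.0 * moments.mu * np.asarray(x, dtype=float) / moments.sigma2


def lo_correct(lo_dir, action: int):
    """Convert direction log odds into log odds of the choice being correct."""
    if action not in (-1, 1):
        raise ValueError("action must be -1 or +1")
    return action * np.asarray(lo_dir, dtype=float)


def confidence_from_logodds(lo, eps: float = CONF_EPS):
    """Logistic transform of log odds, clamped to [eps, 1-eps]."""
    lo = np.asarray(lo, dtype=float)
    with np.errstate(over="ignore"):
        conf = 1.0 / (1.0 + np.exp(-lo))
    return np.clip(conf, eps, 1.0 - eps)


def lo_correct_total(
    x_pre,
    x_post,
    action: int,
    params: SubjectModelParams,
    moments: LikelihoodMoments,
):
    """Vectorized total log odds correct under the subject's variant.

    ``x_post`` may be ``None`` (no post-decision evidence).  ``x_pre`` and
    ``x_post`` broadcast against each other; the same assumed ``moments``
    apply to both samples (the observer is agnostic about which strength
    generated which sample).
    """
    v = params.variant_params
    lc_pre = lo_correct(lo_direction(x_pre, moments), action)
    lc_post = 0.0 if x_post is None else lo_correct(lo_direction(x_post, moments), action)

    if v.variant == "base":
        return lc_pre + lc_post
    if v.variant == "temporal_weighting":
        return v.w_pre * lc_pre + v.w_post * lc_post
    if v.variant == "choice_weighting":
        if x_post is None:
            return lc_pre
        # sign(X_post) == sign(a)  <=>  a * lo_dir_post > 0  <=>  lc_post > 0
        weight = np.where(np.asarray(lc_post) > 0, v.w_confirmatory, v.w_disconfirmatory)
        return lc_pre + weight * lc_post
    if v.variant == "choice_bias":
        # LO_bias = logit(w_bias) for a = +1 and -logit(w_bias) for a = -1 is
        # added to the direction log odds before conditioning on the action;
        # conditioning multiplies by the action, so the correct-odds increment
        # is logit(w_bias) for either action.
        return lc_pre + lc_post + math.log(v.w_bias / (1.0 - v.w_bias))
    raise AssertionError(f"unhandled variant {v.variant}")


def combine_evidence(
    sample: InternalSample,
    params: SubjectModelParams,
    action: int,
    moments: LikelihoodMoments,
) -> ConfidenceComputation:
    """Combine pre- and (optional) post-decision evidence into confidence.

    Returns the full decomposition for one trial.  The choice-bias term is
    applied to the summed direction log odds with a sign set by the action
    and only then conditioned on the action; all other variants weight the
    action-conditioned components directly.
    """
    if action not in (-1, 1):
        raise ValueError("action must be -1 or +1")
    lo_pre = float(lo_direction(sample.x_pre, moments))
    lo_post = 0.0 if sample.x_post is None else float(lo_direction(sample.x_post, moments))
    v = params.variant_params
    lo_bias = 0.0
    if v.variant == "choice_bias":
        lo_bias = action * math.log(v.w_bias / (1.0 - v.w_bias))
    x_post = None if sample.x_post is None else sample.x_post
    total = float(lo_correct_total(sample.x_pre, x_post, action, params, moments))
    return ConfidenceComputation(
        lo_dir_pre=lo_pre,
        lo_dir_post=lo_post,
        lo_bias=lo_bias,
        lo_correct_total=total,
        confidence=float(confidence_from_logodds(total)),
    )


def decide(
    x_pre,
    m: float,
    slope: float = 1000.0,
    mode: str = "deterministic",
    rng: Optional[np.random.Generator] = None,
):
    """Map a pre-decision sample to an action in {-1, +1}.

    ``deterministic`` returns ``sign(x_pre - m)``; an exact tie is resolved
    by a fair coin (requires ``rng``).  ``stochastic`` draws +1 with
    probability ``logistic(slope * (x_pre - m))`` — the steep softmax used in
    the fitting likelihood (default slope 1000 makes it numerically a step).
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    x = np.asarray(x_pre, dtype=float)
    if mode == "deterministic":
        a = np.where(x > m, 1, -1)
        ties = x == m
        if np.any(ties):
            if rng is None:
                rng = np.random.default_rng()
            coin = np.where(rng.random(size=x.shape) < 0.5, 1, -1)
            a = np.where(ties, coin, a)
        return a if a.ndim else int(a)
    if mode == "stochastic":
        if rng is None:
            rng = np.random.default_rng()
        p = confidence_from_logodds(slope * (x - m), eps=0.0)
        a = np.where(rng.random(size=x.shape) < p, 1, -1)
        return a if a.ndim else int(a)
    raise ValueError(f"unknown decision mode {mode!r}")


def snap_to_grid(r):
    """Clip to [0, 1] and snap to the nearest of the 9 rating grid points."""
    r = np.clip(np.asarray(r, dtype=float), 0.0, 1.0)
    return np.round(r * 8.0) / 8.0


def simulate_report(confidence, sigma_report: float, rng: np.random.Generator):
    """Draw a rating: Gaussian report noise around model confidence, clipped
    to [0, 1] and snapped to the 9-point grid."""
    if sigma_report < 0:
        raise ValueError("sigma_report must be non-negative")
    conf = np.asarray(confidence, dtype=float)
    if sigma_report == 0:
        return snap_to_grid(conf)
    return snap_to_grid(conf + sigma_report * rng.standard_normal(size=conf.shape))
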