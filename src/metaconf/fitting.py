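"""MAP fitting of the confidence-model variants to choices and ratings.

The generative model has per-trial latent internal samples; the likelihood
of an observed (choice, rating) pair marginalizes them by deterministic
quadrature.  For task-1 trials this is a 1-D integral of the pre-decision
sample over the half-line selected by the choice (the slope-1000 softmax in
the model is numerically a step, so choice conditioning is a truncation);
task-2 trials add a Gauss-Hermite integral over the post-decision sample.
The truncated pre-decision integral uses a probability-transform
reparameterization (Gauss-Legendre nodes in the truncated CDF), which keeps
the integrand smooth regardless of where the criterion sits.

Estimation maximizes the log joint (likelihood plus the standard priors:
criterion N(0,1), report noise half-normal(0.1), weights N(1,1), choice
bias N(0.5,1) on the probability scale but optimized on the logit scale,
and evidence strengths N(d'/2, 1) anchored to the subject's observed d'
at each stimulus strength).  ``ConfidenceModel.fit`` returns a results
object with estimates, a Laplace covariance, diagnostics, ``summary()`` and
posterior-predictive simulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

from .metrics import dprime_criterion
from .sdt import (
    RATING_GRID,
    SubjectModelParams,
    VariantParams,
    confidence_from_logodds,
    decide,
    mixture_moments,
    simulate_report,
    single_moments,
)

__all__ = [
    "QuadratureConfig",
    "PriorSpec",
    "FitResult",
    "ConfidenceModel",
    "ConfidenceModelResults",
    "trial_loglik",
    "outcome_probabilities",
    "fit_subject",
    "fit_population",
    "posterior_predictive",
]

_SQRT2 = math.sqrt(2.0)
_SQRTPI = math.sqrt(math.pi)

#: rating-bin edges implied by clip-to-[0,1]-then-snap reporting
_BIN_EDGES = np.concatenate(([-np.inf], (RATING_GRID[:-1] + RATING_GRID[1:]) / 2.0, [np.inf]))


@dataclass(frozen=True)
class QuadratureConfig:
    """Node counts for the latent-sample integrals.

    ``n_pre`` Gauss-Legendre nodes for the truncated pre-decision sample,
    ``n_post`` Gauss-Hermite nodes for the post-decision sample.  Fewer than
    ``min_nodes`` nodes per dimension is refused: the rating density is
    sharp (sigma_report ~ 0.1) and very coarse grids bias the likelihood.
    """

    n_pre: int = 61
    n_post: int = 61
    min_nodes: int = 9

    def __post_init__(self) -> None:
        if self.n_pre < self.min_nodes or self.n_post < self.min_nodes:
            raise ValueError(f"quadrature needs at least {self.min_nodes} nodes per dimension")


@lru_cache(maxsize=8)
def _gl_nodes(n: int):
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w  # nodes/weights on (0, 1)


@lru_cache(maxsize=8)
def _gh_nodes(n: int):
    x, w = np.polynomial.hermite.hermgauss(n)
    return _SQRT2 * x, w / _SQRTPI  # E[f(mu + sigma Z)] = sum w f(mu + sigma x)


@dataclass(frozen=True)
class PriorSpec:
    """Priors of the fitting scheme (group scale); all SDs must be positive."""

    m_mean: float = 0.0
    m_sd: float = 1.0
    sigma_report_scale: float = 0.1
    weight_mean: float = 1.0
    weight_sd: float = 1.0
    wbias_mean: float = 0.5
    wbias_sd: float = 1.0
    strength_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("m_sd", "sigma_report_scale", "weight_sd", "wbias_sd", "strength_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


_WEIGHT_NAMES = {
    "base": (),
    "temporal_weighting": ("w_pre", "w_post"),
    "choice_weighting": ("w_confirmatory", "w_disconfirmatory"),
    "choice_bias": ("logit_w_bias",),
}

_BOUNDS = {
    "m": (-3.0, 3.0),
    "mu_low": (0.01, 6.0),
    "mu_high": (0.01, 8.0),
    "log_sigma_report": (math.log(0.01), math.log(0.8)),
    "w_pre": (-4.0, 6.0),
    "w_post": (-4.0, 6.0),
    "w_confirmatory": (-4.0, 6.0),
    "w_disconfirmatory": (-4.0, 6.0),
    "logit_w_bias": (-4.0, 4.0),
}


def _variant_from_names(variant: str, values: Dict[str, float]) -> VariantParams:
    if variant == "base":
        return VariantParams.base()
    if variant == "temporal_weighting":
        return VariantParams.temporal(values["w_pre"], values["w_post"])
    if variant == "choice_weighting":
        return VariantParams.choice_weighting(
            values["w_confirmatory"], values["w_disconfirmatory"]
        )
    if variant == "choice_bias":
        w = 1.0 / (1.0 + math.exp(-values["logit_w_bias"]))
        return VariantParams.choice_bias(min(max(w, 1e-6), 1.0 - 1e-6))
    raise ValueError(f"unknown variant {variant!r}")


def _combine(lc_pre, lc_post, vp: VariantParams):
    """Variant-specific combination of action-conditioned log odds (arrays)."""
    if vp.variant == "base":
        return lc_pre + lc_post
    if vp.variant == "temporal_weighting":
        return vp.w_pre * lc_pre + vp.w_post * lc_post
    if vp.variant == "choice_weighting":
        w = np.where(lc_post > 0, vp.w_confirmatory, vp.w_disconfirmatory)
        return lc_pre + w * lc_post
    if vp.variant == "choice_bias":
        return lc_pre + lc_post + math.log(vp.w_bias / (1.0 - vp.w_bias))
    raise AssertionError(vp.variant)


def _rating_kernel(conf, sigma: float, binned: bool):
    """Likelihood of each of the 9 grid ratings given model confidence.

    ``conf`` has shape (..., nodes).  Density mode evaluates the Gaussian
    report density at the grid value (the fitting likelihood); binned mode
    integrates the report density over each snap interval (exact outcome
    probabilities, summing to 1 over bins).
    Returns shape (..., 9, nodes).
    """
    c = conf[..., None, :]
    if binned:
        lo = _BIN_EDGES[:-1].reshape((1,) * (c.ndim - 2) + (-1, 1))
        hi = _BIN_EDGES[1:].reshape((1,) * (c.ndim - 2) + (-1, 1))
        return ndtr((hi - c) / sigma) - ndtr((lo - c) / sigma)
    r = RATING_GRID.reshape((1,) * (c.ndim - 2) + (-1, 1))
    z = (r - c) / sigma
    return np.exp(-0.5 * z * z) / (sigma * math.sqrt(2.0 * math.pi))


def _outcome_probs(
    m: float,
    mu_low: float,
    mu_high: float,
    sigma_report: float,
    vp: VariantParams,
    d: np.ndarray,
    a: np.ndarray,
    level: np.ndarray,
    quad: QuadratureConfig,
    binned: bool = False,
):
    """Joint outcome quantities for each (d, a, level) combination.

    Returns ``(p_region, p_r)`` where ``p_region[i] = P(a_i | d_i)`` under
    the step decision rule and ``p_r[i, k]`` is the rating likelihood
    (density at grid value k, or bin probability when ``binned``) given the
    choice.  Task-1 combinations are flagged by ``level == 'none'`` and use
    the single-strength likelihood moments; task-2 combinations use the
    agnostic mixture moments for both samples.
    """
    d = np.asarray(d, dtype=float)
    a = np.asarray(a, dtype=float)
    level = np.asarray(level)
    n = len(d)
    p_region = np.empty(n)
    p_r = np.empty((n, len(RATING_GRID)))

    u, wu = _gl_nodes(quad.n_pre)
    mu_mix = 0.5 * (mu_low + mu_high)
    s2_mix = (0.5 * (mu_high - mu_low)) ** 2 + 1.0

    def pre_nodes(dd, aa):
        # truncated-normal probability transform on the half-line chosen by a
        mean = dd * mu_low
        p_reg = ndtr(aa * (mean - m))
        base = np.where(aa > 0, 1.0 - p_reg, 0.0)
        inner = np.clip(base[:, None] + u[None, :] * p_reg[:, None], 1e-15, 1 - 1e-15)
        return p_reg, mean[:, None] + ndtri(inner)

    is_t1 = level == "none"
    if is_t1.any():
        dd, aa = d[is_t1], a[is_t1]
        p_reg, x = pre_nodes(dd, aa)
        lc_pre = aa[:, None] * (2.0 * mu_low * x)  # task-1 moments: mu=mu_low, var=1
        conf = confidence_from_logodds(_combine(lc_pre, np.zeros_like(lc_pre), vp))
        kern = _rating_kernel(conf, sigma_report, binned)  # (n1, 9, n_pre)
        p_region[is_t1] = p_reg
        p_r[is_t1] = kern @ wu

    is_t2 = ~is_t1
    if is_t2.any():
        dd, aa = d[is_t2], a[is_t2]
        theta_post = np.where(level[is_t2] == "high", mu_high, mu_low)
        p_reg, x_pre = pre_nodes(dd, aa)
        h, wh = _gh_nodes(quad.n_post)
        x_post = dd[:, None] * theta_post[:, None] + h[None, :]
        coef = 2.0 * mu_mix / s2_mix
        lc_pre = aa[:, None, None] * (coef * x_pre[:, :, None])
        lc_post = aa[:, None, None] * (coef * x_post[:, None, :])
        conf = confidence_from_logodds(_combine(lc_pre, lc_post, vp))
        conf = conf.reshape(conf.shape[0], -1)  # (n2, n_pre*n_post)
        kern = _rating_kernel(conf, sigma_report, binned)  # (n2, 9, n_pre*n_post)
        w2 = (wu[:, None] * wh[None, :]).ravel()
        p_region[is_t2] = p_reg
        p_r[is_t2] = kern @ w2
    return p_region, p_r


def outcome_probabilities(
    params: SubjectModelParams,
    d: int,
    post_level: str = "none",
    quadrature: QuadratureConfig = QuadratureConfig(),
) -> np.ndarray:
    """Probability table of the 18 discrete outcomes (choice x snapped rating)
    on a trial with true side ``d``; rows are actions (-1, +1), columns the 9
    grid ratings.  Rows of the full table sum to 1 across all 18 cells."""
    vp = params.variant_params
    p_region, p_r = _outcome_probs(
        params.m,
        params.strengths.mu_low,
        params.strengths.mu_high,
        params.sigma_report,
        vp,
        d=np.array([d, d]),
        a=np.array([-1.0, 1.0]),
        level=np.array([post_level, post_level]),
        quad=quadrature,
        binned=True,
    )
    return p_region[:, None] * p_r


def trial_loglik(
    params: SubjectModelParams,
    observation: tuple,
    quadrature: QuadratureConfig = QuadratureConfig(),
    rating_mode: str = "density",
) -> float:
    """Log probability of one observed trial ``(d, post_level, a, r)``.

    ``rating_mode='density'`` treats the rating as a continuous value with
    Gaussian report noise (the fitting likelihood); ``'binned'`` uses the
    probability of the snapped rating bin.
    """
    d, post_level, a, r = observation
    if a not in (-1, 1):
        raise ValueError("action must be -1 or +1")
    if not (0.0 <= r <= 1.0):
        raise ValueError("rating must lie in [0, 1]")
    idx = int(round(r * 8))
    if abs(r - RATING_GRID[idx]) > 1e-9:
        raise ValueError("rating is not on the 9-point grid")
    p_region, p_r = _outcome_probs(
        params.m,
        params.strengths.mu_low,
        params.strengths.mu_high,
        params.sigma_report,
        params.variant_params,
        d=np.array([d], dtype=float),
        a=np.array([a], dtype=float),
        level=np.array([post_level]),
        quad=quadrature,
        binned=(rating_mode == "binned"),
    )
    return float(np.log(max(p_region[0] * p_r[0, idx], 1e-300)))


def _rating_index(r: np.ndarray) -> np.ndarray:
    idx = np.round(r * 8).astype(int)
    if np.any(np.abs(r - RATING_GRID[idx]) > 1e-9):
        raise ValueError("ratings must lie on the 9-point grid")
    return idx


class ConfidenceModel:
    """Confidence-model likelihood for one subject's task-1/task-2 trials.

    Parameters
    ----------
    trials : DataFrame
        One subject's trial table (simulator schema).  Calibration rows, if
        present, provide the high-strength d' that anchors the mu_high
        prior; task rows provide the likelihood.  Missed trials are dropped.
    variant : str
        'base', 'temporal_weighting', 'choice_weighting' or 'choice_bias'.
    sigma_report : float, optional
        Fix the report-noise SD instead of estimating it (used when a
        population-level value is shared across subjects).
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        variant: str = "base",
        priors: Optional[PriorSpec] = None,
        quadrature: Optional[QuadratureConfig] = None,
        dprime_low: Optional[float] = None,
        dprime_high: Optional[float] = None,
        sigma_report: Optional[float] = None,
        rating_mode: str = "binned",
    ) -> None:
        if variant not in _WEIGHT_NAMES:
            raise ValueError(f"unknown variant {variant!r}")
        if rating_mode not in ("binned", "density"):
            raise ValueError("rating_mode must be 'binned' or 'density'")
        self.rating_mode = rating_mode
        self.variant = variant
        self.priors = priors or PriorSpec()
        self.quadrature = quadrature or QuadratureConfig()
        self.fixed_sigma_report = sigma_report
        self.subject_id = (
            str(trials["subject_id"].iloc[0]) if "subject_id" in trials and len(trials) else "s0"
        )

        tasks = trials[trials.phase.isin(("task1", "task2"))] if "phase" in trials else trials
        if "missed" in tasks.columns:
            tasks = tasks[tasks.missed == 0]
        tasks = tasks.dropna(subset=["choice", "confidence"])
        if len(tasks) == 0:
            raise ValueError("empty dataset: no usable task trials")
        self.nobs = len(tasks)

        if dprime_low is None:
            dprime_low, _ = dprime_criterion(tasks)
        calib = (
            trials[(trials.phase == "calibration") & (trials.get("calib_high", 0) == 1)]
            if "phase" in trials
            else trials.iloc[0:0]
        )
        if dprime_high is None:
            if len(calib) >= 10:
                dprime_high, _ = dprime_criterion(calib)
            else:
                # no high-strength calibration probes available: scale the
                # low-strength d' by the nominal strength ratio
                dprime_high = 1.5 * dprime_low
        self.dprime_low = max(float(dprime_low), 0.05)
        self.dprime_high = max(float(dprime_high), self.dprime_low)

        # collapse trials into (d, a, level) combinations x rating counts
        level = np.where(
            tasks.phase.to_numpy() == "task1", "none", tasks.post_level.to_numpy()
        )
        key = pd.DataFrame(
            dict(d=tasks["d"].to_numpy(int), a=tasks["choice"].to_numpy(int), level=level)
        )
        ridx = _rating_index(tasks["confidence"].to_numpy(float))
        groups = key.groupby(["d", "a", "level"], sort=True).indices
        combos, counts = [], []
        for (dd, aa, lev), rows in groups.items():
            combos.append((dd, aa, lev))
            c = np.zeros(len(RATING_GRID))
            np.add.at(c, ridx[rows], 1.0)
            counts.append(c)
        self._d = np.array([c[0] for c in combos], dtype=float)
        self._a = np.array([c[1] for c in combos], dtype=float)
        self._level = np.array([c[2] for c in combos])
        self._counts = np.array(counts)

        self.param_names: List[str] = ["m", "mu_low", "mu_high"]
        if self.fixed_sigma_report is None:
            self.param_names.append("log_sigma_report")
        self.param_names += list(_WEIGHT_NAMES[variant])

    # -- objective ---------------------------------------------------------

    def _unpack(self, x: np.ndarray) -> Dict[str, float]:
        return dict(zip(self.param_names, x))

    def loglike(self, x: np.ndarray) -> float:
        """Marginal log likelihood of all trials at parameter vector ``x``."""
        v = self._unpack(np.asarray(x, dtype=float))
        sigma = (
            self.fixed_sigma_report
            if self.fixed_sigma_report is not None
            else math.exp(v["log_sigma_report"])
        )
        vp = _variant_from_names(self.variant, v)
        p_region, p_r = _outcome_probs(
            v["m"], v["mu_low"], v["mu_high"], sigma, vp,
            self._d, self._a, self._level, self.quadrature,
            binned=self.rating_mode == "binned",
        )
        ll = self._counts * (
            np.log(np.maximum(p_r, 1e-300)) + np.log(np.maximum(p_region, 1e-300))[:, None]
        )
        return float(ll.sum())

    def logprior(self, x: np.ndarray) -> float:
        v = self._unpack(np.asarray(x, dtype=float))
        pr = self.priors
        lp = -0.5 * ((v["m"] - pr.m_mean) / pr.m_sd) ** 2
        lp += -0.5 * ((v["mu_low"] - self.dprime_low / 2.0) / pr.strength_sd) ** 2
        lp += -0.5 * ((v["mu_high"] - self.dprime_high / 2.0) / pr.strength_sd) ** 2
        if self.fixed_sigma_report is None:
            sigma = math.exp(v["log_sigma_report"])
            lp += -0.5 * (sigma / pr.sigma_report_scale) ** 2
        for name in _WEIGHT_NAMES[self.variant]:
            if name == "logit_w_bias":
                w = 1.0 / (1.0 + math.exp(-v[name]))
                lp += -0.5 * ((w - pr.wbias_mean) / pr.wbias_sd) ** 2
            else:
                lp += -0.5 * ((v[name] - pr.weight_mean) / pr.weight_sd) ** 2
        return float(lp)

    def logjoint(self, x: np.ndarray) -> float:
        return self.loglike(x) + self.logprior(x)

    def _start(self) -> np.ndarray:
        v = dict(
            m=0.0,
            mu_low=min(max(self.dprime_low / 2.0, 0.05), 5.9),
            mu_high=min(max(self.dprime_high / 2.0, 0.05), 7.9),
            log_sigma_report=math.log(0.1),
            w_pre=1.0, w_post=1.0, w_confirmatory=1.0, w_disconfirmatory=1.0,
            logit_w_bias=0.0,
        )
        return np.array([v[name] for name in self.param_names])

    def fit(
        self,
        start_params: Optional[np.ndarray] = None,
        n_starts: int = 5,
        seed: int = 0,
        maxiter: int = 300,
    ) -> "ConfidenceModelResults":
        """Maximize the log joint by multi-start L-BFGS-B.

        The first start is the informed one (d'-anchored strengths, prior
        means for the weights); remaining starts perturb it with seeded
        Gaussian noise (clipped to bounds).
        """
        rng = np.random.default_rng(seed)
        bounds = [_BOUNDS[name] for name in self.param_names]
        x0 = self._start() if start_params is None else np.asarray(start_params, dtype=float)
        starts = [x0]
        scale = np.array(
            [0.3 if n in ("m",) else 0.5 if n.startswith(("w", "logit")) else 0.3
             for n in self.param_names]
        )
        for _ in range(max(n_starts - 1, 0)):
            cand = x0 + scale * rng.standard_normal(len(x0))
            starts.append(np.clip(cand, [b[0] for b in bounds], [b[1] for b in bounds]))

        def objective(x):
            return -self.logjoint(x)

        best = None
        n_converged = 0
        for s in starts:
            res = minimize(
                objective, s, method="L-BFGS-B", bounds=bounds,
                options=dict(maxiter=maxiter, ftol=1e-9),
            )
            n_converged += bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        if n_converged == 0:
            warnings.warn(
                f"no start converged for subject {self.subject_id} ({self.variant})",
                RuntimeWarning,
            )
        return ConfidenceModelResults(
            model=self,
            params_vector=np.asarray(best.x, dtype=float),
            llf=-float(best.fun),
            converged=bool(n_converged > 0),
            n_starts=len(starts),
            optimizer_message=str(best.message),
        )


@dataclass
class FitResult:
    """Flat per-subject fit record used by the model-comparison battery."""

    subject_id: str
    variant: str
    params: Dict[str, float]
    llf: float
    converged: bool


class ConfidenceModelResults:
    """MAP estimates and diagnostics for one subject x variant."""

    def __init__(self, model, params_vector, llf, converged, n_starts, optimizer_message=""):
        self.model = model
        self.params_vector = params_vector
        self.llf = llf
        self.converged = converged
        self.n_starts = n_starts
        self.optimizer_message = optimizer_message
        self._cov = None

    @property
    def params(self) -> Dict[str, float]:
        """Estimates on natural scales (sigma_report in rating units,
        w_bias as a probability)."""
        v = dict(zip(self.model.param_names, self.params_vector))
        out = dict(
            m=v["m"], mu_low=v["mu_low"], mu_high=v["mu_high"],
            sigma_report=(
                self.model.fixed_sigma_report
                if self.model.fixed_sigma_report is not None
                else math.exp(v["log_sigma_report"])
            ),
        )
        for name in _WEIGHT_NAMES[self.model.variant]:
            if name == "logit_w_bias":
                out["w_bias"] = 1.0 / (1.0 + math.exp(-v[name]))
            else:
                out[name] = v[name]
        return out

    def subject_params(self) -> SubjectModelParams:
        """Fitted parameters as a generative parameter set."""
        from .sdt import EvidenceStrengthPair

        p = self.params
        mu_low = max(p["mu_low"], 1e-6)
        return SubjectModelParams(
            m=p["m"],
            strengths=EvidenceStrengthPair(mu_low, max(p["mu_high"], mu_low)),
            sigma_report=max(p["sigma_report"], 1e-6),
            variant_params=_variant_from_names(
                self.model.variant,
                dict(zip(self.model.param_names, self.params_vector)),
            ),
        )

    def cov_params(self) -> np.ndarray:
        """Laplace covariance: inverse Hessian of the negative log joint at
        the optimum (pseudo-inverse with a small ridge if ill-conditioned)."""
        if self._cov is None:
            from statsmodels.tools.numdiff import approx_hess

            H = approx_hess(self.params_vector, lambda x: -self.model.logjoint(x))
            H = 0.5 * (H + H.T)
            try:
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(H + 1e-6 * np.eye(len(H)))
            diag = np.diag(cov).copy()
            if np.any(diag <= 0):  # saddle or bound-pinned direction
                cov = np.linalg.pinv(H + (abs(diag.min()) + 1e-4) * np.eye(len(H)))
            self._cov = cov
        return self._cov

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.maximum(np.diag(self.cov_params()), 0.0))

    def to_fit_result(self) -> FitResult:
        return FitResult(
            subject_id=self.model.subject_id,
            variant=self.model.variant,
            params=self.params,
            llf=self.llf,
            converged=self.converged,
        )

    def summary(self) -> str:
        lines = [
            "Confidence model fit",
            f"  subject: {self.model.subject_id}   variant: {self.model.variant}",
            f"  n trials: {self.model.nobs}   log joint: {self.llf:.2f}"
            f"   converged: {self.converged} ({self.n_starts} starts)",
            f"  {'parameter':<16}{'estimate':>10}{'std err':>10}",
        ]
        bse = self.bse
        for i, name in enumerate(self.model.param_names):
            lines.append(f"  {name:<16}{self.params_vector[i]:>10.4f}{bse[i]:>10.4f}")
        extras = self.params
        if "w_bias" in extras:
            lines.append(f"  {'w_bias':<16}{extras['w_bias']:>10.4f}{'':>10}")
        if self.model.fixed_sigma_report is not None:
            lines.append(f"  sigma_report fixed at {self.model.fixed_sigma_report:.4f}")
        return "\n".join(lines)

    def draw_params(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """Draws from the Gaussian (Laplace) approximation around the MAP;
        a single draw returns the MAP itself."""
        if n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if n_draws == 1:
            return self.params_vector[None, :]
        cov = self.cov_params()
        return rng.multivariate_normal(self.params_vector, cov, size=n_draws, method="svd")

    def simulate(
        self,
        n_trials: int,
        rng: np.random.Generator,
        params_vector: Optional[np.ndarray] = None,
    ) -> pd.DataFrame:
        """Simulate ``n_trials`` per condition (task1 / task2-low /
        task2-high) from the fitted (or supplied) parameters; returns
        per-trial condition, accuracy and rating."""
        if n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        x = self.params_vector if params_vector is None else np.asarray(params_vector, float)
        v = dict(zip(self.model.param_names, np.clip(
            x, [_BOUNDS[n][0] for n in self.model.param_names],
            [_BOUNDS[n][1] for n in self.model.param_names],
        )))
        sigma = (
            self.model.fixed_sigma_report
            if self.model.fixed_sigma_report is not None
            else math.exp(v["log_sigma_report"])
        )
        vp = _variant_from_names(self.model.variant, v)
        mu_low, mu_high = max(v["mu_low"], 1e-6), max(v["mu_high"], v["mu_low"], 1e-6)
        mix_mu = 0.5 * (mu_low + mu_high)
        mix_s2 = (0.5 * (mu_high - mu_low)) ** 2 + 1.0
        frames = []
        for condition, level in (("task1", None), ("task2_low", "low"), ("task2_high", "high")):
            d = rng.choice((-1, 1), size=n_trials)
            x_pre = d * mu_low + rng.standard_normal(n_trials)
            actions = np.asarray(decide(x_pre, v["m"], rng=rng))
            if level is None:
                lc_pre = actions * 2.0 * mu_low * x_pre
                total = _combine(lc_pre, np.zeros_like(lc_pre), vp)
            else:
                theta_post = mu_high if level == "high" else mu_low
                x_post = d * theta_post + rng.standard_normal(n_trials)
                coef = 2.0 * mix_mu / mix_s2
                total = _combine(actions * coef * x_pre, actions * coef * x_post, vp)
            conf = confidence_from_logodds(total)
            rating = simulate_report(conf, sigma, rng)
            frames.append(
                pd.DataFrame(
                    dict(condition=condition, accuracy=(actions == d).astype(int),
                         confidence=rating)
                )
            )
        return pd.concat(frames, ignore_index=True)


def fit_subject(
    trials: pd.DataFrame,
    variant: str = "choice_bias",
    priors: Optional[PriorSpec] = None,
    quadrature: Optional[QuadratureConfig] = None,
    sigma_report: Optional[float] = None,
    n_starts: int = 5,
    seed: int = 0,
) -> ConfidenceModelResults:
    """Fit one variant to one subject's trial table (convenience wrapper
    around :class:`ConfidenceModel`)."""
    model = ConfidenceModel(
        trials, variant=variant, priors=priors, quadrature=quadrature,
        sigma_report=sigma_report,
    )
    return model.fit(n_starts=n_starts, seed=seed)


def fit_population(
    subject_tables: Sequence[pd.DataFrame],
    variant: str = "choice_bias",
    priors: Optional[PriorSpec] = None,
    quadrature: Optional[QuadratureConfig] = None,
    hierarchical: bool = False,
    share_sigma_report: bool = True,
    sigma_report: Optional[float] = None,
    n_starts: int = 2,
    seed: int = 0,
    pilot_size: int = 10,
    max_em_iter: int = 5,
    em_tol: float = 1e-2,
) -> List[ConfidenceModelResults]:
    """Fit a variant to every subject of a population.

    With ``share_sigma_report`` the report noise is estimated once (median
    of free-sigma base-model fits on up to 10 subjects) and then fixed for
    all per-subject fits, mirroring a group-level report-noise parameter.
    ``hierarchical=True`` additionally iterates empirical-Bayes updates of
    the group means/SDs of the criterion and weight priors (fixed-point
    scheme) until the group means move less than ``em_tol``; estimates then
    shrink toward the group mean.
    """
    subject_tables = list(subject_tables)
    if len(subject_tables) == 0:
        raise ValueError("no subjects to fit")
    priors = priors or PriorSpec()
    if hierarchical and len(subject_tables) < 2:
        warnings.warn(
            "hierarchical fitting needs >= 2 subjects; falling back to an independent fit",
            RuntimeWarning,
        )
        hierarchical = False

    sigma_shared = sigma_report
    if share_sigma_report and sigma_shared is None:
        pilot = subject_tables[: min(pilot_size, len(subject_tables))]
        sig = []
        for t in pilot:
            res = ConfidenceModel(t, "base", priors=priors, quadrature=quadrature).fit(
                n_starts=1, seed=seed
            )
            sig.append(res.params["sigma_report"])
        sigma_shared = float(np.median(sig))

    def fit_all(pr: PriorSpec) -> List[ConfidenceModelResults]:
        out = []
        for i, t in enumerate(subject_tables):
            model = ConfidenceModel(
                t, variant=variant, priors=pr, quadrature=quadrature,
                sigma_report=sigma_shared,
            )
            out.append(model.fit(n_starts=n_starts, seed=seed + i))
        return out

    results = fit_all(priors)
    if hierarchical:
        pr = priors
        for _ in range(max_em_iter):
            ests = pd.DataFrame([r.params for r in results])
            new_m_mean = float(ests["m"].mean())
            new_m_sd = float(max(ests["m"].std(ddof=1), 0.05))
            updates = dict(m_mean=new_m_mean, m_sd=new_m_sd)
            wnames = [n for n in _WEIGHT_NAMES[variant] if n != "logit_w_bias"]
            if wnames:
                vals = np.concatenate([ests[n].to_numpy() for n in wnames])
                updates["weight_mean"] = float(vals.mean())
                updates["weight_sd"] = float(max(vals.std(ddof=1), 0.05))
            if variant == "choice_bias":
                updates["wbias_mean"] = float(ests["w_bias"].mean())
                updates["wbias_sd"] = float(max(ests["w_bias"].std(ddof=1), 0.02))
            delta = max(
                abs(updates["m_mean"] - pr.m_mean),
                abs(updates.get("weight_mean", pr.weight_mean) - pr.weight_mean),
                abs(updates.get("wbias_mean", pr.wbias_mean) - pr.wbias_mean),
            )
            pr = replace(pr, **updates)
            results = fit_all(pr)
            if delta < em_tol:
                break
    return results


def fits_frame(results: Sequence[ConfidenceModelResults]) -> pd.DataFrame:
    """One row of fitted parameters per subject."""
    rows = []
    for r in results:
        row = dict(subject_id=r.model.subject_id, variant=r.model.variant,
                   llf=r.llf, converged=r.converged)
        row.update(r.params)
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def posterior_predictive(
    results: Sequence[ConfidenceModelResults],
    composite_scores: pd.Series,
    n_draws: int = 100,
    n_trials: int = 4000,
    rng: Optional[np.random.Generator] = None,
    radical_fraction: float = 0.10,
) -> pd.DataFrame:
    """Posterior-predictive confidence table split by radicalism decile.

    For each subject, draws ``n_draws`` parameter vectors from the Laplace
    approximation around the MAP (a single draw uses the MAP itself),
    simulates ``n_trials`` per condition per draw, and averages rating by
    condition x accuracy.  Subjects in the top ``radical_fraction`` of the
    composite score form the 'radical' group; cell means carry 95%
    confidence intervals across subjects.
    """
    if n_draws < 1 or n_trials < 1:
        raise ValueError("n_draws and n_trials must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    per_subject = []
    for res in results:
        draws = res.draw_params(n_draws, rng)
        acc_cells: Dict[tuple, list] = {}
        for draw in draws:
            sim = res.simulate(n_trials, rng, params_vector=draw)
            g = sim.groupby(["condition", "accuracy"]).confidence.mean()
            for key, val in g.items():
                acc_cells.setdefault(key, []).append(val)
        row = {key: float(np.mean(vals)) for key, vals in acc_cells.items()}
        row["subject_id"] = res.model.subject_id
        per_subject.append(row)
    table = pd.DataFrame(per_subject).set_index("subject_id")

    scores = composite_scores.loc[table.index]
    n_rad = int(round(radical_fraction * len(scores)))
    n_rad = max(n_rad, 1)
    radical_ids = scores.sort_values(ascending=False).index[:n_rad]
    group = pd.Series(
        np.where(table.index.isin(radical_ids), "radical", "moderate"), index=table.index
    )
    rows = []
    for grp, sub in table.groupby(group):
        for col in [c for c in table.columns]:
            vals = sub[col].dropna().to_numpy(float)
            if len(vals) == 0:
                continue
            mean = vals.mean()
            se = vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0
            condition, acc = col
            rows.append(
                dict(group=grp, condition=condition,
                     accuracy="correct" if acc == 1 else "incorrect",
                     mean_confidence=mean,
                     ci_low=mean - 1.96 * se, ci_high=mean + 1.96 * se,
                     n_subjects=len(vals))
            )
    return pd.DataFrame(rows)
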