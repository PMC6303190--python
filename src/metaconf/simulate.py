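"""Synthetic-data generator for the dot-density confidence experiment.

Emulates the experimental session of a web-based perceptual study: a
120-trial calibration phase (70-trial 2-down-1-up staircase on the log dot
difference targeting ~71% correct, with 50 interleaved trials at a 1.3x
higher log strength), a 60-trial confidence task (task 1) and a 120-trial
post-decision evidence task (task 2), for simulated signal-detection
observers.  A population generator plants the questionnaire factor
structure (political orientation, dogmatic intolerance, authoritarianism)
and a configurable coupling between composite radicalism and the
choice-bias parameter of the generating confidence model.

Physical stimulus strength (log dot difference) maps to internal evidence
strength through a power psychometric function ``theta = k * logdiff**gamma``;
the staircase itself is self-calibrating, so the map's role is to set how
much more discriminable the 1.3x-log-strength stimulus is.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .sdt import (
    EvidenceStrengthPair,
    SubjectModelParams,
    VariantParams,
    confidence_from_logodds,
    decide,
    lo_correct_total,
    mixture_moments,
    simulate_report,
    single_moments,
)

__all__ = [
    "REFERENCE_DOTS",
    "MAX_DOT_DIFFERENCE",
    "LOG_STRENGTH_BOUNDS",
    "TRIAL_COLUMNS",
    "StimulusSpec",
    "StaircaseState",
    "CalibrationConfig",
    "CalibrationResult",
    "ObserverSpec",
    "RadicalismProfile",
    "PopulationConfig",
    "SimulatedSubject",
    "staircase_step",
    "psychometric_theta",
    "run_calibration",
    "simulate_task1",
    "simulate_task2",
    "simulate_subject",
    "generate_population",
    "population_trials",
    "population_profiles",
    "write_dataset",
    "read_dataset",
]

#: The reference square always holds 313 of the 625 grid cells filled.
REFERENCE_DOTS = 313
#: The comparison square can exceed the reference by at most 625 - 313 cells.
MAX_DOT_DIFFERENCE = 312
#: Staircase bounds on the log dot difference.
LOG_STRENGTH_BOUNDS = (0.0, math.log(MAX_DOT_DIFFERENCE))

TRIAL_COLUMNS = [
    "subject_id",
    "phase",
    "trial",
    "d",
    "log_strength_pre",
    "post_level",
    "choice",
    "accuracy",
    "confidence",
    "confidence_rt_ms",
    "missed",
    "calib_high",
]

PHASES = ("calibration", "task1", "task2")


@dataclass(frozen=True)
class StimulusSpec:
    """Physical stimulus on one trial: dot difference and true side."""

    dot_difference: int
    d: int
    reference_dots: int = REFERENCE_DOTS

    def __post_init__(self) -> None:
        if not (1 <= self.dot_difference <= MAX_DOT_DIFFERENCE):
            raise ValueError("dot_difference outside the 625-cell grid bounds")
        if self.d not in (-1, 1):
            raise ValueError("d must be -1 or +1")

    @property
    def log_dot_difference(self) -> float:
        return math.log(self.dot_difference)


@dataclass(frozen=True)
class StaircaseState:
    """State of the 2-down-1-up staircase on log dot difference."""

    log_strength: float
    consecutive_correct: int = 0
    step_size: float = 0.1
    trial_index: int = 0
    history: tuple = ()

    def __post_init__(self) -> None:
        if self.consecutive_correct not in (0, 1):
            raise ValueError("consecutive_correct counter must be 0 or 1")


def staircase_step(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the 2-down-1-up staircase by one judged trial.

    An error raises the strength by one step and resets the counter; two
    consecutive correct responses lower it by one step.  The asymptotic
    accuracy of this rule is sqrt(0.5) ~ 70.7% correct.  Strength is clipped
    to the physical stimulus bounds.
    """
    lo, hi = LOG_STRENGTH_BOUNDS
    strength = state.log_strength
    if correct:
        if state.consecutive_correct == 1:
            strength = max(lo, strength - state.step_size)
            counter = 0
        else:
            counter = 1
    else:
        strength = min(hi, strength + state.step_size)
        counter = 0
    return replace(
        state,
        log_strength=strength,
        consecutive_correct=counter,
        trial_index=state.trial_index + 1,
        history=state.history + (state.log_strength,),
    )


@dataclass(frozen=True)
class ObserverSpec:
    """Generative ground truth for one simulated subject.

    ``k`` and ``gamma`` define the psychometric map from log dot difference
    to internal evidence strength; the remaining fields parameterize the
    confidence model, rating behavior and lapses.
    """

    k: float = 0.065
    gamma: float = 1.6
    m: float = 0.0
    sigma_report: float = 0.1
    variant_params: VariantParams = field(default_factory=VariantParams.base)
    rt_median_ms: float = 1500.0
    rt_sigma_log: float = 0.4
    miss_probability: float = 0.01
    single_rating_collapse: Optional[float] = None

    def __post_init__(self) -> None:
        if self.k <= 0 or self.gamma <= 0:
            raise ValueError("psychometric gain and exponent must be positive")
        if not (0.0 <= self.miss_probability < 1.0):
            raise ValueError("miss_probability must be in [0, 1)")

    def model_params(self, low_log_strength: float, high_log_strength: float) -> SubjectModelParams:
        theta_low = psychometric_theta(low_log_strength, self)
        theta_high = psychometric_theta(high_log_strength, self)
        return SubjectModelParams(
            m=self.m,
            strengths=EvidenceStrengthPair(theta_low, max(theta_low, theta_high)),
            sigma_report=max(self.sigma_report, 1e-9),
            variant_params=self.variant_params,
        )


def psychometric_theta(log_strength: float, observer: ObserverSpec):
    """Internal evidence strength for a given log dot difference:
    ``theta = k * log_strength**gamma``."""
    ls = np.asarray(log_strength, dtype=float)
    if np.any(ls <= 0):
        raise ValueError("log_strength must be positive")
    out = observer.k * ls**observer.gamma
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CalibrationConfig:
    n_staircase: int = 70
    n_high: int = 50
    burn_in: int = 20
    step_size: float = 0.1
    start_dot_difference: int = 70
    last_n: int = 25
    high_factor: float = 1.3


@dataclass
class CalibrationResult:
    low_log_strength: float
    high_log_strength: float
    accuracy_low: float
    accuracy_high: float
    trials: pd.DataFrame
    pinned: bool = False


def _sim_choice(theta: float, d: int, m: float, rng: np.random.Generator) -> int:
    x = d * theta + rng.standard_normal()
    return int(decide(x, m, rng=rng))


def run_calibration(
    observer: ObserverSpec,
    config: CalibrationConfig = CalibrationConfig(),
    rng: Optional[np.random.Generator] = None,
    subject_id: str = "s0",
) -> CalibrationResult:
    """Simulate the 120-trial calibration phase.

    70 staircase trials (2-down-1-up, step ``step_size`` log units) are run;
    after ``burn_in`` staircase trials, 50 high-strength probes (log strength
    = 1.3x the current staircase value, yoked trial by trial) are randomly
    interleaved with the remaining staircase trials.  The converged low
    strength is the mean of the last 25 staircase log strengths; the stored
    high strength is 1.3x that value.
    """
    rng = np.random.default_rng() if rng is None else rng
    lo, hi = LOG_STRENGTH_BOUNDS
    state = StaircaseState(
        log_strength=min(hi, max(lo, math.log(config.start_dot_difference))),
        step_size=config.step_size,
    )
    # Trial order: burn-in staircase trials, then a shuffled interleaving of
    # the remaining staircase trials and the high-strength probes.
    order = ["s"] * config.burn_in
    tail = ["s"] * (config.n_staircase - config.burn_in) + ["h"] * config.n_high
    tail = [tail[i] for i in rng.permutation(len(tail))]
    order += tail

    rows = []
    presented: List[float] = []
    staircase_correct: List[bool] = []
    high_correct: List[bool] = []
    n_pinned = 0
    for t, kind in enumerate(order):
        d = int(rng.choice((-1, 1)))
        if kind == "s":
            strength = state.log_strength
            presented.append(strength)
            if strength in LOG_STRENGTH_BOUNDS:
                n_pinned += 1
        else:
            strength = min(hi, config.high_factor * state.log_strength)
        theta = psychometric_theta(max(strength, 1e-9), observer)
        a = _sim_choice(theta, d, observer.m, rng)
        correct = a == d
        if kind == "s":
            staircase_correct.append(correct)
            state = staircase_step(state, correct)
        else:
            high_correct.append(correct)
        rows.append(
            dict(
                subject_id=subject_id,
                phase="calibration",
                trial=t,
                d=d,
                log_strength_pre=strength,
                post_level="none",
                choice=float(a),
                accuracy=float(correct),
                confidence=np.nan,
                confidence_rt_ms=np.nan,
                missed=0,
                calib_high=int(kind == "h"),
            )
        )
    if n_pinned > config.n_staircase / 2:
        warnings.warn(
            "staircase pinned at a stimulus bound for more than half of its "
            "trials; the observer may be outside the calibratable range",
            RuntimeWarning,
        )
    low = float(np.mean(presented[-config.last_n :]))
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return CalibrationResult(
        low_log_strength=low,
        high_log_strength=config.high_factor * low,
        accuracy_low=float(np.mean(staircase_correct[-config.last_n :])),
        accuracy_high=float(np.mean(high_correct)) if high_correct else np.nan,
        trials=trials,
        pinned=n_pinned > config.n_staircase / 2,
    )


def _confidence_vector(x_pre, x_post, actions, params, moments):
    """Per-trial model confidence for trial-wise actions in {-1, +1}."""
    conf = np.empty(len(actions), dtype=float)
    for a in (-1, 1):
        mask = actions == a
        if not np.any(mask):
            continue
        xp = None if x_post is None else x_post[mask]
        total = lo_correct_total(x_pre[mask], xp, a, params, moments)
        conf[mask] = confidence_from_logodds(total)
    return conf


def _finish_task_rows(
    observer: ObserverSpec,
    subject_id: str,
    phase: str,
    start_trial: int,
    d: np.ndarray,
    log_strength: float,
    post_level: np.ndarray,
    actions: np.ndarray,
    conf: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = len(d)
    rating = simulate_report(conf, observer.sigma_report, rng)
    if observer.single_rating_collapse is not None:
        # degenerate rater: (almost) always emits the same grid point
        rating = np.full(n, observer.single_rating_collapse)
    rt = np.exp(
        math.log(observer.rt_median_ms) + observer.rt_sigma_log * rng.standard_normal(n)
    )
    missed = rng.random(n) < observer.miss_probability
    choice = actions.astype(float)
    accuracy = (actions == d).astype(float)
    choice[missed] = np.nan
    accuracy[missed] = np.nan
    rating = rating.astype(float)
    rating[missed] = np.nan
    rt[missed] = np.nan
    return pd.DataFrame(
        dict(
            subject_id=subject_id,
            phase=phase,
            trial=np.arange(start_trial, start_trial + n),
            d=d,
            log_strength_pre=log_strength,
            post_level=post_level,
            choice=choice,
            accuracy=accuracy,
            confidence=rating,
            confidence_rt_ms=rt,
            missed=missed.astype(int),
            calib_high=0,
        ),
        columns=TRIAL_COLUMNS,
    )


def _balanced_sides(n: int, rng: np.random.Generator) -> np.ndarray:
    d = np.array([-1, 1] * (n // 2) + [1] * (n % 2))
    return d[rng.permutation(n)]


def simulate_task1(
    observer: ObserverSpec,
    low_log_strength: float,
    rng: np.random.Generator,
    n_trials: int = 60,
    high_log_strength: Optional[float] = None,
    subject_id: str = "s0",
) -> pd.DataFrame:
    """Simulate the confidence task: ``n_trials`` judgments at the converged
    low strength, each followed by a rating; no post-decision evidence.

    Task-1 confidence uses the single-strength likelihood (mu = theta_pre,
    unit variance); a choice-bias observer applies its bias here too.
    """
    if high_log_strength is None:
        high_log_strength = 1.3 * low_log_strength
    params = observer.model_params(low_log_strength, high_log_strength)
    d = _balanced_sides(n_trials, rng)
    theta = params.strengths.mu_low
    x_pre = d * theta + rng.standard_normal(n_trials)
    actions = np.asarray(decide(x_pre, observer.m, rng=rng))
    conf = _confidence_vector(x_pre, None, actions, params, single_moments(theta))
    return _finish_task_rows(
        observer, subject_id, "task1", 0, d, low_log_strength,
        np.array(["none"] * n_trials), actions, conf, rng,
    )


def _interleave_levels(n_low: int, n_high: int, rng: np.random.Generator, max_run: int = 4) -> np.ndarray:
    """Pseudo-random interleaving with no more than ``max_run`` consecutive
    trials of one post-decision level."""
    for _ in range(100):
        remaining = {"low": n_low, "high": n_high}
        out: list = []
        run = 0
        ok = True
        for _i in range(n_low + n_high):
            options = [lev for lev, n in remaining.items() if n > 0]
            if len(options) == 2 and run >= max_run:
                options = [lev for lev in options if lev != out[-1]]
            elif len(options) == 1 and run >= max_run and out and options[0] == out[-1]:
                ok = False
                break
            total = sum(remaining[lev] for lev in options)
            pick = options[0]
            if len(options) == 2:
                pick = "low" if rng.random() < remaining["low"] / total else "high"
            run = run + 1 if (out and pick == out[-1]) else 1
            out.append(pick)
            remaining[pick] -= 1
        if ok:
            return np.array(out)
    raise RuntimeError("could not construct a constrained interleaving")


def simulate_task2(
    observer: ObserverSpec,
    low_log_strength: float,
    high_log_strength: float,
    rng: np.random.Generator,
    n_trials: int = 120,
    subject_id: str = "s0",
) -> pd.DataFrame:
    """Simulate the post-decision evidence task.

    Pre-decision evidence is always at the low strength; post-decision
    evidence (always physically favoring the true side) is at the low or
    high strength, pseudo-randomly interleaved 50/50.  Confidence combines
    both internal samples under the observer's variant, using the agnostic
    two-strength mixture moments for both samples.
    """
    params = observer.model_params(low_log_strength, high_log_strength)
    n_low = n_trials // 2
    levels = _interleave_levels(n_low, n_trials - n_low, rng)
    d = _balanced_sides(n_trials, rng)
    theta_low = params.strengths.mu_low
    theta_post = np.where(levels == "high", params.strengths.mu_high, theta_low)
    x_pre = d * theta_low + rng.standard_normal(n_trials)
    x_post = d * theta_post + rng.standard_normal(n_trials)
    actions = np.asarray(decide(x_pre, observer.m, rng=rng))
    conf = _confidence_vector(x_pre, x_post, actions, params, mixture_moments(params.strengths))
    return _finish_task_rows(
        observer, subject_id, "task2", 0, d, low_log_strength, levels, actions, conf, rng
    )


@dataclass(frozen=True)
class RadicalismProfile:
    """Questionnaire factor scores and nuisance demographics for one subject."""

    political_orientation: float
    dogmatic_intolerance: float
    authoritarianism: float
    composite_radicalism: float
    age: int
    gender: int
    education: int


@dataclass(frozen=True)
class PopulationConfig:
    """Defaults encode the planted population structure: the quadratic
    orientation->dogmatism coefficient, the linear orientation->authoritarianism
    coefficient, the residual dogmatism-authoritarianism correlation, and the
    standardized coupling of composite radicalism to logit(w_bias)."""

    n_subjects: int = 100
    quad_coef: float = 0.37
    lin_coef: float = 0.38
    factor_corr: float = 0.21
    wbias_coupling: float = 0.18
    wbias_logit_mean: float = 0.15
    wbias_logit_sd: float = 0.4
    sigma_report: float = 0.1
    sigma_report_coupling: float = 0.0
    m_sd: float = 0.2
    k_median: float = 0.065
    k_log_sd: float = 0.2
    gamma: float = 1.6
    miss_probability: float = 0.01
    rt_median_ms: float = 1500.0
    rt_sigma_log: float = 0.4
    variant: str = "choice_bias"
    weight_sd: float = 0.25
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    n_task1: int = 60
    n_task2: int = 120

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name in ("quad_coef", "lin_coef", "factor_corr", "wbias_coupling"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class SimulatedSubject:
    subject_id: str
    observer: ObserverSpec
    profile: RadicalismProfile
    calibration: CalibrationResult
    trials: pd.DataFrame


def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / (s if s > 0 else 1.0)


def _factor_scores(config: PopulationConfig, rng: np.random.Generator):
    """Generate (orientation, dogmatism, authoritarianism) with the planted
    quadratic / linear / residual-correlation structure, all unit variance."""
    n = config.n_subjects
    o = rng.standard_normal(n)
    zo = _zscore(o)
    zq = _zscore(zo**2)  # standardized quadratic term, uncorrelated with zo
    sd_d = math.sqrt(max(1.0 - config.quad_coef**2, 1e-12))
    sd_a = math.sqrt(max(1.0 - config.lin_coef**2, 1e-12))
    rho = config.factor_corr / (sd_d * sd_a)
    if abs(rho) >= 1:
        raise ValueError("factor_corr incompatible with quad/lin coefficients")
    e1 = rng.standard_normal(n)
    e2 = rho * e1 + math.sqrt(1 - rho**2) * rng.standard_normal(n)
    dog = config.quad_coef * zq + sd_d * e1
    auth = config.lin_coef * zo + sd_a * e2
    return zo, dog, auth


def _variant_params(config: PopulationConfig, logit_wbias: float, rng: np.random.Generator) -> VariantParams:
    if config.variant == "base":
        return VariantParams.base()
    if config.variant == "choice_bias":
        w = 1.0 / (1.0 + math.exp(-logit_wbias))
        return VariantParams.choice_bias(min(max(w, 1e-4), 1 - 1e-4))
    if config.variant == "temporal_weighting":
        w = np.clip(1.0 + config.weight_sd * rng.standard_normal(2), 0.05, 3.0)
        return VariantParams.temporal(float(w[0]), float(w[1]))
    if config.variant == "choice_weighting":
        w = np.clip(1.0 + config.weight_sd * rng.standard_normal(2), 0.05, 3.0)
        return VariantParams.choice_weighting(float(w[0]), float(w[1]))
    raise ValueError(f"unknown generating variant {config.variant!r}")


def simulate_subject(
    observer: ObserverSpec,
    rng: np.random.Generator,
    subject_id: str = "s0",
    calibration: CalibrationConfig = CalibrationConfig(),
    n_task1: int = 60,
    n_task2: int = 120,
) -> tuple:
    """Run one observer through calibration, task 1 and task 2; returns the
    calibration result and the full trial table."""
    calib = run_calibration(observer, calibration, rng, subject_id=subject_id)
    t1 = simulate_task1(
        observer, calib.low_log_strength, rng, n_trials=n_task1,
        high_log_strength=calib.high_log_strength, subject_id=subject_id,
    )
    t2 = simulate_task2(
        observer, calib.low_log_strength, calib.high_log_strength, rng,
        n_trials=n_task2, subject_id=subject_id,
    )
    trials = pd.concat([calib.trials, t1, t2], ignore_index=True)
    return calib, trials


def generate_population(
    config: PopulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[SimulatedSubject]:
    """Simulate a full population: factor scores, observers whose choice-bias
    parameter is coupled to composite radicalism, and complete per-subject
    sessions.  Ground truth (observer specs) is retained for recovery tests.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = config.n_subjects
    zo, dog, auth = _factor_scores(config, rng)
    composite = _zscore(dog) + _zscore(auth)
    zc = _zscore(composite)

    rho = config.wbias_coupling
    eps = rng.standard_normal(n)
    logit_wb = config.wbias_logit_mean + config.wbias_logit_sd * (
        rho * zc + math.sqrt(max(1 - rho**2, 0.0)) * eps
    )
    sigma_rep = config.sigma_report * np.exp(config.sigma_report_coupling * zc)
    m = config.m_sd * rng.standard_normal(n)
    k = config.k_median * np.exp(config.k_log_sd * rng.standard_normal(n))
    age = rng.integers(18, 71, size=n)
    gender = rng.integers(0, 2, size=n)
    education = rng.integers(1, 6, size=n)

    subjects = []
    for j in range(n):
        sid = f"s{j:04d}"
        observer = ObserverSpec(
            k=float(k[j]),
            gamma=config.gamma,
            m=float(m[j]),
            sigma_report=float(sigma_rep[j]),
            variant_params=_variant_params(config, float(logit_wb[j]), rng),
            rt_median_ms=config.rt_median_ms,
            rt_sigma_log=config.rt_sigma_log,
            miss_probability=config.miss_probability,
        )
        profile = RadicalismProfile(
            political_orientation=float(zo[j]),
            dogmatic_intolerance=float(dog[j]),
            authoritarianism=float(auth[j]),
            composite_radicalism=float(composite[j]),
            age=int(age[j]),
            gender=int(gender[j]),
            education=int(education[j]),
        )
        calib, trials = simulate_subject(
            observer, rng, subject_id=sid, calibration=config.calibration,
            n_task1=config.n_task1, n_task2=config.n_task2,
        )
        subjects.append(SimulatedSubject(sid, observer, profile, calib, trials))
    return subjects


def population_trials(subjects: Sequence[SimulatedSubject]) -> pd.DataFrame:
    return pd.concat([s.trials for s in subjects], ignore_index=True)


def population_profiles(subjects: Sequence[SimulatedSubject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = dataclasses.asdict(s.profile)
        row["subject_id"] = s.subject_id
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def _observer_truth(s: SimulatedSubject) -> dict:
    v = s.observer.variant_params
    return dict(
        k=s.observer.k,
        gamma=s.observer.gamma,
        m=s.observer.m,
        sigma_report=s.observer.sigma_report,
        variant=v.variant,
        w_pre=v.w_pre,
        w_post=v.w_post,
        w_confirmatory=v.w_confirmatory,
        w_disconfirmatory=v.w_disconfirmatory,
        w_bias=v.w_bias,
        miss_probability=s.observer.miss_probability,
        rt_median_ms=s.observer.rt_median_ms,
        low_log_strength=s.calibration.low_log_strength,
        high_log_strength=s.calibration.high_log_strength,
        accuracy_low=s.calibration.accuracy_low,
        accuracy_high=s.calibration.accuracy_high,
    )


def write_dataset(subjects: Sequence[SimulatedSubject], path) -> None:
    """Write a population to ``path/trials.csv`` plus a JSON sidecar with
    radicalism profiles and generative ground truth."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    population_trials(subjects).to_csv(path / "trials.csv", index=False)
    sidecar = {
        s.subject_id: dict(
            profile=dataclasses.asdict(s.profile),
            observer=_observer_truth(s),
        )
        for s in subjects
    }
    with open(path / "subjects.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


@dataclass
class Dataset:
    trials: pd.DataFrame
    profiles: pd.DataFrame
    ground_truth: dict

    def subject_trials(self, subject_id: str) -> pd.DataFrame:
        return self.trials[self.trials.subject_id == subject_id]


def read_dataset(path) -> Dataset:
    """Read a dataset written by :func:`write_dataset`; validates the schema."""
    path = Path(path)
    trials = pd.read_csv(path / "trials.csv")
    for col in TRIAL_COLUMNS:
        if col not in trials.columns:
            raise ValueError(f"trials.csv is missing required column {col!r}")
    bad = set(trials.phase.unique()) - set(PHASES)
    if bad:
        raise ValueError(f"unknown phase labels {sorted(bad)!r}")
    sidecar = path / "subjects.json"
    ground_truth = {}
    profiles = pd.DataFrame()
    if sidecar.exists():
        with open(sidecar) as fh:
            ground_truth = json.load(fh)
        profiles = pd.DataFrame(
            {sid: rec["profile"] for sid, rec in ground_truth.items()}
        ).T
        profiles.index.name = "subject_id"
    return Dataset(trials=trials, profiles=profiles, ground_truth=ground_truth)
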