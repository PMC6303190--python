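"""Per-subject regressions quantifying post-decision evidence integration.

Evidence conditions are coded ordinally — confidence task 0, low
post-decision evidence 1, high post-decision evidence 2 — and confidence
(on the [0, 1] scale) is regressed on that code by ordinary least squares,
separately for correct and incorrect trials.  On incorrect trials the slope
is sign-flipped so that larger values always mean stronger integration of
the (dis)confirming evidence.  A separate task-2-only model with accuracy,
evidence strength and their interaction summarizes overall sensitivity to
post-decision evidence independently of task-1-based measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["IntegrationBetas", "evidence_code", "integration_betas", "pde_sensitivity"]


@dataclass(frozen=True)
class IntegrationBetas:
    beta_confirmatory: float
    beta_disconfirmatory: float


def evidence_code(trials: pd.DataFrame) -> np.ndarray:
    """0/1/2 coding of the post-decision evidence condition."""
    code = np.zeros(len(trials))
    code[(trials.phase == "task2").to_numpy() & (trials.post_level == "low").to_numpy()] = 1.0
    code[(trials.phase == "task2").to_numpy() & (trials.post_level == "high").to_numpy()] = 2.0
    return code


def _clean(trials: pd.DataFrame) -> pd.DataFrame:
    t = trials
    if "missed" in t.columns:
        t = t[t.missed == 0]
    return t.dropna(subset=["choice", "confidence"])


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(coef[1])


def integration_betas(trials: pd.DataFrame) -> IntegrationBetas:
    """Confirmatory and disconfirmatory integration slopes from trials pooled
    across tasks 1 and 2.

    Confirmatory: OLS slope of confidence on the 0/1/2 evidence code over
    correct trials.  Disconfirmatory: the negated slope over incorrect
    trials (confidence should fall with disconfirming evidence, so more
    negative raw slopes mean more integration).  Either is ``nan`` when its
    accuracy class spans fewer than two evidence levels.
    """
    t = _clean(trials)
    code = evidence_code(t)
    acc = (t["d"].to_numpy(int) == t["choice"].to_numpy(int))
    conf = t["confidence"].to_numpy(float)

    def slope_for(mask: np.ndarray) -> float:
        if mask.sum() < 2 or len(np.unique(code[mask])) < 2:
            return float("nan")
        return _ols_slope(code[mask], conf[mask])

    raw_confirm = slope_for(acc)
    raw_disconfirm = slope_for(~acc)
    return IntegrationBetas(
        beta_confirmatory=raw_confirm,
        beta_disconfirmatory=-raw_disconfirm if np.isfinite(raw_disconfirm) else raw_disconfirm,
    )


def pde_sensitivity(task2_trials: pd.DataFrame) -> float:
    """Accuracy x evidence-strength interaction coefficient on task-2 trials.

    Predictors: accuracy (correct +1, incorrect -1), post-decision strength
    (low 1, high 2), and their product; confidence is the outcome.  The
    interaction captures confidence rising with stronger evidence when
    correct and falling when incorrect.  Raises if either accuracy class or
    either strength level is absent.
    """
    t = _clean(task2_trials)
    t = t[t.phase == "task2"]
    acc = np.where(t["d"].to_numpy(int) == t["choice"].to_numpy(int), 1.0, -1.0)
    strength = np.where(t["post_level"].to_numpy() == "high", 2.0, 1.0)
    if len(np.unique(acc)) < 2:
        raise ValueError("need both correct and incorrect task-2 trials")
    if len(np.unique(strength)) < 2:
        raise ValueError("need both post-decision evidence strengths")
    X = np.column_stack([np.ones(len(t)), acc, strength, acc * strength])
    coef, *_ = np.linalg.lstsq(X, t["confidence"].to_numpy(float), rcond=None)
    return float(coef[3])
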