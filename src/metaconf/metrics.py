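"""Per-subject type-1 and type-2 signal-detection measures.

Type-1 sensitivity (d') and criterion follow standard equal-variance SDT
with a 0.5-count padding of extreme cells.  Metacognitive sensitivity is
quantified as meta-d': the type-1 sensitivity an SDT-ideal rater would need,
at the subject's own type-1 criterion, to reproduce the observed
response-conditional confidence distributions.  meta-d' is estimated here by
maximum likelihood on the multinomial type-2 counts; for a metacognitively
ideal observer meta-d' equals d', and report noise or confidence biases can
only lower it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

from .integration import integration_betas, pde_sensitivity
from .sdt import RATING_GRID

__all__ = [
    "Type1Counts",
    "Type2Counts",
    "MetacogSummary",
    "dprime_criterion",
    "meta_d",
    "confidence_bias",
    "earnings",
    "summarize_subject",
    "summarize_population",
]


@dataclass(frozen=True)
class Type1Counts:
    """2x2 counts of (true side x choice) with the padding constant noted."""

    n_left_left: float
    n_left_right: float
    n_right_left: float
    n_right_right: float
    padding: float = 0.5

    @property
    def hit_rate(self) -> float:
        n = self.n_right_right + self.n_right_left + 2 * self.padding
        return (self.n_right_right + self.padding) / n

    @property
    def false_alarm_rate(self) -> float:
        n = self.n_left_right + self.n_left_left + 2 * self.padding
        return (self.n_left_right + self.padding) / n


@dataclass(frozen=True)
class Type2Counts:
    """Confidence-bin counts per (stimulus, response) cell.

    ``counts`` has shape (2, 2, n_bins): axis 0 is the true side (left,
    right), axis 1 the response (left, right), axis 2 the confidence bin in
    increasing order.  ``bin_values`` are the rating values the bins stand
    for (unused bins are collapsed away).
    """

    counts: np.ndarray
    bin_values: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]


def _type_arrays(trials) -> tuple:
    if isinstance(trials, pd.DataFrame):
        t = trials
        if "missed" in t.columns:
            t = t[t.missed == 0]
        t = t.dropna(subset=["choice"])
        return t["d"].to_numpy(int), t["choice"].to_numpy(int), t
    raise TypeError("expected a trial DataFrame")


def dprime_criterion(trials: pd.DataFrame) -> tuple:
    """Equal-variance SDT sensitivity and criterion from a trial table.

    d' = z(H) - z(FA) and c = -0.5 (z(H) + z(FA)), treating "right" (+1) as
    the signal class; 0.5 is added to every cell so extreme rates stay
    finite.
    """
    d, a, _ = _type_arrays(trials)
    if not ((d == 1).any() and (d == -1).any()):
        raise ValueError("need at least one trial per true side")
    counts = Type1Counts(
        n_left_left=float(((d == -1) & (a == -1)).sum()),
        n_left_right=float(((d == -1) & (a == 1)).sum()),
        n_right_left=float(((d == 1) & (a == -1)).sum()),
        n_right_right=float(((d == 1) & (a == 1)).sum()),
    )
    zh, zfa = ndtri(counts.hit_rate), ndtri(counts.false_alarm_rate)
    return float(zh - zfa), float(-0.5 * (zh + zfa))


def type2_counts(trials: pd.DataFrame) -> Type2Counts:
    """Tabulate confidence ratings per (stimulus, response) cell, collapsing
    rating values that never occur (the bins are ordinal, so only the used
    levels matter)."""
    d, a, t = _type_arrays(trials)
    r = t["confidence"].to_numpy(float)
    keep = ~np.isnan(r)
    d, a, r = d[keep], a[keep], r[keep]
    values = np.unique(r)
    counts = np.zeros((2, 2, len(values)))
    for i, s in enumerate((-1, 1)):
        for j, resp in enumerate((-1, 1)):
            mask = (d == s) & (a == resp)
            if mask.any():
                idx = np.searchsorted(values, r[mask])
                np.add.at(counts[i, j], idx, 1.0)
    return Type2Counts(counts=counts, bin_values=values)


def _meta_nll(params: np.ndarray, counts: np.ndarray, meta_c_ratio: float) -> float:
    k = counts.shape[2]
    md = params[0]
    inc_plus = np.exp(params[1 : k])
    inc_minus = np.exp(params[k : 2 * k - 1])
    meta_c = meta_c_ratio * md
    edges_plus = np.concatenate(([meta_c], meta_c + np.cumsum(inc_plus), [np.inf]))
    edges_minus = np.concatenate(([meta_c], meta_c - np.cumsum(inc_minus), [-np.inf]))
    nll = 0.0
    for i, s in enumerate((-1, 1)):
        mu = s * md / 2.0
        cdf_plus = ndtr(edges_plus - mu)
        p_plus = np.diff(cdf_plus)
        denom_plus = max(1.0 - ndtr(meta_c - mu), 1e-12)
        cdf_minus = ndtr(edges_minus - mu)
        p_minus = -np.diff(cdf_minus)
        denom_minus = max(ndtr(meta_c - mu), 1e-12)
        nll -= float(counts[i, 1] @ np.log(np.maximum(p_plus / denom_plus, 1e-300)))
        nll -= float(counts[i, 0] @ np.log(np.maximum(p_minus / denom_minus, 1e-300)))
    return nll


def meta_d(trials: pd.DataFrame, n_bins: int = 9) -> float:
    """Maximum-likelihood meta-d'.

    Fits the type-1 sensitivity of an SDT rater whose type-1 criterion is
    locked to the subject's (scaled as meta-c = c * meta-d'/d') and whose
    free type-2 criteria best reproduce the observed response-conditional
    confidence counts under a multinomial likelihood.  Each cell is padded
    with ``1/(2*K)`` where K is the number of rating bins actually used
    (unused bins are collapsed, which makes the estimate invariant to
    monotone relabelling of the rating scale).

    Returns ``nan`` when undefined: a single rating bin used, no correct or
    no incorrect trials, or non-positive d'.
    """
    t = trials
    if "missed" in t.columns:
        t = t[t.missed == 0]
    t = t.dropna(subset=["choice", "confidence"])
    acc = (t["d"].to_numpy(int) == t["choice"].to_numpy(int)).astype(int)
    if acc.size == 0 or acc.all() or not acc.any():
        raise ValueError("need at least one correct and one incorrect rated trial")
    t2 = type2_counts(t)
    k = t2.n_bins
    if k < 2:
        return float("nan")
    if k > n_bins:
        raise ValueError("more rating levels than n_bins")
    d1, c1 = dprime_criterion(t)
    if d1 <= 0.05:
        return float("nan")
    counts = t2.counts + 1.0 / (2.0 * k)
    x0 = np.concatenate(([d1], np.full(2 * (k - 1), math.log(max(2.5 / max(k - 1, 1), 1e-3)))))
    res = minimize(
        _meta_nll,
        x0,
        args=(counts, c1 / d1),
        method="L-BFGS-B",
        bounds=[(-5.0, 5.0)] + [(-10.0, 3.0)] * (2 * (k - 1)),
        options=dict(maxiter=500),
    )
    return float(res.x[0])


def confidence_bias(trials: pd.DataFrame, mode: str = "relative") -> float:
    """Overall confidence bias.

    ``relative`` (default): mean confidence minus proportion correct, so
    positive values are overconfidence.  ``raw``: mean confidence alone.
    """
    t = trials
    if "missed" in t.columns:
        t = t[t.missed == 0]
    t = t.dropna(subset=["confidence"])
    if len(t) == 0:
        raise ValueError("no rated trials")
    mean_conf = float(t["confidence"].mean())
    if mode == "raw":
        return mean_conf
    if mode == "relative":
        acc = (t["d"].to_numpy(int) == t["choice"].to_numpy(int)).mean()
        return mean_conf - float(acc)
    raise ValueError(f"unknown confidence-bias mode {mode!r}")


def earnings(trials: pd.DataFrame, scale: float = 1.0) -> float:
    """Quadratic-scoring-rule points: ``1 - (accuracy - confidence)^2`` per
    rated trial, summed and scaled.  Maximal when fully confident and
    correct or minimally confident and wrong."""
    t = trials
    if "missed" in t.columns:
        t = t[t.missed == 0]
    t = t.dropna(subset=["confidence"])
    acc = (t["d"].to_numpy(int) == t["choice"].to_numpy(int)).astype(float)
    conf = t["confidence"].to_numpy(float)
    return float(np.sum(1.0 - (acc - conf) ** 2) * scale)


@dataclass
class MetacogSummary:
    """All per-subject derived measures entering the group-level battery."""

    subject_id: str
    dprime_task1: float = np.nan
    dprime_task2: float = np.nan
    dprime_mean: float = np.nan
    criterion: float = np.nan
    meta_d: float = np.nan
    confidence_bias: float = np.nan
    beta_confirmatory: float = np.nan
    beta_disconfirmatory: float = np.nan
    pde_sensitivity: float = np.nan
    earnings: float = np.nan
    accuracy_task: float = np.nan
    log_strength: float = np.nan
    accuracy_high: float = np.nan
    modal_rating_freq: float = np.nan
    median_confidence_rt_ms: float = np.nan
    miss_rate: float = np.nan
    n_bins_used: int = 0
    degenerate_confidence: bool = False


def summarize_subject(trials: pd.DataFrame, subject_id: Optional[str] = None) -> MetacogSummary:
    """Compute the full metric set for one subject's trial table (all phases).

    meta-d' and confidence bias are task-1 measures; d' is computed per task
    and averaged; the evidence-integration slopes pool tasks 1 and 2;
    post-decision-evidence sensitivity uses task 2 only.
    """
    if subject_id is None:
        subject_id = str(trials["subject_id"].iloc[0]) if "subject_id" in trials else "s0"
    out = MetacogSummary(subject_id=subject_id)
    task1 = trials[trials.phase == "task1"]
    task2 = trials[trials.phase == "task2"]
    tasks = trials[trials.phase.isin(("task1", "task2"))]
    calib_high = trials[(trials.phase == "calibration") & (trials.calib_high == 1)]

    ok = tasks[tasks.missed == 0].dropna(subset=["choice"])
    out.miss_rate = float(tasks.missed.mean()) if len(tasks) else np.nan
    if len(ok):
        out.accuracy_task = float((ok["d"] == ok["choice"]).mean())
    rated = ok.dropna(subset=["confidence"])
    if len(rated):
        out.modal_rating_freq = float(rated.confidence.value_counts(normalize=True).iloc[0])
        out.median_confidence_rt_ms = float(rated.confidence_rt_ms.median())
        out.n_bins_used = int(rated.confidence.nunique())
        out.degenerate_confidence = out.n_bins_used < 2
        out.earnings = earnings(tasks)
    if len(task1):
        out.log_strength = float(task1.log_strength_pre.iloc[0])
    if len(calib_high):
        out.accuracy_high = float(calib_high.accuracy.mean())
    try:
        out.dprime_task1, out.criterion = dprime_criterion(task1)
        out.dprime_task2, _ = dprime_criterion(task2)
        out.dprime_mean = 0.5 * (out.dprime_task1 + out.dprime_task2)
    except ValueError:
        pass
    try:
        out.confidence_bias = confidence_bias(task1)
    except ValueError:
        pass
    if not out.degenerate_confidence:
        try:
            out.meta_d = meta_d(task1)
        except ValueError:
            out.meta_d = np.nan
    betas = integration_betas(tasks)
    out.beta_confirmatory = betas.beta_confirmatory
    out.beta_disconfirmatory = betas.beta_disconfirmatory
    try:
        out.pde_sensitivity = pde_sensitivity(task2)
    except ValueError:
        out.pde_sensitivity = np.nan
    return out


def summarize_population(trials: pd.DataFrame) -> pd.DataFrame:
    """One :class:`MetacogSummary` row per subject in a pooled trial table."""
    rows = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        rows.append(vars(summarize_subject(sub, subject_id=str(sid))))
    return pd.DataFrame(rows).set_index("subject_id")
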