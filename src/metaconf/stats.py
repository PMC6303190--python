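"""Group-level statistical battery.

Robust (Tukey bisquare) regressions with standardized coefficients link the
per-subject behavioral measures to the radicalism factor scores; variance
inflation factors screen for multicollinearity; Gaussian-likelihood BIC
compares regression models, including the battery that pits the three
confidence-model variants (via their fitted parameters) against each other
as predictors of composite radicalism.  Exclusion screening applies the
four behavioral data-quality filters before any subject enters a group
analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

__all__ = [
    "RegressionResult",
    "ExclusionReport",
    "robust_regress",
    "vif",
    "partial_r2",
    "regression_bic",
    "composite_radicalism",
    "quad_vs_linear",
    "compare_models_radicalism",
    "apply_exclusions",
]

#: MATLAB fitlm's default bisquare tuning constant (95% Gaussian efficiency).
BISQUARE_TUNING = 4.685


@dataclass
class RegressionResult:
    """Standardized robust-regression output.

    ``params``/``bse``/``pvalues`` are indexed by predictor name (intercept
    excluded from ``params`` but included in the parameter count ``k`` along
    with the error variance).  ``r2`` is 1 - RSS/TSS of the robust fit on
    the standardized data.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r2: float
    partial_r2: pd.Series
    vifs: pd.Series
    n: int
    rss: float
    k: int
    bic: float = field(init=False)

    def __post_init__(self) -> None:
        self.bic = regression_bic(self.n, self.rss, self.k)

    @property
    def predictors(self) -> List[str]:
        return list(self.params.index)

    def summary(self) -> str:
        lines = [
            f"Robust regression (bisquare, c={BISQUARE_TUNING}), n={self.n}, "
            f"R2={self.r2:.3f}, BIC={self.bic:.1f}",
            f"  {'predictor':<24}{'beta':>8}{'SE':>8}{'p':>10}{'pR2':>8}{'VIF':>8}",
        ]
        for name in self.predictors:
            vif_s = f"{self.vifs.get(name, float('nan')):>8.2f}"
            lines.append(
                f"  {name:<24}{self.params[name]:>8.3f}{self.bse[name]:>8.3f}"
                f"{self.pvalues[name]:>10.4f}{self.partial_r2.get(name, float('nan')):>8.4f}{vif_s}"
            )
        return "\n".join(lines)


def _zscore_frame(X: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col in X.columns:
        x = X[col].to_numpy(float)
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"predictor {col!r} is constant")
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=X.index)


def _robust_fit(y: np.ndarray, X: np.ndarray):
    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_TUNING))
    return model.fit()


def robust_regress(
    y,
    X: pd.DataFrame,
    one_tailed: Optional[Dict[str, int]] = None,
    compute_partial_r2: bool = True,
) -> RegressionResult:
    """Robust linear regression with standardized variables.

    Outcome and predictors are z-scored before an iteratively reweighted
    least-squares fit with Tukey bisquare weights (tuning constant 4.685),
    so coefficients are standardized betas.  ``one_tailed`` maps predictor
    names to a hypothesized sign (+1/-1); their two-tailed p is halved when
    the estimate matches the declared direction (and the complement is used
    otherwise).  Per-predictor R2 is the drop in explained variance when the
    predictor is removed (robust refits).
    """
    X = pd.DataFrame(X).copy()
    y = np.asarray(y, dtype=float)
    if len(y) != len(X):
        raise ValueError("y and X lengths differ")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    Xz = _zscore_frame(X)
    design = np.column_stack([np.ones(len(Xz)), Xz.to_numpy()])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (collinear predictors)")
    sd = y.std(ddof=0)
    if sd == 0:
        raise ValueError("outcome is constant")
    yz = (y - y.mean()) / sd

    fit = _robust_fit(yz, design)
    names = list(X.columns)
    params = pd.Series(fit.params[1:], index=names)
    bse = pd.Series(fit.bse[1:], index=names)
    zvals = params / bse
    pvals = 2.0 * norm.sf(np.abs(zvals))
    pvalues = pd.Series(pvals, index=names)
    if one_tailed:
        for name, sign in one_tailed.items():
            if name not in pvalues.index:
                raise KeyError(f"one-tailed direction given for unknown predictor {name!r}")
            half = pvalues[name] / 2.0
            pvalues[name] = half if np.sign(params[name]) == np.sign(sign) else 1.0 - half
    resid = yz - design @ fit.params
    rss = float(resid @ resid)
    tss = float(((yz - yz.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss

    pr2 = pd.Series(dtype=float)
    if compute_partial_r2 and len(names) >= 2:
        vals = {}
        for name in names:
            reduced = robust_regress(
                yz, Xz.drop(columns=[name]), compute_partial_r2=False
            )
            vals[name] = r2 - reduced.r2
        pr2 = pd.Series(vals)
    elif compute_partial_r2:
        pr2 = pd.Series({names[0]: r2})

    vifs = vif(Xz) if len(names) >= 2 else pd.Series({n: 1.0 for n in names})
    return RegressionResult(
        params=params, bse=bse, pvalues=pvalues, r2=r2, partial_r2=pr2,
        vifs=vifs, n=len(yz), rss=rss, k=len(names) + 2,
    )


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1-R2_j) per predictor, from OLS of each
    predictor on the others.  Perfect collinearity yields ``inf`` (flagged
    by a warning above the standard cut-off of 10)."""
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    out = {}
    for col in X.columns:
        others = X.drop(columns=[col])
        design = np.column_stack([np.ones(len(X)), others.to_numpy(float)])
        coef, *_ = np.linalg.lstsq(design, X[col].to_numpy(float), rcond=None)
        resid = X[col].to_numpy(float) - design @ coef
        tss = float(((X[col] - X[col].mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
        out[col] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    s = pd.Series(out)
    if (s > 10).any():
        import warnings

        warnings.warn(
            f"VIF above 10 for: {list(s.index[s > 10])}", RuntimeWarning
        )
    return s


def partial_r2(full: RegressionResult, reduced: RegressionResult) -> float:
    """Difference in explained variance between a full model and a nested
    reduced model (the R2 contribution of the dropped predictors)."""
    if not set(reduced.predictors) < set(full.predictors):
        raise ValueError("reduced model is not nested in the full model")
    if reduced.n != full.n:
        raise ValueError("models were fitted on different samples")
    return full.r2 - reduced.r2


def regression_bic(n: int, rss: float, k: int) -> float:
    """Gaussian-likelihood BIC for a regression: ``n log(RSS/n) + k log n``.

    ``k`` counts all estimated quantities (slopes, intercept and error
    variance); only BIC differences within a comparison are meaningful.
    """
    if rss <= 0:
        raise ValueError("RSS must be positive")
    return float(n * math.log(rss / n) + k * math.log(n))


def composite_radicalism(profiles: pd.DataFrame) -> pd.Series:
    """Composite radicalism: sum of the z-scored dogmatic-intolerance and
    authoritarianism factor scores."""
    for col in ("dogmatic_intolerance", "authoritarianism"):
        if col not in profiles.columns:
            raise ValueError(f"profiles missing factor score {col!r}")
        if profiles[col].isna().any():
            raise ValueError(f"missing values in {col!r}")

    def z(s):
        v = s.to_numpy(float)
        sd = v.std(ddof=0)
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    return pd.Series(
        z(profiles["dogmatic_intolerance"]) + z(profiles["authoritarianism"]),
        index=profiles.index,
        name="composite_radicalism",
    )


@dataclass
class QuadLinResult:
    label: str
    structure: str
    fit: RegressionResult


def quad_vs_linear(x, y) -> QuadLinResult:
    """Classify a bivariate relation as linear or quadratic by BIC.

    Fits robust regressions of y on x, on x^2, and on both, and returns the
    BIC-minimizing structure.  The label is 'linear' or 'quadratic'; when
    the joint model wins, the label follows the larger |standardized beta|.
    """
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("degenerate x for quadratic comparison")
    if len(x) < 10:
        raise ValueError("need n >= 10")
    X = pd.DataFrame({"x": x, "x2": x**2})
    fits = {
        "linear": robust_regress(y, X[["x"]], compute_partial_r2=False),
        "quadratic": robust_regress(y, X[["x2"]], compute_partial_r2=False),
        "linear+quadratic": robust_regress(y, X, compute_partial_r2=False),
    }
    structure = min(fits, key=lambda k: fits[k].bic)
    best = fits[structure]
    if structure == "linear+quadratic":
        label = "quadratic" if abs(best.params["x2"]) >= abs(best.params["x"]) else "linear"
    else:
        label = structure
    return QuadLinResult(label=label, structure=structure, fit=best)


#: regression predictor sets per variant for the radicalism model comparison;
#: reduced single-weight variants guard against the choice-bias model winning
#: on parameter count alone.
_COMPARISON_SETS = {
    "choice_bias": ["w_bias"],
    "temporal_weighting": ["w_pre", "w_post"],
    "temporal_weighting:w_pre": ["w_pre"],
    "temporal_weighting:w_post": ["w_post"],
    "choice_weighting": ["w_confirmatory", "w_disconfirmatory"],
    "choice_weighting:w_confirmatory": ["w_confirmatory"],
    "choice_weighting:w_disconfirmatory": ["w_disconfirmatory"],
}


def compare_models_radicalism(
    fits_by_variant: Dict[str, pd.DataFrame],
    composite: pd.Series,
) -> pd.DataFrame:
    """BIC table of regressions predicting composite radicalism from fitted
    model parameters.

    For each variant, composite radicalism is regressed on (mu_low, mu_high)
    plus the variant's weight parameter(s); single-parameter reductions of
    the two-weight variants are included so that the comparison is not
    decided by predictor count alone.  Returns one row per candidate with
    BIC and delta_bic = BIC - min(BIC); the best model has delta_bic 0.
    """
    needed = {"temporal_weighting", "choice_weighting", "choice_bias"}
    missing = needed - set(fits_by_variant)
    if missing:
        raise ValueError(f"missing fits for variants: {sorted(missing)}")
    index = None
    for name, frame in fits_by_variant.items():
        idx = frame.index
        if index is None:
            index = idx
        elif not index.equals(idx):
            raise ValueError("subject sets differ across variant fits")
    y = composite.loc[index]

    rows = []
    for candidate, weights in _COMPARISON_SETS.items():
        variant = candidate.split(":")[0]
        frame = fits_by_variant[variant]
        X = frame[["mu_low", "mu_high"] + weights]
        fit = robust_regress(y, X, compute_partial_r2=False)
        rows.append(dict(model=candidate, variant=variant, bic=fit.bic,
                         r2=fit.r2, n=fit.n,
                         **{f"beta_{w}": fit.params[w] for w in weights}))
    table = pd.DataFrame(rows).set_index("model")
    table["delta_bic"] = table["bic"] - table["bic"].min()
    return table.sort_values("delta_bic")


@dataclass
class ExclusionReport:
    """Per-subject data-quality flags and the retained subject set."""

    flags: pd.DataFrame
    counts: Dict[str, int]
    retained: List[str]
    excluded: List[str]


#: strict thresholds, as stated: performance above 85% or below 60%, a single
#: rating more than 90% of the time, median confidence RT below 850 ms, and
#: more than 5% missed trials.
EXCLUSION_RULES = dict(
    performance_high=0.85, performance_low=0.60,
    single_rating=0.90, fast_rt_ms=850.0, missed=0.05,
)


def apply_exclusions(summaries: pd.DataFrame) -> ExclusionReport:
    """Apply the four behavioral data-quality filters to a summary table.

    Expects the per-subject columns ``accuracy_task`` (proportion correct in
    the perceptual task), ``modal_rating_freq`` (computed after dropping
    missed trials), ``median_confidence_rt_ms`` and ``miss_rate``.  All
    comparisons are strict; a subject is excluded if any rule fires.
    """
    required = ["accuracy_task", "modal_rating_freq", "median_confidence_rt_ms", "miss_rate"]
    for col in required:
        if col not in summaries.columns:
            raise ValueError(f"summaries missing required field {col!r}")
    acc = summaries["accuracy_task"]
    flags = pd.DataFrame(
        {
            "performance_out_of_range": (acc > EXCLUSION_RULES["performance_high"])
            | (acc < EXCLUSION_RULES["performance_low"]),
            "single_rating": summaries["modal_rating_freq"] > EXCLUSION_RULES["single_rating"],
            "fast_confidence_rt": summaries["median_confidence_rt_ms"]
            < EXCLUSION_RULES["fast_rt_ms"],
            "missed_trials": summaries["miss_rate"] > EXCLUSION_RULES["missed"],
        },
        index=summaries.index,
    )
    any_flag = flags.any(axis=1)
    return ExclusionReport(
        flags=flags,
        counts={col: int(flags[col].sum()) for col in flags.columns},
        retained=list(summaries.index[~any_flag]),
        excluded=list(summaries.index[any_flag]),
    )
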