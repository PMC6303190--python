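"""End-to-end analysis pipeline.

simulate population -> data-quality exclusions -> metacognition and
evidence-integration metrics -> group-level robust-regression battery ->
confidence-model fits per variant -> BIC model comparison against composite
radicalism -> posterior-predictive confidence table.

The regression battery mirrors the study design:

1. factor interrelations (dogmatism/authoritarianism vs orientation, BIC
   labelled linear-vs-quadratic; authoritarianism vs dogmatism);
2. post-decision-evidence sensitivity predicted by task-1 meta-d',
   performance, confidence bias, stimulus strength and high-strength
   performance;
3. each factor score predicted by the full behavioral battery plus
   demographics;
4. task earnings predicted by composite radicalism controlling for
   performance and stimulus strength.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .fitting import (
    QuadratureConfig,
    fit_population,
    fits_frame,
    posterior_predictive,
)
from .metrics import summarize_population
from .simulate import PopulationConfig, generate_population, population_profiles, population_trials
from .stats import (
    RegressionResult,
    apply_exclusions,
    compare_models_radicalism,
    composite_radicalism,
    quad_vs_linear,
    robust_regress,
)

__all__ = ["PipelineConfig", "run_full_pipeline"]

FACTOR_BATTERY_PREDICTORS = [
    "meta_d",
    "confidence_bias",
    "beta_confirmatory",
    "beta_disconfirmatory",
    "dprime_mean",
    "log_strength",
    "accuracy_high",
    "age",
    "gender",
    "education",
]

PDE_BATTERY_PREDICTORS = [
    "meta_d",
    "dprime_mean",
    "confidence_bias",
    "log_strength",
    "accuracy_high",
]


@dataclass
class PipelineConfig:
    population: PopulationConfig = field(default_factory=lambda: PopulationConfig(n_subjects=200))
    seed: int = 0
    include_model_fits: bool = True
    include_posterior_predictive: bool = False
    quadrature_n_pre: int = 21
    quadrature_n_post: int = 15
    fit_n_starts: int = 2
    ppc_n_draws: int = 20
    ppc_n_trials: int = 1000

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        pop = raw.pop("population", {})
        if not isinstance(pop, PopulationConfig):
            pop = PopulationConfig(**pop)
        return cls(population=pop, **raw)


def _regression_record(fit: RegressionResult) -> dict:
    return dict(
        beta=fit.params.round(6).to_dict(),
        se=fit.bse.round(6).to_dict(),
        p=fit.pvalues.round(6).to_dict(),
        partial_r2={k: round(v, 6) for k, v in fit.partial_r2.to_dict().items()},
        vif={k: round(v, 4) for k, v in fit.vifs.to_dict().items()},
        r2=round(fit.r2, 6),
        n=fit.n,
        bic=round(fit.bic, 4),
    )


def run_full_pipeline(
    config: PipelineConfig,
    out_dir: Optional[str] = None,
) -> dict:
    """Run the whole analysis on a freshly simulated population.

    Returns the report as a plain dict (JSON-serializable); when ``out_dir``
    is given, writes ``report.json``, the per-subject summary CSV, and (if
    fitted) the parameter and model-comparison CSVs there.  The run is fully
    determined by ``config`` including its seed.
    """
    rng = np.random.default_rng(config.seed)
    report: dict = {"config": {"seed": config.seed,
                               "population": dataclasses.asdict(config.population)}}
    log = report.setdefault("log", [])

    log.append("simulate: generating population")
    subjects = generate_population(config.population, rng)
    trials = population_trials(subjects)
    profiles = population_profiles(subjects)

    log.append("metrics: per-subject summaries")
    summaries = summarize_population(trials)
    summaries = summaries.join(profiles)

    log.append("exclusions: applying data-quality filters")
    report_excl = apply_exclusions(summaries)
    report["exclusions"] = dict(
        counts=report_excl.counts,
        n_excluded=len(report_excl.excluded),
        n_retained=len(report_excl.retained),
    )
    kept = summaries.loc[report_excl.retained].copy()
    kept["composite"] = composite_radicalism(kept)

    log.append("regressions: factor interrelations")
    interrel = {}
    for factor in ("dogmatic_intolerance", "authoritarianism"):
        res = quad_vs_linear(kept["political_orientation"], kept[factor])
        interrel[factor] = dict(label=res.label, structure=res.structure,
                                **_regression_record(res.fit))
    fit_da = robust_regress(
        kept["authoritarianism"], kept[["dogmatic_intolerance"]], compute_partial_r2=False
    )
    interrel["authoritarianism_on_dogmatism"] = _regression_record(fit_da)
    report["factor_interrelations"] = interrel

    battery = kept.dropna(subset=set(FACTOR_BATTERY_PREDICTORS) | {"pde_sensitivity", "earnings"})
    report["n_battery"] = len(battery)

    log.append("regressions: PDE sensitivity on metacognition")
    report["pde_sensitivity_regression"] = _regression_record(
        robust_regress(battery["pde_sensitivity"], battery[PDE_BATTERY_PREDICTORS])
    )

    log.append("regressions: factor batteries")
    factors = {}
    for factor in ("dogmatic_intolerance", "authoritarianism", "political_orientation", "composite"):
        factors[factor] = _regression_record(
            robust_regress(battery[factor], battery[FACTOR_BATTERY_PREDICTORS])
        )
    report["factor_regressions"] = factors

    log.append("regressions: earnings")
    report["earnings_regression"] = _regression_record(
        robust_regress(
            battery["earnings"], battery[["composite", "dprime_mean", "log_strength"]]
        )
    )

    fits_tables: Dict[str, pd.DataFrame] = {}
    if config.include_model_fits:
        log.append("fits: per-subject variant fits")
        quad = QuadratureConfig(config.quadrature_n_pre, config.quadrature_n_post)
        subject_tables = [
            s.trials for s in subjects if s.subject_id in set(battery.index)
        ]
        pilot = fit_population(
            subject_tables[:10], variant="base", quadrature=quad,
            share_sigma_report=False, n_starts=1, seed=config.seed,
        )
        sigma_shared = float(np.median([r.params["sigma_report"] for r in pilot]))
        report["sigma_report_shared"] = round(sigma_shared, 6)
        results_by_variant = {}
        for variant in ("temporal_weighting", "choice_weighting", "choice_bias"):
            results = fit_population(
                subject_tables, variant=variant, quadrature=quad,
                sigma_report=sigma_shared,
                n_starts=config.fit_n_starts, seed=config.seed,
            )
            results_by_variant[variant] = results
            fits_tables[variant] = fits_frame(results)
        log.append("comparison: BIC across variants")
        comparison = compare_models_radicalism(
            fits_tables, battery["composite"]
        )
        report["model_comparison"] = json.loads(comparison.round(6).to_json(orient="index"))
        report["best_model"] = str(comparison.index[0])

        if config.include_posterior_predictive:
            log.append("posterior predictive: choice-bias model")
            ppc = posterior_predictive(
                results_by_variant["choice_bias"], battery["composite"],
                n_draws=config.ppc_n_draws, n_trials=config.ppc_n_trials,
                rng=np.random.default_rng(config.seed + 1),
            )
            report["posterior_predictive"] = json.loads(
                ppc.round(6).to_json(orient="records")
            )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summaries.to_csv(out / "subject_summaries.csv")
        for variant, frame in fits_tables.items():
            frame.to_csv(out / f"fits_{variant}.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report
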