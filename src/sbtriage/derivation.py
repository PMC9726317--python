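"""Derivation pipeline for the mural-lesion risk model.

Reproduces the published procedure: seeded cohort split, univariate
screening of all candidate covariates, a multivariate fit of the
univariately significant ones, and a final refit on the five prespecified
predictors regardless of multivariate significance, followed by
Youden-index cutoff selection on the derivation scores and hold-out
validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from sbtriage.fitting import FittedLogistic, SeparationError, fit_logistic_ml
from sbtriage.risk import (
    ClassificationMetrics,
    RiskModel,
    RocCurve,
    confusion_metrics,
    roc_auc,
    score_cohort,
)

#: screening candidates, mirroring the study's univariate table
DEFAULT_CANDIDATES = (
    "age",
    "sex",
    "diabetes",
    "atherosclerosis",
    "ckd",
    "chronic_liver_disease",
    "immunocompromised",
    "cancer_history",
    "nsaids",
    "antiplatelet",
    "anticoagulant",
    "overt_bleeding",
    "abdominal_pain",
    "weight_loss",
    "hemoglobin",
    "albumin",
)

#: the final model always refits these five, whatever the screens say
FINAL_PREDICTORS = ("age", "atherosclerosis", "ckd", "antiplatelet", "albumin")

OUTCOME_COLUMN = "mural"
SIGNIFICANCE_LEVEL = 0.05
WALD_Z = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass(frozen=True)
class UnivariateResult:
    """One covariate's single-predictor logistic screen.

    ``computable`` is False when the fit separates (e.g. a zero cell for a
    binary covariate); the odds ratio and CI are then undefined.
    """

    covariate: str
    odds_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_value: Optional[float]
    computable: bool = True
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.computable:
            if not self.ci_low <= self.odds_ratio <= self.ci_high:
                raise ValueError("odds ratio must lie inside its CI")
            object.__setattr__(
                self, "significant", self.p_value < SIGNIFICANCE_LEVEL
            )
        else:
            object.__setattr__(self, "significant", False)


@dataclass(frozen=True)
class DerivationReport:
    """Everything the derivation pipeline produces."""

    model: RiskModel
    univariate: tuple[UnivariateResult, ...]
    multivariate: tuple[UnivariateResult, ...]
    multivariate_fit: Optional[FittedLogistic]
    final_fit: FittedLogistic
    derivation_roc: RocCurve
    validation_roc: RocCurve
    validation_metrics: ClassificationMetrics
    n_derivation: int
    n_validation: int
    seed: int
    derivation_fraction: float


def split_cohort(
    cohort: pd.DataFrame, derivation_fraction: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded disjoint split into derivation and validation cohorts.

    Implemented as a seeded permutation followed by a prefix take of
    ``round(n * fraction)`` rows; the same seed always yields the same
    partition.
    """
    if not 0.0 < derivation_fraction < 1.0:
        raise ValueError(
            f"derivation_fraction must lie in (0, 1), got {derivation_fraction!r}"
        )
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    n = len(cohort)
    k = int(math.floor(n * derivation_fraction + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    derivation = cohort.iloc[perm[:k]].reset_index(drop=True)
    validation = cohort.iloc[perm[k:]].reset_index(drop=True)
    return derivation, validation


def _wald_result(name: str, slope: float, se: float) -> UnivariateResult:
    or_ = math.exp(slope)
    z = slope / se
    p = 2.0 * stats.norm.sf(abs(z))
    return UnivariateResult(
        covariate=name,
        odds_ratio=or_,
        ci_low=math.exp(slope - WALD_Z * se),
        ci_high=math.exp(slope + WALD_Z * se),
        p_value=float(p),
    )


def univariate_screen(
    cohort: pd.DataFrame, candidates: Sequence[str] = DEFAULT_CANDIDATES
) -> list[UnivariateResult]:
    """Single-covariate logistic fit per candidate with Wald OR/CI/p.

    Candidates whose fit separates (diverging coefficient) are reported as
    not computable rather than dropped.
    """
    if len(candidates) == 0:
        raise ValueError("candidate list is empty")
    if OUTCOME_COLUMN not in cohort.columns:
        raise ValueError(f"cohort lacks outcome column {OUTCOME_COLUMN!r}")
    missing = [c for c in candidates if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks candidate column(s): {', '.join(missing)}")
    y = cohort[OUTCOME_COLUMN].to_numpy(dtype=float)
    results: list[UnivariateResult] = []
    for name in candidates:
        x = cohort[name].to_numpy(dtype=float)
        try:
            fit = fit_logistic_ml(x, y)
        except SeparationError:
            results.append(
                UnivariateResult(
                    covariate=name,
                    odds_ratio=None,
                    ci_low=None,
                    ci_high=None,
                    p_value=None,
                    computable=False,
                )
            )
            continue
        results.append(_wald_result(name, float(fit.coef[1]), float(fit.se[1])))
    return results


def _fit_named(
    cohort: pd.DataFrame, predictors: Sequence[str]
) -> tuple[FittedLogistic, list[UnivariateResult]]:
    X = cohort[list(predictors)].to_numpy(dtype=float)
    y = cohort[OUTCOME_COLUMN].to_numpy(dtype=float)
    fit = fit_logistic_ml(X, y)
    adjusted = [
        _wald_result(name, float(fit.coef[i + 1]), float(fit.se[i + 1]))
        for i, name in enumerate(predictors)
    ]
    return fit, adjusted


def derive_mural_model(
    cohort: pd.DataFrame,
    seed: int,
    derivation_fraction: float = 0.7,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
) -> DerivationReport:
    """Run the full derivation pipeline on a labelled cohort.

    Split -> univariate screen on the derivation cohort -> multivariate fit
    of the univariately significant covariates -> final logistic refit on
    the five prespecified predictors -> Youden cutoff on derivation scores
    -> metrics on the held-out validation cohort at that cutoff.
    """
    derivation, validation = split_cohort(cohort, derivation_fraction, seed)
    univariate = univariate_screen(derivation, candidates)

    significant = [r.covariate for r in univariate if r.significant]
    multivariate_fit: Optional[FittedLogistic] = None
    multivariate: list[UnivariateResult] = []
    if significant:
        multivariate_fit, multivariate = _fit_named(derivation, significant)

    final_fit, _ = _fit_named(derivation, FINAL_PREDICTORS)
    coef = final_fit.coef

    derivation_scores = _scores_from_fit(derivation, coef)
    derivation_roc = roc_auc(derivation_scores, derivation[OUTCOME_COLUMN])
    cutoff = derivation_roc.youden_cutoff

    model = RiskModel(
        intercept=float(coef[0]),
        coef_age=float(coef[1]),
        coef_atherosclerosis=float(coef[2]),
        coef_ckd=float(coef[3]),
        coef_antiplatelet=float(coef[4]),
        coef_albumin=float(coef[5]),
        cutoff_percent=float(cutoff),
    )

    validation_scores = score_cohort(validation, model)
    validation_roc = roc_auc(validation_scores, validation[OUTCOME_COLUMN])
    predicted = (validation_scores >= model.cutoff_percent).astype(int)
    validation_metrics = confusion_metrics(validation[OUTCOME_COLUMN], predicted)

    return DerivationReport(
        model=model,
        univariate=tuple(univariate),
        multivariate=tuple(multivariate),
        multivariate_fit=multivariate_fit,
        final_fit=final_fit,
        derivation_roc=derivation_roc,
        validation_roc=validation_roc,
        validation_metrics=validation_metrics,
        n_derivation=len(derivation),
        n_validation=len(validation),
        seed=seed,
        derivation_fraction=derivation_fraction,
    )


def _scores_from_fit(cohort: pd.DataFrame, coef: np.ndarray) -> np.ndarray:
    lp = np.full(len(cohort), coef[0])
    for i, name in enumerate(FINAL_PREDICTORS):
        lp += coef[i + 1] * cohort[name].to_numpy(dtype=float)
    return 100.0 / (1.0 + np.exp(-lp))
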