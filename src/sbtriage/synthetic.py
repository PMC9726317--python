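"""Synthetic patient cohorts and a patient-level diagnostic simulator.

``generate_cohort`` emulates the study cohort's covariate structure in two
modes: *group-conditional* (draw the outcome label first, then covariates
from per-group distributions) and *mechanism* (draw covariates from pooled
distributions, then label via a Bernoulli draw on the logistic
probability).  Binary covariates are sampled independently within group;
only per-group marginal rates are available, so no correlation structure
is imposed.

``simulate_diagnostic_cohort`` is the stochastic counterpart of the
expected-value decision model and serves as its Monte-Carlo oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from sbtriage.cea import LESIONS, MURAL_LESION, CeaParameters, STRATEGIES
from sbtriage.risk import RiskModel

AGE_BOUNDS = (18.0, 100.0)
ALBUMIN_BOUNDS = (1.0, 6.0)
HEMOGLOBIN_BOUNDS = (1.0, 20.0)

#: per-group covariate distributions in the derivation cohort
#: (normal mean/sd for continuous, Bernoulli rate for flags)
MURAL_GROUP = {
    "age": (57.7, 13.0),
    "albumin": (3.87, 0.71),
    "hemoglobin": (6.92, 1.94),
    "sex": 21 / 34,
    "diabetes": 6 / 34,
    "atherosclerosis": 3 / 34,
    "ckd": 4 / 34,
    "chronic_liver_disease": 4 / 34,
    "immunocompromised": 0 / 34,
    "cancer_history": 6 / 34,
    "nsaids": 3 / 34,
    "antiplatelet": 3 / 34,
    "anticoagulant": 2 / 34,
    "overt_bleeding": 22 / 34,
    "abdominal_pain": 1 / 34,
    "weight_loss": 5 / 34,
}

NON_MURAL_GROUP = {
    "age": (65.3, 15.4),
    "albumin": (3.35, 0.74),
    "hemoglobin": (7.35, 2.21),
    "sex": 78 / 162,
    "diabetes": 52 / 162,
    "atherosclerosis": 63 / 162,
    "ckd": 58 / 162,
    "chronic_liver_disease": 30 / 162,
    "immunocompromised": 11 / 162,
    "cancer_history": 22 / 162,
    "nsaids": 8 / 162,
    "antiplatelet": 58 / 162,
    "anticoagulant": 26 / 162,
    "overt_bleeding": 107 / 162,
    "abdominal_pain": 7 / 162,
    "weight_loss": 10 / 162,
}

#: pooled covariate distributions (complete-laboratory cohort marginals)
POOLED = {
    "age": (66.5, 15.0),
    "albumin": (3.41, 0.74),
    "hemoglobin": (7.3, 2.1),
    "sex": 147 / 296,
    "diabetes": 92 / 296,
    "atherosclerosis": 107 / 296,
    "ckd": 97 / 296,
    "chronic_liver_disease": 0.091,
    "immunocompromised": 14 / 296,
    "cancer_history": 41 / 296,
    "nsaids": 18 / 296,
    "antiplatelet": 97 / 296,
    "anticoagulant": 42 / 296,
    "overt_bleeding": 200 / 296,
    "abdominal_pain": 12 / 296,
    "weight_loss": 25 / 296,
}

DEFAULT_MURAL_PREVALENCE = 34 / 196

CONTINUOUS = ("age", "albumin", "hemoglobin")
_BOUNDS = {"age": AGE_BOUNDS, "albumin": ALBUMIN_BOUNDS, "hemoglobin": HEMOGLOBIN_BOUNDS}
BINARY = tuple(k for k in MURAL_GROUP if k not in CONTINUOUS)

COHORT_COLUMNS = CONTINUOUS + BINARY + ("mural",)


@dataclass
class SyntheticCohortSpec:
    """Recipe for a synthetic labelled cohort.

    mode ``"group"``: Bernoulli outcome at ``mural_prevalence``, then
    covariates from per-group distributions.  mode ``"mechanism"``:
    covariates from pooled distributions, then outcome via the logistic
    probability of ``model``.
    """

    mode: str = "group"
    n: int = 100
    seed: int = 0
    mural_prevalence: float = DEFAULT_MURAL_PREVALENCE
    mural_group: dict = field(default_factory=lambda: dict(MURAL_GROUP))
    non_mural_group: dict = field(default_factory=lambda: dict(NON_MURAL_GROUP))
    pooled: dict = field(default_factory=lambda: dict(POOLED))
    model: RiskModel = field(default_factory=RiskModel)

    def __post_init__(self) -> None:
        if self.mode not in ("group", "mechanism"):
            raise ValueError(f"mode must be 'group' or 'mechanism', got {self.mode!r}")
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if not 0.0 <= self.mural_prevalence <= 1.0:
            raise ValueError("mural_prevalence must lie in [0, 1]")
        for table in (self.mural_group, self.non_mural_group, self.pooled):
            for name in CONTINUOUS:
                mean, sd = table[name]
                if sd <= 0:
                    raise ValueError(f"{name} sd must be positive, got {sd!r}")
            for name in BINARY:
                rate = table[name]
                if not 0.0 <= rate <= 1.0:
                    raise ValueError(f"{name} rate must lie in [0, 1], got {rate!r}")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float], n: int
) -> np.ndarray:
    lo, hi = bounds
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _draw_covariates(rng: np.random.Generator, table: dict, n: int) -> dict[str, np.ndarray]:
    draws: dict[str, np.ndarray] = {}
    for name in CONTINUOUS:
        mean, sd = table[name]
        draws[name] = _truncated_normal(rng, mean, sd, _BOUNDS[name], n)
    for name in BINARY:
        draws[name] = (rng.random(n) < table[name]).astype(int)
    return draws


def generate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Generate a labelled cohort data frame; identical spec => identical
    cohort."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in COHORT_COLUMNS})

    if spec.mode == "group":
        mural = (rng.random(n) < spec.mural_prevalence).astype(int)
        mural_draws = _draw_covariates(rng, spec.mural_group, n)
        non_mural_draws = _draw_covariates(rng, spec.non_mural_group, n)
        data = {
            name: np.where(mural == 1, mural_draws[name], non_mural_draws[name])
            for name in CONTINUOUS + BINARY
        }
        data["mural"] = mural
    else:
        data = _draw_covariates(rng, spec.pooled, n)
        frame = pd.DataFrame(data)
        lp = np.full(n, spec.model.intercept)
        for name, coef in spec.model.coefficients.items():
            lp += coef * frame[name].to_numpy()
        prob = 1.0 / (1.0 + np.exp(-lp))
        data["mural"] = (rng.random(n) < prob).astype(int)

    frame = pd.DataFrame(data, columns=list(COHORT_COLUMNS))
    for name in BINARY + ("mural",):
        frame[name] = frame[name].astype(int)
    return frame


@dataclass(frozen=True)
class SimulationTallies:
    """Patient-level trajectories and their aggregate tallies."""

    strategy: str
    n: int
    seed: int
    lesions: np.ndarray  # lesion index per patient
    missed: np.ndarray  # bool per patient: own lesion undetected at the end
    vce_per_patient: np.ndarray  # int count of VCE charges per patient
    cte_per_patient: np.ndarray  # int count of CTE charges per patient
    lesion_counts: dict[str, int]
    missed_counts: dict[str, int]
    vce_count: int
    cte_count: int
    cost_total: dict[str, float]

    def per_hundred(self, value: float) -> float:
        return 100.0 * value / self.n


def simulate_diagnostic_cohort(
    n: int,
    params: CeaParameters,
    strategy: str,
    seed: int,
) -> SimulationTallies:
    """Monte-Carlo simulation of one strategy over ``n`` patients.

    Mirrors the expected-value engine's conventions exactly: staging CTEs
    after a VCE tumor call detect nothing; false tumor calls are drawn
    independently of own-lesion detection; VCE-negatives of a sequential
    strategy always cross over while CTE-negatives cross over only when no
    false-positive call occurred (probability = CTE specificity).  In the
    VCE-then-CTE strategy a patient can be charged two CTEs (one staging,
    one crossover), matching the additive expected count.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if n <= 0:
        raise ValueError("n must be positive")
    params.validate()
    rng = np.random.default_rng(seed)

    prev = np.array([params.prevalence[lesion] for lesion in LESIONS])
    lesions = rng.choice(len(LESIONS), size=n, p=prev)
    tumor_idx = LESIONS.index(MURAL_LESION)
    is_tumor = lesions == tumor_idx

    vce_sens = np.array([params.vce_sensitivity[lesion] for lesion in LESIONS])
    cte_sens = np.array([params.cte_sensitivity[lesion] for lesion in LESIONS])

    detect_vce = rng.random(n) < vce_sens[lesions]
    detect_cte = rng.random(n) < cte_sens[lesions]
    false_tumor_call = ~is_tumor & (
        rng.random(n) < 1.0 - params.vce_specificity[MURAL_LESION]
    )
    # a CTE with no false-positive call; gates crossover after a missed CTE
    cte_truly_negative = rng.random(n) < params.cte_specificity[MURAL_LESION]
    triage_mural = np.where(
        is_tumor,
        rng.random(n) < params.triage_sensitivity,
        rng.random(n) < 1.0 - params.triage_specificity,
    )

    vce_charges = np.zeros(n, dtype=np.int64)
    cte_charges = np.zeros(n, dtype=np.int64)
    tumor_call = (is_tumor & detect_vce) | false_tumor_call

    if strategy == "vce":
        vce_charges += 1
        cte_charges += tumor_call
        missed = ~detect_vce
    elif strategy == "cte":
        cte_charges += 1
        missed = ~detect_cte
    elif strategy == "triage":
        to_cte = triage_mural
        cte_charges += to_cte
        vce_charges += ~to_cte
        cte_charges += ~to_cte & tumor_call
        missed = np.where(to_cte, ~detect_cte, ~detect_vce)
    elif strategy == "vce_cte":
        vce_charges += 1
        first_missed = ~detect_vce
        cte_charges += first_missed.astype(np.int64) + tumor_call.astype(np.int64)
        missed = first_missed & ~detect_cte
    elif strategy == "cte_vce":
        cte_charges += 1
        first_missed = ~detect_cte
        crossover = first_missed & cte_truly_negative
        vce_charges += crossover
        missed = first_missed & ~(crossover & detect_vce)
    else:  # triage_crossover
        to_cte = triage_mural
        cte_charges += to_cte
        vce_charges += ~to_cte
        cte_first_missed = to_cte & ~detect_cte
        cte_crossover = cte_first_missed & cte_truly_negative
        vce_charges += cte_crossover
        vce_first_missed = ~to_cte & ~detect_vce
        cte_charges += vce_first_missed
        cte_charges += ~to_cte & tumor_call
        missed_cte_arm = cte_first_missed & ~(cte_crossover & detect_vce)
        missed_vce_arm = vce_first_missed & ~detect_cte
        missed = np.where(to_cte, missed_cte_arm, missed_vce_arm)

    lesion_counts = {
        lesion: int((lesions == i).sum()) for i, lesion in enumerate(LESIONS)
    }
    missed_counts = {
        lesion: int((missed & (lesions == i)).sum())
        for i, lesion in enumerate(LESIONS)
    }
    vce_count = int(vce_charges.sum())
    cte_count = int(cte_charges.sum())
    cost_total = {
        currency: vce_count * table["vce"] + cte_count * table["cte"]
        for currency, table in params.costs.items()
    }
    return SimulationTallies(
        strategy=strategy,
        n=n,
        seed=seed,
        lesions=lesions,
        missed=missed,
        vce_per_patient=vce_charges,
        cte_per_patient=cte_charges,
        lesion_counts=lesion_counts,
        missed_counts=missed_counts,
        vce_count=vce_count,
        cte_count=cte_count,
        cost_total=cost_total,
    )
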