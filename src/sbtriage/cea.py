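"""Expected-value decision model for six diagnostic strategies.

Each patient in a standard cohort (default 100) carries exactly one lesion
(angiodysplasia, ulcer/inflammation, or tumor).  A test detects the
patient's own lesion with the lesion-specific sensitivity.  Tumor is the
mural lesion class: the triage classifier routes tumor patients with its
sensitivity and non-tumor patients with one minus its specificity.

Modelling conventions (reconstructed from the published outcome table):

* Any VCE tumor call — a true positive (tumor patients x tumor
  sensitivity) or a false positive (non-tumor patients x (1 - tumor
  specificity)) — triggers a staging CTE.  The staging CTE contributes to
  test counts and cost but detects nothing further.
* After a negative CTE, the crossover pool is the expected misses
  multiplied by the CTE specificity (patients with a false-positive CTE
  call do not cross over and stay missed).  After a negative VCE, the
  crossover pool is NOT specificity-adjusted.  The asymmetry reproduces
  the published VCE and CTE follow-up counts.
* Reported integers use round-half-down (4.5 -> 4); expected values are
  kept unrounded alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

LESIONS = ("angiodysplasia", "ulcer", "tumor")
MURAL_LESION = "tumor"
CURRENCIES = ("USD", "THB")
STRATEGIES = ("vce", "cte", "triage", "vce_cte", "cte_vce", "triage_crossover")

_PREVALENCE_TOL = 1e-9


def round_half_down(x: float) -> int:
    """Round to the nearest integer, with exact halves rounding down.

    The value is first snapped to 9 decimals so that binary float noise
    (e.g. 30 * 0.15000000000000002) cannot flip a half across the rule.
    """
    return int(math.ceil(round(x, 9) - 0.5))


def _default_prevalence() -> dict[str, float]:
    return {"angiodysplasia": 0.50, "ulcer": 0.30, "tumor": 0.20}


def _default_vce_sens() -> dict[str, float]:
    return {"angiodysplasia": 0.90, "ulcer": 0.85, "tumor": 0.55}


def _default_vce_spec() -> dict[str, float]:
    return {"angiodysplasia": 0.90, "ulcer": 0.99, "tumor": 0.90}


def _default_cte_sens() -> dict[str, float]:
    return {"angiodysplasia": 0.20, "ulcer": 0.30, "tumor": 0.90}


def _default_cte_spec() -> dict[str, float]:
    return {"angiodysplasia": 0.99, "ulcer": 0.99, "tumor": 0.99}


def _default_costs() -> dict[str, dict[str, float]]:
    return {
        "USD": {"vce": 1247.0, "cte": 518.0},
        "THB": {"vce": 42000.0, "cte": 15400.0},
    }


#: plausible ranges for one-way sensitivity analysis (base-case source table)
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "vce_sensitivity.angiodysplasia": (0.60, 1.00),
    "vce_specificity.angiodysplasia": (0.86, 1.00),
    "vce_sensitivity.ulcer": (0.81, 1.00),
    "vce_specificity.ulcer": (0.99, 1.00),
    "vce_sensitivity.tumor": (0.33, 0.70),
    "vce_specificity.tumor": (0.86, 1.00),
    "cte_sensitivity.angiodysplasia": (0.00, 0.80),
    "cte_specificity.angiodysplasia": (0.99, 1.00),
    "cte_sensitivity.ulcer": (0.09, 0.667),
    "cte_specificity.ulcer": (0.99, 1.00),
    "cte_sensitivity.tumor": (0.70, 1.00),
    "cte_specificity.tumor": (0.97, 1.00),
}


@dataclass
class CeaParameters:
    """Base-case parameters of the decision model."""

    cohort_size: float = 100.0
    prevalence: dict[str, float] = field(default_factory=_default_prevalence)
    vce_sensitivity: dict[str, float] = field(default_factory=_default_vce_sens)
    vce_specificity: dict[str, float] = field(default_factory=_default_vce_spec)
    cte_sensitivity: dict[str, float] = field(default_factory=_default_cte_sens)
    cte_specificity: dict[str, float] = field(default_factory=_default_cte_spec)
    triage_sensitivity: float = 0.735
    triage_specificity: float = 0.790
    costs: dict[str, dict[str, float]] = field(default_factory=_default_costs)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be positive")
        for table_name in (
            "prevalence",
            "vce_sensitivity",
            "vce_specificity",
            "cte_sensitivity",
            "cte_specificity",
        ):
            table = getattr(self, table_name)
            for lesion in LESIONS:
                if lesion not in table:
                    raise ValueError(f"{table_name} lacks lesion {lesion!r}")
                value = table[lesion]
                if not 0.0 <= value <= 1.0:
                    raise ValueError(
                        f"{table_name}[{lesion!r}] must lie in [0, 1], got {value!r}"
                    )
        total = sum(self.prevalence[lesion] for lesion in LESIONS)
        if abs(total - 1.0) > _PREVALENCE_TOL:
            raise ValueError(f"prevalences must sum to 1, got {total!r}")
        for prob_name in ("triage_sensitivity", "triage_specificity"):
            value = getattr(self, prob_name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{prob_name} must lie in [0, 1], got {value!r}")
        for currency, table in self.costs.items():
            for modality in ("vce", "cte"):
                if modality not in table:
                    raise ValueError(f"costs[{currency!r}] lacks {modality!r}")
                if table[modality] <= 0:
                    raise ValueError(
                        f"costs[{currency!r}][{modality!r}] must be positive"
                    )

    def lesion_count(self, lesion: str) -> float:
        return self.prevalence[lesion] * self.cohort_size

    def copy(self) -> "CeaParameters":
        return CeaParameters(
            cohort_size=self.cohort_size,
            prevalence=dict(self.prevalence),
            vce_sensitivity=dict(self.vce_sensitivity),
            vce_specificity=dict(self.vce_specificity),
            cte_sensitivity=dict(self.cte_sensitivity),
            cte_specificity=dict(self.cte_specificity),
            triage_sensitivity=self.triage_sensitivity,
            triage_specificity=self.triage_specificity,
            costs={c: dict(t) for c, t in self.costs.items()},
        )


@dataclass(frozen=True)
class StrategyOutcome:
    """Expected outcomes of one strategy over the standard cohort."""

    strategy: str
    missed: dict[str, float]
    missed_rounded: dict[str, int]
    total_missed: float
    total_missed_rounded: int
    vce_count: float
    cte_count: float
    vce_count_rounded: int
    cte_count_rounded: int
    total_investigations: float
    total_investigations_rounded: int
    cost_per_patient: dict[str, float]
    cost_per_patient_rounded: dict[str, int]


def _tumor_calls(counts: Mapping[str, float], params: CeaParameters) -> float:
    """Expected VCE tumor calls (true + false positives) in a subpopulation."""
    calls = counts[MURAL_LESION] * params.vce_sensitivity[MURAL_LESION]
    fp_rate = 1.0 - params.vce_specificity[MURAL_LESION]
    for lesion in LESIONS:
        if lesion != MURAL_LESION:
            calls += counts[lesion] * fp_rate
    return calls


def _outcome(
    strategy: str,
    missed: dict[str, float],
    vce_count: float,
    cte_count: float,
    params: CeaParameters,
) -> StrategyOutcome:
    missed_rounded = {lesion: round_half_down(missed[lesion]) for lesion in LESIONS}
    total_missed = sum(missed.values())
    cost = {}
    cost_rounded = {}
    for currency, table in params.costs.items():
        per_patient = (
            vce_count * table["vce"] + cte_count * table["cte"]
        ) / params.cohort_size
        cost[currency] = per_patient
        cost_rounded[currency] = round_half_down(per_patient)
    total = vce_count + cte_count
    return StrategyOutcome(
        strategy=strategy,
        missed=missed,
        missed_rounded=missed_rounded,
        total_missed=total_missed,
        total_missed_rounded=sum(missed_rounded.values()),
        vce_count=vce_count,
        cte_count=cte_count,
        vce_count_rounded=round_half_down(vce_count),
        cte_count_rounded=round_half_down(cte_count),
        total_investigations=total,
        total_investigations_rounded=round_half_down(vce_count)
        + round_half_down(cte_count),
        cost_per_patient=cost,
        cost_per_patient_rounded=cost_rounded,
    )


def _triage_arms(params: CeaParameters) -> tuple[dict[str, float], dict[str, float]]:
    """Per-lesion expected counts routed to the CTE (predicted mural) and
    VCE (predicted non-mural) arms by the triage classifier."""
    cte_arm = {}
    vce_arm = {}
    for lesion in LESIONS:
        n = params.lesion_count(lesion)
        if lesion == MURAL_LESION:
            to_cte = n * params.triage_sensitivity
        else:
            to_cte = n * (1.0 - params.triage_specificity)
        cte_arm[lesion] = to_cte
        vce_arm[lesion] = n - to_cte
    return cte_arm, vce_arm


def evaluate_strategy(
    strategy: str,
    params: CeaParameters,
    compat_triage_followup: bool = False,
) -> StrategyOutcome:
    """Deterministic expected-value outcomes for one strategy.

    ``compat_triage_followup`` replicates the published follow-up-CTE
    heuristic for the triage-first strategy (the whole-cohort VCE follow-up
    rate applied to the triage VCE arm) instead of the first-principles
    per-arm tumor-call computation.
    """
    if strategy not in STRATEGIES:
        raise ValueError(
            f"unknown strategy {strategy!r}; expected one of {STRATEGIES}"
        )
    params.validate()
    counts = {lesion: params.lesion_count(lesion) for lesion in LESIONS}
    vce_miss = {
        lesion: 1.0 - params.vce_sensitivity[lesion] for lesion in LESIONS
    }
    cte_miss = {
        lesion: 1.0 - params.cte_sensitivity[lesion] for lesion in LESIONS
    }
    cte_neg_rate = params.cte_specificity[MURAL_LESION]

    if strategy == "vce":
        missed = {lesion: counts[lesion] * vce_miss[lesion] for lesion in LESIONS}
        vce_count = params.cohort_size
        cte_count = _tumor_calls(counts, params)

    elif strategy == "cte":
        missed = {lesion: counts[lesion] * cte_miss[lesion] for lesion in LESIONS}
        vce_count = 0.0
        cte_count = params.cohort_size

    elif strategy == "triage":
        cte_arm, vce_arm = _triage_arms(params)
        missed = {
            lesion: cte_arm[lesion] * cte_miss[lesion]
            + vce_arm[lesion] * vce_miss[lesion]
            for lesion in LESIONS
        }
        vce_count = sum(vce_arm.values())
        if compat_triage_followup:
            whole_cohort_rate = _tumor_calls(counts, params) / params.cohort_size
            followups = vce_count * whole_cohort_rate
        else:
            followups = _tumor_calls(vce_arm, params)
        cte_count = sum(cte_arm.values()) + followups

    elif strategy == "vce_cte":
        first_missed = {
            lesion: counts[lesion] * vce_miss[lesion] for lesion in LESIONS
        }
        missed = {
            lesion: first_missed[lesion] * cte_miss[lesion] for lesion in LESIONS
        }
        vce_count = params.cohort_size
        cte_count = sum(first_missed.values()) + _tumor_calls(counts, params)

    elif strategy == "cte_vce":
        first_missed = {
            lesion: counts[lesion] * cte_miss[lesion] for lesion in LESIONS
        }
        crossover = {
            lesion: first_missed[lesion] * cte_neg_rate for lesion in LESIONS
        }
        missed = {
            lesion: first_missed[lesion]
            - crossover[lesion] * params.vce_sensitivity[lesion]
            for lesion in LESIONS
        }
        vce_count = sum(crossover.values())
        cte_count = params.cohort_size

    else:  # triage_crossover
        cte_arm, vce_arm = _triage_arms(params)
        # CTE-first arm: misses cross to VCE after a truly negative CTE
        cte_arm_missed = {
            lesion: cte_arm[lesion] * cte_miss[lesion] for lesion in LESIONS
        }
        cte_arm_crossover = {
            lesion: cte_arm_missed[lesion] * cte_neg_rate for lesion in LESIONS
        }
        # VCE-first arm: all misses cross to CTE; tumor calls add staging CTEs
        vce_arm_missed = {
            lesion: vce_arm[lesion] * vce_miss[lesion] for lesion in LESIONS
        }
        missed = {
            lesion: (
                cte_arm_missed[lesion]
                - cte_arm_crossover[lesion] * params.vce_sensitivity[lesion]
            )
            + vce_arm_missed[lesion] * cte_miss[lesion]
            for lesion in LESIONS
        }
        vce_count = sum(vce_arm.values()) + sum(cte_arm_crossover.values())
        cte_count = (
            sum(cte_arm.values())
            + sum(vce_arm_missed.values())
            + _tumor_calls(vce_arm, params)
        )

    return _outcome(strategy, missed, vce_count, cte_count, params)


def compare_strategies(
    params: CeaParameters | None = None,
    compat_triage_followup: bool = False,
) -> list[StrategyOutcome]:
    """Evaluate all six strategies, ordered as published."""
    if params is None:
        params = CeaParameters()
    return [
        evaluate_strategy(s, params, compat_triage_followup=compat_triage_followup)
        for s in STRATEGIES
    ]


def cost_difference_vs_vce(
    outcomes: Iterable[StrategyOutcome],
) -> dict[str, dict[str, float]]:
    """Per-strategy cost-per-patient difference relative to the VCE-first
    strategy, per currency (negative = cheaper than VCE)."""
    by_name = {o.strategy: o for o in outcomes}
    reference = by_name["vce"]
    return {
        name: {
            currency: o.cost_per_patient[currency]
            - reference.cost_per_patient[currency]
            for currency in o.cost_per_patient
        }
        for name, o in by_name.items()
    }


def _set_parameter(params: CeaParameters, name: str, value: float) -> None:
    parts = name.split(".")
    target = params
    obj: object = params
    for part in parts[:-1]:
        if isinstance(obj, dict):
            if part not in obj:
                raise ValueError(f"unknown parameter path {name!r}")
            obj = obj[part]
        else:
            if not hasattr(obj, part):
                raise ValueError(f"unknown parameter path {name!r}")
            obj = getattr(obj, part)
    leaf = parts[-1]
    if isinstance(obj, dict):
        if leaf not in obj:
            raise ValueError(f"unknown parameter path {name!r}")
        obj[leaf] = value
    else:
        if not hasattr(obj, leaf):
            raise ValueError(f"unknown parameter path {name!r}")
        setattr(obj, leaf, value)
    target.validate()


def one_way_sensitivity(
    params: CeaParameters | None = None,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    compat_triage_followup: bool = False,
) -> list[dict]:
    """Re-evaluate all strategies at each parameter-range endpoint.

    One parameter moves at a time; everything else stays at base case.
    Returns tidy long-format records with keys ``parameter``, ``endpoint``
    (``low``/``high``), ``parameter_value``, ``strategy``, ``outcome``,
    ``value``.
    """
    if params is None:
        params = CeaParameters()
    if ranges is None:
        ranges = DEFAULT_RANGES
    records: list[dict] = []
    for name, endpoints in ranges.items():
        try:
            low, high = endpoints
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"range for {name!r} must be a (low, high) pair"
            ) from exc
        if low > high:
            raise ValueError(f"range for {name!r} has low > high")
        for endpoint, value in (("low", low), ("high", high)):
            perturbed = params.copy()
            _set_parameter(perturbed, name, value)
            for outcome in compare_strategies(
                perturbed, compat_triage_followup=compat_triage_followup
            ):
                rows = {
                    **{
                        f"missed_{lesion}": outcome.missed[lesion]
                        for lesion in LESIONS
                    },
                    "total_missed": outcome.total_missed,
                    "vce_count": outcome.vce_count,
                    "cte_count": outcome.cte_count,
                    **{
                        f"cost_per_patient_{currency}": outcome.cost_per_patient[
                            currency
                        ]
                        for currency in outcome.cost_per_patient
                    },
                }
                for outcome_name, outcome_value in rows.items():
                    records.append(
                        {
                            "parameter": name,
                            "endpoint": endpoint,
                            "parameter_value": value,
                            "strategy": outcome.strategy,
                            "outcome": outcome_name,
                            "value": outcome_value,
                        }
                    )
    return records
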