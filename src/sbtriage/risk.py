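"""Logistic risk score for mural-based small-bowel bleeding lesions.

The default :class:`RiskModel` carries the published five-predictor formula
(age, atherosclerosis, chronic kidney disease, antiplatelet use, serum
albumin) and its classification cutoff.  Probabilities are handled in
percent units throughout; conversion to (0, 1) happens only inside the
likelihood arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: predictors the risk formula requires, in formula order
REQUIRED_PREDICTORS = ("age", "atherosclerosis", "ckd", "antiplatelet", "albumin")

#: additional covariates a cohort may carry (screening candidates, outcome)
OPTIONAL_BINARY_COVARIATES = (
    "sex",
    "diabetes",
    "chronic_liver_disease",
    "immunocompromised",
    "cancer_history",
    "nsaids",
    "anticoagulant",
    "overt_bleeding",
    "abdominal_pain",
    "weight_loss",
)


def _check_binary(name: str, value) -> None:
    if value not in (0, 1):
        raise ValueError(f"{name} must be 0 or 1, got {value!r}")


@dataclass
class PatientCovariates:
    """One patient's predictors, optional screening covariates, and outcome.

    ``age`` in years, ``albumin`` in g/dL; all flags are 0/1 indicators.
    ``mural`` is the optional outcome label (1 = mural-based lesion).
    """

    age: float
    atherosclerosis: int
    ckd: int
    antiplatelet: int
    albumin: float
    sex: Optional[int] = None
    diabetes: Optional[int] = None
    chronic_liver_disease: Optional[int] = None
    immunocompromised: Optional[int] = None
    cancer_history: Optional[int] = None
    nsaids: Optional[int] = None
    anticoagulant: Optional[int] = None
    overt_bleeding: Optional[int] = None
    abdominal_pain: Optional[int] = None
    weight_loss: Optional[int] = None
    hemoglobin: Optional[float] = None
    mural: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("age", "albumin"):
            value = getattr(self, name)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise ValueError(f"missing required predictor: {name}")
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value!r}")
        for name in ("atherosclerosis", "ckd", "antiplatelet"):
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"missing required predictor: {name}")
            _check_binary(name, value)
        for name in OPTIONAL_BINARY_COVARIATES + ("mural",):
            value = getattr(self, name)
            if value is not None:
                _check_binary(name, value)


@dataclass
class RiskModel:
    """Intercept, five per-unit log-odds coefficients, and a percent cutoff.

    Defaults reproduce the published formula:

        P = 100 / (1 + exp(-(-3.7207 - 0.00696*age - 1.0531*atherosclerosis
                             - 0.6161*ckd - 0.8276*antiplatelet
                             + 0.8627*albumin)))

    with classification cutoff 24.2 (percent).
    """

    intercept: float = -3.7207
    coef_age: float = -0.00696
    coef_atherosclerosis: float = -1.0531
    coef_ckd: float = -0.6161
    coef_antiplatelet: float = -0.8276
    coef_albumin: float = 0.8627
    cutoff_percent: float = 24.2

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not math.isfinite(value):
                raise ValueError(f"{f.name} must be finite, got {value!r}")
        if not 0.0 < self.cutoff_percent < 100.0:
            raise ValueError(
                f"cutoff_percent must lie in (0, 100), got {self.cutoff_percent!r}"
            )

    @property
    def coefficients(self) -> dict[str, float]:
        """Predictor name -> coefficient, excluding the intercept."""
        return {
            "age": self.coef_age,
            "atherosclerosis": self.coef_atherosclerosis,
            "ckd": self.coef_ckd,
            "antiplatelet": self.coef_antiplatelet,
            "albumin": self.coef_albumin,
        }

    def linear_predictor(self, cov: PatientCovariates) -> float:
        lp = self.intercept
        for name, coef in self.coefficients.items():
            lp += coef * getattr(cov, name)
        return lp


@dataclass(frozen=True)
class ClassificationMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        n = self.tp + self.fp + self.tn + self.fn
        object.__setattr__(self, "sensitivity", self.tp / (self.tp + self.fn))
        object.__setattr__(self, "specificity", self.tn / (self.tn + self.fp))
        object.__setattr__(self, "accuracy", (self.tp + self.tn) / n)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class RocCurve:
    """ROC points (1-specificity, sensitivity), AUROC, and Youden cutoff."""

    points: tuple[tuple[float, float], ...]
    auc: float
    youden_cutoff: float
    youden_j: float


def _expit(x: float) -> float:
    # numerically safe for large |x|
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def mural_probability(cov: PatientCovariates, model: RiskModel | None = None) -> float:
    """Percent probability of a mural-based lesion for one patient.

    Returns ``100 * logistic(intercept + sum(coef * value))``, strictly
    inside (0, 100) for finite inputs.
    """
    if model is None:
        model = RiskModel()
    return 100.0 * _expit(model.linear_predictor(cov))


def score_cohort(cohort: pd.DataFrame, model: RiskModel | None = None) -> np.ndarray:
    """Vectorised percent probabilities for a cohort data frame.

    The frame must carry the five required predictor columns; rows are
    scored independently.
    """
    if model is None:
        model = RiskModel()
    for name in REQUIRED_PREDICTORS:
        if name not in cohort.columns:
            raise ValueError(f"missing required predictor column: {name}")
        if cohort[name].isna().any():
            raise ValueError(f"missing values in predictor column: {name}")
    lp = np.full(len(cohort), model.intercept, dtype=float)
    for name, coef in model.coefficients.items():
        lp += coef * cohort[name].to_numpy(dtype=float)
    with np.errstate(over="ignore"):
        return 100.0 / (1.0 + np.exp(-lp))


def classify_patient(prob_percent: float, cutoff_percent: float) -> str:
    """Classify a percent probability at a percent cutoff.

    Returns ``"mural"`` iff ``prob >= cutoff`` (a tie counts as mural, so
    the published cutoff value itself is actionable), else ``"non-mural"``.
    """
    if not 0.0 < prob_percent < 100.0:
        raise ValueError(f"prob_percent must lie in (0, 100), got {prob_percent!r}")
    if not 0.0 < cutoff_percent < 100.0:
        raise ValueError(f"cutoff_percent must lie in (0, 100), got {cutoff_percent!r}")
    return "mural" if prob_percent >= cutoff_percent else "non-mural"


def _as_binary_array(values: Sequence, what: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValueError(f"{what} is empty")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{what} must contain only 0/1 values")
    return arr.astype(int)


def confusion_metrics(true_labels: Sequence, predicted_labels: Sequence) -> ClassificationMetrics:
    """Confusion counts and sensitivity/specificity/accuracy.

    Requires equal-length 0/1 sequences and at least one positive and one
    negative in the truth.
    """
    y = _as_binary_array(true_labels, "true_labels")
    yhat = _as_binary_array(predicted_labels, "predicted_labels")
    if y.shape != yhat.shape:
        raise ValueError("true_labels and predicted_labels differ in length")
    if y.all():
        raise ValueError("degenerate truth: no negative labels")
    if not y.any():
        raise ValueError("degenerate truth: no positive labels")
    tp = int(((y == 1) & (yhat == 1)).sum())
    fp = int(((y == 0) & (yhat == 1)).sum())
    tn = int(((y == 0) & (yhat == 0)).sum())
    fn = int(((y == 1) & (yhat == 0)).sum())
    return ClassificationMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def _roc_points(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """FPR/TPR swept over all distinct score thresholds (>= rule), plus the
    distinct thresholds in descending order."""
    thresholds = np.unique(scores)[::-1]
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        call = scores >= t
        tpr.append(float((call & (y == 1)).sum() / n_pos))
        fpr.append(float((call & (y == 0)).sum() / n_neg))
    # close the curve at (1, 1); already there when min(score) sweeps all in
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:
        fpr.append(1.0)
        tpr.append(1.0)
    return np.asarray(fpr), np.asarray(tpr), thresholds


def _validate_scores_labels(scores: Sequence, true_labels: Sequence) -> tuple[np.ndarray, np.ndarray]:
    y = _as_binary_array(true_labels, "true_labels")
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and true_labels differ in length")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if y.all() or not y.any():
        missing = "negative" if y.all() else "positive"
        raise ValueError(f"degenerate truth: no {missing} labels")
    return s, y


def youden_optimal_cutoff(scores: Sequence, true_labels: Sequence) -> tuple[float, float]:
    """Observed score maximizing J = sensitivity + specificity - 1.

    Classification uses the >= rule; ties in J break toward the larger
    cutoff (higher specificity).  Returns ``(cutoff, J)``.
    """
    s, y = _validate_scores_labels(scores, true_labels)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    best_cutoff = math.nan
    best_j = -math.inf
    for t in np.unique(s)[::-1]:  # descending: first hit wins ties upward
        call = s >= t
        sens = float((call & (y == 1)).sum() / n_pos)
        spec = float((~call & (y == 0)).sum() / n_neg)
        j = sens + spec - 1.0
        if j > best_j:
            best_j = j
            best_cutoff = float(t)
    return best_cutoff, best_j


def roc_auc(scores: Sequence, true_labels: Sequence) -> RocCurve:
    """ROC curve over all distinct thresholds with trapezoidal AUROC.

    The trapezoidal area equals the Mann-Whitney statistic
    P(score_pos > score_neg) + 0.5 * P(tie) for any score vector.
    """
    s, y = _validate_scores_labels(scores, true_labels)
    fpr, tpr, _ = _roc_points(s, y)
    auc = float(np.trapezoid(tpr, fpr))
    cutoff, j = youden_optimal_cutoff(s, y)
    points = tuple((float(x), float(t)) for x, t in zip(fpr, tpr))
    return RocCurve(points=points, auc=auc, youden_cutoff=cutoff, youden_j=j)
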