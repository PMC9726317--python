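"""File formats: cohort CSV, model JSON, decision-model parameter config.

Cohort files are plain CSV with a header of canonical column names
(``age, atherosclerosis, ckd, antiplatelet, albumin, ..., mural``); an
empty field is the missing-value token.  Model files are JSON objects with
keys ``intercept``, ``coef_age``, ``coef_atherosclerosis``, ``coef_ckd``,
``coef_antiplatelet``, ``coef_albumin``, ``cutoff_percent``.  Decision
parameters round-trip as JSON or YAML keyed like :class:`CeaParameters`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from sbtriage.cea import CeaParameters
from sbtriage.risk import (
    OPTIONAL_BINARY_COVARIATES,
    REQUIRED_PREDICTORS,
    RiskModel,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

BINARY_COLUMNS = ("atherosclerosis", "ckd", "antiplatelet") + OPTIONAL_BINARY_COVARIATES
MODEL_KEYS = (
    "intercept",
    "coef_age",
    "coef_atherosclerosis",
    "coef_ckd",
    "coef_antiplatelet",
    "coef_albumin",
    "cutoff_percent",
)


class CohortValidationError(ValueError):
    """Raised with one message line per offending row."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid cohort rows:\n" + "\n".join(errors))


def _row_errors(frame: pd.DataFrame) -> list[str]:
    errors: list[str] = []
    # data rows start at line 2 (line 1 is the header)
    for idx, row in frame.iterrows():
        line = idx + 2
        for name in ("age", "albumin"):
            value = row[name]
            if pd.isna(value):
                errors.append(f"line {line}: missing {name}")
            elif not value > 0:
                errors.append(f"line {line}: {name} must be positive, got {value!r}")
        for name in BINARY_COLUMNS:
            if name not in frame.columns:
                continue
            value = row[name]
            if pd.isna(value):
                if name in REQUIRED_PREDICTORS:
                    errors.append(f"line {line}: missing {name}")
            elif value not in (0, 1):
                errors.append(f"line {line}: {name} must be 0 or 1, got {value!r}")
        if "mural" in frame.columns:
            value = row["mural"]
            if not pd.isna(value) and value not in (0, 1):
                errors.append(f"line {line}: mural must be 0 or 1, got {value!r}")
    return errors


def read_cohort(path: PathLike, skip_invalid: bool = False) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Malformed rows raise :class:`CohortValidationError` with line numbers
    unless ``skip_invalid`` is set, in which case they are dropped and the
    skipped count is logged.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except ValueError as exc:
        raise ValueError(f"{path}: not parseable as CSV: {exc}") from exc
    for name in REQUIRED_PREDICTORS:
        if name not in frame.columns:
            raise ValueError(f"{path}: missing required column: {name}")
    for name in ("age", "albumin", "hemoglobin"):
        if name in frame.columns and frame[name].dtype == object:
            bad = frame[pd.to_numeric(frame[name], errors="coerce").isna() & frame[name].notna()]
            if len(bad):
                lines = ", ".join(str(i + 2) for i in bad.index)
                raise CohortValidationError(
                    [f"line {lines}: non-numeric {name}"]
                )
    errors = _row_errors(frame)
    if errors:
        if not skip_invalid:
            raise CohortValidationError(errors)
        bad_lines = {int(e.split()[1].rstrip(":")) for e in errors}
        keep = [i for i in frame.index if i + 2 not in bad_lines]
        logger.warning(
            "skipped %d invalid row(s) in %s", len(frame) - len(keep), path
        )
        frame = frame.loc[keep].reset_index(drop=True)
    return frame


def write_cohort(cohort: pd.DataFrame, path: PathLike) -> None:
    cohort.to_csv(path, index=False)


def read_model(path: PathLike) -> RiskModel:
    with open(path) as handle:
        payload = json.load(handle)
    missing = [k for k in MODEL_KEYS if k not in payload]
    if missing:
        raise ValueError(f"{path}: model file missing key(s): {', '.join(missing)}")
    return RiskModel(**{k: float(payload[k]) for k in MODEL_KEYS})


def write_model(model: RiskModel, path: PathLike) -> None:
    payload = {k: getattr(model, k) for k in MODEL_KEYS}
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_cea_params(path: PathLike) -> CeaParameters:
    """Read a parameter config (JSON or YAML by extension); unspecified
    keys keep their base-case defaults."""
    path = Path(path)
    with open(path) as handle:
        if path.suffix.lower() in (".yaml", ".yml"):
            payload = yaml.safe_load(handle)
        else:
            payload = json.load(handle)
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: parameter file must be a mapping")
    known = {f.name for f in dataclasses.fields(CeaParameters)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(
            f"{path}: unknown parameter key(s): {', '.join(sorted(unknown))}"
        )
    base = CeaParameters()
    merged: dict = {}
    for f in dataclasses.fields(CeaParameters):
        default = getattr(base, f.name)
        if f.name not in payload:
            merged[f.name] = default
        elif isinstance(default, dict):
            value = dict(default)
            if f.name == "costs":
                for currency, table in payload[f.name].items():
                    value[currency] = {**value.get(currency, {}), **table}
            else:
                value.update(payload[f.name])
            merged[f.name] = value
        else:
            merged[f.name] = payload[f.name]
    return CeaParameters(**merged)


def write_cea_params(params: CeaParameters, path: PathLike) -> None:
    path = Path(path)
    payload = dataclasses.asdict(params)
    with open(path, "w") as handle:
        if path.suffix.lower() in (".yaml", ".yml"):
            yaml.safe_dump(payload, handle, sort_keys=True)
        else:
            json.dump(payload, handle, indent=2, sort_keys=True)
            handle.write("\n")


def to_jsonable(obj):
    """Recursively convert dataclasses/numpy containers to JSON-safe types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
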