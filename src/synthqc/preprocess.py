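"""Preprocessing of raw clinical cohort extracts into the analysis schema.

Four derivations turn a raw cohort into analysis-ready form:

1. censored assay strings (``">1,700"``, ``"<200"``) are mapped to numeric
   sentinel values just outside the detection range (1701, 199);
2. body-mass index from measured height (cm) and weight (kg);
3. a binary amyloid-positivity flag, positive when CSF ABeta(1-42) is
   strictly below 1,000 pg/ml;
4. a binary family-history-of-dementia flag, set when a *biological* father
   or mother had a history of dementia.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from synthqc.cohort_table import (
    _CENSOR_RE,
    _parse_number,
    Cohort,
    CohortSchema,
    VariableSpec,
    is_missing,
)

__all__ = [
    "PreprocessConfig",
    "amyloid_flag",
    "compute_bmi",
    "family_history_flag",
    "parse_censored_value",
    "preprocess_epad",
]

YES = "yes"
NO = "no"

#: default raw-column bindings for EPAD-style extracts
DEFAULT_COLUMNS = {
    "abeta": "abeta_1_42",
    "height": "height",
    "weight": "weight",
    "father_history": "father_history",
    "father_biological": "father_biological",
    "mother_history": "mother_history",
    "mother_biological": "mother_biological",
}


@dataclass(frozen=True)
class PreprocessConfig:
    """Censoring maps, amyloid threshold and raw-column bindings.

    The detection-limit maps reproduce the conventional transformation of
    out-of-range assay strings to values just outside the limit; for limits
    other than the configured ones the mapping generalizes to limit+1 (upper)
    and limit-1 (lower).
    """

    abeta_upper_censor: float = 1700.0
    abeta_upper_value: float = 1701.0
    abeta_lower_censor: float = 200.0
    abeta_lower_value: float = 199.0
    amyloid_threshold: float = 1000.0  # pg/ml
    columns: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMNS))

    def __post_init__(self):
        if self.abeta_upper_value <= self.abeta_upper_censor:
            raise ValueError("upper censor mapped value must exceed the limit")
        if self.abeta_lower_value >= self.abeta_lower_censor:
            raise ValueError("lower censor mapped value must be below the limit")
        if self.amyloid_threshold <= 0:
            raise ValueError("amyloid_threshold must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PreprocessConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cols = dict(DEFAULT_COLUMNS)
        cols.update(raw.pop("columns", {}))
        return cls(columns=cols, **raw)


def parse_censored_value(raw, config: PreprocessConfig | None = None) -> float:
    """Resolve a possibly-censored numeric string to a number.

    Plain numbers (thousands separators allowed) pass through; ``">x"`` maps
    to the configured value above the limit (default ``x + 1``) and ``"<x"``
    to the configured value below it (default ``x - 1``).  Any other string
    raises :class:`ValueError` naming the offending token.
    """
    config = config or PreprocessConfig()
    if isinstance(raw, (int, float, np.floating, np.integer)):
        return float(raw)
    token = str(raw).strip()
    m = _CENSOR_RE.match(token)
    if m is None:
        try:
            return _parse_number(token)
        except ValueError:
            raise ValueError(f"cannot parse censored value {raw!r}") from None
    direction, number = m.group(1), _parse_number(m.group(2))
    if direction == ">":
        if number == config.abeta_upper_censor:
            return float(config.abeta_upper_value)
        return number + 1.0
    if number == config.abeta_lower_censor:
        return float(config.abeta_lower_value)
    return number - 1.0


def compute_bmi(weight, height) -> float:
    """BMI in kg/m^2 from weight in kg and height in cm.

    Either input MISSING propagates to a MISSING result; non-positive inputs
    raise :class:`ValueError`.
    """
    if is_missing(weight) or is_missing(height):
        return float("nan")
    weight, height = float(weight), float(height)
    if weight <= 0 or height <= 0:
        raise ValueError(f"non-positive weight/height: {weight}, {height}")
    return weight / (height / 100.0) ** 2


def amyloid_flag(abeta, threshold: float = 1000.0) -> float:
    """1 when ABeta is strictly below the positivity threshold, else 0.

    Amyloid positivity is defined as CSF ABeta(1-42) < 1,000 pg/ml; the
    boundary value 1,000 itself is negative (strict inequality).  MISSING
    propagates.
    """
    if is_missing(abeta):
        return float("nan")
    return 1.0 if float(abeta) < threshold else 0.0


def _is_yes(value) -> bool:
    return (not is_missing(value)) and str(value).strip().lower() == YES


def family_history_flag(father_history, father_biological,
                        mother_history, mother_biological) -> float:
    """1 if a biological father or mother had a history of dementia, else 0.

    A parent contributes only when both the history and the biological
    indicator are "yes"; MISSING answers make that parent non-contributing.
    """
    father = _is_yes(father_history) and _is_yes(father_biological)
    mother = _is_yes(mother_history) and _is_yes(mother_biological)
    return 1.0 if (father or mother) else 0.0


FLAG_LEVELS = (NO, YES)


def _flag_to_level(flag: float):
    if math.isnan(flag):
        return None
    return YES if flag == 1.0 else NO


def preprocess_epad(cohort: Cohort, config: PreprocessConfig | None = None) -> Cohort:
    """Apply the four preprocessing rules to a raw cohort.

    Resolves censored ABeta strings, adds ``bmi`` (numeric), the amyloid
    positivity flag ``abeta_lt_1000`` and ``family_history`` (both yes/no
    categorical), and drops the four raw parental-history columns.  Record
    count and order are preserved.  Missing source columns raise
    :class:`ValueError` listing them.
    """
    config = config or PreprocessConfig()
    cols = config.columns
    required = [cols[k] for k in ("abeta", "height", "weight", "father_history",
                                  "father_biological", "mother_history",
                                  "mother_biological")]
    absent = [c for c in required if c not in cohort.schema]
    if absent:
        raise ValueError(f"preprocess requires missing columns: {absent}")

    parental = {cols[k] for k in ("father_history", "father_biological",
                                  "mother_history", "mother_biological")}

    abeta_name = cols["abeta"]
    abeta_raw = cohort.data[abeta_name]
    abeta = np.array([
        float("nan") if is_missing(v) else parse_censored_value(v, config)
        for v in abeta_raw
    ])

    height = cohort.numeric_values(cols["height"])
    weight = cohort.numeric_values(cols["weight"])
    bmi = np.array([compute_bmi(w, h) for w, h in zip(weight, height)])

    fh = cohort.data[cols["father_history"]]
    fb = cohort.data[cols["father_biological"]]
    mh = cohort.data[cols["mother_history"]]
    mb = cohort.data[cols["mother_biological"]]
    family = [family_history_flag(a, b, c, d) for a, b, c, d in zip(fh, fb, mh, mb)]

    amyloid = [amyloid_flag(v, config.amyloid_threshold) for v in abeta]

    specs: list[VariableSpec] = []
    columns: dict[str, pd.Series] = {}
    for spec in cohort.schema:
        if spec.name in parental:
            continue
        if spec.name == abeta_name:
            specs.append(replace(spec, censor_rule=False))
            columns[spec.name] = pd.Series(abeta, dtype=float)
        else:
            specs.append(spec)
            columns[spec.name] = cohort.data[spec.name].copy()

    specs.append(VariableSpec("bmi", "numeric", units="kg/m2"))
    columns["bmi"] = pd.Series(bmi, dtype=float)
    specs.append(VariableSpec("abeta_lt_1000", "categorical", levels=FLAG_LEVELS))
    columns["abeta_lt_1000"] = pd.Series([_flag_to_level(f) for f in amyloid],
                                         dtype=object)
    specs.append(VariableSpec("family_history", "categorical", levels=FLAG_LEVELS))
    columns["family_history"] = pd.Series([_flag_to_level(f) for f in family],
                                          dtype=object)

    schema = CohortSchema(specs)
    df = pd.DataFrame(columns, columns=schema.names)
    return Cohort(schema=schema, data=df, label=cohort.label)
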