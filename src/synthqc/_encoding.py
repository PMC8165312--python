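"""Shared numeric encoding of mixed-type cohorts for correlation and learners.

Categorical variables enter numeric analyses as 0/1 indicators: a two-level
variable becomes a single indicator of its second schema level; a multi-level
variable becomes one indicator per level except a dropped reference level
(by default the most frequent, so the retained indicators carry the most
variance).  MISSING propagates to NaN in every derived indicator.

When two cohorts are compared, the reference levels must agree on both sides;
:func:`pooled_drop_levels` computes them from the pooled level frequencies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from synthqc.cohort_table import Cohort, is_missing

__all__ = ["encode_cohort", "pooled_drop_levels"]


def pooled_drop_levels(*cohorts: Cohort) -> dict[str, str]:
    """Reference (dropped) level per multi-level categorical, chosen as the
    most frequent level over all given cohorts; ties break by level order."""
    schema = cohorts[0].schema
    drop: dict[str, str] = {}
    for spec in schema:
        if spec.kind != "categorical" or len(spec.levels) <= 2:
            continue
        counts = {lv: 0 for lv in spec.levels}
        for cohort in cohorts:
            vc = cohort.data[spec.name].value_counts(dropna=True)
            for lv in spec.levels:
                counts[lv] += int(vc.get(lv, 0))
        drop[spec.name] = max(spec.levels, key=lambda lv: counts[lv])
    return drop


def encode_cohort(
    cohort: Cohort,
    variables: list[str] | None = None,
    drop_levels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Encode a cohort to an all-float frame with NaN for MISSING.

    Numeric variables pass through (unresolved censored strings raise);
    binary categoricals map to one 0/1 indicator of the second schema level,
    multi-level categoricals to leave-one-out indicators named
    ``"var=level"``.
    """
    if drop_levels is None:
        drop_levels = pooled_drop_levels(cohort)
    names = variables if variables is not None else cohort.schema.names
    out: dict[str, np.ndarray] = {}
    for name in names:
        spec = cohort.schema[name]
        if spec.kind == "numeric":
            if cohort.censored_mask(name).any():
                raise ValueError(
                    f"variable {name!r} still holds censored strings; "
                    "run preprocessing first"
                )
            out[name] = cohort.numeric_values(name)
            continue
        col = cohort.data[name]
        missing = np.array([is_missing(v) for v in col], dtype=bool)
        if len(spec.levels) == 2:
            ind = np.where(col.to_numpy() == spec.levels[1], 1.0, 0.0)
            ind[missing] = np.nan
            out[f"{name}={spec.levels[1]}"] = ind
        else:
            dropped = drop_levels.get(name, spec.levels[0])
            for level in spec.levels:
                if level == dropped:
                    continue
                ind = np.where(col.to_numpy() == level, 1.0, 0.0)
                ind[missing] = np.nan
                out[f"{name}={level}"] = ind
    return pd.DataFrame(out)
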