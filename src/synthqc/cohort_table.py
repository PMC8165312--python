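"""Schema-typed cohort tables with first-class missing data.

A :class:`Cohort` is a rectangular table of mixed numeric/categorical cells.
Missingness is a first-class cell state (``NaN`` for numerics, ``None`` for
categoricals), never a numeric sentinel: clinical cohort extracts carry heavy
structured missingness (whole assay panels absent for a participant) and any
sentinel encoding would silently leak into summary statistics.

Numeric variables may additionally carry *censored* raw strings such as
``">1,700"`` or ``"<200"`` when their :class:`VariableSpec` enables
``censor_rule``; these are preserved verbatim on read and resolved by the
preprocessing step.
"""

from __future__ import annotations

import csv
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING_SENTINELS",
    "Cohort",
    "CohortSchema",
    "CohortReadError",
    "DescriptiveTable",
    "VariableSpec",
    "is_missing",
    "read_cohort_csv",
    "summarize",
    "write_cohort_csv",
]

#: cell strings interpreted as MISSING on read
MISSING_SENTINELS = ("", "NA")

_CENSOR_RE = re.compile(r"^\s*([<>])\s*([\d,]+(?:\.\d+)?)\s*$")


class CohortReadError(ValueError):
    """Raised when a CSV cell cannot be reconciled with the schema."""


def is_missing(value) -> bool:
    """True for the cell states this package treats as MISSING."""
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def _parse_number(token: str) -> float:
    """Parse a numeric cell, accepting thousands separators ("1,701")."""
    return float(token.replace(",", "").strip())


def _looks_numeric(token: str) -> bool:
    try:
        _parse_number(token)
        return True
    except ValueError:
        return False


def _looks_censored(token: str) -> bool:
    return _CENSOR_RE.match(token) is not None


@dataclass(frozen=True)
class VariableSpec:
    """Type declaration for one cohort variable.

    Parameters
    ----------
    name
        Column name, unique within a schema.
    kind
        ``"numeric"`` or ``"categorical"``.
    units
        Free-text units for numeric variables (``"cm"``, ``"pg/ml"``, ...);
        must be empty for categorical variables.
    levels
        Ordered allowed category labels; required iff categorical.
    censor_rule
        When True (numeric only), prefix-censored strings like ``">1,700"``
        are accepted on read and stored verbatim for later preprocessing.
    """

    name: str
    kind: str
    units: str = ""
    levels: tuple[str, ...] | None = None
    censor_rule: bool = False

    def __post_init__(self):
        if self.kind not in ("numeric", "categorical"):
            raise ValueError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical":
            if not self.levels:
                raise ValueError(f"categorical variable {self.name!r} needs levels")
            if self.units:
                raise ValueError(f"categorical variable {self.name!r} cannot have units")
            object.__setattr__(self, "levels", tuple(str(lv) for lv in self.levels))
        else:
            if self.levels is not None:
                raise ValueError(f"numeric variable {self.name!r} cannot have levels")

    def to_dict(self) -> dict:
        d = {"name": self.name, "kind": self.kind, "units": self.units,
             "censor_rule": self.censor_rule}
        if self.levels is not None:
            d["levels"] = list(self.levels)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "VariableSpec":
        levels = d.get("levels")
        return cls(
            name=d["name"],
            kind=d["kind"],
            units=d.get("units", ""),
            levels=tuple(levels) if levels is not None else None,
            censor_rule=bool(d.get("censor_rule", False)),
        )


class CohortSchema:
    """Ordered collection of :class:`VariableSpec` with unique names."""

    def __init__(self, variables: Iterable[VariableSpec]):
        self.variables: tuple[VariableSpec, ...] = tuple(variables)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate variable names in schema: {dupes}")
        self._by_name = {v.name: v for v in self.variables}

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self) -> Iterator[VariableSpec]:
        return iter(self.variables)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> VariableSpec:
        return self._by_name[name]

    def __eq__(self, other) -> bool:
        return isinstance(other, CohortSchema) and self.variables == other.variables

    def __repr__(self) -> str:
        return f"CohortSchema({len(self)} variables: {', '.join(self.names)})"

    def numeric_names(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == "numeric"]

    def categorical_names(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == "categorical"]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"variables": [v.to_dict() for v in self.variables]}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSchema":
        data = json.loads(Path(path).read_text())
        return cls(VariableSpec.from_dict(d) for d in data["variables"])


@dataclass
class Cohort:
    """A schema-typed cohort table.

    ``data`` holds one column per schema variable, in schema order.  Numeric
    columns are float64 unless the variable carries unresolved censored
    strings (then object dtype mixing floats and raw strings); categorical
    columns are object dtype with labels from the variable's levels.
    """

    schema: CohortSchema
    data: pd.DataFrame
    label: str = ""

    def __post_init__(self):
        if list(self.data.columns) != self.schema.names:
            raise ValueError(
                "data columns do not match schema: "
                f"{list(self.data.columns)} vs {self.schema.names}"
            )
        self.data = self.data.reset_index(drop=True)

    @property
    def n_records(self) -> int:
        return len(self.data)

    def numeric_values(self, name: str) -> np.ndarray:
        """Float view of a numeric column; censored strings become NaN."""
        spec = self.schema[name]
        if spec.kind != "numeric":
            raise ValueError(f"{name!r} is not numeric")
        col = self.data[name]
        if col.dtype == object:
            out = np.full(len(col), np.nan)
            for i, v in enumerate(col):
                if isinstance(v, str):
                    continue
                if not is_missing(v):
                    out[i] = float(v)
            return out
        return col.to_numpy(dtype=float)

    def censored_mask(self, name: str) -> np.ndarray:
        """Boolean mask of cells still holding raw censored strings."""
        col = self.data[name]
        if col.dtype != object:
            return np.zeros(len(col), dtype=bool)
        return np.array([isinstance(v, str) for v in col], dtype=bool)

    def categorical_values(self, name: str) -> pd.Series:
        spec = self.schema[name]
        if spec.kind != "categorical":
            raise ValueError(f"{name!r} is not categorical")
        return self.data[name]

    def copy(self, label: str | None = None) -> "Cohort":
        return Cohort(self.schema, self.data.copy(),
                      self.label if label is None else label)

    def equals(self, other: "Cohort") -> bool:
        """Cell-for-cell equality including MISSING placement."""
        if self.schema != other.schema or self.n_records != other.n_records:
            return False
        for name in self.schema.names:
            a, b = self.data[name], other.data[name]
            for x, y in zip(a, b):
                if is_missing(x) != is_missing(y):
                    return False
                if is_missing(x):
                    continue
                if isinstance(x, str) != isinstance(y, str):
                    return False
                if isinstance(x, str):
                    if x != y:
                        return False
                elif self.schema[name].kind == "numeric":
                    if float(x) != float(y):
                        return False
                elif x != y:
                    return False
        return True


def _infer_schema(columns: Sequence[str], raw: dict[str, list[str | None]]) -> CohortSchema:
    """Infer per-column kind: numeric if >=90% of non-missing cells parse as
    numbers after censor-rule stripping, else categorical."""
    specs = []
    for name in columns:
        cells = [c for c in raw[name] if c is not None]
        if not cells:
            specs.append(VariableSpec(name, "numeric"))
            continue
        n_num = sum(_looks_numeric(c) for c in cells)
        n_cens = sum(_looks_censored(c) for c in cells if not _looks_numeric(c))
        if (n_num + n_cens) / len(cells) >= 0.9:
            specs.append(VariableSpec(name, "numeric", censor_rule=n_cens > 0))
        else:
            levels = tuple(sorted(set(cells)))
            specs.append(VariableSpec(name, "categorical", levels=levels))
    return CohortSchema(specs)


def read_cohort_csv(
    path: str | Path,
    schema: CohortSchema | None = None,
    missing_sentinels: Sequence[str] = MISSING_SENTINELS,
    label: str = "",
) -> Cohort:
    """Read a cohort CSV (UTF-8, comma-separated, header row required).

    With ``schema=None`` the per-column kind is inferred (numeric when at
    least 90% of non-missing cells parse as numbers, tolerating censored
    strings); otherwise cells are validated against the explicit schema and
    an unparseable cell raises :class:`CohortReadError` naming row, column
    and value.  If a JSON sidecar ``<path>.schema.json`` exists and no schema
    is passed, it is used instead of inference.
    """
    path = Path(path)
    if schema is None:
        sidecar = path.with_name(path.name + ".schema.json")
        if sidecar.exists():
            schema = CohortSchema.from_json(sidecar)

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortReadError(f"{path}: no header row")
        if len(set(header)) != len(header):
            dupes = sorted({c for c in header if header.count(c) > 1})
            raise CohortReadError(f"{path}: duplicate column names {dupes}")
        rows = [row for row in reader]

    sentinels = set(missing_sentinels)
    raw: dict[str, list[str | None]] = {name: [] for name in header}
    for row in rows:
        if len(row) != len(header):
            raise CohortReadError(
                f"{path}: row with {len(row)} fields, expected {len(header)}"
            )
        for name, cell in zip(header, row):
            raw[name].append(None if cell.strip() in sentinels else cell)

    if schema is None:
        schema = _infer_schema(header, raw)
    else:
        missing_cols = [v.name for v in schema if v.name not in header]
        if missing_cols:
            raise CohortReadError(f"{path}: schema columns absent from file: {missing_cols}")

    columns = {}
    for spec in schema:
        cells = raw[spec.name]
        if spec.kind == "numeric":
            has_censored = False
            parsed: list = []
            for i, c in enumerate(cells):
                if c is None:
                    parsed.append(np.nan)
                elif _looks_numeric(c):
                    parsed.append(_parse_number(c))
                elif spec.censor_rule and _looks_censored(c):
                    parsed.append(c.strip())
                    has_censored = True
                else:
                    raise CohortReadError(
                        f"{path}: row {i + 2}, column {spec.name!r}: "
                        f"cannot parse numeric value {c!r}"
                    )
            dtype = object if has_censored else float
            columns[spec.name] = pd.Series(parsed, dtype=dtype)
        else:
            vals: list = []
            allowed = set(spec.levels)
            for i, c in enumerate(cells):
                if c is None:
                    vals.append(None)
                elif c in allowed:
                    vals.append(c)
                else:
                    raise CohortReadError(
                        f"{path}: row {i + 2}, column {spec.name!r}: "
                        f"value {c!r} not in levels {sorted(allowed)}"
                    )
            columns[spec.name] = pd.Series(vals, dtype=object)

    df = pd.DataFrame(columns, columns=schema.names)
    return Cohort(schema=schema, data=df, label=label)


def write_cohort_csv(cohort: Cohort, path: str | Path,
                     write_schema_sidecar: bool = True) -> None:
    """Write a cohort as CSV; MISSING cells become empty fields.

    Floats are written with ``repr`` so that ``read(write(c))`` equals ``c``
    cell for cell.  By default the schema is saved to ``<path>.schema.json``.
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cohort.schema.names)
        cols = [cohort.data[name] for name in cohort.schema.names]
        for i in range(cohort.n_records):
            row = []
            for col in cols:
                v = col.iloc[i]
                if is_missing(v):
                    row.append("")
                elif isinstance(v, str):
                    row.append(v)
                elif isinstance(v, (float, np.floating)):
                    row.append(repr(float(v)))
                else:
                    row.append(str(v))
            writer.writerow(row)
    if write_schema_sidecar:
        cohort.schema.to_json(path.with_name(path.name + ".schema.json"))


@dataclass
class DescriptiveTable:
    """Table-1-style descriptive summary of a cohort.

    ``numeric[name]`` maps to ``{"n_missing", "n_censored", "mean", "sd"}``
    (mean/sd over non-missing, non-censored values; sd is the sample standard
    deviation and NaN when fewer than two values contribute).
    ``categorical[name]`` maps to ``{"n_missing", "levels": {level: (count,
    percent)}}`` with percentages over the non-missing denominator.
    """

    n_records: int
    numeric: dict[str, dict] = field(default_factory=dict)
    categorical: dict[str, dict] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, s in self.numeric.items():
            rows.append({"variable": name, "level": "", "n_missing": s["n_missing"],
                         "mean": s["mean"], "sd": s["sd"], "count": np.nan,
                         "percent": np.nan})
        for name, s in self.categorical.items():
            for level, (count, pct) in s["levels"].items():
                rows.append({"variable": name, "level": level,
                             "n_missing": s["n_missing"], "mean": np.nan,
                             "sd": np.nan, "count": count, "percent": pct})
        return pd.DataFrame(rows)


def summarize(cohort: Cohort) -> DescriptiveTable:
    """Descriptive statistics in the Mean (SD) / n (%) layout.

    Numeric: mean and sample sd (denominator n-1) over non-missing values;
    with fewer than two contributing values the sd is NaN (undefined), never
    an exception.  Categorical: per-level count and percentage over the
    non-missing denominator.  Unresolved censored strings are tallied
    separately (``n_censored``) and excluded from the moments.
    """
    table = DescriptiveTable(n_records=cohort.n_records)
    for spec in cohort.schema:
        col = cohort.data[spec.name]
        if spec.kind == "numeric":
            vals = cohort.numeric_values(spec.name)
            cens = cohort.censored_mask(spec.name)
            n_missing = int(sum(is_missing(v) for v in col))
            finite = vals[~np.isnan(vals)]
            mean = float(np.mean(finite)) if finite.size else float("nan")
            sd = float(np.std(finite, ddof=1)) if finite.size >= 2 else float("nan")
            table.numeric[spec.name] = {
                "n_missing": n_missing,
                "n_censored": int(cens.sum()),
                "mean": mean,
                "sd": sd,
            }
        else:
            n_missing = int(sum(is_missing(v) for v in col))
            denom = cohort.n_records - n_missing
            levels = {}
            counts = col.value_counts(dropna=True)
            for level in spec.levels:
                count = int(counts.get(level, 0))
                pct = 100.0 * count / denom if denom else float("nan")
                levels[level] = (count, pct)
            table.categorical[spec.name] = {"n_missing": n_missing, "levels": levels}
    return table
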