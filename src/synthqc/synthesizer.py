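"""Transparent Gaussian-copula baseline synthesizer for mixed-type cohorts.

Each variable is transformed to a latent standard-normal score — numerics by
rank (normal scores, average ranks for ties), categoricals by uniform jitter
within the cumulative band of their level frequency — together with a binary
missingness indicator per variable that has missing cells, so that joint
(block) missingness patterns are part of the dependence model.  The latent
correlation matrix is estimated pairwise-complete and repaired to positive
semi-definiteness by eigenvalue clipping.  Sampling draws a latent
multivariate normal and maps back through inverse empirical quantiles and
level thresholds.

This is a deliberately simple, fully transparent baseline that preserves
marginals, pairwise latent correlation and missingness structure; it makes
no claim of equivalence to any proprietary generation engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

from synthqc.cohort_table import Cohort, CohortSchema, VariableSpec, is_missing

__all__ = ["CopulaModel", "fit_synthesizer", "sample_synthetic"]

_EIG_FLOOR = 1e-6  # PSD repair: clip eigenvalues at this floor


def _nearest_psd(corr: np.ndarray) -> np.ndarray:
    """Clip eigenvalues at a small floor and renormalize to unit diagonal."""
    corr = (corr + corr.T) / 2.0
    w, v = np.linalg.eigh(corr)
    if w.min() >= _EIG_FLOOR:
        return corr
    w = np.clip(w, _EIG_FLOOR, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


@dataclass
class CopulaModel:
    """Fitted Gaussian-copula model of a cohort.

    ``marginals[name]`` holds the sorted non-missing empirical values for a
    numeric variable or the level frequencies for a categorical one;
    ``miss_rates[name]`` the per-variable missingness rate (only variables
    with any missing cells appear); ``corr`` the latent correlation matrix
    over ``latent_names`` (variables followed by missingness indicators).
    """

    schema: CohortSchema
    marginals: dict = field(default_factory=dict)
    miss_rates: dict = field(default_factory=dict)
    latent_names: list = field(default_factory=list)
    corr: np.ndarray | None = None
    n_fitted: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema": {"variables": [v.to_dict() for v in self.schema]},
            "marginals": {
                name: ({"kind": "numeric", "values": list(map(float, m["values"]))}
                       if m["kind"] == "numeric"
                       else {"kind": "categorical", "levels": list(m["levels"]),
                             "freqs": list(map(float, m["freqs"]))})
                for name, m in self.marginals.items()
            },
            "miss_rates": {k: float(v) for k, v in self.miss_rates.items()},
            "latent_names": self.latent_names,
            "corr": self.corr.tolist(),
            "n_fitted": self.n_fitted,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CopulaModel":
        d = json.loads(Path(path).read_text())
        schema = CohortSchema(
            VariableSpec.from_dict(v) for v in d["schema"]["variables"]
        )
        marginals = {}
        for name, m in d["marginals"].items():
            if m["kind"] == "numeric":
                marginals[name] = {"kind": "numeric",
                                   "values": np.asarray(m["values"], dtype=float)}
            else:
                marginals[name] = {"kind": "categorical",
                                   "levels": list(m["levels"]),
                                   "freqs": np.asarray(m["freqs"], dtype=float)}
        return cls(schema=schema, marginals=marginals,
                   miss_rates=dict(d["miss_rates"]),
                   latent_names=list(d["latent_names"]),
                   corr=np.asarray(d["corr"], dtype=float),
                   n_fitted=int(d["n_fitted"]))


def _latent_numeric(values: np.ndarray) -> np.ndarray:
    """Normal scores of a numeric column (NaN preserved)."""
    z = np.full(values.shape, np.nan)
    ok = ~np.isnan(values)
    n = int(ok.sum())
    if n == 0:
        return z
    ranks = rankdata(values[ok], method="average")
    z[ok] = ndtri((ranks - 0.5) / n)
    return z


def _latent_categorical(codes: np.ndarray, freqs: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Jittered normal scores: each record uniform within its level's band."""
    cum = np.concatenate([[0.0], np.cumsum(freqs)])
    cum[-1] = 1.0
    z = np.full(codes.shape, np.nan, dtype=float)
    ok = codes >= 0
    u = cum[codes[ok]] + rng.uniform(size=int(ok.sum())) * (
        cum[codes[ok] + 1] - cum[codes[ok]]
    )
    z[ok] = ndtri(np.clip(u, 1e-12, 1 - 1e-12))
    return z


def fit_synthesizer(real: Cohort, seed: int = 0) -> CopulaModel:
    """Fit the Gaussian copula to a cohort.

    Requires at least two records and at least one non-missing value per
    variable (an all-missing column raises, naming it).  Censored strings
    must be resolved (preprocessed) first.
    """
    if real.n_records < 2:
        raise ValueError("need at least 2 records to fit the synthesizer")
    rng = np.random.default_rng(seed)
    model = CopulaModel(schema=real.schema, n_fitted=real.n_records)

    latent_cols: dict[str, np.ndarray] = {}
    for spec in real.schema:
        name = spec.name
        if spec.kind == "numeric":
            if real.censored_mask(name).any():
                raise ValueError(
                    f"variable {name!r} holds censored strings; preprocess first"
                )
            values = real.numeric_values(name)
            nonmiss = values[~np.isnan(values)]
            if nonmiss.size == 0:
                raise ValueError(f"variable {name!r} is all-missing")
            model.marginals[name] = {"kind": "numeric", "values": np.sort(nonmiss)}
            latent_cols[name] = _latent_numeric(values)
            miss = np.isnan(values)
        else:
            col = real.data[name]
            miss = np.array([is_missing(v) for v in col], dtype=bool)
            observed = col[~miss]
            if observed.size == 0:
                raise ValueError(f"variable {name!r} is all-missing")
            counts = observed.value_counts()
            freqs = np.array([counts.get(lv, 0) for lv in spec.levels], dtype=float)
            freqs = freqs / freqs.sum()
            model.marginals[name] = {"kind": "categorical",
                                     "levels": list(spec.levels), "freqs": freqs}
            code_of = {lv: i for i, lv in enumerate(spec.levels)}
            codes = np.array([-1 if m else code_of[v]
                              for v, m in zip(col, miss)], dtype=int)
            latent_cols[name] = _latent_categorical(codes, freqs, rng)
        rate = float(miss.mean())
        if rate > 0:
            model.miss_rates[name] = rate
            ind_freqs = np.array([1.0 - rate, rate])
            latent_cols[f"__miss__{name}"] = _latent_categorical(
                miss.astype(int), ind_freqs, rng
            )

    model.latent_names = list(latent_cols)
    frame = pd.DataFrame(latent_cols)
    corr = frame.corr(min_periods=2).to_numpy()
    corr[np.isnan(corr)] = 0.0  # constant columns / no overlap: no information
    np.fill_diagonal(corr, 1.0)
    model.corr = _nearest_psd(corr)
    return model


def sample_synthetic(model: CopulaModel, n: int, seed: int = 0) -> Cohort:
    """Draw ``n`` synthetic records from a fitted copula model.

    Fully reproducible given (model, n, seed); output schema and column
    order are identical to the fitted cohort's.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    m = len(model.latent_names)
    try:
        factor = np.linalg.cholesky(model.corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(model.corr)
        factor = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n, m)) @ factor.T
    u = ndtr(z)
    u_by_name = {name: u[:, j] for j, name in enumerate(model.latent_names)}

    columns: dict[str, pd.Series] = {}
    for spec in model.schema:
        name = spec.name
        marg = model.marginals[name]
        uu = u_by_name[name]
        if marg["kind"] == "numeric":
            vals = np.quantile(marg["values"], uu, method="linear")
            if f"__miss__{name}" in u_by_name:
                rate = model.miss_rates[name]
                vals = np.where(u_by_name[f"__miss__{name}"] > 1.0 - rate,
                                np.nan, vals)
            columns[name] = pd.Series(vals, dtype=float)
        else:
            cum = np.cumsum(marg["freqs"])
            idx = np.minimum(np.searchsorted(cum, uu, side="right"),
                             len(marg["levels"]) - 1)
            levels = np.asarray(marg["levels"], dtype=object)
            vals = levels[idx]
            out = pd.Series(vals, dtype=object)
            if f"__miss__{name}" in u_by_name:
                rate = model.miss_rates[name]
                out[u_by_name[f"__miss__{name}"] > 1.0 - rate] = None
            columns[name] = out

    df = pd.DataFrame(columns, columns=model.schema.names)
    return Cohort(schema=model.schema, data=df, label="synthetic")
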