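"""Seeded generators of realistic raw cohort fixtures and toy defect pairs.

:func:`generate_epad_like` emits a raw preclinical-dementia-style cohort with
the published descriptive marginals of a deeply phenotyped n=1,498 sample:
age (>= 50), sex, ethnicity, education years, height/weight, parental
dementia history, CSF analytes (p-tau, t-tau, ABeta(1-42) with detection
limits rendered as censored strings), ApoE genotype and RBANS total score,
with per-variable missingness rates and block-missing CSF panels.  A planted
dependence of ABeta on ApoE-e4 allele count and age creates a learnable
amyloid-positivity signal so the utility metrics are non-degenerate.

The fixture claims schema and moment realism only — the marginal families
and the latent correlations are stand-ins, not estimates of any real cohort's
joint distribution.

:func:`generate_toy_pair` returns small (real, synthetic) pairs with a known
planted defect for exercising the defect-detection behavior of every metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from synthqc.cohort_table import Cohort, CohortSchema, VariableSpec

__all__ = ["FixtureConfig", "generate_epad_like", "generate_toy_pair"]

N_TABLE = 1498  # reference sample size behind the default missingness counts


def _calibrated_truncnorm(target_mean: float, target_sd: float, lower: float):
    """(loc, scale, a) of a lower-truncated normal whose realized mean and sd
    equal the targets.

    Naive truncation of N(target_mean, target_sd) at the bound shifts the
    realized moments; solving for the underlying parameters keeps the support
    constraint and the published moments simultaneously true.
    """

    def eqs(params):
        loc, scale = params
        a = (lower - loc) / scale
        mean, var = stats.truncnorm.stats(a, np.inf, loc=loc, scale=scale,
                                          moments="mv")
        return [mean - target_mean, np.sqrt(var) - target_sd]

    loc, scale = optimize.fsolve(eqs, [target_mean, target_sd], xtol=1e-12)
    return float(loc), float(scale), (lower - loc) / scale


@dataclass
class FixtureConfig:
    """Marginal parameters, missingness rates and planted effects.

    Defaults reproduce the published descriptive table of the n=1,498
    sample: normal means/sds per numeric variable, level frequencies per
    categorical, missingness counts out of 1,498, plus invented latent
    correlations (height/weight 0.5, p-tau/t-tau 0.9) and the planted
    ABeta effects (pg/ml shift per ApoE-e4 allele and per year of age over
    50) that induce the amyloid-positivity signal.
    """

    n: int = N_TABLE
    seed: int = 0

    age_mean: float = 65.6
    age_sd: float = 7.2
    age_lower: float = 50.0
    female_prop: float = 0.569
    edu_mean: float = 14.5
    edu_sd: float = 3.7
    height_mean: float = 166.7  # cm
    height_sd: float = 9.3
    weight_mean: float = 73.4  # kg
    weight_sd: float = 14.5
    rbans_mean: float = 103.4
    rbans_sd: float = 13.7
    ptau_mean: float = 19.0
    ptau_sd: float = 10.2
    ttau_mean: float = 219.6
    ttau_sd: float = 93.1
    abeta_mean: float = 1247.4  # pg/ml
    abeta_sd: float = 420.8
    abeta_lower_limit: float = 200.0
    abeta_upper_limit: float = 1700.0
    abeta_calc_mean: float = 2276.5
    abeta_calc_sd: float = 633.0
    rad_pct_mean: float = 5681.2
    rad_pct_sd: float = 1055.3

    family_history_prob: float = 0.616
    apoe_freqs: dict = field(default_factory=lambda: {
        "e2/e2": 0.002, "e2/e3": 0.083, "e2/e4": 0.033,
        "e3/e3": 0.537, "e3/e4": 0.306, "e4/e4": 0.039,
    })
    ethnicity_freqs: dict = field(default_factory=lambda: {
        "Asian": 2, "Black": 2, "Caucasian/White": 1128, "Other": 1,
        "Hispanic": 1, "Latin American": 1, "Mauricienne": 1, "Moroccan": 1,
        "South East Asian": 1,
    })

    # missingness counts out of 1,498 (applied as rates at any n)
    miss_csf: float = 236 / N_TABLE  # shared by p-tau, t-tau, ABeta (block)
    miss_height: float = 41 / N_TABLE
    miss_weight: float = 37 / N_TABLE
    miss_edu: float = 8 / N_TABLE
    miss_rbans: float = 62 / N_TABLE
    miss_ethnicity: float = 359 / N_TABLE
    miss_apoe: float = 178 / N_TABLE
    miss_rad_pct: float = 106 / N_TABLE
    miss_abeta_calc: float = 1130 / N_TABLE

    # invented latent correlations
    corr_height_weight: float = 0.5
    corr_ptau_ttau: float = 0.9

    # planted amyloid signal (set both to 0 to disable)
    abeta_per_e4_allele: float = -150.0  # pg/ml per allele
    abeta_per_year_over_50: float = -5.0  # pg/ml per year

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("field n: must be >= 1")
        for name in ("age_sd", "edu_sd", "height_sd", "weight_sd", "rbans_sd",
                     "ptau_sd", "ttau_sd", "abeta_sd", "abeta_calc_sd",
                     "rad_pct_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"field {name}: sd must be positive")
        for name in ("female_prop", "family_history_prob", "miss_csf",
                     "miss_height", "miss_weight", "miss_edu", "miss_rbans",
                     "miss_ethnicity", "miss_apoe", "miss_rad_pct",
                     "miss_abeta_calc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"field {name}: probability outside [0,1]")
        total = sum(self.apoe_freqs.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"field apoe_freqs: frequencies sum to {total}, not 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _raw_schema(config: FixtureConfig) -> CohortSchema:
    yn = ("no", "yes")
    return CohortSchema([
        VariableSpec("age", "numeric", units="years"),
        VariableSpec("sex", "categorical", levels=("Female", "Male")),
        VariableSpec("ethnicity", "categorical",
                     levels=tuple(sorted(config.ethnicity_freqs))),
        VariableSpec("edu_years", "numeric", units="years"),
        VariableSpec("height", "numeric", units="cm"),
        VariableSpec("weight", "numeric", units="kg"),
        VariableSpec("father_history", "categorical", levels=yn),
        VariableSpec("father_biological", "categorical", levels=yn),
        VariableSpec("mother_history", "categorical", levels=yn),
        VariableSpec("mother_biological", "categorical", levels=yn),
        VariableSpec("ptau", "numeric", units="pg/ml"),
        VariableSpec("ttau", "numeric", units="pg/ml"),
        VariableSpec("abeta_1_42", "numeric", units="pg/ml", censor_rule=True),
        VariableSpec("abeta_calc", "numeric"),
        VariableSpec("rad_pct", "numeric"),
        VariableSpec("rbans_total", "numeric"),
        VariableSpec("apoe", "categorical",
                     levels=tuple(sorted(config.apoe_freqs))),
    ])


def _format_limit(direction: str, limit: float) -> str:
    return f"{direction}{limit:,.0f}"


def generate_epad_like(config: FixtureConfig | None = None) -> Cohort:
    """Generate a raw cohort fixture; seeded, fully reproducible.

    BMI is deliberately NOT precomputed and out-of-range ABeta values are
    rendered as censored strings, so the preprocessing step has real work to
    do on the output.
    """
    config = config or FixtureConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    age_loc, age_scale, age_a = _calibrated_truncnorm(
        config.age_mean, config.age_sd, config.age_lower)
    age = stats.truncnorm.rvs(age_a, np.inf, loc=age_loc, scale=age_scale,
                              size=n, random_state=rng)

    edu_loc, edu_scale, edu_a = _calibrated_truncnorm(
        config.edu_mean, config.edu_sd, 0.0)
    edu = stats.truncnorm.rvs(edu_a, np.inf, loc=edu_loc, scale=edu_scale,
                              size=n, random_state=rng)

    sex = np.where(rng.uniform(size=n) < config.female_prop, "Female", "Male")

    eth_levels = sorted(config.ethnicity_freqs)
    eth_w = np.array([config.ethnicity_freqs[lv] for lv in eth_levels],
                     dtype=float)
    ethnicity = rng.choice(eth_levels, size=n, p=eth_w / eth_w.sum())

    # height/weight with latent correlation
    zh = rng.standard_normal(n)
    zw = config.corr_height_weight * zh + np.sqrt(
        1 - config.corr_height_weight**2) * rng.standard_normal(n)
    height = config.height_mean + config.height_sd * zh
    weight = config.weight_mean + config.weight_sd * zw

    # CSF tau pair with latent correlation
    zp = rng.standard_normal(n)
    zt = config.corr_ptau_ttau * zp + np.sqrt(
        1 - config.corr_ptau_ttau**2) * rng.standard_normal(n)
    ptau = config.ptau_mean + config.ptau_sd * zp
    ttau = config.ttau_mean + config.ttau_sd * zt

    rbans = config.rbans_mean + config.rbans_sd * rng.standard_normal(n)
    rad_pct = config.rad_pct_mean + config.rad_pct_sd * rng.standard_normal(n)
    abeta_calc = (config.abeta_calc_mean
                  + config.abeta_calc_sd * rng.standard_normal(n))

    apoe_levels = sorted(config.apoe_freqs)
    apoe_p = np.array([config.apoe_freqs[lv] for lv in apoe_levels])
    apoe = rng.choice(apoe_levels, size=n, p=apoe_p / apoe_p.sum())
    e4_count = np.array([gt.count("e4") for gt in apoe], dtype=float)

    # planted amyloid effect, centered and variance-budgeted so the ABeta
    # marginal keeps its configured mean and sd
    allele_mean = float(sum(config.apoe_freqs[gt] * gt.count("e4")
                            for gt in apoe_levels))
    allele_var = float(sum(config.apoe_freqs[gt] * gt.count("e4") ** 2
                           for gt in apoe_levels) - allele_mean**2)
    age_var = float(stats.truncnorm.stats(age_a, np.inf, loc=age_loc,
                                          scale=age_scale, moments="v"))
    effect = (config.abeta_per_e4_allele * (e4_count - allele_mean)
              + config.abeta_per_year_over_50 * (age - config.age_mean))
    effect_var = (config.abeta_per_e4_allele**2 * allele_var
                  + config.abeta_per_year_over_50**2 * age_var)
    noise_sd = np.sqrt(max(config.abeta_sd**2 - effect_var,
                           (0.1 * config.abeta_sd) ** 2))
    abeta_num = config.abeta_mean + effect + noise_sd * rng.standard_normal(n)

    abeta_cells: list = []
    for v in abeta_num:
        if v > config.abeta_upper_limit:
            abeta_cells.append(_format_limit(">", config.abeta_upper_limit))
        elif v < config.abeta_lower_limit:
            abeta_cells.append(_format_limit("<", config.abeta_lower_limit))
        else:
            abeta_cells.append(float(v))

    # parental history raw columns consistent with the target flag rate
    flag = rng.uniform(size=n) < config.family_history_prob
    which_parent = rng.uniform(size=n) < 0.5  # True -> father carries history
    father_history = np.where(flag & which_parent, "yes", "no")
    mother_history = np.where(flag & ~which_parent, "yes", "no")
    father_biological = np.full(n, "yes", dtype=object)
    mother_biological = np.full(n, "yes", dtype=object)

    def miss(rate: float) -> np.ndarray:
        return rng.uniform(size=n) < rate

    csf_missing = miss(config.miss_csf)  # one indicator for the whole panel

    def with_missing(values: np.ndarray, mask: np.ndarray) -> pd.Series:
        out = pd.Series(values, dtype=float)
        out[mask] = np.nan
        return out

    def cat_with_missing(values, mask: np.ndarray) -> pd.Series:
        out = pd.Series(list(values), dtype=object)
        out[mask] = None
        return out

    abeta_col = pd.Series(abeta_cells, dtype=object)
    abeta_col[csf_missing] = np.nan

    columns = {
        "age": pd.Series(age, dtype=float),
        "sex": pd.Series(sex, dtype=object),
        "ethnicity": cat_with_missing(ethnicity, miss(config.miss_ethnicity)),
        "edu_years": with_missing(edu, miss(config.miss_edu)),
        "height": with_missing(height, miss(config.miss_height)),
        "weight": with_missing(weight, miss(config.miss_weight)),
        "father_history": pd.Series(father_history, dtype=object),
        "father_biological": pd.Series(father_biological, dtype=object),
        "mother_history": pd.Series(mother_history, dtype=object),
        "mother_biological": pd.Series(mother_biological, dtype=object),
        "ptau": with_missing(ptau, csf_missing),
        "ttau": with_missing(ttau, csf_missing),
        "abeta_1_42": abeta_col,
        "abeta_calc": with_missing(abeta_calc, miss(config.miss_abeta_calc)),
        "rad_pct": with_missing(rad_pct, miss(config.miss_rad_pct)),
        "rbans_total": pd.Series(rbans, dtype=float).where(
            ~miss(config.miss_rbans), np.nan),
        "apoe": cat_with_missing(apoe, miss(config.miss_apoe)),
    }
    schema = _raw_schema(config)
    df = pd.DataFrame(columns, columns=schema.names)
    return Cohort(schema=schema, data=df, label="real")


# ---------------------------------------------------------------------------
# toy defect pairs


_TOY_CORR = np.array([
    # x1    x2    x3    x4    latent for the binary variable
    [1.00, 0.50, 0.40, 0.45, 0.30],
    [0.50, 1.00, 0.30, 0.35, 0.50],
    [0.40, 0.30, 1.00, 0.40, 0.25],
    [0.45, 0.35, 0.40, 1.00, 0.30],
    [0.30, 0.50, 0.25, 0.30, 1.00],
])


def _toy_real(n: int, rng: np.random.Generator) -> Cohort:
    L = np.linalg.cholesky(_TOY_CORR)
    z = rng.standard_normal((n, 5)) @ L.T
    schema = CohortSchema([
        VariableSpec("x1", "numeric"),
        VariableSpec("x2", "numeric"),
        VariableSpec("x3", "numeric"),
        VariableSpec("x4", "numeric"),
        VariableSpec("group", "categorical", levels=("a", "b")),
    ])
    df = pd.DataFrame({
        "x1": 10.0 + 2.0 * z[:, 0],
        "x2": -5.0 + 1.0 * z[:, 1],
        "x3": 100.0 + 15.0 * z[:, 2],
        "x4": 0.0 + 1.0 * z[:, 3],
        "group": pd.Series(np.where(z[:, 4] > 0, "b", "a"), dtype=object),
    }, columns=schema.names)
    return Cohort(schema=schema, data=df, label="real")


def generate_toy_pair(kind: str, n: int = 1000, seed: int = 0) -> tuple[Cohort, Cohort]:
    """(real, synthetic) pair with a known planted defect.

    ``identical``: synthetic is an exact copy — every fidelity metric should
    sit at its ideal value.  ``shifted``: one variable's mean moved by one
    standard deviation — the KS test must reject.  ``decorrelated``: columns
    independently permuted — marginals survive but PCD-L1 rises to about the
    real cohort's mean absolute off-diagonal correlation.  ``memorized``:
    synthetic rows are copies of real rows — the mean-DCR ratio collapses
    to 0.
    """
    rng = np.random.default_rng(seed)
    real = _toy_real(n, rng)
    if kind == "identical":
        syn_df = real.data.copy()
    elif kind == "shifted":
        syn_df = real.data.copy()
        sd = float(syn_df["x1"].std(ddof=1))
        syn_df["x1"] = syn_df["x1"] + sd
    elif kind == "decorrelated":
        syn_df = real.data.copy()
        for col in syn_df.columns:
            syn_df[col] = syn_df[col].to_numpy()[rng.permutation(n)]
    elif kind == "memorized":
        rows = rng.integers(0, n, size=n)
        syn_df = real.data.iloc[rows].reset_index(drop=True)
    else:
        raise ValueError(f"unknown toy pair kind {kind!r}")
    syn = Cohort(schema=real.schema, data=syn_df, label="synthetic")
    return real, syn
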