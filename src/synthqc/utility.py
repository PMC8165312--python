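"""Downstream-utility comparison between real- and synthetic-trained models.

A binary outcome (by default amyloid positivity) is predicted from a fixed
set of covariates with a gradient-boosted-trees model and a logistic
regression, separately within the real and the synthetic cohort; AUCs from
repeated stratified cross-validation are compared, and the agreement of the
two GBT models' SHAP feature-importance rankings is scored with normalized
discounted cumulative gain (nDCG).

Shapley values are computed with LightGBM's built-in TreeSHAP
(``pred_contrib=True``), the exact polynomial-time algorithm for tree
ensembles; the importance of a feature is its mean absolute Shapley
contribution over records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from synthqc._encoding import encode_cohort, pooled_drop_levels
from synthqc.cohort_table import Cohort, is_missing
from synthqc.fidelity import _spawn_ints

__all__ = [
    "UtilityReport",
    "ndcg",
    "outcome_auc",
    "shap_importances",
    "utility_comparison",
]

#: default predictor roster for the amyloid-positivity model
DEFAULT_PREDICTORS = [
    "age", "sex", "edu_years", "bmi", "family_history", "apoe", "rbans_total",
]


def _binary_outcome(cohort: Cohort, outcome: str) -> np.ndarray:
    """Map an outcome column to float 0/1 with NaN for MISSING."""
    spec = cohort.schema[outcome]
    if spec.kind == "categorical":
        if len(spec.levels) != 2:
            raise ValueError(f"outcome {outcome!r} must have exactly 2 levels")
        col = cohort.data[outcome]
        y = np.where(col.to_numpy() == spec.levels[1], 1.0, 0.0)
        y[[is_missing(v) for v in col]] = np.nan
        return y
    y = cohort.numeric_values(outcome)
    finite = y[~np.isnan(y)]
    if not np.isin(finite, [0.0, 1.0]).all():
        raise ValueError(f"numeric outcome {outcome!r} must be 0/1")
    return y


def _design(cohort: Cohort, outcome: str, predictors: list[str],
            drop_levels: dict[str, str] | None = None):
    if not predictors:
        raise ValueError("predictor list is empty")
    bad = [p for p in predictors if p not in cohort.schema]
    if bad:
        raise ValueError(f"predictors not in schema: {bad}")
    if outcome in predictors:
        raise ValueError("outcome cannot be among the predictors")
    y = _binary_outcome(cohort, outcome)
    X = encode_cohort(cohort, variables=predictors, drop_levels=drop_levels)
    keep = ~np.isnan(y)
    X, y = X.loc[keep].reset_index(drop=True), y[keep]
    if len(np.unique(y)) < 2:
        raise ValueError(f"outcome {outcome!r} has a single class")
    return X, y


def _make_model(model_kind: str, seed: int):
    from lightgbm import LGBMClassifier
    from sklearn.impute import SimpleImputer
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    if model_kind == "gbt":
        return LGBMClassifier(n_estimators=100, random_state=seed,
                              n_jobs=1, verbose=-1)
    if model_kind == "logistic":
        return make_pipeline(
            SimpleImputer(strategy="median"),
            StandardScaler(),
            LogisticRegression(max_iter=1000),
        )
    raise ValueError(f"unknown model_kind {model_kind!r}")


def outcome_auc(
    cohort: Cohort,
    outcome: str,
    predictors: list[str],
    model_kind: str = "gbt",
    n_repeats: int = 10,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Cross-validated AUC (mean, sd) of an outcome model within one cohort.

    Stratified k-fold cross-validation with AUC on the pooled out-of-fold
    predicted probabilities, repeated ``n_repeats`` times with derived seeds.
    The tree learner receives missing predictor values natively; the logistic
    pipeline median-imputes and standardizes inside each training fold.
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    X, y = _design(cohort, outcome, predictors)
    aucs = []
    for rep_seed in _spawn_ints(seed, n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rep_seed)
        oof = np.empty(len(y))
        for train, test in skf.split(X, y):
            model = _make_model(model_kind, rep_seed)
            model.fit(X.iloc[train], y[train])
            oof[test] = model.predict_proba(X.iloc[test])[:, 1]
        aucs.append(float(roc_auc_score(y, oof)))
    arr = np.asarray(aucs)
    sd = float(arr.std(ddof=1)) if len(aucs) > 1 else 0.0
    return float(arr.mean()), sd


def shap_importances(
    cohort: Cohort,
    outcome: str,
    predictors: list[str],
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Mean |SHAP| feature importances of a GBT model fit on the full cohort.

    Returns (feature, importance) pairs in descending importance, ties broken
    by feature name.
    """
    X, y = _design(cohort, outcome, predictors)
    model = _make_model("gbt", seed)
    model.fit(X, y)
    contrib = model.booster_.predict(X, pred_contrib=True)
    imp = np.abs(contrib[:, :-1]).mean(axis=0)  # last column is the bias term
    pairs = list(zip(X.columns, map(float, imp)))
    return sorted(pairs, key=lambda kv: (-kv[1], kv[0]))


def ndcg(reference: list[tuple[str, float]], candidate) -> float:
    """Rank agreement of a candidate feature order against a reference.

    The relevance of a feature is its importance in the *reference* ranking
    (which must be sorted descending); DCG of an order is
    ``sum_i rel(f_i) / log2(i + 1)`` with 1-based positions, and nDCG is
    DCG(candidate) / DCG(reference), in (0, 1], equal to 1 iff the orders
    agree up to ties in relevance.
    """
    rel = dict(reference)
    cand_names = [c[0] if isinstance(c, tuple) else c for c in candidate]
    if set(rel) != set(cand_names) or len(cand_names) != len(rel):
        raise ValueError("reference and candidate must cover the same feature set")

    def dcg(order: list[str]) -> float:
        return sum(rel[f] / np.log2(i + 2) for i, f in enumerate(order))

    ref_order = [f for f, _ in reference]
    denom = dcg(ref_order)
    if denom == 0:
        raise ValueError("all reference relevances are zero")
    return float(dcg(cand_names) / denom)


@dataclass
class UtilityReport:
    """AUCs, importance rankings and nDCG for the real/synthetic pair."""

    auc: dict = field(default_factory=dict)  # (dataset, model) -> (mean, sd)
    importances_real: list = field(default_factory=list)
    importances_syn: list = field(default_factory=list)
    ndcg: float = float("nan")
    n_repeats: int = 0
    outcome: str = ""
    predictors: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictors": list(self.predictors),
            "n_repeats": self.n_repeats,
            "auc": {f"{ds}_{m}": {"mean": v[0], "sd": v[1]}
                    for (ds, m), v in self.auc.items()},
            "importances_real": [[f, v] for f, v in self.importances_real],
            "importances_syn": [[f, v] for f, v in self.importances_syn],
            "ndcg": self.ndcg,
        }


def utility_comparison(
    real: Cohort,
    syn: Cohort,
    outcome: str,
    predictors: list[str] | None = None,
    n_repeats: int = 10,
    n_folds: int = 5,
    seed: int = 0,
) -> UtilityReport:
    """Full utility comparison: four AUC entries and one nDCG.

    Runs the GBT and logistic outcome models within each cohort, computes
    SHAP importance rankings for both GBT models, and scores the synthetic
    ranking against the real one with nDCG (relevance = real-model mean
    |SHAP|).
    """
    if real.schema != syn.schema:
        raise ValueError("cohorts must share a schema")
    if predictors is None:
        predictors = [p for p in DEFAULT_PREDICTORS if p in real.schema]
    seeds = _spawn_ints(seed, 6)
    report = UtilityReport(outcome=outcome, predictors=list(predictors),
                           n_repeats=n_repeats)
    for i, (ds_name, cohort) in enumerate([("real", real), ("syn", syn)]):
        for j, model_kind in enumerate(["gbt", "logistic"]):
            report.auc[(ds_name, model_kind)] = outcome_auc(
                cohort, outcome, predictors, model_kind=model_kind,
                n_repeats=n_repeats, n_folds=n_folds, seed=seeds[2 * i + j],
            )
    report.importances_real = shap_importances(real, outcome, predictors,
                                               seed=seeds[4])
    report.importances_syn = shap_importances(syn, outcome, predictors,
                                              seed=seeds[5])
    report.ndcg = ndcg(report.importances_real, report.importances_syn)
    return report
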