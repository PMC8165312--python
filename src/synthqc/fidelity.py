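"""Statistical-fidelity metrics between a real and a synthetic cohort.

Univariate fidelity uses the two-sample Kolmogorov-Smirnov test for numeric
variables (a high p-value means the marginals are indistinguishable) and the
Kullback-Leibler divergence KL(real || synthetic), in nats, for categorical
variables.  Joint structure is compared through the pairwise-correlation
distance PCD-L1 (mean absolute difference of the two Pearson correlation
matrices over the strict upper triangle), a gradient-boosted discriminator
trained to tell real records from synthetic ones (cross-validated AUC close
to 0.5 means indistinguishable), and the fraction of the real data's UMAP
embedding that synthetic points cover.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from synthqc._encoding import encode_cohort, pooled_drop_levels
from synthqc.cohort_table import Cohort, is_missing

__all__ = [
    "DiscriminatorResult",
    "UmapCoverage",
    "compare_descriptives",
    "correlation_matrix",
    "discriminator_auc",
    "kl_divergence",
    "ks_pvalue",
    "pcd_from_matrices",
    "pcd_l1",
    "umap_coverage",
]

logger = logging.getLogger(__name__)


def _spawn_ints(seed: int, n: int) -> list[int]:
    """Derive n child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# univariate metrics


def ks_pvalue(real_col, syn_col) -> float:
    """Asymptotic two-sample Kolmogorov-Smirnov p-value (missing dropped).

    Symmetric in its arguments; each side needs at least two non-missing
    values.
    """
    a = np.asarray(real_col, dtype=float)
    b = np.asarray(syn_col, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("ks_pvalue needs >= 2 non-missing values per side")
    return float(stats.ks_2samp(a, b, method="asymp").pvalue)


def kl_divergence(real_col, syn_col, alpha: float = 0.5) -> float:
    """KL(P_real || Q_syn) in nats over the union of observed levels.

    Add-``alpha`` smoothing (default 0.5) is applied to both sides before
    normalization; ``alpha=0`` gives the raw plug-in divergence, which is
    infinite when a level observed in the real data never occurs in the
    synthetic data.  Missing values are dropped.
    """
    a = [v for v in real_col if not is_missing(v)]
    b = [v for v in syn_col if not is_missing(v)]
    if not a or not b:
        raise ValueError("kl_divergence needs >= 1 non-missing value per side")
    levels = sorted(set(a) | set(b))
    ca = np.array([a.count(lv) for lv in levels], dtype=float)
    cb = np.array([b.count(lv) for lv in levels], dtype=float)
    p = (ca + alpha) / (ca.sum() + alpha * len(levels))
    q = (cb + alpha) / (cb.sum() + alpha * len(levels))
    with np.errstate(divide="ignore"):
        terms = np.where(p > 0, p * (np.log(p) - np.log(q)), 0.0)
    if np.any((p > 0) & (q == 0)):
        return float("inf")
    return float(terms.sum())


# ---------------------------------------------------------------------------
# correlation structure


def correlation_matrix(
    cohort: Cohort,
    drop_levels: dict[str, str] | None = None,
    min_periods: int = 3,
) -> pd.DataFrame:
    """Pearson correlation matrix on pairwise-complete observations.

    Categorical variables are 0/1-indicator encoded (see ``_encoding``);
    constant encoded columns are excluded with a logged warning; entries with
    fewer than ``min_periods`` complete pairs are set to 0.
    """
    enc = encode_cohort(cohort, drop_levels=drop_levels)
    if enc.shape[1] < 2:
        raise ValueError("need >= 2 encoded variables for a correlation matrix")
    constant = [c for c in enc.columns if enc[c].dropna().nunique() <= 1]
    if constant:
        logger.warning("excluding constant columns from correlation: %s", constant)
        enc = enc.drop(columns=constant)
    if enc.shape[1] < 2:
        raise ValueError("no usable variable pairs after dropping constants")
    corr = enc.corr(method="pearson", min_periods=min_periods)
    corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def pcd_from_matrices(corr_real: pd.DataFrame, corr_syn: pd.DataFrame,
                      reduce: str = "mean") -> float:
    """Pairwise-correlation distance from two aligned correlation matrices:
    mean (or sum) absolute difference over the strict upper triangle."""
    if list(corr_real.columns) != list(corr_syn.columns):
        raise ValueError("correlation matrices are not aligned")
    diff = np.abs(corr_real.to_numpy() - corr_syn.to_numpy())
    iu = np.triu_indices_from(diff, k=1)
    vals = diff[iu]
    if reduce == "mean":
        return float(vals.mean()) if vals.size else 0.0
    if reduce == "sum":
        return float(vals.sum())
    raise ValueError(f"unknown reduce {reduce!r}")


@dataclass
class CorrelationComparison:
    corr_real: pd.DataFrame
    corr_syn: pd.DataFrame
    pcd_l1: float
    reduce: str = "mean"


def pcd_l1(real: Cohort, syn: Cohort, reduce: str = "mean",
           return_matrices: bool = False):
    """Pairwise-correlation distance between two cohorts sharing a schema.

    Both cohorts are encoded with the same indicator reference levels
    (pooled frequencies) and compared entrywise over the strict upper
    triangle of their Pearson correlation matrices; ``reduce="mean"`` (the
    default) reports the mean absolute difference, ``reduce="sum"`` the sum.
    Columns constant in either cohort are excluded from both matrices.
    """
    if real.schema != syn.schema:
        differing = sorted(
            set(real.schema.names).symmetric_difference(syn.schema.names)
        ) or ["(same names, different specs)"]
        raise ValueError(f"schema mismatch between cohorts: {differing}")
    drop = pooled_drop_levels(real, syn)
    enc_r = encode_cohort(real, drop_levels=drop)
    enc_s = encode_cohort(syn, drop_levels=drop)
    constant = sorted(
        {c for c in enc_r.columns if enc_r[c].dropna().nunique() <= 1}
        | {c for c in enc_s.columns if enc_s[c].dropna().nunique() <= 1}
    )
    if constant:
        logger.warning("excluding constant columns from PCD: %s", constant)
    keep = [c for c in enc_r.columns if c not in constant]
    if len(keep) < 2:
        raise ValueError("no usable variable pairs for PCD")
    corr_r = enc_r[keep].corr(min_periods=3).fillna(0.0)
    corr_s = enc_s[keep].corr(min_periods=3).fillna(0.0)
    value = pcd_from_matrices(corr_r, corr_s, reduce=reduce)
    if return_matrices:
        return CorrelationComparison(corr_r, corr_s, value, reduce)
    return value


# ---------------------------------------------------------------------------
# discriminator


@dataclass
class DiscriminatorResult:
    """Cross-validated AUC of a real-vs-synthetic discriminator."""

    auc_mean: float
    auc_sd: float
    n_repeats: int
    n_folds: int
    seed: int
    aucs: list = field(default_factory=list)


def discriminator_auc(
    real: Cohort,
    syn: Cohort,
    n_repeats: int = 10,
    n_folds: int = 5,
    seed: int = 0,
) -> DiscriminatorResult:
    """AUC of a gradient-boosted classifier separating real from synthetic.

    Records are stacked with labels real=0 / synthetic=1 and scored by
    stratified k-fold cross-validation; the AUC is computed on the pooled
    out-of-fold predicted probabilities and the whole procedure repeated
    ``n_repeats`` times with derived seeds.  Missing values are passed
    natively to the tree learner.  An AUC close to 0.5 means the cohorts are
    statistically indistinguishable to the model.

    Records with byte-identical encoded feature rows are kept in the same
    fold (grouped CV).  Without this, an exact copy of a record with the
    opposite label sitting on the other side of the split lets the learner
    memorize and *anti*-predict, driving the AUC of a perfect synthetic copy
    toward 0 instead of the correct "indistinguishable" 0.5; for cohorts
    without cross-label duplicates the grouping is a no-op.
    """
    from lightgbm import LGBMClassifier
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedGroupKFold

    if real.n_records == 0 or syn.n_records == 0:
        raise ValueError("both cohorts must be non-empty")
    if real.schema != syn.schema:
        raise ValueError("cohorts must share a schema")
    if n_folds > min(real.n_records, syn.n_records):
        raise ValueError("n_folds exceeds the size of a class")

    drop = pooled_drop_levels(real, syn)
    X = pd.concat(
        [encode_cohort(real, drop_levels=drop),
         encode_cohort(syn, drop_levels=drop)],
        ignore_index=True,
    )
    y = np.concatenate([np.zeros(real.n_records), np.ones(syn.n_records)])

    # identical encoded rows share a group so twins never straddle the split
    Xa = np.ascontiguousarray(X.to_numpy())
    row_keys = {}
    groups = np.empty(len(y), dtype=int)
    for i in range(len(y)):
        groups[i] = row_keys.setdefault(Xa[i].tobytes(), len(row_keys))

    aucs = []
    for rep_seed in _spawn_ints(seed, n_repeats):
        skf = StratifiedGroupKFold(n_splits=n_folds, shuffle=True,
                                   random_state=rep_seed)
        oof = np.empty(len(y))
        for train, test in skf.split(X, y, groups):
            clf = LGBMClassifier(
                n_estimators=100, random_state=rep_seed, n_jobs=1, verbose=-1
            )
            clf.fit(X.iloc[train], y[train])
            oof[test] = clf.predict_proba(X.iloc[test])[:, 1]
        aucs.append(float(roc_auc_score(y, oof)))
    aucs_arr = np.asarray(aucs)
    return DiscriminatorResult(
        auc_mean=float(aucs_arr.mean()),
        auc_sd=float(aucs_arr.std(ddof=1)) if len(aucs) > 1 else 0.0,
        n_repeats=n_repeats,
        n_folds=n_folds,
        seed=seed,
        aucs=aucs,
    )


# ---------------------------------------------------------------------------
# UMAP coverage


@dataclass
class UmapCoverage:
    """Grid coverage of the real data's 2D UMAP embedding by synthetic points.

    The grid quantification is this package's own device: the underlying
    check in the literature is visual (do synthetic points populate every
    cluster of real points?), and ``coverage`` makes it a number — the
    fraction of occupied grid cells (cells of the real points' bounding box
    containing at least one real point) that also contain a synthetic point.
    """

    coords_real: np.ndarray
    coords_syn: np.ndarray
    grid_size: int
    coverage: float
    uncovered_cells: list = field(default_factory=list)


def umap_coverage(
    real: Cohort,
    syn: Cohort,
    n_neighbors: int = 50,
    min_dist: float = 0.1,
    grid_size: int = 20,
    seed: int = 0,
) -> UmapCoverage:
    """Embed both cohorts with a UMAP model trained on the real data only.

    Encoded columns are median-imputed and standardized with statistics from
    the real cohort; both cohorts are then projected through the same fitted
    model (deterministic ``transform``), the bounding box of the real points
    is split into ``grid_size`` x ``grid_size`` cells, and coverage is the
    fraction of real-occupied cells that also hold a synthetic point.
    """
    import umap

    if real.n_records <= n_neighbors:
        raise ValueError("real cohort must have more records than n_neighbors")

    drop = pooled_drop_levels(real, syn)
    enc_r = encode_cohort(real, drop_levels=drop)
    enc_s = encode_cohort(syn, drop_levels=drop)

    med = enc_r.median()
    sd = enc_r.std(ddof=0).replace(0.0, 1.0).fillna(1.0)
    Xr = ((enc_r.fillna(med) - med) / sd).to_numpy()
    Xs = ((enc_s.fillna(med) - med) / sd).to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_neighbors=n_neighbors, min_dist=min_dist, n_components=2,
            random_state=seed, n_jobs=1,
        )
        reducer.fit(Xr)
        coords_r = reducer.transform(Xr)
        coords_s = reducer.transform(Xs)

    x0, x1 = coords_r[:, 0].min(), coords_r[:, 0].max()
    y0, y1 = coords_r[:, 1].min(), coords_r[:, 1].max()
    dx = (x1 - x0) or 1.0
    dy = (y1 - y0) or 1.0

    def cell_ids(coords: np.ndarray, clip_outside: bool) -> set[tuple[int, int]]:
        inside = (
            (coords[:, 0] >= x0) & (coords[:, 0] <= x1)
            & (coords[:, 1] >= y0) & (coords[:, 1] <= y1)
        )
        ix = np.clip(np.floor((coords[:, 0] - x0) / dx * grid_size).astype(int),
                     0, grid_size - 1)
        iy = np.clip(np.floor((coords[:, 1] - y0) / dy * grid_size).astype(int),
                     0, grid_size - 1)
        if clip_outside:
            return {(int(a), int(b)) for a, b, ok in zip(ix, iy, inside) if ok}
        return {(int(a), int(b)) for a, b in zip(ix, iy)}

    real_cells = cell_ids(coords_r, clip_outside=False)
    syn_cells = cell_ids(coords_s, clip_outside=True)
    uncovered = sorted(real_cells - syn_cells)
    coverage = 1.0 - len(uncovered) / len(real_cells)
    return UmapCoverage(
        coords_real=coords_r, coords_syn=coords_s,
        grid_size=grid_size, coverage=float(coverage),
        uncovered_cells=uncovered,
    )


# ---------------------------------------------------------------------------
# Table-1-style descriptive comparison


def compare_descriptives(real: Cohort, syn: Cohort) -> dict[str, float]:
    """Per-variable p-values for differences in means or proportions.

    Numeric variables: Welch two-sample t-test.  Categorical variables: a
    two-proportion z-test per level (keys ``"var=level"``).  Missing values
    are dropped; a degenerate comparison (zero variance on both sides, or a
    level absent from both cohorts) reports NaN rather than raising.
    """
    from statsmodels.stats.proportion import proportions_ztest

    if real.schema != syn.schema:
        raise ValueError("cohorts must share a schema")
    out: dict[str, float] = {}
    for spec in real.schema:
        name = spec.name
        if spec.kind == "numeric":
            a = real.numeric_values(name)
            b = syn.numeric_values(name)
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            if a.size < 2 or b.size < 2:
                out[name] = float("nan")
                continue
            if np.var(a) == 0 and np.var(b) == 0:
                out[name] = 1.0 if a[0] == b[0] else float("nan")
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[name] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        else:
            col_r = real.data[name].dropna()
            col_s = syn.data[name].dropna()
            n1, n2 = len(col_r), len(col_s)
            for level in spec.levels:
                key = f"{name}={level}"
                if n1 == 0 or n2 == 0:
                    out[key] = float("nan")
                    continue
                k1 = int((col_r == level).sum())
                k2 = int((col_s == level).sum())
                if (k1 + k2 == 0) or (k1 == n1 and k2 == n2):
                    # identical degenerate proportions on both sides
                    out[key] = 1.0 if (k1 / n1 == k2 / n2) else float("nan")
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, p = proportions_ztest([k1, k2], [n1, n2])
                out[key] = float(p)
    return out
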