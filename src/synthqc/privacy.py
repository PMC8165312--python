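"""Distance-to-closest-record (DCR) privacy assessment.

Numeric variables are discretized into 25 equal-width bins over the pooled
observed range (so both cohorts share edges) and every variable becomes
categorical; the distance between two records is the number of positions
where their categories differ (a Hamming distance, with MISSING matching
MISSING by default).  For each synthetic record we find the distance to its
closest real record, and for each real record the distance to its closest
*other* real record; the ratio of the two mean distances summarizes
memorization risk — near 1 means synthetic records sit no closer to real
ones than real records sit to each other, near 0 flags copying.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from synthqc.cohort_table import Cohort, is_missing

__all__ = ["BinnedCohort", "PrivacyReport", "bin_cohorts", "dcr_report",
           "record_distance"]

logger = logging.getLogger(__name__)

MISSING_CODE = -1


@dataclass
class BinnedCohort:
    """All-categorical view of a cohort after numeric binning.

    ``codes`` is an (n_records, p) integer matrix; numeric variables carry
    bin indices, categoricals level indices, and MISSING the dedicated code
    -1.  ``bin_edges`` records the shared numeric bin boundaries.
    """

    names: list[str]
    codes: np.ndarray
    bin_edges: dict = field(default_factory=dict)
    label: str = ""

    @property
    def n_records(self) -> int:
        return self.codes.shape[0]

    @property
    def p(self) -> int:
        return self.codes.shape[1]


def _bin_numeric(values: np.ndarray, lo: float, hi: float, n_bins: int) -> np.ndarray:
    codes = np.full(values.shape, MISSING_CODE, dtype=int)
    ok = ~np.isnan(values)
    if hi == lo:
        codes[ok] = 0
        return codes
    width = (hi - lo) / n_bins
    idx = np.floor((values[ok] - lo) / width).astype(int)
    codes[ok] = np.clip(idx, 0, n_bins - 1)  # top bin right-closed
    return codes


def bin_cohorts(real: Cohort, syn: Cohort, n_bins: int = 25,
                strategy: str = "width") -> tuple[BinnedCohort, BinnedCohort]:
    """Discretize both cohorts with shared bin edges.

    Equal-width bins over the pooled non-missing range by default
    (``strategy="quantile"`` uses pooled quantile edges instead); categorical
    variables pass through as level codes; MISSING maps to its own category.
    A zero-range numeric variable collapses to a single bin with a logged
    warning.
    """
    if real.schema != syn.schema:
        raise ValueError("cohorts must share a schema")
    names = real.schema.names
    edges: dict[str, np.ndarray] = {}
    cols_r, cols_s = [], []
    for spec in real.schema:
        name = spec.name
        if spec.kind == "numeric":
            vr = real.numeric_values(name)
            vs = syn.numeric_values(name)
            pooled = np.concatenate([vr, vs])
            pooled = pooled[~np.isnan(pooled)]
            if pooled.size == 0:
                cols_r.append(np.full(real.n_records, MISSING_CODE, dtype=int))
                cols_s.append(np.full(syn.n_records, MISSING_CODE, dtype=int))
                continue
            lo, hi = float(pooled.min()), float(pooled.max())
            if hi == lo:
                logger.warning("zero-range variable %r collapses to one bin", name)
            if strategy == "width":
                edges[name] = np.linspace(lo, hi, n_bins + 1)
                cols_r.append(_bin_numeric(vr, lo, hi, n_bins))
                cols_s.append(_bin_numeric(vs, lo, hi, n_bins))
            elif strategy == "quantile":
                qs = np.quantile(pooled, np.linspace(0, 1, n_bins + 1))
                edges[name] = qs
                inner = qs[1:-1]

                def qbin(v):
                    codes = np.full(v.shape, MISSING_CODE, dtype=int)
                    ok = ~np.isnan(v)
                    codes[ok] = np.searchsorted(inner, v[ok], side="right")
                    return codes

                cols_r.append(qbin(vr))
                cols_s.append(qbin(vs))
            else:
                raise ValueError(f"unknown binning strategy {strategy!r}")
        else:
            code_of = {lv: i for i, lv in enumerate(spec.levels)}

            def ccode(col):
                return np.array(
                    [MISSING_CODE if is_missing(v) else code_of[v] for v in col],
                    dtype=int,
                )

            cols_r.append(ccode(real.data[name]))
            cols_s.append(ccode(syn.data[name]))
    binned_r = BinnedCohort(names=list(names), codes=np.column_stack(cols_r),
                            bin_edges=edges, label=real.label or "real")
    binned_s = BinnedCohort(names=list(names), codes=np.column_stack(cols_s),
                            bin_edges=edges, label=syn.label or "synthetic")
    return binned_r, binned_s


def record_distance(x: np.ndarray, y: np.ndarray,
                    missing_matches: bool = True) -> int:
    """Mismatch count between two binned records (integer Hamming distance).

    MISSING equals MISSING by default (matching missingness patterns is a
    genuine similarity signal); with ``missing_matches=False`` any position
    involving MISSING counts as a mismatch.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("records have different lengths")
    diff = x != y
    if not missing_matches:
        diff = diff | (x == MISSING_CODE) | (y == MISSING_CODE)
    return int(diff.sum())


def _nearest_distances(queries: np.ndarray, reference: np.ndarray,
                       exclude_self: bool, missing_matches: bool,
                       chunk: int = 256) -> np.ndarray:
    """Exhaustive nearest-neighbor mismatch distances, chunked O(n^2 p)."""
    n = queries.shape[0]
    out = np.empty(n, dtype=int)
    for start in range(0, n, chunk):
        q = queries[start:start + chunk]
        diff = q[:, None, :] != reference[None, :, :]
        if not missing_matches:
            diff = diff | (q[:, None, :] == MISSING_CODE) \
                        | (reference[None, :, :] == MISSING_CODE)
        dists = diff.sum(axis=2)
        if exclude_self:
            rows = np.arange(start, start + q.shape[0])
            dists[np.arange(q.shape[0]), rows] = queries.shape[1] + 1
        out[start:start + q.shape[0]] = dists.min(axis=1)
    return out


@dataclass
class PrivacyReport:
    """DCR distributions and the mean-DCR ratio.

    ``mean_dcr_ratio`` = mean(synthetic-to-real DCR) / mean(real-to-real
    DCR); values near or above 1 indicate synthetic records are no closer to
    real records than real records are to each other, values near 0 flag
    memorization.  When the real data itself contains exact (binned)
    duplicates the real-to-real mean is 0 and the ratio is undefined (NaN,
    with ``warning`` set).
    """

    dcr_syn_to_real: np.ndarray
    dcr_real_to_real: np.ndarray
    mean_dcr_ratio: float
    n_bins: int
    p: int
    warning: str = ""

    def histogram(self, which: str = "syn") -> dict[int, int]:
        d = self.dcr_syn_to_real if which == "syn" else self.dcr_real_to_real
        counts = np.bincount(d, minlength=self.p + 1)
        return {int(i): int(c) for i, c in enumerate(counts)}

    def to_dict(self) -> dict:
        return {
            "mean_dcr_syn_to_real": float(self.dcr_syn_to_real.mean()),
            "mean_dcr_real_to_real": float(self.dcr_real_to_real.mean()),
            "mean_dcr_ratio": self.mean_dcr_ratio,
            "n_bins": self.n_bins,
            "n_variables": self.p,
            "histogram_syn_to_real": self.histogram("syn"),
            "histogram_real_to_real": self.histogram("real"),
            "warning": self.warning,
        }


def dcr_report(real: Cohort, syn: Cohort, n_bins: int = 25,
               strategy: str = "width", missing_matches: bool = True) -> PrivacyReport:
    """Full DCR assessment between a real and a synthetic cohort.

    Exhaustive nearest-neighbor search over binned records; the synthetic
    side is matched against all real records, the real side against all
    *other* real records (self-matches excluded by index).
    """
    if real.n_records < 2:
        raise ValueError("real cohort needs >= 2 records for real-to-real DCR")
    binned_r, binned_s = bin_cohorts(real, syn, n_bins=n_bins, strategy=strategy)
    s2r = _nearest_distances(binned_s.codes, binned_r.codes,
                             exclude_self=False, missing_matches=missing_matches)
    r2r = _nearest_distances(binned_r.codes, binned_r.codes,
                             exclude_self=True, missing_matches=missing_matches)
    mean_r2r = float(r2r.mean())
    warning = ""
    if mean_r2r == 0.0:
        ratio = float("nan")
        warning = ("real-to-real mean DCR is 0 (duplicated real records); "
                   "ratio undefined")
        warnings.warn(warning)
    else:
        ratio = float(s2r.mean()) / mean_r2r
    return PrivacyReport(
        dcr_syn_to_real=s2r, dcr_real_to_real=r2r,
        mean_dcr_ratio=ratio, n_bins=n_bins, p=binned_r.p, warning=warning,
    )
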