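"""Assembly of the full validation report (fidelity + utility + privacy).

One master seed deterministically spawns per-module seeds, so a full run is
reproducible from a single knob; every derived seed is echoed in the report.
Verdict flags compare each metric against configurable thresholds — the KS
threshold (p > 0.05) is the conventional one, the remaining defaults are this
package's own and are labeled as such in the report.  Verdicts are data, not
errors: a failing verdict never changes the exit status.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from synthqc.cohort_table import Cohort, read_cohort_csv, summarize
from synthqc.fidelity import (
    _spawn_ints,
    compare_descriptives,
    discriminator_auc,
    kl_divergence,
    ks_pvalue,
    pcd_l1,
    umap_coverage,
)
from synthqc.preprocess import PreprocessConfig, preprocess_epad
from synthqc.privacy import dcr_report
from synthqc.utility import DEFAULT_PREDICTORS, utility_comparison

__all__ = ["DEFAULT_THRESHOLDS", "ValidationReport", "render_markdown",
           "run_full_validation", "verdicts"]

logger = logging.getLogger(__name__)


def _package_version() -> str:
    import synthqc

    return synthqc.__version__


#: verdict thresholds; only ks_p_min is a field convention, the rest are
#: this package's own defaults
DEFAULT_THRESHOLDS = {
    "ks_p_min": 0.05,
    "discriminator_auc_band": 0.1,
    "dcr_ratio_warn": 0.5,
    "dcr_ratio_fail": 0.1,
    "umap_coverage_warn": 0.8,
}


def _json_safe(value):
    if isinstance(value, float) and (math.isnan(value) or math.isinf(value)):
        return None if math.isnan(value) else ("inf" if value > 0 else "-inf")
    if isinstance(value, (np.floating, np.integer)):
        return _json_safe(float(value))
    if isinstance(value, dict):
        return {str(k): _json_safe(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_json_safe(v) for v in value]
    return value


@dataclass
class ValidationReport:
    """JSON-serializable container for one full validation run."""

    metadata: dict = field(default_factory=dict)
    descriptives: dict = field(default_factory=dict)
    univariate: dict = field(default_factory=dict)
    correlation: dict = field(default_factory=dict)
    discriminator: dict = field(default_factory=dict)
    umap: dict = field(default_factory=dict)
    utility: dict = field(default_factory=dict)
    privacy: dict = field(default_factory=dict)
    verdicts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return _json_safe({
            "metadata": self.metadata,
            "descriptives": self.descriptives,
            "univariate": self.univariate,
            "correlation": self.correlation,
            "discriminator": self.discriminator,
            "umap": self.umap,
            "utility": self.utility,
            "privacy": self.privacy,
            "verdicts": self.verdicts,
        })


def verdicts(report: ValidationReport | dict,
             thresholds: dict | None = None) -> dict:
    """Per-metric pass/warn/fail flags against configured thresholds."""
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    d = report.to_dict() if isinstance(report, ValidationReport) else report

    flags: dict = {"thresholds": thr}

    ks_flags = {}
    for name, entry in d.get("univariate", {}).items():
        if entry.get("metric") == "ks_pvalue":
            p = entry.get("value")
            ks_flags[name] = "pass" if (p is not None and p > thr["ks_p_min"]) \
                else "fail"
    flags["ks"] = ks_flags

    auc = d.get("discriminator", {}).get("auc_mean")
    if auc is not None:
        flags["discriminator"] = (
            "pass" if abs(auc - 0.5) <= thr["discriminator_auc_band"] else "warn"
        )

    ratio = d.get("privacy", {}).get("mean_dcr_ratio")
    if ratio is None:
        flags["privacy"] = "warn"  # undefined ratio (duplicated real records)
    elif ratio < thr["dcr_ratio_fail"]:
        flags["privacy"] = "fail"
    elif ratio < thr["dcr_ratio_warn"]:
        flags["privacy"] = "warn"
    else:
        flags["privacy"] = "pass"

    cov = d.get("umap", {}).get("coverage")
    if cov is not None:
        flags["umap"] = "pass" if cov >= thr["umap_coverage_warn"] else "warn"

    return _json_safe(flags)


def _descriptive_section(real: Cohort, syn: Cohort) -> dict:
    sr, ss = summarize(real), summarize(syn)
    pvals = compare_descriptives(real, syn)
    section: dict = {"n_real": real.n_records, "n_syn": syn.n_records,
                     "variables": {}}
    for name, s in sr.numeric.items():
        section["variables"][name] = {
            "kind": "numeric",
            "real": s, "syn": ss.numeric[name],
            "p_value": pvals.get(name),
        }
    for name, s in sr.categorical.items():
        levels = {
            lv: {"real": list(s["levels"][lv]),
                 "syn": list(ss.categorical[name]["levels"][lv]),
                 "p_value": pvals.get(f"{name}={lv}")}
            for lv in s["levels"]
        }
        section["variables"][name] = {
            "kind": "categorical",
            "n_missing_real": s["n_missing"],
            "n_missing_syn": ss.categorical[name]["n_missing"],
            "levels": levels,
        }
    return section


def run_full_validation(
    real_path: str | Path,
    syn_path: str | Path,
    out_dir: str | Path,
    seed: int = 0,
    config_path: str | Path | None = None,
    do_preprocess: bool = False,
    outcome: str | None = None,
    predictors: list[str] | None = None,
    run_umap: bool = True,
    n_bins: int = 25,
    thresholds: dict | None = None,
) -> ValidationReport:
    """Read, optionally preprocess, validate, and write report.json/report.md.

    The optional YAML config may set ``outcome``, ``predictors``,
    ``thresholds``, ``preprocess`` (bool) and ``n_bins``; explicit keyword
    arguments win over the file.
    """
    cfg: dict = {}
    if config_path is not None:
        cfg = yaml.safe_load(Path(config_path).read_text()) or {}
    outcome = outcome if outcome is not None else cfg.get("outcome")
    predictors = predictors if predictors is not None else cfg.get("predictors")
    thresholds = thresholds if thresholds is not None else cfg.get("thresholds")
    do_preprocess = do_preprocess or bool(cfg.get("preprocess", False))
    n_bins = cfg.get("n_bins", n_bins)

    real = read_cohort_csv(real_path, label="real")
    syn = read_cohort_csv(syn_path, label="synthetic")
    if do_preprocess:
        pp = PreprocessConfig()
        real = preprocess_epad(real, pp)
        syn = preprocess_epad(syn, pp)
        if outcome is None:
            outcome = "abeta_lt_1000"
    if real.schema != syn.schema:
        raise ValueError("real and synthetic schemas do not reconcile")

    seeds = _spawn_ints(seed, 4)
    report = ValidationReport()
    report.metadata = {
        "tool": "synthqc",
        "version": _package_version(),
        "master_seed": seed,
        "module_seeds": {"discriminator": seeds[0], "umap": seeds[1],
                         "utility": seeds[2]},
        "config_echo": {"preprocess": do_preprocess, "outcome": outcome,
                        "predictors": predictors, "n_bins": n_bins},
    }

    logger.info("descriptive comparison")
    report.descriptives = _descriptive_section(real, syn)

    logger.info("univariate fidelity")
    uni: dict = {}
    for spec in real.schema:
        name = spec.name
        try:
            if spec.kind == "numeric":
                uni[name] = {
                    "metric": "ks_pvalue",
                    "value": ks_pvalue(real.numeric_values(name),
                                       syn.numeric_values(name)),
                }
            else:
                uni[name] = {
                    "metric": "kl_divergence",
                    "value": kl_divergence(real.data[name], syn.data[name],
                                           alpha=0.5),
                    "value_raw": kl_divergence(real.data[name], syn.data[name],
                                               alpha=0.0),
                }
        except ValueError as exc:
            uni[name] = {"metric": "error", "error": str(exc)}
    report.univariate = uni

    logger.info("correlation structure")
    comp = pcd_l1(real, syn, return_matrices=True)
    report.correlation = {
        "pcd_l1": comp.pcd_l1,
        "pcd_l1_sum": pcd_l1(real, syn, reduce="sum"),
        "encoded_variables": list(comp.corr_real.columns),
        "corr_real": comp.corr_real.to_numpy().tolist(),
        "corr_syn": comp.corr_syn.to_numpy().tolist(),
        "note": "PCD-L1 is the mean absolute upper-triangle difference",
    }

    logger.info("discriminator AUC")
    disc = discriminator_auc(real, syn, seed=seeds[0])
    report.discriminator = {
        "auc_mean": disc.auc_mean, "auc_sd": disc.auc_sd,
        "n_repeats": disc.n_repeats, "n_folds": disc.n_folds,
        "seed": disc.seed, "aucs": disc.aucs,
    }

    if run_umap:
        logger.info("UMAP coverage")
        n_neighbors = min(50, max(2, real.n_records - 1))
        cov = umap_coverage(real, syn, n_neighbors=n_neighbors, seed=seeds[1])
        report.umap = {
            "coverage": cov.coverage,
            "grid_size": cov.grid_size,
            "n_neighbors": n_neighbors,
            "min_dist": 0.1,
            "n_uncovered_cells": len(cov.uncovered_cells),
            "note": ("grid coverage quantifies the visual cluster-coverage "
                     "check; invented metric, not from the literature"),
        }

    if outcome is not None and outcome in real.schema:
        logger.info("utility comparison")
        ur = utility_comparison(real, syn, outcome, predictors, seed=seeds[2])
        report.utility = ur.to_dict()
    elif outcome is not None:
        report.utility = {"skipped": f"outcome {outcome!r} not in schema"}

    logger.info("privacy (DCR)")
    priv = dcr_report(real, syn, n_bins=n_bins)
    report.privacy = priv.to_dict()

    report.verdicts = verdicts(report, thresholds)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = report.to_dict()
    (out_dir / "report.json").write_text(json.dumps(payload, indent=2))
    (out_dir / "report.md").write_text(render_markdown(payload))
    return report


# ---------------------------------------------------------------------------
# markdown rendering (regenerable from report.json alone)


def _fmt(v, digits: int = 4) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v:.{digits}f}"
    return str(v)


def render_markdown(payload: dict) -> str:
    """Render report.md from the report.json payload (and nothing else)."""
    lines = ["# Synthetic cohort validation report", ""]
    meta = payload.get("metadata", {})
    lines += [f"- tool: {meta.get('tool')} {meta.get('version')}",
              f"- master seed: {meta.get('master_seed')}", ""]

    desc = payload.get("descriptives", {})
    if desc:
        lines += ["## Descriptive comparison",
                  f"n real = {desc.get('n_real')}, "
                  f"n synthetic = {desc.get('n_syn')}", "",
                  "| variable | real | synthetic | p-value |",
                  "|---|---|---|---|"]
        for name, entry in desc.get("variables", {}).items():
            if entry["kind"] == "numeric":
                r, s = entry["real"], entry["syn"]
                lines.append(
                    f"| {name} | {_fmt(r['mean'], 2)} ({_fmt(r['sd'], 2)}) "
                    f"| {_fmt(s['mean'], 2)} ({_fmt(s['sd'], 2)}) "
                    f"| {_fmt(entry.get('p_value'))} |")
            else:
                for lv, e in entry["levels"].items():
                    lines.append(
                        f"| {name}={lv} | {e['real'][0]} ({_fmt(e['real'][1], 1)}%) "
                        f"| {e['syn'][0]} ({_fmt(e['syn'][1], 1)}%) "
                        f"| {_fmt(e.get('p_value'))} |")
        lines.append("")

    uni = payload.get("univariate", {})
    if uni:
        lines += ["## Univariate fidelity",
                  "| variable | metric | value |", "|---|---|---|"]
        for name, entry in uni.items():
            lines.append(f"| {name} | {entry.get('metric')} "
                         f"| {_fmt(entry.get('value'))} |")
        lines.append("")

    corr = payload.get("correlation", {})
    if corr:
        lines += ["## Correlation structure",
                  f"PCD-L1 (mean |diff|): {_fmt(corr.get('pcd_l1'))}",
                  f"PCD-L1 (sum |diff|): {_fmt(corr.get('pcd_l1_sum'))}", ""]

    disc = payload.get("discriminator", {})
    if disc:
        lines += ["## Discriminator AUC",
                  f"{_fmt(disc.get('auc_mean'))} ± {_fmt(disc.get('auc_sd'))} "
                  f"({disc.get('n_repeats')} repeats, {disc.get('n_folds')} folds)",
                  ""]

    um = payload.get("umap", {})
    if um:
        lines += ["## UMAP coverage",
                  f"coverage {_fmt(um.get('coverage'))} on a "
                  f"{um.get('grid_size')}x{um.get('grid_size')} grid", ""]

    util = payload.get("utility", {})
    if util and "auc" in util:
        lines += ["## Utility", "| dataset/model | AUC mean | AUC sd |",
                  "|---|---|---|"]
        for key, v in util["auc"].items():
            lines.append(f"| {key} | {_fmt(v['mean'])} | {_fmt(v['sd'])} |")
        lines += [f"", f"nDCG (synthetic vs real ranking): {_fmt(util.get('ndcg'))}",
                  ""]

    priv = payload.get("privacy", {})
    if priv:
        lines += ["## Privacy (DCR)",
                  f"mean DCR synthetic→real: {_fmt(priv.get('mean_dcr_syn_to_real'))}",
                  f"mean DCR real→real: {_fmt(priv.get('mean_dcr_real_to_real'))}",
                  f"mean-DCR ratio: {_fmt(priv.get('mean_dcr_ratio'))}", ""]

    verd = payload.get("verdicts", {})
    if verd:
        lines += ["## Verdicts", "```json",
                  json.dumps(verd, indent=2, sort_keys=True), "```", ""]
    return "\n".join(lines)
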