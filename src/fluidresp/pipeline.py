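"""End-to-end analysis pipeline: cohort -> ROC table -> gray zones -> report.

Ties the modules together with a single top-level seed (fanned out to
per-stage child seeds so stages can be rerun independently), deterministic
JSON serialization, and CSV exports of the ROC and bootstrap-histogram
coordinates for plotting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import grayzone as gz
from . import groupstats, roc, simulate
from .responder import classify_cohort

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

DEFAULT_PREDICTORS = ("PPV_T1", "PPV_T2", "delta_ppv", "SVV_T1", "SVV_T2", "delta_svv")

__all__ = ["PipelineConfig", "simulate_cohort", "analyze_cohort", "render_report", "write_results_json"]


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline settings; the defaults are the study's printed settings.

    18 responders / 22 non-responders, 1,000 bootstrap resamples for the
    gray zone, 90% sensitivity/specificity floors, and a 10% stroke-volume
    responder threshold.
    """

    seed: int = 0
    n_responders: int = 18
    n_nonresponders: int = 22
    correlation_within_patient: float = 0.6
    b_bootstrap: int = 1000
    se_floor: float = 0.90
    sp_floor: float = 0.90
    responder_threshold_percent: float = 10.0
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "predictors" in d:
            d = {**d, "predictors": tuple(d["predictors"])}
        return cls(**d)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Fan a top-level seed out to independent 31-bit child seeds."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def simulate_cohort(config: PipelineConfig, dists=None, changes=None) -> pd.DataFrame:
    """Generate the synthetic cohort stage of the pipeline."""
    sim_seed = _child_seeds(config.seed, 1)[0]
    logger.info("simulate: seed=%d (child of %d)", sim_seed, config.seed)
    spec = simulate.CohortSpec(
        n_responders=config.n_responders,
        n_nonresponders=config.n_nonresponders,
        correlation_within_patient=config.correlation_within_patient,
        seed=sim_seed,
    )
    return simulate.generate_cohort(spec, dists=dists, changes=changes)


def analyze_cohort(cohort: pd.DataFrame, config: PipelineConfig) -> dict:
    """Run responder labeling, ROC/HM inference and both gray zones.

    Returns a JSON-serializable dict keyed by predictor; raises with an
    actionable message when neither a responder column nor the stroke-volume
    columns needed to derive one are present.
    """
    cohort = cohort.copy()
    if "responder" not in cohort.columns:
        if {"SV_T3", "SV_T4"} <= set(cohort.columns):
            cohort = classify_cohort(cohort, threshold=config.responder_threshold_percent)
        else:
            raise ValueError(
                "cohort has no 'responder' column and no SV_T3/SV_T4 columns to derive it; "
                "add responder labels or the stroke-volume columns"
            )
    labels = cohort["responder"].astype(bool).to_numpy()
    missing = [p for p in config.predictors if p not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing predictor columns: {missing}")
    boot_seeds = _child_seeds(config.seed, 1 + len(config.predictors))[1:]
    results: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "n_pos": int(labels.sum()),
        "n_neg": int((~labels).sum()),
        "predictors": {},
    }
    for pred, bseed in zip(config.predictors, boot_seeds):
        scores = cohort[pred].to_numpy(dtype=float)
        curve = roc.empirical_roc(scores, labels, predictor_name=pred)
        op = roc.youden_cutoff(curve)
        thresholds = gz.bootstrap_thresholds(scores, labels, B=config.b_bootstrap, seed=bseed)
        zone_boot = gz.gray_zone_from_bootstrap(thresholds)
        zone_split = gz.split_curve_zone(curve, se_floor=config.se_floor, sp_floor=config.sp_floor)
        results["predictors"][pred] = {
            "auc": curve.auc,
            "se_auc": curve.se_auc,
            "ci95": list(curve.ci95),
            "p_vs_null": roc.auc_p_vs_null(curve),
            "cutoff": op.cutoff,
            "youden_j": op.youden_j,
            "sensitivity": op.sensitivity,
            "sensitivity_ci": list(op.sensitivity_ci),
            "specificity": op.specificity,
            "specificity_ci": list(op.specificity_ci),
            "ppv_pred": None if np.isnan(op.ppv_pred) else op.ppv_pred,
            "ppv_pred_ci": None if np.isnan(op.ppv_pred_ci[0]) else list(op.ppv_pred_ci),
            "npv_pred": None if np.isnan(op.npv_pred) else op.npv_pred,
            "npv_pred_ci": None if np.isnan(op.npv_pred_ci[0]) else list(op.npv_pred_ci),
            "gray_zone_bootstrap": {
                "low": zone_boot.low,
                "high": zone_boot.high,
                "width": zone_boot.width,
                "n_patients_inside": gz.count_inside(scores, zone_boot),
                "n_bootstrap": zone_boot.n_bootstrap,
            },
            "gray_zone_split_curve": {
                "low": zone_split.low,
                "high": zone_split.high,
                "width": zone_split.width,
                "empty": zone_split.is_empty,
                "n_patients_inside": gz.count_inside(scores, zone_split),
                "se_floor": config.se_floor,
                "sp_floor": config.sp_floor,
            },
            "bootstrap_seed": bseed,
        }
    return results


def roc_coordinates(cohort: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Long-format ROC coordinates (predictor, threshold, Se, Sp) for plotting."""
    labels = cohort["responder"].astype(bool).to_numpy()
    frames = []
    for pred in config.predictors:
        curve = roc.empirical_roc(cohort[pred].to_numpy(dtype=float), labels, predictor_name=pred)
        frames.append(
            pd.DataFrame(
                {
                    "predictor": pred,
                    "threshold": curve.thresholds,
                    "sensitivity": curve.sensitivity,
                    "specificity": curve.specificity,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def group_tables(cohort: pd.DataFrame, variables=None) -> dict[str, pd.DataFrame]:
    """The two challenge-phase within-group tables plus the between-group table."""
    if variables is None:
        prefixes = sorted({c.rsplit("_", 1)[0] for c in cohort.columns if c.endswith("_T1")})
        variables = [p for p in prefixes if f"{p}_T2" in cohort.columns]
    out = {
        "peep_challenge": groupstats.within_group_table(cohort, variables, "T1", "T2"),
        "fluid_loading": groupstats.within_group_table(cohort, variables, "T3", "T4"),
    }
    deltas = [c for c in ("delta_ppv", "delta_svv") if c in cohort.columns]
    if deltas:
        out["between_groups"] = groupstats.between_group_table(cohort, deltas)
    return out


def write_results_json(results: dict, path) -> None:
    """Deterministic (sorted-key) JSON dump; reruns on identical input are byte-identical."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _fmt_ci(value, ci, digits=0) -> str:
    if value is None:
        return "--"
    return f"{value:.{digits}f} ({ci[0]:.{digits}f}-{ci[1]:.{digits}f})"


def render_report(results: dict) -> str:
    """Human-readable summary of an analysis-results dict; no recomputation."""
    preds = results.get("predictors", {})
    if not preds:
        return ""
    lines = [
        f"Fluid-responsiveness ROC analysis  (n responders = {results['n_pos']}, "
        f"non-responders = {results['n_neg']})",
        "",
        f"{'predictor':<12}{'AUC (95% CI)':<22}{'p':<10}{'cutoff':<9}"
        f"{'Se% (CI)':<15}{'Sp% (CI)':<15}{'PPV% (CI)':<15}{'NPV% (CI)':<15}",
    ]
    for name, r in preds.items():
        auc_s = f"{r['auc']:.2f} ({r['ci95'][0]:.2f}-{r['ci95'][1]:.2f})"
        p = r["p_vs_null"]
        p_s = "<0.001" if p < 0.001 else f"{p:.3f}"
        lines.append(
            f"{name:<12}{auc_s:<22}{p_s:<10}{r['cutoff']:<9.2f}"
            f"{_fmt_ci(r['sensitivity'], r['sensitivity_ci']):<15}"
            f"{_fmt_ci(r['specificity'], r['specificity_ci']):<15}"
            f"{_fmt_ci(r['ppv_pred'], r['ppv_pred_ci'] or (0, 0)):<15}"
            f"{_fmt_ci(r['npv_pred'], r['npv_pred_ci'] or (0, 0)):<15}"
        )
    lines.append("")
    lines.append("Gray zones (inconclusive ranges):")
    lines.append(
        f"{'predictor':<12}{'bootstrap 95% CI':<24}{'inside':<8}{'split-curve zone':<24}{'inside':<8}"
    )
    for name, r in preds.items():
        b = r["gray_zone_bootstrap"]
        s = r["gray_zone_split_curve"]
        b_s = f"{b['low']:.2f} to {b['high']:.2f}"
        s_s = "empty" if s["empty"] else f"{s['low']:.2f} to {s['high']:.2f}"
        lines.append(
            f"{name:<12}{b_s:<24}{b['n_patients_inside']:<8}{s_s:<24}{s['n_patients_inside']:<8}"
        )
    return "\n".join(lines) + "\n"
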