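"""End-to-end experiment: cohort → calibration → conformal regions → volumes,
metrics, coverage, agreement, stratified summaries.

The full chain is deterministic given the configured seeds.  Summaries
report mean ± SD for variables whose Shapiro–Wilk test does not reject
normality at 0.05, and median (Q1–Q3) otherwise.  No multiple-testing
correction is applied across the metric comparisons; reports flag this.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .agreement import AgreementSummary, PairedSeries, paired_difference_test, summarize_agreement
from .conformal import MondrianConformalSegmenter, certain_masks, empirical_coverage, threshold_map
from .metrics import UndefinedMetricError, asd, brier, dice, ece
from .phantom import PhantomExam, PhantomSpec, generate_cohort
from .volumetry import mask_volume, rvd

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "stratify_by_volume"]

_METRICS = ("dsc", "asd_mm", "rvd", "ece", "brier")


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of the full synthetic-cohort experiment."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    n_calibration: int = 40
    n_evaluation: int = 200
    alphas: tuple[float, ...] = (0.01, 0.05, 0.10, 0.15, 0.20)
    primary_alpha: float = 0.15
    per_class_cap: int = 2000
    master_seed: int = 20240101
    calibration_seed: int = 7
    ece_bins: int = 10
    #: how WITH_CP metrics treat uncertain voxels: "exclude" drops them from
    #: prediction and reference; "background" keeps them as negative calls
    cp_mask_mode: str = "exclude"
    #: volume stratum cut-points in mL: <= first = small, >= second = large
    strata_ml: tuple[float, float] = (35.0, 50.0)
    n_boot: int = 2000
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_calibration < 1 or self.n_evaluation < 1:
            raise ValueError("calibration and evaluation splits must each hold >= 1 exam")
        for a in (*self.alphas, self.primary_alpha):
            if not 0 < a < 1:
                raise ValueError(f"alpha must lie in (0, 1), got {a}")
        if self.primary_alpha not in self.alphas:
            raise ValueError("primary_alpha must be in the alpha sweep")
        if self.cp_mask_mode not in ("exclude", "background"):
            raise ValueError(f"cp_mask_mode must be 'exclude' or 'background', got {self.cp_mask_mode!r}")


@dataclass
class ExperimentReport:
    """All experiment outputs; every summary is recomputable from ``per_exam``."""

    per_exam: pd.DataFrame
    coverage: pd.DataFrame
    summaries: dict
    paired_tests: dict
    agreement: dict[str, AgreementSummary]
    strata: dict
    config: ExperimentConfig


def _summary_stats(values: np.ndarray) -> dict:
    """Normality-gated cohort summary of one variable."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    out = {
        "n": int(values.size),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "median": float(np.median(values)),
        "q1": float(np.percentile(values, 25)),
        "q3": float(np.percentile(values, 75)),
    }
    if values.size >= 3 and np.ptp(values) > 0:
        out["normal"] = bool(stats.shapiro(values).pvalue > 0.05)
    else:
        out["normal"] = True
    out["display"] = (
        f"{out['mean']:.2f} ± {out['sd']:.2f}"
        if out["normal"]
        else f"{out['median']:.2f} ({out['q1']:.2f}–{out['q3']:.2f})"
    )
    return out


def _exam_row(exam: PhantomExam, condition, alpha, pred, ref, prob, exclude, pv, cfg) -> dict:
    try:
        asd_val = asd(pred, ref, exclude=exclude)
    except UndefinedMetricError:
        asd_val = np.nan
    return {
        "exam_id": exam.exam_id,
        "condition": condition,
        "alpha": alpha,
        "dsc": dice(pred, ref, exclude=exclude),
        "asd_mm": asd_val,
        "rvd": rvd(pv, exam.pv_ref_ml),
        "ece": ece(prob, ref, n_bins=cfg.ece_bins, exclude=exclude),
        "brier": brier(prob, ref, exclude=exclude),
        "pv_ml": pv,
        "pv_ref_ml": exam.pv_ref_ml,
    }


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full chain on a synthetic cohort and assemble the report."""
    cfg = config
    n_total = cfg.n_calibration + cfg.n_evaluation
    logger.info("generating %d phantom exams (master seed %d)", n_total, cfg.master_seed)
    cohort = generate_cohort(cfg.phantom, n_total, cfg.master_seed)
    cal, ev = cohort[: cfg.n_calibration], cohort[cfg.n_calibration :]

    clf = MondrianConformalSegmenter(
        alpha=cfg.primary_alpha,
        per_class_cap=cfg.per_class_cap,
        random_state=cfg.calibration_seed,
    ).fit([e.prob for e in cal], [e.mask for e in cal])
    logger.info(
        "calibrated on %d exams: %d bg / %d fg scores",
        cfg.n_calibration,
        clf.scores_bg_.size,
        clf.scores_fg_.size,
    )

    rows = []
    cov_rows = []
    base_rows: dict[str, dict] = {}
    for exam in ev:
        pred_dl = threshold_map(exam.prob)
        pv_dl = mask_volume(pred_dl)
        base_rows[exam.exam_id] = _exam_row(
            exam, "WITHOUT_CP", np.nan, pred_dl, exam.mask, exam.prob, None, pv_dl, cfg
        )

    for alpha in cfg.alphas:
        regions = [clf.predict(e.prob, alpha=alpha) for e in ev]
        for label in (0, 1):
            cov_rows.append(
                {
                    "alpha": alpha,
                    "class_label": label,
                    "coverage": empirical_coverage(regions, [e.mask for e in ev], label),
                    "n_voxels": int(sum((e.mask.voxels == label).sum() for e in ev)),
                }
            )
        for exam, reg in zip(ev, regions):
            base = dict(base_rows[exam.exam_id])
            base["alpha"] = alpha
            rows.append(base)
            certain_fg, uncertain = certain_masks(reg)
            pv_cp = mask_volume(certain_fg)
            excl = uncertain if cfg.cp_mask_mode == "exclude" else None
            rows.append(
                _exam_row(exam, "WITH_CP", alpha, certain_fg, exam.mask, exam.prob, excl, pv_cp, cfg)
            )

    per_exam = pd.DataFrame(rows)
    coverage = pd.DataFrame(cov_rows)

    summaries: dict = {}
    paired_tests: dict = {}
    for alpha in cfg.alphas:
        sub = per_exam[per_exam["alpha"] == alpha]
        without = sub[sub["condition"] == "WITHOUT_CP"].set_index("exam_id")
        with_cp = sub[sub["condition"] == "WITH_CP"].set_index("exam_id")
        summaries[alpha] = {
            cond: {m: _summary_stats(frame[m].to_numpy()) for m in (*_METRICS, "pv_ml")}
            for cond, frame in (("WITHOUT_CP", without), ("WITH_CP", with_cp))
        }
        tests = {}
        for m in _METRICS:
            a = without[m].to_numpy()
            b = with_cp.loc[without.index, m].to_numpy()
            if m in ("rvd",):
                a, b = np.abs(a), np.abs(b)
            ok = ~np.isnan(a) & ~np.isnan(b)
            name, p = paired_difference_test((a[ok], b[ok]))
            tests[m] = {"test": name, "p_value": p, "n": int(ok.sum())}
        paired_tests[alpha] = tests

    prim = per_exam[per_exam["alpha"] == cfg.primary_alpha]
    pv_dl = prim[prim["condition"] == "WITHOUT_CP"].set_index("exam_id")["pv_ml"]
    pv_cp = prim[prim["condition"] == "WITH_CP"].set_index("exam_id")["pv_ml"]
    pv_ref = prim[prim["condition"] == "WITHOUT_CP"].set_index("exam_id")["pv_ref_ml"]
    order = pv_dl.index
    agreement = {
        "PV_CP_vs_PV_ref": summarize_agreement(
            PairedSeries(pv_cp[order].to_numpy(), pv_ref[order].to_numpy()),
            n_boot=cfg.n_boot,
            seed=cfg.master_seed,
        ),
        "PV_DL_vs_PV_ref": summarize_agreement(
            PairedSeries(pv_dl[order].to_numpy(), pv_ref[order].to_numpy()),
            n_boot=cfg.n_boot,
            seed=cfg.master_seed,
        ),
        "PV_DL_vs_PV_CP": summarize_agreement(
            PairedSeries(pv_dl[order].to_numpy(), pv_cp[order].to_numpy()),
            n_boot=cfg.n_boot,
            seed=cfg.master_seed,
        ),
    }

    strata = stratify_by_volume(prim, cfg.strata_ml)

    report = ExperimentReport(per_exam, coverage, summaries, paired_tests, agreement, strata, cfg)
    if cfg.out_dir is not None:
        _write_report(report, Path(cfg.out_dir))
    return report


def stratify_by_volume(rows: pd.DataFrame, cut_points=(35.0, 50.0)) -> dict:
    """Per-stratum summaries on PV_ref: small <= cut1 < medium < cut2 <= large.

    The lower boundary belongs to the small stratum, the upper boundary to
    the large one.  Empty strata are reported with count 0 and no summaries.
    """
    lo, hi = cut_points
    if not lo < hi:
        raise ValueError("cut points must be increasing")
    pv_ref = rows["pv_ref_ml"]
    strata = {
        f"<= {lo:g} mL": rows[pv_ref <= lo],
        f"{lo:g}-{hi:g} mL": rows[(pv_ref > lo) & (pv_ref < hi)],
        f">= {hi:g} mL": rows[pv_ref >= hi],
    }
    out = {}
    for name, sub in strata.items():
        n = sub["exam_id"].nunique()
        entry: dict = {"n_exams": int(n)}
        if n > 0:
            entry["summary"] = {
                cond: {
                    m: _summary_stats(sub[sub["condition"] == cond][m].to_numpy())
                    for m in _METRICS
                }
                for cond in ("WITHOUT_CP", "WITH_CP")
                if (sub["condition"] == cond).any()
            }
        out[name] = entry
    return out


def _jsonable(obj):
    if isinstance(obj, AgreementSummary):
        return asdict(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (tuple, list, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def _write_report(report: ExperimentReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.per_exam.to_csv(out_dir / "per_exam.csv", index=False, float_format="%.6g")
    report.coverage.to_csv(out_dir / "coverage.csv", index=False, float_format="%.6g")
    payload = {
        "summaries": _jsonable(report.summaries),
        "paired_tests": _jsonable(report.paired_tests),
        "agreement": _jsonable(report.agreement),
        "strata": _jsonable(report.strata),
        "note": "no multiple-testing correction applied across metric comparisons",
    }
    (out_dir / "summary.json").write_text(json.dumps(payload, indent=2))
    logger.info("report written to %s", out_dir)
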