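"""End-to-end QA study: cohort -> gamma -> DVH %DE -> correlations/ROC -> report.

``run_study`` executes the full analysis on a simulated or loaded cohort and
writes the study outputs as CSV/JSON plus a human-readable markdown summary:

* ``table1_gp.csv``   — mean +/- SD %GP per acceptance criterion and method;
* ``table23_de.csv``  — cohort %DE per structure/metric (mean of per-plan
  signed %DE, with the mean reference/evaluated doses alongside);
* ``table45_corr.csv``— Pearson r/r^2/p per (criterion, method, structure,
  metric) cell;
* ``table67_meanR.csv``— mean |r| per criterion and method, with the share of
  negative coefficients;
* ``roc.json``        — ROC/AUC and FN-TP counts at the clinical action
  levels, per method at the 3%/3mm criterion;
* ``report.md``, ``study_log.json``, and the raw per-case tables.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dvh import evaluate_metric_set
from .gamma import GammaCriteria, gamma_map
from .stats import (
    DE_ACTION_LEVEL,
    GP_ACTION_LEVEL,
    StudyTable,
    mean_r_summary,
    roc,
    summarize_correlations,
)
from .synthetic import CohortErrorLaw, PlanRecord, SiteTemplate, load_cohort, simulate_cohort

__all__ = ["StudyConfig", "StageError", "build_study_table", "run_study", "report"]

DEFAULT_CRITERIA: tuple[tuple[float, float], ...] = ((1.0, 1.0), (2.0, 2.0), (3.0, 3.0))


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclasses.dataclass(frozen=True)
class StudyConfig:
    """Configuration of one QA study run.

    Exactly one input source: ``cohort_dir`` (a directory written by
    :func:`vmatqa.synthetic.write_cohort`) or simulation (``site`` + ``n`` +
    ``seed`` + ``error_law``).
    """

    out_dir: str
    cohort_dir: str | None = None
    site: str = "prostate"
    n: int = 25
    seed: int = 0
    error_law: str = "study"
    criteria: tuple[tuple[float, float], ...] = DEFAULT_CRITERIA
    methods: tuple[str, ...] = ("2D", "3D")
    normalization: str = "local"
    low_dose_threshold: float = 0.10
    resample_step: float = 1.0
    gp_action: float = GP_ACTION_LEVEL
    de_action: float = DE_ACTION_LEVEL

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ValueError("need at least one acceptance criterion")
        if not self.methods:
            raise ValueError("need at least one method")
        for m in self.methods:
            if m not in ("2D", "3D"):
                raise ValueError(f"unknown method {m!r}")

    def make_criteria(self, dose_tol: float, dta: float) -> GammaCriteria:
        return GammaCriteria(
            dose_tol=dose_tol,
            dta=dta,
            normalization=self.normalization,
            low_dose_threshold=self.low_dose_threshold,
            resample_step=self.resample_step,
        )


def _error_law(name: str) -> CohortErrorLaw:
    factory = getattr(CohortErrorLaw, name, None)
    if factory is None or not callable(factory):
        raise ValueError(f"unknown error law {name!r}")
    return factory()


def axial_max_plane_index(record: PlanRecord) -> int:
    """Axial (z) plane index through the planned dose maximum: the 2D method's plane."""
    return int(np.unravel_index(np.argmax(record.planned.values), record.planned.dims)[2])


def build_study_table(
    records: Sequence[PlanRecord],
    config: StudyConfig,
    plane_index: int | None = None,
) -> StudyTable:
    """Gamma (%GP per criterion x method) and DVH (%DE per metric) for a cohort.

    The 2D method compares the axial plane through each plan's dose maximum
    (or a fixed ``plane_index``); the 3D method compares the full volume.
    """
    gp_rows, de_frames = [], []
    for rec in records:
        for dose_tol, dta in config.criteria:
            crit = config.make_criteria(dose_tol, dta)
            for method in config.methods:
                plane = None
                if method == "2D":
                    idx = plane_index if plane_index is not None else axial_max_plane_index(rec)
                    plane = ("z", idx)
                result = gamma_map(rec.planned, rec.reconstructed, crit, plane=plane)
                gp_rows.append(
                    {
                        "plan_id": rec.plan_id,
                        "method": method,
                        "criteria": crit.label,
                        "gp": result.gp,
                        "n_evaluated": result.n_evaluated,
                    }
                )
        de = evaluate_metric_set(rec.planned, rec.reconstructed, rec.masks, rec.site)
        de.insert(0, "plan_id", rec.plan_id)
        de_frames.append(de)
    return StudyTable(gp=pd.DataFrame(gp_rows), de=pd.concat(de_frames, ignore_index=True))


def _table1(gp: pd.DataFrame) -> pd.DataFrame:
    grouped = gp.groupby(["criteria", "method"], sort=True)["gp"]
    out = grouped.agg(gp_mean="mean", gp_sd=lambda v: float(np.std(v, ddof=1)), n="size")
    return out.reset_index()


def _table23(de: pd.DataFrame) -> pd.DataFrame:
    grouped = de.groupby(["structure", "metric"], sort=False)
    out = grouped.agg(
        d_ref_mean=("d_ref", "mean"),
        d_ref_sd=("d_ref", lambda v: float(np.std(v, ddof=1))),
        d_eval_mean=("d_eval", "mean"),
        d_eval_sd=("d_eval", lambda v: float(np.std(v, ddof=1))),
        de_percent_mean=("de_percent", "mean"),  # mean of per-plan signed %DE
        de_percent_sd=("de_percent", lambda v: float(np.std(v, ddof=1))),
        n=("de_percent", "size"),
    )
    return out.reset_index()


def _roc_summaries(table: StudyTable, config: StudyConfig) -> dict:
    """ROC per method at the loosest (clinical) criterion, 3%/3mm by default."""
    clinical = config.make_criteria(*config.criteria[-1]).label
    joined = table.joined()
    out: dict = {
        "criteria": clinical,
        "gp_action": config.gp_action,
        "de_action": config.de_action,
        "methods": {},
    }
    for method in config.methods:
        sub = joined[(joined["criteria"] == clinical) & (joined["method"] == method)]
        cases = [
            (row.gp, abs(row.de_percent) > config.de_action)
            for row in sub.itertuples()
        ]
        try:
            res = roc(cases, config.gp_action, config.de_action)
            out["methods"][method] = {
                "auc": res.auc,
                "counts": res.counts,
                "n_cases": len(cases),
                "fpr": res.fpr.tolist(),
                "tpr": res.tpr.tolist(),
            }
        except ValueError as exc:  # single-class cohort
            out["methods"][method] = {"auc": None, "n_cases": len(cases), "note": str(exc)}
    return out


def report(table: StudyTable, out_dir: str | Path, config: StudyConfig | None = None) -> Path:
    """Write the human-readable markdown summary; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if table.gp.empty:
        raise ValueError("empty study table")
    lines = ["# VMAT QA study report", ""]
    lines += ["## %GP by acceptance criterion (mean +/- SD)", ""]
    t1 = _table1(table.gp)
    methods = list(dict.fromkeys(table.gp["method"]))
    for method in ("2D", "3D"):
        if method not in methods:
            lines.append(f"*(method {method} not present in this study)*")
    lines.append("| Criterion | Method | %GP |")
    lines.append("|---|---|---|")
    for row in t1.itertuples():
        sd = 0.0 if np.isnan(row.gp_sd) else row.gp_sd
        lines.append(f"| {row.criteria} | {row.method} | {row.gp_mean:.2f} +/- {sd:.2f} |")
    lines += ["", "## %DE by structure and DVH metric (cohort mean +/- SD)", ""]
    lines.append("| Structure | Metric | D_ref (Gy) | D_eval (Gy) | %DE |")
    lines.append("|---|---|---|---|---|")
    for row in _table23(table.de).itertuples():
        lines.append(
            f"| {row.structure} | {row.metric} | {row.d_ref_mean:.2f} | "
            f"{row.d_eval_mean:.2f} | {row.de_percent_mean:+.2f} +/- "
            f"{0.0 if np.isnan(row.de_percent_sd) else row.de_percent_sd:.2f} |"
        )
    if config is not None:
        lines += ["", f"Action levels: %GP > {config.gp_action:g}%, |%DE| > {config.de_action:g}%."]
    path = out_dir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path


def run_study(config: StudyConfig, records: Sequence[PlanRecord] | None = None):
    """Run the full study and write all outputs to ``config.out_dir``.

    Returns ``(StudyTable, dict of output paths)``. Any stage failure raises
    :class:`StageError` naming the stage, after removing partial outputs.
    """
    out_dir = Path(config.out_dir)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    t_start = time.time()

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.time()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is None:
                    log["stages"][name] = {"seconds": round(time.time() - self.t0, 3)}
                return False

        return _Timer()

    try:
        with stage("input"):
            if records is None:
                if config.cohort_dir is not None:
                    records = load_cohort(config.cohort_dir)
                else:
                    template = (
                        SiteTemplate.prostate()
                        if config.site == "prostate"
                        else SiteTemplate.endometrial()
                    )
                    records = simulate_cohort(
                        config.n, template, _error_law(config.error_law), config.seed
                    )
        with stage("gamma_dvh"):
            table = build_study_table(records, config)
        with stage("stats"):
            correlations = summarize_correlations(table)
            mean_r = mean_r_summary(correlations)
            roc_json = _roc_summaries(table, config)
        with stage("write"):
            paths = {
                "table1_gp": out_dir / "table1_gp.csv",
                "table23_de": out_dir / "table23_de.csv",
                "table45_corr": out_dir / "table45_corr.csv",
                "table67_meanR": out_dir / "table67_meanR.csv",
                "roc": out_dir / "roc.json",
                "gp_cases": out_dir / "gp_per_plan.csv",
                "de_cases": out_dir / "de_per_plan.csv",
                "log": out_dir / "study_log.json",
            }
            _table1(table.gp).to_csv(paths["table1_gp"], index=False)
            _table23(table.de).to_csv(paths["table23_de"], index=False)
            correlations.to_csv(paths["table45_corr"], index=False)
            mean_r.to_csv(paths["table67_meanR"], index=False)
            table.gp.to_csv(paths["gp_cases"], index=False)
            table.de.to_csv(paths["de_cases"], index=False)
            with open(paths["roc"], "w") as fh:
                json.dump(roc_json, fh, indent=2)
            paths["report"] = report(table, out_dir, config)
        log["total_seconds"] = round(time.time() - t_start, 3)
        with open(paths["log"], "w") as fh:
            json.dump(log, fh, indent=2)
    except StageError:
        raise
    except BaseException as exc:
        failed_stage = next(
            (nm for nm in ("input", "gamma_dvh", "stats", "write") if nm not in log["stages"]),
            "unknown",
        )
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        else:  # remove only this run's (possibly partial) outputs
            for name in (
                "table1_gp.csv", "table23_de.csv", "table45_corr.csv",
                "table67_meanR.csv", "roc.json", "gp_per_plan.csv",
                "de_per_plan.csv", "study_log.json", "report.md",
            ):
                (out_dir / name).unlink(missing_ok=True)
        raise StageError(failed_stage, exc) from exc
    return table, paths
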