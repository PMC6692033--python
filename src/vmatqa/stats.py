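"""Correlation and sensitivity analysis for QA passing rates vs dose errors.

Given per-plan percentage gamma passing rates (%GP) and per-(structure,
metric) percentage dose errors (%DE), this module quantifies how well the
gamma test predicts clinically relevant dose errors: Pearson correlations per
metric cell, paired t-tests between dose sources, the false-negative /
true-positive classification at clinical action levels (%GP 95%, %DE 3%),
and ROC curves with AUC over the %GP decision threshold.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "StudyTable",
    "PearsonResult",
    "PairedTResult",
    "RocResult",
    "pearson",
    "paired_t_test",
    "classify_case",
    "classification_counts",
    "roc",
    "summarize_correlations",
    "mean_r_summary",
]

GP_ACTION_LEVEL = 95.0  # percent; clinical %GP action level
DE_ACTION_LEVEL = 3.0  # percent; dose-error magnitude deemed clinically relevant


@dataclasses.dataclass(frozen=True)
class StudyTable:
    """Joined per-plan gamma and DVH results for a cohort.

    gp : DataFrame (plan_id, method, criteria, gp)
        One %GP per (plan, verification method, acceptance criterion).
    de : DataFrame (plan_id, structure, metric, d_ref, d_eval, de_percent)
        One signed %DE per (plan, structure, DVH metric).
    """

    gp: pd.DataFrame
    de: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.gp.duplicated(["plan_id", "method", "criteria"])
        if dup.any():
            raise ValueError("duplicate (plan_id, method, criteria) rows in gp table")
        for frame, cols in ((self.gp, ["gp"]), (self.de, ["de_percent"])):
            vals = frame[cols].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError("non-finite percent values in study table")
        unknown = set(self.de["plan_id"]) - set(self.gp["plan_id"])
        if unknown:
            raise ValueError(f"%DE rows reference unknown plans: {sorted(unknown)}")

    def joined(self) -> pd.DataFrame:
        """One row per (plan, method, criteria, structure, metric) case."""
        return self.gp.merge(self.de, on="plan_id", how="inner")


@dataclasses.dataclass(frozen=True)
class PearsonResult:
    r: float
    r_squared: float
    p_value: float
    n: int


@dataclasses.dataclass(frozen=True)
class PairedTResult:
    t: float
    p_value: float
    degenerate: bool  # zero-variance differences
    n: int


@dataclasses.dataclass(frozen=True)
class RocResult:
    """ROC of the %GP score for detecting clinically relevant dose errors.

    The decision score is -gp (a lower passing rate is more suspicious); the
    curve sweeps the threshold over all distinct scores. ``counts`` holds the
    (TP, FN, FP, TN) confusion at the %GP action level.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds_gp: np.ndarray
    auc: float
    counts: dict[str, int]
    gp_action: float
    de_action: float


def pearson(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Sample Pearson correlation with the two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = _sps.pearsonr(x, y)
    r = float(res.statistic)
    return PearsonResult(r, r * r, float(res.pvalue), x.size)


def paired_t_test(d_ref: Sequence[float], d_eval: Sequence[float]) -> PairedTResult:
    """Two-sided paired t-test on per-plan dose differences."""
    d_ref = np.asarray(d_ref, dtype=float)
    d_eval = np.asarray(d_eval, dtype=float)
    if d_ref.shape != d_eval.shape:
        raise ValueError("length mismatch")
    if d_ref.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = d_eval - d_ref
    if np.ptp(diff) == 0:
        # zero-variance differences: the test statistic is undefined (identical
        # vectors) or infinite (constant offset); flag and report accordingly
        if diff[0] == 0:
            return PairedTResult(0.0, 1.0, True, d_ref.size)
        return PairedTResult(np.sign(diff[0]) * np.inf, 0.0, True, d_ref.size)
    t, p = _sps.ttest_rel(d_eval, d_ref)
    return PairedTResult(float(t), float(p), False, d_ref.size)


def classify_case(
    gp: float,
    de: float,
    gp_action: float = GP_ACTION_LEVEL,
    de_action: float = DE_ACTION_LEVEL,
    signed: bool = False,
) -> str:
    """Classify one (plan, structure-metric) case at the QA action levels.

    Condition-positive means a clinically relevant dose error: |%DE| >
    ``de_action`` (or signed %DE > de_action with ``signed=True``). A %GP
    above the action level counts as a QA pass; gp exactly at the action
    level is assigned to the pass side. Pass + positive = FN (the gamma test
    missed a real error); fail + positive = TP; fail + clean = FP; pass +
    clean = TN.
    """
    if not (np.isfinite(gp) and np.isfinite(de)):
        raise ValueError("gp and de must be finite")
    positive = de > de_action if signed else abs(de) > de_action
    qa_pass = gp >= gp_action
    if positive:
        return "FN" if qa_pass else "TP"
    return "TN" if qa_pass else "FP"


def classification_counts(
    cases: Iterable[tuple[float, float]],
    gp_action: float = GP_ACTION_LEVEL,
    de_action: float = DE_ACTION_LEVEL,
    signed: bool = False,
) -> dict[str, int]:
    """Confusion counts over (gp, de) cases; always TP+FN+FP+TN = n."""
    counts = {"TP": 0, "FN": 0, "FP": 0, "TN": 0}
    for gp, de in cases:
        counts[classify_case(gp, de, gp_action, de_action, signed)] += 1
    return counts


def roc(
    cases: Sequence[tuple[float, bool]],
    gp_action: float = GP_ACTION_LEVEL,
    de_action: float = DE_ACTION_LEVEL,
) -> RocResult:
    """ROC curve and AUC of -gp as a detector of condition-positive cases.

    Parameters
    ----------
    cases : sequence of (gp, condition_positive)
    gp_action, de_action : floats
        Action levels recorded with the confusion counts; the counts use the
        same pass-side convention as :func:`classify_case`.
    """
    gp = np.array([c[0] for c in cases], dtype=float)
    positive = np.array([bool(c[1]) for c in cases])
    if positive.all() or not positive.any():
        raise ValueError("ROC undefined: need at least one positive and one negative case")
    fpr, tpr, thr = _sk_roc_curve(positive, -gp, drop_intermediate=False)
    auc_value = float(_sk_auc(fpr, tpr))
    counts = {"TP": 0, "FN": 0, "FP": 0, "TN": 0}
    for g, pos in zip(gp, positive):
        qa_pass = g >= gp_action
        if pos:
            counts["FN" if qa_pass else "TP"] += 1
        else:
            counts["TN" if qa_pass else "FP"] += 1
    return RocResult(fpr, tpr, -thr, auc_value, counts, gp_action, de_action)


def summarize_correlations(table: StudyTable, min_plans: int = 3) -> pd.DataFrame:
    """Per-(criteria, method, structure, metric) Pearson correlation of %GP vs %DE.

    Cells with fewer than ``min_plans`` plans, or with constant %GP or %DE,
    are flagged in the ``status`` column and carry NaN statistics.
    """
    joined = table.joined()
    rows = []
    keys = ["criteria", "method", "structure", "metric"]
    for key, cell in joined.groupby(keys, sort=True):
        record = dict(zip(keys, key))
        record.update({"r": np.nan, "r_squared": np.nan, "p_value": np.nan, "n": len(cell)})
        if len(cell) < min_plans:
            record["status"] = "underpopulated"
        elif np.ptp(cell["gp"].to_numpy()) == 0 or np.ptp(cell["de_percent"].to_numpy()) == 0:
            record["status"] = "constant_input"
        else:
            res = pearson(cell["gp"].to_numpy(), cell["de_percent"].to_numpy())
            record.update(
                {"r": res.r, "r_squared": res.r_squared, "p_value": res.p_value, "status": "ok"}
            )
        rows.append(record)
    return pd.DataFrame(rows)


def mean_r_summary(correlations: pd.DataFrame) -> pd.DataFrame:
    """Mean |r| per (criteria, method), plus the share of negative r values.

    Mirrors the usual cohort summary: correlation *strength* averages over
    metric cells regardless of sign, with the sign structure reported
    separately as the fraction of negative coefficients.
    """
    ok = correlations[correlations["status"] == "ok"]
    if ok.empty:
        return pd.DataFrame(columns=["criteria", "method", "mean_abs_r", "negative_r_share", "n_cells"])
    grouped = ok.groupby(["criteria", "method"], sort=True)
    out = grouped["r"].agg(
        mean_abs_r=lambda r: float(np.mean(np.abs(r))),
        negative_r_share=lambda r: float(np.mean(r < 0)),
        n_cells="size",
    )
    return out.reset_index()
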