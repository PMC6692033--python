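"""Cumulative dose-volume histograms, clinical DVH metrics, and %DE.

The cumulative DVH of a structure gives, for each dose level D, the fraction
of the structure volume receiving at least D. Metrics are read off the exact
sorted voxel-dose sample (no histogram binning), which makes the inverse
interpolation for D_x% deterministic: D_x% is the dose that the hottest x%
of the structure volume receives.

The percentage dosimetric error between an evaluated (reconstructed or
recalculated) dose and the planned reference dose is the signed quantity

    %DE = 100 * (D_eval - D_ref) / D_ref.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid_io import DoseGrid, GridValidationError, StructureMask, require_coregistered

__all__ = [
    "DVHCurve",
    "MetricSpec",
    "SITE_METRIC_PRESETS",
    "compute_dvh",
    "dose_at_volume",
    "d_max_mean",
    "percent_dose_error",
    "evaluate_metric_set",
]


@dataclasses.dataclass(frozen=True)
class DVHCurve:
    """A cumulative DVH built from the exact sorted voxel-dose sample.

    ``dose_axis`` / ``volume_fraction`` trace the curve from (0, 1) down to
    0 just above the maximum dose; ``doses_sorted`` keeps the underlying
    ascending voxel-dose sample so quantile metrics stay exact.
    """

    dose_axis: np.ndarray
    volume_fraction: np.ndarray
    doses_sorted: np.ndarray
    voxel_volume_mm3: float

    @property
    def n_voxels(self) -> int:
        return int(self.doses_sorted.size)

    def volume_fraction_at(self, dose: float | np.ndarray) -> np.ndarray:
        """Fraction of the structure receiving >= dose (exact counting)."""
        dose = np.asarray(dose, dtype=float)
        n = self.doses_sorted.size
        below = np.searchsorted(self.doses_sorted, dose, side="left")
        return (n - below) / n


@dataclasses.dataclass(frozen=True)
class MetricSpec:
    """One DVH metric on one structure: D_x%, D_max or D_mean."""

    structure: str
    kind: str  # "d_at_volume" | "d_max" | "d_mean"
    x: float | None = None  # percent volume, for d_at_volume

    def __post_init__(self) -> None:
        if self.kind not in ("d_at_volume", "d_max", "d_mean"):
            raise ValueError(f"unknown metric kind {self.kind!r}")
        if self.kind == "d_at_volume":
            if self.x is None or not (0 < self.x <= 100):
                raise ValueError("d_at_volume requires 0 < x <= 100")

    @property
    def label(self) -> str:
        if self.kind == "d_at_volume":
            return f"D_{self.x:g}%"
        return {"d_max": "D_max", "d_mean": "D_mean"}[self.kind]


def _dv(structure: str, x: float) -> MetricSpec:
    return MetricSpec(structure, "d_at_volume", x)


# Clinical metric sets per treatment site: target coverage on the PTV and the
# standard pelvic organ-at-risk dose points.
SITE_METRIC_PRESETS: Mapping[str, tuple[MetricSpec, ...]] = {
    "prostate": (
        _dv("ptv", 1), _dv("ptv", 98), MetricSpec("ptv", "d_mean"),
        _dv("bladder", 15), _dv("bladder", 25), _dv("bladder", 35), _dv("bladder", 50),
        _dv("rectum", 15), _dv("rectum", 25), _dv("rectum", 35), _dv("rectum", 50),
        MetricSpec("bowel", "d_max"),
        MetricSpec("femoral_head_r", "d_max"), _dv("femoral_head_r", 25), _dv("femoral_head_r", 40),
        MetricSpec("femoral_head_l", "d_max"), _dv("femoral_head_l", 25), _dv("femoral_head_l", 40),
        MetricSpec("penile_bulb", "d_mean"),
    ),
    "endometrial": (
        _dv("ptv", 1), _dv("ptv", 98), MetricSpec("ptv", "d_mean"),
        _dv("bladder", 35), _dv("bladder", 50),
        _dv("rectum", 35), _dv("rectum", 50), _dv("rectum", 60),
        _dv("bowel", 30), _dv("bowel", 10),
        MetricSpec("femoral_head_r", "d_max"), _dv("femoral_head_r", 15),
        MetricSpec("femoral_head_l", "d_max"), _dv("femoral_head_l", 15),
        MetricSpec("bone_marrow", "d_mean"),
    ),
}


def compute_dvh(grid: DoseGrid, mask: StructureMask) -> DVHCurve:
    """Cumulative DVH of the masked voxel doses.

    Volume is voxel-counted (voxel count x voxel volume); the curve is the
    exact empirical survival function of the masked dose sample.
    """
    require_coregistered(grid, mask)
    if mask.n_true == 0:
        raise GridValidationError(f"mask {mask.name!r} is empty")
    doses = np.sort(grid.values[mask.voxels].astype(float))
    d_max = doses[-1]
    eps = max(d_max, 1.0) * 1e-9
    # survival curve: starts at (0, 1), steps down, hits 0 just above D_max
    dose_axis = np.unique(np.concatenate([[0.0], doses, [d_max + eps]]))
    curve = DVHCurve(dose_axis, np.empty(0), doses, float(np.prod(grid.spacing)))
    volume_fraction = curve.volume_fraction_at(dose_axis)
    return dataclasses.replace(curve, volume_fraction=volume_fraction)


def dose_at_volume(curve: DVHCurve, x: float) -> float:
    """D_x%: dose received by the hottest x% of the structure volume.

    Inverse linear interpolation of the empirical quantile function on the
    exact sorted sample; D_100% is the minimum masked dose.
    """
    if not (0 < x <= 100):
        raise ValueError(f"x must be in (0, 100], got {x}")
    return float(np.quantile(curve.doses_sorted, 1.0 - x / 100.0, method="linear"))


def d_max_mean(grid: DoseGrid, mask: StructureMask) -> tuple[float, float]:
    """(maximum, mean) masked voxel dose in Gy."""
    require_coregistered(grid, mask)
    if mask.n_true == 0:
        raise GridValidationError(f"mask {mask.name!r} is empty")
    doses = grid.values[mask.voxels]
    return float(doses.max()), float(doses.mean())


def percent_dose_error(d_eval: float, d_ref: float) -> float:
    """Signed %DE = 100 (d_eval - d_ref) / d_ref; requires d_ref > 0."""
    if d_ref <= 0:
        raise ValueError(
            f"%DE undefined for reference dose {d_ref} Gy <= 0; "
            f"report the dose difference ({d_eval - d_ref:+g} Gy) instead"
        )
    return 100.0 * (d_eval - d_ref) / d_ref


def _evaluate_one(grid: DoseGrid, mask: StructureMask, spec: MetricSpec) -> float:
    if spec.kind == "d_at_volume":
        return dose_at_volume(compute_dvh(grid, mask), spec.x)
    mx, mean = d_max_mean(grid, mask)
    return mx if spec.kind == "d_max" else mean


def evaluate_metric_set(
    planned: DoseGrid,
    reconstructed: DoseGrid,
    masks: Iterable[StructureMask],
    metrics: str | Sequence[MetricSpec],
) -> pd.DataFrame:
    """Evaluate a metric set on a planned/reconstructed grid pair.

    Parameters
    ----------
    metrics : preset name ("prostate" / "endometrial") or explicit MetricSpec list.

    Returns
    -------
    DataFrame with columns (structure, metric, d_ref, d_eval, de_percent);
    metrics naming a structure absent from ``masks`` are collected in the
    frame's ``attrs["missing_structures"]`` and their rows omitted.
    """
    if isinstance(metrics, str):
        metrics = SITE_METRIC_PRESETS[metrics]
    by_name = {m.name: m for m in masks}
    rows, missing = [], []
    for spec in metrics:
        mask = by_name.get(spec.structure)
        if mask is None:
            missing.append(spec.structure)
            continue
        d_ref = _evaluate_one(planned, mask, spec)
        d_eval = _evaluate_one(reconstructed, mask, spec)
        rows.append(
            {
                "structure": spec.structure,
                "metric": spec.label,
                "d_ref": d_ref,
                "d_eval": d_eval,
                "de_percent": percent_dose_error(d_eval, d_ref),
            }
        )
    frame = pd.DataFrame(rows, columns=["structure", "metric", "d_ref", "d_eval", "de_percent"])
    frame.attrs["missing_structures"] = sorted(set(missing))
    return frame
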