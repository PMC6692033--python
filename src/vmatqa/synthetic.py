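"""Synthetic pelvic VMAT cohorts: stylised plans plus measurement-chain errors.

This module stands in for the clinical measurement chain (treatment planning
system, delivery, detector array, dose reconstruction). It produces paired
planned/reconstructed 3D dose grids with pelvic-like anatomy so that the
gamma / DVH / correlation pipeline can be exercised under *known* injected
errors:

* ``make_plan`` builds a planned dose: a prescription-level plateau over a
  jittered ellipsoidal PTV with sigmoidal penumbra fall-off and a decaying
  low-dose bath, normalised so the PTV mean dose equals the prescription,
  plus the organ-at-risk masks of the treatment site.
* ``apply_errors`` perturbs a planned dose the way a measurement chain would:
  rigid shift, detector-resolution blur, global output scale, localised
  hot/cold spots, and multiplicative stochastic noise — in that fixed order.
* ``simulate_cohort`` draws a cohort of plan pairs from a parameter law,
  storing the injected truth per plan so downstream recovery is testable.

Anatomy is an ellipsoidal stylisation, not CT-derived; that is sufficient
because the downstream analysis consumes only dose grids and masks.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .grid_io import (
    DoseGrid,
    StructureMask,
    rasterize_ellipsoid,
    read_grid,
    read_mask,
    write_grid,
    write_mask,
)

__all__ = [
    "DETECTOR_PITCH_MM",
    "Hotspot",
    "ErrorModel",
    "CohortErrorLaw",
    "SiteTemplate",
    "PlanRecord",
    "make_plan",
    "apply_errors",
    "simulate_cohort",
    "write_cohort",
    "load_cohort",
]

DETECTOR_PITCH_MM = 7.62
"""Centre-to-centre ion-chamber pitch of a 32x32 2D detector array, mm."""

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclasses.dataclass(frozen=True)
class Hotspot:
    """A localised multiplicative dose deviation (hot if amplitude > 0)."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    amplitude_percent: float


@dataclasses.dataclass(frozen=True)
class ErrorModel:
    """Measurement-chain perturbation of one plan. Defaults are the identity.

    Parameters
    ----------
    global_scale : fractional dose-output error (0.02 = +2%).
    shift_mm : rigid displacement of the delivered pattern, mm.
    blur_fwhm_mm : Gaussian smoothing FWHM emulating finite detector
        resolution; an uncorrected array at :data:`DETECTOR_PITCH_MM` pitch
        corresponds to a FWHM of about that pitch, a reconstruction-corrected
        chain to a small residual blur.
    hotspots : localised multiplicative hot/cold spots.
    noise_sd : fractional sd of multiplicative Gaussian noise per voxel
        (0.005 emulates a 0.5% Monte-Carlo statistical uncertainty).
    seed : seed for the noise draw; required when noise_sd > 0.
    """

    global_scale: float = 0.0
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    blur_fwhm_mm: float = 0.0
    hotspots: tuple[Hotspot, ...] = ()
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.blur_fwhm_mm < 0:
            raise ValueError("blur_fwhm_mm must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for h in self.hotspots:
            if not np.isfinite(h.amplitude_percent):
                raise ValueError("hotspot amplitude must be finite")

    def is_identity(self) -> bool:
        return (
            self.global_scale == 0.0
            and all(s == 0.0 for s in self.shift_mm)
            and self.blur_fwhm_mm == 0.0
            and not self.hotspots
            and self.noise_sd == 0.0
        )


def apply_errors(planned: DoseGrid, model: ErrorModel) -> DoseGrid:
    """Perturb a planned dose with a measurement-chain error model.

    Composition order is fixed: shift -> blur -> global scale -> hotspots ->
    noise. The shift is linear-interpolated and zero-padded (dose moved off
    the grid is lost, with a warning). Deterministic given ``model.seed``.
    """
    values = planned.values.astype(float)

    if any(s != 0.0 for s in model.shift_mm):
        shift_vox = np.asarray(model.shift_mm, dtype=float) / planned.spacing
        edge_dose = _edge_dose_fraction(values, shift_vox)
        if edge_dose > 1e-3:
            warnings.warn(
                f"rigid shift {model.shift_mm} mm moves {100 * edge_dose:.2f}% "
                "of the integral dose outside the grid (zero-padded)",
                stacklevel=2,
            )
        values = ndimage.shift(values, shift_vox, order=1, mode="constant", cval=0.0)

    if model.blur_fwhm_mm > 0:
        sigma_vox = model.blur_fwhm_mm * _FWHM_TO_SIGMA / planned.spacing
        values = ndimage.gaussian_filter(values, sigma_vox, mode="nearest")

    if model.global_scale != 0.0:
        values = values * (1.0 + model.global_scale)

    for spot in model.hotspots:
        r2 = _squared_distance_map(planned, spot.center_mm) / spot.radius_mm**2
        values = values * (1.0 + spot.amplitude_percent / 100.0 * np.exp(-r2))

    if model.noise_sd > 0:
        if model.seed is None:
            raise ValueError("noise_sd > 0 requires an ErrorModel seed")
        rng = np.random.default_rng(model.seed)
        values = values * (1.0 + rng.normal(0.0, model.noise_sd, values.shape))

    return planned.with_values(np.clip(values, 0.0, None))


def _edge_dose_fraction(values: np.ndarray, shift_vox: np.ndarray) -> float:
    """Fraction of integral dose within the margin a shift would push off-grid."""
    total = values.sum()
    if total == 0:
        return 0.0
    lost = 0.0
    for ax, s in enumerate(shift_vox):
        if s == 0:
            continue
        n_full = int(np.floor(abs(s)))
        frac = abs(s) - n_full
        sl = [slice(None)] * values.ndim
        if n_full:
            sl[ax] = slice(-n_full, None) if s > 0 else slice(0, n_full)
            lost += values[tuple(sl)].sum()
        if frac:
            if s > 0:
                sl[ax] = slice(-(n_full + 1), -n_full if n_full else None)
            else:
                sl[ax] = slice(n_full, n_full + 1)
            lost += frac * values[tuple(sl)].sum()
    return float(lost / total)


def _squared_distance_map(grid: DoseGrid, center_mm: Sequence[float]) -> np.ndarray:
    c = np.asarray(center_mm, dtype=float)
    dx = grid.axis_coords(0) - c[0]
    dy = grid.axis_coords(1) - c[1]
    dz = grid.axis_coords(2) - c[2]
    return dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2


# ---------------------------------------------------------------------------
# Site templates and planned-dose synthesis
# ---------------------------------------------------------------------------

# per structure: list of (center offset from isocentre, radii), both mm.
# Unions of several ellipsoids model non-ellipsoidal organs (bone marrow).
_PROSTATE_STRUCTURES: dict[str, list[tuple[tuple, tuple]]] = {
    "ptv": [((0, 0, 0), (32, 27, 30))],
    "bladder": [((0, 36, 14), (28, 22, 22))],
    "rectum": [((0, -32, 0), (15, 13, 42))],
    "bowel": [((0, 14, 56), (44, 34, 10))],
    "femoral_head_r": [((-62, 0, -6), (18, 18, 22))],
    "femoral_head_l": [((62, 0, -6), (18, 18, 22))],
    "penile_bulb": [((0, -6, -42), (10, 8, 8))],
}

_ENDOMETRIAL_STRUCTURES: dict[str, list[tuple[tuple, tuple]]] = {
    "ptv": [((0, 0, 4), (42, 32, 42))],
    "bladder": [((0, 38, 0), (26, 20, 22))],
    "rectum": [((0, -36, -4), (15, 13, 42))],
    "bowel": [((0, 10, 54), (46, 36, 12))],
    "femoral_head_r": [((-64, 0, -10), (18, 18, 22))],
    "femoral_head_l": [((64, 0, -10), (18, 18, 22))],
    "bone_marrow": [((-58, -6, 16), (16, 22, 34)), ((58, -6, 16), (16, 22, 34))],
}


@dataclasses.dataclass(frozen=True)
class SiteTemplate:
    """Geometry and prescription of a stylised pelvic treatment site.

    Defaults mirror a radical pelvic series: 50 Gy in 25 fractions to a
    prostate-like target or 45 Gy in 25 fractions to an endometrial-like
    target, planned on a 3 mm calculation grid.
    """

    site: str
    prescription_gy: float
    n_fractions: int = 25
    spacing_mm: float = 3.0
    dims: tuple[int, int, int] = (64, 64, 48)
    penumbra_mm: float = 3.0  # sigmoid length scale of the target fall-off
    penumbra_margin_mm: float = 9.0  # plateau extension beyond the PTV surface
    bath_fraction: float = 0.30  # arc low-dose bath amplitude at the target edge
    bath_decay_mm: float = 55.0
    heterogeneity_sd: float = 0.012  # smooth multiplicative plan texture
    jitter_sd_mm: float = 2.0  # per-structure anatomical variation

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0:
            raise ValueError("prescription must be positive")
        if self.site not in ("prostate", "endometrial"):
            raise ValueError(f"unknown site {self.site!r}")

    @classmethod
    def prostate(cls, **overrides) -> "SiteTemplate":
        return cls(site="prostate", prescription_gy=50.0, **overrides)

    @classmethod
    def endometrial(cls, **overrides) -> "SiteTemplate":
        return cls(site="endometrial", prescription_gy=45.0, **overrides)

    @property
    def structures(self) -> dict[str, list[tuple[tuple, tuple]]]:
        return _PROSTATE_STRUCTURES if self.site == "prostate" else _ENDOMETRIAL_STRUCTURES

    def empty_grid(self, frame_id: str = "synthetic") -> DoseGrid:
        dims = np.asarray(self.dims)
        spacing = np.full(3, self.spacing_mm)
        origin = -(dims - 1) * spacing / 2.0
        return DoseGrid(origin, spacing, np.zeros(self.dims), frame_id)


@dataclasses.dataclass(frozen=True)
class PlanRecord:
    """One synthetic patient: planned and reconstructed dose, masks, truth."""

    plan_id: str
    planned: DoseGrid
    reconstructed: DoseGrid
    masks: tuple[StructureMask, ...]
    injected: ErrorModel
    site: str

    def mask(self, name: str) -> StructureMask:
        for m in self.masks:
            if m.name == name:
                return m
        raise KeyError(name)


def _signed_distance_to_ellipsoid(grid: DoseGrid, center, radii) -> np.ndarray:
    """First-order signed distance (mm) to an axis-aligned ellipsoid surface.

    Negative inside. Uses d = (rho - 1) / |grad rho| with
    rho = sqrt(sum(((x - c) / a)^2)); exact for spheres, a good approximation
    for the moderate aspect ratios used here.
    """
    c = np.asarray(center, dtype=float)
    a = np.asarray(radii, dtype=float)
    dx = (grid.axis_coords(0) - c[0])
    dy = (grid.axis_coords(1) - c[1])
    dz = (grid.axis_coords(2) - c[2])
    u2 = (
        (dx[:, None, None] / a[0]) ** 2
        + (dy[None, :, None] / a[1]) ** 2
        + (dz[None, None, :] / a[2]) ** 2
    )
    rho = np.sqrt(u2)
    grad2 = (
        (dx[:, None, None] / a[0] ** 2) ** 2
        + (dy[None, :, None] / a[1] ** 2) ** 2
        + (dz[None, None, :] / a[2] ** 2) ** 2
    )
    grad = np.sqrt(grad2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (rho - 1.0) * rho / np.where(grad > 0, grad, np.inf)
    d[grad == 0] = -float(a.min())  # ellipsoid centre
    return d


_MAX_PLAN_RETRIES = 5


def make_plan(
    template: SiteTemplate, seed: int, frame_id: str | None = None
) -> tuple[DoseGrid, list[StructureMask]]:
    """Synthesise one planned dose grid and its structure masks.

    The dose field is a sigmoidal plateau over the jittered PTV (plateau
    extended ``penumbra_margin_mm`` beyond the surface so the PTV stays
    covered), plus an exponentially decaying low-dose bath, modulated by a
    smooth heterogeneity texture, and normalised so that the PTV mean dose
    equals the prescription. Deterministic given (template, seed).
    """
    rng = np.random.default_rng(seed)
    frame = frame_id or f"synthetic-{template.site}-{seed}"
    grid0 = template.empty_grid(frame)
    half_extent = grid0.extent() / 2.0

    for attempt in range(_MAX_PLAN_RETRIES):
        geometry = {}
        ok = True
        for name, lobes in template.structures.items():
            jitter = rng.normal(0.0, template.jitter_sd_mm, size=3)
            placed = []
            for center, radii in lobes:
                c = np.asarray(center, dtype=float) + jitter
                r = np.asarray(radii, dtype=float)
                if np.any(np.abs(c) + r > half_extent):
                    ok = False
                placed.append((c, r))
            geometry[name] = placed
        if ok:
            break
        warnings.warn(
            f"structure collided with the grid boundary (attempt {attempt + 1}); "
            "re-drawing anatomy",
            stacklevel=2,
        )
    else:
        raise RuntimeError(
            f"could not place structures inside the grid after {_MAX_PLAN_RETRIES} attempts"
        )

    # dose synthesis from the (single-lobe) PTV
    ptv_center, ptv_radii = geometry["ptv"][0]
    d = _signed_distance_to_ellipsoid(grid0, ptv_center, ptv_radii)
    plateau = 1.0 / (1.0 + np.exp((d - template.penumbra_margin_mm) / template.penumbra_mm))
    bath = template.bath_fraction * np.exp(-np.clip(d, 0.0, None) / template.bath_decay_mm)
    dose = plateau + bath * (1.0 - plateau)

    # smooth multiplicative texture (plan-to-plan variability of the plateau)
    texture = rng.normal(0.0, 1.0, grid0.dims)
    texture = ndimage.gaussian_filter(texture, sigma=4.0, mode="nearest")
    texture /= max(texture.std(), 1e-12)
    dose = dose * (1.0 + template.heterogeneity_sd * texture)
    dose = np.clip(dose, 0.0, None)

    masks = []
    for name, placed in geometry.items():
        voxels = np.zeros(grid0.dims, dtype=bool)
        for c, r in placed:
            voxels |= rasterize_ellipsoid(grid0, c, r, name=name).voxels
        masks.append(StructureMask(name, grid0.origin, grid0.spacing, voxels, frame))

    ptv_voxels = masks[[m.name for m in masks].index("ptv")].voxels
    dose *= template.prescription_gy / dose[ptv_voxels].mean()
    return grid0.with_values(dose), masks


# ---------------------------------------------------------------------------
# Cohort error laws
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CohortErrorLaw:
    """Distributions the per-plan :class:`ErrorModel` parameters are drawn from.

    ``scale_range`` is uniform; shifts are per-axis zero-mean normal;
    ``blur_fwhm_range`` uniform; each plan receives a hotspot with
    probability ``hotspot_prob``, with uniform amplitude/radius and a centre
    placed at a uniform distance from the isocentre in a random direction
    (localised errors away from the target). ``noise_sd`` is fixed.
    """

    scale_range: tuple[float, float] = (0.0, 0.0)
    shift_sd_mm: float = 0.0
    blur_fwhm_range: tuple[float, float] = (0.0, 0.0)
    hotspot_prob: float = 0.0
    hotspot_amp_range: tuple[float, float] = (-8.0, 8.0)
    hotspot_radius_range: tuple[float, float] = (8.0, 14.0)
    hotspot_distance_range: tuple[float, float] = (40.0, 65.0)
    noise_sd: float = 0.005

    def is_degenerate(self) -> bool:
        """True when every draw is the identity apart from noise."""
        return (
            self.scale_range == (0.0, 0.0)
            and self.shift_sd_mm == 0.0
            and self.blur_fwhm_range == (0.0, 0.0)
            and self.hotspot_prob == 0.0
        )

    @classmethod
    def zero(cls) -> "CohortErrorLaw":
        """No errors at all (noise off): reconstructed == planned."""
        return cls(noise_sd=0.0)

    @classmethod
    def noise_only(cls, noise_sd: float = 0.005) -> "CohortErrorLaw":
        return cls(noise_sd=noise_sd)

    @classmethod
    def scale_only(cls, lo: float = 0.0, hi: float = 0.04) -> "CohortErrorLaw":
        """Global dose-output drift straddling the 3% action level."""
        return cls(scale_range=(lo, hi))

    @classmethod
    def recovery(cls, half_width: float = 0.04) -> "CohortErrorLaw":
        """Symmetric scale law for injected-truth slope recovery."""
        return cls(scale_range=(-half_width, half_width))

    @classmethod
    def hotspot_only(cls) -> "CohortErrorLaw":
        """Localised hot/cold spots far from the target, every plan."""
        return cls(hotspot_prob=1.0)

    @classmethod
    def study(cls) -> "CohortErrorLaw":
        """Default mixed law: the small residual errors of a tuned QA chain."""
        return cls(
            scale_range=(-0.02, 0.02),
            shift_sd_mm=0.8,
            blur_fwhm_range=(1.5, 3.5),
            hotspot_prob=0.3,
            hotspot_amp_range=(-6.0, 6.0),
        )

    def draw(self, rng: np.random.Generator, noise_seed: int) -> ErrorModel:
        scale = float(rng.uniform(*self.scale_range))
        shift = tuple(rng.normal(0.0, self.shift_sd_mm, 3)) if self.shift_sd_mm > 0 else (0.0, 0.0, 0.0)
        blur = float(rng.uniform(*self.blur_fwhm_range))
        hotspots: tuple[Hotspot, ...] = ()
        if rng.uniform() < self.hotspot_prob:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            center = tuple(direction * rng.uniform(*self.hotspot_distance_range))
            hotspots = (
                Hotspot(
                    center_mm=center,
                    radius_mm=float(rng.uniform(*self.hotspot_radius_range)),
                    amplitude_percent=float(rng.uniform(*self.hotspot_amp_range)),
                ),
            )
        return ErrorModel(
            global_scale=scale,
            shift_mm=shift,
            blur_fwhm_mm=blur,
            hotspots=hotspots,
            noise_sd=self.noise_sd,
            seed=noise_seed,
        )


def simulate_cohort(
    n: int,
    template: SiteTemplate,
    law: CohortErrorLaw,
    seed: int,
    progress: Callable[[str], None] | None = None,
) -> list[PlanRecord]:
    """Simulate ``n`` independent plan pairs under one error law.

    Randomness splitting: the cohort seed feeds a ``numpy.random.SeedSequence``
    whose spawned children drive, per plan, (a) the anatomy jitter and plan
    texture, (b) the error-parameter draw, and (c) the measurement noise.
    Two runs with equal arguments are bit-identical.
    """
    if n < 3:
        raise ValueError("cohort size must be >= 3")
    if law.is_degenerate() and law.noise_sd == 0.0:
        warnings.warn("degenerate error law: reconstructed doses equal planned doses", stacklevel=2)
    root = np.random.SeedSequence(seed)
    records = []
    for i, child in enumerate(root.spawn(n)):
        plan_seed, law_seed, noise_seed = (
            int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(3)
        )
        plan_id = f"{template.site}-{i:03d}"
        planned, masks = make_plan(template, plan_seed, frame_id=plan_id)
        model = law.draw(np.random.default_rng(law_seed), noise_seed)
        reconstructed = apply_errors(planned, model)
        records.append(PlanRecord(plan_id, planned, reconstructed, tuple(masks), model, template.site))
        if progress is not None:
            progress(plan_id)
    return records


# ---------------------------------------------------------------------------
# Cohort persistence: portable grid/mask files + a manifest of injected truth
# ---------------------------------------------------------------------------

def _model_to_dict(model: ErrorModel) -> dict:
    d = dataclasses.asdict(model)
    d["hotspots"] = [dataclasses.asdict(h) for h in model.hotspots]
    return d


def _model_from_dict(d: dict) -> ErrorModel:
    hotspots = tuple(
        Hotspot(tuple(h["center_mm"]), h["radius_mm"], h["amplitude_percent"])
        for h in d.get("hotspots", [])
    )
    return ErrorModel(
        global_scale=d["global_scale"],
        shift_mm=tuple(d["shift_mm"]),
        blur_fwhm_mm=d["blur_fwhm_mm"],
        hotspots=hotspots,
        noise_sd=d["noise_sd"],
        seed=d.get("seed"),
    )


def write_cohort(records: Sequence[PlanRecord], directory: str | Path) -> None:
    """Write a cohort as portable text grids/masks plus ``manifest.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"plans": []}
    for rec in records:
        plan_dir = directory / rec.plan_id
        plan_dir.mkdir(exist_ok=True)
        write_grid(rec.planned, plan_dir / "planned.grid")
        write_grid(rec.reconstructed, plan_dir / "reconstructed.grid")
        for mask in rec.masks:
            write_mask(mask, plan_dir / f"mask_{mask.name}.grid")
        manifest["plans"].append(
            {
                "plan_id": rec.plan_id,
                "site": rec.site,
                "structures": [m.name for m in rec.masks],
                "injected": _model_to_dict(rec.injected),
            }
        )
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_cohort(directory: str | Path) -> list[PlanRecord]:
    """Load a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    records = []
    for entry in manifest["plans"]:
        plan_dir = directory / entry["plan_id"]
        masks = tuple(
            read_mask(plan_dir / f"mask_{name}.grid") for name in entry["structures"]
        )
        records.append(
            PlanRecord(
                plan_id=entry["plan_id"],
                planned=read_grid(plan_dir / "planned.grid"),
                reconstructed=read_grid(plan_dir / "reconstructed.grid"),
                masks=masks,
                injected=_model_from_dict(entry["injected"]),
                site=entry["site"],
            )
        )
    return records
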