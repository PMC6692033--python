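"""Gamma-index comparison of dose distributions.

The gamma index of Low et al. scores each reference point r against an
evaluated distribution by

    gamma(r) = min_e sqrt( (D_e(e) - D_r(r))^2 / tol(r)^2  +  |e - r|^2 / dta^2 )

where ``tol(r)`` is the dose tolerance (a percentage of the local reference
dose, or of the global reference maximum) and ``dta`` the distance-to-agreement
tolerance in mm. A point passes when gamma <= 1; the percentage gamma passing
rate (%GP) is the fraction of evaluated (non-threshold-excluded) reference
points that pass.

Implementation: the evaluated grid is multilinearly resampled onto a fine
lattice whose nodes contain the reference voxel centres (default 1 mm step),
and the minimisation runs over integer lattice shifts sorted by distance,
with early termination once the distance term alone exceeds every point's
current best gamma. An independent exhaustive ``brute_force_gamma`` (full
O(N_ref x N_eval) minimisation over the same candidate lattice) serves as a
test oracle.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .grid_io import DoseGrid, GridValidationError, require_coregistered

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "resample",
    "extract_plane",
    "gamma_map",
    "brute_force_gamma",
]

_AXIS_NAMES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}


@dataclasses.dataclass(frozen=True)
class GammaCriteria:
    """Acceptance criteria and evaluation options for a gamma comparison.

    Parameters
    ----------
    dose_tol : float
        Dose-difference tolerance, percent (1, 2, 3 for the usual 1%/1mm,
        2%/2mm, 3%/3mm criteria).
    dta : float
        Distance-to-agreement tolerance, mm.
    normalization : {"local", "global"}
        Whether ``dose_tol`` references the local reference-point dose or the
        global reference maximum.
    low_dose_threshold : float
        Points with dose below this fraction of the maximum are excluded from
        the evaluation (both numerator and denominator of %GP).
    threshold_on : {"reference", "evaluated"}
        Which distribution the low-dose threshold is applied to.
    resample_step : float
        Target step (mm) of the fine search lattice the evaluated dose is
        interpolated onto. The actual step is the voxel pitch divided by a
        whole number, snapped to the nearest divisor <= the requested step.
    search_radius_factor : float
        Search radius in units of ``dta``; gamma values are reported capped at
        this factor. Any cap > ``pass_limit`` cannot flip pass/fail.
    pass_limit : float
        Gamma value counted as a pass.
    pass_inclusive : bool
        If True (default) gamma == pass_limit passes.
    boundary_tol : float
        Absolute tolerance applied at the pass boundary, so that a dose
        difference exactly at tolerance (gamma == 1 up to floating-point
        rounding) classifies deterministically.
    """

    dose_tol: float
    dta: float
    normalization: str = "local"
    low_dose_threshold: float = 0.10
    threshold_on: str = "reference"
    resample_step: float = 1.0
    search_radius_factor: float = 3.0
    pass_limit: float = 1.0
    pass_inclusive: bool = True
    boundary_tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.dose_tol <= 0:
            raise ValueError("dose_tol must be > 0")
        if self.dta <= 0:
            raise ValueError("dta must be > 0")
        if not (0.0 <= self.low_dose_threshold < 1.0):
            raise ValueError("low_dose_threshold must be in [0, 1)")
        if self.resample_step <= 0:
            raise ValueError("resample_step must be > 0")
        if self.normalization not in ("local", "global"):
            raise ValueError("normalization must be 'local' or 'global'")
        if self.threshold_on not in ("reference", "evaluated"):
            raise ValueError("threshold_on must be 'reference' or 'evaluated'")
        if self.search_radius_factor <= self.pass_limit:
            raise ValueError("search_radius_factor must exceed pass_limit")

    @property
    def label(self) -> str:
        return f"{self.dose_tol:g}%/{self.dta:g}mm"


@dataclasses.dataclass(frozen=True)
class GammaResult:
    """Gamma map plus the passing-rate summary.

    ``gamma`` holds NaN at threshold-excluded points; ``excluded`` flags them.
    """

    gamma: np.ndarray
    excluded: np.ndarray
    gp: float
    n_evaluated: int
    criteria: GammaCriteria

    @property
    def n_excluded(self) -> int:
        return int(self.excluded.sum())

    @property
    def n_pass(self) -> int:
        crit = self.criteria
        valid = ~self.excluded
        if crit.pass_inclusive:
            return int((self.gamma[valid] <= crit.pass_limit + crit.boundary_tol).sum())
        return int((self.gamma[valid] < crit.pass_limit - crit.boundary_tol).sum())


def extract_plane(grid: DoseGrid, axis: int | str, index: int) -> DoseGrid:
    """Extract one plane as a grid with a singleton axis, geometry preserved."""
    ax = _AXIS_NAMES[axis]
    if not (0 <= index < grid.dims[ax]):
        raise IndexError(f"plane index {index} out of range for axis {ax} (dim {grid.dims[ax]})")
    sl = [slice(None)] * 3
    sl[ax] = slice(index, index + 1)
    origin = grid.origin.copy()
    origin[ax] += index * grid.spacing[ax]
    return DoseGrid(origin, grid.spacing, grid.values[tuple(sl)], grid.frame_id)


def resample(grid: DoseGrid, step: float | Sequence[float]) -> DoseGrid:
    """Multilinearly resample a grid to a new step over the same extent.

    Axes with a single voxel are kept as-is, so a 2D plane resamples
    bilinearly and a volume trilinearly. No extrapolation: the new lattice
    runs from the grid origin in ``step`` increments up to the source extent.
    """
    step = np.broadcast_to(np.asarray(step, dtype=float), (3,)).copy()
    if np.any(step <= 0):
        raise ValueError("step must be positive")
    extent = grid.extent()
    new_dims = np.ones(3, dtype=int)
    for ax in range(3):
        if grid.dims[ax] == 1:
            step[ax] = grid.spacing[ax]
            continue
        new_dims[ax] = int(np.floor(extent[ax] / step[ax] + 1e-9)) + 1
        if new_dims[ax] < 2:
            raise GridValidationError(
                f"resample step {step[ax]:g} mm exceeds grid extent "
                f"{extent[ax]:g} mm on axis {ax}"
            )
    new_coords = [grid.origin[ax] + step[ax] * np.arange(new_dims[ax]) for ax in range(3)]
    values = _interp_on_lattice(grid, new_coords)
    return DoseGrid(grid.origin, step, values, grid.frame_id)


def _interp_on_lattice(grid: DoseGrid, coords: list[np.ndarray]) -> np.ndarray:
    """Evaluate the grid's multilinear interpolant on a product lattice."""
    src_axes = [grid.axis_coords(ax) for ax in range(3)]
    # RegularGridInterpolator requires >= 2 nodes per axis; collapse singletons
    keep = [ax for ax in range(3) if grid.dims[ax] > 1]
    values = grid.values
    if len(keep) == 0:
        out_shape = tuple(len(c) for c in coords)
        return np.full(out_shape, values.ravel()[0], dtype=float)
    squeezed = np.squeeze(values, axis=tuple(ax for ax in range(3) if ax not in keep))
    interp = RegularGridInterpolator(
        [src_axes[ax] for ax in keep], squeezed, method="linear", bounds_error=True
    )
    mesh = np.meshgrid(*[coords[ax] for ax in keep], indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    out = interp(pts).reshape([len(coords[ax]) for ax in keep])
    return out.reshape(tuple(len(coords[ax]) if ax in keep else 1 for ax in range(3)))


def _subdivide_linear(values: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Exact integer-factor linear subdivision: node (i*k) keeps the source value."""
    for ax in range(3):
        if k[ax] == 1:
            continue
        n = values.shape[ax]
        shape = list(values.shape)
        shape[ax] = (n - 1) * k[ax] + 1
        out = np.empty(shape, dtype=float)
        left = [slice(None)] * 3
        right = [slice(None)] * 3
        left[ax] = slice(0, n - 1)
        right[ax] = slice(1, n)
        a, b = values[tuple(left)], values[tuple(right)]
        for j in range(k[ax]):
            w = j / k[ax]
            dest = [slice(None)] * 3
            dest[ax] = slice(j, j + (n - 1) * k[ax], k[ax])
            out[tuple(dest)] = (1.0 - w) * a + w * b
        last = [slice(None)] * 3
        last[ax] = slice(shape[ax] - 1, shape[ax])
        src_last = [slice(None)] * 3
        src_last[ax] = slice(n - 1, n)
        out[tuple(last)] = values[tuple(src_last)]
        values = out
    return values


def _fine_lattice(reference: DoseGrid, evaluated: DoseGrid, step: float):
    """Resample the evaluated dose onto a lattice containing the reference nodes.

    Per axis the subdivision factor is k = round(spacing / step) clipped to
    >= 1 (singleton axes use k = 1), so reference voxel (i, j, l) sits exactly
    at fine node (i*kx, j*ky, l*kz) and the multilinear interpolation reduces
    to separable integer-factor subdivision.
    """
    k = np.ones(3, dtype=int)
    for ax in range(3):
        if reference.dims[ax] > 1:
            k[ax] = max(1, round(reference.spacing[ax] / step))
    fine_spacing = reference.spacing / k
    fine = _subdivide_linear(evaluated.values.astype(float), k)
    return k, fine_spacing, fine


def _exclusion_and_tolerance(reference, evaluated, criteria):
    """Low-dose exclusion mask and per-point absolute dose tolerance (Gy)."""
    ref = reference.values
    if criteria.threshold_on == "reference":
        basis = ref
    else:
        basis = evaluated.values
    basis_max = float(basis.max())
    excluded = basis < criteria.low_dose_threshold * basis_max
    if criteria.normalization == "local":
        excluded = excluded | (ref <= 0.0)  # local-norm division hazard
        tol = criteria.dose_tol / 100.0 * ref
    else:
        tol = np.full_like(ref, criteria.dose_tol / 100.0 * float(ref.max()))
    if excluded.all():
        raise GridValidationError(
            "all reference points fall below the low-dose threshold; "
            "nothing to evaluate"
        )
    tol = np.where(excluded, np.inf, tol)  # excluded points never constrain
    return excluded, tol


def _offsets_sorted(max_offsets: np.ndarray, fine_spacing: np.ndarray, radius: float):
    """Integer lattice offsets with |o * spacing| <= radius, sorted by distance."""
    ranges = [
        np.arange(-min(m, int(radius / s)), min(m, int(radius / s)) + 1)
        for m, s in zip(max_offsets, fine_spacing)
    ]
    ox, oy, oz = np.meshgrid(*ranges, indexing="ij")
    offsets = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=-1)
    dists = np.sqrt(((offsets * fine_spacing) ** 2).sum(axis=1))
    keep = dists <= radius + 1e-12
    offsets, dists = offsets[keep], dists[keep]
    order = np.argsort(dists, kind="stable")
    return offsets[order], dists[order]


def gamma_map(
    reference: DoseGrid,
    evaluated: DoseGrid,
    criteria: GammaCriteria,
    plane: tuple[int | str, int] | None = None,
) -> GammaResult:
    """Compute the gamma map and %GP for a co-registered grid pair.

    Parameters
    ----------
    reference, evaluated : DoseGrid
        Co-registered grids (same origin, spacing, dims, frame).
    criteria : GammaCriteria
    plane : (axis, index), optional
        Restrict the comparison to one plane of both grids (2D mode): the
        search then stays within that plane, as for a planar detector array.
    """
    require_coregistered(reference, evaluated)
    if plane is not None:
        ax, index = plane
        reference = extract_plane(reference, ax, index)
        evaluated = extract_plane(evaluated, ax, index)

    k, fine_spacing, fine = _fine_lattice(reference, evaluated, criteria.resample_step)
    excluded, tol = _exclusion_and_tolerance(reference, evaluated, criteria)
    ref = reference.values
    dims = np.array(reference.dims)
    fine_dims = np.array(fine.shape)
    cap = criteria.search_radius_factor
    radius = cap * criteria.dta

    gamma = np.full(ref.shape, np.inf)
    gamma[excluded] = 0.0  # sentinel: keeps the running max honest
    offsets, dists = _offsets_sorted(fine_dims - 1, fine_spacing, radius)

    for o, dist in zip(offsets, dists):
        d_norm = dist / criteria.dta
        if d_norm >= min(cap, float(gamma.max())):
            break
        ref_sl, fine_sl = [], []
        for ax in range(3):
            # smallest i with i*k + o >= 0 and largest with i*k + o <= fine_dim-1
            i_lo = max(0, int(np.ceil(-o[ax] / k[ax])))
            i_hi = min(dims[ax] - 1, int(np.floor((fine_dims[ax] - 1 - o[ax]) / k[ax])))
            if i_hi < i_lo:
                ref_sl = None
                break
            ref_sl.append(slice(i_lo, i_hi + 1))
            fine_sl.append(slice(i_lo * k[ax] + o[ax], i_hi * k[ax] + o[ax] + 1, k[ax]))
        if ref_sl is None:
            continue
        ref_sl, fine_sl = tuple(ref_sl), tuple(fine_sl)
        diff = fine[fine_sl] - ref[ref_sl]
        cand = np.sqrt((diff / tol[ref_sl]) ** 2 + d_norm**2)
        np.minimum(gamma[ref_sl], cand, out=gamma[ref_sl])

    np.minimum(gamma, cap, out=gamma)
    gamma_out = np.where(excluded, np.nan, gamma)
    n_eval = int((~excluded).sum())
    result = GammaResult(gamma_out, excluded, 0.0, n_eval, criteria)
    gp = 100.0 * result.n_pass / n_eval
    return dataclasses.replace(result, gp=gp)


BRUTE_FORCE_MAX_PAIRS = 50_000_000
"""Size cap (reference x candidate pairs) above which brute_force_gamma refuses."""


def brute_force_gamma(
    reference: DoseGrid,
    evaluated: DoseGrid,
    criteria: GammaCriteria,
    plane: tuple[int | str, int] | None = None,
) -> GammaResult:
    """Exhaustive gamma: full minimisation over every fine-lattice candidate.

    Independent oracle for :func:`gamma_map`: no search radius, no cap —
    gamma values above ``search_radius_factor`` are reported as-is. Uses the
    same evaluated-dose resampling so the candidate set is identical. Refuses
    problems above :data:`BRUTE_FORCE_MAX_PAIRS` pairs.
    """
    require_coregistered(reference, evaluated)
    if plane is not None:
        ax, index = plane
        reference = extract_plane(reference, ax, index)
        evaluated = extract_plane(evaluated, ax, index)

    k, fine_spacing, fine = _fine_lattice(reference, evaluated, criteria.resample_step)
    excluded, tol = _exclusion_and_tolerance(reference, evaluated, criteria)
    ref = reference.values
    n_eval = int((~excluded).sum())
    if n_eval * fine.size > BRUTE_FORCE_MAX_PAIRS:
        raise ValueError(
            f"problem size {n_eval} x {fine.size} exceeds the brute-force cap "
            f"of {BRUTE_FORCE_MAX_PAIRS} pairs"
        )

    fine_coords = [
        reference.origin[ax] + fine_spacing[ax] * np.arange(fine.shape[ax])
        for ax in range(3)
    ]
    fx, fy, fz = np.meshgrid(*fine_coords, indexing="ij")
    fine_pos = np.stack([fx.ravel(), fy.ravel(), fz.ravel()], axis=-1)
    fine_flat = fine.ravel()

    idx = np.argwhere(~excluded)
    ref_pos = reference.origin + idx * reference.spacing
    ref_vals = ref[~excluded]
    tol_vals = tol[~excluded]

    gamma_vals = np.empty(len(idx))
    chunk = max(1, BRUTE_FORCE_MAX_PAIRS // (4 * fine_flat.size))
    for start in range(0, len(idx), chunk):
        sl = slice(start, start + chunk)
        dose_term = (fine_flat[None, :] - ref_vals[sl, None]) / tol_vals[sl, None]
        d2 = ((fine_pos[None, :, :] - ref_pos[sl, None, :]) ** 2).sum(axis=-1)
        g2 = dose_term**2 + d2 / criteria.dta**2
        gamma_vals[sl] = np.sqrt(g2.min(axis=1))

    gamma = np.full(ref.shape, np.nan)
    gamma[~excluded] = gamma_vals
    result = GammaResult(gamma, excluded, 0.0, n_eval, criteria)
    gp = 100.0 * result.n_pass / n_eval
    return dataclasses.replace(result, gp=gp)
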