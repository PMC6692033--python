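"""Dose grids, structure masks, and portable/DICOM I/O.

The geometry contract used throughout the package:

* coordinates are millimetres, voxel centres, 0-based indices;
* axis order is ``(x, y, z)`` and dose arrays are indexed ``values[ix, iy, iz]``;
* the physical position of voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``;
* two grids are *co-registered* iff origin, spacing, dims and frame_id all match.

Grids and masks can be stored in a plain-text portable format (documented in
the README) that round-trips float64 dose values bit-exactly; DICOM RTDOSE /
RTSTRUCT support is optional and only imported on demand.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DoseGrid",
    "StructureMask",
    "GridFormatError",
    "GridValidationError",
    "coregistered",
    "read_grid",
    "write_grid",
    "read_mask",
    "write_mask",
    "rasterize_ellipsoid",
    "rasterize_contours",
]

_COORD_ATOL = 1e-9  # mm; origin/spacing equality tolerance for co-registration


class GridFormatError(ValueError):
    """A file does not parse under the declared dialect."""


class GridValidationError(ValueError):
    """Grid or mask content violates a geometry/value invariant."""


@dataclasses.dataclass(frozen=True)
class DoseGrid:
    """A 3D scalar dose field in Gy on a regular grid.

    Parameters
    ----------
    origin : (3,) array-like
        Position of voxel (0, 0, 0) centre, mm.
    spacing : (3,) array-like
        Voxel pitch per axis, mm; strictly positive.
    values : ndarray, shape (nx, ny, nz)
        Dose per voxel, Gy; finite and non-negative.
    frame_id : str
        Opaque frame-of-reference label.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    frame_id: str = "default"

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise GridValidationError(f"values must be 3D, got ndim={values.ndim}")
        if not np.all(spacing > 0):
            raise GridValidationError(f"spacing must be strictly positive, got {spacing}")
        if not np.all(np.isfinite(origin)):
            raise GridValidationError("origin must be finite")
        if not np.all(np.isfinite(values)):
            raise GridValidationError("dose values must be finite")
        if np.any(values < 0):
            raise GridValidationError("dose values must be non-negative")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "values", values)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.values.size)

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical voxel-centre coordinates along one axis, mm."""
        n = self.dims[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def extent(self) -> np.ndarray:
        """Physical span from first to last voxel centre per axis, mm."""
        return self.spacing * (np.array(self.dims) - 1)

    def with_values(self, values: np.ndarray) -> "DoseGrid":
        """Same geometry, new dose array (shape must match)."""
        if values.shape != self.values.shape:
            raise GridValidationError(
                f"shape mismatch: {values.shape} vs {self.values.shape}"
            )
        return DoseGrid(self.origin, self.spacing, values, self.frame_id)


@dataclasses.dataclass(frozen=True)
class StructureMask:
    """A named boolean volume on a :class:`DoseGrid` geometry."""

    name: str
    origin: np.ndarray
    spacing: np.ndarray
    voxels: np.ndarray
    frame_id: str = "default"

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        voxels = np.asarray(self.voxels, dtype=bool)
        if voxels.ndim != 3:
            raise GridValidationError("mask voxels must be 3D")
        if not np.all(spacing > 0):
            raise GridValidationError("spacing must be strictly positive")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "voxels", voxels)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_true(self) -> int:
        return int(self.voxels.sum())

    def volume_mm3(self) -> float:
        return self.n_true * float(np.prod(self.spacing))


def coregistered(a: DoseGrid | StructureMask, b: DoseGrid | StructureMask) -> bool:
    """True iff the two objects share origin, spacing, dims and frame_id."""
    return (
        a.dims == b.dims
        and a.frame_id == b.frame_id
        and np.allclose(a.origin, b.origin, rtol=0.0, atol=_COORD_ATOL)
        and np.allclose(a.spacing, b.spacing, rtol=0.0, atol=_COORD_ATOL)
    )


def require_coregistered(a: DoseGrid | StructureMask, b: DoseGrid | StructureMask) -> None:
    if not coregistered(a, b):
        raise GridValidationError(
            "grids are not co-registered "
            f"(dims {a.dims} vs {b.dims}, origin {a.origin} vs {b.origin}, "
            f"spacing {a.spacing} vs {b.spacing}, frame {a.frame_id!r} vs {b.frame_id!r})"
        )


# ---------------------------------------------------------------------------
# Portable plain-text format
#
#   # vmatqa grid v1
#   kind: dose | mask
#   frame_id: <label>
#   name: <structure name, masks only>
#   dims: nx ny nz
#   spacing: sx sy sz          (mm, %.17g)
#   origin: ox oy oz           (mm, %.17g)
#   data:
#   <nx*ny rows of nz whitespace-separated values, index order (x, y, z),
#    z fastest; doses as %.17g (bit-exact float64 round trip), masks as 0/1>
# ---------------------------------------------------------------------------

_MAGIC = "# vmatqa grid v1"


def _parse_header(lines: Iterable[str], path: str) -> tuple[dict, int]:
    fields: dict[str, str] = {}
    n_header = 0
    it = iter(lines)
    first = next(it, None)
    if first is None or first.strip() != _MAGIC:
        raise GridFormatError(f"{path}: missing magic line {_MAGIC!r}")
    n_header += 1
    for line in it:
        n_header += 1
        stripped = line.strip()
        if stripped == "data:":
            return fields, n_header
        if ":" not in stripped:
            raise GridFormatError(f"{path}: malformed header line {stripped!r}")
        key, _, value = stripped.partition(":")
        fields[key.strip()] = value.strip()
    raise GridFormatError(f"{path}: missing 'data:' separator")


def _header_vec(fields: dict, key: str, path: str, cast=float) -> np.ndarray:
    if key not in fields:
        raise GridFormatError(f"{path}: missing header field {key!r}")
    try:
        vec = np.array([cast(tok) for tok in fields[key].split()])
    except ValueError as exc:
        raise GridFormatError(f"{path}: unparseable field {key!r}: {exc}") from None
    if vec.shape != (3,):
        raise GridFormatError(f"{path}: field {key!r} must have 3 components")
    return vec


def _read_portable(path: Path) -> tuple[dict, np.ndarray]:
    with open(path, "r") as fh:
        lines = fh.readlines()
    fields, n_header = _parse_header(lines, str(path))
    dims = _header_vec(fields, "dims", str(path), cast=int).astype(int)
    if np.any(dims <= 0):
        raise GridFormatError(f"{path}: dims must be positive, got {dims}")
    payload = " ".join(lines[n_header:])
    try:
        flat = np.array(payload.split(), dtype=float)
    except ValueError as exc:
        raise GridFormatError(f"{path}: unparseable data payload: {exc}") from None
    if flat.size != int(np.prod(dims)):
        raise GridFormatError(
            f"{path}: expected {int(np.prod(dims))} values for dims {tuple(dims)}, "
            f"got {flat.size}"
        )
    fields["_dims"] = dims
    return fields, flat.reshape(tuple(dims))


def read_grid(path: str | Path, format: str = "portable") -> DoseGrid:
    """Read a dose grid from the portable text format or DICOM RTDOSE.

    Parameters
    ----------
    path : path
    format : {"portable", "rtdose"}
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "rtdose":
        return _read_rtdose(path)
    if format != "portable":
        raise ValueError(f"unknown format {format!r}")
    fields, values = _read_portable(path)
    if fields.get("kind", "dose") != "dose":
        raise GridFormatError(f"{path}: kind is {fields.get('kind')!r}, expected 'dose'")
    return DoseGrid(
        origin=_header_vec(fields, "origin", str(path)),
        spacing=_header_vec(fields, "spacing", str(path)),
        values=values,
        frame_id=fields.get("frame_id", "default"),
    )


def _write_portable(path: Path, header: dict[str, str], array: np.ndarray, fmt: str) -> None:
    nx, ny, nz = array.shape
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        for key, value in header.items():
            fh.write(f"{key}: {value}\n")
        fh.write(f"dims: {nx} {ny} {nz}\n")
        fh.write("data:\n")
        np.savetxt(fh, array.reshape(nx * ny, nz), fmt=fmt)


def write_grid(grid: DoseGrid, path: str | Path) -> None:
    """Write a grid in the portable text format (bit-exact float64 round trip)."""
    header = {
        "kind": "dose",
        "frame_id": grid.frame_id,
        "spacing": " ".join(f"{v:.17g}" for v in grid.spacing),
        "origin": " ".join(f"{v:.17g}" for v in grid.origin),
    }
    _write_portable(Path(path), header, grid.values, fmt="%.17g")


def read_mask(path: str | Path) -> StructureMask:
    """Read a structure mask from the portable text format."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fields, values = _read_portable(path)
    if fields.get("kind") != "mask":
        raise GridFormatError(f"{path}: kind is {fields.get('kind')!r}, expected 'mask'")
    if not np.all(np.isin(values, (0.0, 1.0))):
        raise GridFormatError(f"{path}: mask payload must be 0/1")
    return StructureMask(
        name=fields.get("name", path.stem),
        origin=_header_vec(fields, "origin", str(path)),
        spacing=_header_vec(fields, "spacing", str(path)),
        voxels=values.astype(bool),
        frame_id=fields.get("frame_id", "default"),
    )


def write_mask(mask: StructureMask, path: str | Path) -> None:
    header = {
        "kind": "mask",
        "name": mask.name,
        "frame_id": mask.frame_id,
        "spacing": " ".join(f"{v:.17g}" for v in mask.spacing),
        "origin": " ".join(f"{v:.17g}" for v in mask.origin),
    }
    _write_portable(Path(path), header, mask.voxels.astype(np.uint8), fmt="%d")


# ---------------------------------------------------------------------------
# Synthetic structure rasterisation
# ---------------------------------------------------------------------------

def rasterize_ellipsoid(
    grid: DoseGrid,
    center: Sequence[float],
    radii: Sequence[float],
    name: str = "structure",
) -> StructureMask:
    """Rasterise an axis-aligned ellipsoid onto a grid's geometry.

    A voxel is inside iff its centre satisfies
    ``sum(((p - center) / radii)**2) <= 1``.
    """
    center = np.asarray(center, dtype=float).reshape(3)
    radii = np.asarray(radii, dtype=float).reshape(3)
    if not np.all(radii > 0):
        raise ValueError(f"radii must be positive, got {radii}")
    x = (grid.axis_coords(0) - center[0]) / radii[0]
    y = (grid.axis_coords(1) - center[1]) / radii[1]
    z = (grid.axis_coords(2) - center[2]) / radii[2]
    rho2 = (
        x[:, None, None] ** 2 + y[None, :, None] ** 2 + z[None, None, :] ** 2
    )
    voxels = rho2 <= 1.0
    if not voxels.any():
        raise GridValidationError(
            f"ellipsoid (center {center}, radii {radii}) covers no voxel centre"
        )
    return StructureMask(name, grid.origin, grid.spacing, voxels, grid.frame_id)


def rasterize_contours(
    grid: DoseGrid,
    contours: Sequence[np.ndarray],
    name: str = "structure",
) -> StructureMask:
    """Rasterise planar closed contours (point-in-polygon per axial slice).

    Parameters
    ----------
    contours : sequence of (n_points, 3) arrays
        Each contour is a closed polygon in patient coordinates (mm) lying on
        one axial (constant-z) plane, the convention of DICOM RTSTRUCT
        contour data. Points on a slice not matching a grid z-plane within
        half a voxel are rejected.
    """
    from skimage.draw import polygon2mask

    voxels = np.zeros(grid.dims, dtype=bool)
    z_coords = grid.axis_coords(2)
    for contour in contours:
        pts = np.asarray(contour, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("each contour must be an (n, 3) array")
        z = pts[:, 2]
        if np.ptp(z) > _COORD_ATOL:
            raise ValueError("contour is not planar in z")
        k = int(np.argmin(np.abs(z_coords - z[0])))
        if abs(z_coords[k] - z[0]) > grid.spacing[2] / 2:
            raise ValueError(f"contour z={z[0]:g} mm matches no grid slice")
        # polygon in fractional index coordinates of the (x, y) plane
        ij = (pts[:, :2] - grid.origin[:2]) / grid.spacing[:2]
        voxels[:, :, k] |= polygon2mask(grid.dims[:2], ij)
    return StructureMask(name, grid.origin, grid.spacing, voxels, grid.frame_id)


# ---------------------------------------------------------------------------
# DICOM (optional, lazy)
# ---------------------------------------------------------------------------

def _require_pydicom():
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError(
            "DICOM support requires the optional 'pydicom' dependency; "
            "install vmatqa[dicom] or use the portable text format"
        ) from exc
    return pydicom


def _read_rtdose(path: Path) -> DoseGrid:
    """Read a DICOM RTDOSE file: dose = stored integers x DoseGridScaling."""
    pydicom = _require_pydicom()
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise GridFormatError(f"{path}: Modality is {getattr(ds, 'Modality', None)!r}, expected RTDOSE")
    for field in ("ImagePositionPatient", "PixelSpacing", "GridFrameOffsetVector", "DoseGridScaling"):
        if field not in ds:
            raise GridFormatError(f"{path}: missing required RTDOSE field {field}")
    scaling = float(ds.DoseGridScaling)
    # pixel_array is (frames, rows, cols) = (z, y, x); transpose to (x, y, z)
    values = ds.pixel_array.astype(float) * scaling
    values = np.transpose(values, (2, 1, 0))
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    if offsets.size >= 2:
        dz_all = np.diff(offsets)
        if np.ptp(dz_all) > 1e-6:
            raise GridFormatError(f"{path}: non-uniform GridFrameOffsetVector")
        dz = float(dz_all[0])
    else:
        dz = 1.0
    row_spacing, col_spacing = (float(v) for v in ds.PixelSpacing)  # rows=y, cols=x
    origin = np.asarray(ds.ImagePositionPatient, dtype=float) + np.array([0.0, 0.0, offsets[0]])
    return DoseGrid(
        origin=origin,
        spacing=np.array([col_spacing, row_spacing, dz]),
        values=values,
        frame_id=str(getattr(ds, "FrameOfReferenceUID", "default")),
    )
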