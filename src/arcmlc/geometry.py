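"""Voxel-grid target geometry: spheres, directional margin expansion, masks.

Coordinate conventions
----------------------
The fixed patient frame is right-handed with

* ``+x`` toward the patient's left,
* ``+y`` toward posterior,
* ``+z`` toward superior,

all in millimetres.  Arrays are indexed ``[ix, iy, iz]`` and ``GridSpec.origin``
is the physical position of the *centre* of voxel ``(0, 0, 0)``.

Voxel membership is decided by the voxel-centre-inside rule.  Because a binary
mask quantizes volume, small spheres voxelized with the raw centre-inside rule
at the nominal radius can miss the requested volume by several percent (lattice
point-count fluctuation).  :func:`make_sphere_structure` therefore calibrates
the radius cut so that the voxel count best matches the requested volume; the
calibrated cut converges to the nominal radius as the grid is refined.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .errors import FormatVersionError, GridExtentError, InputError, MarginClipError

_AXIS_NAMES = ("x", "y", "z")

#: Each directional margin is inflated by this fraction of the voxel spacing
#: when the dilation kernel is rasterized.  A discrete kernel systematically
#: under-reaches off-axis (lattice offsets rarely land exactly on the margin
#: surface); 0.1 voxel compensates that deficit without over-reaching on-axis.
KERNEL_INFLATION = 0.1


@dataclass(frozen=True)
class GridSpec:
    """A regular 3D voxel grid (origin = centre of voxel (0,0,0), mm)."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        for name, vals, cond in (
            ("spacing", self.spacing, lambda v: v > 0),
            ("shape", self.shape, lambda v: v > 0),
        ):
            for ax, v in zip(_AXIS_NAMES, vals):
                if not cond(v):
                    raise InputError(f"GridSpec.{name} must be positive on axis {ax}, got {v}")

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def extent(self, axis: int) -> tuple[float, float]:
        """Physical outer edges of the grid along one axis (voxel faces)."""
        lo = self.origin[axis] - 0.5 * self.spacing[axis]
        hi = self.origin[axis] + (self.shape[axis] - 0.5) * self.spacing[axis]
        return lo, hi


@dataclass(frozen=True)
class MarginSpec:
    """Directional margins in mm; sup/inf along z, ant/post along y, left/right along x."""

    sup: float = 0.0
    inf: float = 0.0
    left: float = 0.0
    right: float = 0.0
    ant: float = 0.0
    post: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sup", "inf", "left", "right", "ant", "post"):
            if getattr(self, name) < 0:
                raise InputError(f"MarginSpec.{name} must be non-negative")

    @classmethod
    def isotropic(cls, m: float) -> "MarginSpec":
        return cls(sup=m, inf=m, left=m, right=m, ant=m, post=m)

    @property
    def is_zero(self) -> bool:
        return all(
            getattr(self, n) == 0 for n in ("sup", "inf", "left", "right", "ant", "post")
        )


@dataclass
class StructureVolume:
    """A named boolean voxel mask on a grid."""

    name: str
    grid: GridSpec
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise InputError(
                f"mask shape {self.mask.shape} does not match grid shape {self.grid.shape}"
            )

    @property
    def volume_cc(self) -> float:
        return structure_volume_cc(self)

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) physical coordinates of all true voxels."""
        idx = np.argwhere(self.mask)
        return np.asarray(self.grid.origin) + idx * np.asarray(self.grid.spacing)


def structure_volume_cc(s: StructureVolume) -> float:
    """Voxel count times voxel volume, in cc."""
    return float(s.mask.sum()) * s.grid.voxel_volume_mm3 / 1000.0


def sphere_radius_mm(volume_cc: float) -> float:
    """Closed-form radius of a sphere of the given volume: r = (3V/4pi)^(1/3)."""
    if volume_cc <= 0:
        raise InputError(f"sphere volume must be positive, got {volume_cc}")
    return (3.0 * volume_cc * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def make_sphere_structure(
    center: tuple[float, float, float],
    volume_cc: float,
    grid: GridSpec,
    name: str = "sphere",
) -> StructureVolume:
    """Voxelize a sphere of the requested volume centred at ``center`` (mm).

    The radius cut is calibrated (within half a voxel of the nominal radius)
    so the voxelized volume matches ``volume_cc`` to the nearest whole voxel.
    """
    r = sphere_radius_mm(volume_cc)
    for ax in range(3):
        lo, hi = grid.extent(ax)
        if center[ax] - r < lo or center[ax] + r > hi:
            raise GridExtentError(
                f"sphere of radius {r:.3f} mm at {center} extends beyond the grid "
                f"on axis {_AXIS_NAMES[ax]} (grid extent [{lo:.2f}, {hi:.2f}] mm)"
            )

    cx = grid.axis_coords(0) - center[0]
    cy = grid.axis_coords(1) - center[1]
    cz = grid.axis_coords(2) - center[2]
    d2 = (
        cx[:, None, None] ** 2 + cy[None, :, None] ** 2 + cz[None, None, :] ** 2
    )

    s_max = max(grid.spacing)
    target = volume_cc * 1000.0 / grid.voxel_volume_mm3
    k = max(1, int(round(target)))
    cand = np.flatnonzero(d2 <= (r + 2.0 * s_max) ** 2)
    if cand.size < k:
        raise GridExtentError("sphere does not cover enough voxel centres")
    # exactly k voxels nearest the centre (deterministic index tie-break within
    # equidistant lattice shells): volume error is at most half a voxel
    order = np.lexsort((cand, d2.ravel()[cand]))
    mask = np.zeros(grid.shape, dtype=bool)
    mask.ravel()[cand[order[:k]]] = True
    return StructureVolume(name=name, grid=grid, mask=mask)


def _margin_kernel(m: MarginSpec, spacing: tuple[float, float, float]) -> np.ndarray:
    """Rasterize the per-octant half-ellipsoid dilation kernel.

    An offset ``p`` belongs to the kernel when ``sum((p_i / h_i)^2) <= 1``
    where each half-axis ``h_i`` is the directional margin for the octant of
    ``p`` (inflated by ``KERNEL_INFLATION`` voxels, see module docstring).
    """
    sx, sy, sz = spacing
    pos = (m.left + KERNEL_INFLATION * sx, m.post + KERNEL_INFLATION * sy, m.sup + KERNEL_INFLATION * sz)
    neg = (m.right + KERNEL_INFLATION * sx, m.ant + KERNEL_INFLATION * sy, m.inf + KERNEL_INFLATION * sz)
    n = [int(math.floor(max(p, q) / s)) for p, q, s in zip(pos, neg, spacing)]

    offs = [np.arange(-ni, ni + 1) * s for ni, s in zip(n, spacing)]
    q = np.zeros((2 * n[0] + 1, 2 * n[1] + 1, 2 * n[2] + 1), dtype=float)
    for ax, off in enumerate(offs):
        h = np.where(off >= 0, pos[ax], neg[ax])
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(off == 0, 0.0, (off / h) ** 2)
        term = np.where(np.isfinite(term), term, np.inf)
        shape = [1, 1, 1]
        shape[ax] = len(off)
        q = q + term.reshape(shape)
    return q <= 1.0


def expand_margin(s: StructureVolume, m: MarginSpec, name: str | None = None) -> StructureVolume:
    """Morphological (Minkowski) dilation by the directional-margin kernel.

    Raises :class:`MarginClipError` if the expanded structure would extend
    beyond the grid; the result is never silently truncated.
    """
    if name is None:
        name = s.name if m.is_zero else f"{s.name}+margin"
    if m.is_zero:
        return StructureVolume(name=name, grid=s.grid, mask=s.mask.copy())

    kernel = _margin_kernel(m, s.grid.spacing)
    half = [k // 2 for k in kernel.shape]
    padded = np.pad(s.mask, [(h, h) for h in half])
    conv = fftconvolve(padded.astype(np.float32), kernel.astype(np.float32), mode="same")
    dilated = conv > 0.5

    core = dilated[
        half[0] : half[0] + s.grid.shape[0],
        half[1] : half[1] + s.grid.shape[1],
        half[2] : half[2] + s.grid.shape[2],
    ].copy()
    if int(dilated.sum()) != int(core.sum()):
        raise MarginClipError(
            f"margin expansion of '{s.name}' would clip at the grid boundary; "
            "enlarge the grid instead of truncating"
        )
    return StructureVolume(name=name, grid=s.grid, mask=core)


def surface_mask(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels under 6-connectivity (true voxels with a false face-neighbour)."""
    if not mask.any():
        return np.zeros_like(mask)
    struct = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return mask & ~eroded


# ---------------------------------------------------------------------------
# Serialization: versioned gzip text mask format
# ---------------------------------------------------------------------------

_MASK_MAGIC = "MASKTEXT"
_MASK_VERSION = 1


def save_mask(s: StructureVolume, path) -> None:
    """Write a structure mask as versioned gzip text ('0'/'1' rows)."""
    nz = s.grid.shape[2]
    rows = (s.mask.reshape(-1, nz).astype(np.uint8) + ord("0")).astype(np.uint8)
    body = np.hstack([rows, np.full((rows.shape[0], 1), ord("\n"), np.uint8)])
    header = (
        f"{_MASK_MAGIC} {_MASK_VERSION}\n"
        f"name {s.name}\n"
        "origin {:.6g} {:.6g} {:.6g}\n".format(*s.grid.origin)
        + "spacing {:.6g} {:.6g} {:.6g}\n".format(*s.grid.spacing)
        + "shape {} {} {}\n".format(*s.grid.shape)
    )
    with open(path, "wb") as raw, gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as f:
        f.write(header.encode("ascii"))
        f.write(body.tobytes())


def load_mask(path) -> StructureVolume:
    with gzip.open(path, "rt") as f:
        magic = f.readline().split()
        if len(magic) != 2 or magic[0] != _MASK_MAGIC:
            raise FormatVersionError(f"{path}: not a {_MASK_MAGIC} file")
        if int(magic[1]) != _MASK_VERSION:
            raise FormatVersionError(
                f"{path}: unsupported {_MASK_MAGIC} version {magic[1]} (expected {_MASK_VERSION})"
            )
        name = f.readline().split(maxsplit=1)[1].strip()
        origin = tuple(float(v) for v in f.readline().split()[1:4])
        spacing = tuple(float(v) for v in f.readline().split()[1:4])
        shape = tuple(int(v) for v in f.readline().split()[1:4])
        data = f.read().replace("\n", "")
    grid = GridSpec(origin=origin, spacing=spacing, shape=shape)
    n = shape[0] * shape[1] * shape[2]
    if len(data) != n:
        raise InputError(f"{path}: expected {n} mask entries, found {len(data)}")
    mask = (np.frombuffer(data.encode("ascii"), dtype=np.uint8) - ord("0")).astype(bool)
    return StructureVolume(name=name, grid=grid, mask=mask.reshape(shape))


# ---------------------------------------------------------------------------
# Planar contour import (even-odd fill), used by the RT-STRUCT reader
# ---------------------------------------------------------------------------


def contours_to_mask(
    contours: list[np.ndarray], grid: GridSpec, name: str = "structure", z_tol: float | None = None
) -> StructureVolume:
    """Rasterize planar (x, y, z) contours into a mask by even-odd fill.

    Each contour is an (N, 3) array of vertices lying on one axial plane;
    contours sharing a slice are XOR-combined, so holes (rings inside rings)
    are handled.  Contours are matched to the nearest grid slice; a contour
    farther than ``z_tol`` (default: half the z spacing) from any slice is an
    error.
    """
    from matplotlib.path import Path  # local import: only needed for contour import

    if z_tol is None:
        z_tol = 0.5 * grid.spacing[2]
    zc = grid.axis_coords(2)
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    pts = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1).reshape(-1, 2)
    mask = np.zeros(grid.shape, dtype=bool)
    for contour in contours:
        contour = np.asarray(contour, dtype=float)
        if contour.ndim != 2 or contour.shape[1] != 3 or contour.shape[0] < 3:
            raise InputError("each contour must be an (N>=3, 3) array of x,y,z vertices")
        z = contour[:, 2]
        if np.ptp(z) > 1e-6:
            raise InputError("contours must be planar (constant z)")
        iz = int(np.argmin(np.abs(zc - z[0])))
        if abs(zc[iz] - z[0]) > z_tol:
            raise InputError(
                f"contour at z={z[0]:.3f} mm does not match any grid slice within {z_tol:.3f} mm"
            )
        inside = Path(contour[:, :2]).contains_points(pts).reshape(grid.shape[0], grid.shape[1])
        mask[:, :, iz] ^= inside
    return StructureVolume(name=name, grid=grid, mask=mask)
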