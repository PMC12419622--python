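"""Beam's-eye-view projection and conformal (zero-margin) aperture fitting.

BEV frame: for a coplanar arc with collimator 0, the in-plane axes at the
isocenter plane are

* ``u`` — leaf-travel direction, the unit vector ``(cos g, sin g, 0)`` in the
  patient frame (so ``u = +x`` at gantry 0),
* ``v`` — the patient ``z`` axis (leaf-pair bands stack along ``v``).

The source sits at ``(sad*sin g, -sad*cos g, 0)``: gantry 0 enters from
anterior, gantry 90 from the patient's left (IEC 61217).  Divergent mode
projects each point from the source onto the isocenter plane by similar
triangles; parallel mode drops the beam-axis coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, InputError
from .geometry import StructureVolume, surface_mask
from .plans import ControlPoint, MachineModel

_MODES = ("divergent", "parallel")


@dataclass
class BevSilhouette:
    """Projected point set (u, v) in the isocenter plane for one gantry angle."""

    gantry_angle: float
    points: np.ndarray  # (N, 2), mm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)


@dataclass
class Aperture:
    """Per-leaf-pair open intervals at the isocenter plane for one gantry angle.

    Closed pairs carry both tips at u=0 with ``open=False``; they contribute
    zero open area and block the full band.
    """

    gantry_angle: float
    left: np.ndarray
    right: np.ndarray
    open: np.ndarray
    machine: MachineModel

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.open = np.asarray(self.open, dtype=bool)
        n = self.machine.n_pairs
        if not (self.left.size == self.right.size == self.open.size == n):
            raise InputError(f"aperture arrays must have {n} entries (one per leaf pair)")
        if np.any(self.left[self.open] > self.right[self.open] + 1e-9):
            raise InputError("open leaf pairs must satisfy left <= right")


def project_points(
    points: np.ndarray, gantry_angle: float, machine: MachineModel, mode: str = "divergent"
) -> np.ndarray:
    """Project (N, 3) patient-frame points (mm) into the BEV at the isocenter plane."""
    if mode not in _MODES:
        raise InputError(f"projection mode must be one of {_MODES}, got {mode!r}")
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    g = math.radians(gantry_angle)
    u = p[:, 0] * math.cos(g) + p[:, 1] * math.sin(g)
    v = p[:, 2]
    if mode == "parallel":
        return np.column_stack([u, v])
    depth = machine.sad + (-p[:, 0] * math.sin(g) + p[:, 1] * math.cos(g))
    if np.any(depth <= 1e-9):
        raise GeometryError(
            f"point at or behind the source (sad={machine.sad} mm) at gantry {gantry_angle} deg"
        )
    scale = machine.sad / depth
    return np.column_stack([u * scale, v * scale])


def project_to_bev(
    s: StructureVolume,
    gantry_angle: float,
    machine: MachineModel,
    mode: str = "divergent",
    surface_only: bool = True,
) -> BevSilhouette:
    """Project a structure's voxels into the BEV.

    By default only 6-connectivity surface voxels are projected (the interior
    cannot change per-band extrema); ``surface_only=False`` projects the full
    volume and serves as the brute-force oracle.
    """
    if not s.mask.any():
        raise InputError(f"structure '{s.name}' is empty; nothing to project")
    mask = surface_mask(s.mask) if surface_only else s.mask
    idx = np.argwhere(mask)
    pts = np.asarray(s.grid.origin) + idx * np.asarray(s.grid.spacing)
    return BevSilhouette(gantry_angle=gantry_angle, points=project_points(pts, gantry_angle, machine, mode))


def fit_conformal_aperture(
    silhouette: BevSilhouette, machine: MachineModel, margin_mm: float = 0.0
) -> Aperture:
    """Fit the conformal aperture: per band, [min u - margin, max u + margin].

    Bands are half-open ``[y_i, y_{i+1})``.  Bands the silhouette does not
    reach are closed.  Zero margin yields the reference (zero-margin) aperture.
    """
    if margin_mm < 0:
        raise InputError(f"margin_mm must be non-negative, got {margin_mm}")
    n = machine.n_pairs
    bounds = machine.boundaries
    left = np.zeros(n)
    right = np.zeros(n)
    is_open = np.zeros(n, dtype=bool)
    pts = silhouette.points
    if pts.size:
        band = np.digitize(pts[:, 1], bounds) - 1
        ok = (band >= 0) & (band < n)
        for i in np.unique(band[ok]):
            u = pts[ok & (band == i), 0]
            left[i] = max(u.min() - margin_mm, -machine.max_leaf_position)
            right[i] = min(u.max() + margin_mm, machine.max_leaf_position)
            is_open[i] = True
    return Aperture(
        gantry_angle=silhouette.gantry_angle, left=left, right=right, open=is_open, machine=machine
    )


def aperture_open_area(a: Aperture) -> float:
    """Total open area in mm^2: sum of (right - left) x band height over open pairs."""
    heights = a.machine.band_heights
    return float(np.sum((a.right - a.left)[a.open] * heights[a.open]))


def aperture_from_control_point(cp: ControlPoint, machine: MachineModel) -> Aperture:
    """Interpret a control point's leaf banks as an aperture (zero-width pairs closed)."""
    width = cp.bank_b - cp.bank_a
    is_open = width > 1e-9
    return Aperture(
        gantry_angle=cp.gantry_angle,
        left=cp.bank_a.copy(),
        right=cp.bank_b.copy(),
        open=is_open,
        machine=machine,
    )
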