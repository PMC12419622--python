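"""Arc-plan domain model, MU bookkeeping, and the versioned plan-text dialect.

Conventions
-----------
* Gantry angles follow IEC 61217 (0 deg = beam entering from anterior,
  increasing clockwise viewed from the couch foot) and are stored in
  ``[0, 360)``.
* ``bank_a`` is the bank whose leaves approach from the negative BEV-x side,
  ``bank_b`` from the positive side; for every pair ``bank_a <= bank_b``.
* Cumulative meterset weights are dimensionless, non-decreasing, 0 at the
  first control point and 1 at the last.  The segment between control points
  ``i`` and ``i+1`` is attributed to control point ``i`` (start-of-segment).

Plan-text dialect (version 1)
-----------------------------
Line-oriented ASCII.  Leaf positions and gantry angles are stored at 0.01 mm /
0.01 deg precision; meterset weights and MU at full float precision::

    ARCPLAN-TEXT 1
    sad <mm>
    boundaries <N+1 floats, mm>
    max_leaf_position <mm>
    total_mu <MU>
    prescription <Gy/fx> <n fx> <IDL %>      (optional line)
    control_points <count>
    cp <index> <gantry deg> <cumulative weight>
    a <N floats, mm>
    b <N floats, mm>
    ... repeated per control point
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import FormatVersionError, InputError, MalformedPlanError

_BANK_TOL = 1e-6


@dataclass(frozen=True)
class MachineModel:
    """Delivery geometry: source-axis distance and leaf-pair layout at isocenter."""

    sad: float = 1000.0
    leaf_pair_boundaries: tuple = field(
        default_factory=lambda: tuple(np.linspace(-100.0, 100.0, 41))
    )
    max_leaf_position: float = 200.0

    def __post_init__(self) -> None:
        b = np.asarray(self.leaf_pair_boundaries, dtype=float)
        object.__setattr__(self, "leaf_pair_boundaries", tuple(b))
        if self.sad <= 0:
            raise InputError(f"sad must be positive, got {self.sad}")
        if b.size < 2:
            raise InputError("need at least one leaf pair (2 boundaries)")
        if not np.all(np.diff(b) > 0):
            raise InputError("leaf pair boundaries must be strictly increasing")
        if self.max_leaf_position <= 0:
            raise InputError("max_leaf_position must be positive")

    @property
    def n_pairs(self) -> int:
        return len(self.leaf_pair_boundaries) - 1

    @property
    def band_heights(self) -> np.ndarray:
        return np.diff(np.asarray(self.leaf_pair_boundaries))

    @property
    def boundaries(self) -> np.ndarray:
        return np.asarray(self.leaf_pair_boundaries)


@dataclass(frozen=True)
class PrescriptionSpec:
    """Prescription: dose per fraction, fraction count, and IDL percentage."""

    dose_per_fraction: float
    n_fractions: int
    idl_percent: float = 100.0

    def __post_init__(self) -> None:
        if self.dose_per_fraction <= 0 or self.n_fractions <= 0:
            raise InputError("prescription doses and fraction count must be positive")
        if not (0 < self.idl_percent <= 100):
            raise InputError(f"idl_percent must be in (0, 100], got {self.idl_percent}")

    @property
    def total_dose_gy(self) -> float:
        return self.dose_per_fraction * self.n_fractions


@dataclass
class ControlPoint:
    """One sampled arc state: gantry angle, both leaf banks, cumulative weight."""

    gantry_angle: float
    bank_a: np.ndarray
    bank_b: np.ndarray
    cumulative_meterset_weight: float

    def __post_init__(self) -> None:
        self.bank_a = np.asarray(self.bank_a, dtype=float)
        self.bank_b = np.asarray(self.bank_b, dtype=float)
        self.gantry_angle = float(self.gantry_angle) % 360.0
        if self.bank_a.shape != self.bank_b.shape or self.bank_a.ndim != 1:
            raise MalformedPlanError("bank_a and bank_b must be 1D arrays of equal length")
        bad = np.nonzero(self.bank_a > self.bank_b + _BANK_TOL)[0]
        if bad.size:
            raise MalformedPlanError(
                f"leaf pair {bad[0]}: bank_a ({self.bank_a[bad[0]]:.2f}) exceeds "
                f"bank_b ({self.bank_b[bad[0]]:.2f})"
            )
        if not (-_BANK_TOL <= self.cumulative_meterset_weight <= 1 + _BANK_TOL):
            raise MalformedPlanError(
                f"cumulative meterset weight {self.cumulative_meterset_weight} outside [0, 1]"
            )

    @property
    def n_pairs(self) -> int:
        return self.bank_a.size


@dataclass
class ArcPlan:
    """An ordered list of control points plus machine, MU, and prescription."""

    machine: MachineModel
    control_points: list
    total_mu: float
    prescription: Optional[PrescriptionSpec] = None
    name: str = "plan"

    def __post_init__(self) -> None:
        if len(self.control_points) < 2:
            raise MalformedPlanError("an arc plan requires at least 2 control points")
        for cp in self.control_points:
            if cp.n_pairs != self.machine.n_pairs:
                raise MalformedPlanError(
                    f"control point has {cp.n_pairs} leaf pairs, machine has {self.machine.n_pairs}"
                )
        w = self.weights
        if np.any(np.diff(w) < -_BANK_TOL):
            raise MalformedPlanError("cumulative meterset weights must be non-decreasing")
        if abs(w[0]) > _BANK_TOL or abs(w[-1] - 1.0) > _BANK_TOL:
            raise MalformedPlanError(
                f"cumulative weights must run from 0 to 1, got [{w[0]}, {w[-1]}]"
            )
        if self.total_mu < 0:
            raise MalformedPlanError("total_mu must be non-negative")

    @property
    def weights(self) -> np.ndarray:
        return np.array([cp.cumulative_meterset_weight for cp in self.control_points])

    @property
    def gantry_angles(self) -> np.ndarray:
        return np.array([cp.gantry_angle for cp in self.control_points])

    def segment_mu(self) -> np.ndarray:
        """MU per segment; segment i spans control points i..i+1 (length n-1)."""
        return np.diff(self.weights) * self.total_mu


def mu_reduction_percent(mu_ref: float, mu_new: float) -> float:
    """Percent MU reduction of ``mu_new`` relative to ``mu_ref``, 1-decimal rounded."""
    if mu_ref <= 0:
        raise InputError(f"reference MU must be positive, got {mu_ref}")
    return round(100.0 * (mu_ref - mu_new) / mu_ref, 1)


def arc_control_point_count(arc_span_deg: float, spacing_deg: float) -> int:
    """Number of control points for an arc sampled every ``spacing_deg``, endpoints inclusive."""
    if spacing_deg <= 0 or arc_span_deg <= 0:
        raise InputError("arc span and spacing must be positive")
    ratio = arc_span_deg / spacing_deg
    if abs(ratio - round(ratio)) > 1e-9:
        raise InputError(
            f"spacing {spacing_deg} deg does not divide the arc span {arc_span_deg} deg"
        )
    return int(round(ratio)) + 1


# ---------------------------------------------------------------------------
# Plan-text dialect
# ---------------------------------------------------------------------------

_PLAN_MAGIC = "ARCPLAN-TEXT"
_PLAN_VERSION = 1


def _fmt(values: Sequence[float], fmt: str = "%.2f") -> str:
    return " ".join(fmt % v for v in values)


def write_plan_text(plan: ArcPlan, path) -> None:
    """Serialize a plan to the versioned text dialect (see module docstring)."""
    if len(plan.control_points) < 2:
        raise MalformedPlanError("refusing to write a plan with fewer than 2 control points")
    lines = [f"{_PLAN_MAGIC} {_PLAN_VERSION}"]
    lines.append("sad %.2f" % plan.machine.sad)
    lines.append("boundaries " + _fmt(plan.machine.leaf_pair_boundaries))
    lines.append("max_leaf_position %.2f" % plan.machine.max_leaf_position)
    lines.append("total_mu %.17g" % plan.total_mu)
    if plan.prescription is not None:
        rx = plan.prescription
        lines.append(
            "prescription %.17g %d %.17g" % (rx.dose_per_fraction, rx.n_fractions, rx.idl_percent)
        )
    lines.append(f"control_points {len(plan.control_points)}")
    for i, cp in enumerate(plan.control_points):
        lines.append("cp %d %.2f %.17g" % (i, cp.gantry_angle, cp.cumulative_meterset_weight))
        lines.append("a " + _fmt(cp.bank_a))
        lines.append("b " + _fmt(cp.bank_b))
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


def read_plan_text(path) -> ArcPlan:
    with open(path) as f:
        lines = [ln.rstrip("\n") for ln in f if ln.strip()]
    if not lines:
        raise FormatVersionError(f"{path}: empty file")
    magic = lines[0].split()
    if len(magic) != 2 or magic[0] != _PLAN_MAGIC:
        raise FormatVersionError(f"{path}: not an {_PLAN_MAGIC} file")
    if int(magic[1]) != _PLAN_VERSION:
        raise FormatVersionError(
            f"{path}: unsupported {_PLAN_MAGIC} version {magic[1]} (expected {_PLAN_VERSION})"
        )

    kv: dict[str, str] = {}
    i = 1
    while i < len(lines) and not lines[i].startswith("cp "):
        key, _, rest = lines[i].partition(" ")
        kv[key] = rest
        i += 1
    try:
        machine = MachineModel(
            sad=float(kv["sad"]),
            leaf_pair_boundaries=tuple(float(v) for v in kv["boundaries"].split()),
            max_leaf_position=float(kv["max_leaf_position"]),
        )
        total_mu = float(kv["total_mu"])
        n_cp = int(kv["control_points"])
    except KeyError as e:
        raise MalformedPlanError(f"{path}: missing header field {e}") from e
    prescription = None
    if "prescription" in kv:
        d, n, idl = kv["prescription"].split()
        prescription = PrescriptionSpec(float(d), int(n), float(idl))

    cps = []
    while i < len(lines):
        head = lines[i].split()
        if head[0] != "cp" or i + 2 >= len(lines):
            raise MalformedPlanError(f"{path}: malformed control point block at line {i + 1}")
        angle, weight = float(head[2]), float(head[3])
        bank_a = np.array([float(v) for v in lines[i + 1].split()[1:]])
        bank_b = np.array([float(v) for v in lines[i + 2].split()[1:]])
        cps.append(
            ControlPoint(
                gantry_angle=angle, bank_a=bank_a, bank_b=bank_b, cumulative_meterset_weight=weight
            )
        )
        i += 3
    if len(cps) != n_cp:
        raise MalformedPlanError(f"{path}: header promises {n_cp} control points, found {len(cps)}")
    return ArcPlan(machine=machine, control_points=cps, total_mu=total_mu, prescription=prescription)
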