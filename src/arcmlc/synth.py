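"""Synthetic phantom, arc plans with controlled intrusion, and analytic dose.

Everything here exists so that each metric in the toolkit has a closed-form
or oracle-checkable answer without any external data: a small spherical GTV
with directional ITV/PTV margins, conformal arc plans whose deviation from
the zero-margin reference is injected by construction, and a radial-falloff
dose field whose isodose volumes are analytically tractable.

The synthetic dose model is explicitly NOT a dose engine; its only contract
is analytic tractability.  All randomness is seeded through the spec objects;
there is no global random state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .bev import fit_conformal_aperture, project_to_bev
from .dosemetrics import DoseGrid, dvh_d_cc
from .errors import ConfigError, InputError
from .geometry import (
    GridSpec,
    MarginSpec,
    StructureVolume,
    make_sphere_structure,
    sphere_radius_mm,
)
from .plans import ArcPlan, ControlPoint, MachineModel, PrescriptionSpec


@dataclass(frozen=True)
class PhantomSpec:
    """Target geometry: GTV volume plus ITV/PTV margins on an isotropic-ish grid."""

    gtv_volume_cc: float = 0.51
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    itv_margin: MarginSpec = field(
        default_factory=lambda: MarginSpec(sup=10.0, inf=3.0, left=3.0, right=3.0, ant=3.0, post=3.0)
    )
    ptv_margin: MarginSpec = field(default_factory=lambda: MarginSpec.isotropic(5.0))
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    pad_mm: float = 25.0  # clearance beyond the PTV (>= 20 mm keeps D2cm evaluable)

    def __post_init__(self) -> None:
        if self.gtv_volume_cc <= 0:
            raise ConfigError("gtv_volume_cc must be positive")
        if self.pad_mm < 0:
            raise ConfigError("pad_mm must be non-negative")


def phantom_grid(spec: PhantomSpec) -> GridSpec:
    """Grid sized to hold GTV + both margin shells + padding, centred on the target."""
    r = sphere_radius_mm(spec.gtv_volume_cc)
    im, pm = spec.itv_margin, spec.ptv_margin
    neg = (
        r + im.right + pm.right + spec.pad_mm,
        r + im.ant + pm.ant + spec.pad_mm,
        r + im.inf + pm.inf + spec.pad_mm,
    )
    pos = (
        r + im.left + pm.left + spec.pad_mm,
        r + im.post + pm.post + spec.pad_mm,
        r + im.sup + pm.sup + spec.pad_mm,
    )
    shape = []
    origin = []
    for ax in range(3):
        s = spec.spacing_mm[ax]
        n_neg = int(math.ceil(neg[ax] / s)) + 1
        n_pos = int(math.ceil(pos[ax] / s)) + 1
        shape.append(n_neg + n_pos + 1)
        origin.append(spec.center[ax] - n_neg * s)
    return GridSpec(origin=tuple(origin), spacing=spec.spacing_mm, shape=tuple(shape))


def generate_phantom(spec: PhantomSpec | None = None) -> dict[str, StructureVolume]:
    """Build GTV, ITV, and PTV masks on one shared grid."""
    from .geometry import expand_margin

    if spec is None:
        spec = PhantomSpec()
    grid = phantom_grid(spec)
    gtv = make_sphere_structure(spec.center, spec.gtv_volume_cc, grid, name="GTV")
    itv = expand_margin(gtv, spec.itv_margin, name="ITV")
    ptv = expand_margin(itv, spec.ptv_margin, name="PTV")
    return {"GTV": gtv, "ITV": itv, "PTV": ptv}


# ---------------------------------------------------------------------------
# Synthetic arc plans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntrusionModel:
    """How actual leaves deviate inward from the fitted aperture.

    kinds:
      * ``none`` — leaves stay exactly on the fitted aperture;
      * ``fixed_depth`` — every open pair moves inward by ``depth_mm``
        (``bank='a'``, ``'b'`` or ``'both'``), clamped at the opposite tip;
      * ``sinusoidal`` — depth oscillates between 0 and ``depth_mm`` with
        ``period_cp`` control points per cycle;
      * ``speed_limited`` — leaves chase the fitted aperture but per-control-
        point travel is clamped to ``max_travel_mm_per_deg`` x gantry spacing.
    """

    kind: str = "none"
    depth_mm: float = 0.0
    bank: str = "both"
    period_cp: float = 20.0
    max_travel_mm_per_deg: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "fixed_depth", "sinusoidal", "speed_limited"):
            raise ConfigError(f"unknown intrusion kind {self.kind!r}")
        if self.depth_mm < 0 or self.period_cp <= 0 or self.max_travel_mm_per_deg < 0:
            raise ConfigError("intrusion parameters must be non-negative (period positive)")
        if self.bank not in ("a", "b", "both"):
            raise ConfigError(f"bank must be 'a', 'b' or 'both', got {self.bank!r}")


@dataclass(frozen=True)
class SynthPlanSpec:
    """Recipe for a synthetic conformal arc plan."""

    n_control_points: int = 121
    arc_span_deg: float = 360.0
    start_angle_deg: float = 0.0
    margin_mm: float = 0.0
    intrusion: IntrusionModel = field(default_factory=IntrusionModel)
    total_mu: float = 4000.0
    mu_profile: tuple | None = None  # per-segment MU fractions; None = constant
    projection_mode: str = "divergent"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control_points < 2:
            raise ConfigError("a plan needs at least 2 control points")
        if self.arc_span_deg <= 0 or self.margin_mm < 0 or self.total_mu < 0:
            raise ConfigError("arc span must be positive; margin and MU non-negative")
        if self.mu_profile is not None and len(self.mu_profile) != self.n_control_points - 1:
            raise ConfigError(
                f"mu_profile needs {self.n_control_points - 1} per-segment entries"
            )

    def angles(self) -> np.ndarray:
        step = self.arc_span_deg / (self.n_control_points - 1)
        return (self.start_angle_deg + np.arange(self.n_control_points) * step) % 360.0


# Quantization to the plan-text precision (0.01 mm / 0.01 deg).  Values are
# produced as n/100 with integer n — the exact float that parsing the "%.2f"
# serialization yields — so write/read round-trips are bit-identical.


def _quantize(x: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(x) * 100.0) / 100.0


def _quantize_outward(a: np.ndarray, b: np.ndarray):
    """Quantize an interval to the serialization grid without shrinking it.

    Bank A rounds down and bank B up, so quantization can only retract leaves
    (which the intrusion-only metric ignores), never introduce intrusion.
    """
    return np.floor(np.asarray(a) * 100.0) / 100.0, np.ceil(np.asarray(b) * 100.0) / 100.0


def generate_conformal_plan(
    target: StructureVolume,
    machine: MachineModel,
    spec: SynthPlanSpec,
    prescription: PrescriptionSpec | None = None,
    name: str = "synthetic",
) -> ArcPlan:
    """Fit the conformal aperture at every angle, then inject the intrusion model.

    Leaf positions and gantry angles are quantized to the plan-text precision
    (0.01 mm / 0.01 deg) so serialization round-trips are exact.
    """
    if not target.mask.any():
        raise InputError(f"target '{target.name}' is empty")
    angles = _quantize(spec.angles())
    step_deg = spec.arc_span_deg / (spec.n_control_points - 1)

    fitted = []
    for angle in angles:
        sil = project_to_bev(target, angle, machine, mode=spec.projection_mode)
        fitted.append(fit_conformal_aperture(sil, machine, margin_mm=spec.margin_mm))

    model = spec.intrusion
    cps: list[ControlPoint] = []
    prev_a = prev_b = None
    for i, (angle, ap) in enumerate(zip(angles, fitted)):
        a, b = ap.left.copy(), ap.right.copy()
        o = ap.open
        if model.kind == "fixed_depth":
            depth = model.depth_mm
        elif model.kind == "sinusoidal":
            depth = model.depth_mm * 0.5 * (1.0 - math.cos(2.0 * math.pi * i / model.period_cp))
        else:
            depth = 0.0
        if model.kind in ("fixed_depth", "sinusoidal") and depth > 0:
            if model.bank in ("a", "both"):
                a[o] = np.minimum(a[o] + depth, b[o])
            if model.bank in ("b", "both"):
                b[o] = np.maximum(b[o] - depth, a[o])
        if model.kind == "speed_limited" and prev_a is not None:
            travel = model.max_travel_mm_per_deg * step_deg
            a = prev_a + np.clip(a - prev_a, -travel, travel)
            b = prev_b + np.clip(b - prev_b, -travel, travel)
            b = np.maximum(a, b)
        prev_a, prev_b = a, b
        cps.append((angle, *_quantize_outward(a, b)))

    if all(np.all(a >= b) for _, a, b in cps):
        warnings.warn("intrusion model closed every leaf pair at every control point")

    if spec.mu_profile is None:
        weights = np.arange(spec.n_control_points) / (spec.n_control_points - 1)
    else:
        prof = np.asarray(spec.mu_profile, dtype=float)
        if np.any(prof < 0) or prof.sum() <= 0:
            raise ConfigError("mu_profile entries must be non-negative with a positive sum")
        weights = np.concatenate([[0.0], np.cumsum(prof) / prof.sum()])
        weights[-1] = 1.0

    control_points = [
        ControlPoint(gantry_angle=angle, bank_a=np.minimum(a, b), bank_b=b, cumulative_meterset_weight=w)
        for (angle, a, b), w in zip(cps, weights)
    ]
    return ArcPlan(
        machine=machine,
        control_points=control_points,
        total_mu=spec.total_mu,
        prescription=prescription,
        name=name,
    )


# ---------------------------------------------------------------------------
# Synthetic analytic dose
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthDoseSpec:
    """Plateau inside the PTV, radial falloff exp(-(d/scale)^exponent) outside."""

    plateau_gy: float = 90.0
    falloff_scale_mm: float = 10.0
    falloff_exponent: float = 1.5
    prescription: PrescriptionSpec = field(
        default_factory=lambda: PrescriptionSpec(dose_per_fraction=15.0, n_fractions=3, idl_percent=50.0)
    )
    coverage_fraction: float = 0.95
    noise_sd_gy: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plateau_gy <= 0:
            raise ConfigError("plateau dose must be positive")
        if self.falloff_scale_mm < 0 or self.falloff_exponent <= 0:
            raise ConfigError("falloff must be strictly decreasing (scale >= 0, exponent > 0)")
        if not (0 < self.coverage_fraction <= 1):
            raise ConfigError("coverage_fraction must be in (0, 1]")
        if self.noise_sd_gy < 0:
            raise ConfigError("noise_sd_gy must be non-negative")

    def falloff(self, distance_mm):
        """Dose multiplier at a distance outside the PTV surface."""
        d = np.asarray(distance_mm, dtype=float)
        if self.falloff_scale_mm == 0:
            return np.where(d > 0, 0.0, 1.0)
        return np.exp(-((d / self.falloff_scale_mm) ** self.falloff_exponent))

    def half_dose_distance_mm(self) -> float:
        """Distance at which the falloff reaches 1/2 (closed form)."""
        if self.falloff_scale_mm == 0:
            return 0.0
        return self.falloff_scale_mm * math.log(2.0) ** (1.0 / self.falloff_exponent)


def generate_synthetic_dose(
    ptv: StructureVolume, spec: SynthDoseSpec, grid: GridSpec | None = None
) -> DoseGrid:
    """Analytic dose: plateau on the PTV, radial falloff outside, coverage-scaled.

    After construction the field is scaled up, if needed, so that at least
    ``coverage_fraction`` of the PTV receives the full prescription.
    """
    if not ptv.mask.any():
        raise InputError(f"PTV '{ptv.name}' is empty")
    if grid is not None and grid != ptv.grid:
        raise InputError("synthetic dose must be generated on the PTV grid")
    grid = ptv.grid
    dist = ndimage.distance_transform_edt(~ptv.mask, sampling=grid.spacing)
    dose = spec.plateau_gy * spec.falloff(dist)
    dose[ptv.mask] = spec.plateau_gy
    if spec.noise_sd_gy > 0:
        rng = np.random.default_rng(spec.seed)
        dose = np.clip(dose + rng.normal(0.0, spec.noise_sd_gy, dose.shape), 0.0, None)

    dg = DoseGrid(grid=grid, dose=dose)
    rx = spec.prescription.total_dose_gy
    cover_cc = spec.coverage_fraction * ptv.volume_cc
    d_cover = dvh_d_cc(dg, ptv, cover_cc)
    if d_cover < rx:
        dg = DoseGrid(grid=grid, dose=dose * (rx / d_cover))
    return dg


# ---------------------------------------------------------------------------
# Delivery-style presets
# ---------------------------------------------------------------------------


def delivery_presets(seed: int = 0) -> dict[str, SynthPlanSpec]:
    """Five synthetic delivery styles for the end-to-end comparison workflow.

    These emulate qualitative behaviours (modulated leaves, tight static
    margins, speed-limited chasing, conformal margins, constant meterset),
    not any vendor's optimizer.
    """
    return {
        "modulated": SynthPlanSpec(
            intrusion=IntrusionModel(kind="sinusoidal", depth_mm=3.0, period_cp=15.0),
            total_mu=5200.0,
            seed=seed,
        ),
        "limited-mu": SynthPlanSpec(margin_mm=1.0, total_mu=4900.0, seed=seed),
        "speed-limited": SynthPlanSpec(
            intrusion=IntrusionModel(kind="speed_limited", max_travel_mm_per_deg=0.1),
            total_mu=5100.0,
            seed=seed,
        ),
        "conformal-arc": SynthPlanSpec(margin_mm=3.0, total_mu=5200.0, seed=seed),
        "conformal-arc-constant": SynthPlanSpec(
            margin_mm=3.0,
            total_mu=5300.0,
            mu_profile=tuple([1.0] * 120),
            seed=seed,
        ),
    }
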