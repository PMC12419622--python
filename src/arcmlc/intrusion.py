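"""Intrusion-only ratio-of-area-difference between a plan and its reference apertures.

For every control point the zero-margin reference aperture is fitted to the
target's BEV silhouette at that control point's actual gantry angle.  Only
leaf pairs whose reference is open participate; for each such pair the
intrusion is the part of the reference opening blocked by the actual leaves.
Leaves retracted beyond the reference contribute nothing (no credit, no
penalty).  The score is

    ratio = 100 * sum(intrusion areas) / sum(reference open areas)

so an exactly conformal plan scores 0 % and a fully blocked one 100 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bev import fit_conformal_aperture, project_to_bev
from .errors import InputError, MetricUndefinedError
from .geometry import StructureVolume
from .plans import ArcPlan, MachineModel


@dataclass
class AreaDifferenceResult:
    """Per-control-point and total intrusion/reference areas plus the ratio."""

    gantry_angles: np.ndarray
    per_cp_intrusion_mm2: np.ndarray
    per_cp_reference_mm2: np.ndarray
    mu_weighted: bool = False
    weights: np.ndarray = field(default=None)

    @property
    def total_intrusion_mm2(self) -> float:
        w = self.weights if self.mu_weighted else np.ones_like(self.per_cp_intrusion_mm2)
        return float(np.sum(w * self.per_cp_intrusion_mm2))

    @property
    def total_reference_mm2(self) -> float:
        w = self.weights if self.mu_weighted else np.ones_like(self.per_cp_reference_mm2)
        return float(np.sum(w * self.per_cp_reference_mm2))

    @property
    def ratio_percent(self) -> float:
        ref = self.total_reference_mm2
        if ref <= 0:
            raise MetricUndefinedError(
                "reference aperture area is zero everywhere (target never in view)"
            )
        return 100.0 * self.total_intrusion_mm2 / ref


def leaf_pair_intrusion(
    ref: tuple[float, float], actual: tuple[float, float] | None, band_height: float
) -> float:
    """Intrusion area (mm^2) of the actual leaf pair into one open reference pair.

    ``actual=None`` means the pair is fully closed (the whole reference
    opening is blocked).
    """
    r_left, r_right = ref
    if r_left > r_right:
        raise InputError(f"inverted reference interval ({r_left}, {r_right})")
    if band_height < 0:
        raise InputError(f"band height must be non-negative, got {band_height}")
    if actual is None:
        overlap = 0.0
    else:
        a_left, a_right = actual
        if a_left > a_right:
            raise InputError(f"inverted actual interval ({a_left}, {a_right})")
        overlap = max(0.0, min(r_right, a_right) - max(r_left, a_left))
    return ((r_right - r_left) - overlap) * band_height


def area_difference_ratio(
    plan: ArcPlan,
    target: StructureVolume,
    machine: MachineModel | None = None,
    projection_mode: str = "divergent",
    margin_mm: float = 0.0,
    mu_weighted: bool = False,
) -> AreaDifferenceResult:
    """Score a plan against per-angle zero-margin reference apertures.

    Control points are weighted equally unless ``mu_weighted`` is set, in
    which case each control point's areas are weighted by the MU of the
    segment it starts (the last control point starts no segment and gets
    weight 0).
    """
    if machine is None:
        machine = plan.machine
    if machine.n_pairs != plan.machine.n_pairs:
        raise InputError(
            f"machine has {machine.n_pairs} leaf pairs but plan control points carry "
            f"{plan.machine.n_pairs}"
        )
    heights = machine.band_heights
    n_cp = len(plan.control_points)
    intrusion = np.zeros(n_cp)
    reference = np.zeros(n_cp)
    for k, cp in enumerate(plan.control_points):
        sil = project_to_bev(target, cp.gantry_angle, machine, mode=projection_mode)
        ref = fit_conformal_aperture(sil, machine, margin_mm=margin_mm)
        if not ref.open.any():
            continue
        o = ref.open
        ref_width = ref.right[o] - ref.left[o]
        overlap = np.maximum(
            0.0,
            np.minimum(ref.right[o], cp.bank_b[o]) - np.maximum(ref.left[o], cp.bank_a[o]),
        )
        intrusion[k] = float(np.sum((ref_width - overlap) * heights[o]))
        reference[k] = float(np.sum(ref_width * heights[o]))

    weights = None
    if mu_weighted:
        weights = np.append(plan.segment_mu(), 0.0)
    result = AreaDifferenceResult(
        gantry_angles=plan.gantry_angles,
        per_cp_intrusion_mm2=intrusion,
        per_cp_reference_mm2=reference,
        mu_weighted=mu_weighted,
        weights=weights,
    )
    result.ratio_percent  # raises MetricUndefinedError if the target is never in view
    return result
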