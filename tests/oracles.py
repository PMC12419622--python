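"""Independent brute-force oracles used to cross-check the fast implementations.

These deliberately avoid the library code paths they validate: interval
arithmetic is checked against pixel rasterization, EDT-based distances against
all-pairs distances, and interpolated DVH points against a directly coded
sort-based definition.
"""

import numpy as np


def rasterized_intrusion(ref, actual, band_height, pitch=0.1, extent=250.0):
    """Pixel-count intrusion area of ``actual`` into open reference ``ref`` (mm^2)."""
    centers = np.arange(-extent, extent, pitch) + pitch / 2.0
    r_l, r_r = ref
    in_ref = (centers > r_l) & (centers < r_r)
    if actual is None:
        blocked = in_ref
    else:
        a_l, a_r = actual
        blocked = in_ref & ~((centers > a_l) & (centers < a_r))
    return blocked.sum() * pitch * band_height


def rasterized_plan_ratio(plan, ref_apertures, pitch=0.1):
    """Rasterized equivalent of the area-difference ratio (same reference apertures)."""
    heights = plan.machine.band_heights
    total_int = 0.0
    total_ref = 0.0
    for cp, ref in zip(plan.control_points, ref_apertures):
        for i in np.flatnonzero(ref.open):
            total_int += rasterized_intrusion(
                (ref.left[i], ref.right[i]), (cp.bank_a[i], cp.bank_b[i]), heights[i], pitch
            )
            total_ref += rasterized_intrusion(
                (ref.left[i], ref.right[i]), None, heights[i], pitch
            )
    return 100.0 * total_int / total_ref


def brute_force_far_max_dose(dose, ptv_mask, grid, distance_mm):
    """All-pairs voxel-centre distance version of the distant-maximum search."""
    spacing = np.asarray(grid.spacing)
    ptv_pts = np.argwhere(ptv_mask) * spacing
    out_idx = np.argwhere(~ptv_mask)
    out_pts = out_idx * spacing
    best = 0.0
    for idx, p in zip(out_idx, out_pts):
        d = np.sqrt(((ptv_pts - p) ** 2).sum(axis=1)).min()
        if d >= distance_mm:
            best = max(best, dose[tuple(idx)])
    return best


def dvh_d_cc_oracle(doses_gy, voxel_cc, x_cc):
    """Sort-based cumulative-DVH definition of D_xcc, coded independently."""
    d = sorted(doses_gy, reverse=True)
    cum = [voxel_cc * (i + 1) for i in range(len(d))]
    if x_cc <= cum[0]:
        return d[0]
    for i in range(1, len(d)):
        if cum[i] >= x_cc:
            f = (x_cc - cum[i - 1]) / (cum[i] - cum[i - 1])
            return d[i - 1] + f * (d[i] - d[i - 1])
    raise ValueError("x exceeds structure volume")


def dvh_v_gy_oracle(doses_gy, d_gy):
    return 100.0 * sum(1 for v in doses_gy if v >= d_gy) / len(doses_gy)
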