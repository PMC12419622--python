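"""Dose-distribution index panel: CN, CI, HI, R50%, D2cm, and DVH metrics.

All volume thresholds use the closed convention (``>=``): a voxel whose dose
equals the threshold counts as receiving it.  When dose and structure live on
different grids the dose is resampled to the structure grid by trilinear
interpolation (zero outside the dose grid) before any counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .errors import GridExtentError, InputError, MetricUndefinedError
from .geometry import GridSpec, StructureVolume
from .plans import PrescriptionSpec

#: Default minor-deviation thresholds for the gradient metrics (protocol
#: values interpolated for the phantom's PTV size; configurable).
DEFAULT_R50_THRESHOLD = 5.8
DEFAULT_D2CM_THRESHOLD = 58.0


@dataclass
class DoseGrid:
    """3D dose in Gy on a regular grid."""

    grid: GridSpec
    dose: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.grid.shape:
            raise InputError(
                f"dose shape {self.dose.shape} does not match grid shape {self.grid.shape}"
            )
        if np.any(self.dose < 0):
            raise InputError("dose values must be non-negative")

    @property
    def max_gy(self) -> float:
        return float(self.dose.max())


def resample_dose_to_grid(dose: DoseGrid, grid: GridSpec) -> DoseGrid:
    """Trilinearly resample a dose grid onto another grid (0 outside)."""
    if dose.grid == grid:
        return dose
    interp = RegularGridInterpolator(
        tuple(dose.grid.axis_coords(ax) for ax in range(3)),
        dose.dose,
        bounds_error=False,
        fill_value=0.0,
    )
    coords = np.stack(
        np.meshgrid(*(grid.axis_coords(ax) for ax in range(3)), indexing="ij"), axis=-1
    )
    return DoseGrid(grid=grid, dose=interp(coords.reshape(-1, 3)).reshape(grid.shape))


def _aligned(dose: DoseGrid, structure: StructureVolume) -> np.ndarray:
    return resample_dose_to_grid(dose, structure.grid).dose


@dataclass(frozen=True)
class ConformationNumber:
    value: float
    v_t_cc: float
    v_ref_cc: float
    v_t_ref_cc: float


def conformation_number(
    dose: DoseGrid,
    target: StructureVolume,
    ref_dose_gy: float,
    body: StructureVolume | None = None,
) -> ConformationNumber:
    """CN = (VT,ref / VT) * (VT,ref / Vref): coverage times selectivity.

    ``Vref`` is counted over the whole grid unless a body mask is given.
    """
    if ref_dose_gy <= 0:
        raise InputError(f"reference dose must be positive, got {ref_dose_gy}")
    if not target.mask.any():
        raise InputError(f"target '{target.name}' is empty")
    d = _aligned(dose, target)
    hot = d >= ref_dose_gy
    if body is not None:
        hot = hot & body.mask
    vv = target.grid.voxel_volume_mm3 / 1000.0
    v_t = float(target.mask.sum()) * vv
    v_ref = float(hot.sum()) * vv
    v_t_ref = float((hot & target.mask).sum()) * vv
    if v_ref == 0:
        raise MetricUndefinedError(
            f"no voxel receives the reference dose {ref_dose_gy} Gy; CN is undefined"
        )
    return ConformationNumber(
        value=(v_t_ref / v_t) * (v_t_ref / v_ref), v_t_cc=v_t, v_ref_cc=v_ref, v_t_ref_cc=v_t_ref
    )


def conformality_index(
    dose: DoseGrid,
    target: StructureVolume,
    ref_dose_gy: float,
    body: StructureVolume | None = None,
) -> float:
    """CI = prescription volume / target volume."""
    if ref_dose_gy <= 0:
        raise InputError(f"reference dose must be positive, got {ref_dose_gy}")
    if not target.mask.any():
        raise InputError(f"target '{target.name}' is empty")
    d = _aligned(dose, target)
    hot = d >= ref_dose_gy
    if body is not None:
        hot = hot & body.mask
    return float(hot.sum()) / float(target.mask.sum())


def homogeneity_index(
    dose_max_gy: float, prescription_gy: float, idl_percent: float = 100.0
) -> tuple[float, float]:
    """HI = Dmax / Rx; the normalized variant multiplies by IDL/100.

    The normalized value equals 1 exactly when Dmax sits at the maximum the
    IDL prescription implies.
    """
    if prescription_gy <= 0:
        raise InputError("prescription dose must be positive")
    if not (0 < idl_percent <= 100):
        raise InputError(f"idl_percent must be in (0, 100], got {idl_percent}")
    hi = dose_max_gy / prescription_gy
    return hi, hi * idl_percent / 100.0


def idl_to_max_percent(idl_percent: float) -> int:
    """Maximum-dose percentage implied by an IDL prescription: round(100^2 / IDL)."""
    if not (0 < idl_percent <= 100):
        raise InputError(f"idl_percent must be in (0, 100], got {idl_percent}")
    return int(round(100.0 * 100.0 / idl_percent))


def r50(dose: DoseGrid, ptv: StructureVolume, prescription_gy: float) -> float:
    """Ratio of the half-prescription isodose volume to the PTV volume."""
    if not ptv.mask.any():
        raise InputError(f"PTV '{ptv.name}' is empty")
    if prescription_gy <= 0:
        raise InputError("prescription dose must be positive")
    d = _aligned(dose, ptv)
    return float((d >= 0.5 * prescription_gy).sum()) / float(ptv.mask.sum())


def d2cm(
    dose: DoseGrid, ptv: StructureVolume, prescription_gy: float, distance_mm: float = 20.0
) -> float:
    """Maximum dose at >= ``distance_mm`` from the PTV surface, in % of prescription.

    Raises :class:`GridExtentError` if the grid does not extend at least that
    far beyond the PTV on every side (a clipped maximum is never reported).
    """
    if not ptv.mask.any():
        raise InputError(f"PTV '{ptv.name}' is empty")
    if prescription_gy <= 0:
        raise InputError("prescription dose must be positive")
    grid = ptv.grid
    idx = np.argwhere(ptv.mask)
    for ax in range(3):
        coords = grid.axis_coords(ax)
        lo_gap = coords[idx[:, ax].min()] - coords[0]
        hi_gap = coords[-1] - coords[idx[:, ax].max()]
        if lo_gap < distance_mm or hi_gap < distance_mm:
            raise GridExtentError(
                f"grid extends only {min(lo_gap, hi_gap):.1f} mm beyond the PTV on axis "
                f"{'xyz'[ax]}; need >= {distance_mm} mm to evaluate the distant maximum"
            )
    d = _aligned(dose, ptv)
    dist = ndimage.distance_transform_edt(~ptv.mask, sampling=grid.spacing)
    far = dist >= distance_mm
    return float(d[far].max()) * 100.0 / prescription_gy


def dvh_d_cc(dose: DoseGrid, structure: StructureVolume, x_cc: float) -> float:
    """D_xcc: largest dose d such that at least x cc of the structure receives >= d.

    Computed from descending-sorted voxel doses with linear partial-volume
    interpolation at the x-cc cut.
    """
    if not structure.mask.any():
        raise InputError(f"structure '{structure.name}' is empty")
    if x_cc <= 0:
        raise InputError(f"D_xcc requires positive x, got {x_cc}")
    d = _aligned(dose, structure)[structure.mask]
    vv = structure.grid.voxel_volume_mm3 / 1000.0
    total = d.size * vv
    if x_cc > total * (1 + 1e-12):
        raise InputError(
            f"D_{x_cc:g}cc exceeds the structure volume ({total:.3f} cc of '{structure.name}')"
        )
    sorted_desc = np.sort(d)[::-1]
    cum = vv * np.arange(1, d.size + 1)
    if x_cc <= cum[0]:
        return float(sorted_desc[0])
    return float(np.interp(x_cc, cum, sorted_desc))


def dvh_v_gy(dose: DoseGrid, structure: StructureVolume, d_gy: float) -> float:
    """V_d: percent of the structure volume receiving >= d Gy."""
    if not structure.mask.any():
        raise InputError(f"structure '{structure.name}' is empty")
    d = _aligned(dose, structure)[structure.mask]
    return 100.0 * float((d >= d_gy).sum()) / d.size


def parse_dvh_query(query: str) -> tuple[str, float]:
    """Parse 'D10cc' / 'D0.03cc' -> ('D', cc) and 'V11.4' -> ('V', Gy)."""
    q = query.strip()
    if q[:1].upper() == "D" and q.lower().endswith("cc"):
        return "D", float(q[1:-2])
    if q[:1].upper() == "V":
        return "V", float(q[1:])
    raise InputError(f"unrecognized DVH query {query!r} (expected Dxcc or Vd)")


def dvh_metrics(dose: DoseGrid, structure: StructureVolume, queries) -> dict:
    """Evaluate a list of DVH query strings; per-query errors are reported, not raised."""
    out: dict[str, dict] = {}
    for q in queries:
        try:
            kind, value = parse_dvh_query(q)
            if kind == "D":
                out[q] = {"value": dvh_d_cc(dose, structure, value), "units": "Gy"}
            else:
                out[q] = {"value": dvh_v_gy(dose, structure, value), "units": "%"}
        except InputError as e:
            out[q] = {"error": str(e)}
    return out


def gradient_flag(value: float, threshold: float) -> str:
    """'pass' when value <= threshold, else 'minor-deviation'."""
    return "pass" if value <= threshold else "minor-deviation"


@dataclass
class IndexReport:
    """The full index panel with every component needed to audit it."""

    cn: float
    cn_v_t_cc: float
    cn_v_ref_cc: float
    cn_v_t_ref_cc: float
    ci: float
    hi: float
    hi_normalized: float
    r50: float
    r50_flag: str
    d2cm_percent: float
    d2cm_flag: str
    prescription_gy: float
    idl_percent: float
    dose_max_gy: float
    oar_dvh: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cn": {
                "value": self.cn,
                "v_t_cc": self.cn_v_t_cc,
                "v_ref_cc": self.cn_v_ref_cc,
                "v_t_ref_cc": self.cn_v_t_ref_cc,
            },
            "ci": {
                "value": self.ci,
                "prescription_volume_cc": self.cn_v_ref_cc,
                "target_volume_cc": self.cn_v_t_cc,
            },
            "hi": {"value": self.hi, "normalized": self.hi_normalized},
            "r50": {"value": self.r50, "flag": self.r50_flag},
            "d2cm": {"value_percent": self.d2cm_percent, "flag": self.d2cm_flag},
            "prescription_gy": self.prescription_gy,
            "idl_percent": self.idl_percent,
            "dose_max_gy": self.dose_max_gy,
            "oar_dvh": self.oar_dvh,
        }


# ---------------------------------------------------------------------------
# Serialization: versioned gzip text dose format (mirrors the mask format)
# ---------------------------------------------------------------------------

_DOSE_MAGIC = "DOSETEXT"
_DOSE_VERSION = 1


def save_dose(d: DoseGrid, path) -> None:
    import gzip

    header = (
        f"{_DOSE_MAGIC} {_DOSE_VERSION}\n"
        "origin {:.6g} {:.6g} {:.6g}\n".format(*d.grid.origin)
        + "spacing {:.6g} {:.6g} {:.6g}\n".format(*d.grid.spacing)
        + "shape {} {} {}\n".format(*d.grid.shape)
    )
    nz = d.grid.shape[2]
    rows = d.dose.reshape(-1, nz)
    with open(path, "wb") as raw, gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as f:
        f.write(header.encode("ascii"))
        for row in rows:
            f.write((" ".join("%.9g" % v for v in row) + "\n").encode("ascii"))


def load_dose(path) -> DoseGrid:
    import gzip

    from .errors import FormatVersionError

    with gzip.open(path, "rt") as f:
        magic = f.readline().split()
        if len(magic) != 2 or magic[0] != _DOSE_MAGIC:
            raise FormatVersionError(f"{path}: not a {_DOSE_MAGIC} file")
        if int(magic[1]) != _DOSE_VERSION:
            raise FormatVersionError(
                f"{path}: unsupported {_DOSE_MAGIC} version {magic[1]} (expected {_DOSE_VERSION})"
            )
        origin = tuple(float(v) for v in f.readline().split()[1:4])
        spacing = tuple(float(v) for v in f.readline().split()[1:4])
        shape = tuple(int(v) for v in f.readline().split()[1:4])
        values = np.array(f.read().split(), dtype=float)
    grid = GridSpec(origin=origin, spacing=spacing, shape=shape)
    n = shape[0] * shape[1] * shape[2]
    if values.size != n:
        raise InputError(f"{path}: expected {n} dose values, found {values.size}")
    return DoseGrid(grid=grid, dose=values.reshape(shape))


def compute_index_report(
    dose: DoseGrid,
    target: StructureVolume,
    prescription: PrescriptionSpec,
    oars: dict[str, tuple[StructureVolume, list]] | None = None,
    body: StructureVolume | None = None,
    r50_threshold: float = DEFAULT_R50_THRESHOLD,
    d2cm_threshold: float = DEFAULT_D2CM_THRESHOLD,
) -> IndexReport:
    """Assemble the full panel for one dose distribution and target."""
    rx = prescription.total_dose_gy
    cn = conformation_number(dose, target, rx, body=body)
    ci = conformality_index(dose, target, rx, body=body)
    hi, hi_norm = homogeneity_index(dose.max_gy, rx, prescription.idl_percent)
    r50_val = r50(dose, target, rx)
    d2cm_val = d2cm(dose, target, rx)
    oar_dvh = {}
    for name, (structure, queries) in (oars or {}).items():
        oar_dvh[name] = dvh_metrics(dose, structure, queries)
    return IndexReport(
        cn=cn.value,
        cn_v_t_cc=cn.v_t_cc,
        cn_v_ref_cc=cn.v_ref_cc,
        cn_v_t_ref_cc=cn.v_t_ref_cc,
        ci=ci,
        hi=hi,
        hi_normalized=hi_norm,
        r50=r50_val,
        r50_flag=gradient_flag(r50_val, r50_threshold),
        d2cm_percent=d2cm_val,
        d2cm_flag=gradient_flag(d2cm_val, d2cm_threshold),
        prescription_gy=rx,
        idl_percent=prescription.idl_percent,
        dose_max_gy=dose.max_gy,
        oar_dvh=oar_dvh,
    )
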