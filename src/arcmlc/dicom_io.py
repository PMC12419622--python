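"""DICOM RT object mapping: RT-PLAN read/write, RT-DOSE and RT-STRUCT read.

Leaf position sign convention: DICOM ``MLCX`` LeafJawPositions carry the N
bank-"A" tips (negative BEV-x side) followed by the N bank-"B" tips, in mm at
the isocenter plane — mapped one-to-one onto ``ControlPoint.bank_a`` /
``bank_b``.  Control points may omit unchanged gantry angles or leaf
positions; values are carried forward from the previous control point.
Cumulative meterset weights are normalized so the final weight is 1.
"""

from __future__ import annotations

import hashlib

import numpy as np

from . import dicomlite as dcm
from .errors import InputError, MalformedPlanError, UnsupportedPlanError
from .geometry import GridSpec, StructureVolume, contours_to_mask
from .plans import ArcPlan, ControlPoint, MachineModel, PrescriptionSpec

RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"
RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"

_UID_ROOT = "1.2.826.0.1.3680043.10.1437"

# Tag shorthands
SOP_CLASS = (0x0008, 0x0016)
SOP_INSTANCE = (0x0008, 0x0018)
MODALITY = (0x0008, 0x0060)
BEAM_SEQ = (0x300A, 0x00B0)
BLD_SEQ = (0x300A, 0x00B6)
BLD_TYPE = (0x300A, 0x00B8)
N_PAIRS = (0x300A, 0x00BC)
BOUNDARIES = (0x300A, 0x00BE)
BEAM_NUMBER = (0x300A, 0x00C0)
BEAM_NAME = (0x300A, 0x00C2)
SAD = (0x300A, 0x00B4)
N_CP = (0x300A, 0x0110)
CP_SEQ = (0x300A, 0x0111)
CP_INDEX = (0x300A, 0x0112)
GANTRY = (0x300A, 0x011E)
CUM_WEIGHT = (0x300A, 0x0134)
FINAL_WEIGHT = (0x300A, 0x010E)
BLD_POS_SEQ = (0x300A, 0x011A)
LEAF_POS = (0x300A, 0x011C)
FRACTION_GROUP_SEQ = (0x300A, 0x0070)
N_FRACTIONS = (0x300A, 0x0078)
REF_BEAM_SEQ = (0x300C, 0x0004)
BEAM_METERSET = (0x300A, 0x0086)
REF_BEAM_NUMBER = (0x300C, 0x0006)


def _content_uid(payload: bytes) -> str:
    return _UID_ROOT + "." + str(int(hashlib.sha1(payload).hexdigest()[:12], 16))


# ---------------------------------------------------------------------------
# RT-PLAN
# ---------------------------------------------------------------------------


def read_rtplan(path, beam: int | str | None = None) -> ArcPlan:
    """Read one beam of an RT-PLAN as an :class:`ArcPlan`.

    ``beam`` selects by 0-based index (int) or by beam name (str); default is
    the first beam.
    """
    ds = dcm.read_file(path)
    sop = ds.string(SOP_CLASS, "")
    if sop != RTPLAN_SOP_CLASS and ds.string(MODALITY, "") != "RTPLAN":
        raise UnsupportedPlanError(f"{path}: not an RT-PLAN object (SOP class {sop!r})")
    beams = ds.sequence(BEAM_SEQ)
    if not beams:
        raise UnsupportedPlanError(f"{path}: RT-PLAN contains no beams")

    if beam is None:
        beam_ds = beams[0]
    elif isinstance(beam, int):
        if not (0 <= beam < len(beams)):
            raise InputError(f"{path}: beam index {beam} out of range (plan has {len(beams)})")
        beam_ds = beams[beam]
    else:
        named = [b for b in beams if b.string(BEAM_NAME, "") == beam]
        if not named:
            raise InputError(f"{path}: no beam named {beam!r}")
        beam_ds = named[0]

    mlc = None
    for bld in beam_ds.sequence(BLD_SEQ):
        if bld.string(BLD_TYPE, "") in ("MLCX", "MLCY"):
            mlc = bld
            break
    if mlc is None:
        raise UnsupportedPlanError(f"{path}: selected beam has no MLC device")
    boundaries = mlc.floats(BOUNDARIES)
    if boundaries is None:
        raise UnsupportedPlanError(f"{path}: MLC device lacks leaf position boundaries")
    n_pairs = len(boundaries) - 1

    machine = MachineModel(
        sad=beam_ds.float1(SAD, 1000.0),
        leaf_pair_boundaries=tuple(boundaries),
        max_leaf_position=max(abs(min(boundaries)), abs(max(boundaries)), 200.0),
    )

    total_mu = 1.0
    beam_number = beam_ds.int1(BEAM_NUMBER, None)
    for fg in ds.sequence(FRACTION_GROUP_SEQ):
        for rb in fg.sequence(REF_BEAM_SEQ):
            if beam_number is None or rb.int1(REF_BEAM_NUMBER, None) == beam_number:
                ms = rb.float1(BEAM_METERSET, None)
                if ms is not None:
                    total_mu = ms

    cps_raw = beam_ds.sequence(CP_SEQ)
    if len(cps_raw) < 2:
        raise MalformedPlanError(f"{path}: beam has fewer than 2 control points")

    final_weight = beam_ds.float1(FINAL_WEIGHT, None)
    gantry = None
    bank_a = bank_b = None
    weights = []
    cps = []
    for cp_ds in cps_raw:
        g = cp_ds.float1(GANTRY, None)
        if g is not None:
            gantry = g
        pos = None
        for bld in cp_ds.sequence(BLD_POS_SEQ):
            if bld.string(BLD_TYPE, "") in ("MLCX", "MLCY"):
                pos = bld.floats(LEAF_POS)
        if pos is not None:
            if len(pos) != 2 * n_pairs:
                raise MalformedPlanError(
                    f"{path}: control point has {len(pos)} leaf positions, expected {2 * n_pairs}"
                )
            bank_a = np.array(pos[:n_pairs])
            bank_b = np.array(pos[n_pairs:])
        if gantry is None or bank_a is None:
            raise MalformedPlanError(f"{path}: first control point lacks gantry angle or MLC positions")
        w = cp_ds.float1(CUM_WEIGHT, None)
        if w is None:
            raise MalformedPlanError(f"{path}: control point lacks cumulative meterset weight")
        weights.append(w)
        cps.append((gantry, bank_a.copy(), bank_b.copy()))

    weights = np.asarray(weights)
    if np.any(np.diff(weights) < -1e-9):
        raise MalformedPlanError(f"{path}: cumulative meterset weights are not monotone")
    final = final_weight if final_weight else weights[-1]
    if final <= 0:
        raise MalformedPlanError(f"{path}: final cumulative meterset weight is not positive")
    weights = weights / final

    control_points = [
        ControlPoint(gantry_angle=g, bank_a=a, bank_b=b, cumulative_meterset_weight=w)
        for (g, a, b), w in zip(cps, weights)
    ]
    return ArcPlan(
        machine=machine,
        control_points=control_points,
        total_mu=total_mu,
        prescription=None,
        name=beam_ds.string(BEAM_NAME, "beam"),
    )


def write_rtplan(plan: ArcPlan, path, n_fractions: int | None = None) -> None:
    """Write an :class:`ArcPlan` as a minimal conformant RT-PLAN file."""
    if len(plan.control_points) < 2:
        raise MalformedPlanError("refusing to write a plan with fewer than 2 control points")
    if n_fractions is None:
        n_fractions = plan.prescription.n_fractions if plan.prescription else 1

    mlc = dcm.Dataset()
    mlc.set(BLD_TYPE, "CS", "MLCX")
    mlc.set(N_PAIRS, "IS", plan.machine.n_pairs)
    mlc.set(BOUNDARIES, "DS", list(plan.machine.leaf_pair_boundaries))

    cp_items = []
    for i, cp in enumerate(plan.control_points):
        pos = dcm.Dataset()
        pos.set(BLD_TYPE, "CS", "MLCX")
        pos.set(LEAF_POS, "DS", list(cp.bank_a) + list(cp.bank_b))
        cp_ds = dcm.Dataset()
        cp_ds.set(CP_INDEX, "IS", i)
        cp_ds.set(GANTRY, "DS", cp.gantry_angle)
        cp_ds.set(CUM_WEIGHT, "DS", cp.cumulative_meterset_weight)
        cp_ds.set(BLD_POS_SEQ, "SQ", [pos])
        cp_items.append(cp_ds)

    beam = dcm.Dataset()
    beam.set(BEAM_NUMBER, "IS", 1)
    beam.set(BEAM_NAME, "LO", plan.name)
    beam.set(SAD, "DS", plan.machine.sad)
    beam.set(BLD_SEQ, "SQ", [mlc])
    beam.set(FINAL_WEIGHT, "DS", 1.0)
    beam.set(N_CP, "IS", len(cp_items))
    beam.set(CP_SEQ, "SQ", cp_items)

    ref_beam = dcm.Dataset()
    ref_beam.set(REF_BEAM_NUMBER, "IS", 1)
    ref_beam.set(BEAM_METERSET, "DS", plan.total_mu)
    fg = dcm.Dataset()
    fg.set(N_FRACTIONS, "IS", n_fractions)
    fg.set(REF_BEAM_SEQ, "SQ", [ref_beam])

    ds = dcm.Dataset()
    ds.set(MODALITY, "CS", "RTPLAN")
    ds.set(SOP_CLASS, "UI", RTPLAN_SOP_CLASS)
    ds.set((0x300A, 0x0002), "SH", plan.name[:16])
    ds.set(FRACTION_GROUP_SEQ, "SQ", [fg])
    ds.set(BEAM_SEQ, "SQ", [beam])
    payload = dcm.encode_dataset(ds)
    ds.set(SOP_INSTANCE, "UI", _content_uid(payload))
    dcm.write_file(ds, path, RTPLAN_SOP_CLASS, _content_uid(payload))


# ---------------------------------------------------------------------------
# RT-DOSE
# ---------------------------------------------------------------------------


def read_rtdose(path):
    """Read an RT-DOSE file into a :class:`~arcmlc.dosemetrics.DoseGrid` (Gy)."""
    from .dosemetrics import DoseGrid

    ds = dcm.read_file(path)
    if ds.string(SOP_CLASS, "") != RTDOSE_SOP_CLASS and ds.string(MODALITY, "") != "RTDOSE":
        raise InputError(f"{path}: not an RT-DOSE object")
    rows = ds.ushort((0x0028, 0x0010))
    cols = ds.ushort((0x0028, 0x0011))
    frames = ds.int1((0x0028, 0x0008), 1)
    bits = ds.ushort((0x0028, 0x0100), 32)
    scaling = ds.float1((0x3004, 0x000E), 1.0)
    ipp = ds.floats((0x0020, 0x0032), [0.0, 0.0, 0.0])
    pixel_spacing = ds.floats((0x0028, 0x0030), [1.0, 1.0])  # [row (y), col (x)]
    offsets = ds.floats((0x3004, 0x000C))
    if offsets is None or len(offsets) != frames:
        raise InputError(f"{path}: missing or inconsistent GridFrameOffsetVector")
    dz = np.diff(offsets)
    if frames > 1 and not np.allclose(dz, dz[0], atol=1e-6):
        raise InputError(f"{path}: non-uniform frame spacing is not supported")
    zs = float(dz[0]) if frames > 1 else 1.0

    dtype = np.uint32 if bits == 32 else np.uint16
    raw = np.frombuffer(ds.raw((0x7FE0, 0x0010)), dtype=dtype, count=frames * rows * cols)
    dose_zyx = raw.reshape(frames, rows, cols).astype(np.float64) * scaling
    dose = np.ascontiguousarray(dose_zyx.transpose(2, 1, 0))  # -> [x, y, z]

    grid = GridSpec(
        origin=(ipp[0], ipp[1], ipp[2] + offsets[0]),
        spacing=(pixel_spacing[1], pixel_spacing[0], abs(zs)),
        shape=(cols, rows, frames),
    )
    return DoseGrid(grid=grid, dose=dose)


def write_rtdose(dose_grid, path) -> None:
    """Write a DoseGrid as a 32-bit RT-DOSE file (testing/interchange helper)."""
    grid = dose_grid.grid
    dmax = float(dose_grid.dose.max())
    scaling = (dmax / (2**32 - 1)) if dmax > 0 else 1.0
    raw = np.round(dose_grid.dose / scaling).astype(np.uint32)
    pixels = np.ascontiguousarray(raw.transpose(2, 1, 0))  # [z, y, x]

    ds = dcm.Dataset()
    ds.set(MODALITY, "CS", "RTDOSE")
    ds.set(SOP_CLASS, "UI", RTDOSE_SOP_CLASS)
    ds.set((0x0028, 0x0002), "US", 1)
    ds.set((0x0028, 0x0008), "IS", grid.shape[2])
    ds.set((0x0028, 0x0010), "US", grid.shape[1])
    ds.set((0x0028, 0x0011), "US", grid.shape[0])
    ds.set((0x0028, 0x0030), "DS", [grid.spacing[1], grid.spacing[0]])
    ds.set((0x0028, 0x0100), "US", 32)
    ds.set((0x0028, 0x0101), "US", 32)
    ds.set((0x0028, 0x0102), "US", 31)
    ds.set((0x0028, 0x0103), "US", 0)
    ds.set((0x0020, 0x0032), "DS", list(grid.origin))
    ds.set((0x3004, 0x0002), "CS", "GY")
    ds.set((0x3004, 0x0004), "CS", "PHYSICAL")
    ds.set((0x3004, 0x000C), "DS", [i * grid.spacing[2] for i in range(grid.shape[2])])
    ds.set((0x3004, 0x000E), "DS", scaling)
    ds.set((0x7FE0, 0x0010), "OW", pixels.tobytes())
    payload = dcm.encode_dataset(ds)
    ds.set(SOP_INSTANCE, "UI", _content_uid(payload))
    dcm.write_file(ds, path, RTDOSE_SOP_CLASS, _content_uid(payload))


# ---------------------------------------------------------------------------
# RT-STRUCT
# ---------------------------------------------------------------------------

ROI_CONTOUR_SEQ = (0x3006, 0x0039)
CONTOUR_SEQ = (0x3006, 0x0040)
CONTOUR_DATA = (0x3006, 0x0050)
CONTOUR_TYPE = (0x3006, 0x0042)
REF_ROI_NUMBER = (0x3006, 0x0084)
SSROI_SEQ = (0x3006, 0x0020)
ROI_NUMBER = (0x3006, 0x0022)
ROI_NAME = (0x3006, 0x0026)


def read_rtstruct_masks(path, grid: GridSpec, names=None) -> dict[str, StructureVolume]:
    """Rasterize RT-STRUCT planar contours onto ``grid`` (even-odd fill)."""
    ds = dcm.read_file(path)
    if ds.string(SOP_CLASS, "") != RTSTRUCT_SOP_CLASS and ds.string(MODALITY, "") != "RTSTRUCT":
        raise InputError(f"{path}: not an RT-STRUCT object")
    roi_names = {
        item.int1(ROI_NUMBER): item.string(ROI_NAME, f"roi{item.int1(ROI_NUMBER)}")
        for item in ds.sequence(SSROI_SEQ)
    }
    out: dict[str, StructureVolume] = {}
    for roi in ds.sequence(ROI_CONTOUR_SEQ):
        name = roi_names.get(roi.int1(REF_ROI_NUMBER), f"roi{roi.int1(REF_ROI_NUMBER)}")
        if names is not None and name not in names:
            continue
        contours = []
        for c in roi.sequence(CONTOUR_SEQ):
            data = c.floats(CONTOUR_DATA, [])
            contours.append(np.asarray(data, dtype=float).reshape(-1, 3))
        out[name] = contours_to_mask(contours, grid, name=name)
    return out


def write_rtstruct(structures: dict[str, list], path) -> None:
    """Write named planar contour lists ((N,3) mm arrays) as a minimal RT-STRUCT."""
    ssrois, rois = [], []
    for i, (name, contours) in enumerate(structures.items(), start=1):
        ssroi = dcm.Dataset()
        ssroi.set(ROI_NUMBER, "IS", i)
        ssroi.set(ROI_NAME, "LO", name)
        ssrois.append(ssroi)
        c_items = []
        for contour in contours:
            c = dcm.Dataset()
            c.set(CONTOUR_TYPE, "CS", "CLOSED_PLANAR")
            c.set((0x3006, 0x0046), "IS", len(contour))
            c.set(CONTOUR_DATA, "DS", [float(v) for v in np.asarray(contour).ravel()])
            c_items.append(c)
        roi = dcm.Dataset()
        roi.set(REF_ROI_NUMBER, "IS", i)
        roi.set(CONTOUR_SEQ, "SQ", c_items)
        rois.append(roi)
    ds = dcm.Dataset()
    ds.set(MODALITY, "CS", "RTSTRUCT")
    ds.set(SOP_CLASS, "UI", RTSTRUCT_SOP_CLASS)
    ds.set(SSROI_SEQ, "SQ", ssrois)
    ds.set(ROI_CONTOUR_SEQ, "SQ", rois)
    payload = dcm.encode_dataset(ds)
    ds.set(SOP_INSTANCE, "UI", _content_uid(payload))
    dcm.write_file(ds, path, RTSTRUCT_SOP_CLASS, _content_uid(payload))
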