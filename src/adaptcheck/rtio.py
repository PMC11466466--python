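"""Readers and writers for the DICOM-RT family plus an internal fixture format.

The workflow consumes a planning CT series, RTSTRUCT, RTPLAN and RTDOSE, and
a fraction-day CBCT series.  Synthetic test cases instead use the internal
fixture format: one NIfTI volume per image plus a single ``case.json``
sidecar holding structures (as per-slice contour polygons), the plan, the
prescription and — for phantom cases — the ground-truth motion.

Structure rasterization uses the voxel-center rule: a voxel belongs to a
structure iff its center lies inside the contour polygon stack, with the
even-odd rule for nested rings (rings XOR together).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path as FSPath

import numpy as np
import nibabel as nib
from matplotlib.path import Path as MplPath

from .core import ImageGrid, ImageVolume, StructureSet

log = logging.getLogger("adaptcheck.io")

__all__ = [
    "PlanInfo",
    "DoseVolume",
    "read_image_series",
    "read_structures",
    "read_plan",
    "read_dose",
    "write_report",
    "write_fixture",
    "read_fixture",
    "rasterize_contours",
    "extract_contours",
]


@dataclass
class PlanInfo:
    """Treatment-plan facts the workflow needs.

    ``isocenter`` may be absent (``None``): the prealignment stage then falls
    back to geometric-center alignment.  ``prescription_dose`` is the
    full-course prescription in Gy.
    """

    isocenter: tuple | None = None
    prescription_dose: float = 45.0
    number_of_fractions: int = 25
    beams: list = field(default_factory=list)
    #: relative output scaling (the plan's effective monitor units): applied
    #: after the engine's isocenter normalization so a plan can be normalized
    #: to a clinical coverage goal such as "PTV D_97% = prescription"
    norm_factor: float = 1.0

    def __post_init__(self):
        if self.prescription_dose <= 0:
            raise ValueError("prescription dose must be positive")
        if self.beams:
            w = [float(b.get("weight", 1.0)) for b in self.beams]
            if any(x < 0 for x in w):
                raise ValueError("beam weights must be >= 0")
            if not any(x > 0 for x in w):
                raise ValueError("at least one beam weight must be > 0")

    def to_dict(self) -> dict:
        return {
            "isocenter": list(self.isocenter) if self.isocenter is not None else None,
            "prescription_dose": self.prescription_dose,
            "number_of_fractions": self.number_of_fractions,
            "beams": self.beams,
            "norm_factor": self.norm_factor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlanInfo":
        iso = d.get("isocenter")
        return cls(
            isocenter=tuple(iso) if iso is not None else None,
            prescription_dose=float(d.get("prescription_dose", 45.0)),
            number_of_fractions=int(d.get("number_of_fractions", 25)),
            beams=list(d.get("beams", [])),
            norm_factor=float(d.get("norm_factor", 1.0)),
        )


class DoseVolume(ImageVolume):
    """An ImageVolume in Gy carrying the plan's prescription reference."""

    def __init__(self, grid, values, prescription: float | None = None):
        super().__init__(grid, values, unit="Gy", role="dose")
        self.prescription = prescription

    def copy(self) -> "DoseVolume":
        return DoseVolume(self.grid, self.values.copy(), self.prescription)


# ---------------------------------------------------------------------------
# DICOM image series
# ---------------------------------------------------------------------------

def _read_dicom_series(path: FSPath) -> ImageVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FileNotFoundError(f"no .dcm files in {path}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    uids = {s.SeriesInstanceUID for s in slices}
    if len(uids) > 1:
        raise ValueError(f"mixed series in {path}: {len(uids)} SeriesInstanceUIDs")
    for tag in ("ImagePositionPatient", "ImageOrientationPatient", "PixelSpacing"):
        for s in slices:
            if tag not in s:
                raise ValueError(f"slice missing required geometry tag {tag}")

    iop = np.asarray(slices[0].ImageOrientationPatient, float)
    row, col = iop[:3], iop[3:]
    normal = np.cross(row, col)
    slices.sort(key=lambda s: float(np.dot(normal, np.asarray(s.ImagePositionPatient, float))))
    positions = np.array(
        [np.dot(normal, np.asarray(s.ImagePositionPatient, float)) for s in slices]
    )
    if len(slices) > 1:
        gaps = np.diff(positions)
        if gaps.min() <= 0:
            raise ValueError("duplicate or unsorted slice positions")
        if not np.allclose(gaps, gaps[0], atol=0.01):
            raise ValueError(
                f"non-uniform slice gap: min {gaps.min():.3f} mm, max {gaps.max():.3f} mm"
            )
        dz = float(gaps[0])
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))

    ps = np.asarray(slices[0].PixelSpacing, float)  # (row spacing, col spacing)
    arrs = []
    for s in slices:
        a = s.pixel_array.astype(float)
        slope = float(getattr(s, "RescaleSlope", 1.0))
        inter = float(getattr(s, "RescaleIntercept", 0.0))
        arrs.append(a * slope + inter)
    # pixel_array is (rows, cols) = (y, x); build (x, y, z)
    vol = np.stack(arrs, axis=-1).transpose(1, 0, 2)
    direction = np.column_stack([row, col, normal])
    grid = ImageGrid(
        size=vol.shape,
        spacing=(float(ps[1]), float(ps[0]), dz),
        origin=tuple(np.asarray(slices[0].ImagePositionPatient, float)),
        direction=tuple(map(tuple, direction)),
    )
    modality = getattr(slices[0], "Modality", "CT")
    role = "cbct" if str(modality).upper() in ("CBCT",) else "planning_ct"
    return ImageVolume(grid, vol, unit="HU", role=role)


def _grid_to_affine(grid: ImageGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = grid.direction_matrix * np.asarray(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_affine(aff: np.ndarray, shape) -> ImageGrid:
    M = aff[:3, :3]
    spacing = np.linalg.norm(M, axis=0)
    direction = M / spacing
    return ImageGrid(
        size=tuple(shape), spacing=tuple(spacing), origin=tuple(aff[:3, 3]),
        direction=tuple(map(tuple, direction)),
    )


def read_image_series(path, unit: str = "HU", role: str | None = None) -> ImageVolume:
    """Read one DICOM CT/CBCT series (directory) or one internal-format
    NIfTI volume (file) into an :class:`ImageVolume`.

    Internal volumes store LPS-mm affines directly (fixtures are written and
    read by this module only, so no RAS flip is applied).
    """
    path = FSPath(path)
    if path.is_dir():
        vol = _read_dicom_series(path)
    else:
        img = nib.load(str(path))
        grid = _grid_from_affine(img.affine, img.shape)
        vol = ImageVolume(grid, np.asarray(img.dataobj, dtype=np.float64), unit=unit,
                          role=role or "planning_ct")
        return vol
    if role is not None:
        vol.role = role
    return vol


def write_image(vol: ImageVolume, path) -> None:
    """Write a volume in the internal NIfTI-style fixture format (lossless
    float64)."""
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float64),
                          _grid_to_affine(vol.grid))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Contours
# ---------------------------------------------------------------------------

def rasterize_contours(contours, grid: ImageGrid) -> np.ndarray:
    """Rasterize a stack of closed planar contours to a binary mask.

    ``contours`` is a list of ``(z_mm, points)`` rings with ``points`` an
    (N, 2) array of in-plane (x, y) mm.  Rings on the same slice combine by
    XOR (even-odd rule: nested rings carve holes).  A ring is assigned to
    the nearest grid slice when within half a slice spacing; farther rings
    and degenerate (<3 point) rings are skipped with a warning.
    """
    if not np.allclose(grid.direction_matrix, np.eye(3)):
        raise ValueError("contour rasterization requires an axis-aligned grid")
    nx, ny, nz = grid.size
    ox, oy, oz = grid.origin
    sx, sy, sz = grid.spacing
    mask = np.zeros(grid.size, dtype=bool)
    xc = ox + sx * np.arange(nx)
    yc = oy + sy * np.arange(ny)
    XX, YY = np.meshgrid(xc, yc, indexing="ij")
    centers = np.column_stack([XX.ravel(), YY.ravel()])
    for z_mm, pts in contours:
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        if pts.shape[0] < 3:
            warnings.warn(f"skipping degenerate contour ({pts.shape[0]} points) at z={z_mm}")
            continue
        k = (float(z_mm) - oz) / sz
        ki = int(round(k))
        if not (0 <= ki < nz) or abs(k - ki) > 0.5 + 1e-9:
            warnings.warn(f"contour at z={z_mm} mm is farther than half a slice "
                          f"spacing from any grid slice; skipped")
            continue
        inside = MplPath(pts).contains_points(centers).reshape(nx, ny)
        mask[:, :, ki] ^= inside
    return mask


def extract_contours(mask: np.ndarray, grid: ImageGrid) -> list:
    """Per-slice boundary polygons of a binary mask (inverse of
    :func:`rasterize_contours` up to the voxel-center rule; the round trip
    rasterize -> extract -> rasterize is idempotent)."""
    from skimage import measure

    contours = []
    oz, sz = grid.origin[2], grid.spacing[2]
    for k in range(grid.size[2]):
        sl = mask[:, :, k]
        if not sl.any():
            continue
        padded = np.pad(sl.astype(float), 1)
        for ring in measure.find_contours(padded, 0.5):
            # ring coords are (x_index, y_index) in padded pixels
            xy = np.empty_like(ring)
            xy[:, 0] = grid.origin[0] + (ring[:, 0] - 1.0) * grid.spacing[0]
            xy[:, 1] = grid.origin[1] + (ring[:, 1] - 1.0) * grid.spacing[1]
            contours.append((oz + sz * k, xy))
    return contours


def _structures_from_json(d: dict, grid: ImageGrid) -> StructureSet:
    masks, roles = {}, {}
    for name, entry in d.items():
        contours = [(c["z"], np.asarray(c["points"], float)) for c in entry["contours"]]
        if not contours:
            m = np.zeros(grid.size, dtype=bool)
            log.warning("structure %s has an empty contour list; flagged empty", name)
        else:
            m = rasterize_contours(contours, grid)
            if not m.any():
                log.warning("structure %s rasterized to zero voxels", name)
        masks[name] = m
        roles[name] = entry.get("role", "rigid_organ")
    return StructureSet(grid, masks, roles)


def _read_dicom_structures(path: FSPath, grid: ImageGrid) -> StructureSet:
    import pydicom

    ds = pydicom.dcmread(str(path))
    names = {}
    for roi in ds.StructureSetROISequence:
        names[int(roi.ROINumber)] = str(roi.ROIName)
    masks, roles = {}, {}
    for rc in ds.ROIContourSequence:
        name = names.get(int(rc.ReferencedROINumber), f"roi_{rc.ReferencedROINumber}")
        contours = []
        for c in getattr(rc, "ContourSequence", []):
            data = np.asarray(c.ContourData, float).reshape(-1, 3)
            contours.append((float(np.mean(data[:, 2])), data[:, :2]))
        masks[name] = rasterize_contours(contours, grid) if contours else np.zeros(
            grid.size, dtype=bool
        )
        roles[name] = "rigid_organ"
    return StructureSet(grid, masks, roles)


def read_structures(path, grid: ImageGrid) -> StructureSet:
    """Read an RTSTRUCT file (or JSON sidecar) and rasterize every structure
    onto ``grid``."""
    path = FSPath(path)
    if path.suffix.lower() == ".json":
        with open(path) as f:
            d = json.load(f)
        return _structures_from_json(d.get("structures", d), grid)
    return _read_dicom_structures(path, grid)


# ---------------------------------------------------------------------------
# Plan / dose
# ---------------------------------------------------------------------------

def _read_dicom_plan(path: FSPath) -> PlanInfo:
    import pydicom

    ds = pydicom.dcmread(str(path))
    iso = None
    beams = []
    sads = {}
    for beam in getattr(ds, "BeamSequence", []):
        cp = beam.ControlPointSequence[0]
        if iso is None and "IsocenterPosition" in cp:
            iso = tuple(float(v) for v in cp.IsocenterPosition)
        aperture = None
        for bld in getattr(cp, "BeamLimitingDevicePositionSequence", []):
            t = str(bld.RTBeamLimitingDeviceType).upper()
            pos = [float(v) for v in bld.LeafJawPositions]
            if t in ("X", "ASYMX"):
                aperture = aperture or {"type": "rectangle"}
                aperture["x"] = pos[:2]
            elif t in ("Y", "ASYMY"):
                aperture = aperture or {"type": "rectangle"}
                aperture["y"] = pos[:2]
        beams.append(
            {
                "gantry_angle": float(getattr(cp, "GantryAngle", 0.0)),
                "source_axis_distance": float(getattr(beam, "SourceAxisDistance", 1000.0)),
                "aperture": aperture,
                "weight": float(getattr(beam, "FinalCumulativeMetersetWeight", 1.0)),
            }
        )
    n_fx = 25
    rx = 45.0
    for fg in getattr(ds, "FractionGroupSequence", []):
        n_fx = int(getattr(fg, "NumberOfFractionsPlanned", n_fx))
    for dr in getattr(ds, "DoseReferenceSequence", []):
        if "TargetPrescriptionDose" in dr:
            rx = float(dr.TargetPrescriptionDose)
    return PlanInfo(isocenter=iso, prescription_dose=rx, number_of_fractions=n_fx,
                    beams=beams)


def read_plan(path) -> PlanInfo:
    """Read RTPLAN (or JSON sidecar).  An absent isocenter is not an error:
    it selects the geometric-center prealignment branch downstream."""
    path = FSPath(path)
    if path.suffix.lower() == ".json":
        with open(path) as f:
            d = json.load(f)
        return PlanInfo.from_dict(d.get("plan", d))
    return _read_dicom_plan(path)


def read_dose(path, prescription: float | None = None) -> DoseVolume:
    """Read RTDOSE (DICOM file) or an internal fixture dose volume."""
    path = FSPath(path)
    if path.suffix.lower() in (".nii", ".gz") or str(path).endswith(".nii.gz"):
        vol = read_image_series(path, unit="Gy", role="dose")
        return DoseVolume(vol.grid, vol.values, prescription)
    import pydicom

    ds = pydicom.dcmread(str(path))
    scaling = float(ds.DoseGridScaling)
    arr = ds.pixel_array.astype(float) * scaling  # (frames, rows, cols)
    if arr.min() < 0:
        raise ValueError("negative scaled dose in RTDOSE")
    offsets = np.asarray(ds.GridFrameOffsetVector, float)
    dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    ps = np.asarray(ds.PixelSpacing, float)
    iop = np.asarray(ds.ImageOrientationPatient, float)
    direction = np.column_stack([iop[:3], iop[3:], np.cross(iop[:3], iop[3:])])
    grid = ImageGrid(
        size=(arr.shape[2], arr.shape[1], arr.shape[0]),
        spacing=(float(ps[1]), float(ps[0]), dz),
        origin=tuple(np.asarray(ds.ImagePositionPatient, float)),
        direction=tuple(map(tuple, direction)),
    )
    return DoseVolume(grid, arr.transpose(2, 1, 0), prescription)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(report, path_base) -> None:
    """Write a FractionReport as JSON (machine) and CSV (one row per metric).

    Refuses to write a report containing a NaN metric, naming the metric.
    """
    d = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    for s, metrics in d.get("metrics", {}).items():
        for m, vals in metrics.items():
            for k, v in vals.items():
                if v is not None and isinstance(v, float) and not np.isfinite(v):
                    raise ValueError(f"refusing to write report: metric {s}/{m} ({k}) is not finite")
    base = FSPath(path_base)
    base.parent.mkdir(parents=True, exist_ok=True)
    with open(base.with_suffix(".json"), "w") as f:
        json.dump(d, f, indent=2)
    import csv

    with open(base.with_suffix(".csv"), "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["structure", "metric", "original", "fraction", "delta", "flag"])
        flags = d.get("flags", {})
        for s, metrics in d.get("metrics", {}).items():
            for m, vals in metrics.items():
                w.writerow([
                    s, m, vals.get("original"), vals.get("fraction"),
                    vals.get("delta"), flags.get(f"{s}:{m}", ""),
                ])


# ---------------------------------------------------------------------------
# Fixture cases
# ---------------------------------------------------------------------------

def _structures_to_json(ss: StructureSet) -> dict:
    out = {}
    for name in ss.names():
        rings = extract_contours(ss.masks[name], ss.grid)
        out[name] = {
            "role": ss.roles[name],
            "contours": [{"z": float(z), "points": np.asarray(p).tolist()} for z, p in rings],
        }
    return out


def write_fixture(case, path) -> None:
    """Write a PhantomCase to ``path`` (directory) in the internal format."""
    path = FSPath(path)
    path.mkdir(parents=True, exist_ok=True)
    write_image(case.planning_ct, path / "planning_ct.nii.gz")
    write_image(case.cbct, path / "cbct.nii.gz")
    if case.reference_dose is not None:
        write_image(case.reference_dose, path / "reference_dose.nii.gz")
    truth = {
        "rigid": {
            "rotation": list(case.true_rigid.rotation),
            "translation": list(case.true_rigid.translation),
            "center": list(case.true_rigid.center),
        },
        "dvf": {
            "grid": {
                "size": list(case.true_dvf.control_grid.size),
                "spacing": list(case.true_dvf.control_grid.spacing),
                "origin": list(case.true_dvf.control_grid.origin),
            },
            "displacements": case.true_dvf.control_displacements.tolist(),
        },
    }
    sidecar = {
        "seed": case.seed,
        "plan": case.plan.to_dict(),
        "structures": _structures_to_json(case.structures),
        "fraction_structures": _structures_to_json(case.fraction_structures),
        "truth": truth,
    }
    with open(path / "case.json", "w") as f:
        json.dump(sidecar, f)


def read_fixture(path):
    """Read a fixture directory back into a PhantomCase."""
    from .core import DisplacementField, RigidTransform
    from .phantom import PhantomCase

    path = FSPath(path)
    with open(path / "case.json") as f:
        d = json.load(f)
    ct = read_image_series(path / "planning_ct.nii.gz", unit="HU", role="planning_ct")
    cbct = read_image_series(path / "cbct.nii.gz", unit="HU", role="cbct")
    dose_path = path / "reference_dose.nii.gz"
    plan = PlanInfo.from_dict(d["plan"])
    dose = (
        DoseVolume(*(lambda v: (v.grid, v.values))(read_image_series(dose_path, unit="Gy", role="dose")),
                   prescription=plan.prescription_dose)
        if dose_path.exists() else None
    )
    structures = _structures_from_json(d["structures"], ct.grid)
    fraction_structures = _structures_from_json(d["fraction_structures"], cbct.grid)
    tr = d["truth"]["rigid"]
    rigid = RigidTransform(tuple(tr["rotation"]), tuple(tr["translation"]), tuple(tr["center"]))
    tg = d["truth"]["dvf"]["grid"]
    cgrid = ImageGrid(tuple(tg["size"]), tuple(tg["spacing"]), tuple(tg["origin"]))
    dvf = DisplacementField(cgrid, np.asarray(d["truth"]["dvf"]["displacements"], float))
    return PhantomCase(
        planning_ct=ct, structures=structures, plan=plan, reference_dose=dose,
        cbct=cbct, fraction_structures=fraction_structures,
        true_rigid=rigid, true_dvf=dvf, seed=int(d["seed"]),
    )
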