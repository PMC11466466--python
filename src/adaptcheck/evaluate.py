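"""Plan-evaluation metrics and the adaptive-replanning decision.

Implements the quantities a physicist inspects when deciding whether a
fraction needs online adaptive replanning: Dice similarity of contours,
cumulative dose-volume histograms with the D_i / V_i / V_100% family, the
3D gamma index, the per-fraction dosimetric parameter panel, and the final
recommendation.

Clinical target constraints: CTV V_100% >= 99%, PTV V_100% >= 95%, and
CTV D_99% / PTV D_95% at least the prescription (45 Gy by default); a
fraction violating any of these is recommended for adaptation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import ImageGrid, StructureSet
from .rtio import DoseVolume, PlanInfo

log = logging.getLogger("adaptcheck.evaluate")

__all__ = [
    "DVHCurve",
    "GammaCriteria",
    "FractionReport",
    "ARTPolicy",
    "dsc",
    "cumulative_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "gamma_pass_rate",
    "evaluate_fraction",
    "art_recommendation",
]

_EPS = 1e-9


def dsc(a: np.ndarray, b: np.ndarray, grid_a: ImageGrid = None, grid_b: ImageGrid = None) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|).

    Two empty masks are defined as perfectly similar (1.0, logged)."""
    if grid_a is not None and grid_b is not None and grid_a != grid_b:
        raise ValueError("masks live on different grids")
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        log.warning("DSC of two empty masks; defined as 1.0")
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of the structure receiving >= each dose."""

    dose_bins: np.ndarray  # Gy, ascending
    cumulative_volume: np.ndarray  # fraction in [0, 1], non-increasing
    structure: str = ""
    prescription: float | None = None

    def __post_init__(self):
        self.dose_bins = np.asarray(self.dose_bins, float)
        self.cumulative_volume = np.asarray(self.cumulative_volume, float)
        if np.any(np.diff(self.dose_bins) <= 0):
            raise ValueError("dose bins must be strictly ascending")
        if np.any(np.diff(self.cumulative_volume) > 1e-12):
            raise ValueError("cumulative volume must be non-increasing")


def cumulative_dvh(
    dose: DoseVolume, mask: np.ndarray, bin_width: float = 0.01, structure: str = ""
) -> DVHCurve:
    """Cumulative DVH of ``dose`` within ``mask`` (default 0.01 Gy bins)."""
    mask = np.asarray(mask, bool)
    if tuple(mask.shape) != tuple(dose.grid.size):
        raise ValueError("dose and mask are not on one grid")
    vals = np.sort(np.asarray(dose.values, float)[mask])
    if vals.size == 0:
        raise ValueError(f"structure {structure or '<unnamed>'} has an empty mask")
    n_bins = int(np.ceil(vals[-1] / bin_width)) + 2
    edges = np.round(np.arange(n_bins) * bin_width, 9)
    # volume fraction with dose >= edge
    frac = 1.0 - np.searchsorted(vals, edges, side="left") / vals.size
    return DVHCurve(edges, frac, structure=structure, prescription=dose.prescription)


def dose_at_volume(dvh: DVHCurve, i: float) -> float:
    """D_i: the minimum dose received by the hottest i% of the volume —
    the largest dose whose cumulative volume is still >= i/100, linearly
    interpolated between bins."""
    if not 0 < i <= 100:
        raise ValueError("i must be in (0, 100]")
    if dvh.dose_bins.size == 0:
        raise ValueError("empty DVH curve")
    t = i / 100.0
    V = dvh.cumulative_volume
    d = dvh.dose_bins
    above = np.flatnonzero(V >= t - 1e-12)
    if above.size == 0:
        return 0.0
    k = above[-1]
    if k + 1 >= len(d) or V[k] <= t + 1e-12:
        return float(d[k])
    # interpolate across the bin where the curve crosses t
    drop = V[k] - V[k + 1]
    if drop <= 0:
        return float(d[k])
    return float(d[k] + (d[k + 1] - d[k]) * (V[k] - t) / drop)


def volume_at_dose(
    dvh: DVHCurve, d: float, as_percent_of_prescription: bool = False
) -> float:
    """V_d: percent of the structure receiving at least ``d``.

    With the flag, ``d`` is a percentage of the prescription (V_100% is
    ``volume_at_dose(dvh, 100, True)``); requires a prescription on the
    curve."""
    if as_percent_of_prescription:
        if dvh.prescription is None:
            raise ValueError("V_i% of prescription requested but no prescription attached")
        d = d / 100.0 * dvh.prescription
    if d < 0:
        raise ValueError("dose must be >= 0")
    if d <= dvh.dose_bins[0]:
        return 100.0 * float(dvh.cumulative_volume[0])
    if d >= dvh.dose_bins[-1]:
        return 100.0 * float(dvh.cumulative_volume[-1])
    return 100.0 * float(np.interp(d, dvh.dose_bins, dvh.cumulative_volume))


# ---------------------------------------------------------------------------
# gamma
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaCriteria:
    """Global 3D gamma criteria: dose tolerance (% of the reference maximum),
    distance to agreement (mm), low-dose threshold (% of the maximum)."""

    dose_tolerance: float = 2.0
    dta: float = 2.0
    low_dose_threshold: float = 10.0
    search_radius_factor: float = 3.0
    step_divisor: int = 10

    def __post_init__(self):
        if min(self.dose_tolerance, self.dta, self.low_dose_threshold) <= 0:
            raise ValueError("gamma criteria must all be positive")


def _gamma_offsets(criteria: GammaCriteria, radius: float) -> np.ndarray:
    """Search offsets (mm) within ``radius``, on a dta/step_divisor lattice,
    sorted by distance from the origin."""
    step = criteria.dta / criteria.step_divisor
    k = int(np.floor(radius / step))
    ax = step * np.arange(-k, k + 1)
    O = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    r = np.linalg.norm(O, axis=1)
    keep = r <= radius + 1e-9
    O, r = O[keep], r[keep]
    order = np.argsort(r, kind="stable")
    return O[order], r[order]


def gamma_pass_rate(
    reference: DoseVolume, evaluated: DoseVolume, criteria: GammaCriteria
) -> float:
    """Global 3D gamma pass rate (%).

    For every reference voxel at or above the low-dose threshold (applied to
    the reference, normalization = max of the reference dose), the evaluated
    dose is trilinearly interpolated on a dta/10 lattice of offsets; the
    voxel passes if some offset gives
    ``(dD / tol)^2 + (r / dta)^2 <= 1``.  Offsets are scanned in order of
    increasing distance and a voxel stops searching once it passes; offsets
    beyond one DTA cannot rescue a voxel (their distance term alone exceeds
    1), so the scan over [0, dta] is exhaustive for pass/fail purposes.
    """
    norm = float(np.max(reference.values))
    if norm <= 0:
        raise ValueError("reference dose is identically zero")
    thresh = criteria.low_dose_threshold / 100.0 * norm
    tol = criteria.dose_tolerance / 100.0 * norm
    eval_mask = np.asarray(reference.values) >= thresh
    if not eval_mask.any():
        raise ValueError("no reference voxels above the low-dose threshold")

    ref_pts = reference.grid.voxel_centers()[eval_mask]
    ref_dose = np.asarray(reference.values, float)[eval_mask]
    ev = np.asarray(evaluated.values, float)
    offsets, radii = _gamma_offsets(criteria, criteria.dta)

    passed = np.zeros(len(ref_pts), dtype=bool)
    for off, r in zip(offsets, radii):
        active = np.flatnonzero(~passed)
        if active.size == 0:
            break
        pts = ref_pts[active] + off
        coords = evaluated.grid.physical_to_voxel(pts).T
        dv = ndimage.map_coordinates(
            ev, coords, order=1, mode="constant", cval=np.nan, prefilter=False
        )
        g2 = ((dv - ref_dose[active]) / tol) ** 2 + (r / criteria.dta) ** 2
        ok = g2 <= 1.0  # NaN (outside evaluated grid) compares False
        passed[active[ok]] = True
    return 100.0 * float(passed.mean())


# ---------------------------------------------------------------------------
# fraction report / decision
# ---------------------------------------------------------------------------

#: the dosimetric parameter panel: structure aliases and metric definitions
_PANEL = [
    ("CTV", ("ctv",), [("V_100%", "v_rx", None), ("D_99%", "d", 99.0)], True),
    ("PTV", ("ptv",), [("V_100%", "v_rx", None), ("D_95%", "d", 95.0)], True),
    ("Bladder", ("bladder",), [("V_40Gy", "v", 40.0)], False),
    ("Rectum", ("rectum",), [("V_40Gy", "v", 40.0)], False),
    ("Bowel", ("small_intestine", "bowel", "small bowel"), [("V_40Gy", "v", 40.0)], False),
    ("Bone marrow", ("bone_marrow", "bone marrow"), [("V_10Gy", "v", 10.0)], False),
    ("Femur head left", ("femoral_head_l", "femur_head_l"), [("V_30Gy", "v", 30.0)], False),
    ("Femur head right", ("femoral_head_r", "femur_head_r"), [("V_30Gy", "v", 30.0)], False),
]


@dataclass
class FractionReport:
    """The per-fraction dosimetric panel, pass/fail flags, recommendation."""

    metrics: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)
    recommendation: str = "no_adaptation"
    prescription: float = 45.0

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics,
            "flags": self.flags,
            "recommendation": self.recommendation,
            "prescription": self.prescription,
        }

    def target_failures(self) -> list:
        return [k for k, v in self.flags.items() if v == "fail"]


@dataclass(frozen=True)
class ARTPolicy:
    """Decision policy.  Target rules are the clinical constraints; the OAR
    review margin (percentage points of V) is a configurable safety net."""

    ctv_v100_min: float = 99.0
    ptv_v100_min: float = 95.0
    oar_delta: float = 5.0


def _find_structure(structs: StructureSet, aliases) -> str | None:
    for a in aliases:
        for name in structs.names():
            if name.lower() == a.lower():
                return name
    return None


def _metric_value(dose: DoseVolume, mask, kind: str, arg, rx: float) -> float:
    curve = cumulative_dvh(dose, mask)
    curve.prescription = rx
    if kind == "v_rx":
        return volume_at_dose(curve, 100.0, as_percent_of_prescription=True)
    if kind == "v":
        return volume_at_dose(curve, arg)
    if kind == "d":
        return dose_at_volume(curve, arg)
    raise ValueError(kind)


def evaluate_fraction(
    dose_fraction: DoseVolume,
    structures_fraction: StructureSet,
    dose_original: DoseVolume,
    structures_original: StructureSet,
    plan: PlanInfo,
    policy: ARTPolicy | None = None,
) -> FractionReport:
    """Compute the dosimetric parameter panel for the original plan and the
    fraction recomputation, with deltas, clinical flags and recommendation.

    Targets (CTV/PTV) must exist on both sides; a missing OAR marks its
    metrics absent without failing the evaluation.  Flags (on the fraction
    values): CTV V_100% < 99% fails, PTV V_100% < 95% fails, CTV D_99% or
    PTV D_95% below the prescription fails.  Boundary values pass.
    """
    pol = policy or ARTPolicy()
    rx = plan.prescription_dose
    report = FractionReport(prescription=rx)

    for panel_name, aliases, metric_defs, is_target in _PANEL:
        n_orig = _find_structure(structures_original, aliases)
        n_frac = _find_structure(structures_fraction, aliases)
        if n_orig is None or n_frac is None:
            if is_target:
                raise ValueError(f"missing target structure {panel_name}")
            report.metrics[panel_name] = {
                m[0]: {"original": None, "fraction": None, "delta": None,
                       "absent": True}
                for m in metric_defs
            }
            continue
        entry = {}
        for metric_name, kind, arg in metric_defs:
            orig = _metric_value(
                dose_original, structures_original.get(n_orig), kind, arg, rx
            )
            frac = _metric_value(
                dose_fraction, structures_fraction.get(n_frac), kind, arg, rx
            )
            entry[metric_name] = {
                "original": orig, "fraction": frac, "delta": frac - orig,
            }
        report.metrics[panel_name] = entry

    def _flag(structure, metric, value, minimum):
        report.flags[f"{structure}:{metric}"] = (
            "pass" if value >= minimum - _EPS else "fail"
        )

    _flag("CTV", "V_100%", report.metrics["CTV"]["V_100%"]["fraction"], pol.ctv_v100_min)
    _flag("PTV", "V_100%", report.metrics["PTV"]["V_100%"]["fraction"], pol.ptv_v100_min)
    _flag("CTV", "D_99%", report.metrics["CTV"]["D_99%"]["fraction"], rx)
    _flag("PTV", "D_95%", report.metrics["PTV"]["D_95%"]["fraction"], rx)

    report.recommendation = art_recommendation(report, pol)
    return report


def art_recommendation(report: FractionReport, policy: ARTPolicy | None = None) -> str:
    """Deterministic decision: ``adapt`` if any target constraint fails;
    ``review`` if any OAR volume metric rose by more than the policy margin
    over the original plan; else ``no_adaptation``."""
    pol = policy or ARTPolicy()
    if report.target_failures():
        return "adapt"
    for structure, metrics in report.metrics.items():
        if structure in ("CTV", "PTV"):
            continue
        for name, vals in metrics.items():
            delta = vals.get("delta")
            if name.startswith("V_") and delta is not None and delta > pol.oar_delta:
                return "review"
    return "no_adaptation"
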