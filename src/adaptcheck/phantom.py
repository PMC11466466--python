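"""Pelvis-like digital phantom generator with known ground truth.

Each generated case bundles what one treatment fraction of a cervical-cancer
patient provides to the adaptive-check workflow: a planning CT with nine
organ structures plus CTV/PTV, a four-field box plan prescribed 45 Gy in 25
fractions, the reference dose computed on the planning CT, and a fraction
CBCT derived from the CT by a *known* rigid setup offset plus a *known*
smooth deformation (bladder volume change + random anatomy drift), degraded
with a reduced cylindrical field of view, HU bias/cupping and noise.

Because the motion is known, registration and contour-propagation accuracy
can be scored against exact ground truth, standing in for the clinical
datasets the method was originally evaluated on.

The generator is deterministic: one RNG stream per case, keyed by the seed,
with sub-stages drawing in a fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import (
    CompositeTransform,
    DisplacementField,
    ImageGrid,
    ImageVolume,
    RigidTransform,
    StructureSet,
    resample,
)
from .rtio import DoseVolume, PlanInfo

__all__ = ["PhantomParams", "PhantomCase", "generate_case", "sample_deformation",
           "degrade_to_cbct"]

# HU values painted into the phantom (tissue-appropriate round numbers)
_HU = {
    "air": -1000.0, "fat": -90.0, "soft": 40.0, "bone": 700.0, "marrow": 200.0,
    "cord": 35.0, "rectum": -60.0, "intestine": 20.0, "bladder": 15.0, "ctv": 75.0,
}


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters.  Defaults define the reference test conditions."""

    size: tuple = (96, 96, 96)
    spacing: tuple = (2.5, 2.5, 2.5)
    cbct_size: tuple = (56, 56, 64)
    # anatomy (mm)
    body_semiaxes: tuple = (100.0, 85.0)
    ptv_margin_mm: float = 7.0
    organ_jitter: float = 0.05  #: fractional size/position jitter per case
    # motion / anatomy-of-the-day
    deformation_mm: float = 8.0  #: max dense displacement of the random field
    bladder_scale: float = 1.3  #: fraction-day bladder volume factor
    ctv_shift_mm: float = 0.0  #: bulk posterior shift of the target region
    rigid_mm: float = 5.0  #: per-axis translation range (uniform +-)
    rigid_deg: float = 2.0  #: per-axis rotation range (uniform +-)
    control_spacing_mm: float = 20.0
    # CBCT degradation
    fov_radius_frac: float = 0.7  #: cylinder radius / smaller body semi-axis
    fov_length_frac: float = 0.7  #: cylinder length / CT axial extent
    cupping_hu: float = 80.0  #: center-to-edge HU offset
    hu_shift: float = 30.0
    noise_hu: float = 20.0
    # plan / dose
    prescription_gy: float = 45.0
    number_of_fractions: int = 25
    with_dose: bool = True
    overlap_tolerance: float = 0.02


@dataclass
class PhantomCase:
    planning_ct: ImageVolume
    structures: StructureSet
    plan: PlanInfo
    reference_dose: DoseVolume | None
    cbct: ImageVolume
    fraction_structures: StructureSet
    true_rigid: RigidTransform
    true_dvf: DisplacementField
    seed: int
    params: PhantomParams = field(default_factory=PhantomParams)


# ---------------------------------------------------------------------------
# anatomy primitives
# ---------------------------------------------------------------------------

def _coords(grid: ImageGrid):
    xs = [grid.origin[i] + grid.spacing[i] * np.arange(grid.size[i]) for i in range(3)]
    return np.meshgrid(*xs, indexing="ij")


def _ellipsoid(X, Y, Z, center, semi):
    return ((X - center[0]) / semi[0]) ** 2 + ((Y - center[1]) / semi[1]) ** 2 + (
        (Z - center[2]) / semi[2]
    ) ** 2 <= 1.0


def _tube_z(X, Y, Z, center_xy, radius, z_range):
    return (
        ((X - center_xy[0]) ** 2 + (Y - center_xy[1]) ** 2 <= radius**2)
        & (Z >= z_range[0])
        & (Z <= z_range[1])
    )


def _dilate_mm(mask, grid, mm):
    if mm <= 0:
        return mask.copy()
    d = ndimage.distance_transform_edt(~mask, sampling=grid.spacing)
    return d <= mm


def _erode_mm(mask, grid, mm):
    if mm <= 0:
        return mask.copy()
    d = ndimage.distance_transform_edt(mask, sampling=grid.spacing)
    return d > mm


def _build_anatomy(grid: ImageGrid, p: PhantomParams, rng: np.random.Generator):
    """Paint organ masks and the HU volume.  Jitter draws happen in a fixed
    order so the case is reproducible."""
    X, Y, Z = _coords(grid)
    j = lambda: 1.0 + p.organ_jitter * rng.uniform(-1, 1)  # noqa: E731
    shift = lambda s: s * rng.uniform(-1, 1)  # noqa: E731

    ax, ay = p.body_semiaxes
    body = ((X / ax) ** 2 + (Y / ay) ** 2) <= 1.0

    ring_c = (shift(3.0), 8.0 + shift(3.0))
    outer = ((X - ring_c[0]) / (82.0 * j())) ** 2 + ((Y - ring_c[1]) / (68.0 * j())) ** 2 <= 1.0
    inner = ((X - ring_c[0]) / 62.0) ** 2 + ((Y - ring_c[1]) / 48.0) ** 2 <= 1.0
    ring = outer & ~inner & (np.abs(Z) <= 50.0)
    # open the anterior arch (no pubic wall in front of the bladder)
    ang = np.arctan2(Y - ring_c[1], X - ring_c[0])
    ring &= ~(np.abs(ang + np.pi / 2) < np.deg2rad(50.0))

    fem_r = 20.0 * j()
    fem_l = _ellipsoid(X, Y, Z, (72.0 + shift(3.0), 5.0, -25.0 + shift(4.0)),
                       (fem_r, fem_r, fem_r * 1.15))
    fem_rt = _ellipsoid(X, Y, Z, (-72.0 + shift(3.0), 5.0, -25.0 + shift(4.0)),
                        (fem_r, fem_r, fem_r * 1.15))
    # spinal canal runs through the sacral part of the ring
    cord_xy = (shift(2.0), 60.0 + shift(2.0))
    cord = _tube_z(X, Y, Z, cord_xy, 6.0, (-20.0, 118.0)) & body
    canal = _tube_z(X, Y, Z, cord_xy, 9.0, (-25.0, 120.0))
    bone = (ring | fem_l | fem_rt) & body & ~canal
    rectum = _tube_z(X, Y, Z, (shift(3.0), 38.0 + shift(2.0)), 13.0 * j(), (-55.0, 35.0))
    rectum &= ~bone
    bladder_c = (shift(3.0), -22.0 + shift(3.0), -8.0 + shift(4.0))
    bladder_s = (26.0 * j(), 20.0 * j(), 22.0 * j())
    bladder = _ellipsoid(X, Y, Z, bladder_c, bladder_s) & ~bone
    intestine = _ellipsoid(X, Y, Z, (shift(4.0), -5.0, 62.0 + shift(4.0)),
                           (50.0 * j(), 40.0 * j(), 35.0 * j()))
    intestine &= body & ~bone & ~bladder & ~rectum & ~cord

    ctv = _ellipsoid(X, Y, Z, (shift(2.0), 6.0 + shift(2.0), shift(3.0)),
                     (26.0 * j(), 20.0 * j(), 28.0 * j()))
    ctv &= ~bladder & ~rectum & ~bone
    marrow = _erode_mm(bone, grid, 5.0)

    organs = {
        "skin": body, "femoral_head_l": fem_l & body, "femoral_head_r": fem_rt & body,
        "pelvis": ring & body, "spinal_cord": cord, "rectum": rectum,
        "small_intestine": intestine, "bladder": bladder, "bone_marrow": marrow,
    }
    # organs must fit inside the body outline
    soft = ["bladder", "rectum", "small_intestine", "spinal_cord"]
    for name in soft:
        m = organs[name]
        if not m.any() or (m & body).sum() / m.sum() < 0.98:
            raise ValueError(
                f"organ {name} does not fit inside the body outline; "
                "use smaller organ sizes or a larger body"
            )
    # pairwise-overlap sanity among soft organs that must be disjoint
    for i, a in enumerate(soft):
        for b in soft[i + 1:]:
            inter = np.count_nonzero(organs[a] & organs[b])
            small = max(1, min(np.count_nonzero(organs[a]), np.count_nonzero(organs[b])))
            if inter / small > 0.02:
                raise ValueError(
                    f"organs {a} and {b} overlap by {100 * inter / small:.1f}% of the "
                    "smaller organ; use smaller organ sizes"
                )
    if not ctv.any():
        raise ValueError("CTV is empty; use smaller organ sizes or less jitter")

    hu = np.full(grid.size, _HU["air"])
    hu[body] = _HU["soft"]
    fat_shell = body & ~_erode_mm(body, grid, 12.0)
    hu[fat_shell] = _HU["fat"]
    hu[bone] = _HU["bone"]
    hu[marrow] = _HU["marrow"]
    hu[cord] = _HU["cord"]
    hu[intestine] = _HU["intestine"]
    hu[rectum] = _HU["rectum"]
    hu[bladder] = _HU["bladder"]
    hu[ctv] = _HU["ctv"]
    hu = ndimage.gaussian_filter(hu, 0.8)

    return hu, organs, ctv, (bladder_c, bladder_s)


# ---------------------------------------------------------------------------
# deformation
# ---------------------------------------------------------------------------

def sample_deformation(
    params: PhantomParams,
    seed_or_rng,
    grid: ImageGrid,
    bladder_center=(0.0, -22.0, -8.0),
    bladder_radius: float = 22.0,
    target_center=(0.0, 6.0, 0.0),
) -> DisplacementField:
    """Draw the fraction-day deformation: a smooth random field plus a radial
    bladder volume-change component, guaranteed fold-free.

    The field is a pull mapping from fraction-day (deformed) space back to
    planning space, so a bladder *larger* on the fraction day corresponds to
    an inward (contracting) radial pull displacement.

    Max |dense displacement| is bounded by ``params.deformation_mm`` plus the
    radial component's amplitude (B-spline weights are a partition of unity).
    Folding triggers damped resampling; after 5 attempts an error is raised.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    h = float(params.control_spacing_mm)
    if h < 4 * max(grid.spacing):
        raise ValueError("control spacing must be >= 4 voxels")
    lo = np.asarray(grid.origin) - 2 * h
    extent = grid.extent_mm
    n_ctrl = np.ceil((extent + 4 * h) / h).astype(int) + 1
    cgrid = ImageGrid(tuple(n_ctrl), (h, h, h), tuple(lo))

    # radial bladder component: exact local volume scaling inside the bladder,
    # cosine decay to zero by r1.  Prefiltered so the spline interpolates it.
    cpts = cgrid.voxel_centers()
    rel = cpts - np.asarray(bladder_center)
    r = np.linalg.norm(rel, axis=-1)
    s_lin = float(params.bladder_scale) ** (1.0 / 3.0)
    k = 1.0 / s_lin - 1.0  # signed radial strain of the pull map
    r0, r1 = bladder_radius, bladder_radius + 2.5 * h
    amp = np.where(
        r <= r0,
        k,
        np.where(r < r1, k * 0.5 * (1 + np.cos(np.pi * (r - r0) / (r1 - r0))), 0.0),
    )
    radial = amp[..., None] * rel
    if params.ctv_shift_mm != 0.0:
        # bulk target displacement (fraction-day anatomy): the pull map for a
        # target shifted posteriorly (+y) samples planning space at -shift
        rt = np.linalg.norm(cpts - np.asarray(target_center), axis=-1)
        r0t, r1t = 40.0, 85.0
        wt = np.where(
            rt <= r0t, 1.0,
            np.where(rt < r1t, 0.5 * (1 + np.cos(np.pi * (rt - r0t) / (r1t - r0t))), 0.0),
        )
        radial[..., 1] += -params.ctv_shift_mm * wt
    radial = np.stack(
        [ndimage.spline_filter(radial[..., c], order=3, mode="mirror") for c in range(3)],
        axis=-1,
    )

    base_random = rng.normal(size=tuple(n_ctrl) + (3,))
    smoothed = np.stack(
        [ndimage.gaussian_filter(base_random[..., c], 1.0) for c in range(3)], axis=-1
    )
    # normalize so that the max *dense* displacement of the random component
    # equals deformation_mm (the dense field of smoothed coefficients is
    # weaker than the coefficients themselves)
    if params.deformation_mm > 0:
        probe = DisplacementField(cgrid, smoothed)
        coarse_probe = ImageGrid(
            tuple(np.maximum(1, np.asarray(grid.size) // 2)),
            tuple(2 * s for s in grid.spacing), grid.origin,
        )
        peak = float(np.linalg.norm(probe.dense(coarse_probe), axis=-1).max())
    else:
        peak = 0.0
    damp = 1.0
    for _attempt in range(5):
        if peak > 0 and params.deformation_mm > 0:
            rand = smoothed * (damp * params.deformation_mm / peak)
        else:
            rand = np.zeros_like(smoothed)
        dvf = DisplacementField(cgrid, rand + radial)
        if (
            params.deformation_mm == 0
            and params.bladder_scale == 1.0
            and params.ctv_shift_mm == 0.0
        ):
            return dvf
        coarse = ImageGrid(
            tuple(np.maximum(1, np.asarray(grid.size) // 2)),
            tuple(2 * s for s in grid.spacing), grid.origin,
        )
        if dvf.jacobian_determinant(coarse).min() > 0.05:
            return dvf
        damp *= 0.7
    raise ValueError("could not sample a fold-free deformation after 5 attempts")


# ---------------------------------------------------------------------------
# CBCT degradation
# ---------------------------------------------------------------------------

def degrade_to_cbct(
    ct: ImageVolume,
    true_rigid: RigidTransform,
    true_dvf: DisplacementField | None,
    params: PhantomParams,
    seed_or_rng,
    cbct_grid: ImageGrid | None = None,
) -> ImageVolume:
    """Produce the fraction CBCT: warp the planning CT by the ground-truth
    motion, crop to a cylindrical FOV, and add cupping, HU shift and noise.

    The pull mapping from a CBCT-grid point ``y`` back to planning space is
    ``dvf(rigid(y))`` — the patient first deformed, then was set up with a
    rigid offset.  Outside the FOV cylinder voxels are exactly -1000 HU.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    if cbct_grid is None:
        cbct_grid = default_cbct_grid(params)
    fov_r = params.fov_radius_frac * min(params.body_semiaxes)
    fov_halflen = 0.5 * params.fov_length_frac * ct.grid.extent_mm[2]
    if 2 * fov_r > min(ct.grid.extent_mm[:2]) or 2 * fov_halflen > ct.grid.extent_mm[2]:
        raise ValueError("CBCT FOV exceeds the planning-CT extent")

    steps = [true_rigid] + ([true_dvf] if true_dvf is not None else [])
    transform = CompositeTransform(steps)
    if true_rigid.is_identity() and true_dvf is None and cbct_grid == ct.grid:
        warped = ct.copy()
    else:
        warped = resample(ct, cbct_grid, transform, "linear", fill=-1000.0)

    X, Y, Z = _coords(cbct_grid)
    rho = np.sqrt(X**2 + Y**2)
    fov = (rho <= fov_r) & (np.abs(Z) <= fov_halflen)
    hu = warped.values.copy()
    hu[fov] += params.hu_shift + params.cupping_hu * (rho[fov] / fov_r) ** 2
    if params.noise_hu > 0:
        hu[fov] += rng.normal(0.0, params.noise_hu, size=int(fov.sum()))
    hu[~fov] = -1000.0
    return ImageVolume(cbct_grid, hu, unit="HU", role="cbct")


def default_cbct_grid(params: PhantomParams) -> ImageGrid:
    size = params.cbct_size
    sp = params.spacing
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(size, sp))
    return ImageGrid(size, sp, origin)


def fov_cylinder(params: PhantomParams, ct_grid: ImageGrid):
    """(radius_mm, half_length_mm) of the CBCT field-of-view cylinder,
    centered on the CBCT frame origin."""
    return (
        params.fov_radius_frac * min(params.body_semiaxes),
        0.5 * params.fov_length_frac * ct_grid.extent_mm[2],
    )


# ---------------------------------------------------------------------------
# full case
# ---------------------------------------------------------------------------

_ROLE_MAP = {
    "skin": "rigid_organ", "femoral_head_l": "rigid_organ", "femoral_head_r": "rigid_organ",
    "pelvis": "rigid_organ", "spinal_cord": "rigid_organ", "bone_marrow": "rigid_organ",
    "rectum": "influencer", "small_intestine": "influencer", "bladder": "influencer",
    "CTV": "target", "PTV": "target",
}


def _box_plan(ptv: np.ndarray, grid: ImageGrid, p: PhantomParams) -> PlanInfo:
    """Four-field box with rectangular apertures fitted to the PTV."""
    idx = np.argwhere(ptv)
    centroid = grid.voxel_to_physical(idx.mean(axis=0))
    pts = grid.voxel_to_physical(idx.astype(float)) - centroid
    margin = 5.0
    ext = {
        "x": (pts[:, 0].min() - margin, pts[:, 0].max() + margin),
        "y": (pts[:, 1].min() - margin, pts[:, 1].max() + margin),
        "z": (pts[:, 2].min() - margin, pts[:, 2].max() + margin),
    }
    beams = []
    for g in (0.0, 90.0, 180.0, 270.0):
        lateral = ext["x"] if g in (0.0, 180.0) else ext["y"]
        if g in (180.0, 270.0):
            lateral = (-lateral[1], -lateral[0])
        beams.append(
            {
                "gantry_angle": g,
                "source_axis_distance": 1000.0,
                "aperture": {"type": "rectangle", "x": list(lateral), "y": list(ext["z"])},
                "weight": 1.0,
            }
        )
    return PlanInfo(
        isocenter=tuple(float(v) for v in centroid),
        prescription_dose=p.prescription_gy,
        number_of_fractions=p.number_of_fractions,
        beams=beams,
    )


def _propagate_all(structures: StructureSet, transform, grid: ImageGrid) -> StructureSet:
    # one shared coordinate evaluation for all masks (the transform apply is
    # the expensive part, not the interpolation)
    pts = grid.voxel_centers().reshape(-1, 3)
    moved = transform.apply(pts)
    coords = structures.grid.physical_to_voxel(moved).T
    masks = {}
    for n in structures.names():
        warped = ndimage.map_coordinates(
            structures.masks[n].astype(float), coords, order=1,
            mode="constant", cval=0.0, prefilter=False,
        ).reshape(grid.size)
        masks[n] = warped >= 0.5
    return StructureSet(grid, masks, dict(structures.roles))


def generate_case(params: PhantomParams | None = None, seed: int = 0) -> PhantomCase:
    """Generate one fully self-contained fraction case.

    Deterministic given ``(params, seed)``.  The fraction-day structures are
    the planning structures propagated by the ground-truth motion, so every
    downstream accuracy metric has an exact reference.
    """
    p = params or PhantomParams()
    rng = np.random.default_rng(seed)
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(p.size, p.spacing))
    grid = ImageGrid(p.size, p.spacing, origin)

    hu, organs, ctv, (bl_c, bl_s) = _build_anatomy(grid, p, rng)
    ptv = _dilate_mm(ctv, grid, p.ptv_margin_mm)
    masks = dict(organs)
    masks["CTV"] = ctv
    masks["PTV"] = ptv
    structures = StructureSet(grid, masks, dict(_ROLE_MAP))
    ct = ImageVolume(grid, hu, unit="HU", role="planning_ct")
    plan = _box_plan(ptv, grid, p)

    # ground-truth motion (draws in fixed order after anatomy)
    angles = np.deg2rad(rng.uniform(-p.rigid_deg, p.rigid_deg, 3))
    trans = rng.uniform(-p.rigid_mm, p.rigid_mm, 3)
    if p.rigid_mm == 0 and p.rigid_deg == 0:
        true_rigid = RigidTransform()
    else:
        true_rigid = RigidTransform(tuple(angles), tuple(trans), tuple(plan.isocenter))
    bl_radius = float(np.mean(bl_s))
    ctv_centroid = grid.voxel_to_physical(np.argwhere(ctv).mean(axis=0))
    true_dvf = sample_deformation(p, rng, grid, bladder_center=bl_c,
                                  bladder_radius=bl_radius,
                                  target_center=tuple(ctv_centroid))

    cbct_grid = default_cbct_grid(p)
    cbct = degrade_to_cbct(ct, true_rigid, true_dvf, p, rng, cbct_grid)
    transform = CompositeTransform([true_rigid, true_dvf])
    fraction_structures = _propagate_all(structures, transform, cbct_grid)

    reference_dose = None
    if p.with_dose:
        from .dose import compute_plan_dose
        from .evaluate import cumulative_dvh, dose_at_volume

        # clinical plan normalization: scale the output so PTV D_97% equals
        # the prescription — the original plan then satisfies the coverage
        # constraints (CTV V_100% >= 99%, PTV V_100% >= 95%) with margin
        raw = compute_plan_dose(ct, plan, grid)
        d97 = dose_at_volume(cumulative_dvh(raw, ptv, structure="PTV"), 97.0)
        if d97 <= 0:
            raise ValueError("reference plan delivers no dose to the PTV")
        plan.norm_factor = p.prescription_gy / d97
        reference_dose = DoseVolume(
            grid, raw.values * plan.norm_factor, prescription=p.prescription_gy
        )

    return PhantomCase(
        planning_ct=ct, structures=structures, plan=plan,
        reference_dose=reference_dose, cbct=cbct,
        fraction_structures=fraction_structures, true_rigid=true_rigid,
        true_dvf=true_dvf, seed=seed, params=p,
    )
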