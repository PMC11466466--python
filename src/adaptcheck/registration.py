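"""Rigid and deformable registration.

Rigid: isocenter-prealigned 6-parameter registration (three rotations, three
translations).  When the plan provides an isocenter, prealignment exploits
the clinical convention that the planned isocenter coincides with the CBCT
scan center (physical origin); otherwise the geometric centers of the two
grids are aligned.  The iterative refinement runs on SimpleITK's ITK
registration framework (Euler3D transform, Mattes mutual information by
default, multi-resolution regular-step gradient descent).

Deformable: a free-form-deformation engine optimizing cubic-B-spline control
displacements against a (possibly multi-channel) sum-of-squared-differences
metric plus a bending-energy penalty, by L-BFGS with analytic gradients on
an image pyramid.  The same engine drives both intensity registration
(planning CT vs. combined CT) and the structure-guided ROI registration.

All transforms are pull maps (fixed physical point -> moving physical point).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, optimize

from .core import (
    DisplacementField,
    ImageGrid,
    ImageVolume,
    RigidTransform,
    _bspline_weights,
    resample,
)

log = logging.getLogger("adaptcheck.registration")

_HU_WINDOW = (-150.0, 250.0)  # soft-tissue window for intensity DIR
_MAX_POINTS = 70000  # per-level cap on metric sample points

__all__ = [
    "RegistrationConfig",
    "prealign",
    "register_rigid",
    "register_bspline",
    "warp_image",
    "propagate_mask",
]


@dataclass(frozen=True)
class RegistrationConfig:
    """Knobs for rigid and deformable registration.

    ``metric`` applies to the rigid stage ("mutual_information" for CT vs.
    raw CBCT, "mean_squared_difference" for same-modality pairs).  The
    deformable stage always uses (multi-channel) SSD, which is appropriate
    because it only ever sees HU-calibrated image pairs or distance maps.
    """

    metric: str = "mutual_information"
    pyramid_levels: int = 2
    control_spacing: float = 25.0  # mm
    smoothness_weight: float = 0.05
    max_iterations: int = 80
    convergence_tol: float = 1e-7

    def __post_init__(self):
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if self.metric not in ("mutual_information", "mean_squared_difference"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.smoothness_weight < 0:
            raise ValueError("smoothness_weight must be >= 0")


# ---------------------------------------------------------------------------
# rigid
# ---------------------------------------------------------------------------

def prealign(
    fixed_ct: ImageVolume, moving_cbct: ImageVolume, isocenter=None
) -> RigidTransform:
    """Center prealignment (always succeeds, zero rotation).

    With an isocenter: pure translation mapping the planning-CT physical
    point ``isocenter`` to the CBCT physical point (0, 0, 0) — under the
    pull convention, ``translation = -isocenter``.  Without one: align the
    geometric centers of the two grids.  The chosen branch is recorded on
    the returned transform as ``.prealign_branch`` and logged.
    """
    if isocenter is not None:
        t = RigidTransform(translation=tuple(-np.asarray(isocenter, float)))
        branch = "isocenter"
    else:
        delta = np.asarray(moving_cbct.grid.center) - np.asarray(fixed_ct.grid.center)
        t = RigidTransform(translation=tuple(delta))
        branch = "geometric_center"
    log.info("prealignment branch: %s", branch)
    object.__setattr__(t, "prealign_branch", branch)
    return t


def _to_sitk(vol: ImageVolume):
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(
        np.ascontiguousarray(vol.values.transpose(2, 1, 0).astype(np.float32))
    )
    img.SetSpacing(tuple(float(s) for s in vol.grid.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.grid.origin))
    img.SetDirection(tuple(vol.grid.direction_matrix.flatten()))
    return img


def _sitk_mask(vol: ImageVolume, threshold: float):
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(
        np.ascontiguousarray(
            (vol.values > threshold).transpose(2, 1, 0).astype(np.uint8)
        )
    )
    img.SetSpacing(tuple(float(s) for s in vol.grid.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.grid.origin))
    img.SetDirection(tuple(vol.grid.direction_matrix.flatten()))
    return img


def _euler_from_rigid(t: RigidTransform):
    import SimpleITK as sitk

    e = sitk.Euler3DTransform()
    e.SetComputeZYX(True)
    e.SetCenter(tuple(float(v) for v in t.center))
    e.SetRotation(*(float(a) for a in t.rotation))
    e.SetTranslation(tuple(float(v) for v in t.translation))
    return e


def _rigid_from_euler(e) -> RigidTransform:
    angles = (e.GetAngleX(), e.GetAngleY(), e.GetAngleZ())
    wrapped = tuple(float(np.angle(np.exp(1j * a))) for a in angles)
    return RigidTransform(wrapped, tuple(e.GetTranslation()), tuple(e.GetCenter()))


def register_rigid(
    fixed: ImageVolume,
    moving: ImageVolume,
    init: RigidTransform | None = None,
    config: RegistrationConfig | None = None,
) -> RigidTransform:
    """Six-parameter rigid registration refined from ``init`` (multi-
    resolution gradient descent on ``config.metric``).

    The result is guaranteed not to be worse than ``init`` under the chosen
    metric: if the optimizer diverges, ``init`` is returned unchanged.
    Raises if the initial transform produces no field-of-view overlap.
    """
    import SimpleITK as sitk

    cfg = config or RegistrationConfig()
    init = init or RigidTransform()

    indicator = ImageVolume(
        moving.grid, np.ones(moving.grid.size), unit="1", role="mask"
    )
    probe = resample(indicator, fixed.grid, init, "linear", fill=0.0)
    if not (probe.values > 0.5).any():
        raise ValueError(
            "no overlap between fixed and moving volumes after initialization; "
            "prealign manually"
        )

    # The CBCT has the smaller field of view, so the optimization runs with
    # it as the (masked) fixed image — every sample then lands inside the
    # planning CT and the metric cannot be gamed by pushing samples off the
    # moving image.  The optimized transform is inverted back to the
    # CT -> CBCT pull convention of the public interface.
    f_img, m_img = _to_sitk(moving), _to_sitk(fixed)
    f_mask = _sitk_mask(moving, -999.5)
    init_sw = init.inverse()
    shrink = [2**k for k in range(cfg.pyramid_levels, 0, -1)] + [1]
    smooth = [float(k) for k in range(cfg.pyramid_levels, 0, -1)] + [0.0]

    def _new_method():
        r = sitk.ImageRegistrationMethod()
        if cfg.metric == "mutual_information":
            r.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
        else:
            r.SetMetricAsMeanSquares()
        r.SetMetricSamplingStrategy(r.NONE)  # dense: deterministic
        r.SetInterpolator(sitk.sitkLinear)
        r.SetMetricFixedMask(f_mask)
        return r

    reg = _new_method()
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-5,
        numberOfIterations=cfg.max_iterations,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=cfg.convergence_tol,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel(smooth)
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(_euler_from_rigid(init_sw), inPlace=False)
    final = reg.Execute(f_img, m_img)
    inner = final.GetNthTransform(0) if hasattr(final, "GetNthTransform") else final
    result_sw = _rigid_from_euler(sitk.Euler3DTransform(inner))

    # monotone contract: keep init if refinement did not improve the metric
    def _metric_of(t: RigidTransform) -> float:
        r = _new_method()
        r.SetInitialTransform(_euler_from_rigid(t), inPlace=False)
        return float(r.MetricEvaluate(f_img, m_img))

    if _metric_of(result_sw) > _metric_of(init_sw):
        log.warning("rigid refinement did not improve the metric; keeping init")
        return init
    return result_sw.inverse()


# ---------------------------------------------------------------------------
# free-form deformation engine
# ---------------------------------------------------------------------------

def _control_grid_for(grid: ImageGrid, spacing_mm: float) -> ImageGrid:
    lo = np.asarray(grid.origin) - 2 * spacing_mm
    n = np.ceil((grid.extent_mm + 4 * spacing_mm) / spacing_mm).astype(int) + 1
    return ImageGrid(tuple(n), (spacing_mm,) * 3, tuple(lo))


class _BasisGather:
    """Precomputed cubic-B-spline sampling structure for a fixed set of
    points: 64 (weight, flat-control-index) pairs per point, with
    out-of-range control nodes masked to a zero dummy coefficient."""

    def __init__(self, points: np.ndarray, cgrid: ImageGrid):
        t = cgrid.physical_to_voxel(points)
        i0 = np.floor(t).astype(np.int64)
        f = t - i0
        wx, wy, wz = (_bspline_weights(f[:, ax]) for ax in range(3))
        n = np.asarray(cgrid.size)
        self.n_ctrl = int(n.prod())
        W, IDX = [], []
        for kx in range(4):
            ix = i0[:, 0] + (kx - 1)
            for ky in range(4):
                iy = i0[:, 1] + (ky - 1)
                for kz in range(4):
                    iz = i0[:, 2] + (kz - 1)
                    ok = (
                        (ix >= 0) & (ix < n[0]) & (iy >= 0) & (iy < n[1])
                        & (iz >= 0) & (iz < n[2])
                    )
                    lin = (ix * n[1] + iy) * n[2] + iz
                    W.append(np.where(ok, wx[kx] * wy[ky] * wz[kz], 0.0))
                    IDX.append(np.where(ok, lin, self.n_ctrl))  # dummy slot
        self.W = np.stack(W)  # (64, N)
        self.IDX = np.stack(IDX)

    def evaluate(self, coeffs_flat: np.ndarray) -> np.ndarray:
        """coeffs_flat: (n_ctrl, 3) -> displacement (N, 3)."""
        c = np.vstack([coeffs_flat, np.zeros((1, 3))])
        out = np.zeros((self.W.shape[1], 3))
        for k in range(64):
            out += self.W[k][:, None] * c[self.IDX[k]]
        return out

    def scatter(self, weights_vec: np.ndarray) -> np.ndarray:
        """Adjoint: accumulate per-point 3-vectors into control nodes."""
        acc = np.zeros((self.n_ctrl + 1, 3))
        for k in range(64):
            for d in range(3):
                acc[:, d] += np.bincount(
                    self.IDX[k], weights=self.W[k] * weights_vec[:, d],
                    minlength=self.n_ctrl + 1,
                )
        return acc[:-1]


def _bending_energy_and_grad(C: np.ndarray):
    """Approximate bending energy: mean squared second difference of the
    control coefficients along each lattice axis (per component, mm^2)."""
    kern = np.array([1.0, -2.0, 1.0])
    n = C.size
    e = 0.0
    g = np.zeros_like(C)
    for ax in range(3):
        if C.shape[ax] < 3:
            continue
        for d in range(3):
            s = ndimage.correlate1d(C[..., d], kern, axis=ax, mode="constant")
            e += float(np.sum(s * s)) / n
            g[..., d] += (2.0 / n) * ndimage.correlate1d(s, kern, axis=ax, mode="constant")
    return e, g


def _downsampled_grid(grid: ImageGrid, factor: int) -> ImageGrid:
    n = tuple(max(1, s // factor) for s in grid.size)
    return ImageGrid(n, tuple(s * factor for s in grid.spacing), grid.origin)


def ffd_register_channels(
    fixed_channels: list,
    moving_channels: list,
    fixed_grid: ImageGrid,
    moving_grid: ImageGrid,
    config: RegistrationConfig,
    active_band: float | None = None,
) -> DisplacementField:
    """Multi-channel SSD free-form deformation registration.

    Channels are paired arrays (fixed on ``fixed_grid``, moving on
    ``moving_grid``); each pair is normalized by the standard deviation of
    its fixed channel so the bending weight is scale-free.  Returns the
    pull displacement field (fixed point -> moving point) parameterized on a
    control grid of ``config.control_spacing`` mm covering the fixed domain.

    ``active_band`` (channel units, e.g. mm for distance maps): when given,
    only working points where some fixed channel's magnitude is below the
    band enter the metric — with clamped distance maps everything farther is
    a constant plateau with zero gradient, so this is purely a speedup.
    """
    if len(fixed_channels) != len(moving_channels) or not fixed_channels:
        raise ValueError("need equal, non-zero numbers of fixed/moving channels")
    cgrid = _control_grid_for(fixed_grid, float(config.control_spacing))
    nc = int(np.prod(cgrid.size))
    C = np.zeros((nc, 3))

    scales = []
    for fc in fixed_channels:
        s = float(np.std(fc))
        scales.append(s if s > 1e-9 else 1.0)

    sp_m = np.asarray(moving_grid.spacing)
    for level in range(config.pyramid_levels, 0, -1):
        # finest working resolution is 2x the voxel spacing: the control
        # spacing (>= 15 mm) cannot represent detail below that anyway
        factor = 2**level
        wgrid = _downsampled_grid(fixed_grid, factor)
        pts = wgrid.voxel_centers().reshape(-1, 3)
        sigma = factor / 2.0

        # Moving channels and their spatial gradients are sampled with cubic
        # spline interpolation and nearest-edge extension: the interpolant is
        # then C2 everywhere (no kinks on the lattice, no cliff at the
        # boundary), which the line search requires.
        F = []
        M = []
        G = []
        for ch, (fc, mc) in enumerate(zip(fixed_channels, moving_channels)):
            s = scales[ch]
            f_s = ndimage.gaussian_filter(np.asarray(fc, float), sigma) / s
            m_s = ndimage.gaussian_filter(np.asarray(mc, float), sigma) / s
            F.append(f_s[:: factor, :: factor, :: factor][
                : wgrid.size[0], : wgrid.size[1], : wgrid.size[2]
            ].ravel())
            M.append(
                ndimage.spline_filter(m_s, order=3, mode="nearest").astype(np.float32)
            )
            G.append([
                ndimage.spline_filter(
                    np.gradient(m_s, sp_m[ax], axis=ax), order=3, mode="nearest"
                ).astype(np.float32)
                for ax in range(3)
            ])
        if active_band is not None:
            keep = np.zeros(pts.shape[0], dtype=bool)
            for ch in range(len(F)):
                keep |= np.abs(F[ch] * scales[ch]) < active_band
            if not keep.any():
                keep[:] = True
            pts = pts[keep]
            F = [f[keep] for f in F]
        # cap the per-iteration cost on huge point sets: a deterministic
        # stride is unbiased for the smooth channels used here
        if pts.shape[0] > _MAX_POINTS:
            stride = int(np.ceil(pts.shape[0] / _MAX_POINTS))
            pts = pts[::stride]
            F = [f[::stride] for f in F]
        gather = _BasisGather(pts, cgrid)
        npts = pts.shape[0]

        def metric_and_grad(x):
            Cl = x.reshape(nc, 3)
            u = gather.evaluate(Cl)
            q = pts + u
            coords = moving_grid.physical_to_voxel(q).T
            total = 0.0
            tvec = np.zeros((npts, 3))
            for ch in range(len(F)):
                mv = ndimage.map_coordinates(
                    M[ch], coords, order=3, mode="nearest", prefilter=False
                )
                r = mv - F[ch]
                total += float(np.mean(r * r))
                w = (2.0 / npts) * r
                for d in range(3):
                    gd = ndimage.map_coordinates(
                        G[ch][d], coords, order=3, mode="nearest", prefilter=False
                    )
                    tvec[:, d] += w * gd
            return total, gather.scatter(tvec)

        # the bending weight is expressed relative to the level's starting
        # metric value, making it scale-free in both image units and size
        m0, _ = metric_and_grad(C.ravel())
        lam = config.smoothness_weight * m0

        def objective(x):
            total, grad = metric_and_grad(x)
            be, bg = _bending_energy_and_grad(
                x.reshape(tuple(cgrid.size) + (3,))
            )
            total += lam * be
            grad = grad + lam * bg.reshape(nc, 3)
            return total, grad.ravel()

        # precondition: scale the objective so the starting gradient has unit
        # infinity norm; otherwise the first quasi-Newton steps are orders of
        # magnitude below the millimetre scale of meaningful displacements
        _, g0 = objective(C.ravel())
        gmax = float(np.abs(g0).max())
        if gmax < 1e-14:  # already at a stationary point (e.g. identical inputs)
            continue
        K = 1.0 / gmax

        def scaled(x):
            f, g = objective(x)
            return K * f, K * g

        # coefficients are box-bounded at 0.4x the control spacing — the
        # classical sufficient condition against folding, which also stops
        # the coarse level from chasing aliased matches far away
        bound = 0.4 * float(config.control_spacing)
        # the cheap coarse level gets the full iteration budget; finer levels
        # only refine and need about half
        maxiter = (
            config.max_iterations
            if level == config.pyramid_levels
            else max(10, config.max_iterations // 2)
        )
        res = optimize.minimize(
            scaled, C.ravel(), jac=True, method="L-BFGS-B",
            bounds=[(-bound, bound)] * (nc * 3),
            options={"maxiter": maxiter, "ftol": config.convergence_tol,
                     "gtol": 1e-10},
        )
        C = res.x.reshape(nc, 3)

    return DisplacementField(cgrid, C.reshape(tuple(cgrid.size) + (3,)))


def register_bspline(
    fixed: ImageVolume,
    moving: ImageVolume,
    init_rigid: RigidTransform | None = None,
    config: RegistrationConfig | None = None,
) -> DisplacementField:
    """Intensity deformable registration (single-channel SSD FFD).

    ``moving`` is first brought into the fixed frame by ``init_rigid`` (if
    given); the returned field is defined over the fixed grid and maps fixed
    points to points in the rigidly-aligned moving frame.  If the optimized
    field folds (non-positive Jacobian anywhere), the smoothness weight is
    raised tenfold and the registration re-run once.
    """
    cfg = config or RegistrationConfig()
    if init_rigid is not None and not init_rigid.is_identity():
        moving_a = resample(moving, fixed.grid, init_rigid, "linear")
    elif moving.grid != fixed.grid:
        moving_a = resample(moving, fixed.grid, None, "linear")
    else:
        moving_a = moving

    f_vals = np.asarray(fixed.values, float)
    m_vals = np.asarray(moving_a.values, float)
    if fixed.unit == "HU":
        # register on a soft-tissue window: bone/air edges otherwise dominate
        # the SSD a hundredfold and drown the organ signal that matters here
        f_vals = np.clip(f_vals, *_HU_WINDOW)
        m_vals = np.clip(m_vals, *_HU_WINDOW)
    dvf = ffd_register_channels([f_vals], [m_vals], fixed.grid, fixed.grid, cfg)
    if dvf.jacobian_determinant(_downsampled_grid(fixed.grid, 2)).min() <= 0:
        warnings.warn("deformable registration folded; retrying with 10x smoothness")
        cfg2 = replace(cfg, smoothness_weight=cfg.smoothness_weight * 10)
        dvf = ffd_register_channels([f_vals], [m_vals], fixed.grid, fixed.grid, cfg2)
    return dvf


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------

def warp_image(vol: ImageVolume, dvf, target_grid: ImageGrid | None = None) -> ImageVolume:
    """Pull-warp an image: output voxel x takes the value at ``dvf(x)``."""
    return resample(vol, target_grid or vol.grid, dvf, "linear")


def propagate_mask(
    mask: np.ndarray,
    transform,
    source_grid: ImageGrid,
    target_grid: ImageGrid | None = None,
) -> np.ndarray:
    """Propagate a binary mask through a pull transform: warp the 0/1 field
    with linear interpolation and threshold at 0.5 (ties count inside)."""
    target_grid = target_grid or source_grid
    vol = ImageVolume(source_grid, mask.astype(float), unit="1", role="mask")
    warped = resample(vol, target_grid, transform, "linear", fill=0.0)
    return warped.values >= 0.5
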