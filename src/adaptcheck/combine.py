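"""Combined-CT construction: HU calibration of the CBCT and splicing.

The fraction CBCT only covers a reduced cylindrical field of view and its
intensities carry shift/cupping bias.  This module (a) maps CBCT values to
CT-like HU with a monotone piecewise-linear calibration fitted against the
rigidly aligned planning CT (a deterministic stand-in for a learned
synthetic-CT generator — any callable with the same signature can replace
:func:`calibrate_hu`), and (b) splices the calibrated CBCT into the planning
CT on the planning grid: CBCT values inside the FOV, planning CT outside,
with a cosine blend ramp at the seam.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .core import DisplacementField, ImageGrid, ImageVolume, RigidTransform, resample

__all__ = ["calibrate_hu", "build_combined_ct", "make_deformed_ct"]

_CAL_RANGE = (-1000.0, 1500.0)
_N_KNOTS = 16
_MIN_PAIRS = 1000
_MIN_BIN = 20


def _pava(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: weighted isotonic (non-decreasing) fit."""
    y = y.astype(float).copy()
    w = w.astype(float).copy()
    blocks = [[i] for i in range(len(y))]
    vals = list(y)
    wts = list(w)
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1] + 1e-12:
            tot = wts[i] + wts[i + 1]
            vals[i] = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / tot
            wts[i] = tot
            blocks[i] += blocks[i + 1]
            del vals[i + 1], wts[i + 1], blocks[i + 1]
            if i > 0:
                i -= 1
        else:
            i += 1
    out = np.empty_like(y)
    for v, idxs in zip(vals, blocks):
        out[idxs] = v
    return out


def _shading_field(diff: np.ndarray, fov: np.ndarray, grid) -> np.ndarray:
    """Radial shading (cupping + shift) estimate inside the FOV cylinder.

    CBCT shading is, to first order, radially symmetric about the scanner
    axis (the z axis of the CBCT frame): the estimate is the per-annulus
    median of the CT-vs-CBCT residual, linearly interpolated along the
    in-plane radius.  The residual is clipped to +-120 HU first — anatomy
    mismatch at bone/air edges produces huge dipoles that would otherwise
    leak in, while true shading stays within this range.  Medians make the
    profile insensitive to organ-scale anatomical differences.
    """
    diff = np.clip(diff, -120.0, 120.0)
    xs = [grid.origin[i] + grid.spacing[i] * np.arange(grid.size[i]) for i in range(2)]
    RHO = np.sqrt(xs[0][:, None, None] ** 2 + xs[1][None, :, None] ** 2)
    RHO = np.broadcast_to(RHO, diff.shape)
    r = RHO[fov]
    d = diff[fov]
    rmax = float(r.max()) if r.size else 0.0
    if rmax <= 0:
        return np.zeros_like(diff)
    n_ann = 16
    edges = np.linspace(0.0, rmax + 1e-6, n_ann + 1)
    which = np.clip(np.digitize(r, edges) - 1, 0, n_ann - 1)
    centers, meds = [], []
    for b in range(n_ann):
        sel = which == b
        if sel.sum() >= 50:
            centers.append(float(np.median(r[sel])))
            meds.append(float(np.median(d[sel])))
    if len(centers) < 2:
        level = float(np.median(d)) if d.size else 0.0
        return np.where(fov, level, 0.0)
    prof = np.interp(RHO, np.asarray(centers), np.asarray(meds))
    return np.where(fov, prof, 0.0)


def calibrate_hu(
    cbct: ImageVolume,
    ct_aligned: ImageVolume,
    fov_mask: np.ndarray | None = None,
    correct_shading: bool = True,
) -> ImageVolume:
    """CBCT -> CT-like HU calibration (deterministic synthetic-CT stand-in).

    Two stages, both fitted against the rigidly aligned planning CT inside
    the FOV: (1) a robust radial shading correction for the cupping/shift
    bias (see :func:`_shading_field`); (2) a monotone piecewise-linear
    intensity map — pairs are
    binned into 16 knots over [-1000, 1500] by CBCT value, each knot is the
    (median CBCT, median CT) of its bin, isotonic-corrected so the mapping
    never reorders two HU values, linear between knots and extended with the
    end-segment slopes outside.  Requires >= 1000 voxel pairs.
    """
    if cbct.grid != ct_aligned.grid:
        raise ValueError("cbct and ct_aligned must share one grid")
    if fov_mask is None:
        fov_mask = cbct.values > -999.5
    work = np.asarray(cbct.values, float).copy()
    if correct_shading:
        diff = work - np.asarray(ct_aligned.values, float)
        work -= _shading_field(diff, fov_mask, cbct.grid)
    x = work[fov_mask]
    y = np.asarray(ct_aligned.values, float)[fov_mask]
    ok = (x >= _CAL_RANGE[0]) & (x <= _CAL_RANGE[1])
    x, y = x[ok], y[ok]
    if x.size < _MIN_PAIRS:
        raise ValueError(f"only {x.size} valid voxel pairs (need >= {_MIN_PAIRS})")

    edges = np.linspace(*_CAL_RANGE, _N_KNOTS + 1)
    which = np.clip(np.digitize(x, edges) - 1, 0, _N_KNOTS - 1)
    kx, ky, kw = [], [], []
    for b in range(_N_KNOTS):
        sel = which == b
        n = int(sel.sum())
        if n >= _MIN_BIN:
            kx.append(float(np.median(x[sel])))
            ky.append(float(np.median(y[sel])))
            kw.append(n)
    if len(kx) < 2:
        # degenerate dynamic range (e.g. near-uniform phantom): fall back to
        # a pure median shift, which is the only robustly estimable term
        shift = float(np.median(y) - np.median(x))
        vals = work
        vals[fov_mask] = vals[fov_mask] + shift
        vals[~fov_mask] = -1000.0
        out = ImageVolume(cbct.grid, vals, unit="HU", role="sct")
        out.calibration_knots = (np.array([0.0, 1.0]), np.array([shift, 1 + shift]))
        return out
    kx = np.asarray(kx)
    ky = _pava(np.asarray(ky), np.asarray(kw))

    def apply_map(v):
        out = np.interp(v, kx, ky)
        lo_slope = (ky[1] - ky[0]) / (kx[1] - kx[0]) if kx[1] > kx[0] else 1.0
        hi_slope = (ky[-1] - ky[-2]) / (kx[-1] - kx[-2]) if kx[-1] > kx[-2] else 1.0
        below = v < kx[0]
        above = v > kx[-1]
        out[below] = ky[0] + lo_slope * (v[below] - kx[0])
        out[above] = ky[-1] + hi_slope * (v[above] - kx[-1])
        return out

    vals = work
    vals[fov_mask] = apply_map(vals[fov_mask])
    vals[~fov_mask] = -1000.0
    out = ImageVolume(cbct.grid, vals, unit="HU", role="sct")
    out.calibration_knots = (kx, ky)  # recorded for provenance
    return out


def build_combined_ct(
    planning_ct: ImageVolume,
    cbct_or_sct: ImageVolume,
    rigid: RigidTransform,
    fov_mask: np.ndarray | None = None,
    blend_mm: float = 5.0,
) -> ImageVolume:
    """Splice the (calibrated) CBCT into the planning CT on the planning grid.

    A voxel whose rigidly mapped point lies deeper than ``blend_mm`` inside
    the CBCT FOV takes exactly the resampled CBCT value; a voxel outside the
    FOV takes exactly the planning CT value; in between, a cosine ramp
    blends the two.  The blend weight field is recorded on the result as
    ``.fov_weight``.
    """
    if fov_mask is None:
        fov_mask = cbct_or_sct.values != -1000.0
    if not fov_mask.any():
        raise ValueError("empty CBCT field of view")
    d = (
        ndimage.distance_transform_edt(fov_mask, sampling=cbct_or_sct.grid.spacing)
        - ndimage.distance_transform_edt(~fov_mask, sampling=cbct_or_sct.grid.spacing)
    )
    if blend_mm > 0:
        w = np.clip(d / blend_mm, 0.0, 1.0)
        w = 0.5 * (1.0 - np.cos(np.pi * w))
        w[d >= blend_mm] = 1.0
        w[d <= 0.0] = 0.0
    else:
        w = (d > 0).astype(float)

    wv = ImageVolume(cbct_or_sct.grid, w, unit="1", role="mask")
    w_r = resample(wv, planning_ct.grid, rigid, "linear", fill=0.0).values
    sct_r = resample(cbct_or_sct, planning_ct.grid, rigid, "linear", fill=-1000.0).values
    if not (w_r > 0).any():
        raise ValueError("no overlap between the CBCT FOV and the planning grid")

    plan = np.asarray(planning_ct.values, float)
    combined = np.where(
        w_r >= 1.0, sct_r, np.where(w_r <= 0.0, plan, w_r * sct_r + (1.0 - w_r) * plan)
    )
    out = ImageVolume(planning_ct.grid, combined, unit="HU", role="combined_ct")
    out.fov_weight = w_r
    return out


def make_deformed_ct(
    planning_ct: ImageVolume,
    dvf_dir: DisplacementField,
    target_grid: ImageGrid | None = None,
) -> ImageVolume:
    """Warp the planning CT onto the combined-CT frame: the dose-calculation
    image (deformed planning CT).  A folding field only warns — the dose
    image tolerates local overlap."""
    jac = dvf_dir.jacobian_determinant(
        ImageGrid(
            tuple(max(1, s // 2) for s in planning_ct.grid.size),
            tuple(2 * x for x in planning_ct.grid.spacing),
            planning_ct.grid.origin,
        )
    )
    if jac.min() <= 0:
        warnings.warn("deformation field folds; proceeding (dose image tolerant)")
    out = resample(planning_ct, target_grid or planning_ct.grid, dvf_dir, "linear")
    out.role = "dpct"
    return out
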