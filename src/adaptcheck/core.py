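"""Geometric data model shared by every pipeline stage.

Physical coordinates are LPS millimetres (DICOM patient convention), voxel
indices are 0-based, and a grid position refers to the *center* of a voxel.
All spatial transforms follow the pull/backward-warping convention: a
transform maps a fixed-image physical point to the corresponding
moving-image physical point, and resampling evaluates the moving image
there.  This single convention is used everywhere, including deformation
vector fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageGrid",
    "ImageVolume",
    "StructureSet",
    "RigidTransform",
    "DisplacementField",
    "CompositeTransform",
    "voxel_to_physical",
    "physical_to_voxel",
    "resample",
]

# Fill values used when a resampled point falls outside the source volume.
HU_AIR = -1000.0  #: air, used for CT-like volumes
FILL_DOSE = 0.0  #: zero dose outside a dose grid

_ORTHO_TOL = 1e-6


def _as_tuple3(x, dtype=float) -> tuple:
    t = tuple(dtype(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"expected a length-3 sequence, got {x!r}")
    return t


@dataclass(frozen=True)
class ImageGrid:
    """A regular 3D sampling lattice in physical (LPS, mm) space.

    Parameters
    ----------
    size
        Number of voxels along (x, y, z).
    spacing
        Voxel spacing in mm, all components > 0.
    origin
        Physical position (mm) of the center of voxel (0, 0, 0).
    direction
        3x3 orthonormal direction-cosine matrix; columns are the physical
        directions of the voxel axes.  Defaults to identity.
    """

    size: tuple
    spacing: tuple
    origin: tuple
    direction: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))

    def __post_init__(self):
        object.__setattr__(self, "size", _as_tuple3(self.size, int))
        object.__setattr__(self, "spacing", _as_tuple3(self.spacing, float))
        object.__setattr__(self, "origin", _as_tuple3(self.origin, float))
        d = np.asarray(self.direction, dtype=float).reshape(3, 3)
        object.__setattr__(self, "direction", tuple(map(tuple, d)))
        if any(n < 1 for n in self.size):
            raise ValueError(f"grid size components must be >= 1, got {self.size}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        if not np.allclose(d @ d.T, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("direction matrix is not orthonormal (tol 1e-6)")

    # -- derived geometry ---------------------------------------------------
    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.size

    @property
    def center(self) -> np.ndarray:
        """Physical center of the grid (mm)."""
        mid = (np.asarray(self.size, float) - 1.0) / 2.0
        return self.voxel_to_physical(mid[None, :])[0]

    @property
    def extent_mm(self) -> np.ndarray:
        """Edge-to-edge physical extent along each voxel axis."""
        return np.asarray(self.size, float) * np.asarray(self.spacing, float)

    def voxel_to_physical(self, indices) -> np.ndarray:
        """Map (continuous) voxel indices, shape (..., 3), to physical mm."""
        idx = np.asarray(indices, dtype=float)
        return (
            np.asarray(self.origin)
            + (idx * np.asarray(self.spacing)) @ self.direction_matrix.T
        )

    def physical_to_voxel(self, points) -> np.ndarray:
        """Inverse of :meth:`voxel_to_physical` (continuous indices)."""
        p = np.asarray(points, dtype=float)
        local = (p - np.asarray(self.origin)) @ self.direction_matrix
        return local / np.asarray(self.spacing)

    def voxel_centers(self) -> np.ndarray:
        """All voxel-center physical coordinates, shape (nx, ny, nz, 3)."""
        ii = np.stack(
            np.meshgrid(*(np.arange(n, dtype=float) for n in self.size), indexing="ij"),
            axis=-1,
        )
        return self.voxel_to_physical(ii)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def voxel_to_physical(index: Sequence[int], grid: ImageGrid) -> np.ndarray:
    """Physical position (mm) of the center of ``index``; bounds-checked."""
    idx = tuple(int(v) for v in index)
    for ax, (i, n) in enumerate(zip(idx, grid.size)):
        if not 0 <= i < n:
            raise IndexError(
                f"index {i} out of bounds for axis {'xyz'[ax]} (size {n})"
            )
    return grid.voxel_to_physical(np.asarray(idx, float))


def physical_to_voxel(point, grid: ImageGrid) -> np.ndarray:
    return grid.physical_to_voxel(point)


@dataclass
class ImageVolume:
    """A scalar volume (HU, Gy or dimensionless) living on an :class:`ImageGrid`.

    ``role`` tags the modality slot the volume fills in the workflow:
    planning CT, fraction CBCT, synthetic CT (sCT), combined CT, deformed
    planning CT (dpCT) or dose.
    """

    grid: ImageGrid
    values: np.ndarray
    unit: str = "HU"  # {"HU", "Gy", "1"}
    role: str = "planning_ct"

    _ROLES = ("planning_ct", "cbct", "sct", "combined_ct", "dpct", "dose", "mask")
    _UNITS = ("HU", "Gy", "1")

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if tuple(self.values.shape) != tuple(self.grid.size):
            raise ValueError(
                f"value array shape {self.values.shape} != grid size {self.grid.size}"
            )
        if self.unit not in self._UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.role not in self._ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.unit == "HU" and not np.isfinite(self.values).all():
            raise ValueError("HU volume contains non-finite values")
        if self.unit == "Gy" and np.any(self.values < 0):
            raise ValueError("dose volume contains negative values")

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.grid, self.values.copy(), self.unit, self.role)

    def with_values(self, values, **kw) -> "ImageVolume":
        d = dict(grid=self.grid, values=values, unit=self.unit, role=self.role)
        d.update(kw)
        return ImageVolume(**d)


# Structure role tags: deformable organs near the target drive the
# structure-guided registration ("influencers"); stable bony/neural anatomy
# is propagated by intensity registration ("rigid organs"); CTV/PTV are the
# targets propagated by the ROI registration.
STRUCTURE_ROLES = ("influencer", "rigid_organ", "target")


@dataclass
class StructureSet:
    """Named binary masks sharing one grid, each tagged with a role."""

    grid: ImageGrid
    masks: dict
    roles: dict

    def __post_init__(self):
        for name, m in self.masks.items():
            m = np.asarray(m)
            if tuple(m.shape) != tuple(self.grid.size):
                raise ValueError(f"mask {name!r} shape {m.shape} != grid {self.grid.size}")
            self.masks[name] = m.astype(bool)
            if name not in self.roles:
                raise ValueError(f"structure {name!r} has no role assigned")
        for name, r in self.roles.items():
            if r not in STRUCTURE_ROLES:
                raise ValueError(f"unknown role {r!r} for structure {name!r}")

    def names(self):
        return list(self.masks)

    def with_role(self, role: str):
        return [n for n, r in self.roles.items() if r == role]

    def get(self, name: str) -> np.ndarray:
        """Case-insensitive mask lookup."""
        if name in self.masks:
            return self.masks[name]
        low = {k.lower(): k for k in self.masks}
        if name.lower() in low:
            return self.masks[low[name.lower()]]
        raise KeyError(name)

    def has(self, name: str) -> bool:
        try:
            self.get(name)
            return True
        except KeyError:
            return False

    def subset(self, names: Iterable[str]) -> "StructureSet":
        names = list(names)
        return StructureSet(
            self.grid,
            {n: self.masks[n] for n in names},
            {n: self.roles[n] for n in names},
        )


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def _rot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


@dataclass(frozen=True)
class RigidTransform:
    """Six-parameter rigid transform: three rotation angles + translation.

    The rotation matrix is ``Rz @ Ry @ Rx`` (angles in radians, applied about
    ``center``), matching ITK's Euler3DTransform with ComputeZYX enabled:

        T(p) = R (p - center) + center + translation
    """

    rotation: tuple = (0.0, 0.0, 0.0)
    translation: tuple = (0.0, 0.0, 0.0)
    center: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "rotation", _as_tuple3(self.rotation))
        object.__setattr__(self, "translation", _as_tuple3(self.translation))
        object.__setattr__(self, "center", _as_tuple3(self.center))
        for a in self.rotation:
            if not (-np.pi < a <= np.pi):
                raise ValueError(f"rotation angle {a} outside (-pi, pi]")
        if not all(np.isfinite(self.rotation + self.translation + self.center)):
            raise ValueError("non-finite rigid transform parameters")

    @property
    def matrix(self) -> np.ndarray:
        ax, ay, az = self.rotation
        return _rot_z(az) @ _rot_y(ay) @ _rot_x(ax)

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        c = np.asarray(self.center)
        return (p - c) @ self.matrix.T + c + np.asarray(self.translation)

    def inverse(self) -> "RigidTransform":
        R = self.matrix.T
        # solve R'(q - c) + c + t' = R.T (q - c - t) + c
        t_inv = -R @ np.asarray(self.translation)
        return RigidTransform(_euler_zyx_from_matrix(R), tuple(t_inv), self.center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return T with T(p) = self(other(p)); centers merged into self's."""
        A, B = self.matrix, other.matrix
        R = A @ B
        c = np.asarray(self.center)
        # full affine: self(other(p)) = A(B(p - co) + co + to - c) + c + t
        co = np.asarray(other.center)
        offset = (
            A @ (B @ (-co) + co + np.asarray(other.translation) - c)
            + c
            + np.asarray(self.translation)
        )
        # re-express with center c: R(p - c) + c + t'  =>  t' = offset + R c - c
        t_new = offset + R @ c - c
        return RigidTransform(_euler_zyx_from_matrix(R), tuple(t_new), tuple(c))

    def is_identity(self, atol: float = 0.0) -> bool:
        return bool(
            np.all(np.abs(self.rotation) <= atol)
            and np.all(np.abs(self.translation) <= atol)
        )

    @property
    def parameters(self) -> np.ndarray:
        """The six-element parameter array (angles then translations)."""
        return np.asarray(self.rotation + self.translation)


def _euler_zyx_from_matrix(R: np.ndarray) -> tuple:
    """Angles (ax, ay, az) with R = Rz(az) Ry(ay) Rx(ax)."""
    ay = np.arcsin(np.clip(-R[2, 0], -1.0, 1.0))
    if abs(np.cos(ay)) > 1e-9:
        ax = np.arctan2(R[2, 1], R[2, 2])
        az = np.arctan2(R[1, 0], R[0, 0])
    else:  # gimbal lock; fold everything into az
        ax = 0.0
        az = np.arctan2(-R[0, 1], R[1, 1])
    return (float(ax), float(ay), float(az))


# Cubic B-spline basis weights for offsets -1, 0, 1, 2 around floor(t).
def _bspline_weights(f: np.ndarray) -> tuple:
    f2 = f * f
    f3 = f2 * f
    w0 = (1.0 - 3.0 * f + 3.0 * f2 - f3) / 6.0
    w1 = (3.0 * f3 - 6.0 * f2 + 4.0) / 6.0
    w2 = (-3.0 * f3 + 3.0 * f2 + 3.0 * f + 1.0) / 6.0
    w3 = f3 / 6.0
    return w0, w1, w2, w3


class DisplacementField:
    """Free-form deformation: a dense displacement field parameterized by a
    uniform cubic B-spline control grid.

    ``control_grid`` must be axis-aligned (identity direction).  Control
    displacements are physical mm vectors; the dense field at physical point
    ``p`` is the tensor-product cubic B-spline interpolation of the control
    coefficients, so zero coefficients give the identity mapping and the
    field is C2-smooth by construction.  As a transform it is pull-style:
    ``apply(p) = p + u(p)`` maps fixed-image points to moving-image points.
    """

    def __init__(self, control_grid: ImageGrid, control_displacements):
        if not np.allclose(control_grid.direction_matrix, np.eye(3)):
            raise ValueError("control grid must be axis-aligned")
        disp = np.asarray(control_displacements, dtype=float)
        expected = tuple(control_grid.size) + (3,)
        if disp.shape != expected:
            raise ValueError(f"control displacements shape {disp.shape} != {expected}")
        if not np.isfinite(disp).all():
            raise ValueError("non-finite control displacements")
        self.control_grid = control_grid
        self.control_displacements = disp
        self._dense_cache: dict = {}

    # -- evaluation ---------------------------------------------------------
    def displacement_at(self, points) -> np.ndarray:
        """Displacement (mm) at arbitrary physical points, shape (..., 3)."""
        p = np.asarray(points, dtype=float)
        flat = p.reshape(-1, 3)
        t = self.control_grid.physical_to_voxel(flat)  # continuous control index
        i0 = np.floor(t).astype(np.int64)
        f = t - i0
        wx = _bspline_weights(f[:, 0])
        wy = _bspline_weights(f[:, 1])
        wz = _bspline_weights(f[:, 2])
        n = np.asarray(self.control_grid.size)
        c = self.control_displacements
        cflat = c.reshape(-1, 3)
        out = np.zeros((flat.shape[0], 3))
        for kx in range(4):
            ix = i0[:, 0] + (kx - 1)
            okx = (ix >= 0) & (ix < n[0])
            for ky in range(4):
                iy = i0[:, 1] + (ky - 1)
                wxy = wx[kx] * wy[ky]
                okxy = okx & (iy >= 0) & (iy < n[1])
                for kz in range(4):
                    iz = i0[:, 2] + (kz - 1)
                    ok = okxy & (iz >= 0) & (iz < n[2])
                    if not ok.any():
                        continue
                    w = wxy * wz[kz]
                    lin = (ix * n[1] + iy) * n[2] + iz
                    if ok.all():
                        out += w[:, None] * cflat[lin]
                    else:
                        out[ok] += w[ok, None] * cflat[lin[ok]]
        return out.reshape(p.shape)

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p + self.displacement_at(p)

    def dense(self, grid: ImageGrid) -> np.ndarray:
        """Displacement sampled at every voxel center of ``grid``;
        cached per grid."""
        key = (grid.size, grid.spacing, grid.origin, grid.direction)
        if key not in self._dense_cache:
            self._dense_cache[key] = self.displacement_at(grid.voxel_centers())
        return self._dense_cache[key]

    def max_displacement(self, grid: ImageGrid) -> float:
        return float(np.linalg.norm(self.dense(grid), axis=-1).max())

    def jacobian_determinant(self, grid: ImageGrid) -> np.ndarray:
        """Determinant of d(apply)/dp on grid voxels (finite differences)."""
        u = self.dense(grid)
        sp = np.asarray(grid.spacing)
        J = np.empty(tuple(grid.size) + (3, 3))
        for comp in range(3):
            for ax in range(3):
                J[..., comp, ax] = np.gradient(u[..., comp], sp[ax], axis=ax)
            J[..., comp, comp] += 1.0
        return np.linalg.det(J)


class CompositeTransform:
    """Sequential composition; ``apply`` runs the member transforms in list
    order, so ``CompositeTransform([a, b]).apply(p) == b.apply(a.apply(p))``."""

    def __init__(self, transforms):
        self.transforms = list(transforms)

    def apply(self, points) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        for t in self.transforms:
            p = t.apply(p)
        return p


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _transform_points(transform, points):
    if transform is None:
        return points
    return transform.apply(points)


def resample(
    vol: ImageVolume,
    target: ImageGrid,
    transform=None,
    interpolation: str = "linear",
    fill: float | None = None,
) -> ImageVolume:
    """Resample ``vol`` onto ``target`` through a pull transform.

    ``transform`` maps target (fixed) physical points into the moving
    image's physical space; ``None`` means identity.  Points that land
    outside ``vol`` receive ``fill`` (default: -1000 for HU volumes, 0
    otherwise).
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if fill is None:
        fill = HU_AIR if vol.unit == "HU" else FILL_DOSE
    if isinstance(transform, RigidTransform) and not all(
        np.isfinite(transform.parameters)
    ):
        raise ValueError("non-finite transform parameters")

    # identity fast path: bit-identical output on a matching grid
    if transform is None and target == vol.grid:
        return vol.copy()

    pts = target.voxel_centers().reshape(-1, 3)
    if isinstance(transform, DisplacementField):
        # full-grid pull warp: reuse the per-grid dense-field cache, which
        # repeated mask/image propagation through one field hits every time
        moved = pts + transform.dense(target).reshape(-1, 3)
    else:
        moved = _transform_points(transform, pts)
    if not np.isfinite(moved).all():
        raise ValueError("transform produced non-finite points")
    coords = vol.grid.physical_to_voxel(moved).T  # (3, N)
    order = 1 if interpolation == "linear" else 0
    out = ndimage.map_coordinates(
        np.asarray(vol.values, dtype=float),
        coords,
        order=order,
        mode="grid-constant" if order == 0 else "constant",
        cval=fill,
        prefilter=False,
    )
    out = out.reshape(target.size)
    if vol.unit == "Gy":
        out = np.maximum(out, 0.0)
    return ImageVolume(target, out, unit=vol.unit, role=vol.role)
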