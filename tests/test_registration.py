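"""Rigid and deformable registration: prealignment branch logic, recovery of
known transforms, warping oracles."""

import numpy as np
import pytest

from adaptcheck.core import (
    DisplacementField,
    ImageGrid,
    ImageVolume,
    RigidTransform,
    resample,
)
from adaptcheck.registration import (
    RegistrationConfig,
    ffd_register_channels,
    prealign,
    propagate_mask,
    register_bspline,
    register_rigid,
    warp_image,
)


def _vol(n=16, spacing=2.0, seed=0, center=True):
    origin = tuple(-(n - 1) / 2 * spacing if center else 0.0 for _ in range(3))
    grid = ImageGrid((n, n, n), (spacing,) * 3, origin)
    vals = np.random.default_rng(seed).normal(0, 100, (n, n, n))
    return ImageVolume(grid, vals)


class TestPrealign:
    def test_isocenter_branch_negates_isocenter(self):
        t = prealign(_vol(), _vol(), isocenter=(10, -20, 5))
        assert t.translation == (-10.0, 20.0, -5.0)
        assert t.rotation == (0.0, 0.0, 0.0)
        assert t.prealign_branch == "isocenter"

    def test_absent_isocenter_centered_grids_identity(self):
        t = prealign(_vol(), _vol(), isocenter=None)
        assert np.allclose(t.translation, 0.0)
        assert t.prealign_branch == "geometric_center"

    def test_absent_isocenter_center_difference(self):
        fixed = _vol()
        grid = ImageGrid((16, 16, 16), (2.0,) * 3,
                         (3.0 - 15.0, -15.0, -15.0))
        moving = ImageVolume(grid, fixed.values.copy())
        # CT grid center at (3,0,0), CBCT center at (0,0,0): pull translation
        # from CT points to CBCT points is -3 along x... the transform maps
        # fixed (CT) physical points to moving (CBCT) physical points
        t = prealign(ImageVolume(grid, fixed.values.copy()), _vol(), None)
        assert np.allclose(t.translation, (-3.0, 0.0, 0.0))


class TestRegisterRigid:
    def test_identical_volumes_give_identity(self, clean_case):
        ct = clean_case.planning_ct
        est = register_rigid(ct, ct, RigidTransform(),
                             RegistrationConfig(metric="mean_squared_difference"))
        assert np.linalg.norm(est.translation) < 0.1
        assert np.abs(np.rad2deg(est.rotation)).max() < 0.05

    def test_recovers_known_transform(self):
        """Ground-truth recovery: moving is the fixed phantom under a known
        rigid motion; the estimate must invert it within 0.5 mm / 0.2 deg."""
        from adaptcheck.phantom import PhantomParams, generate_case

        p = PhantomParams(with_dose=False, deformation_mm=0, bladder_scale=1.0,
                          rigid_mm=0, rigid_deg=0, noise_hu=0, cupping_hu=0,
                          hu_shift=0)
        case = generate_case(p, seed=9)
        ct = case.planning_ct
        true = RigidTransform((0, 0, np.deg2rad(2.0)), (5.0, -3.0, 2.0))
        moving = resample(ct, ct.grid, true)
        est = register_rigid(ct, moving, RigidTransform(),
                             RegistrationConfig(metric="mean_squared_difference"))
        comp = est.compose(true)  # should be identity
        center = np.zeros((1, 3))
        terr = float(np.linalg.norm(comp.apply(center) - center))
        rerr = np.rad2deg(np.arccos(np.clip((np.trace(comp.matrix) - 1) / 2, -1, 1)))
        assert terr < 0.5
        assert rerr < 0.2

    def test_no_overlap_raises(self):
        fixed = _vol(seed=1)
        with pytest.raises(ValueError, match="overlap"):
            register_rigid(fixed, _vol(seed=2),
                           RigidTransform(translation=(1e4, 0, 0)))


def _blob_pair(n=32, spacing=4.0, shift=6.0):
    origin = tuple(-(n - 1) / 2 * spacing for _ in range(3))
    grid = ImageGrid((n, n, n), (spacing,) * 3, origin)
    xs = [origin[i] + spacing * np.arange(n) for i in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    blob = lambda cx: 100 * np.exp(-((X - cx) ** 2 + Y**2 + Z**2) / (2 * 20.0**2))
    return grid, blob(shift), blob(0.0)


class TestRegisterBspline:
    CFG = RegistrationConfig(metric="mean_squared_difference",
                             control_spacing=32.0, smoothness_weight=0.05,
                             pyramid_levels=1, max_iterations=60)

    def test_identical_inputs_give_identity_field(self):
        grid, fixedv, _ = _blob_pair()
        vol = ImageVolume(grid, fixedv, unit="1", role="mask")
        dvf = register_bspline(vol, vol, None, self.CFG)
        assert dvf.max_displacement(grid) < 0.5

    def test_recovers_uniform_shift(self):
        grid, fixedv, movingv = _blob_pair(shift=6.0)
        dvf = ffd_register_channels([fixedv], [movingv], grid, grid, self.CFG)
        u = dvf.dense(grid)
        xs = np.linspace(-60, 60, 31)
        X, Y, Z = np.meshgrid(
            *[grid.origin[i] + grid.spacing[i] * np.arange(grid.size[i])
              for i in range(3)], indexing="ij")
        core = (np.abs(X) < 20) & (np.abs(Y) < 20) & (np.abs(Z) < 20)
        assert abs(u[..., 0][core].mean() - (-6.0)) < 1.0

    def test_smoothness_weight_sweep_monotone(self):
        """A stiffer field moves less: max displacement decreases
        monotonically as the bending weight grows on a fixed pair."""
        grid, fixedv, movingv = _blob_pair(shift=6.0)
        maxima = []
        for w in (0.02, 2.0, 200.0):
            cfg = RegistrationConfig(metric="mean_squared_difference",
                                     control_spacing=32.0, smoothness_weight=w,
                                     pyramid_levels=1, max_iterations=60)
            dvf = ffd_register_channels([fixedv], [movingv], grid, grid, cfg)
            maxima.append(dvf.max_displacement(grid))
        assert maxima[0] >= maxima[1] >= maxima[2]

    def test_known_dvf_recovery_dsc(self, clean_case):
        """Known-field recovery experiment: a mid-size mask propagated by
        the recovered field overlaps the truth-propagated mask at DSC >= 0.90."""
        ct = clean_case.planning_ct
        warped = resample(ct, ct.grid, clean_case.true_dvf)
        dvf = register_bspline(warped, ct, None)
        mask = clean_case.structures.get("CTV")
        gt = propagate_mask(mask, clean_case.true_dvf, ct.grid)
        rec = propagate_mask(mask, dvf, ct.grid)
        from adaptcheck.evaluate import dsc

        assert dsc(rec, gt) >= 0.90


class TestWarping:
    def test_identity_dvf_leaves_mask_unchanged(self, rng):
        grid = ImageGrid((16, 16, 16), (2.0,) * 3, (0, 0, 0))
        cgrid = ImageGrid((6, 6, 6), (12.0,) * 3, (-12, -12, -12))
        dvf = DisplacementField(cgrid, np.zeros((6, 6, 6, 3)))
        mask = rng.random((16, 16, 16)) > 0.7
        assert np.array_equal(propagate_mask(mask, dvf, grid), mask)

    def test_translation_dvf_is_integer_shift(self):
        grid = ImageGrid((16, 16, 16), (2.0,) * 3, (0, 0, 0))
        cgrid = ImageGrid((8, 8, 8), (12.0,) * 3, (-24, -24, -24))
        disp = np.zeros((8, 8, 8, 3))
        disp[..., 0] = 2.0  # exactly one voxel along x
        dvf = DisplacementField(cgrid, disp)
        mask = np.zeros((16, 16, 16), bool)
        mask[6:10, 6:10, 6:10] = True
        out = propagate_mask(mask, dvf, grid)
        assert np.array_equal(out[:-1], mask[1:])

    def test_radial_expansion_volume_matches_jacobian(self):
        """Pull map p -> c + (p-c)/s shrinks sampling coordinates, so the
        warped sphere's volume grows by ~s^3 (the inverse-Jacobian integral)."""
        n, sp = 48, 2.0
        origin = tuple(-(n - 1) / 2 * sp for _ in range(3))
        grid = ImageGrid((n, n, n), (sp,) * 3, origin)
        ncx = 14
        cg = ImageGrid((ncx,) * 3, (10.0,) * 3, (-65.0,) * 3)
        cpts = cg.voxel_centers()
        s = 1.15
        disp = (1.0 / s - 1.0) * cpts  # linear field: exactly representable
        dvf = DisplacementField(cg, disp)
        X, Y, Z = np.meshgrid(
            *[origin[i] + sp * np.arange(n) for i in range(3)], indexing="ij")
        sphere = X**2 + Y**2 + Z**2 <= 20.0**2
        out = propagate_mask(sphere, dvf, grid)
        ratio = out.sum() / sphere.sum()
        assert abs(ratio - s**3) / s**3 < 0.05

    def test_warp_image_identity(self):
        grid = ImageGrid((12, 12, 12), (2.0,) * 3, (0, 0, 0))
        cgrid = ImageGrid((6, 6, 6), (10.0,) * 3, (-10, -10, -10))
        dvf = DisplacementField(cgrid, np.zeros((6, 6, 6, 3)))
        vol = ImageVolume(grid, np.random.default_rng(3).normal(0, 50, (12,) * 3))
        out = warp_image(vol, dvf)
        assert np.allclose(out.values, vol.values, atol=1e-9)
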