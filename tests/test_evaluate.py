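"""Evaluation metrics: DSC, DVH family, gamma index, fraction report and the
adaptation decision."""

import numpy as np
import pytest
from scipy import ndimage

from adaptcheck.core import ImageGrid, StructureSet
from adaptcheck.evaluate import (
    ARTPolicy,
    GammaCriteria,
    art_recommendation,
    cumulative_dvh,
    dose_at_volume,
    dsc,
    evaluate_fraction,
    gamma_pass_rate,
    volume_at_dose,
)
from adaptcheck.rtio import DoseVolume, PlanInfo

GRID8 = ImageGrid((8, 8, 8), (2.5,) * 3, (0, 0, 0))


class TestDsc:
    def test_examples(self):
        a = np.zeros((6, 6, 6), bool)
        a[1:3, 1:3, 1:3] = True
        assert dsc(a, a) == 1.0
        b = np.zeros_like(a)
        b[4:6, 4:6, 4:6] = True
        assert dsc(a, b) == 0.0
        shifted = np.zeros_like(a)
        shifted[2:4, 1:3, 1:3] = True  # one-voxel shift of a 2x2x2 cube
        assert dsc(a, shifted) == pytest.approx(2 * 4 / 16)

    def test_both_empty_defined_as_one(self):
        assert dsc(np.zeros((4, 4, 4), bool), np.zeros((4, 4, 4), bool)) == 1.0

    def test_grid_mismatch_rejected(self):
        g2 = ImageGrid((8, 8, 8), (2.0,) * 3, (0, 0, 0))
        with pytest.raises(ValueError):
            dsc(np.ones(GRID8.size, bool), np.ones(g2.size, bool), GRID8, g2)


def _uniform_dose(value, prescription=45.0, grid=GRID8):
    return DoseVolume(grid, np.full(grid.size, float(value)), prescription)


def _half_half(lo=40.0, hi=50.0, grid=GRID8):
    vals = np.full(grid.size, lo)
    vals[: grid.size[0] // 2] = hi
    return DoseVolume(grid, vals, 45.0)


class TestDvh:
    def test_uniform_structure(self):
        c = cumulative_dvh(_uniform_dose(45.0), np.ones(GRID8.size, bool))
        assert c.cumulative_volume[0] == 1.0
        assert volume_at_dose(c, 45.0) == pytest.approx(100.0, abs=0.2)
        assert volume_at_dose(c, 45.5) == 0.0

    def test_half_half_step_curve(self):
        c = cumulative_dvh(_half_half(), np.ones(GRID8.size, bool))
        assert volume_at_dose(c, 39.0) == pytest.approx(100.0)
        assert volume_at_dose(c, 45.0) == pytest.approx(50.0, abs=0.2)
        assert volume_at_dose(c, 51.0) == 0.0

    def test_curve_non_increasing_for_random_dose(self, rng):
        dose = DoseVolume(GRID8, rng.gamma(2.0, 10.0, GRID8.size), 45.0)
        mask = rng.random(GRID8.size) > 0.4
        c = cumulative_dvh(dose, mask)
        assert np.all(np.diff(c.cumulative_volume) <= 1e-12)

    def test_empty_mask_names_structure(self):
        with pytest.raises(ValueError, match="CTV"):
            cumulative_dvh(_uniform_dose(10.0), np.zeros(GRID8.size, bool),
                           structure="CTV")


class TestDiVi:
    def test_d99_uniform(self):
        c = cumulative_dvh(_uniform_dose(45.0), np.ones(GRID8.size, bool))
        assert dose_at_volume(c, 99.0) == pytest.approx(45.0, abs=0.011)

    def test_half_half_d_metrics(self):
        c = cumulative_dvh(_half_half(), np.ones(GRID8.size, bool))
        assert dose_at_volume(c, 95.0) == pytest.approx(40.0, abs=0.011)
        # exactly half the volume is at 50: the boundary belongs to D_50
        assert dose_at_volume(c, 50.0) == pytest.approx(50.0, abs=0.011)

    def test_v100_flag_requires_prescription(self):
        c = cumulative_dvh(_uniform_dose(45.0), np.ones(GRID8.size, bool))
        c.prescription = None
        with pytest.raises(ValueError, match="prescription"):
            volume_at_dose(c, 100.0, as_percent_of_prescription=True)

    def test_zero_dose_v10(self):
        c = cumulative_dvh(_uniform_dose(0.0), np.ones(GRID8.size, bool))
        assert volume_at_dose(c, 10.0) == 0.0

    def test_matches_voxel_sorting_oracle(self, rng):
        """D_i / V_d from the binned curve equal the direct voxel-sorting
        answer within one bin width, across random dose/mask pairs."""
        for _ in range(50):
            vals = rng.gamma(3.0, 8.0, GRID8.size)
            mask = rng.random(GRID8.size) > 0.5
            if not mask.any():
                continue
            dose = DoseVolume(GRID8, vals, 45.0)
            c = cumulative_dvh(dose, mask)
            inside = np.sort(vals[mask])[::-1]
            for i in (10.0, 50.0, 95.0):
                k = max(int(np.ceil(i / 100.0 * inside.size)) - 1, 0)
                assert dose_at_volume(c, i) == pytest.approx(inside[k], abs=0.011)
            for d in (10.0, 25.0):
                frac = 100.0 * (inside >= d).sum() / inside.size
                assert volume_at_dose(c, d) == pytest.approx(frac, abs=0.11)


def brute_force_gamma_pass(ref, ev, crit, radius_factor=3.0):
    """Independent oracle: per-voxel min gamma by exhaustive scan of the
    offset ball (no early exit, no active-set shrinking).

    For pass/fail purposes ``radius_factor=1`` is already exhaustive — any
    offset beyond one DTA has a distance term above 1 on its own — so the
    wider scan only matters as a cross-check that the claim holds.
    """
    norm = float(ref.values.max())
    thr = crit.low_dose_threshold / 100 * norm
    tol = crit.dose_tolerance / 100 * norm
    mask = np.asarray(ref.values) >= thr
    pts = ref.grid.voxel_centers()[mask]
    rd = np.asarray(ref.values, float)[mask]
    step = crit.dta / crit.step_divisor
    k = int(np.floor(radius_factor * crit.dta / step))
    ax = step * np.arange(-k, k + 1)
    offs = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), -1).reshape(-1, 3)
    rr = np.linalg.norm(offs, axis=1)
    keep = rr <= radius_factor * crit.dta + 1e-9
    offs, rr = offs[keep], rr[keep]
    best = np.full(len(pts), np.inf)
    ev_vals = np.asarray(ev.values, float)
    chunk = max(1, int(2e6 // max(len(pts), 1)))
    for start in range(0, len(offs), chunk):
        off = offs[start:start + chunk]  # (c, 3)
        r = rr[start:start + chunk]
        sample = pts[None, :, :] + off[:, None, :]  # (c, n, 3)
        co = ev.grid.physical_to_voxel(sample.reshape(-1, 3)).T
        dv = ndimage.map_coordinates(ev_vals, co, order=1, mode="constant",
                                     cval=np.nan, prefilter=False)
        g2 = ((dv.reshape(len(off), -1) - rd[None, :]) / tol) ** 2 \
            + (r[:, None] / crit.dta) ** 2
        best = np.fmin(best, np.nanmin(np.where(np.isnan(g2), np.inf, g2), axis=0))
    return best <= 1.0


class TestGamma:
    CRIT = GammaCriteria(2.0, 2.0, 10.0)

    def test_identical_doses_pass_fully(self, rng):
        d = DoseVolume(GRID8, np.abs(rng.normal(20, 5, GRID8.size)))
        assert gamma_pass_rate(d, DoseVolume(GRID8, d.values.copy()),
                               self.CRIT) == 100.0

    def test_uniform_three_percent_offset_fails_everywhere(self):
        a = DoseVolume(GRID8, np.ones(GRID8.size))
        b = DoseVolume(GRID8, np.full(GRID8.size, 1.03))
        assert gamma_pass_rate(a, b, self.CRIT) == 0.0

    def test_agrees_with_brute_force_per_voxel(self, rng):
        """The production scan (sorted offsets, early exit) and the
        exhaustive 3xDTA-ball oracle give the same per-voxel verdicts."""
        g = ImageGrid((8, 8, 8), (2.5,) * 3, (0, 0, 0))
        a = DoseVolume(g, np.abs(10 + 3 * rng.standard_normal(g.size)))
        b = DoseVolume(g, np.abs(a.values * (1 + 0.025 * rng.standard_normal(g.size))))
        oracle = brute_force_gamma_pass(a, b, self.CRIT)
        fast = gamma_pass_rate(a, b, self.CRIT)
        assert fast == pytest.approx(100.0 * oracle.mean(), abs=1e-9)

    def test_scale_invariance(self, rng):
        a = DoseVolume(GRID8, np.abs(10 + 3 * rng.standard_normal(GRID8.size)))
        b = DoseVolume(GRID8, np.abs(a.values * (1 + 0.02 * rng.standard_normal(GRID8.size))))
        r1 = gamma_pass_rate(a, b, self.CRIT)
        r2 = gamma_pass_rate(DoseVolume(GRID8, 7 * a.values),
                             DoseVolume(GRID8, 7 * b.values), self.CRIT)
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_loosening_criteria_never_decreases_rate(self, rng):
        for _ in range(5):
            a = DoseVolume(GRID8, np.abs(10 + 3 * rng.standard_normal(GRID8.size)))
            b = DoseVolume(GRID8, np.abs(a.values * (1 + 0.03 * rng.standard_normal(GRID8.size))))
            rates = [gamma_pass_rate(a, b, GammaCriteria(dd, dta, 10.0))
                     for dd, dta in ((2, 2), (2, 3), (3, 2), (3, 3))]
            assert rates[0] <= rates[3]
            assert rates[0] <= rates[1] <= rates[3]
            assert rates[0] <= rates[2] <= rates[3]

    def test_all_below_threshold_rejected(self):
        a = DoseVolume(GRID8, np.zeros(GRID8.size))
        with pytest.raises(ValueError):
            gamma_pass_rate(a, a, self.CRIT)


GRID10 = ImageGrid((10, 10, 10), (2.5,) * 3, (0, 0, 0))


def _structures(grid=GRID10, names=("CTV", "PTV", "bladder")):
    masks, roles = {}, {}
    # a 1000-voxel structure: 0.1% steps in V_100% are exact voxel counts
    full = np.ones(grid.size, bool)
    for n in names:
        masks[n] = full.copy()
        roles[n] = "target" if n in ("CTV", "PTV") else "influencer"
    return StructureSet(grid, masks, roles)


class TestEvaluateFraction:
    PLAN = PlanInfo(isocenter=(0, 0, 0), prescription_dose=45.0)

    def _dose_with_v100(self, pct, grid=GRID10):
        """Dose giving exactly pct% of the structure >= 45 Gy."""
        vals = np.full(grid.size, 46.0)
        n_cold = int(round((100.0 - pct) / 100.0 * vals.size))
        flat = vals.ravel()
        flat[:n_cold] = 40.0
        return DoseVolume(grid, flat.reshape(grid.size), 45.0)

    def test_boundary_flags(self):
        s = _structures()
        good = self._dose_with_v100(100.0)
        for pct, expected in ((99.0, "pass"), (98.9, "fail")):
            r = evaluate_fraction(self._dose_with_v100(pct), s, good, s, self.PLAN)
            assert r.flags["CTV:V_100%"] == expected, pct
        r = evaluate_fraction(self._dose_with_v100(95.0), s, good, s, self.PLAN)
        assert r.flags["PTV:V_100%"] == "pass"
        r = evaluate_fraction(self._dose_with_v100(94.5), s, good, s, self.PLAN)
        assert r.flags["PTV:V_100%"] == "fail"

    def test_identical_inputs_give_zero_deltas_and_pass(self):
        s = _structures()
        d = self._dose_with_v100(100.0)
        r = evaluate_fraction(d, s, d, s, self.PLAN)
        assert r.recommendation == "no_adaptation"
        for metrics in r.metrics.values():
            for vals in metrics.values():
                if vals.get("delta") is not None:
                    assert vals["delta"] == pytest.approx(0.0, abs=1e-9)

    def test_missing_oar_is_absent_not_fatal(self):
        s = _structures(names=("CTV", "PTV"))
        d = self._dose_with_v100(100.0)
        r = evaluate_fraction(d, s, d, s, self.PLAN)
        assert r.metrics["Rectum"]["V_40Gy"].get("absent") is True

    def test_missing_target_is_fatal(self):
        s = _structures(names=("CTV",))
        d = self._dose_with_v100(100.0)
        with pytest.raises(ValueError, match="PTV"):
            evaluate_fraction(d, s, d, s, self.PLAN)


class TestArtRecommendation:
    def _report(self, ctv_v100=100.0, rectum_delta=0.0):
        from adaptcheck.evaluate import FractionReport

        r = FractionReport(prescription=45.0)
        r.metrics = {
            "CTV": {"V_100%": {"original": 100.0, "fraction": ctv_v100,
                               "delta": ctv_v100 - 100.0}},
            "Rectum": {"V_40Gy": {"original": 20.0,
                                  "fraction": 20.0 + rectum_delta,
                                  "delta": rectum_delta}},
        }
        r.flags = {"CTV:V_100%": "pass" if ctv_v100 >= 99.0 else "fail"}
        return r

    def test_all_equal_no_adaptation(self):
        assert art_recommendation(self._report()) == "no_adaptation"

    def test_target_failure_triggers_adapt(self):
        assert art_recommendation(self._report(ctv_v100=96.0)) == "adapt"

    def test_oar_excess_triggers_review(self):
        assert art_recommendation(self._report(rectum_delta=6.0)) == "review"
        assert art_recommendation(self._report(rectum_delta=4.0)) == "no_adaptation"

    def test_policy_margin_configurable(self):
        pol = ARTPolicy(oar_delta=10.0)
        assert art_recommendation(self._report(rectum_delta=6.0), pol) == "no_adaptation"
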