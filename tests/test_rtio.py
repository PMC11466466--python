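"""DICOM-RT readers, contour rasterization and the fixture format."""

import json

import numpy as np
import pydicom
import pytest
from matplotlib.path import Path as MplPath
from pydicom.dataset import FileDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from adaptcheck.core import ImageGrid
from adaptcheck.phantom import PhantomParams, generate_case
from adaptcheck.rtio import (
    PlanInfo,
    extract_contours,
    rasterize_contours,
    read_dose,
    read_fixture,
    read_image_series,
    read_plan,
    write_fixture,
    write_report,
)


def _ct_slice(path, z, series_uid, rows=8, cols=8, spacing=(1.0, 1.0)):
    ds = FileDataset(str(path), {}, file_meta=None, preamble=b"\0" * 128)
    ds.file_meta = pydicom.dataset.FileMetaDataset()
    ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
    ds.SOPClassUID = pydicom.uid.CTImageStorage
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.SeriesInstanceUID = series_uid
    ds.Rows, ds.Columns = rows, cols
    ds.PixelSpacing = [spacing[1], spacing[0]]
    ds.ImagePositionPatient = [-3.5, -3.5, z]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.RescaleSlope, ds.RescaleIntercept = 1.0, -1024.0
    ds.BitsAllocated = ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = (np.arange(rows * cols, dtype=np.uint16) % 2000).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


class TestImageSeries:
    def test_geometry_echoed(self, tmp_path):
        d = tmp_path / "series"
        d.mkdir()
        uid = generate_uid()
        for i, z in enumerate((0.0, 2.0, 4.0)):
            _ct_slice(d / f"ct{i}.dcm", z, uid)
        vol = read_image_series(d)
        assert vol.grid.spacing == (1.0, 1.0, 2.0)
        assert vol.grid.size == (8, 8, 3)
        assert vol.values.min() == -1024.0  # rescale applied

    def test_missing_middle_slice_reports_gap(self, tmp_path):
        d = tmp_path / "gap"
        d.mkdir()
        uid = generate_uid()
        for i, z in enumerate((0.0, 2.0, 6.0)):
            _ct_slice(d / f"ct{i}.dcm", z, uid)
        with pytest.raises(ValueError, match="non-uniform slice gap"):
            read_image_series(d)

    def test_mixed_series_rejected(self, tmp_path):
        d = tmp_path / "mixed"
        d.mkdir()
        _ct_slice(d / "a.dcm", 0.0, generate_uid())
        _ct_slice(d / "b.dcm", 2.0, generate_uid())
        with pytest.raises(ValueError, match="mixed series"):
            read_image_series(d)


def _brute_force_even_odd(rings, grid):
    """Independent rasterization oracle: XOR of per-ring point-in-polygon
    over every voxel center."""
    nx, ny, _ = grid.size
    out = np.zeros((nx, ny), dtype=bool)
    xs = grid.origin[0] + grid.spacing[0] * np.arange(nx)
    ys = grid.origin[1] + grid.spacing[1] * np.arange(ny)
    for pts in rings:
        path = MplPath(pts)
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                out[i, j] ^= bool(path.contains_point((x, y)))
    return out


class TestContours:
    def test_square_hundred_voxels(self):
        grid = ImageGrid((20, 20, 1), (1, 1, 1), (0.5, 0.5, 0.0))
        square = np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float)
        mask = rasterize_contours([(0.0, square)], grid)
        assert mask.sum() == 100
        assert np.array_equal(mask[:, :, 0], _brute_force_even_odd([square], grid))

    def test_nested_rings_even_odd(self):
        grid = ImageGrid((20, 20, 1), (1, 1, 1), (0.5, 0.5, 0.0))
        outer = np.array([[0, 0], [12, 0], [12, 12], [0, 12]], float)
        inner = np.array([[3, 3], [9, 3], [9, 9], [3, 9]], float)
        mask = rasterize_contours([(0.0, outer), (0.0, inner)], grid)
        oracle = _brute_force_even_odd([outer, inner], grid)
        assert np.array_equal(mask[:, :, 0], oracle)
        assert mask.sum() == oracle.sum() == 144 - 36

    def test_degenerate_ring_skipped_with_warning(self):
        grid = ImageGrid((10, 10, 1), (1, 1, 1), (0, 0, 0))
        with pytest.warns(UserWarning, match="degenerate"):
            mask = rasterize_contours([(0.0, np.array([[1, 1], [2, 2]]))], grid)
        assert not mask.any()

    def test_far_slice_skipped_with_warning(self):
        grid = ImageGrid((10, 10, 2), (1, 1, 2), (0, 0, 0))
        ring = np.array([[0, 0], [5, 0], [5, 5], [0, 5]], float)
        with pytest.warns(UserWarning, match="half a slice"):
            rasterize_contours([(7.0, ring)], grid)

    def test_rasterize_extract_rasterize_idempotent(self, clean_case):
        grid = clean_case.structures.grid
        for name in ("bladder", "CTV", "femoral_head_l"):
            m1 = clean_case.structures.get(name)
            m2 = rasterize_contours(extract_contours(m1, grid), grid)
            m3 = rasterize_contours(extract_contours(m2, grid), grid)
            assert np.array_equal(m2, m3)


class TestPlanAndDose:
    def test_plan_json_round_trip(self, tmp_path):
        plan = PlanInfo(isocenter=(10, -20, 5), beams=[
            {"gantry_angle": 0.0, "source_axis_distance": 1000.0,
             "aperture": None, "weight": 1.0},
            {"gantry_angle": 180.0, "source_axis_distance": 1000.0,
             "aperture": None, "weight": 1.0},
        ])
        p = tmp_path / "plan.json"
        p.write_text(json.dumps({"plan": plan.to_dict()}))
        back = read_plan(p)
        assert back.isocenter == (10, -20, 5)
        assert len(back.beams) == 2

    def test_absent_isocenter_is_not_an_error(self, tmp_path):
        p = tmp_path / "plan.json"
        p.write_text(json.dumps({"plan": {"prescription_dose": 45.0}}))
        assert read_plan(p).isocenter is None

    def test_beam_weight_invariants(self):
        with pytest.raises(ValueError):
            PlanInfo(beams=[{"weight": 0.0}])
        with pytest.raises(ValueError):
            PlanInfo(prescription_dose=0.0)

    def test_rtdose_scaling(self, tmp_path):
        ds = FileDataset(str(tmp_path / "d.dcm"), {}, file_meta=None,
                         preamble=b"\0" * 128)
        ds.file_meta = pydicom.dataset.FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.RTDoseStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.SOPClassUID = pydicom.uid.RTDoseStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.Modality = "RTDOSE"
        ds.DoseGridScaling = 0.01
        ds.GridFrameOffsetVector = [0.0, 2.0]
        ds.PixelSpacing = [1.0, 1.0]
        ds.ImagePositionPatient = [0, 0, 0]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.Rows = ds.Columns = 2
        ds.NumberOfFrames = 2
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = np.full(8, 4500, dtype=np.uint16).tobytes()
        ds.save_as(str(tmp_path / "d.dcm"), enforce_file_format=True)
        dose = read_dose(tmp_path / "d.dcm")
        assert np.allclose(dose.values, 45.0)

    def test_report_refuses_nan(self, tmp_path):
        report = {"metrics": {"CTV": {"V_100%": {"original": float("nan"),
                                                 "fraction": 1.0, "delta": 0.0}}},
                  "flags": {}}
        with pytest.raises(ValueError, match="CTV/V_100%"):
            write_report(report, tmp_path / "r")

    def test_report_written_as_json_and_csv(self, tmp_path):
        report = {"metrics": {"CTV": {"V_100%": {"original": 99.5,
                                                 "fraction": 99.1,
                                                 "delta": -0.4}}},
                  "flags": {"CTV:V_100%": "pass"}}
        write_report(report, tmp_path / "r")
        assert (tmp_path / "r.json").exists()
        lines = (tmp_path / "r.csv").read_text().strip().splitlines()
        assert lines[0].startswith("structure,metric")
        assert "CTV" in lines[1]


class TestFixture:
    def test_round_trip(self, tmp_path, degraded_case):
        write_fixture(degraded_case, tmp_path / "case")
        back = read_fixture(tmp_path / "case")
        assert np.array_equal(back.planning_ct.values, degraded_case.planning_ct.values)
        assert np.array_equal(back.cbct.values, degraded_case.cbct.values)
        assert np.allclose(back.true_rigid.parameters,
                           degraded_case.true_rigid.parameters)
        assert np.allclose(back.true_dvf.control_displacements,
                           degraded_case.true_dvf.control_displacements)
        for name in degraded_case.structures.names():
            assert np.array_equal(back.structures.get(name),
                                  degraded_case.structures.get(name)), name
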