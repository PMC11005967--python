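"""Workflow drivers, tables, DICOM-RT input and volume export."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from overlapdose.dose_engine import preset
from overlapdose.workflow_io import (
    ExperimentConfig,
    IncompatibleFrameError,
    StructureLookupError,
    case_manifest,
    evaluate_cohort,
    read_rt_inputs,
    run_experiment,
    save_volume_nrrd,
    summarize_cohort,
)

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")


# ---------------------------------------------------------------------------
# cohort evaluation and experiment driver
# ---------------------------------------------------------------------------

class TestEvaluateCohort:
    def test_table_shape_and_identities(self, sim1_cases):
        table = evaluate_cohort(sim1_cases, preset("IMRT"), seed=2)
        assert len(table) == 6
        # POPP identity per OAR
        np.testing.assert_allclose(
            table["rectum_popp"],
            table["rectum_copp"] * table["ptv_cc"] / table["rv_cc"],
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            table["bladder_popp"],
            table["bladder_copp"] * table["ptv_cc"] / table["bv_cc"],
            rtol=1e-12,
        )
        assert table["goals_pass"].dtype == bool

    def test_sweep_columns_monotone_in_dose(self, sim1_cases):
        table = evaluate_cohort(sim1_cases, preset("VMAT"), seed=2)
        levels = np.arange(20.0, 75.5, 1.0)
        for _, row in table.iterrows():
            vals = [row[f"rectum_v{lev:g}gy"] for lev in levels]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_same_seed_reproduces_table(self, sim1_cases):
        t1 = evaluate_cohort(sim1_cases, preset("IMRT"), seed=5)
        t2 = evaluate_cohort(sim1_cases, preset("IMRT"), seed=5)
        pd.testing.assert_frame_equal(t1, t2)


class TestSummary:
    def test_constant_metric_has_zero_sd(self):
        n = 5
        data = {"rectum_copp": np.linspace(0.05, 0.2, n),
                "bladder_copp": np.linspace(0.04, 0.1, n)}
        data["rectum_popp"] = data["rectum_copp"] * 3.0
        data["bladder_popp"] = data["bladder_copp"] * 1.2
        for oar in ("rectum", "bladder"):
            for metric in ("dmean", "v70gy", "v60gy", "v37.5gy"):
                data[f"{oar}_{metric}"] = np.full(n, 42.0)
        summary = summarize_cohort(pd.DataFrame(data))
        assert (summary["sd"] == 0.0).all()
        assert set(summary["oar"]) == {"rectum", "bladder"}

    def test_summary_r_matches_regression_layer(self, sim1_cases):
        from overlapdose.regression_stats import pearson_r

        table = evaluate_cohort(sim1_cases, preset("IMRT"), seed=2)
        summary = summarize_cohort(table).set_index(["oar", "metric"])
        expected = pearson_r(table["rectum_copp"], table["rectum_v70gy"])
        assert summary.loc[("rectum", "v70gy"), "r_copp"] == expected


class TestRunExperiment:
    def test_simulation1_run_writes_consistent_outputs(self, tmp_path):
        config = ExperimentConfig(
            family="simulation1", modality="IMRT", seed=3,
            output_dir=str(tmp_path / "a"), write_plots=True,
        )
        result = run_experiment(config)
        mres = result.per_modality["IMRT"]
        assert len(mres.cases) == 6
        assert set(mres.cases["rov_target_cc"].round(1)) == {3.3, 5.3, 7.7}
        written = {p.name for p in result.output_files}
        assert {"cases_IMRT.csv", "summary_IMRT.csv", "manifest.json"} <= written
        assert any(name.endswith(".svg") for name in written)

        # per-case CSV round-trips numerically
        disk = pd.read_csv(tmp_path / "a" / "cases_IMRT.csv")
        for col in ("rectum_copp", "rectum_v70gy", "cn", "hi"):
            np.testing.assert_allclose(disk[col], mres.cases[col], atol=1e-9)

    def test_rerun_is_byte_identical(self, tmp_path):
        outputs = []
        for sub in ("r1", "r2"):
            config = ExperimentConfig(
                family="simulation1", modality="IMRT", seed=3,
                output_dir=str(tmp_path / sub), write_plots=False,
            )
            run_experiment(config)
            outputs.append((tmp_path / sub / "cases_IMRT.csv").read_bytes())
        assert outputs[0] == outputs[1]

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            run_experiment(ExperimentConfig(family="simulation9"))

    def test_config_yaml_round_trip(self, tmp_path):
        config = ExperimentConfig(family="simulation1", modality="VMAT", seed=9)
        path = tmp_path / "cfg.yaml"
        import yaml

        path.write_text(yaml.safe_dump(config.to_dict()))
        again = ExperimentConfig.from_yaml(path)
        assert again == config
        assert again.config_hash() == config.config_hash()


class TestCaseManifest:
    def test_manifest_carries_provenance_and_features(self, sim1_cases):
        manifest = case_manifest(sim1_cases)
        assert len(manifest) == 6
        for col in ("case_id", "rov_cc", "bov_cc", "rectum_copp", "rectum_popp"):
            assert col in manifest.columns
        np.testing.assert_allclose(
            manifest["rectum_copp"], manifest["rov_cc"] / manifest["rv_cc"], rtol=1e-12
        )


# ---------------------------------------------------------------------------
# DICOM-RT fixtures (generated in-memory, nothing stored on disk)
# ---------------------------------------------------------------------------

def _write_rtdose(path, shape_xyz=(40, 40, 30), spacing=(2.0, 2.0, 2.0),
                  stored_value=7560, scaling=0.01, frame_uid="1.2.3.4"):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    nx, ny, nz = shape_xyz
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.2")
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.FrameOfReferenceUID = frame_uid
    ds.Rows, ds.Columns, ds.NumberOfFrames = ny, nx, nz
    ds.PixelSpacing = [spacing[1], spacing[0]]  # [row=y, col=x]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = [
        -(nx - 1) * spacing[0] / 2, -(ny - 1) * spacing[1] / 2, -(nz - 1) * spacing[2] / 2,
    ]
    ds.GridFrameOffsetVector = [k * spacing[2] for k in range(nz)]
    ds.DoseGridScaling = scaling
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    arr = np.full((nz, ny, nx), stored_value, dtype=np.uint32)
    ds.PixelData = arr.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return ds


def _sphere_contours(center, radius, n_pts=72):
    """Closed planar circles on the fixture dose-grid slice planes
    (z = -29, -27, ... 29), as CT-aligned contours would be."""
    cx, cy, cz = center
    contours = []
    for z in np.arange(-29.0, 30.0, 2.0):
        r2 = radius**2 - (z - cz) ** 2
        if r2 <= 1.0:
            continue
        r = np.sqrt(r2)
        theta = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
        pts = np.c_[cx + r * np.cos(theta), cy + r * np.sin(theta), np.full(n_pts, z)]
        contours.append(pts)
    return contours


def _write_rtstruct(path, rois, frame_uid="1.2.3.4", skip_contours=()):
    import pydicom
    from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.3")
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ref = Dataset()
    ref.FrameOfReferenceUID = frame_uid
    ds.ReferencedFrameOfReferenceSequence = [ref]

    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for number, (name, contours) in enumerate(rois.items(), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = frame_uid
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        if name not in skip_contours:
            for pts in contours:
                c = Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                c.NumberOfContourPoints = len(pts)
                c.ContourData = [float(v) for v in pts.ravel()]
                rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    ds.save_as(str(path), enforce_file_format=True)
    return ds


NAME_MAP = {"ptv": "PTV", "rectum": "Rectum", "bladder": "Bladder"}


@pytest.fixture()
def dicom_pair(tmp_path):
    rois = {
        "PTV": _sphere_contours((0, 0, 0), 25.0),
        "Rectum": _sphere_contours((0, -28, 0), 8.0),
        "Bladder": _sphere_contours((0, 28, 0), 8.0),
    }
    struct_path = tmp_path / "rtstruct.dcm"
    dose_path = tmp_path / "rtdose.dcm"
    _write_rtstruct(struct_path, rois)
    _write_rtdose(dose_path)
    return struct_path, dose_path


class TestDicomInput:
    def test_sphere_volume_and_dose_scaling(self, dicom_pair):
        case, dose = read_rt_inputs(*dicom_pair, NAME_MAP)
        analytic = 4.0 / 3.0 * np.pi * 25**3 / 1000.0
        assert case.ptv_cc == pytest.approx(analytic, rel=0.03)
        # stored 7560 x scaling 0.01 -> 75.6 Gy everywhere
        assert np.all(dose.dose == pytest.approx(75.6))

    def test_axis_orientation_preserved(self, dicom_pair):
        case, _ = read_rt_inputs(*dicom_pair, NAME_MAP)
        assert case.rectum.centroid_mm()[1] < -20
        assert case.bladder.centroid_mm()[1] > 20
        assert case.rov_cc > 0 and case.bov_cc > 0

    def test_missing_roi_name_raises(self, dicom_pair):
        with pytest.raises(StructureLookupError):
            read_rt_inputs(*dicom_pair, {**NAME_MAP, "rectum": "Colon"})

    def test_role_without_name_raises(self, dicom_pair):
        with pytest.raises(StructureLookupError):
            read_rt_inputs(*dicom_pair, {"ptv": "PTV"})

    def test_empty_contour_list_raises(self, tmp_path):
        rois = {
            "PTV": _sphere_contours((0, 0, 0), 25.0),
            "Rectum": _sphere_contours((0, -28, 0), 8.0),
            "Bladder": _sphere_contours((0, 28, 0), 8.0),
        }
        sp, dp = tmp_path / "s.dcm", tmp_path / "d.dcm"
        _write_rtstruct(sp, rois, skip_contours=("Bladder",))
        _write_rtdose(dp)
        with pytest.raises(StructureLookupError):
            read_rt_inputs(sp, dp, NAME_MAP)

    def test_frame_mismatch_raises(self, tmp_path):
        rois = {"PTV": _sphere_contours((0, 0, 0), 25.0),
                "Rectum": _sphere_contours((0, -28, 0), 8.0),
                "Bladder": _sphere_contours((0, 28, 0), 8.0)}
        sp, dp = tmp_path / "s.dcm", tmp_path / "d.dcm"
        _write_rtstruct(sp, rois, frame_uid="1.2.3.4")
        _write_rtdose(dp, frame_uid="9.8.7.6")
        with pytest.raises(IncompatibleFrameError):
            read_rt_inputs(sp, dp, NAME_MAP)


class TestVolumeExport:
    def test_nrrd_round_trip(self, tmp_path, small_grid, rng):
        data = rng.random(small_grid.shape).astype(np.float32)
        path = save_volume_nrrd(small_grid, data, tmp_path / "vol.nrrd")
        blob = path.read_bytes()
        header, _, raw = blob.partition(b"\n\n")
        text = header.decode()
        assert "NRRD" in text and f"sizes: {small_grid.shape[0]}" in text
        back = np.frombuffer(raw, dtype="<f4").reshape(small_grid.shape, order="F")
        np.testing.assert_array_equal(back, data)

    def test_shape_mismatch_rejected(self, tmp_path, small_grid):
        with pytest.raises(ValueError):
            save_volume_nrrd(small_grid, np.zeros((2, 2, 2)), tmp_path / "x.nrrd")
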