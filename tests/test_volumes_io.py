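"""Volume I/O, geometry handling, and SUV conversion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from skelburden.volumes import (
    AcquisitionMeta,
    ImageVolume,
    Modality,
    StudyPair,
    ValueKind,
    read_volume,
    to_suv,
    write_volume,
)

# hand-evaluated before the build: C = 5 kBq/mL, A_inj = 222 MBq (18F,
# half-life 109.77 min), uptake 60 min, W = 80 kg
# A_scan = 222e6 * 2**(-60/109.77) = 151.9885e6 Bq; SUV = 5000/(A_scan/80000)
HAND_SUV = 2.6317779211204115


class TestImageVolume:
    def test_rejects_nonpositive_spacing(self):
        with pytest.raises(ValueError, match="spacing"):
            ImageVolume(np.zeros((4, 4, 4)), (4.0, 0.0, 4.0))

    def test_rejects_non_3d(self):
        with pytest.raises(ValueError, match="3-D"):
            ImageVolume(np.zeros((4, 4)), (4.0, 4.0, 4.0))

    def test_ct_must_be_hu(self):
        with pytest.raises(ValueError, match="HU"):
            ImageVolume(np.zeros((4, 4, 4)), (4, 4, 4), modality=Modality.CT, value_kind=ValueKind.SUV)

    def test_voxel_volume(self):
        vol = ImageVolume(np.zeros((2, 2, 2)), (4.0, 4.0, 4.0))
        assert vol.voxel_volume_ml == pytest.approx(0.064)


class TestNiftiRoundTrip:
    def test_isotropic_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(1)
        vol = ImageVolume(rng.normal(size=(20, 20, 20)), (4.0, 4.0, 4.0), (1.0, -2.0, 3.0))
        path = tmp_path / "vol.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.values, vol.values)
        assert back.spacing == pytest.approx(vol.spacing)
        assert back.origin == pytest.approx(vol.origin)

    def test_anisotropic_spacing_preserved(self, tmp_path):
        vol = ImageVolume(np.zeros((8, 8, 8)), (4.0, 4.0, 3.0))
        path = tmp_path / "aniso.nii.gz"
        write_volume(vol, path)
        assert read_volume(path).spacing == pytest.approx((4.0, 4.0, 3.0))

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(IOError):
            read_volume(tmp_path / "nope.nii.gz")

    def test_non_3d_payload_rejected(self, tmp_path):
        import nibabel as nib

        img = nib.Nifti1Image(np.zeros((4, 4, 4, 2)), np.eye(4))
        nib.save(img, tmp_path / "fourd.nii.gz")
        with pytest.raises(ValueError, match="3-D"):
            read_volume(tmp_path / "fourd.nii.gz")


def _write_dicom_series(out_dir, n_slices=10, rows=8, cols=6, thickness=4.0):
    """Create a minimal CT series with pydicom; slice files written out of order."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    out_dir.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    rng = np.random.default_rng(9)
    arrays = rng.integers(0, 1000, size=(n_slices, rows, cols)).astype(np.int16)
    order = rng.permutation(n_slices)  # shuffle on disk; reader must sort
    for file_idx, k in enumerate(order):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.Rows, ds.Columns = rows, cols
        ds.PixelSpacing = ["2.0", "1.5"]  # (row, col) -> y, x
        ds.SliceThickness = str(thickness)
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [0.0, 0.0, float(k) * thickness]
        ds.RescaleSlope = "1.0"
        ds.RescaleIntercept = "-1024.0"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = arrays[k].tobytes()
        ds.save_as(out_dir / f"slice_{file_idx:03d}.dcm", enforce_file_format=True)
    return arrays


class TestDicomSeries:
    def test_series_assembled_sorted_and_rescaled(self, tmp_path):
        arrays = _write_dicom_series(tmp_path / "series", n_slices=10, thickness=4.0)
        vol = read_volume(tmp_path / "series", format="dicom")
        # single volume: z spacing 4 mm, 10 slices -> 40 mm z-extent
        assert vol.shape == (6, 8, 10)
        assert vol.spacing == pytest.approx((1.5, 2.0, 4.0))
        assert vol.shape[2] * vol.spacing[2] == pytest.approx(40.0)
        # independent assembly: sort by z, transpose (row, col) -> (x, y)
        expected = np.stack([arrays[k].T for k in range(10)], axis=-1) - 1024.0
        np.testing.assert_allclose(vol.values, expected)

    def test_empty_directory_raises(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(IOError, match="no readable DICOM"):
            read_volume(tmp_path / "empty", format="dicom")


class TestSUVConversion:
    def _meta(self, **kw):
        defaults = dict(injected_activity_mbq=222.0, body_weight_kg=80.0,
                        uptake_time_min=60.0, half_life_min=109.77)
        defaults.update(kw)
        return AcquisitionMeta(**defaults)

    def _pet(self, values):
        return ImageVolume(values, (4, 4, 4), modality=Modality.PET_NAF,
                           value_kind=ValueKind.ACTIVITY_CONC)

    def test_uniform_concentration_gives_suv_one(self):
        meta = self._meta()
        c = meta.activity_at_scan_bq() / (80.0 * 1000.0)
        suv = to_suv(self._pet(np.full((4, 4, 4), c)), meta)
        np.testing.assert_allclose(suv.values, 1.0)
        assert suv.value_kind is ValueKind.SUV

    def test_zero_concentration_gives_zero(self):
        suv = to_suv(self._pet(np.zeros((4, 4, 4))), self._meta())
        np.testing.assert_array_equal(suv.values, 0.0)

    def test_hand_computed_single_voxel(self):
        suv = to_suv(self._pet(np.full((1, 1, 1), 5000.0)), self._meta())
        assert suv.values[0, 0, 0] == pytest.approx(HAND_SUV, rel=1e-12)

    def test_no_uptake_means_no_decay(self):
        meta = self._meta(uptake_time_min=0.0)
        assert meta.activity_at_scan_bq() == pytest.approx(222.0e6)

    def test_requires_activity_input(self):
        pet = ImageVolume(np.ones((2, 2, 2)), (4, 4, 4), modality=Modality.PET_NAF,
                          value_kind=ValueKind.SUV)
        with pytest.raises(ValueError, match="ACTIVITY_CONC"):
            to_suv(pet, self._meta())

    @given(scale=st.floats(0.01, 100.0))
    def test_conversion_is_linear(self, scale):
        meta = self._meta()
        base = np.linspace(0, 9000, 8).reshape(2, 2, 2)
        one = to_suv(self._pet(base), meta).values
        scaled = to_suv(self._pet(scale * base), meta).values
        np.testing.assert_allclose(scaled, scale * one, rtol=1e-12)

    @pytest.mark.parametrize("field", ["injected_activity_mbq", "body_weight_kg", "half_life_min"])
    def test_nonpositive_metadata_rejected(self, field):
        with pytest.raises(ValueError):
            self._meta(**{field: 0.0})


class TestStudyPair:
    def test_grid_mismatch_detected(self, small_phantom):
        study, _ = small_phantom
        bad = ImageVolume(np.zeros((4, 4, 4)), (4, 4, 4), modality=Modality.PET_NAF,
                          value_kind=ValueKind.SUV)
        from dataclasses import replace

        with pytest.raises(ValueError, match="grids differ"):
            replace(study, naf=bad).validate_grid()

    def test_negative_psa_rejected(self, small_phantom):
        study, _ = small_phantom
        from dataclasses import replace

        with pytest.raises(ValueError, match="psa"):
            replace(study, psa=-1.0)
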