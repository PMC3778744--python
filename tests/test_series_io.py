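import nibabel as nib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from perfquant.errors import ConfigurationError, DimensionError
from perfquant.series_io import (
    Layout,
    PerfusionSeries,
    read_series,
    reorganize,
    write_map_nifti,
)


def _write_nifti(path, xyzt, dt=None, slope=None, inter=None, dtype=np.int16,
                 time_units="sec"):
    img = nib.Nifti1Image(np.asarray(xyzt, dtype=dtype), np.eye(4))
    if dt is not None:
        img.header["pixdim"][4] = dt
        img.header.set_xyzt_units("mm", time_units)
    if slope is not None:
        img.header["scl_slope"] = slope
        img.header["scl_inter"] = inter
    nib.save(img, str(path))
    return path


def _make_series(data_tzyx, dims, dt=1.0):
    return PerfusionSeries(
        data=np.asarray(data_tzyx, dtype=np.float64),
        dims=dims,
        dt=dt,
        layout=Layout.TIME_MAJOR,
        affine=np.eye(4),
    )


class TestReadSeries:
    def test_identity_read_small_volume(self, tmp_path):
        """A 2x2x1x3 file containing 0..11 loads as those values, time major."""
        xyzt = np.arange(12).reshape(2, 2, 1, 3, order="F")
        path = _write_nifti(tmp_path / "s.nii", xyzt, dt=2.0)
        s = read_series(path)
        assert s.dims == (2, 2, 1, 3)
        assert s.layout is Layout.TIME_MAJOR
        assert s.dt == 2.0
        assert sorted(s.data.ravel().tolist()) == list(range(12))
        # value at (x, y, z, t) must land at data[t, z, y, x]
        for x in range(2):
            for y in range(2):
                for t in range(3):
                    assert s.data[t, 0, y, x] == xyzt[x, y, 0, t]

    def test_dt_override_beats_header(self, tmp_path):
        xyzt = np.zeros((4, 4, 2, 5))
        path = _write_nifti(tmp_path / "s.nii", xyzt, dt=2.0)
        assert read_series(path, dt_override=1.5).dt == 1.5

    def test_scale_slope_and_intercept_applied(self, tmp_path):
        """Stored 5 with slope 2 and intercept 1 reads back as 11.0."""
        xyzt = np.full((2, 2, 1, 2), 5, dtype=np.int16)
        path = _write_nifti(tmp_path / "s.nii", xyzt, dt=1.0, slope=2.0, inter=1.0)
        s = read_series(path)
        assert np.all(s.data == 11.0)

    def test_msec_header_units_converted(self, tmp_path):
        xyzt = np.zeros((2, 2, 1, 3))
        path = _write_nifti(tmp_path / "s.nii", xyzt, dt=1500.0, time_units="msec")
        assert read_series(path).dt == pytest.approx(1.5)

    def test_non_4d_input_rejected(self, tmp_path):
        img = nib.Nifti1Image(np.zeros((4, 4, 2), dtype=np.int16), np.eye(4))
        nib.save(img, str(tmp_path / "s3.nii"))
        with pytest.raises(DimensionError):
            read_series(tmp_path / "s3.nii")

    def test_missing_time_step_without_override(self, tmp_path):
        img = nib.Nifti1Image(np.zeros((2, 2, 1, 3), dtype=np.int16), np.eye(4))
        img.header["pixdim"][4] = 0.0  # scanner wrote no frame timing
        nib.save(img, str(tmp_path / "s.nii"))
        with pytest.raises(ConfigurationError):
            read_series(tmp_path / "s.nii")


class TestReorganize:
    def test_labeled_values_land_at_predicted_indices(self):
        """A[t,z,y,x] = 1000t + 100z + 10y + x moves to A'[z,y,x,t] unchanged."""
        d1, d2, d3, nt = 3, 2, 2, 2  # x, y, z, time
        a = np.empty((nt, d3, d2, d1))
        for t in range(nt):
            for z in range(d3):
                for y in range(d2):
                    for x in range(d1):
                        a[t, z, y, x] = 1000 * t + 100 * z + 10 * y + x
        s = _make_series(a, (d1, d2, d3, nt))
        v = reorganize(s, Layout.VOXEL_MAJOR)
        assert v.layout is Layout.VOXEL_MAJOR
        for t in range(nt):
            for z in range(d3):
                for y in range(d2):
                    for x in range(d1):
                        assert v.data[z, y, x, t] == 1000 * t + 100 * z + 10 * y + x

    def test_single_voxel_series_is_order_preserving(self):
        a = np.arange(5.0).reshape(5, 1, 1, 1)
        v = reorganize(_make_series(a, (1, 1, 1, 5)), Layout.VOXEL_MAJOR)
        assert np.array_equal(v.data.ravel(), np.arange(5.0))

    def test_same_layout_call_is_identity(self):
        s = _make_series(np.zeros((3, 1, 2, 2)), (2, 2, 1, 3))
        assert reorganize(s, Layout.TIME_MAJOR) is s

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        hnp.arrays(
            np.float64,
            st.tuples(st.integers(2, 5), st.integers(1, 4),
                      st.integers(1, 4), st.integers(1, 4)),
            elements=st.floats(-1e6, 1e6),
        )
    )
    def test_round_trip_is_elementwise_identity(self, arr):
        nt, d3, d2, d1 = arr.shape
        s = _make_series(arr, (d1, d2, d3, nt))
        back = reorganize(reorganize(s, Layout.VOXEL_MAJOR), Layout.TIME_MAJOR)
        assert np.array_equal(back.data, arr)
        # bijection on positions: the multiset of values is preserved
        vox = reorganize(s, Layout.VOXEL_MAJOR)
        assert np.array_equal(np.sort(vox.data.ravel()), np.sort(arr.ravel()))


class TestWriteMapNifti:
    def _ref(self):
        return _make_series(np.zeros((3, 2, 4, 5)), (5, 4, 2, 3))

    def test_round_trip_under_random_mask(self, tmp_path, rng):
        ref = self._ref()
        map3d = rng.normal(size=ref.spatial_shape)
        mask = rng.random(ref.spatial_shape) > 0.4
        write_map_nifti(map3d, mask, ref, tmp_path / "m.nii")
        back = np.asarray(nib.load(str(tmp_path / "m.nii")).dataobj).transpose(2, 1, 0)
        assert np.allclose(back[mask], map3d[mask].astype(np.float32))
        assert np.all(np.isnan(back[~mask]))

    def test_all_false_mask_writes_nan_volume(self, tmp_path):
        ref = self._ref()
        write_map_nifti(np.full(ref.spatial_shape, 7.0),
                        np.zeros(ref.spatial_shape, bool), ref, tmp_path / "m.nii")
        back = np.asarray(nib.load(str(tmp_path / "m.nii")).dataobj)
        assert np.all(np.isnan(back))

    def test_dimension_mismatch_rejected(self, tmp_path):
        ref = self._ref()
        with pytest.raises(DimensionError):
            write_map_nifti(np.zeros((1, 1, 1)), np.ones((1, 1, 1), bool),
                            ref, tmp_path / "m.nii")


class TestPerfusionSeriesInvariants:
    def test_layout_tag_must_match_axis_order(self):
        with pytest.raises(DimensionError):
            PerfusionSeries(np.zeros((2, 3, 4, 5)), (5, 4, 3, 2), 1.0,
                            Layout.VOXEL_MAJOR, np.eye(4))

    def test_dt_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            _make_series(np.zeros((3, 1, 2, 2)), (2, 2, 1, 3), dt=0.0)
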