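import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perfquant.aif import (
    AIFVector,
    aif_from_labels,
    build_aif_matrix,
    generate_local_aif,
    read_aif_text,
    select_global_aif,
)
from perfquant.errors import ConfigurationError, DimensionError
from perfquant.series_io import Layout, PerfusionSeries, reorganize
from perfquant.synth import PHANTOM_MASK_FRAC
from perfquant.preprocess import compute_brain_mask


class TestBuildAIFMatrix:
    def test_three_sample_structure(self):
        m = build_aif_matrix(AIFVector([2.0, 3.0, 5.0], dt=2.0)).matrix
        assert np.array_equal(m, [[4, 0, 0], [6, 4, 0], [10, 6, 4]])

    def test_unit_impulse_gives_identity(self):
        aif = AIFVector(np.r_[1.0, np.zeros(4)], dt=1.0)
        assert np.array_equal(build_aif_matrix(aif).matrix, np.eye(5))

    def test_two_sample_scaling(self):
        m = build_aif_matrix(AIFVector([2.0, 1.0], dt=0.5)).matrix
        assert np.array_equal(m, [[1.0, 0.0], [0.5, 1.0]])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.integers(2, 80),
        st.floats(0.1, 5.0),
        st.integers(0, 2**31 - 1),
    )
    def test_structure_and_determinant(self, n, dt, seed):
        """Lower-triangular Toeplitz with entry dt*Ca[i-j]; det = (dt*Ca[0])^N."""
        rng = np.random.default_rng(seed)
        ca = rng.uniform(0.5, 2.0, size=n)
        m = build_aif_matrix(AIFVector(ca, dt)).matrix
        assert np.array_equal(m, np.tril(m))
        i, j = np.indices((n, n))
        lower = i >= j
        assert np.allclose(m[lower], dt * ca[(i - j)[lower]])
        sign, logdet = np.linalg.slogdet(m)
        assert sign == 1.0
        # LU-based slogdet roundoff grows with n and conditioning
        assert logdet == pytest.approx(n * np.log(dt * ca[0]), rel=1e-3, abs=1e-6)

    def test_empty_aif_rejected(self):
        with pytest.raises(DimensionError):
            AIFVector([], dt=1.0)


def _vox(data_zyxt, dt=1.0):
    d3, d2, d1, nt = data_zyxt.shape
    return PerfusionSeries(np.asarray(data_zyxt, np.float64), (d1, d2, d3, nt),
                           dt, Layout.VOXEL_MAJOR, np.eye(4))


def brute_force_top_k(curves, flat_idx, top_k):
    """Score = peak/(1+ttp index); pick top_k by (score desc, index asc)."""
    scored = sorted(
        range(len(curves)),
        key=lambda i: (-(curves[i].max() / (1 + int(curves[i].argmax()))), flat_idx[i]),
    )
    return [flat_idx[i] for i in scored[:top_k]]


class TestGlobalAIFSelection:
    def test_phantom_arterial_voxels_selected(self, tiny_phantom):
        """Selection must find exactly the phantom's arterial strip."""
        series, truth = tiny_phantom
        vox = reorganize(series, Layout.VOXEL_MAJOR)
        mask = compute_brain_mask(vox, PHANTOM_MASK_FRAC)
        curves = vox.data.reshape(-1, vox.n_time)
        flat_idx = np.flatnonzero(mask.ravel())
        n_arterial = 8  # 4x1 strip in both slices
        chosen = brute_force_top_k(curves[flat_idx], flat_idx, n_arterial)
        arterial = np.flatnonzero(np.abs(
            curves - truth.aif.values
        ).max(axis=1) == 0.0)
        assert sorted(chosen) == sorted(arterial.tolist())
        got = select_global_aif(vox, mask, top_k=n_arterial)
        assert np.array_equal(got.values, truth.aif.values)

    def test_single_voxel_mask_returns_curve_verbatim(self, rng):
        data = rng.random((1, 2, 2, 6))
        vox = _vox(data)
        mask = np.zeros((1, 2, 2), bool)
        mask[0, 1, 0] = True
        got = select_global_aif(vox, mask, top_k=1)
        assert np.array_equal(got.values, data[0, 1, 0])

    def test_mean_of_identical_candidates_is_their_curve(self):
        data = np.zeros((1, 1, 3, 5))
        data[0, 0, :2] = [0.0, 3.0, 1.0, 0.5, 0.2]
        data[0, 0, 2] = [0.0, 0.1, 0.05, 0.0, 0.0]
        got = select_global_aif(_vox(data), np.ones((1, 1, 3), bool), top_k=2)
        assert np.array_equal(got.values, data[0, 0, 0])

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ConfigurationError):
            select_global_aif(_vox(np.ones((1, 1, 2, 4))),
                              np.ones((1, 1, 2), bool), top_k=3)


class TestLocalAIF:
    def test_neighbourhood_containing_arterial_voxels(self, tiny_phantom):
        series, truth = tiny_phantom
        vox = reorganize(series, Layout.VOXEL_MAJOR)
        mask = compute_brain_mask(vox, PHANTOM_MASK_FRAC)
        fallback = AIFVector(np.ones(vox.n_time), vox.dt)
        # voxel adjacent to the arterial strip at y=0, x in [6,10)
        got = generate_local_aif(vox, (7, 2, 0), radius=3, top_k=4,
                                 fallback=fallback, mask=mask)
        assert np.array_equal(got.values, truth.aif.values)

    def test_all_zero_neighbourhood_falls_back(self):
        data = np.zeros((1, 8, 8, 5))
        fallback = AIFVector([1.0, 2.0, 1.0, 0.5, 0.2], 1.0)
        got = generate_local_aif(_vox(data), (4, 4, 0), radius=2, top_k=2,
                                 fallback=fallback)
        assert got is fallback

    def test_whole_volume_neighbourhood_equals_global(self, tiny_phantom):
        series, _ = tiny_phantom
        vox = reorganize(series, Layout.VOXEL_MAJOR)
        mask = compute_brain_mask(vox, PHANTOM_MASK_FRAC)
        fallback = AIFVector(np.ones(vox.n_time), vox.dt)
        local = generate_local_aif(vox, (8, 8, 0), radius=20, top_k=5,
                                   fallback=fallback, mask=mask)
        global_ = select_global_aif(vox, mask, top_k=5)
        assert np.array_equal(local.values, global_.values)


class TestExternalAIFInputs:
    def test_text_vector_round_trip(self, tmp_path):
        values = np.array([0.0, 1.5, 3.25, 1.0])
        np.savetxt(tmp_path / "aif.txt", values)
        got = read_aif_text(tmp_path / "aif.txt", dt=1.5)
        assert np.array_equal(got.values, values)
        assert got.dt == 1.5

    def test_label_volume_averages_label_one(self, rng):
        data = rng.random((1, 2, 3, 4))
        labels = np.zeros((1, 2, 3), dtype=int)
        labels[0, 0, 1] = labels[0, 1, 2] = 1
        got = aif_from_labels(_vox(data), labels)
        expected = (data[0, 0, 1] + data[0, 1, 2]) / 2
        assert np.allclose(got.values, expected)

    def test_empty_label_volume_rejected(self):
        with pytest.raises(ConfigurationError):
            aif_from_labels(_vox(np.ones((1, 1, 2, 3))), np.zeros((1, 1, 2), int))
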