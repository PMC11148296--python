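"""Texture-feature families: filters, shape, first-order, GLCM, extraction."""

import numpy as np
import pytest

from _oracles import (
    firstorder_oracle, glcm_counts_oracle, glcm_features_oracle,
)
from habitex.errors import InvalidScaleError
from habitex.features import (
    apply_log_filter, apply_wavelet_bank, extract_all, FeatureConfig,
    firstorder_features, glcm_compute, glcm_features,
    reconstruct_wavelet_bank, shape_features,
)
from habitex.features.extract import feature_names
from habitex.features.filters import WAVELET_SUBBANDS
from habitex.features.glcm import GLCM_FEATURE_NAMES, GlcmMatrix, OFFSETS_13
from habitex.imaging_io import VolumeGrid


# ---------------------------------------------------------------------------
# Laplacian of Gaussian


def test_log_of_constant_is_zero():
    vol = VolumeGrid(np.full((16, 16, 16), 42.0), (1, 1, 1))
    assert np.abs(apply_log_filter(vol, 2.0).data).max() < 1e-9


def test_log_of_linear_ramp_is_zero_in_interior():
    # interior = beyond the smoothing kernel radius (4 sigma) + 1 stencil voxel
    ramp = np.broadcast_to(np.arange(30.0), (30, 30, 30)).copy()
    out = apply_log_filter(VolumeGrid(ramp, (1, 1, 1)), 2.0)
    assert np.abs(out.data[10:-10, 10:-10, 10:-10]).max() < 1e-9


def test_log_of_gaussian_blob_matches_closed_form():
    """Peak |LoG| of a Gaussian blob: 3 A s0^3 / (s0^2 + s^2)^(5/2)."""
    s0, s, amp, n = 4.0, 2.0, 10.0, 57
    ax = np.arange(n) - n // 2
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    blob = amp * np.exp(-(z**2 + y**2 + x**2) / (2 * s0**2))
    resp = apply_log_filter(VolumeGrid(blob, (1, 1, 1)), s)
    peak = np.abs(resp.data).max()
    expected = 3 * amp * s0**3 / (s0**2 + s**2) ** 2.5
    assert peak == pytest.approx(expected, rel=0.02)


def test_log_scale_is_physical_not_voxel(rng):
    """The same physical field sampled at two spacings gives the same
    response at matching physical locations."""
    s0 = 6.0
    ax1 = np.arange(48) - 24.0
    z, y, x = np.meshgrid(ax1, ax1, ax1, indexing="ij")
    blob1 = np.exp(-(z**2 + y**2 + x**2) / (2 * s0**2))
    ax2 = (np.arange(24) - 12.0) * 2.0
    z2, y2, x2 = np.meshgrid(ax2, ax2, ax2, indexing="ij")
    blob2 = np.exp(-(z2**2 + y2**2 + x2**2) / (2 * s0**2))
    r1 = apply_log_filter(VolumeGrid(blob1, (1, 1, 1)), 3.0)
    r2 = apply_log_filter(VolumeGrid(blob2, (2, 2, 2)), 3.0)
    assert np.abs(r1.data).max() == pytest.approx(np.abs(r2.data).max(),
                                                  rel=0.05)


def test_log_sigma_too_large_rejected():
    vol = VolumeGrid(np.zeros((10, 10, 10)), (1, 1, 1))
    with pytest.raises(InvalidScaleError):
        apply_log_filter(vol, 6.0)


# ---------------------------------------------------------------------------
# wavelet bank


def test_wavelet_constant_maps_to_lll_only():
    vol = VolumeGrid(np.full((16, 16, 16), 3.25), (1, 1, 1))
    sub = apply_wavelet_bank(vol)
    assert set(sub) == set(WAVELET_SUBBANDS)
    assert np.allclose(sub["LLL"].data, 3.25, atol=1e-12)
    for b in WAVELET_SUBBANDS[1:]:
        assert np.abs(sub[b].data).max() < 1e-9


def test_wavelet_nyquist_sinusoid_energy_in_x_highpass(rng):
    """A Nyquist oscillation along x concentrates in the *,*,H subbands."""
    x = np.arange(16)
    vol_data = np.broadcast_to((-1.0) ** x, (16, 16, 16)).copy()
    sub = apply_wavelet_bank(VolumeGrid(vol_data, (1, 1, 1)))
    e = {b: float((sub[b].data ** 2).sum()) for b in WAVELET_SUBBANDS}
    e_h = sum(v for b, v in e.items() if b[2] == "H")
    e_l = sum(v for b, v in e.items() if b[2] == "L")
    assert e_h > 100 * e_l


def test_wavelet_perfect_reconstruction(rng):
    vol = VolumeGrid(rng.standard_normal((16, 12, 10)), (1, 1, 1))
    rec = reconstruct_wavelet_bank(apply_wavelet_bank(vol))
    assert np.abs(rec.data - vol.data).max() < 1e-6


def test_wavelet_rejects_tiny_volume(rng):
    with pytest.raises(ValueError):
        apply_wavelet_bank(VolumeGrid(rng.random((4, 16, 16)), (1, 1, 1)))


# ---------------------------------------------------------------------------
# shape


def test_single_voxel_diameters_are_cube_diagonals():
    mask = np.zeros((5, 5, 5), dtype=bool)
    mask[2, 2, 2] = True
    f = shape_features(mask, (1, 1, 1))
    assert f["Maximum3DDiameter"] == pytest.approx(np.sqrt(3))
    assert f["Maximum2DDiameterColumn"] == pytest.approx(np.sqrt(2))
    assert f["VoxelVolume"] == 1.0
    assert all(np.isfinite(v) for v in f.values())


def test_rod_dominates_coronal_diameter():
    mask = np.zeros((3, 3, 12), dtype=bool)
    mask[1, 1, 1:11] = True  # 10 voxels along x
    f = shape_features(mask, (1, 1, 1))
    assert f["Maximum2DDiameterColumn"] >= 10.0
    assert f["Flatness"] < 0.3  # a rod is anything but isotropic


def test_sphere_volume_and_sphericity():
    r = 10.0
    ax = np.arange(26) - 12.5
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    mask = z**2 + y**2 + x**2 <= r**2
    f = shape_features(mask, (1, 1, 1))
    assert f["MeshVolume"] == pytest.approx(4 / 3 * np.pi * r**3, rel=0.02)
    assert f["Sphericity"] == pytest.approx(1.0, rel=0.02)
    # corner-based diameter overshoots 2r by at most one voxel diagonal
    assert 2 * r <= f["Maximum3DDiameter"] <= 2 * r + 2.0


def test_shape_translation_invariance_and_spacing_scaling(rng):
    mask = np.zeros((12, 12, 12), dtype=bool)
    mask[3:7, 4:9, 2:6] = True
    f0 = shape_features(mask, (1, 1, 1))
    shifted = np.roll(mask, (2, 1, 3), axis=(0, 1, 2))
    f1 = shape_features(shifted, (1, 1, 1))
    for k in f0:
        assert f0[k] == pytest.approx(f1[k], rel=1e-9)
    f2 = shape_features(mask, (2, 2, 2))
    for k in ("Maximum3DDiameter", "Maximum2DDiameterSlice",
              "Maximum2DDiameterColumn", "Maximum2DDiameterRow"):
        assert f2[k] == pytest.approx(2 * f0[k], rel=1e-9)


# ---------------------------------------------------------------------------
# first order


def test_firstorder_hand_arithmetic():
    f = firstorder_features(np.array([1.0, 2, 3, 4]), 1.0, 5.0)
    assert f["Mean"] == 2.5
    assert f["Range"] == 3.0
    assert f["Variance"] == 1.25


def test_firstorder_constant_sample_degenerates_cleanly():
    f = firstorder_features(np.full(20, 9.0), 2.0, 5.0)
    assert f["Variance"] == 0.0
    assert f["Skewness"] == 0.0
    assert f["Entropy"] == 0.0
    assert f["Uniformity"] == 1.0
    assert f["TotalEnergy"] == pytest.approx(2.0 * 20 * 81.0)


def test_firstorder_normal_sample_moments(rng):
    x = rng.standard_normal(10_000)
    f = firstorder_features(x, 1.0, 0.5)
    assert f["Skewness"] == pytest.approx(0.0, abs=0.05)
    assert f["Kurtosis"] == pytest.approx(3.0, abs=0.1)  # Pearson convention


def test_firstorder_matches_independent_oracle(rng):
    for _ in range(10):
        vals = rng.uniform(-50, 150, int(rng.integers(20, 300)))
        mine = firstorder_features(vals, 1.7, 5.0)
        ref = firstorder_oracle(vals, 1.7, 5.0)
        for k, v in ref.items():
            assert mine[k] == pytest.approx(v, rel=1e-10, abs=1e-10), k


# ---------------------------------------------------------------------------
# GLCM


def test_glcm_toy_grid_rowwise_pairs():
    binned = np.array([[[1, 1], [2, 2]]])  # shape (1, 2, 2)
    mask = np.ones_like(binned, dtype=bool)
    g = glcm_compute(binned, mask, offsets=((0, 0, 1),))
    assert g.p.shape == (1, 2, 2)
    assert g.p[0, 0, 0] == pytest.approx(0.5)
    assert g.p[0, 1, 1] == pytest.approx(0.5)
    assert g.p[0, 0, 1] == 0.0


def test_glcm_constant_region_degenerate_identities():
    binned = np.ones((4, 4, 4), dtype=np.int64)
    g = glcm_compute(binned, np.ones((4, 4, 4), dtype=bool))
    f = glcm_features(g)
    assert f["Idm"] == 1.0
    assert f["ClusterShade"] == 0.0
    assert f["Imc2"] == 0.0
    assert f["MaximumProbability"] == 1.0


def test_glcm_matrices_normalized_and_symmetric(rng):
    binned = rng.integers(1, 7, (6, 6, 6))
    mask = rng.random((6, 6, 6)) > 0.3
    g = glcm_compute(binned, mask)
    for d in range(g.p.shape[0]):
        assert g.p[d].sum() == pytest.approx(1.0)
        assert np.allclose(g.p[d], g.p[d].T)


def test_glcm_counts_match_pair_enumeration(rng):
    binned = rng.integers(1, 5, (5, 5, 5))
    mask = rng.random((5, 5, 5)) > 0.25
    for off in ((0, 0, 1), (1, -1, 0), (1, 1, 1)):
        got = glcm_compute(binned, mask, offsets=(off,))
        ref = glcm_counts_oracle(binned, mask, off)
        assert np.allclose(got.p[0], ref / ref.sum())


def test_glcm_features_match_definition_oracle(rng):
    """Random 5x5 matrices: all 24 features vs an independent coding."""
    for _ in range(25):
        m = rng.random((5, 5))
        m = m + m.T
        p = m / m.sum()
        mine = glcm_features(GlcmMatrix(p=p[None], offsets=((0, 0, 1),)))
        ref = glcm_features_oracle(p)
        for k in GLCM_FEATURE_NAMES:
            assert mine[k] == pytest.approx(ref[k], abs=1e-10), k


def test_cluster_shade_zero_for_symmetric_gray_distribution():
    # palindromic matrix: p(i,j) = p(ng+1-i, ng+1-j)
    p = np.array([[0.1, 0.2, 0.0],
                  [0.2, 0.0, 0.2],
                  [0.0, 0.2, 0.1]])
    f = glcm_features(GlcmMatrix(p=p[None] / p.sum(), offsets=((0, 0, 1),)))
    assert f["ClusterShade"] == pytest.approx(0.0, abs=1e-12)


def test_glcm_rotation_invariance_of_direction_average(rng):
    """90-degree in-plane rotation leaves the 13-direction mean unchanged."""
    binned = rng.integers(1, 6, (8, 8, 8))
    mask = rng.random((8, 8, 8)) > 0.3
    f0 = glcm_features(glcm_compute(binned, mask))
    rot_b = np.rot90(binned, k=1, axes=(1, 2))
    rot_m = np.rot90(mask, k=1, axes=(1, 2))
    f1 = glcm_features(glcm_compute(rot_b, rot_m))
    for k in GLCM_FEATURE_NAMES:
        assert f0[k] == pytest.approx(f1[k], abs=1e-9), k


# ---------------------------------------------------------------------------
# full extraction


def test_feature_count_with_single_log_scale():
    cfg = FeatureConfig(log_sigmas_mm=(4.0,))
    names = feature_names(cfg)
    assert len(names) == 14 + 10 * (18 + 24) == 434
    assert "log_sigma_4_0_mm_3D_glcm_Imc2" in names
    assert "wavelet_LLH_glcm_Idm" in names
    assert "original_shape_Maximum2DDiameterColumn" in names


def test_extraction_is_deterministic_and_finite(phantom_study):
    f1 = extract_all(phantom_study)
    f2 = extract_all(phantom_study)
    assert f1 == f2
    assert list(f1) == feature_names()
    assert all(np.isfinite(v) for v in f1.values())


def test_extraction_invariant_to_global_intensity_scale(phantom_study):
    """z-scoring makes the discretized features blind to a global gain."""
    import copy
    scaled = copy.deepcopy(phantom_study)
    for v in scaled.volumes:
        v.data = v.data * 3.7
    f0 = extract_all(phantom_study)
    f1 = extract_all(scaled)
    for k in f0:
        if "_glcm_" in k or "_shape_" in k:
            assert f1[k] == pytest.approx(f0[k], rel=1e-9), k
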