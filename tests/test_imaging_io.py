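"""NIfTI round trips and the three preprocessing operators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from habitex.errors import (
    DegenerateIntensityError, DegenerateVOIError, GridMismatchError,
)
from habitex.imaging_io import (
    PreprocessConfig, VolumeGrid, discretize_fixed_binwidth, load_dce_series,
    load_volume, normalize_mu3sigma, resample_isotropic, save_volume,
)
from habitex.phantom import write_study


def test_nifti_round_trip(tmp_path, rng):
    vol = VolumeGrid(rng.random((6, 7, 8)) * 100, (1.2, 1.0, 0.9))
    save_volume(vol, tmp_path / "v.nii.gz")
    back = load_volume(tmp_path / "v.nii.gz")
    assert back.shape == vol.shape
    assert back.spacing == pytest.approx(vol.spacing)
    assert np.allclose(back.data, vol.data, atol=1e-5)


def test_load_dce_series_from_phantom(tmp_path, phantom_study):
    write_study(phantom_study, tmp_path)
    paths = [tmp_path / f"phase_{i}.nii.gz" for i in range(7)]
    study = load_dce_series(paths, tmp_path / "voi.nii.gz")
    assert len(study.volumes) == 7
    assert study.voi.sum() == phantom_study.voi.sum()


def test_load_rejects_grid_mismatch(tmp_path, rng):
    save_volume(VolumeGrid(rng.random((6, 6, 6)), (1, 1, 1)), tmp_path / "a.nii.gz")
    save_volume(VolumeGrid(rng.random((6, 6, 5)), (1, 1, 1)), tmp_path / "b.nii.gz")
    save_volume(VolumeGrid(np.ones((6, 6, 6)), (1, 1, 1)), tmp_path / "m.nii.gz")
    with pytest.raises(GridMismatchError):
        load_dce_series([tmp_path / "a.nii.gz", tmp_path / "b.nii.gz"],
                        tmp_path / "m.nii.gz")


def test_mask_binarization_preserves_voxel_count(tmp_path, rng):
    vol = VolumeGrid(rng.random((6, 6, 6)), (1, 1, 1))
    labels = np.zeros((6, 6, 6))
    labels[rng.random((6, 6, 6)) > 0.6] = 2  # labels {0, 2}
    save_volume(vol, tmp_path / "p0.nii.gz")
    save_volume(vol, tmp_path / "p1.nii.gz")
    save_volume(VolumeGrid(labels, (1, 1, 1)), tmp_path / "m.nii.gz")
    study = load_dce_series([tmp_path / "p0.nii.gz", tmp_path / "p1.nii.gz"],
                            tmp_path / "m.nii.gz")
    assert set(np.unique(study.voi)) <= {False, True}
    assert study.voi.sum() == np.count_nonzero(labels == 2)


# ---------------------------------------------------------------------------
# resampling


def test_identity_resample_preserves_values(rng):
    vol = VolumeGrid(rng.random((12, 12, 12)), (1, 1, 1))
    out, _ = resample_isotropic(vol)
    assert out.shape == vol.shape
    assert np.allclose(out.data, vol.data, atol=1e-6)


def test_constant_volume_resamples_to_constant():
    vol = VolumeGrid(np.full((10, 10, 10), 7.25), (2.0, 1.5, 1.0))
    out, _ = resample_isotropic(vol)
    assert np.allclose(out.data, 7.25, atol=1e-6)


def test_linear_ramp_resample_matches_analytic_values():
    """Downsampling a 2 mm ramp: new voxel centers hit the analytic line."""
    n = 16
    x_mm = np.arange(n) * 2.0  # center of voxel i sits at 2i mm
    ramp = np.broadcast_to(x_mm, (n, n, n)).copy()
    vol = VolumeGrid(ramp, (2.0, 2.0, 2.0))
    out, _ = resample_isotropic(vol)
    # spline boundary effects decay geometrically; stay 12 voxels inside
    interior = out.data[12:-12, 12:-12, 12:-12]
    expect = np.broadcast_to(np.arange(out.shape[2]) * 1.0,
                             out.shape)[12:-12, 12:-12, 12:-12]
    assert np.allclose(interior, expect, atol=1e-3)


def test_resampling_conserves_voi_volume(phantom_study):
    mask = phantom_study.voi
    spacing = phantom_study.volumes[0].spacing
    vol = phantom_study.volumes[1]
    _, mask_rs = resample_isotropic(vol, mask.astype(np.uint8))
    v_in = mask.sum() * np.prod(spacing)
    v_out = mask_rs.data.sum() * 1.0
    assert v_out == pytest.approx(v_in, rel=0.05)


def test_empty_mask_after_resampling_raises():
    vol = VolumeGrid(np.zeros((8, 8, 8)), (1, 1, 1))
    mask = np.zeros((8, 8, 8), dtype=np.uint8)
    with pytest.raises(DegenerateVOIError):
        resample_isotropic(vol, mask)


# ---------------------------------------------------------------------------
# normalization


def test_normalization_scale_and_clipping(rng):
    # uniform sample: |z| < sqrt(3) << 3, so nothing is clipped
    x = rng.uniform(0, 80, (16, 16, 16)) + 1000
    out = normalize_mu3sigma(VolumeGrid(x, (1, 1, 1)), PreprocessConfig())
    assert out.data.mean() == pytest.approx(0.0, abs=1e-9)
    assert out.data.std() == pytest.approx(100.0, abs=1e-9)
    x[0, 0, 0] = x.mean() + 10 * x.std()  # a gross outlier
    out = normalize_mu3sigma(VolumeGrid(x, (1, 1, 1)))
    assert out.data[0, 0, 0] == pytest.approx(300.0)


def test_normalization_round_trip_on_unclipped_voxels(rng):
    x = rng.standard_normal((10, 10, 10)) * 5 + 50
    vol = VolumeGrid(x, (1, 1, 1))
    out = normalize_mu3sigma(vol)
    back = out.data / 100.0 * x.std() + x.mean()
    unclipped = np.abs(out.data) < 300
    assert np.allclose(back[unclipped], x[unclipped], atol=1e-9)


def test_constant_volume_cannot_be_normalized():
    with pytest.raises(DegenerateIntensityError):
        normalize_mu3sigma(VolumeGrid(np.full((5, 5, 5), 3.0), (1, 1, 1)))


# ---------------------------------------------------------------------------
# discretization


def test_discretize_examples():
    assert discretize_fixed_binwidth(np.array([0, 4.9, 5, 12]), 5).tolist() \
        == [1, 1, 2, 3]
    assert discretize_fixed_binwidth(np.full(9, 2.2), 5).tolist() == [1] * 9


def test_discretize_uniform_sample(rng):
    vals = rng.uniform(0, 100, 10_000)
    vals[0], vals[1] = 0.0, 99.999  # pin the range
    bins = discretize_fixed_binwidth(vals, 5)
    assert bins.max() == 20
    counts = np.bincount(bins)[1:]
    assert np.all(np.abs(counts - 500) < 120)


@given(shift=st.floats(-1e4, 1e4), scale=st.floats(0.01, 100))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_discretize_shift_invariance_and_scale_equivariance(shift, scale):
    rng = np.random.default_rng(0)
    vals = rng.uniform(0, 50, 200)
    base = discretize_fixed_binwidth(vals, 5)
    assert (discretize_fixed_binwidth(vals + shift, 5) == base).all()
    assert (discretize_fixed_binwidth(vals * scale, 5 * scale) == base).all()
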