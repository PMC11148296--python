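"""Volume I/O and the three preprocessing operators applied before
feature extraction.

Conventions
-----------
Arrays are indexed ``(z, y, x)`` with ``spacing`` giving the voxel size in
mm along the same axes.  NIfTI files store data in ``(x, y, z)`` order, so
readers/writers transpose.  Masks are binarized on load (any nonzero voxel
is in-VOI).

The three preprocessing operators mirror the standard radiomics recipe:

* isotropic resampling to 1x1x1 mm (smooth interpolation for the image,
  nearest-neighbour for masks),
* mu +/- 3 sigma intensity normalization: z-score over the whole volume,
  rescale to ``scale`` (default 100), clip outliers beyond ``k`` standard
  deviations,
* fixed-bin-width gray-level discretization (default bin width 5 on
  normalized units).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .errors import (
    DegenerateIntensityError,
    DegenerateVOIError,
    GridMismatchError,
)

__all__ = [
    "VolumeGrid",
    "PreprocessConfig",
    "load_volume",
    "save_volume",
    "load_dce_series",
    "resample_isotropic",
    "normalize_mu3sigma",
    "discretize_fixed_binwidth",
]


@dataclass
class VolumeGrid:
    """A 3D scalar volume with voxel spacing in mm, axes ordered (z, y, x)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical_extent(self) -> tuple[float, float, float]:
        """Edge-to-edge physical size in mm along each axis."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def same_grid(self, other: "VolumeGrid", rtol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing, rtol=rtol
        )

    def copy_with(self, data: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(data, self.spacing, self.origin)


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``normalize_before_resample`` switches the order of the first two
    operators; the default (normalize, then resample, then discretize
    within the mask) makes the bins reflect final voxel values.
    """

    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bin_width: float = 5.0
    norm_scale: float = 100.0
    outlier_k: float = 3.0
    normalize_before_resample: bool = True

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.norm_scale <= 0:
            raise ValueError("norm_scale must be > 0")
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be > 0")


# ---------------------------------------------------------------------------
# NIfTI I/O


def load_volume(path: str | Path) -> VolumeGrid:
    """Read a NIfTI volume into (z, y, x) order."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise GridMismatchError(f"{path}: expected 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    data = np.transpose(data, (2, 1, 0))
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return VolumeGrid(data, spacing)


def save_volume(vol: VolumeGrid, path: str | Path) -> None:
    """Write a volume as NIfTI with a diagonal affine built from spacing."""
    sz, sy, sx = vol.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    data = np.transpose(np.asarray(vol.data), (2, 1, 0))
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_dce_series(
    volume_paths: Sequence[str | Path],
    voi_path: str | Path,
    times_s: Sequence[float] | None = None,
    label: str | None = None,
):
    """Load an ordered multi-phase series plus its VOI mask as a DceStudy.

    The first path is the pre-contrast ("plain") volume.  All volumes and
    the mask must share shape and spacing; the mask is binarized (any
    nonzero label is in-VOI).
    """
    from .phantom import DceStudy  # local import to avoid a cycle

    if len(volume_paths) < 2:
        raise GridMismatchError("need the plain volume plus at least one phase")
    volumes = [load_volume(p) for p in volume_paths]
    ref = volumes[0]
    for p, v in zip(volume_paths, volumes):
        if not v.same_grid(ref):
            raise GridMismatchError(
                f"{p}: grid {v.shape}/{v.spacing} does not match "
                f"{volume_paths[0]}: {ref.shape}/{ref.spacing}"
            )
    mask_vol = load_volume(voi_path)
    if not mask_vol.same_grid(ref):
        raise GridMismatchError("VOI mask grid does not match the volumes")
    voi = mask_vol.data != 0
    if not voi.any():
        raise DegenerateVOIError(f"VOI mask {voi_path} is empty")
    if times_s is None:
        times_s = [0.0] + [60.0 * i for i in range(1, len(volumes))]
    return DceStudy(
        volumes=volumes,
        times_s=list(float(t) for t in times_s),
        voi=voi,
        label=label,
    )


# ---------------------------------------------------------------------------
# Preprocessing operators


def _to_sitk(vol: VolumeGrid) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data, dtype=np.float64))
    img.SetSpacing(tuple(reversed(vol.spacing)))  # sitk wants (x, y, z)
    return img


def resample_isotropic(
    volume: VolumeGrid,
    mask: VolumeGrid | np.ndarray | None = None,
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[VolumeGrid, VolumeGrid | None]:
    """Resample image (B-spline) and mask (nearest-neighbour) to a common
    isotropic grid, preserving the physical extent within one voxel."""
    target = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target):
        raise ValueError("target spacing must be positive")

    new_shape = tuple(
        max(1, int(round(n * s / t)))
        for n, s, t in zip(volume.shape, volume.spacing, target)
    )
    img = _to_sitk(volume)
    resampler = sitk.ResampleImageFilter()
    resampler.SetOutputSpacing(tuple(reversed(target)))
    resampler.SetSize(tuple(int(n) for n in reversed(new_shape)))
    resampler.SetOutputOrigin(img.GetOrigin())
    resampler.SetOutputDirection(img.GetDirection())
    # voxels whose centers fall past the last input center take the edge
    # value instead of a zero background
    resampler.SetUseNearestNeighborExtrapolator(True)
    resampler.SetInterpolator(sitk.sitkBSpline)
    out = sitk.GetArrayFromImage(resampler.Execute(img))
    out_vol = VolumeGrid(out, target, volume.origin)

    out_mask = None
    if mask is not None:
        if isinstance(mask, np.ndarray):
            mask = VolumeGrid(mask.astype(np.uint8), volume.spacing, volume.origin)
        mimg = sitk.GetImageFromArray(
            np.ascontiguousarray(mask.data != 0, dtype=np.uint8)
        )
        mimg.SetSpacing(tuple(reversed(mask.spacing)))
        resampler.SetInterpolator(sitk.sitkNearestNeighbor)
        m = sitk.GetArrayFromImage(resampler.Execute(mimg))
        if not m.any():
            raise DegenerateVOIError("mask is empty after resampling")
        out_mask = VolumeGrid(m.astype(np.uint8), target, volume.origin)
    return out_vol, out_mask


def normalize_mu3sigma(
    volume: VolumeGrid, config: PreprocessConfig | None = None
) -> VolumeGrid:
    """mu +/- k sigma normalization over the whole volume.

    Output is ``scale * (x - mu) / sigma`` clipped to ``[-k*scale, k*scale]``.
    """
    cfg = config or PreprocessConfig()
    x = np.asarray(volume.data, dtype=np.float64)
    mu = x.mean()
    sigma = x.std()
    if sigma == 0:
        raise DegenerateIntensityError("volume has zero intensity variance")
    z = cfg.norm_scale * (x - mu) / sigma
    bound = cfg.outlier_k * cfg.norm_scale
    return volume.copy_with(np.clip(z, -bound, bound))


def discretize_fixed_binwidth(values: np.ndarray, bin_width: float = 5.0) -> np.ndarray:
    """Fixed-bin-width discretization: ``bin(x) = floor((x - min)/W) + 1``.

    Labels start at 1; the number of gray levels is ``bin(max)``.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot discretize an empty sample")
    bins = np.floor((values - values.min()) / bin_width).astype(np.int64) + 1
    return bins
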