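"""Laplacian-of-Gaussian and undecimated wavelet filter banks.

Both operate on the full (already resampled) volume before any masking, so
filter responses near the mask boundary see real image context.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

from ..errors import InvalidScaleError
from ..imaging_io import VolumeGrid

__all__ = ["apply_log_filter", "apply_wavelet_bank", "reconstruct_wavelet_bank",
           "WAVELET_SUBBANDS"]

#: Subband letter order corresponds to axes (z, y, x); L = low-pass.
WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def apply_log_filter(volume: VolumeGrid, sigma_mm: float) -> VolumeGrid:
    """Laplacian-of-Gaussian response at physical scale ``sigma_mm``.

    The Gaussian kernel is expressed in voxel units per axis so the scale
    is isotropic in mm even on anisotropic grids.  The response is the
    plain (non-scale-normalized) Laplacian of the smoothed image.
    """
    if sigma_mm <= 0:
        raise InvalidScaleError("sigma must be > 0")
    extent = volume.physical_extent()
    if sigma_mm > min(extent) / 2:
        raise InvalidScaleError(
            f"sigma {sigma_mm} mm exceeds half the field of view {extent}")
    sigma_vox = [sigma_mm / s for s in volume.spacing]
    data = np.asarray(volume.data, dtype=np.float64)
    smoothed = ndimage.gaussian_filter(data, sigma=sigma_vox, mode="nearest")
    # exact zero-sum discrete Laplacian in physical units: a truncated
    # Gaussian-derivative kernel would leak a nonzero response on constant
    # and linear fields, which the [1, -2, 1] stencil annihilates exactly
    out = np.zeros_like(data)
    for ax in range(3):
        d2 = ndimage.correlate1d(smoothed, np.array([1.0, -2.0, 1.0]),
                                 axis=ax, mode="nearest")
        out += d2 / volume.spacing[ax] ** 2
    return volume.copy_with(out)


def _even_pad(data: np.ndarray) -> tuple[np.ndarray, tuple[slice, ...]]:
    pads = [(0, n % 2) for n in data.shape]
    crop = tuple(slice(0, n) for n in data.shape)
    if any(p[1] for p in pads):
        data = np.pad(data, pads, mode="edge")
    return data, crop


def apply_wavelet_bank(volume: VolumeGrid, wavelet: str = "coif1"
                       ) -> dict[str, VolumeGrid]:
    """Single-level undecimated 3D separable wavelet decomposition.

    Returns 8 same-size subbands labeled LLL..HHH with letters ordered
    (z, y, x).  Filters are normalized so the low-pass DC gain is 1 (a
    constant volume maps to itself in LLL).  Odd-length axes are edge-padded
    to even length and the subbands cropped back.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    if min(data.shape) < 8:
        raise ValueError("volume must have at least 8 voxels per axis")
    w = pywt.Wavelet(wavelet)
    if min(data.shape) < w.dec_len:
        raise ValueError(f"axis shorter than the {wavelet} filter")
    padded, crop = _even_pad(data)
    coeffs = pywt.swtn(padded, wavelet, level=1, norm=True, trim_approx=False)[0]
    out = {}
    for key, arr in coeffs.items():
        label = key.replace("a", "L").replace("d", "H")
        out[label] = volume.copy_with(arr[crop])
    return out


def reconstruct_wavelet_bank(subbands: dict[str, VolumeGrid],
                             wavelet: str = "coif1") -> VolumeGrid:
    """Invert :func:`apply_wavelet_bank` (exact for even-length axes)."""
    any_vol = next(iter(subbands.values()))
    coeffs = {label.replace("L", "a").replace("H", "d"): np.asarray(v.data, float)
              for label, v in subbands.items()}
    rec = pywt.iswtn([coeffs], wavelet, norm=True)
    return any_vol.copy_with(rec)
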