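"""Per-study feature extraction: preprocessing, filter bank, all families.

The chain for one study is

    first-phase volume -> mu+/-3sigma normalization -> 1 mm^3 resampling
    -> {original, LoG(sigma set), 8 wavelet subbands}
    -> per image: fixed-bin-width discretization within the malignant mask
       -> first-order (18) + GLCM (24)
    plus the 14 shape features of the mask itself,

for a default total of 14 + 10 x 42 = 434 named features.  Names follow
``<image>_<family>_<feature>`` with image one of ``original``,
``log_sigma_<s>_mm_3D`` and ``wavelet_<subband>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..imaging_io import (
    PreprocessConfig,
    VolumeGrid,
    discretize_fixed_binwidth,
    normalize_mu3sigma,
    resample_isotropic,
)
from ..subregions import build_subregion_map, malignant_mask
from .filters import apply_log_filter, apply_wavelet_bank
from .firstorder import firstorder_features
from .glcm import glcm_compute, glcm_features
from .shape import shape_features

__all__ = ["FeatureConfig", "extract_all", "feature_names"]


@dataclass
class FeatureConfig:
    """Extraction settings: filter scales, wavelet family, preprocessing."""

    log_sigmas_mm: tuple[float, ...] = (2.0, 4.0)
    wavelet: str = "coif1"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    families: tuple[str, ...] = ("shape", "firstorder", "glcm")

    def image_names(self) -> list[str]:
        names = ["original"]
        names += [_log_name(s) for s in self.log_sigmas_mm]
        from .filters import WAVELET_SUBBANDS
        names += [f"wavelet_{b}" for b in WAVELET_SUBBANDS]
        return names

    def manifest(self) -> dict:
        return {
            "log_sigmas_mm": list(self.log_sigmas_mm),
            "wavelet": self.wavelet,
            "target_spacing_mm": list(self.preprocess.target_spacing),
            "bin_width": self.preprocess.bin_width,
            "norm_scale": self.preprocess.norm_scale,
            "outlier_k": self.preprocess.outlier_k,
            "normalize_before_resample": self.preprocess.normalize_before_resample,
            "families": list(self.families),
            "glcm": {"distance": 1, "n_directions": 13, "symmetric": True,
                     "aggregation": "mean over directions"},
            "subband_letter_axes": "zyx",
            "column_diameter_drops_axis": "y (anterior-posterior)",
        }


def _log_name(sigma: float) -> str:
    return "log_sigma_" + f"{sigma:.1f}".replace(".", "_") + "_mm_3D"


def feature_names(config: FeatureConfig | None = None) -> list[str]:
    """The stable, ordered list of feature names for a configuration."""
    from .firstorder import FIRSTORDER_FEATURE_NAMES
    from .glcm import GLCM_FEATURE_NAMES
    from .shape import SHAPE_FEATURE_NAMES

    cfg = config or FeatureConfig()
    names = []
    if "shape" in cfg.families:
        names += [f"original_shape_{f}" for f in SHAPE_FEATURE_NAMES]
    for img in cfg.image_names():
        if "firstorder" in cfg.families:
            names += [f"{img}_firstorder_{f}" for f in FIRSTORDER_FEATURE_NAMES]
        if "glcm" in cfg.families:
            names += [f"{img}_glcm_{f}" for f in GLCM_FEATURE_NAMES]
    return names


def _filter_images(vol: VolumeGrid, cfg: FeatureConfig) -> dict[str, VolumeGrid]:
    images = {"original": vol}
    for s in cfg.log_sigmas_mm:
        images[_log_name(s)] = apply_log_filter(vol, s)
    for band, sub in apply_wavelet_bank(vol, cfg.wavelet).items():
        images[f"wavelet_{band}"] = sub
    return images


def extract_all(study, mask: np.ndarray | None = None,
                config: FeatureConfig | None = None) -> dict[str, float]:
    """Extract the full feature vector from one study.

    ``mask`` is the malignant mask on the study's native grid; when None it
    is derived by classifying the study's kinetic curves.  Raises
    EmptyMalignantSubregionError when the study has no malignant voxels.
    """
    cfg = config or FeatureConfig()
    pp = cfg.preprocess
    if mask is None:
        mask = malignant_mask(build_subregion_map(study))
    first = study.volumes[1]

    if pp.normalize_before_resample:
        first = normalize_mu3sigma(first, pp)
    vol_rs, mask_rs = resample_isotropic(first, mask.astype(np.uint8),
                                         pp.target_spacing)
    if not pp.normalize_before_resample:
        vol_rs = normalize_mu3sigma(vol_rs, pp)
    m = mask_rs.data.astype(bool)
    voxel_volume = float(np.prod(vol_rs.spacing))

    out: dict[str, float] = {}
    if "shape" in cfg.families:
        for name, val in shape_features(m, vol_rs.spacing).items():
            out[f"original_shape_{name}"] = val

    for img_name, img in _filter_images(vol_rs, cfg).items():
        vals = img.data[m]
        if "firstorder" in cfg.families:
            fo = firstorder_features(vals, voxel_volume, pp.bin_width)
            for name, val in fo.items():
                out[f"{img_name}_firstorder_{name}"] = val
        if "glcm" in cfg.families:
            binned = np.zeros(img.data.shape, dtype=np.int64)
            binned[m] = discretize_fixed_binwidth(vals, pp.bin_width)
            feats = glcm_features(glcm_compute(binned, m))
            for name, val in feats.items():
                out[f"{img_name}_glcm_{name}"] = val
    return out
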