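"""Voxel-wise kinetic-curve classification of the lesion VOI.

Each VOI voxel's enhancement is summarized by two ratios:

* ``ER_first = (SI_first - SI_plain) / SI_plain`` — early enhancement
  relative to the pre-contrast scan,
* ``ER_last = (SI_last - SI_first) / SI_first`` — late change relative to
  the first post-contrast phase.

Voxels with ``ER_first > 0.5`` are enhancing; among those, ``ER_last > 0.1``
is persistent, ``ER_last < -0.1`` is washout, and the rest form the plateau
subregion.  The malignant subregion is the union of washout and plateau.
All three threshold comparisons are strict, so both +/-10% endpoints fall
to plateau.  Classification runs on the native (pre-resampling) grid — the
ratios are properties of acquired voxels.

Label codes: 0 non-enhancing, 1 washout, 2 plateau, 3 persistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateVOIError, EmptyMalignantSubregionError

logger = logging.getLogger(__name__)

NONENHANCING, WASHOUT, PLATEAU, PERSISTENT = 0, 1, 2, 3
LABEL_NAMES = {
    NONENHANCING: "nonenhancing",
    WASHOUT: "washout",
    PLATEAU: "plateau",
    PERSISTENT: "persistent",
}

ER_FIRST_GATE = 0.5
ER_LAST_GATE = 0.1

__all__ = [
    "SubregionMap",
    "enhancement_ratio",
    "classify_voxel",
    "build_subregion_map",
    "malignant_mask",
    "NONENHANCING",
    "WASHOUT",
    "PLATEAU",
    "PERSISTENT",
]


@dataclass
class SubregionMap:
    """Per-voxel subregion labels on the VOI grid plus bookkeeping."""

    labels: np.ndarray  # int array, full grid; 0 outside the VOI
    voi: np.ndarray  # boolean VOI mask
    spacing: tuple[float, float, float]
    n_guarded: int = 0  # voxels forced non-enhancing by the epsilon guard

    @property
    def counts(self) -> dict[str, int]:
        c = {}
        for code, name in LABEL_NAMES.items():
            c[name] = int(np.count_nonzero(self.labels[self.voi] == code))
        return c

    @property
    def fractions(self) -> dict[str, float]:
        n = int(self.voi.sum())
        return {k: v / n for k, v in self.counts.items()}


def enhancement_ratio(si_ref, si_cmp):
    """Relative signal change ``(si_cmp - si_ref) / si_ref``.

    Callers guard ``si_ref > eps``; this is plain arithmetic.
    """
    si_ref = np.asarray(si_ref, dtype=np.float64)
    si_cmp = np.asarray(si_cmp, dtype=np.float64)
    return (si_cmp - si_ref) / si_ref


def classify_voxel(si_plain, si_first, si_last, eps: float = 0.0):
    """Classify voxels by the two enhancement ratios (vectorized).

    Voxels whose plain or first-phase signal is <= ``eps`` are labeled
    non-enhancing (no exception raised); callers pass an epsilon relative
    to the volume maximum.
    """
    si_plain = np.asarray(si_plain, dtype=np.float64)
    si_first = np.asarray(si_first, dtype=np.float64)
    si_last = np.asarray(si_last, dtype=np.float64)

    guarded = (si_plain <= eps) | (si_first <= eps)
    safe_plain = np.where(guarded, 1.0, si_plain)
    safe_first = np.where(guarded, 1.0, si_first)

    er_first = enhancement_ratio(safe_plain, si_first)
    er_last = enhancement_ratio(safe_first, si_last)

    out = np.full(np.broadcast(si_plain, si_first, si_last).shape, NONENHANCING,
                  dtype=np.int8)
    enhancing = (er_first > ER_FIRST_GATE) & ~guarded
    out[enhancing & (er_last > ER_LAST_GATE)] = PERSISTENT
    out[enhancing & (er_last < -ER_LAST_GATE)] = WASHOUT
    out[enhancing & (np.abs(er_last) <= ER_LAST_GATE)] = PLATEAU
    return out if out.shape else out[()]


def build_subregion_map(study) -> SubregionMap:
    """Apply the voxel classifier over the VOI of a multi-phase study.

    Only the plain, first post-contrast, and last post-contrast volumes
    enter the classification.
    """
    if len(study.volumes) < 3:
        raise ValueError("need plain + at least 2 post-contrast phases")
    voi = np.asarray(study.voi, dtype=bool)
    if not voi.any():
        raise DegenerateVOIError("VOI is empty")

    plain = study.volumes[0].data
    first = study.volumes[1].data
    last = study.volumes[-1].data
    eps = 1e-6 * float(plain.max())

    guarded = (plain <= eps) | (first <= eps)
    n_guarded = int(np.count_nonzero(guarded & voi))
    if n_guarded:
        logger.warning("%d VOI voxels had near-zero baseline; labeled "
                       "non-enhancing", n_guarded)

    labels = classify_voxel(plain, first, last, eps=eps)
    labels = np.where(voi, labels, NONENHANCING).astype(np.int8)
    return SubregionMap(labels=labels, voi=voi,
                        spacing=study.volumes[0].spacing, n_guarded=n_guarded)


def malignant_mask(submap: SubregionMap) -> np.ndarray:
    """Union of the washout and plateau subregions as a boolean mask."""
    mask = (submap.labels == WASHOUT) | (submap.labels == PLATEAU)
    if not mask.any():
        raise EmptyMalignantSubregionError(
            "no washout or plateau voxels in the VOI")
    return mask
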