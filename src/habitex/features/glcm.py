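"""Gray-level co-occurrence matrix (GLCM) features.

Construction: distance 1, the 13 unique 3D directions (half of the
26-neighbourhood, each counted with its negation so every matrix is
symmetric), normalized per direction; each feature is computed per
direction and averaged over the 13 directions.

Entropy-valued features (JointEntropy, SumEntropy, DifferenceEntropy) are
in bits (log2).  The information-measure features Imc1/Imc2 use natural
logarithms throughout so that ``Imc2 = sqrt(1 - exp(-2 (HXY2 - HXY)))``
stays in [0, 1) by construction.

A mask with no co-occurring pairs degenerates to the 1x1 matrix, for which
Idm = Id = 1, ClusterShade = 0, Imc2 = 0, Correlation = MCC = 1.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["GlcmMatrix", "glcm_compute", "glcm_features", "OFFSETS_13",
           "GLCM_FEATURE_NAMES"]

#: 13 unique distance-1 directions in (dz, dy, dx), one per +/- pair.
OFFSETS_13 = tuple(
    (dz, dy, dx)
    for dz, dy, dx in itertools.product((-1, 0, 1), repeat=3)
    if (dz, dy, dx) > (0, 0, 0)
)

GLCM_FEATURE_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
)


@dataclass
class GlcmMatrix:
    """Stack of per-direction co-occurrence probability matrices."""

    p: np.ndarray  # (n_dirs, N_g, N_g); each slice sums to 1
    offsets: tuple

    @property
    def n_gray(self) -> int:
        return self.p.shape[1]


def glcm_compute(binned: np.ndarray, mask: np.ndarray,
                 offsets=OFFSETS_13) -> GlcmMatrix:
    """Count symmetric co-occurrences of bin labels at each offset.

    ``binned`` holds 1-based gray levels on the full grid (values outside
    the mask are ignored); pairs require both voxels inside the mask.
    Directions with no valid pair fall back to the identity-like matrix of
    the empty direction and are excluded from the average (flagged in the
    log); if no direction has a pair, the degenerate 1x1 matrix is returned.
    """
    binned = np.asarray(binned)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    n_gray = int(binned[mask].max())
    mats = []
    kept_offsets = []
    for off in offsets:
        src = tuple(slice(max(0, -o), n - max(0, o))
                    for o, n in zip(off, binned.shape))
        dst = tuple(slice(max(0, o), n - max(0, -o))
                    for o, n in zip(off, binned.shape))
        valid = mask[src] & mask[dst]
        i = binned[src][valid] - 1
        j = binned[dst][valid] - 1
        if i.size == 0:
            continue
        counts = np.zeros((n_gray, n_gray), dtype=np.float64)
        np.add.at(counts, (i, j), 1.0)
        counts = counts + counts.T  # count each pair in both directions
        mats.append(counts / counts.sum())
        kept_offsets.append(off)
    if not mats:
        logger.warning("mask has no co-occurring voxel pairs; "
                       "degenerate 1x1 GLCM")
        return GlcmMatrix(p=np.ones((1, 1, 1)), offsets=((0, 0, 1),))
    if len(kept_offsets) < len(offsets):
        logger.warning("%d of %d GLCM directions had no valid pair",
                       len(offsets) - len(kept_offsets), len(offsets))
    return GlcmMatrix(p=np.stack(mats), offsets=tuple(kept_offsets))


def _features_batch(P: np.ndarray) -> dict[str, np.ndarray]:
    """All 24 features of a stack of symmetric co-occurrence matrices.

    ``P`` has shape (D, Ng, Ng); returns one length-D array per feature.
    Definitions are identical to :func:`_features_single`; the batch form
    exists because extraction evaluates 13 directions per image.
    """
    D, ng, _ = P.shape
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=2)  # (D, Ng); == py by symmetry
    mu = (i * px).sum(axis=1)  # (D,)
    sigma2 = ((i[None, :] - mu[:, None]) ** 2 * px).sum(axis=1)
    eps = np.finfo(float).tiny

    # sum / difference distributions
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    sum_idx = (ii + jj).astype(int).ravel() - 2
    p_sum = np.zeros((D, 2 * ng - 1))
    np.add.at(p_sum, (np.repeat(np.arange(D), ng * ng),
                      np.tile(sum_idx, D)), P.reshape(D, -1).ravel())
    k_diff = np.arange(0, ng, dtype=np.float64)
    diff_idx = np.abs(ii - jj).astype(int).ravel()
    p_diff = np.zeros((D, ng))
    np.add.at(p_diff, (np.repeat(np.arange(D), ng * ng),
                       np.tile(diff_idx, D)), P.reshape(D, -1).ravel())

    def ent2(q):  # entropy in bits along the last axes
        q = np.where(q > 0, q, 1.0)
        return -(q * np.log2(q)).sum(axis=tuple(range(1, q.ndim)))

    def entn(q):  # entropy in nats
        q = np.where(q > 0, q, 1.0)
        return -(q * np.log(q)).sum(axis=tuple(range(1, q.ndim)))

    joint_entropy = ent2(P)
    hxy = entn(P)
    hx = entn(px)
    pxy_outer = np.einsum("di,dj->dij", px, px)
    hxy1 = -(np.where(P > 0, P, 0.0)
             * np.log(np.maximum(pxy_outer, eps))).sum(axis=(1, 2))
    hxy2 = entn(pxy_outer)
    imc1 = np.where(hx > 0, (hxy - hxy1) / np.maximum(hx, eps), 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0, None))

    # MCC: second largest eigenvalue of Q, batched
    if ng > 1:
        px_safe = np.maximum(px, eps)
        A = P / px_safe[:, :, None]  # row i divided by px(i)
        C = P / px_safe[:, None, :]  # column k divided by px(k)
        Q = np.einsum("dik,djk->dij", A, C)
        eigs = np.sort(np.real(np.linalg.eigvals(Q)), axis=1)
        mcc = np.sqrt(np.clip(eigs[:, -2], 0.0, 1.0))
        mcc = np.where(sigma2 > 0, mcc, 1.0)
    else:
        mcc = np.ones(D)

    dmu = ii[None] - jj[None]  # (1, Ng, Ng) gray-level difference
    diff_avg = (k_diff * p_diff).sum(axis=1)
    if ng > 1:
        off = dmu[0] != 0
        inv_var = (P[:, off] / (dmu[0][off] ** 2)).sum(axis=1)
    else:
        inv_var = np.zeros(D)
    ipj = ii[None] + jj[None] - 2 * mu[:, None, None]
    correlation = np.where(
        sigma2 > 0,
        ((ii[None] - mu[:, None, None]) * (jj[None] - mu[:, None, None])
         * P).sum(axis=(1, 2)) / np.maximum(sigma2, eps),
        1.0)

    return {
        "Autocorrelation": (ii[None] * jj[None] * P).sum(axis=(1, 2)),
        "JointAverage": mu,
        "ClusterProminence": (ipj ** 4 * P).sum(axis=(1, 2)),
        "ClusterShade": (ipj ** 3 * P).sum(axis=(1, 2)),
        "ClusterTendency": (ipj ** 2 * P).sum(axis=(1, 2)),
        "Contrast": (dmu ** 2 * P).sum(axis=(1, 2)),
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": ent2(p_diff),
        "DifferenceVariance": (((k_diff[None, :] - diff_avg[:, None]) ** 2
                                * p_diff).sum(axis=1)),
        "JointEnergy": (P ** 2).sum(axis=(1, 2)),
        "JointEntropy": joint_entropy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": (P / (1.0 + dmu ** 2)).sum(axis=(1, 2)),
        "Idmn": (P / (1.0 + (dmu / ng) ** 2)).sum(axis=(1, 2)),
        "Id": (P / (1.0 + np.abs(dmu))).sum(axis=(1, 2)),
        "Idn": (P / (1.0 + np.abs(dmu) / ng)).sum(axis=(1, 2)),
        "InverseVariance": inv_var,
        "MaximumProbability": P.max(axis=(1, 2)),
        "SumAverage": (k_sum * p_sum).sum(axis=1),
        "SumEntropy": ent2(p_sum),
        "SumSquares": sigma2,
        "MCC": mcc,
    }


def _features_single(p: np.ndarray) -> dict[str, float]:
    """All 24 features of one symmetric co-occurrence matrix."""
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())

    eps = np.finfo(float).tiny
    pl = p[p > 0]

    # sum / difference distributions
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())
    k_diff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    def ent2(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    joint_entropy = ent2(p.ravel())

    # information measures (natural log)
    def entn(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    hxy = entn(p.ravel())
    hx = entn(px)
    pxy_outer = np.outer(px, px)
    nz = p > 0
    hxy1 = float(-(p[nz] * np.log(np.maximum(pxy_outer[nz], eps))).sum())
    nz2 = pxy_outer > 0
    hxy2 = float(-(pxy_outer[nz2] * np.log(pxy_outer[nz2])).sum())
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    # MCC: second largest eigenvalue of Q
    if ng > 1 and sigma2 > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) py(k))
            q_mat = (p / np.maximum(px[:, np.newaxis], eps)) @ \
                    (p / np.maximum(px[np.newaxis, :], eps)).T
        eigs = np.sort(np.real(np.linalg.eigvals(q_mat)))
        mcc = float(np.sqrt(max(0.0, min(1.0, eigs[-2]))))
    else:
        mcc = 1.0

    contrast = float((((ii - jj) ** 2) * p).sum())
    diff_avg = float((k_diff * p_diff).sum())
    da = diff_avg
    inv_var_mask = ii != jj
    inverse_variance = float((p[inv_var_mask] /
                              ((ii - jj) ** 2)[inv_var_mask]).sum()) if ng > 1 else 0.0

    correlation = (float(((ii - mu) * (jj - mu) * p).sum()) / sigma2
                   if sigma2 > 0 else 1.0)

    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "JointAverage": mu,
        "ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "Contrast": contrast,
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": ent2(p_diff),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "JointEnergy": float((p ** 2).sum()),
        "JointEntropy": joint_entropy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "InverseVariance": inverse_variance,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": ent2(p_sum),
        "SumSquares": sigma2,
        "MCC": mcc,
    }


def glcm_features(glcm: GlcmMatrix) -> dict[str, float]:
    """Per-direction features averaged over the 13 directions."""
    batch = _features_batch(glcm.p)
    return {name: float(batch[name].mean()) for name in GLCM_FEATURE_NAMES}
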