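"""Independent reference implementations used only by the tests.

Everything here is coded definition-by-definition (explicit loops, textbook
formulas), deliberately ignoring how the package computes the same
quantities, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# Kinetic-curve voxel classification (three nested conditionals)


def classify_voxel_oracle(plain: float, first: float, last: float,
                          eps: float) -> int:
    """0 non-enhancing, 1 washout, 2 plateau, 3 persistent."""
    if plain <= eps or first <= eps:
        return 0
    er_first = (first - plain) / plain
    if er_first <= 0.5:
        return 0
    er_last = (last - first) / first
    if er_last > 0.1:
        return 3
    if er_last < -0.1:
        return 1
    return 2


# ---------------------------------------------------------------------------
# GLCM features, one symmetric probability matrix, explicit loops


def glcm_features_oracle(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    levels = list(range(1, ng + 1))
    px = [sum(p[i - 1][j - 1] for j in levels) for i in levels]
    mu = sum(i * px[i - 1] for i in levels)
    var = sum((i - mu) ** 2 * px[i - 1] for i in levels)

    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(0, ng)}
    for i in levels:
        for j in levels:
            p_sum[i + j] += p[i - 1][j - 1]
            p_diff[abs(i - j)] += p[i - 1][j - 1]

    def ent2(vals):
        return -sum(v * math.log2(v) for v in vals if v > 0)

    def entn(vals):
        return -sum(v * math.log(v) for v in vals if v > 0)

    flat = [p[i - 1][j - 1] for i in levels for j in levels]
    hxy = entn(flat)
    hx = entn(px)
    hxy1 = -sum(p[i - 1][j - 1] * math.log(px[i - 1] * px[j - 1])
                for i in levels for j in levels
                if p[i - 1][j - 1] > 0 and px[i - 1] * px[j - 1] > 0)
    hxy2 = entn([px[i - 1] * px[j - 1] for i in levels for j in levels])
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    if ng > 1 and var > 0:
        q = np.zeros((ng, ng))
        for i in levels:
            for j in levels:
                q[i - 1][j - 1] = sum(
                    p[i - 1][k - 1] * p[j - 1][k - 1] / (px[i - 1] * px[k - 1])
                    for k in levels if px[i - 1] > 0 and px[k - 1] > 0)
        eigs = sorted(np.real(np.linalg.eigvals(q)))
        mcc = math.sqrt(max(0.0, min(1.0, eigs[-2])))
    else:
        mcc = 1.0

    diff_avg = sum(k * v for k, v in p_diff.items())
    corr = (sum((i - mu) * (j - mu) * p[i - 1][j - 1]
                for i in levels for j in levels) / var if var > 0 else 1.0)
    return {
        "Autocorrelation": sum(i * j * p[i - 1][j - 1]
                               for i in levels for j in levels),
        "JointAverage": mu,
        "ClusterProminence": sum((i + j - 2 * mu) ** 4 * p[i - 1][j - 1]
                                 for i in levels for j in levels),
        "ClusterShade": sum((i + j - 2 * mu) ** 3 * p[i - 1][j - 1]
                            for i in levels for j in levels),
        "ClusterTendency": sum((i + j - 2 * mu) ** 2 * p[i - 1][j - 1]
                               for i in levels for j in levels),
        "Contrast": sum((i - j) ** 2 * p[i - 1][j - 1]
                        for i in levels for j in levels),
        "Correlation": corr,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": ent2(p_diff.values()),
        "DifferenceVariance": sum((k - diff_avg) ** 2 * v
                                  for k, v in p_diff.items()),
        "JointEnergy": sum(v ** 2 for v in flat),
        "JointEntropy": ent2(flat),
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": sum(p[i - 1][j - 1] / (1 + (i - j) ** 2)
                   for i in levels for j in levels),
        "Idmn": sum(p[i - 1][j - 1] / (1 + ((i - j) / ng) ** 2)
                    for i in levels for j in levels),
        "Id": sum(p[i - 1][j - 1] / (1 + abs(i - j))
                  for i in levels for j in levels),
        "Idn": sum(p[i - 1][j - 1] / (1 + abs(i - j) / ng)
                   for i in levels for j in levels),
        "InverseVariance": sum(p[i - 1][j - 1] / (i - j) ** 2
                               for i in levels for j in levels if i != j),
        "MaximumProbability": max(flat),
        "SumAverage": sum(k * v for k, v in p_sum.items()),
        "SumEntropy": ent2(p_sum.values()),
        "SumSquares": var,
        "MCC": mcc,
    }


def glcm_counts_oracle(binned: np.ndarray, mask: np.ndarray,
                       offset: tuple[int, int, int]) -> np.ndarray:
    """Symmetric co-occurrence counts by explicit voxel-pair enumeration."""
    ng = int(binned[mask].max())
    counts = np.zeros((ng, ng))
    nz, ny, nx = binned.shape
    dz, dy, dx = offset
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                z2, y2, x2 = z + dz, y + dy, x + dx
                if not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx):
                    continue
                if mask[z, y, x] and mask[z2, y2, x2]:
                    i, j = binned[z, y, x] - 1, binned[z2, y2, x2] - 1
                    counts[i, j] += 1
                    counts[j, i] += 1
    return counts


# ---------------------------------------------------------------------------
# First-order features, definition by definition


def firstorder_oracle(values: np.ndarray, voxel_volume: float,
                      bin_width: float) -> dict[str, float]:
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    mean = x.sum() / n
    var = ((x - mean) ** 2).sum() / n
    sd = math.sqrt(var)
    p10, p25, p50, p75, p90 = (np.percentile(x, q) for q in (10, 25, 50, 75, 90))
    robust = x[(x >= p10) & (x <= p90)]
    hist: dict[int, int] = {}
    for v in x:
        b = math.floor((v - x[0]) / bin_width) + 1
        hist[b] = hist.get(b, 0) + 1
    probs = [c / n for c in hist.values()]
    energy = float((x ** 2).sum())
    return {
        "Mean": mean,
        "Median": float(p50),
        "Minimum": float(x[0]),
        "Maximum": float(x[-1]),
        "Range": float(x[-1] - x[0]),
        "Variance": var,
        "Skewness": (((x - mean) ** 3).sum() / n) / sd ** 3 if sd > 0 else 0.0,
        "Kurtosis": (((x - mean) ** 4).sum() / n) / sd ** 4 if sd > 0 else 3.0,
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume,
        "Entropy": -sum(p * math.log2(p) for p in probs),
        "Uniformity": sum(p * p for p in probs),
        "RootMeanSquared": math.sqrt(energy / n),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation":
            float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0,
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "InterquartileRange": float(p75 - p25),
    }


# ---------------------------------------------------------------------------
# Statistics oracles


def chi2_yates_oracle(table: np.ndarray) -> tuple[float, float]:
    """Textbook chi-square statistic with Yates correction for 2x2,
    uncorrected otherwise; returns (statistic, df)."""
    tab = np.asarray(table, dtype=float)
    r, c = tab.shape
    n = tab.sum()
    row, col = tab.sum(axis=1), tab.sum(axis=0)
    stat = 0.0
    yates = (r, c) == (2, 2)
    for i in range(r):
        for j in range(c):
            e = row[i] * col[j] / n
            d = abs(tab[i, j] - e)
            if yates:
                d = max(0.0, d - 0.5)
            stat += d * d / e
    return stat, (r - 1) * (c - 1)


def auc_pair_count_oracle(scores, labels) -> float:
    """AUC by O(n^2) pair counting; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def youden_oracle(scores, labels) -> tuple[float, float]:
    """(best J, cutoff) by scanning every observed threshold; J ties go to
    the larger cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    best_j, best_t = -2.0, None
    for t in sorted(set(scores)):
        pred = scores >= t
        tp = np.sum(pred & (labels == 1))
        fn = np.sum(~pred & (labels == 1))
        tn = np.sum(~pred & (labels == 0))
        fp = np.sum(pred & (labels == 0))
        j = tp / (tp + fn) + tn / (tn + fp) - 1
        if j >= best_j:
            best_j, best_t = j, t
    return best_j, best_t


def mutual_information_oracle(xb, yb) -> float:
    """Plug-in MI (nats) of two already-discrete samples, brute force."""
    xb = np.asarray(xb)
    yb = np.asarray(yb)
    n = xb.size
    mi = 0.0
    for xv in np.unique(xb):
        for yv in np.unique(yb):
            pxy = np.sum((xb == xv) & (yb == yv)) / n
            if pxy == 0:
                continue
            px = np.sum(xb == xv) / n
            py = np.sum(yb == yv) / n
            mi += pxy * math.log(pxy / (px * py))
    return mi
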