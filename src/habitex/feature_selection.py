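"""Two-stage feature reduction: correlation pruning, then mRMR ranking.

Stage 1 prunes pairwise Pearson correlation above 0.75: while any
surviving pair exceeds the threshold, the pair with the largest |r| is
examined (ties broken lexicographically by the name pair) and the member
with the higher mean absolute correlation against all current survivors is
dropped.  Stage 2 ranks the survivors by the mutual-information-difference
(MID) flavour of minimum-redundancy-maximum-relevance: the first pick
maximizes MI(feature; label); each later pick maximizes
MI(f; label) - mean MI(f; already-selected).

Mutual information uses a plug-in estimate on equal-frequency bins
(floor(sqrt(n)) bins, capped at 10) for continuous variables; class labels
are used as-is.  All tie-breaks are lexicographic so runs are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidCohortError, SelectionError

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionResult",
    "correlation_prune",
    "mutual_information",
    "mrmr_select",
]


@dataclass
class SelectionResult:
    """Audit trail of pruning and mRMR ranking."""

    surviving: list[str]
    dropped: list[dict] = field(default_factory=list)  # feature, against, r, rule
    ranked: list[str] = field(default_factory=list)
    scores: list[dict] = field(default_factory=list)  # per-pick relevance etc.

    def audit_frame(self) -> pd.DataFrame:
        rows = [{"action": "drop", **d} for d in self.dropped]
        rows += [{"action": "pick", **s} for s in self.scores]
        return pd.DataFrame(rows)


def correlation_prune(table: pd.DataFrame, threshold: float = 0.75,
                      method: str = "pearson") -> SelectionResult:
    """Iteratively remove one member of every too-correlated pair."""
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise ValueError("need >= 2 features and >= 3 subjects")
    result = SelectionResult(surviving=sorted(table.columns))

    constant = [c for c in result.surviving if table[c].nunique() <= 1]
    for c in constant:
        logger.warning("feature %s is constant; dropped before pruning", c)
        result.dropped.append({"feature": c, "against": None, "r": np.nan,
                               "rule": "constant"})
        result.surviving.remove(c)

    while len(result.surviving) >= 2:
        corr = table[result.surviving].corr(method=method).abs()
        np.fill_diagonal(corr.values, 0.0)
        # offending pairs ordered by descending |r|, ties lexicographic
        pairs = [
            (corr.iloc[a, b], corr.index[a], corr.columns[b])
            for a in range(len(corr)) for b in range(a + 1, len(corr))
            if corr.iloc[a, b] > threshold
        ]
        if not pairs:
            break
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        r, f1, f2 = pairs[0]
        mean_abs = corr.mean(axis=1)  # over current survivors
        if mean_abs[f1] > mean_abs[f2]:
            victim, kept = f1, f2
        elif mean_abs[f2] > mean_abs[f1]:
            victim, kept = f2, f1
        else:  # exact tie: drop the lexicographically later name
            victim, kept = max(f1, f2), min(f1, f2)
        result.dropped.append({"feature": victim, "against": kept,
                               "r": float(r), "rule": "corr>threshold"})
        result.surviving.remove(victim)
    return result


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="right")


def _discretize(x: np.ndarray, n_bins: int | None) -> np.ndarray:
    x = np.asarray(x)
    uniq = np.unique(x)
    if n_bins is None:
        n_bins = min(int(np.floor(np.sqrt(x.size))), 10)
    n_bins = max(n_bins, 2)
    if uniq.size <= n_bins or not np.issubdtype(x.dtype, np.number):
        # already discrete (class labels, few distinct values)
        return np.searchsorted(uniq, x)
    return _equal_frequency_bins(x.astype(np.float64), n_bins)


def mutual_information(x, y, n_bins: int | None = None,
                       correction: bool = False) -> float:
    """Mutual information (nats) between two samples.

    Continuous variables are discretized into equal-frequency bins;
    already-discrete variables (for example class labels) are used as-is.
    The default is the plug-in estimate; ``correction=True`` applies the
    Miller-Madow bias adjustment ``-(K_xy - K_x - K_y + 1) / (2n)`` over
    occupied cells, which matters when comparing MI values across tables
    of different dimension (as the mRMR score does).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size != y.size or x.size < 4:
        raise ValueError("need two equal-length samples, n >= 4")
    if np.unique(y).size < 2 and not np.issubdtype(y.dtype, np.floating):
        raise InvalidCohortError("labels contain a single class")
    xb = _discretize(x, n_bins)
    yb = _discretize(y, n_bins)
    joint = pd.crosstab(xb, yb).to_numpy().astype(np.float64)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    mi = float((pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum())
    if correction:
        k_xy = int(np.count_nonzero(joint))
        k_x = int(np.count_nonzero(joint.sum(axis=1)))
        k_y = int(np.count_nonzero(joint.sum(axis=0)))
        mi -= (k_xy - k_x - k_y + 1) / (2.0 * x.size)
    return mi


def mrmr_select(table: pd.DataFrame, labels, k: int = 5,
                n_bins: int | None = None) -> SelectionResult:
    """Greedy MID-mRMR ranking of ``k`` features.

    Both relevance and redundancy terms use the Miller-Madow-corrected MI:
    the raw plug-in bias grows with table dimension, so uncorrected scores
    systematically over-penalize continuous-continuous redundancy relative
    to continuous-binary relevance.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise InvalidCohortError("labels contain a single class")
    cols = sorted(table.columns)
    if k > len(cols):
        raise SelectionError(f"k={k} exceeds the {len(cols)} available features")

    relevance = {c: mutual_information(table[c].to_numpy(), labels, n_bins,
                                       correction=True)
                 for c in cols}
    # feature-feature MI computed lazily, cached
    ff_cache: dict[tuple[str, str], float] = {}

    def ff_mi(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in ff_cache:
            ff_cache[key] = mutual_information(table[a].to_numpy(),
                                               table[b].to_numpy(), n_bins,
                                               correction=True)
        return ff_cache[key]

    result = SelectionResult(surviving=list(cols))
    remaining = list(cols)
    while len(result.ranked) < k:
        best_name, best_score, best_rel, best_red = None, -np.inf, 0.0, 0.0
        for c in remaining:  # lexicographic order; strict > keeps the first
            red = (np.mean([ff_mi(c, s) for s in result.ranked])
                   if result.ranked else 0.0)
            score = relevance[c] - red
            if score > best_score:
                best_name, best_score, best_rel, best_red = (
                    c, score, relevance[c], red)
        result.ranked.append(best_name)
        result.scores.append({"feature": best_name, "relevance": best_rel,
                              "redundancy": best_red, "score": best_score,
                              "step": len(result.ranked)})
        remaining.remove(best_name)
    return result
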