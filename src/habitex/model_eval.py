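"""SVM training and ROC/Youden/cross-validation evaluation.

The classifier is an RBF-kernel SVM (C = 1, kernel scale by the `scale`
convention, class-balanced weights for the 81-vs-38 style imbalance) with
Platt probability calibration, so the reported operating cutoff lives on a
probability scale.  Features are z-scored with statistics fit on training
data only.

AUC is the trapezoidal rank statistic (ties count 1/2), identical to the
two-sample Mann-Whitney U divided by n1*n0; its 95% CI is DeLong's
asymptotic rank-based interval.  The operating cutoff maximizes the Youden
index J = sensitivity + specificity - 1 over all observed scores, ties
broken toward higher specificity (the larger cutoff).

By default feature selection happens once on the full cohort and only the
classifier is cross-validated, reproducing the common (optimistic)
radiomics protocol; ``select_in_folds=True`` re-runs pruning + mRMR inside
each training fold for a leakage-free estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.model_selection import StratifiedKFold

from .errors import InvalidCohortError

logger = logging.getLogger(__name__)

__all__ = [
    "SvmConfig",
    "ModelEval",
    "train_svm",
    "roc_auc",
    "youden_metrics",
    "crossvalidate",
    "per_feature_auc",
]


@dataclass
class SvmConfig:
    C: float = 1.0
    kernel: str = "rbf"
    gamma: str | float = "scale"
    class_weight: str | dict | None = "balanced"
    probability: bool = True
    seed: int = 0


@dataclass
class ModelEval:
    """Evaluation bundle: scores, AUC + CI, cutoff, metrics, CV AUCs."""

    scores: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    metrics: dict[str, float]
    fold_aucs: list[float] = field(default_factory=list)
    cv_mean: float = float("nan")
    cv_sd: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci_95": list(self.auc_ci),
            "cutoff": self.cutoff,
            **self.metrics,
            "fold_aucs": list(self.fold_aucs),
            "cv_auc_mean": self.cv_mean,
            "cv_auc_sd": self.cv_sd,
        }


def _encode(labels) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise InvalidCohortError(f"need exactly 2 classes, got {classes}")
    positive = "high" if "high" in classes.tolist() else classes.max()
    return (labels == positive).astype(int)


def train_svm(features: pd.DataFrame | np.ndarray, labels,
              config: SvmConfig | None = None):
    """Fit the standardized RBF-SVM; returns (model, scores on train).

    Scores are Platt-calibrated probabilities of the positive (high) class.
    """
    cfg = config or SvmConfig()
    X = np.asarray(features, dtype=np.float64)
    y = _encode(labels)
    if min(np.bincount(y)) < 2:
        raise InvalidCohortError("need >= 2 subjects per class")
    model = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(C=cfg.C, kernel=cfg.kernel, gamma=cfg.gamma,
                    class_weight=cfg.class_weight,
                    probability=cfg.probability, random_state=cfg.seed)),
    ])
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning)
        model.fit(X, y)
    scores = (model.predict_proba(X)[:, 1] if cfg.probability
              else model.decision_function(X))
    return model, scores


# ---------------------------------------------------------------------------
# ROC / AUC


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(scores, labels, alpha: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Rank AUC with a DeLong asymptotic confidence interval.

    Constant scores give AUC 0.5 with a degenerate CI (warned).
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = _encode(labels)
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise InvalidCohortError("both classes must be present")
    if np.ptp(scores) == 0:
        logger.warning("constant scores; AUC 0.5 with degenerate CI")
        return 0.5, (0.5, 0.5)

    # DeLong: structural components from midranks
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    var = sum(np.var(v, ddof=1) / v.size if v.size > 1 else 0.0
              for v in (v10, v01))
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + alpha / 2)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    return float(auc), (float(lo), float(hi))


def youden_metrics(scores, labels) -> tuple[float, dict[str, float]]:
    """Cutoff maximizing J over observed thresholds, plus the five metrics.

    Predict positive when score >= cutoff; J-ties resolve to the larger
    cutoff (higher specificity).
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = _encode(labels)
    thresholds = np.unique(scores)
    best = None
    for t in thresholds:  # ascending; >= keeps later (larger) t on J ties
        pred = scores >= t
        tp = int(np.sum(pred & (y == 1)))
        fn = int(np.sum(~pred & (y == 1)))
        tn = int(np.sum(~pred & (y == 0)))
        fp = int(np.sum(pred & (y == 0)))
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1
        if best is None or j >= best[0]:
            best = (j, t, tp, fn, tn, fp)
    _, cutoff, tp, fn, tn, fp = best
    return float(cutoff), confusion_metrics(tp, fn, tn, fp)


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, PPV, NPV of a confusion matrix."""
    n = tp + fn + tn + fp
    return {
        "accuracy": (tp + tn) / n,
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
        "ppv": tp / (tp + fp) if tp + fp else 0.0,
        "npv": tn / (tn + fn) if tn + fn else 0.0,
    }


def crossvalidate(features: pd.DataFrame, labels, folds: int = 10,
                  seed: int = 0, config: SvmConfig | None = None,
                  select_in_folds: bool = False, k: int = 5,
                  corr_threshold: float = 0.75) -> tuple[list[float], float, float]:
    """Stratified k-fold CV of the SVM; returns (fold AUCs, mean, SD)."""
    cfg = config or SvmConfig(seed=seed)
    X = features if isinstance(features, pd.DataFrame) else pd.DataFrame(features)
    y = _encode(labels)
    min_class = int(np.bincount(y).min())
    if min_class < folds:
        logger.warning("reducing folds from %d to %d (smallest class size)",
                       folds, min_class)
        folds = max(2, min_class)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs = []
    for train_idx, test_idx in skf.split(X, y):
        y_tr, y_te = y[train_idx], y[test_idx]
        if np.unique(y_tr).size < 2:
            logger.warning("single-class training fold skipped")
            continue
        cols = list(X.columns)
        if select_in_folds:
            from .feature_selection import correlation_prune, mrmr_select
            tr = X.iloc[train_idx]
            pruned = correlation_prune(tr, threshold=corr_threshold)
            kk = min(k, len(pruned.surviving))
            cols = mrmr_select(tr[pruned.surviving], y_tr, k=kk).ranked
        model, _ = train_svm(X.iloc[train_idx][cols], y_tr, cfg)
        s = model.predict_proba(X.iloc[test_idx][cols].to_numpy())[:, 1]
        if np.unique(y_te).size < 2:
            logger.warning("single-class test fold skipped")
            continue
        auc, _ = roc_auc(s, y_te)
        fold_aucs.append(auc)
    return fold_aucs, float(np.mean(fold_aucs)), float(np.std(fold_aucs, ddof=1))


def per_feature_auc(features: pd.DataFrame, labels) -> pd.Series:
    """Univariate rank AUC per feature, oriented so AUC >= 0.5."""
    y = _encode(labels)
    out = {}
    for c in features.columns:
        auc, _ = roc_auc(features[c].to_numpy(), y)
        out[c] = max(auc, 1.0 - auc)
    return pd.Series(out).sort_values(ascending=False)
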