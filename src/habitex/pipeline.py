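"""Configuration-driven end-to-end orchestration.

Stages: cohort (phantom generation or loading from disk) -> subregion
segmentation -> feature extraction -> group screening -> correlation
pruning + mRMR -> SVM training and evaluation.  Every run writes a
manifest JSON capturing parameters, per-stage seeds, and row/voxel counts,
and re-running an identical config is bit-identical.

One master seed fans out to per-stage seeds through a counter scheme:
stage ``i`` uses ``SeedSequence([master_seed, i])``, so any stage can be
re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort_stats import screen_table
from .errors import SelectionError, StageError
from .feature_selection import correlation_prune, mrmr_select
from .features import FeatureConfig, extract_all
from .imaging_io import PreprocessConfig
from .model_eval import (
    SvmConfig,
    crossvalidate,
    per_feature_auc,
    roc_auc,
    train_svm,
    youden_metrics,
)
from .phantom import PhantomSpec, generate_cohort
from .subregions import build_subregion_map, malignant_mask

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_end_to_end", "load_config",
           "screen_select_evaluate"]

STAGES = ("cohort", "segment", "extract", "screen", "select", "evaluate")


@dataclass
class RunConfig:
    """Everything a full run needs; YAML-serializable."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    screening_alpha: float = 0.05
    alpha_normality: float = 0.05
    corr_threshold: float = 0.75
    k: int = 5
    svm: SvmConfig = field(default_factory=SvmConfig)
    folds: int = 10
    select_in_folds: bool = False
    master_seed: int = 0

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        return int(np.random.SeedSequence([self.master_seed, idx])
                   .generate_state(1)[0] % (2 ** 31))


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (missing keys take defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    phantom = PhantomSpec(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in raw.get("phantom", {}).items()})
    feat_raw = dict(raw.get("features", {}))
    pp = PreprocessConfig(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in feat_raw.pop("preprocess", {}).items()})
    features = FeatureConfig(preprocess=pp,
                             **{k: tuple(v) if isinstance(v, list) else v
                                for k, v in feat_raw.items()})
    svm = SvmConfig(**raw.get("svm", {}))
    top = {k: v for k, v in raw.items()
           if k in ("screening_alpha", "alpha_normality", "corr_threshold",
                    "k", "folds", "select_in_folds", "master_seed")}
    return RunConfig(phantom=phantom, features=features, svm=svm, **top)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # tag with the stage, preserve partials
                raise StageError(name, exc) from exc
        return wrapped
    return deco


def screen_select_evaluate(table: pd.DataFrame, labels, *,
                           alpha_normality: float = 0.05,
                           corr_threshold: float = 0.75, k: int = 5,
                           folds: int = 10, seed: int = 0,
                           svm: SvmConfig | None = None,
                           allow_smaller_panel: bool = False) -> dict:
    """The label-dependent half of the pipeline on a ready feature table.

    Screens features, prunes + mRMR-selects a panel, trains the SVM and
    evaluates it (full-cohort ROC/Youden plus stratified CV).  With
    ``allow_smaller_panel`` the panel shrinks to the surviving feature
    count instead of raising; fewer than two significant features always
    raises :class:`SelectionError`.
    """
    labels = np.asarray(labels)
    screen = screen_table(table, labels, alpha_normality=alpha_normality)
    significant = screen.loc[screen["significant"], "feature"].tolist()
    if len(significant) < 2:
        raise SelectionError(
            f"only {len(significant)} significant features; cannot select")
    pruned = correlation_prune(table[significant], threshold=corr_threshold)
    k_eff = k
    if k > len(pruned.surviving):
        if not allow_smaller_panel:
            raise SelectionError(
                f"k={k} exceeds {len(pruned.surviving)} surviving features")
        k_eff = len(pruned.surviving)
    sel = mrmr_select(table[pruned.surviving], labels, k=k_eff)
    panel = sel.ranked

    svm_cfg = dataclasses.replace(svm or SvmConfig(), seed=seed)
    model, scores = train_svm(table[panel], labels, svm_cfg)
    auc, ci = roc_auc(scores, labels)
    cutoff, metrics = youden_metrics(scores, labels)
    fold_aucs, cv_mean, cv_sd = crossvalidate(
        table[panel], labels, folds=folds, seed=seed, config=svm_cfg)
    uni = per_feature_auc(table[panel], labels)
    return {
        "screen": screen, "n_significant": len(significant),
        "pruned": pruned, "selection": sel, "panel": panel,
        "scores": scores, "auc": auc, "auc_ci_95": list(ci),
        "cutoff": cutoff, **metrics, "fold_aucs": fold_aucs,
        "cv_auc_mean": cv_mean, "cv_auc_sd": cv_sd,
        "per_feature_auc": uni.to_dict(),
    }


@_stage("extract")
def _extract_features(studies, cohort, config: RunConfig):
    rows, excluded = [], []
    for study in studies:
        try:
            submap = build_subregion_map(study)
            mask = malignant_mask(submap)
        except Exception as exc:
            logger.warning("subject %s excluded: %s", study.subject_id, exc)
            excluded.append({"subject_id": study.subject_id,
                             "reason": str(exc)})
            continue
        feats = extract_all(study, mask, config.features)
        rows.append({"subject_id": study.subject_id, **feats})
    table = pd.DataFrame(rows).set_index("subject_id")
    return table, excluded


def run_end_to_end(config: RunConfig, outdir: str | Path) -> dict:
    """Run the whole pipeline; returns the summary report dict.

    All per-stage outputs (feature CSV, screen CSV, selection audit CSV,
    evaluation JSON) and a manifest are written under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(config), "stages": {}}

    # --- cohort ------------------------------------------------------------
    spec = dataclasses.replace(config.phantom,
                               seed=config.stage_seed("cohort"))
    try:
        studies, cohort = generate_cohort(spec)
    except Exception as exc:
        raise StageError("cohort", exc) from exc
    cohort.to_csv(outdir / "cohort.csv", index=False)
    manifest["stages"]["cohort"] = {"n": len(studies),
                                    "seed": spec.seed,
                                    "n_high": spec.n_high, "n_low": spec.n_low}

    # --- segment + extract -------------------------------------------------
    table, excluded = _extract_features(studies, cohort, config)
    labels = cohort.set_index("subject_id").loc[table.index, "label"]
    table.to_csv(outdir / "features.csv")
    manifest["stages"]["extract"] = {
        "n_subjects": len(table), "n_features": table.shape[1],
        "excluded": excluded, "settings": config.features.manifest()}

    # --- screen + select + evaluate ---------------------------------------
    seed = config.stage_seed("evaluate")
    try:
        res = screen_select_evaluate(
            table, labels.to_numpy(),
            alpha_normality=config.alpha_normality,
            corr_threshold=config.corr_threshold, k=config.k,
            folds=config.folds, seed=seed, svm=config.svm)
    except StageError:
        raise
    except SelectionError as exc:
        raise StageError("select", exc) from exc
    except Exception as exc:
        raise StageError("evaluate", exc) from exc

    res["screen"].to_csv(outdir / "screen.csv", index=False)
    manifest["stages"]["screen"] = {"n_significant": res["n_significant"]}
    audit = pd.concat([res["pruned"].audit_frame(),
                       res["selection"].audit_frame()], ignore_index=True)
    audit.to_csv(outdir / "selection_audit.csv", index=False)
    panel = res["panel"]
    manifest["stages"]["select"] = {
        "n_pruned": len(res["pruned"].dropped),
        "n_surviving": len(res["pruned"].surviving), "panel": panel}

    evaluation = {k: v for k, v in res.items()
                  if k not in ("screen", "pruned", "selection", "scores")}
    evaluation["scores"] = [float(s) for s in res["scores"]]
    (outdir / "evaluation.json").write_text(json.dumps(evaluation, indent=2))
    manifest["stages"]["evaluate"] = {"seed": seed, "folds": config.folds}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    report = {"n_subjects": len(table), "n_features": table.shape[1],
              "n_significant": res["n_significant"], "panel": panel,
              **{k: v for k, v in evaluation.items()
                 if k not in ("per_feature_auc", "scores")}}
    (outdir / "summary.json").write_text(json.dumps(report, indent=2))
    return report


def _config_dict(config: RunConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return clean(config)
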