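"""End-to-end orchestration: simulate -> preprocess -> window -> train ->
evaluate, plus k-fold cross-validation and input-channel ablation.

One experiment-level seed fans out deterministically to every stage
(cohort generation, windowing, per-architecture training, bootstrap
resampling), so a config plus seed fully reproduces a report bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from ._seeds import derive_seed
from .conditions import get_condition
from .dataio import SessionManifest, load_manifest, read_recording
from .evaluation import EvaluationReport, evaluate_predictions, summarise_folds
from .models import (
    ArchitectureSpec,
    PretrainConfig,
    TrainingConfig,
    build_model,
    count_trainable_parameters,
    predict,
    pretrain_encoder,
    train_classifier,
)
from .preprocess import SteadySegment, preprocess_traversal
from .synth import CohortConfig, simulate_cohort
from .windowing import WindowingConfig, assemble_dataset, standardise_datasets

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "run_ablation",
    "preprocess_manifest",
    "CHANNEL_SUBSETS",
]

# Default ablation ladder: full tri-axial, then progressively fewer axes.
CHANNEL_SUBSETS: tuple[tuple[str, ...], ...] = (
    ("x", "y", "z"), ("x", "y"), ("x", "z"), ("x",), ("z",),
)


@dataclass
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    windowing: WindowingConfig = field(default_factory=WindowingConfig)
    architectures: tuple[str, ...] = ("A2",)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    pretrain_enabled: bool = True
    cv_folds: int = 0  # 0 or 1: single 80/20 split; >1: k-fold CV as well
    channel_subsets: tuple[tuple[str, ...], ...] = CHANNEL_SUBSETS
    bootstrap_B: int = 200
    output_dir: str | Path = "gaitshift_run"
    seed: int = 0


def preprocess_manifest(manifest: SessionManifest) -> list[SteadySegment]:
    """Steady segments for every manifest entry, in manifest order."""
    segments = []
    for e in manifest.entries:
        accel = read_recording(manifest.path_for(e, "accelerometer"),
                               "accelerometer", e.placement)
        segments.append(preprocess_traversal(
            accel, e.markers, get_condition(e.condition), e.participant_id,
            rate=manifest.sampling_rate))
    return segments


def _train_and_eval(arch: str, train_ds, test_ds, cfg: ExperimentConfig,
                    stage: str, in_channels: int | None = None
                    ) -> tuple[EvaluationReport, dict]:
    spec = ArchitectureSpec(name=arch,
                            in_channels=in_channels or len(train_ds.channel_names))
    # Channel-wise standardisation fitted on the training windows only.
    train_ds, test_ds, _, _ = standardise_datasets(train_ds, test_ds)
    seed = derive_seed(cfg.seed, f"{stage}:{arch}")
    model = build_model(spec, seed=seed)
    pre_hist: list[float] = []
    if cfg.pretrain_enabled and cfg.pretrain.epochs > 0 and model.conv_stem:
        pre_cfg = PretrainConfig(**{**cfg.pretrain.__dict__, "seed": seed + 1})
        model, pre_hist = pretrain_encoder(model, train_ds, pre_cfg)
    tr_cfg = TrainingConfig(**{**cfg.training.__dict__, "seed": seed + 2})
    model, history = train_classifier(model, train_ds, tr_cfg)
    probs = predict(model, test_ds)
    pred = probs.argmax(axis=1)
    report = evaluate_predictions(test_ds.labels, pred,
                                  seed=derive_seed(cfg.seed, f"boot:{stage}:{arch}"),
                                  bootstrap_B=cfg.bootstrap_B)
    extras = {"pretrain_loss": pre_hist, "history": history,
              "n_parameters": count_trainable_parameters(model)}
    return report, extras


def run_experiment(config: ExperimentConfig) -> dict:
    """Full experiment for every requested architecture.

    Returns (and writes to ``output_dir/report.json``) a bundle with, per
    architecture, the test-set evaluation report, training history,
    parameter count, and — when ``cv_folds > 1`` — a fold summary with
    Student-t confidence intervals, retraining from scratch per fold.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_cfg = CohortConfig(**{**config.cohort.__dict__,
                                 "seed": derive_seed(config.seed, "cohort")})
    manifest = simulate_cohort(cohort_cfg, out / "cohort")
    segments = preprocess_manifest(manifest)
    win_cfg = WindowingConfig(**{**config.windowing.__dict__,
                                 "seed": derive_seed(config.seed, "windows")})
    train_ds, test_ds = assemble_dataset(segments, win_cfg)

    bundle: dict = {"seed": config.seed, "n_traversals": len(manifest),
                    "n_train_windows": len(train_ds),
                    "n_test_windows": len(test_ds), "models": {}}
    for arch in config.architectures:
        report, extras = _train_and_eval(arch, train_ds, test_ds, config,
                                         stage="split")
        entry = {"report": report.to_dict(), **extras}
        if config.cv_folds > 1:
            fold_metrics: dict[str, list[float]] = {
                "accuracy": [], "weighted_f1": [], "min_recall": [],
                "avg_f1": [], "class_balance_pp": [], "avg_fpr": []}
            for fold in range(config.cv_folds):
                ftr, fte = assemble_dataset(segments, win_cfg, fold=fold,
                                            n_folds=config.cv_folds)
                frep, _ = _train_and_eval(arch, ftr, fte, config,
                                          stage=f"fold{fold}")
                agg = frep.aggregates
                fold_metrics["accuracy"].append(agg.accuracy)
                fold_metrics["weighted_f1"].append(agg.weighted_f1)
                fold_metrics["min_recall"].append(agg.min_recall)
                fold_metrics["avg_f1"].append(agg.avg_f1)
                fold_metrics["class_balance_pp"].append(agg.class_balance_pp)
                fold_metrics["avg_fpr"].append(agg.avg_fpr)
            fs = summarise_folds(fold_metrics)
            entry["cv"] = {"k": fs.k, "metrics": fs.metrics}
        bundle["models"][arch] = entry

    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2)
    return bundle


def run_ablation(config: ExperimentConfig, arch: str = "A5") -> dict:
    """Channel-ablation table for one architecture.

    Every row shares the same cohort, splits and seed stream; only the
    input channels (and hence the first convolution's width) change.
    """
    for subset in config.channel_subsets:
        if not subset:
            raise ValueError("channel subsets must be non-empty")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_cfg = CohortConfig(**{**config.cohort.__dict__,
                                 "seed": derive_seed(config.seed, "cohort")})
    manifest = simulate_cohort(cohort_cfg, out / "cohort")
    segments = preprocess_manifest(manifest)
    win_cfg = WindowingConfig(**{**config.windowing.__dict__,
                                 "seed": derive_seed(config.seed, "windows")})
    train_ds, test_ds = assemble_dataset(segments, win_cfg)

    rows = []
    for subset in config.channel_subsets:
        tr = train_ds.select_channels(subset)
        te = test_ds.select_channels(subset)
        report, extras = _train_and_eval(arch, tr, te, config,
                                         stage=f"ablate:{','.join(subset)}",
                                         in_channels=len(subset))
        rows.append({"channels": list(subset),
                     "n_parameters": extras["n_parameters"],
                     "report": report.to_dict()})
    table = {"architecture": arch, "rows": rows, "seed": config.seed}
    with open(out / "ablation.json", "w") as fh:
        json.dump(table, fh, indent=2)
    return table
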