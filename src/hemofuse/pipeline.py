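"""End-to-end orchestration: preprocess -> segment -> fuse features ->
tune -> classify -> evaluate.

The stages mirror the four-stage design of the method: median filtering,
seagull-optimized multilevel Otsu segmentation (the lesion mask gates the
encoders by default), capsule + inverted-bottleneck feature fusion with
entropy selection, deer-hunting-optimization tuning of classifier
hyperparameters on a validation split, and a one-vs-rest fuzzy SVM.

Everything is driven by :class:`PipelineConfig` (constructible from YAML)
and a global seed; a run is reproducible from (config, seed) alone and the
returned :class:`RunReport` embeds the fully resolved configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import ClassMetrics, confusion, per_class_metrics, write_report
from .features import (
    BottleneckEncoderConfig,
    CapsEncoderConfig,
    bottleneck_encode,
    capsnet_encode,
    entropy_select,
    fuse_features,
)
from .fsvm import FSVMHyperparams, train_multiclass
from .optimizers import DHOParams, ObjectiveSpec, SOAParams, dho_optimize
from .preprocessing import MedianFilterConfig, median_filter_naive
from .segmentation import apply_thresholds, lesion_mask, otsu_soa
from .synthetic import SyntheticConfig, generate_dataset, load_manifest

logger = logging.getLogger("hemofuse")

__all__ = [
    "PipelineConfig",
    "RunReport",
    "tune_hyperparameters",
    "run_pipeline",
    "stratified_split",
    "extract_features",
]


@dataclass(frozen=True)
class TuningConfig:
    """DHO search space for classifier hyperparameters (log10 scales)."""

    enabled: bool = True
    log10_C: tuple[float, float] = (-1.0, 3.0)
    log10_gamma: tuple[float, float] = (-6.0, 0.0)
    dho: DHOParams = DHOParams(population=4, max_iterations=6)
    val_fraction: float = 0.25


@dataclass(frozen=True)
class PipelineConfig:
    data: SyntheticConfig = SyntheticConfig()
    manifest: str | None = None            # load images instead of generating
    median: MedianFilterConfig = MedianFilterConfig()
    k_thresholds: int = 2
    soa: SOAParams = SOAParams(population=15, max_iterations=40)
    use_lesion_mask: bool = True           # encoders see the masked image
    caps: CapsEncoderConfig = CapsEncoderConfig()
    bottleneck: BottleneckEncoderConfig = BottleneckEncoderConfig()
    select_keep: int = 512
    select_bins: int = 16
    fsvm: FSVMHyperparams = FSVMHyperparams()
    membership_scheme: str = "centroid-linear"
    tuning: TuningConfig = TuningConfig()
    test_fraction: float = 0.3
    runs: int = 1
    seed: int = 0

    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        sub = {
            "data": SyntheticConfig,
            "median": MedianFilterConfig,
            "soa": SOAParams,
            "caps": CapsEncoderConfig,
            "bottleneck": BottleneckEncoderConfig,
            "fsvm": FSVMHyperparams,
        }
        for key, val in raw.items():
            if key in sub:
                if key == "data" and "counts" in val:
                    val = dict(val)
                kwargs[key] = sub[key](**val)
            elif key == "tuning":
                dho = DHOParams(**val.pop("dho")) if "dho" in val else TuningConfig().dho
                kwargs[key] = TuningConfig(dho=dho, **val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


@dataclass
class RunReport:
    run_index: int
    confusion: pd.DataFrame
    metrics: ClassMetrics
    macro: pd.Series
    chosen_hyperparams: dict
    selected_features: np.ndarray
    optimizer_history: list
    stage_seconds: dict
    config: dict
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "run_index": self.run_index,
                "confusion": self.confusion.to_dict(),
                "per_class": self.metrics.table.round(4).to_dict(),
                "macro": {k: round(v, 4) for k, v in self.macro.items()},
                "chosen_hyperparams": self.chosen_hyperparams,
                "n_selected_features": int(self.selected_features.size),
                "stage_seconds": {k: round(v, 2) for k, v in self.stage_seconds.items()},
                "seed": self.seed,
                "config": _jsonable(self.config),
            },
            indent=2,
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def stratified_split(
    labels: np.ndarray, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled split; every class keeps >= 1 sample on each side."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    train_idx, test_idx = [], []
    for cls in pd.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_test = int(round(test_fraction * idx.size))
        n_test = min(max(n_test, 1), idx.size - 1)
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def preprocess_stage(images, cfg: PipelineConfig):
    return [median_filter_naive(im, cfg.median, levels=cfg.data.levels) for im in images]


def segment_stage(images, cfg: PipelineConfig):
    """Per-image SOA-Otsu thresholds; returns (masks, masked_images)."""
    masks, masked = [], []
    for i, im in enumerate(images):
        params = dataclasses.replace(cfg.soa, seed=cfg.seed * 100_003 + i)
        t, _, _ = otsu_soa(im, cfg.k_thresholds, params, levels=cfg.data.levels)
        labels = apply_thresholds(im, t, levels=cfg.data.levels)
        m = lesion_mask(labels, n_segments=cfg.k_thresholds + 1)
        masks.append(m)
        masked.append(np.where(m, im, 0).astype(im.dtype) if cfg.use_lesion_mask else im)
    return masks, masked


def extract_features(images, cfg: PipelineConfig) -> np.ndarray:
    """Fused (capsule + bottleneck) feature matrix, one row per image."""
    rows = []
    for im in images:
        a = capsnet_encode(im, cfg.caps, levels=cfg.data.levels)
        b = bottleneck_encode(im, cfg.bottleneck, levels=cfg.data.levels)
        rows.append(fuse_features(a, b).values)
    return np.vstack(rows)


def tune_hyperparameters(
    X_train, y_train, X_val, y_val,
    tuning: TuningConfig,
    hp_base: FSVMHyperparams,
    scheme: str,
    classes,
) -> tuple[FSVMHyperparams, object]:
    """DHO maximizes validation accuracy over (log10 C, log10 gamma)."""
    if len(y_val) == 0:
        raise ValueError("validation split is empty")

    def accuracy(position: np.ndarray) -> float:
        hp = dataclasses.replace(
            hp_base, C=float(10.0 ** position[0]), gamma=float(10.0 ** position[1])
        )
        model = train_multiclass(X_train, y_train, hp=hp, scheme=scheme, classes=classes)
        return float(np.mean(model.predict(X_val) == np.asarray(y_val)))

    spec = ObjectiveSpec(accuracy, [tuning.log10_C, tuning.log10_gamma], sense="maximize")
    result = dho_optimize(spec, tuning.dho)
    best = dataclasses.replace(
        hp_base,
        C=float(10.0 ** result.position[0]),
        gamma=float(10.0 ** result.position[1]),
    )
    return best, result


def run_pipeline(
    cfg: PipelineConfig,
    run_index: int = 0,
    workdir: str | Path | None = None,
    stages: tuple[str, ...] = ("preprocess", "segment", "features", "tune", "train"),
) -> RunReport:
    """Execute the full pipeline for one run; seeds are offset by run index."""
    t0 = time.time()
    timings: dict[str, float] = {}
    run_seed = cfg.seed + run_index
    cfg = dataclasses.replace(cfg, seed=run_seed)
    out = Path(workdir) if workdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def tick(stage):
        timings[stage] = time.time() - sum(timings.values()) - t0

    if cfg.manifest is not None:
        samples = load_manifest(cfg.manifest)
    else:
        samples = generate_dataset(dataclasses.replace(cfg.data, seed=cfg.data.seed + run_index))
    images = [s.image for s in samples]
    labels = np.asarray([s.label for s in samples])
    classes = list(dict.fromkeys(labels.tolist()))
    tick("data")
    logger.info("data: %d samples, classes %s", len(samples), classes)

    if "preprocess" in stages:
        images = preprocess_stage(images, cfg)
    tick("preprocess")
    logger.info("preprocess: median window %d", cfg.median.window)

    masks = None
    if "segment" in stages:
        masks, images = segment_stage(images, cfg)
        if out is not None:
            from .preprocessing import save_grayscale

            mdir = out / "masks"
            mdir.mkdir(exist_ok=True)
            for i, m in enumerate(masks):
                save_grayscale(mdir / f"mask_{i:04d}.png", m.astype(np.uint8) * 255)
    tick("segment")
    logger.info("segment: k=%d thresholds via SOA", cfg.k_thresholds)

    if "train" in stages and "features" not in stages:
        raise ValueError("training requires the features stage")
    if "features" not in stages or ("train" not in stages and "tune" not in stages):
        # preprocessing/segmentation-only invocation: no model artefacts
        return RunReport(
            run_index=run_index,
            confusion=pd.DataFrame(),
            metrics=None,
            macro=pd.Series(dtype=float),
            chosen_hyperparams={},
            selected_features=np.array([]),
            optimizer_history=[],
            stage_seconds=timings,
            config=cfg.resolved(),
            seed=run_seed,
        )

    X = extract_features(images, cfg)
    tick("features")
    logger.info("features: fused dim %d", X.shape[1])

    train_idx, test_idx = stratified_split(labels, cfg.test_fraction, seed=run_seed)
    keep = entropy_select(X[train_idx], keep=cfg.select_keep, bins=cfg.select_bins)
    Xs = X[:, keep]
    mu = Xs[train_idx].mean(axis=0)
    sd = Xs[train_idx].std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xs - mu) / sd
    if out is not None:
        pd.DataFrame(Xs, columns=[str(j) for j in keep]).to_csv(
            out / "features.csv", index=False
        )
    tick("select")

    hp = cfg.fsvm
    history = []
    if "tune" in stages and cfg.tuning.enabled:
        sub_tr, sub_val = stratified_split(
            labels[train_idx], cfg.tuning.val_fraction, seed=run_seed + 1
        )
        hp, result = tune_hyperparameters(
            Xs[train_idx][sub_tr], labels[train_idx][sub_tr],
            Xs[train_idx][sub_val], labels[train_idx][sub_val],
            cfg.tuning, cfg.fsvm, cfg.membership_scheme, classes,
        )
        history = result.history
        logger.info("tune: C=%.4g gamma=%.4g (val acc %.3f)", hp.C, hp.gamma, result.fitness)
    tick("tune")

    model = train_multiclass(
        Xs[train_idx], labels[train_idx], hp=hp,
        scheme=cfg.membership_scheme, classes=classes,
    )
    tick("train")

    pred = model.predict(Xs[test_idx])
    cm = confusion(labels[test_idx], pred, class_order=classes)
    metrics = per_class_metrics(cm)
    macro = metrics.macro()
    tick("evaluate")
    logger.info("evaluate: macro sensitivity %.4f", macro["sensitivity"])

    report = RunReport(
        run_index=run_index,
        confusion=cm,
        metrics=metrics,
        macro=macro,
        chosen_hyperparams={"C": hp.C, "gamma": hp.gamma, "kernel": hp.kernel,
                            "keep": int(cfg.select_keep)},
        selected_features=keep,
        optimizer_history=history,
        stage_seconds=timings,
        config=cfg.resolved(),
        seed=run_seed,
    )
    if out is not None:
        (out / "report.json").write_text(report.to_json())
        write_report(metrics, csv_path=out / "report.csv", md_path=out / "report.md")
        models_json = [m.to_json() for m in model.models]
        (out / "model.json").write_text(json.dumps(
            {"classes": [str(c) for c in classes], "models": models_json}
        ))
    return report
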