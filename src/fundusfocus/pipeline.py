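"""End-to-end orchestration: simulate -> segment -> fuse -> train -> evaluate.

A single ``RunConfig`` drives every stage; the emitted report carries the
configuration hash and seeds, so any output can be traced to the exact
configuration that produced it, and identical configurations reproduce
identical reports.  Disabling the fusion stage trains the classifier on
raw images — the baseline mode the lesion-focused pipeline is compared
against.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classification import (
    ClassifierSpec,
    LabelledImage,
    TrainingConfig,
    build_classifier,
    predict_proba,
    split_dataset_by_patient,
    train_diagnosis,
)
from .evaluation import (
    ThresholdPolicy,
    compute_roc,
    confusion_from_scores,
    records_to_table,
    stratify_by_median,
    table_micro_macro,
)
from .exceptions import ConfigError, StratificationError
from .fusion import (
    FusionCache,
    FusionCacheKey,
    lesion_focused_from_stack,
    select_attention_channels,
)
from .segmentation import (
    SegTrainConfig,
    SegmentationModelSpec,
    SegmentationSample,
    build_retina_unet,
    compute_iou,
    compute_lesion_score,
    compute_normalization_stats,
    predict_mask,
    resize_mask,
    train_segmentation,
)
from .synthetic import DISEASES, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "runs/demo"
    seed: int = 0
    log_level: str = "INFO"
    # stage toggles
    simulate: bool = True
    segment: bool = False
    fuse: bool = True
    train: bool = True
    evaluate: bool = True
    # synthetic cohort
    n_patients: int = 20
    images_per_patient: int = 2
    image_size: int = 64
    class_mix: dict[str, float] | None = None
    # segmentation stage
    segmentation_classes: tuple[str, ...] = ("optic disc",)
    seg_multiplier: float = 0.125
    seg_epochs: int = 20
    # classifier stage
    cls_multiplier: float = 0.25
    cls_epochs: int = 10
    cls_learning_rate: float = 3e-3
    batch_size: int = 16
    patience: int = 3
    # evaluation
    threshold_policy: str = "youden"  # screening | hospital | youden
    bootstrap_reps: int = 200
    cache_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["segmentation_classes"] = list(self.segmentation_classes)
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        except yaml.YAMLError as e:
            mark = getattr(e, "problem_mark", None)
            line = f" at line {mark.line + 1}" if mark else ""
            raise ConfigError(f"cannot parse {path}{line}: {e}") from e
        if not isinstance(raw, dict):
            raise ConfigError(f"{path} does not contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)


def validate_config(config: RunConfig) -> list[str]:
    """All violations, not just the first; empty list iff runnable."""
    issues: list[str] = []
    if config.seed < 0:
        issues.append("seed must be non-negative")
    if config.n_patients < 10 and config.train:
        issues.append("n_patients must be >= 10 for a 7:1:2 patient split")
    if config.class_mix is not None:
        if abs(sum(config.class_mix.values()) - 1.0) > 1e-6:
            issues.append("class_mix must sum to 1")
        for d in config.class_mix:
            if d not in DISEASES:
                issues.append(f"class_mix: unknown disease {d!r}")
    if not 0.0 < config.seg_multiplier <= 1.0:
        issues.append("seg_multiplier must be in (0, 1]")
    if not 0.0 < config.cls_multiplier <= 1.0:
        issues.append("cls_multiplier must be in (0, 1]")
    if config.threshold_policy not in ("screening", "hospital", "youden"):
        issues.append(
            "threshold_policy must be screening, hospital or youden "
            f"(got {config.threshold_policy!r})"
        )
    if config.image_size % 32:
        issues.append("image_size must be a multiple of 32")
    if config.segment and not config.simulate:
        issues.append("segment stage requires the simulate stage for its inputs")
    if config.fuse and not config.simulate:
        issues.append("fuse stage requires the simulate stage (registry + masks)")
    if config.train and not config.simulate:
        issues.append("train stage requires simulated images")
    if config.evaluate and not config.train:
        issues.append("evaluate stage requires the train stage's predictions")
    return issues


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run report."""
    issues = validate_config(config)
    if issues:
        raise ConfigError("; ".join(issues))
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "mode": "lesion_focused" if config.fuse else "baseline",
        "stages": {},
    }
    rng = np.random.default_rng(config.seed)

    cohort = None
    if config.simulate:
        cohort = generate_cohort(
            config.n_patients,
            class_mix=config.class_mix,
            images_per_patient=config.images_per_patient,
            seed=config.seed,
            size=config.image_size,
        )
        report["stages"]["simulate"] = {
            "n_patients": len(cohort.patients),
            "n_images": len(cohort.all_images()),
            "class_counts": cohort.manifest()["disease"].value_counts().to_dict(),
        }

    seg_models = {}
    if config.segment:
        if cohort is None:
            raise ConfigError("segment stage: missing simulated cohort")
        images = [im.image for _, im in cohort.all_images()]
        stats = compute_normalization_stats(images)
        seg_report = []
        for cls_name in config.segmentation_classes:
            samples = [
                SegmentationSample(
                    image=im.image,
                    target=im.masks.plane(cls_name),
                    patient_id=p.patient_id,
                )
                for p, im in cohort.all_images()
            ]
            spec = SegmentationModelSpec(
                target_class=cls_name,
                input_size=config.image_size,
                width_multiplier=config.seg_multiplier,
            )
            model = build_retina_unet(spec, seed=config.seed)
            model, log = train_segmentation(
                model,
                samples,
                SegTrainConfig(seed=config.seed, max_epochs=config.seg_epochs),
                stats=stats,
            )
            ious = {"train": [], "val": []}
            from .segmentation import split_train_val

            tr, va = split_train_val(samples, seed=config.seed)
            for split_name, split in (("train", tr), ("val", va)):
                for s in split:
                    pred = predict_mask(model, s.image, stats)
                    ious[split_name].append(
                        compute_iou(pred, resize_mask(s.target, config.image_size))
                    )
            iou_tr = float(np.mean(ious["train"]))
            iou_va = float(np.mean(ious["val"]))
            seg_models[cls_name] = (model, stats)
            seg_report.append(
                {
                    "class": cls_name,
                    "iou_train": iou_tr,
                    "iou_val": iou_va,
                    "score": compute_lesion_score(iou_tr, iou_va),
                    "epochs": len(log),
                }
            )
        report["stages"]["segment"] = seg_report

    samples: list[LabelledImage] = []
    if config.train or config.fuse:
        if cohort is None:
            raise ConfigError("train stage: missing simulated cohort")
        cache = FusionCache(directory=config.cache_dir)
        for p, im in cohort.all_images():
            if config.fuse:
                key = FusionCacheKey(
                    image_id=im.image.image_id,
                    registry_version=im.masks.registry.version,
                    channels=select_attention_channels(im.masks.registry),
                    fov_threshold=10,
                )
                focused = cache.get_or_compute(
                    key, lambda im=im: lesion_focused_from_stack(im.image, im.masks)
                )
                focused.patient_id = p.patient_id
                focused.image_id = im.image.image_id
                samples.append(LabelledImage(image=focused, label=p.disease))
            else:
                samples.append(LabelledImage(image=im.image, label=p.disease))
        if config.fuse:
            report["stages"]["fuse"] = {
                "n_images": len(samples),
                "cache_hits": cache.hits,
                "cache_misses": cache.misses,
            }

    table = None
    if config.train:
        splits = split_dataset_by_patient(samples, seed=config.seed)
        spec = ClassifierSpec(
            num_classes=len(DISEASES),
            width_multiplier=config.cls_multiplier,
            input_size=config.image_size,
        )
        model = build_classifier(spec, seed=config.seed)
        model, log = train_diagnosis(
            model,
            splits,
            TrainingConfig(
                seed=config.seed,
                learning_rate=config.cls_learning_rate,
                batch_size=config.batch_size,
                max_epochs=config.cls_epochs,
                patience=config.patience,
                classes=DISEASES,
            ),
        )
        records = predict_proba(model, splits[2], classes=DISEASES)
        table = records_to_table(records)
        table.to_csv(outdir / "predictions.csv", index=False)
        report["stages"]["train"] = {
            "epochs_run": len(log),
            "best_val_loss": float(min(l["val_loss"] for l in log)),
            "n_test_images": len(records),
        }

    if config.evaluate:
        if table is None:
            raise ConfigError("evaluate stage: missing prediction table")
        micro, macro = table_micro_macro(table)
        policy = ThresholdPolicy(mode=config.threshold_policy)
        per_disease = {}
        for disease in DISEASES:
            labels = (table["true_label"] == disease).astype(int)
            if labels.nunique() < 2 or labels.sum() == 0:
                continue
            scores = table[f"score_{disease}"]
            roc = compute_roc(scores, labels)
            thr = policy.apply(roc)
            cm = confusion_from_scores(scores, labels, thr)
            entry = {
                "auroc": roc.auc,
                "threshold": thr,
                "sensitivity": cm.sensitivity,
                "specificity": cm.specificity,
                "accuracy": cm.accuracy,
            }
            try:
                strata = stratify_by_median(
                    table,
                    disease,
                    bootstrap_reps=config.bootstrap_reps,
                    seed=config.seed,
                )
                entry["odds_ratio"] = strata.odds_ratio
                entry["or_ci"] = list(strata.or_ci)
                entry["chi2_p"] = strata.p_value
                strata.to_frame().to_csv(
                    outdir / f"strata_{disease}.csv", index=False
                )
            except StratificationError:
                entry["odds_ratio"] = None
            per_disease[disease] = entry
        report["stages"]["evaluate"] = {
            "micro_auroc": micro,
            "macro_auroc": macro,
            "per_disease": per_disease,
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
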