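"""End-to-end experimental protocol.

The corpus is split into three pairwise-disjoint stratified cohorts
(910 = 374 + 352 + 184 by default, mirroring the study design):

1. *base-training cohort* — trains the conventional model and the
   improved-extractor + SVM model;
2. *stacking cohort* — scored by both trained base models; those scores
   train the ANN combiner (base models never retrain on it);
3. *validation cohort* — held out until the final three-way evaluation.

Every stochastic stage draws its seed deterministically from the global
seed, so a fixed config reproduces the whole run bit-for-bit (the metric
JSON is byte-identical across repeats).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import pickle
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import metrics as M
from .backbone import BackboneSpec, FeatureExtractor, build_backbone
from .conventional import ConventionalModel, TrainConfig, predict_proba, \
    train_conventional
from .errors import ValidationError
from .multimodel import Combiner, StackedModel, combine_predict, fit_combiner
from .svm_head import SVMModel, fit_svm, svm_score
from .synthetic import ImageSample, SynthParams, generate_dataset, load_dataset

__all__ = ["CohortSplit", "PipelineConfig", "split_cohorts", "run_pipeline",
           "make_improved_scorer", "audit_report"]

log = logging.getLogger("granulenet.pipeline")


@dataclass(frozen=True)
class CohortSplit:
    """Disjoint sample-index sets for the three protocol cohorts."""

    train_ids: tuple[int, ...]
    stack_ids: tuple[int, ...]
    valid_ids: tuple[int, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        a, b, c = set(self.train_ids), set(self.stack_ids), set(self.valid_ids)
        if a & b or a & c or b & c:
            raise ValidationError("cohorts must be pairwise disjoint")


def _largest_remainder(m: int, sizes: tuple[int, ...], total: int) -> list[int]:
    """Allocate m class members across cohorts proportionally to sizes."""
    quotas = [s * m / total for s in sizes]
    alloc = [int(q) for q in quotas]
    rem = m - sum(alloc)
    order = sorted(range(len(sizes)), key=lambda i: quotas[i] - alloc[i],
                   reverse=True)
    for i in order[:rem]:
        alloc[i] += 1
    return alloc


def split_cohorts(labels_or_dataset, sizes: tuple[int, int, int],
                  seed: int = 0) -> CohortSplit:
    """Seeded stratified split into three disjoint cohorts of exact sizes.

    Each class is allocated across cohorts by largest-remainder rounding of
    its proportional quota, then adjusted so every cohort holds both classes.
    """
    if hasattr(labels_or_dataset[0], "y"):
        labels = np.array([s.y for s in labels_or_dataset])
    else:
        labels = np.asarray(labels_or_dataset).astype(int)
    n = len(labels)
    if sum(sizes) != n:
        raise ValidationError(f"cohort sizes {sizes} do not sum to dataset size {n}")
    if min(sizes) < 2:
        raise ValidationError("every cohort needs >= 2 samples (both classes)")
    rng = np.random.default_rng(seed)
    idx_pos = rng.permutation(np.flatnonzero(labels == 1)).tolist()
    idx_neg = rng.permutation(np.flatnonzero(labels == 0)).tolist()
    if not idx_pos or not idx_neg:
        raise ValidationError("dataset must contain both classes")
    alloc_pos = _largest_remainder(len(idx_pos), sizes, n)
    alloc_neg = [s - a for s, a in zip(sizes, alloc_pos)]
    for i in range(3):  # ensure both classes everywhere
        for alloc_a, alloc_b, pool_a in ((alloc_pos, alloc_neg, idx_pos),
                                         (alloc_neg, alloc_pos, idx_neg)):
            if alloc_a[i] < 1:
                donor = max(range(3), key=lambda j: alloc_a[j])
                alloc_a[donor] -= 1
                alloc_a[i] += 1
                alloc_b[donor] += 1
                alloc_b[i] -= 1
    if min(alloc_pos) < 1 or min(alloc_neg) < 1 or \
            any(a < 0 for a in alloc_pos + alloc_neg):
        raise ValidationError("dataset too imbalanced to stratify these sizes")
    cohorts: list[list[int]] = [[], [], []]
    p = q = 0
    for i in range(3):
        cohorts[i] = idx_pos[p:p + alloc_pos[i]] + idx_neg[q:q + alloc_neg[i]]
        p += alloc_pos[i]
        q += alloc_neg[i]
    return CohortSplit(train_ids=tuple(sorted(cohorts[0])),
                       stack_ids=tuple(sorted(cohorts[1])),
                       valid_ids=tuple(sorted(cohorts[2])), seed=seed)


@dataclass
class PipelineConfig:
    """Everything one run needs; the global seed feeds every stage."""

    synth: SynthParams = field(default_factory=SynthParams.tiny)
    manifest: str | None = None   # CSV manifest of real images; overrides synth
    scale: str = "tiny"
    sizes: tuple[int, int, int] = (60, 40, 40)
    train: TrainConfig | None = None
    svm: dict[str, Any] = field(default_factory=dict)        # fit_svm kwargs
    combiner: dict[str, Any] = field(default_factory=dict)   # fit_combiner kwargs
    seed: int = 11
    out_dir: str | None = None

    def backbone_spec(self) -> BackboneSpec:
        return BackboneSpec.from_scale(self.scale)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output path excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def make_improved_scorer(extractor: FeatureExtractor, model: SVMModel):
    """Image -> improved-model score in (0, 1) (SVM decision, logistic link)."""
    def scorer(image: ImageSample | np.ndarray) -> float:
        return float(svm_score(model, extractor.extract(image).flat))
    return scorer


def _evaluate(y_true: np.ndarray, scores: np.ndarray) -> dict:
    preds = (scores >= 0.5).astype(int)
    cm = M.confusion_matrix(y_true, preds)
    report = M.metrics_report(cm)
    roc = M.roc_curve(y_true, scores)
    report["auroc"] = roc.auroc
    report["roc"] = {"fpr": list(roc.fpr), "tpr": list(roc.tpr)}
    return report


def audit_report(report: dict) -> None:
    """Recompute every table metric from the stored confusion matrices.

    Raises ``ValidationError`` if any stored value disagrees with what the
    metrics module derives from the stored counts.
    """
    for name, entry in report["models"].items():
        c = entry["confusion_matrix"]
        cm = M.ConfusionMatrix(tp=c["TP"], fn=c["FN"], fp=c["FP"], tn=c["TN"])
        expected = M.metrics_report(cm)
        for level in ("raw", "rounded"):
            for key, val in expected[level].items():
                if not np.isclose(entry[level][key], val, atol=0, rtol=0):
                    raise ValidationError(
                        f"self-consistency audit failed: {name}.{level}.{key}")


def _check_disjoint(split: CohortSplit) -> None:
    ids = list(split.train_ids) + list(split.stack_ids) + list(split.valid_ids)
    if len(ids) != len(set(ids)):
        raise ValidationError("a sample id appears in more than one cohort")


def run_pipeline(config: PipelineConfig) -> dict:
    """Full protocol; returns the evaluation report (also written to disk).

    Stages: simulate -> split -> train base models on cohort 1 -> score
    cohort 2 and fit the combiner -> evaluate all three models on cohort 3
    -> audit and write reports.
    """
    t_start = time.time()
    cfg_hash = config.config_hash()
    seed = config.seed
    spec = config.backbone_spec()
    n_total = sum(config.sizes)
    if config.manifest is not None:
        log.info("stage=load config=%s manifest=%s", cfg_hash, config.manifest)
        dataset = load_dataset(config.manifest)
        if len(dataset) != n_total:
            raise ValidationError(
                f"manifest holds {len(dataset)} images; cohort sizes need "
                f"{n_total}")
    else:
        if n_total % 2:
            raise ValidationError("cohort sizes must sum to an even total "
                                  "(balanced synthetic classes)")
        log.info("stage=simulate config=%s n=%d", cfg_hash, n_total)
        dataset = generate_dataset(n_total // 2, config.synth, seed=seed)
    labels = np.array([s.y for s in dataset])

    log.info("stage=split config=%s", cfg_hash)
    split = split_cohorts(labels, config.sizes, seed=seed + 1)
    _check_disjoint(split)
    train_set = [dataset[i] for i in split.train_ids]
    stack_set = [dataset[i] for i in split.stack_ids]
    valid_set = [dataset[i] for i in split.valid_ids]

    log.info("stage=train-improved config=%s", cfg_hash)
    improved_ext = build_backbone(spec, init="random", seed=seed + 2)
    feats_train = np.stack([improved_ext.extract(s).flat for s in train_set])
    y_train = np.array([s.y for s in train_set])
    svm_model = fit_svm(feats_train, y_train, **config.svm)
    improved_scorer = make_improved_scorer(improved_ext, svm_model)

    log.info("stage=train-conventional config=%s", cfg_hash)
    # From-scratch head on frozen features: Adam 1e-2 with small batches
    # (the 1e-5 TrainConfig default is the pretrained fine-tuning rate).
    train_cfg = config.train or TrainConfig(learning_rate=1e-2, batch_size=4,
                                            seed=seed + 3)
    conventional = train_conventional(train_set, spec, train_cfg)

    log.info("stage=train-multimodel config=%s", cfg_hash)
    y_stack = np.array([s.y for s in stack_set])
    s1_stack = np.array([improved_scorer(s) for s in stack_set])
    s2_stack = np.array([predict_proba(conventional, s) for s in stack_set])
    combiner = fit_combiner(s1_stack, s2_stack, y_stack, seed=seed + 4,
                            **config.combiner)
    stacked = StackedModel(improved_scorer=improved_scorer,
                           conventional_model=conventional, combiner=combiner)

    log.info("stage=evaluate config=%s", cfg_hash)
    y_valid = np.array([s.y for s in valid_set])
    s1_valid = np.array([improved_scorer(s) for s in valid_set])
    s2_valid = np.array([predict_proba(conventional, s) for s in valid_set])
    s3_valid = np.array([combine_predict(stacked, s)[0] for s in valid_set])

    report = {
        "config_hash": cfg_hash,
        "seed": seed,
        "scale": config.scale,
        "cohort_sizes": {"train": len(split.train_ids),
                         "stack": len(split.stack_ids),
                         "valid": len(split.valid_ids)},
        "models": {
            "conventional": _evaluate(y_valid, s2_valid),
            "improved_svm": _evaluate(y_valid, s1_valid),
            "multimodel": _evaluate(y_valid, s3_valid),
        },
    }
    audit_report(report)
    log.info("stage=report config=%s wall_s=%.1f", cfg_hash,
             time.time() - t_start)

    if config.out_dir:
        _write_outputs(report, stacked, svm_model, improved_ext, config)
    return report


def _write_outputs(report: dict, stacked: StackedModel, svm_model: SVMModel,
                   improved_ext: FeatureExtractor,
                   config: PipelineConfig) -> None:
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
    # Table-style CSV (rows: metric, columns: the three models).
    rows = ["metric,conventional,improved_svm,multimodel"]
    for key in ("precision", "recall", "f1", "accuracy"):
        vals = [report["models"][m]["rounded"][key]
                for m in ("conventional", "improved_svm", "multimodel")]
        rows.append(",".join([key] + [f"{v:.2f}" for v in vals]))
    rows.append(",".join(["auroc"] + [
        f"{report['models'][m]['auroc']:.3f}"
        for m in ("conventional", "improved_svm", "multimodel")]))
    with open(os.path.join(out, "metrics.csv"), "w") as fh:
        fh.write("\n".join(rows) + "\n")
    plot_roc(report, os.path.join(out, "roc.png"))
    with open(os.path.join(out, "models.pkl"), "wb") as fh:
        pickle.dump({"version": 1, "svm": svm_model,
                     "improved_extractor": improved_ext,
                     "conventional": stacked.conventional_model,
                     "combiner": stacked.combiner,
                     "config_hash": report["config_hash"]}, fh)


def plot_roc(report: dict, path: str) -> None:
    """Three-model ROC figure with the diagonal random-guessing reference."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    colors = {"multimodel": "tab:green", "improved_svm": "tab:orange",
              "conventional": "tab:blue"}
    for name, entry in report["models"].items():
        ax.plot(entry["roc"]["fpr"], entry["roc"]["tpr"],
                label=f"{name} (AUROC={entry['auroc']:.3f})",
                color=colors.get(name))
    ax.plot([0, 1], [0, 1], "r--", label="random guessing")
    ax.set_xlabel("False Positive Rate")
    ax.set_ylabel("True Positive Rate")
    ax.set_title("ROC — model comparison")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
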