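"""Metrics, patient-level splitting, and the multi-arm comparison harness.

Malignant is the positive class throughout.  Splits are patient-level and
class-stratified by default so near-duplicate patches of one patient can
never leak across the train/test boundary; image-level splitting exists
behind a flag for faithfulness experiments.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .dim_raising import RaiserConfig, corrupt, encode as raiser_encode, fit_raiser
from .emr_schema import LABELS, StructuredRecord, encode_record
from .fusion import FusionHeadSpec, TrainingSchedule, fit_head
from .image_backbone import multilevel_features_batch, train_backbone_classifier
from ._nn import MLP, Adam, cross_entropy

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "Arm",
    "accuracy",
    "confusion_counts",
    "roc_auc",
    "patient_split",
    "compare_methods",
]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclasses.dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if counts.total == 0:
        raise ValueError("cannot compute accuracy of zero samples")
    return (counts.TP + counts.TN) / counts.total


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Counts with malignant (1) as the positive class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must share a shape")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """Empirical ROC curve and its trapezoidal area.

    The area equals the proportion of (positive, negative) pairs ranked
    correctly, counting ties as 1/2 (the Mann-Whitney statistic).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("roc_auc requires both classes to be present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def patient_split(
    records: Sequence[StructuredRecord],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Class-stratified patient-level partition into (train ids, test ids)."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    by_class: dict[str, list[str]] = {lab: [] for lab in LABELS}
    for rec in records:
        if rec.label not in LABELS:
            raise ValueError(f"patient {rec.patient_id} has no usable label")
        by_class[rec.label].append(rec.patient_id)
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for lab in LABELS:
        ids = sorted(by_class[lab])
        if len(ids) < 2:
            raise ValueError(f"need at least 2 patients of class {lab!r}")
        rng.shuffle(ids)
        n_train = int(np.clip(round(train_fraction * len(ids)), 1, len(ids) - 1))
        train_ids.extend(ids[:n_train])
        test_ids.extend(ids[n_train:])
    return sorted(train_ids), sorted(test_ids)


# ---------------------------------------------------------------------------
# Comparison harness
# ---------------------------------------------------------------------------

_ARM_KINDS = ("record_only", "image_only", "fused")


@dataclasses.dataclass(frozen=True)
class Arm:
    """One experimental arm of the comparison table."""

    name: str
    kind: str = "fused"
    raiser_method: str = "denoising_autoencoder_l1"
    source_stages: tuple[int, ...] = (3, 4, 5)
    image_projection: int | None = None  # trailing FC width on the image feature

    def __post_init__(self) -> None:
        if self.kind not in _ARM_KINDS:
            raise ValueError(f"unknown arm kind {self.kind!r}; valid: {_ARM_KINDS}")


def _project_image_features(
    train_feats: np.ndarray, y_train: np.ndarray, test_feats: np.ndarray,
    width: int, seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Train an extra (feat -> width -> 2) layer pair and tap the hidden layer.

    Replicates the "trailing fully connected layer of width d on the
    backbone" ablation: the d-wide hidden activation becomes the image
    feature.
    """
    rng = np.random.default_rng(seed)
    mu = train_feats.mean(axis=0)
    sd = train_feats.std(axis=0)
    sd[sd < 1e-8] = 1.0
    Xtr = (train_feats - mu) / sd
    Xte = (test_feats - mu) / sd
    mlp = MLP((train_feats.shape[1], width, 2), rng, output="linear")
    opt = Adam(mlp.parameters(), lr=1e-3)
    for _ in range(60):
        order = rng.permutation(len(Xtr))
        for start in range(0, len(Xtr), 32):
            idx = order[start:start + 32]
            logits, acts = mlp.forward(Xtr[idx], return_hidden=True)
            _, dlogits = cross_entropy(logits, y_train[idx])
            opt.step(mlp.backward(acts, dlogits))
    hidden_tr = mlp.forward(Xtr, return_hidden=True)[1][1]
    hidden_te = mlp.forward(Xte, return_hidden=True)[1][1]
    return hidden_tr, hidden_te


def compare_methods(
    cohort,
    arms: Sequence[Arm],
    n_seeds: int = 10,
    schedule: TrainingSchedule | None = None,
    missing_rates: Sequence[float] = (0.0,),
    train_fraction: float = 0.8,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Train and evaluate every arm on identical splits/seeds.

    Returns a tidy table with one row per (arm, seed, missing_rate) holding
    image-level test accuracy and AUC.  Test-time record corruption at the
    requested ``missing_rates`` implements the robustness sweep; image-only
    arms are unaffected by record corruption by construction.
    """
    from .fusion import TrainingSchedule as _TS

    sched = schedule or _TS()
    names = [a.name for a in arms]
    if len(set(names)) != len(names):
        raise ValueError("arm names must be unique")

    record_by_pid = {r.patient_id: r for r in cohort.records}
    manifest = cohort.manifest
    rows = []
    for k in range(n_seeds):
        seed = base_seed + k
        train_ids, test_ids = patient_split(cohort.records, train_fraction, seed=seed)
        tr_set, te_set = set(train_ids), set(test_ids)
        tr_idx = manifest.index[manifest["patient_id"].isin(tr_set)].to_numpy()
        te_idx = manifest.index[manifest["patient_id"].isin(te_set)].to_numpy()

        imgs_tr = np.stack([cohort.images[i] for i in tr_idx])
        imgs_te = np.stack([cohort.images[i] for i in te_idx])
        y_tr = np.array([LABELS.index(manifest["label"][i]) for i in tr_idx])
        y_te = np.array([LABELS.index(manifest["label"][i]) for i in te_idx])
        rec_tr = np.stack(
            [encode_record(record_by_pid[manifest["patient_id"][i]])[0] for i in tr_idx]
        )
        rec_te = np.stack(
            [encode_record(record_by_pid[manifest["patient_id"][i]])[0] for i in te_idx]
        )

        needs_images = any(a.kind != "record_only" for a in arms)
        backbone = None
        if needs_images:
            backbone = train_backbone_classifier(
                imgs_tr, y_tr, sched.backbone_spec, sched.backbone_train, seed=seed
            )

        # Phase 1 per distinct raiser method, fitted on unique training records.
        unique_tr_records = np.stack(
            [encode_record(record_by_pid[pid])[0] for pid in train_ids]
        )
        raisers = {}
        for arm in arms:
            if arm.kind == "image_only" or arm.raiser_method in raisers:
                continue
            cfg = dataclasses.replace(sched.raiser_config, method=arm.raiser_method)
            raisers[arm.raiser_method] = fit_raiser(unique_tr_records, cfg, seed=seed)

        img_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}

        def image_feats(arm: Arm):
            key = (arm.source_stages, arm.image_projection)
            if key not in img_cache:
                ftr = multilevel_features_batch(backbone, imgs_tr, arm.source_stages)
                fte = multilevel_features_batch(backbone, imgs_te, arm.source_stages)
                if arm.image_projection is not None:
                    ftr, fte = _project_image_features(
                        ftr, y_tr, fte, arm.image_projection, seed
                    )
                img_cache[key] = (ftr, fte)
            return img_cache[key]

        for arm in arms:
            blocks_tr: list[np.ndarray] = []
            if arm.kind != "image_only":
                raiser = raisers[arm.raiser_method]
                blocks_tr.append(raiser_encode(raiser, rec_tr))
            if arm.kind != "record_only":
                ftr, fte = image_feats(arm)
                blocks_tr.append(ftr)
            F_tr = np.concatenate(blocks_tr, axis=1)
            head = fit_head(
                F_tr, y_tr, sched.head_spec, seed=seed, epochs=sched.head_epochs,
                learning_rate=sched.head_learning_rate,
                batch_size=sched.head_batch_size,
            )

            for rate in missing_rates:
                rec_eval = rec_te
                if rate > 0:
                    rec_eval = corrupt(rec_te, rate, seed=seed * 7919 + 13)[0]
                blocks_te: list[np.ndarray] = []
                if arm.kind != "image_only":
                    blocks_te.append(raiser_encode(raisers[arm.raiser_method], rec_eval))
                if arm.kind != "record_only":
                    blocks_te.append(image_feats(arm)[1])
                F_te = np.concatenate(blocks_te, axis=1)
                proba = head.predict_proba(F_te)
                pred = (proba[:, 1] > proba[:, 0]).astype(int)
                acc = accuracy(confusion_counts(y_te, pred))
                auc = roc_auc(proba[:, 1], y_te).auc
                rows.append({
                    "arm": arm.name, "seed": seed, "missing_rate": rate,
                    "accuracy": acc, "auc": auc, "n_test": len(y_te),
                })
    return pd.DataFrame(rows)
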