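"""Fusion of the raised record code with the multilevel image feature, the
fully connected classification head, and the three-phase training schedule.

Phase 1 fits the dimension raiser on the training records alone; phase 2
trains the backbone classifier on the training images alone; phase 3 freezes
both and trains the head (500-100-2 at full scale) with softmax
cross-entropy on fused vectors.  A patient's record code is duplicated
across all of that patient's images.  The fused vector is the record code
followed by the image feature (580 + 1280 = 1860-d at full scale).

Label convention: benign = 0, malignant = 1 (positive class).  Prediction
ties break toward benign.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from ._nn import MLP, Adam, cross_entropy, softmax
from .dim_raising import DimensionRaiser, RaiserConfig, encode as raiser_encode, fit_raiser
from .emr_schema import LABELS, StructuredRecord, encode_record
from .image_backbone import (
    Backbone,
    BackboneSpec,
    TrainConfig,
    multilevel_features_batch,
    train_backbone_classifier,
)

__all__ = [
    "PairedSample",
    "FusionHeadSpec",
    "TrainingSchedule",
    "FusionModel",
    "fuse",
    "fit_head",
    "train_three_phase",
    "predict",
    "predict_patient",
]


@dataclasses.dataclass
class PairedSample:
    image: np.ndarray  # (S, S, 3) in [0,1]
    record: StructuredRecord
    label: str
    patient_id: str

    def __post_init__(self) -> None:
        if self.label != self.record.label:
            raise ValueError(
                f"sample label {self.label!r} differs from record label "
                f"{self.record.label!r} for patient {self.patient_id}"
            )


@dataclasses.dataclass(frozen=True)
class FusionHeadSpec:
    layer_widths: tuple[int, ...] = (500, 100, 2)

    def __post_init__(self) -> None:
        if self.layer_widths[-1] != 2:
            raise ValueError("final head width must equal the number of classes (2)")


@dataclasses.dataclass
class TrainingSchedule:
    raiser_config: RaiserConfig = dataclasses.field(default_factory=RaiserConfig)
    backbone_spec: BackboneSpec = dataclasses.field(default_factory=BackboneSpec)
    backbone_train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    head_spec: FusionHeadSpec = dataclasses.field(default_factory=FusionHeadSpec)
    head_epochs: int = 80
    head_learning_rate: float = 1e-3
    head_batch_size: int = 32
    source_stages: tuple[int, ...] = (3, 4, 5)
    seed: int = 0


class _Head:
    """Fused-vector classifier: train-set standardization + MLP logits."""

    def __init__(self, mlp: MLP, mu: np.ndarray, sigma: np.ndarray) -> None:
        self.mlp = mlp
        self.mu = mu
        self.sigma = sigma
        self.history: list[float] = []

    def logits(self, features: np.ndarray) -> np.ndarray:
        return self.mlp.forward((features - self.mu) / self.sigma)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return softmax(self.logits(features))


def desk_schedule(seed: int = 0) -> TrainingSchedule:
    """Reduced-scale schedule sized so full pipelines run in minutes on one CPU."""
    from .image_backbone import REDUCED

    return TrainingSchedule(
        raiser_config=RaiserConfig(
            layer_widths=(29, 116, 58, 116, 29), epochs=150, batch_size=16,
        ),
        backbone_spec=REDUCED,
        backbone_train=TrainConfig(epochs=16, learning_rate=1e-3, batch_size=16),
        head_spec=FusionHeadSpec((64, 16, 2)),
        head_epochs=60,
        seed=seed,
    )


@dataclasses.dataclass
class FusionModel:
    raiser: DimensionRaiser
    backbone: Backbone
    head: _Head
    source_stages: tuple[int, ...]
    trained: bool = False
    log: list = dataclasses.field(default_factory=list)

    def image_features(self, images: np.ndarray) -> np.ndarray:
        return multilevel_features_batch(self.backbone, images, self.source_stages)

    def record_code(self, record: StructuredRecord) -> np.ndarray:
        vec, _ = encode_record(record)
        return raiser_encode(self.raiser, vec)


def fuse(code: np.ndarray, img_feat) -> np.ndarray:
    """Concatenate record code (first) and image feature (second)."""
    code = np.asarray(code, dtype=np.float64)
    img = np.asarray(getattr(img_feat, "values", img_feat), dtype=np.float64)
    if not (np.all(np.isfinite(code)) and np.all(np.isfinite(img))):
        raise ValueError("fuse requires finite inputs")
    return np.concatenate([code, img], axis=-1)


def fit_head(
    features: np.ndarray,
    labels: np.ndarray,
    head_spec: FusionHeadSpec = FusionHeadSpec(),
    seed: int = 0,
    epochs: int = 80,
    learning_rate: float = 1e-3,
    batch_size: int = 32,
) -> _Head:
    """Train the fully connected head on (fused) feature vectors.

    Features are standardized with train-set statistics (stored in the head)
    so the record-code and image-feature blocks contribute on a common scale.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    sigma[sigma < 1e-8] = 1.0
    Xs = (X - mu) / sigma

    rng = np.random.default_rng(seed)
    mlp = MLP((X.shape[1], *head_spec.layer_widths), rng, output="linear")
    opt = Adam(mlp.parameters(), lr=learning_rate)
    n = X.shape[0]
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            logits, acts = mlp.forward(Xs[idx], return_hidden=True)
            loss, dlogits = cross_entropy(logits, y[idx])
            opt.step(mlp.backward(acts, dlogits))
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / n_batches)
    head = _Head(mlp, mu, sigma)
    head.history = history
    return head


def _pair_arrays(samples: Sequence[PairedSample]):
    images = np.stack([s.image for s in samples])
    labels = np.array([LABELS.index(s.label) for s in samples], dtype=np.int64)
    codes_in = np.stack([encode_record(s.record)[0] for s in samples])
    return images, labels, codes_in


def train_three_phase(
    samples: Sequence[PairedSample],
    schedule: TrainingSchedule | None = None,
    seed: int | None = None,
) -> FusionModel:
    """Run the full three-phase schedule on a paired training cohort."""
    sched = schedule or TrainingSchedule()
    seed = sched.seed if seed is None else seed
    if not samples:
        raise ValueError("empty training cohort")
    labels = {LABELS.index(s.label) for s in samples}
    if len(labels) < 2:
        raise ValueError("training cohort must contain both classes")

    # Phase 1: raiser on the (unique) training records.
    by_patient: dict[str, StructuredRecord] = {}
    for s in samples:
        by_patient.setdefault(s.patient_id, s.record)
    record_matrix = np.stack([encode_record(r)[0] for r in by_patient.values()])
    raiser = fit_raiser(record_matrix, sched.raiser_config, seed=seed)

    # Phase 2: backbone classifier on the training images.
    images, y, codes_in = _pair_arrays(samples)
    backbone = train_backbone_classifier(
        images, y, sched.backbone_spec, sched.backbone_train, seed=seed
    )

    # Phase 3: freeze both, train the head on fused vectors (record codes
    # duplicated across each patient's images by construction of `samples`).
    img_feats = multilevel_features_batch(backbone, images, sched.source_stages)
    codes = raiser_encode(raiser, codes_in)
    fused = np.concatenate([codes, img_feats], axis=1)

    def _frozen_fingerprint() -> tuple[bytes, ...]:
        parts = list(backbone.parameter_fingerprint())
        if raiser.model is not None:
            parts.extend(p.tobytes() for p in raiser.model.parameters())
        return tuple(parts)

    fp_before = _frozen_fingerprint()
    head = fit_head(
        fused, y, sched.head_spec, seed=seed, epochs=sched.head_epochs,
        learning_rate=sched.head_learning_rate, batch_size=sched.head_batch_size,
    )
    fp_after = _frozen_fingerprint()
    return FusionModel(
        raiser=raiser, backbone=backbone, head=head,
        source_stages=tuple(sched.source_stages), trained=True,
        log=[{"phase3_parameters_frozen": fp_before == fp_after}],
    )


def predict(model: FusionModel, sample: PairedSample) -> tuple[float, float]:
    """(benign, malignant) probability pair for one paired sample."""
    if not model.trained:
        raise ValueError("model is not trained")
    code = model.record_code(sample.record)
    img_feat = model.image_features(sample.image[None])[0]
    proba = model.head.predict_proba(fuse(code, img_feat)[None])[0]
    return float(proba[0]), float(proba[1])


def predicted_class(proba: tuple[float, float]) -> str:
    """Argmax with ties broken toward benign."""
    return "malignant" if proba[1] > proba[0] else "benign"


def save_model(model: FusionModel, path) -> None:
    """Serialize a trained fusion model (format v1, single npz archive)."""
    import json

    arrays: dict[str, np.ndarray] = {}
    if model.raiser.model is not None:
        for i, layer in enumerate(model.raiser.model.layers):
            arrays[f"raiser_W{i}"] = layer.W
            arrays[f"raiser_b{i}"] = layer.b
    for i, (W, b) in enumerate(zip(model.backbone.conv_W, model.backbone.conv_b)):
        arrays[f"conv_W{i}"] = W
        arrays[f"conv_b{i}"] = b
    arrays["head_W"] = model.backbone.head_W
    arrays["head_b"] = model.backbone.head_b
    for i, layer in enumerate(model.head.mlp.layers):
        arrays[f"fc_W{i}"] = layer.W
        arrays[f"fc_b{i}"] = layer.b
    arrays["fc_mu"] = model.head.mu
    arrays["fc_sigma"] = model.head.sigma
    meta = {
        "raiser_config": dataclasses.asdict(model.raiser.config),
        "backbone_spec": dataclasses.asdict(model.backbone.spec),
        "head_widths": list(model.head.mlp.widths),
        "source_stages": list(model.source_stages),
    }
    np.savez(path, __format__=np.array("richfuse-fusion-v1"),
             meta=np.array(json.dumps(meta)), **arrays)


def load_model(path) -> FusionModel:
    import json

    from .image_backbone import Backbone

    with np.load(path, allow_pickle=False) as data:
        if str(data["__format__"]) != "richfuse-fusion-v1":
            raise ValueError("unrecognized fusion model archive format")
        meta = json.loads(str(data["meta"]))
        rcfg_d = meta["raiser_config"]
        rcfg_d["layer_widths"] = tuple(rcfg_d["layer_widths"])
        rcfg = RaiserConfig(**rcfg_d)
        raiser_model = None
        if "raiser_W0" in data:
            raiser_model = MLP(rcfg.layer_widths, np.random.default_rng(0), output="sigmoid")
            for i, layer in enumerate(raiser_model.layers):
                layer.W = data[f"raiser_W{i}"]
                layer.b = data[f"raiser_b{i}"]
        raiser = DimensionRaiser(config=rcfg, model=raiser_model, fitted=True)

        bspec_d = meta["backbone_spec"]
        bspec_d["stage_channels"] = tuple(bspec_d["stage_channels"])
        bspec_d["convs_per_stage"] = tuple(bspec_d["convs_per_stage"])
        backbone = Backbone(BackboneSpec(**bspec_d))
        for i in range(len(backbone.conv_W)):
            backbone.conv_W[i] = data[f"conv_W{i}"]
            backbone.conv_b[i] = data[f"conv_b{i}"]
        backbone.head_W = data["head_W"]
        backbone.head_b = data["head_b"]
        backbone.trained = True

        widths = tuple(meta["head_widths"])
        mlp = MLP(widths, np.random.default_rng(0), output="linear")
        for i, layer in enumerate(mlp.layers):
            layer.W = data[f"fc_W{i}"]
            layer.b = data[f"fc_b{i}"]
        head = _Head(mlp, data["fc_mu"], data["fc_sigma"])
        return FusionModel(
            raiser=raiser, backbone=backbone, head=head,
            source_stages=tuple(meta["source_stages"]), trained=True,
        )


def predict_patient(model: FusionModel, samples: Sequence[PairedSample]) -> tuple[float, float]:
    """Patient-level probabilities: arithmetic mean of per-image pairs."""
    if not samples:
        raise ValueError("need at least one sample")
    pids = {s.patient_id for s in samples}
    if len(pids) > 1:
        raise ValueError(f"samples span multiple patients: {sorted(pids)}")
    probs = np.array([predict(model, s) for s in samples])
    mean = probs.mean(axis=0)
    return float(mean[0]), float(mean[1])
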