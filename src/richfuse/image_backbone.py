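"""Five-stage convolutional backbone with multilevel feature extraction.

The full-scale preset is the classic 16-layer layout (stage channel widths
64-128-256-512-512, conv counts 2-2-3-3-3, 224x224 input).  Each stage is a
run of 3x3 same-padding convolutions with ReLU followed by 2x2 max pooling;
the "stage output" tapped for multilevel features is the last conv+ReLU map
of the stage, *before* that stage's pooling, so at full scale stages 3/4/5
give 56x56x256, 28x28x512 and 14x14x512 maps.  Average-pooling those maps to
per-channel means and concatenating them (ascending stage order) yields the
multilevel feature — 256+512+512 = 1280-d at full scale.

All length contracts are sums over configured widths; reduced-scale specs for
desk-size tests are first-class.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from ._nn import (
    Adam,
    conv3x3_backward,
    conv3x3_forward,
    cross_entropy,
    maxpool2_backward,
    maxpool2_forward,
    relu,
    softmax,
)

__all__ = [
    "BackboneSpec",
    "StageFeatureMap",
    "MultilevelFeature",
    "Backbone",
    "TrainConfig",
    "build_backbone",
    "stage_outputs",
    "global_average_pool",
    "multilevel_features",
    "multilevel_features_batch",
    "train_backbone_classifier",
    "FULL_SCALE",
    "REDUCED",
]


@dataclasses.dataclass(frozen=True)
class BackboneSpec:
    stage_channels: tuple[int, ...] = (64, 128, 256, 512, 512)
    convs_per_stage: tuple[int, ...] = (2, 2, 3, 3, 3)
    input_side: int = 224
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.stage_channels) != 5 or len(self.convs_per_stage) != 5:
            raise ValueError("spec requires exactly 5 stages")
        if any(c < 1 for c in self.stage_channels + self.convs_per_stage):
            raise ValueError("stage channels and conv counts must be positive")
        if self.input_side % 32 != 0 or self.input_side <= 0:
            raise ValueError(f"input_side must be a positive multiple of 32, got {self.input_side}")

    def stage_side(self, stage: int) -> int:
        """Pre-pooling spatial side of stage ``stage`` (1-based)."""
        return self.input_side // 2 ** (stage - 1)

    def multilevel_dim(self, source_stages: Sequence[int] = (3, 4, 5)) -> int:
        return sum(self.stage_channels[s - 1] for s in source_stages)


FULL_SCALE = BackboneSpec()
REDUCED = BackboneSpec(stage_channels=(8, 16, 16, 32, 32),
                       convs_per_stage=(1, 1, 1, 1, 1), input_side=64)


@dataclasses.dataclass
class StageFeatureMap:
    stage_index: int
    values: np.ndarray  # (H, W, C)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def channels(self) -> int:
        return self.values.shape[2]


@dataclasses.dataclass
class MultilevelFeature:
    values: np.ndarray
    source_stages: tuple[int, ...] = (3, 4, 5)

    def __len__(self) -> int:
        return self.values.shape[-1]


class Backbone:
    """Stacked conv stages plus a global-average-pool + linear classifier head."""

    def __init__(self, spec: BackboneSpec, seed: int | None = None) -> None:
        self.spec = spec
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        self.conv_W: list[np.ndarray] = []  # im2col layout (9*Cin, Cout)
        self.conv_b: list[np.ndarray] = []
        self.stage_of_conv: list[int] = []
        c_in = 3
        for stage, (c_out, n_convs) in enumerate(
            zip(spec.stage_channels, spec.convs_per_stage), start=1
        ):
            for _ in range(n_convs):
                fan_in = 9 * c_in
                bound = np.sqrt(6.0 / fan_in)
                self.conv_W.append(
                    rng.uniform(-bound, bound, size=(fan_in, c_out)).astype(np.float32)
                )
                self.conv_b.append(np.zeros(c_out, dtype=np.float32))
                self.stage_of_conv.append(stage)
                c_in = c_out
        head_in = spec.stage_channels[-1]
        bound = np.sqrt(6.0 / head_in)
        self.head_W = rng.uniform(-bound, bound, size=(head_in, spec.n_classes)).astype(np.float32)
        self.head_b = np.zeros(spec.n_classes, dtype=np.float32)
        self.trained = False

    # -- parameters ---------------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for W, b in zip(self.conv_W, self.conv_b):
            out.extend((W, b))
        out.extend((self.head_W, self.head_b))
        return out

    def parameter_fingerprint(self) -> tuple[bytes, ...]:
        return tuple(p.tobytes() for p in self.parameters())

    # -- forward ------------------------------------------------------------
    def _forward_stages(self, x: np.ndarray, keep_cache: bool = False):
        """x: (N, S, S, 3) in [0,1].  Returns (stage_maps, pooled_out, cache)."""
        spec = self.spec
        if x.ndim != 4 or x.shape[1] != spec.input_side or x.shape[2] != spec.input_side:
            raise ValueError(
                f"expected (N, {spec.input_side}, {spec.input_side}, 3) input, got {x.shape}"
            )
        h = x.astype(np.float32)
        stage_maps: list[np.ndarray] = []
        cache: list[tuple] = []
        ci = 0
        for stage in range(1, 6):
            for _ in range(spec.convs_per_stage[stage - 1]):
                x_shape = h.shape
                z, cols = conv3x3_forward(h, self.conv_W[ci], self.conv_b[ci])
                a = relu(z)
                if keep_cache:
                    cache.append(("conv", ci, cols, x_shape, z))
                h = a
                ci += 1
            stage_maps.append(h)
            x_shape = h.shape
            h, arg = maxpool2_forward(h)
            if keep_cache:
                cache.append(("pool", None, arg, x_shape, None))
        return stage_maps, h, cache

    def logits(self, x: np.ndarray) -> np.ndarray:
        _, pooled, _ = self._forward_stages(x)
        gap = pooled.mean(axis=(1, 2))
        return gap @ self.head_W + self.head_b

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.logits(x).astype(np.float64))

    # -- training step ------------------------------------------------------
    def _train_step(self, x: np.ndarray, labels: np.ndarray, opt: Adam) -> float:
        _, pooled, cache = self._forward_stages(x, keep_cache=True)
        n, ph, pw, c = pooled.shape
        gap = pooled.mean(axis=(1, 2))
        logits = gap @ self.head_W + self.head_b
        loss, dlogits = cross_entropy(logits.astype(np.float64), labels)
        dlogits = dlogits.astype(np.float32)
        d_headW = gap.T @ dlogits
        d_headb = dlogits.sum(axis=0)
        dgap = dlogits @ self.head_W.T
        dpooled = np.broadcast_to(
            dgap[:, None, None, :] / (ph * pw), pooled.shape
        ).astype(np.float32)

        grads: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        d = dpooled
        for kind, ci, aux, x_shape, z in reversed(cache):
            if kind == "pool":
                d = maxpool2_backward(d, aux, x_shape)
            else:
                d = d * (z > 0)
                d, dW, db = conv3x3_backward(d, aux, self.conv_W[ci], x_shape)
                grads[ci] = (dW, db)

        flat: list[np.ndarray] = []
        for ci in range(len(self.conv_W)):
            flat.extend(grads[ci])
        flat.extend((d_headW, d_headb))
        opt.step(flat)
        return loss


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 32


def build_backbone(spec: BackboneSpec, seed: int | None = None) -> Backbone:
    """Instantiate a backbone with reproducible from-scratch initialization."""
    return Backbone(spec, seed=seed)


def stage_outputs(backbone: Backbone, image: np.ndarray) -> list[StageFeatureMap]:
    """Per-stage pre-pooling feature maps for one ``S x S x 3`` image in [0,1]."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (S, S, 3) image, got shape {image.shape}")
    maps, _, _ = backbone._forward_stages(image[None])
    return [StageFeatureMap(stage_index=k, values=m[0]) for k, m in enumerate(maps, start=1)]


def global_average_pool(fmap: StageFeatureMap | np.ndarray) -> np.ndarray:
    """Reduce an H x W x C map to the length-C vector of per-channel means."""
    values = fmap.values if isinstance(fmap, StageFeatureMap) else np.asarray(fmap)
    if values.ndim != 3 or values.shape[0] < 1 or values.shape[1] < 1:
        raise ValueError(f"expected a non-empty (H, W, C) map, got shape {values.shape}")
    return values.mean(axis=(0, 1)).astype(np.float64)


def multilevel_features(
    backbone: Backbone,
    image: np.ndarray,
    source_stages: Sequence[int] = (3, 4, 5),
) -> MultilevelFeature:
    """Concatenate pooled stage vectors (ascending stage order)."""
    stages = tuple(sorted(set(int(s) for s in source_stages)))
    if not stages:
        raise ValueError("source_stages must be non-empty")
    if any(s < 1 or s > 5 for s in stages):
        raise ValueError(f"stage indices must lie in 1..5, got {stages}")
    maps = stage_outputs(backbone, image)
    vec = np.concatenate([global_average_pool(maps[s - 1]) for s in stages])
    return MultilevelFeature(values=vec, source_stages=stages)


def multilevel_features_batch(
    backbone: Backbone, images: np.ndarray, source_stages: Sequence[int] = (3, 4, 5)
) -> np.ndarray:
    """Vectorized multilevel features for a batch (N, S, S, 3) -> (N, D)."""
    stages = tuple(sorted(set(int(s) for s in source_stages)))
    maps, _, _ = backbone._forward_stages(images)
    return np.concatenate(
        [maps[s - 1].mean(axis=(1, 2)).astype(np.float64) for s in stages], axis=1
    )


def train_backbone_classifier(
    images: np.ndarray,
    labels: np.ndarray,
    spec: BackboneSpec,
    train_config: TrainConfig | None = None,
    seed: int = 0,
) -> Backbone:
    """Train the backbone + linear head with softmax cross-entropy.

    ``images``: (N, S, S, 3) floats in [0,1]; ``labels``: (N,) ints in
    {0 benign, 1 malignant}.  Deterministic for a fixed seed.
    """
    cfg = train_config or TrainConfig()
    labels = np.asarray(labels, dtype=np.int64)
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires at least 2 classes")
    model = Backbone(spec, seed=seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(seed)
    n = images.shape[0]
    history = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            epoch_loss += model._train_step(images[idx], labels[idx], opt)
            n_batches += 1
        history.append(epoch_loss / n_batches)
    model.trained = True
    model.history = history
    return model
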