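"""Raising 29-d encoded records to a higher-dimensional code.

Five methods are provided: plain tiling (``copy``), degree-2 interaction and
polynomial expansion (``interaction_polynomial``), and three autoencoder
variants — plain (``autoencoder``), denoising (``denoising_autoencoder``,
trained on feature-dropout-corrupted inputs against clean targets) and the
denoising sparse variant (``denoising_autoencoder_l1``) whose loss adds an L1
penalty on the weights:

    L(w) = (1/N) sum_i || f(x~_i; w) - x_i ||^2  +  lambda * sum |w|

The code of an autoencoder variant is the post-activation output of the
middle (widest) layer; the default topology 29-290-435-580-435-290-29 yields
580-d codes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import MLP, Adam

__all__ = [
    "METHODS",
    "RaiserConfig",
    "DimensionRaiser",
    "copy_raise",
    "poly_raise",
    "corrupt",
    "dae_loss",
    "fit_raiser",
    "encode",
    "reconstruct",
    "save_raiser",
    "load_raiser",
]

METHODS = (
    "copy",
    "interaction_polynomial",
    "autoencoder",
    "denoising_autoencoder",
    "denoising_autoencoder_l1",
)
_AE_METHODS = METHODS[2:]

DEFAULT_WIDTHS = (29, 290, 435, 580, 435, 290, 29)


@dataclasses.dataclass
class RaiserConfig:
    method: str = "denoising_autoencoder_l1"
    layer_widths: tuple[int, ...] = DEFAULT_WIDTHS
    lam: float | None = None  # L1 coefficient; None -> 1e-4 for the L1 method, else 0
    corruption_rate: float = 0.2
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; valid: {METHODS}")
        self.layer_widths = tuple(int(w) for w in self.layer_widths)
        w = self.layer_widths
        if w != w[::-1]:
            raise ValueError(f"layer_widths must be symmetric, got {w}")
        if len(w) < 3 or len(w) % 2 == 0:
            raise ValueError("layer_widths must have odd length >= 3")
        if not (0.0 <= self.corruption_rate <= 1.0):
            raise ValueError(f"corruption_rate must be in [0,1], got {self.corruption_rate}")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lambda must be non-negative")

    @property
    def input_dim(self) -> int:
        return self.layer_widths[0]

    @property
    def target_dim(self) -> int:
        """Code dimension: the middle (widest) layer width."""
        return self.layer_widths[len(self.layer_widths) // 2]

    @property
    def resolved_lambda(self) -> float:
        if self.lam is not None:
            return float(self.lam)
        return 1e-4 if self.method == "denoising_autoencoder_l1" else 0.0


def copy_raise(v: np.ndarray, target: int) -> np.ndarray:
    """Tile ``v`` to length ``target``: whole copies then a leading remainder."""
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 1:
        raise ValueError("copy_raise expects a 1-d vector")
    d = v.shape[0]
    if target < d:
        raise ValueError(f"target {target} smaller than input dimension {d}")
    reps, rem = divmod(target, d)
    return np.concatenate([np.tile(v, reps), v[:rem]])


def poly_raise(v: np.ndarray) -> np.ndarray:
    """Degree-2 expansion: bias, linear terms, then upper-triangular products.

    Output order is (1, v_1..v_n, v_1*v_1, v_1*v_2, ..., v_n*v_n); the output
    length for n inputs is 1 + n + n(n+1)/2 (465 for n = 29).
    """
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 1:
        raise ValueError("poly_raise expects a 1-d vector")
    n = v.shape[0]
    iu = np.triu_indices(n)
    return np.concatenate([[1.0], v, v[iu[0]] * v[iu[1]]])


def corrupt(
    v: np.ndarray, rate: float, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Zero each component independently with probability ``rate``.

    Kept components are unchanged (no inverse-rate rescaling).  Works on a
    single vector or a batch; returns ``(corrupted, drop_mask)``.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"rate must be in [0,1], got {rate}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = np.asarray(v, dtype=np.float64)
    mask = rng.random(v.shape) < rate
    out = v.copy()
    out[mask] = 0.0
    return out, mask


def dae_loss(
    reconstructions: np.ndarray,
    targets: np.ndarray,
    weights: Sequence[np.ndarray] = (),
    lam: float = 0.0,
) -> float:
    """Mean per-sample squared reconstruction error plus L1 weight penalty.

    ``weights`` are the weight matrices only — biases are excluded from the
    penalty.
    """
    recon = np.atleast_2d(np.asarray(reconstructions, dtype=np.float64))
    tgt = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    if recon.shape != tgt.shape:
        raise ValueError(f"shape mismatch: {recon.shape} vs {tgt.shape}")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    n = recon.shape[0]
    data_term = float(np.sum((recon - tgt) ** 2)) / n
    l1_term = lam * float(sum(np.abs(w).sum() for w in weights))
    return data_term + l1_term


@dataclasses.dataclass
class DimensionRaiser:
    """A fitted 29-d -> code-d mapping (one of the five methods)."""

    config: RaiserConfig
    model: MLP | None = None
    fitted: bool = False
    history: dict = dataclasses.field(default_factory=dict)

    @property
    def output_dim(self) -> int:
        return self.config.target_dim

    def encode(self, v: np.ndarray) -> np.ndarray:
        return encode(self, v)

    def reconstruct(self, v: np.ndarray) -> np.ndarray:
        return reconstruct(self, v)


def _clean_objective(model: MLP, X: np.ndarray, lam: float) -> float:
    recon = model.forward(X)
    return dae_loss(recon, X, model.weight_matrices(), lam)


def fit_raiser(
    records: np.ndarray, config: RaiserConfig, seed: int | None = None
) -> DimensionRaiser:
    """Fit a dimension raiser on encoded record vectors (shape ``(n, 29)``).

    ``copy`` and ``interaction_polynomial`` are parameter-free.  The
    autoencoder variants train with Adam on minibatches: plain AE on
    ``(x, x)``, the denoising variants on ``(corrupt(x), x)`` with fresh
    corruption every epoch.
    """
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    if config.method not in _AE_METHODS:
        return DimensionRaiser(config=config, fitted=True)

    X = np.asarray(records, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-d array with at least 2 training vectors")
    if X.shape[1] != config.input_dim:
        raise ValueError(
            f"records have {X.shape[1]} features, config expects {config.input_dim}"
        )

    rng = np.random.default_rng(config.seed)
    model = MLP(config.layer_widths, rng, output="sigmoid")
    lam = config.resolved_lambda
    denoise = config.method.startswith("denoising")
    opt = Adam(model.parameters(), lr=config.learning_rate)

    untrained_mse = float(np.mean((model.forward(X) - X) ** 2))
    losses = []
    n = X.shape[0]
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            clean = X[idx]
            inp = corrupt(clean, config.corruption_rate, rng)[0] if denoise else clean
            recon, acts = model.forward(inp, return_hidden=True)
            grads = model.backward(acts, 2.0 * (recon - clean) / len(idx))
            if lam > 0:
                for li, layer in enumerate(model.layers):
                    grads[2 * li] = grads[2 * li] + lam * np.sign(layer.W)
            opt.step(grads)
        losses.append(_clean_objective(model, X, lam))

    trained_mse = float(np.mean((model.forward(X) - X) ** 2))
    history = {
        "epoch_loss": losses,
        "untrained_clean_mse": untrained_mse,
        "trained_clean_mse": trained_mse,
    }
    return DimensionRaiser(config=config, model=model, fitted=True, history=history)


def encode(raiser: DimensionRaiser, v: np.ndarray) -> np.ndarray:
    """Map a 29-d vector (or batch) to its raised code.

    Autoencoder variants return the post-activation values of the middle
    layer; copy/IP return the deterministic raised vector.
    """
    if not raiser.fitted:
        raise ValueError("raiser is not fitted")
    cfg = raiser.config
    v = np.asarray(v, dtype=np.float64)
    single = v.ndim == 1

    if cfg.method == "copy":
        if single:
            return copy_raise(v, cfg.target_dim)
        return np.stack([copy_raise(row, cfg.target_dim) for row in v])
    if cfg.method == "interaction_polynomial":
        # Expansion then tiling up to the target (465 -> 580 at full scale);
        # if the expansion already exceeds the target it keeps its natural
        # length — tiling only ever raises dimension.
        def _ip(row: np.ndarray) -> np.ndarray:
            expanded = poly_raise(row)
            return copy_raise(expanded, max(cfg.target_dim, expanded.shape[0]))

        return _ip(v) if single else np.stack([_ip(row) for row in v])

    X = v[None, :] if single else v
    mid = len(raiser.model.layers) // 2
    _, acts = raiser.model.forward(X, return_hidden=True)
    code = acts[mid]
    return code[0] if single else code


def reconstruct(raiser: DimensionRaiser, v: np.ndarray) -> np.ndarray:
    """Full encoder+decoder pass (autoencoder variants only)."""
    if raiser.config.method not in _AE_METHODS:
        raise ValueError(f"reconstruct is undefined for method {raiser.config.method!r}")
    if not raiser.fitted or raiser.model is None:
        raise ValueError("raiser is not fitted")
    v = np.asarray(v, dtype=np.float64)
    single = v.ndim == 1
    X = v[None, :] if single else v
    out = raiser.model.forward(X)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Serialization (format v1: npz with a JSON config plus parameter arrays)
# ---------------------------------------------------------------------------

def save_raiser(raiser: DimensionRaiser, path: str | Path) -> None:
    cfg = dataclasses.asdict(raiser.config)
    arrays: dict[str, np.ndarray] = {}
    if raiser.model is not None:
        for i, layer in enumerate(raiser.model.layers):
            arrays[f"W{i}"] = layer.W
            arrays[f"b{i}"] = layer.b
    np.savez(path, __format__=np.array("richfuse-raiser-v1"),
             config=np.array(json.dumps(cfg)), fitted=np.array(raiser.fitted), **arrays)


def load_raiser(path: str | Path) -> DimensionRaiser:
    with np.load(path, allow_pickle=False) as data:
        if str(data["__format__"]) != "richfuse-raiser-v1":
            raise ValueError("unrecognized raiser archive format")
        cfg_dict = json.loads(str(data["config"]))
        cfg_dict["layer_widths"] = tuple(cfg_dict["layer_widths"])
        config = RaiserConfig(**cfg_dict)
        model = None
        if "W0" in data:
            model = MLP(config.layer_widths, np.random.default_rng(0), output="sigmoid")
            for i, layer in enumerate(model.layers):
                layer.W = data[f"W{i}"]
                layer.b = data[f"b{i}"]
        return DimensionRaiser(config=config, model=model, fitted=bool(data["fitted"]))
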