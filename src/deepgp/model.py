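"""The disease-gene pair classifier: pair tensors, CNN architectures, training.

A disease-gene pair is scored from a 3-channel D x K "image" (D = K = 5 for
the default five-disease panel): channel 0 the gene's GWAS p-value block,
channel 1 its eQTL block (either raw or smoothed by the graph-convolution
step), and channel 2 the target disease's similarity row tiled across rows.
A small CNN — tanh convolutions, ceil-mode 2x2 max-pooling, dense layers and
a sigmoid output — maps the tensor to an association score in [0, 1], trained
with mean-reduced binary cross-entropy.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import nn
from .io import DiseaseSimilarity, ValidationError

CLAMP = 1e-7


def assemble_pair_tensor(
    gene_block: np.ndarray,
    similarity: DiseaseSimilarity,
    target_disease: str,
) -> np.ndarray:
    """Stack gene feature block and tiled disease-similarity row into (3, D, K).

    Requires D == K (the square-image reading of the pair feature). Channel 2
    holds K identical copies of the target disease's 1 x D similarity row,
    columns in panel order, so with an identity similarity matrix it is a
    one-hot column indicator of the target disease.
    """
    gene_block = np.asarray(gene_block, dtype=float)
    if gene_block.ndim != 3 or gene_block.shape[0] != 2:
        raise ValidationError(
            f"gene feature block must have shape (2, D, K), got {gene_block.shape}"
        )
    _, d, k = gene_block.shape
    if d != k:
        raise ValidationError(
            f"pair tensors require D == K (square channels), got D={d}, K={k}"
        )
    if d != len(similarity.disease_ids):
        raise ValidationError(
            f"feature block has {d} disease rows but the panel has "
            f"{len(similarity.disease_ids)} diseases"
        )
    sim_row = similarity.row(target_disease)  # KeyError on unknown disease
    tensor = np.empty((3, d, k))
    tensor[:2] = gene_block
    tensor[2] = np.tile(sim_row, (k, 1))
    return tensor


def bce_loss(
    predictions: np.ndarray, labels: np.ndarray, clamp: float = CLAMP
) -> float:
    """Mean binary cross-entropy, predictions clamped to [clamp, 1 - clamp]."""
    predictions = np.asarray(predictions, dtype=float).reshape(-1)
    labels = np.asarray(labels, dtype=float).reshape(-1)
    if predictions.shape != labels.shape:
        raise ValidationError(
            f"{predictions.size} predictions vs {labels.size} labels"
        )
    p = np.clip(predictions, clamp, 1.0 - clamp)
    return float(-np.mean(labels * np.log(p) + (1.0 - labels) * np.log1p(-p)))


@dataclasses.dataclass
class ConvBlock:
    filters: int
    kernel: int
    pool: bool = True


@dataclasses.dataclass
class CnnArchitecture:
    """Conv/pool blocks followed by dense layers and a sigmoid output unit.

    Hidden activations are tanh throughout; the output layer is a single
    sigmoid unit, so scores cannot escape [0, 1].
    """

    conv_blocks: list[ConvBlock]
    dense: list[int] = dataclasses.field(default_factory=lambda: [64])
    name: str = "custom"


# Reconstructed presets: "A" is the two-block default, "B" the shallower
# single-block variant, "C" the enlarged-kernel variant.
ARCH_PRESETS: dict[str, CnnArchitecture] = {
    "A": CnnArchitecture([ConvBlock(16, 3), ConvBlock(32, 3)], [64], name="A"),
    "B": CnnArchitecture([ConvBlock(16, 3)], [64], name="B"),
    "C": CnnArchitecture([ConvBlock(16, 5)], [64], name="C"),
}


@dataclasses.dataclass
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.epochs < 0 or self.batch_size <= 0:
            raise ValidationError("lr and batch_size must be positive, epochs >= 0")


class CnnModel:
    """A built (optionally fitted) CNN scorer for (3, D, K) pair tensors."""

    def __init__(self, arch: CnnArchitecture, seed: int, input_shape=(3, 5, 5)):
        self.arch = arch
        self.seed = int(seed)
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(self.seed)
        c, h, w = self.input_shape
        layers: list[nn.Layer] = []
        for block in arch.conv_blocks:
            layers += [nn.Conv2DSame(c, block.filters, block.kernel, rng), nn.Tanh()]
            c = block.filters
            if block.pool:
                if h < 1 or w < 1:
                    raise ValidationError("pooling reduced a spatial dim below 1")
                layers.append(nn.MaxPool2x2Ceil())
                h, w = -(-h // 2), -(-w // 2)
        if h < 1 or w < 1:
            raise ValidationError("spatial dimensions collapsed below 1")
        layers.append(nn.Flatten())
        width = c * h * w
        for n_out in arch.dense:
            layers += [nn.Dense(width, n_out, rng), nn.Tanh()]
            width = n_out
        layers.append(nn.Dense(width, 1, rng))
        self.net = nn.Sequential(layers)

    def _check_input(self, tensors: np.ndarray) -> np.ndarray:
        tensors = np.asarray(tensors, dtype=float)
        if tensors.ndim == 3:
            tensors = tensors[None]
        if tensors.shape[1:] != self.input_shape:
            raise ValidationError(
                f"pair tensors of shape {tensors.shape[1:]} do not match the "
                f"model input {self.input_shape}"
            )
        return tensors

    def predict(self, tensors: np.ndarray) -> np.ndarray:
        """Scores in [0, 1], one per pair tensor; deterministic."""
        return self.net.forward(self._check_input(tensors))

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValidationError("weight list does not match the architecture")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ValidationError("weight shapes do not match the architecture")
            p.value[...] = w


def build_cnn(
    arch: CnnArchitecture | str, seed: int, input_shape=(3, 5, 5)
) -> CnnModel:
    """Construct a CNN scorer with seed-deterministic initial weights."""
    if isinstance(arch, str):
        try:
            arch = ARCH_PRESETS[arch]
        except KeyError:
            raise ValidationError(
                f"unknown architecture preset {arch!r}; options: "
                f"{sorted(ARCH_PRESETS)}"
            ) from None
    return CnnModel(arch, seed, input_shape)


def train_cnn(
    model: CnnModel,
    tensors: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
) -> list[float]:
    """Fit the CNN on pre-assembled pair tensors; returns the loss history.

    history[0] is the full-dataset loss before any update, history[e] the loss
    after epoch e. Training is deterministic given cfg.seed. Requires at
    least one sample of each class.
    """
    tensors = model._check_input(tensors)
    labels = np.asarray(labels, dtype=float).reshape(-1)
    if tensors.shape[0] != labels.size:
        raise ValidationError("tensor/label count mismatch")
    if len(np.unique(labels)) < 2:
        raise ValidationError("training set must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.params(), lr=cfg.lr)
    history = [bce_loss(model.predict(tensors), labels)]
    n = labels.size
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            xb, yb = tensors[idx], labels[idx]
            opt.zero_grad()
            p = np.clip(model.net.forward(xb), CLAMP, 1.0 - CLAMP)
            model.net.backward_from_logits((p - yb) / yb.size)
            opt.step()
        history.append(bce_loss(model.predict(tensors), labels))
    return history
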