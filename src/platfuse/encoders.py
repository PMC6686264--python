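"""The three encoding networks and bottleneck feature extraction.

Three unsupervised networks learn compressed representations of paired
two-platform expression data:

* a plain autoencoder (``kind="ae"``) trained on one platform;
* a pooled autoencoder (``kind="pooled"``) trained on the row-wise pooled
  samples of both platforms in the shared gene space, so one encoder serves
  either platform;
* a cross-platform translation autoencoder (``kind="cross"``) trained on
  both translation directions with shared weights: it reconstructs its input
  platform while an extra cross-entropy term penalizes divergence of the
  reconstruction from the *paired* sample on the other platform, forcing the
  bottleneck to carry platform-independent information.

Every network shares the same encoder shape (default hidden sizes
4096/3072/2048 with a 1024-unit bottleneck, tanh activations, dropout 0.2)
and a mirrored decoder ending in a sigmoid output layer, trained with
per-feature binary cross-entropy on [0, 1]-normalized expression.

Bottleneck features from the three kinds are concatenated into a single
fused per-sample feature block for downstream supervised modeling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .io_data import ExpressionMatrix

DEFAULT_ENCODER_SIZES = (4096, 3072, 2048, 1024)


@dataclass
class EncoderSpec:
    """Hyper-parameters of one encoding network.

    ``encoder_layer_sizes`` lists the encoder's hidden widths ending in the
    bottleneck; the decoder mirrors them in reverse and ends in
    ``input_dim``. ``cross_loss_weight`` only matters for the translation
    network.
    """

    input_dim: int
    encoder_layer_sizes: tuple[int, ...] = DEFAULT_ENCODER_SIZES
    hidden_activation: str = "tanh"
    output_activation: str = "sigmoid"
    dropout_rate: float = 0.2
    reconstruction_loss: str = "binary_cross_entropy"
    cross_loss_weight: float = 1.0
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-4
    optimizer_name: str = "adam"
    seed: int = 0

    def __post_init__(self):
        self.encoder_layer_sizes = tuple(int(s) for s in self.encoder_layer_sizes)
        if self.input_dim <= 0 or any(s <= 0 for s in self.encoder_layer_sizes):
            raise ValueError("all layer sizes must be positive")
        if self.reconstruction_loss not in ("binary_cross_entropy", "mean_squared_error"):
            raise ValueError(f"unknown reconstruction loss {self.reconstruction_loss!r}")

    @property
    def latent_dim(self) -> int:
        return self.encoder_layer_sizes[-1]

    @property
    def layer_widths(self) -> list[int]:
        """All node-bearing layer widths, input through reconstruction."""
        enc = list(self.encoder_layer_sizes)
        dec = enc[-2::-1] + [self.input_dim]
        return [self.input_dim] + enc + dec

    def scaled(self, scale: float) -> "EncoderSpec":
        """Same spec with every hidden width multiplied by ``scale``."""
        sizes = tuple(max(1, round(s * scale)) for s in self.encoder_layer_sizes)
        spec = asdict(self)
        spec["encoder_layer_sizes"] = sizes
        return EncoderSpec(**spec)


@dataclass
class TrainLog:
    """Per-epoch losses; ``cross`` stays None for plain autoencoders."""

    reconstruction: list[float] = field(default_factory=list)
    cross: list[float] | None = None

    @property
    def total(self) -> list[float]:
        if self.cross is None:
            return list(self.reconstruction)
        return [r + c for r, c in zip(self.reconstruction, self.cross)]


_ACTS = {"tanh": nn.Tanh, "relu": nn.Relu, "sigmoid": nn.Sigmoid}


def _build_autoencoder(spec: EncoderSpec, rng) -> tuple[nn.Sequential, int]:
    """Full encoder+decoder stack; returns it and the encoder's layer count."""
    act = _ACTS[spec.hidden_activation]
    layers: list[nn.Layer] = []
    prev = spec.input_dim
    for size in spec.encoder_layer_sizes:
        layers.append(nn.Dense(prev, size, rng))
        layers.append(act())
        if spec.dropout_rate > 0:
            layers.append(nn.Dropout(spec.dropout_rate, rng))
        prev = size
    n_encoder_layers = len(layers)
    for size in spec.encoder_layer_sizes[-2::-1]:
        layers.append(nn.Dense(prev, size, rng))
        layers.append(act())
        if spec.dropout_rate > 0:
            layers.append(nn.Dropout(spec.dropout_rate, rng))
        prev = size
    layers.append(nn.Dense(prev, spec.input_dim, rng))
    layers.append(_ACTS[spec.output_activation]())
    return nn.Sequential(layers), n_encoder_layers


@dataclass
class EncodingNetwork:
    """A trained encoding network exposing the encode contract.

    ``branches`` maps an input platform tag to the model serving it; for
    ``kind="cross"`` both platforms map to the shared-weight translation
    network and ``encode`` requires the sample's platform tag to be one the
    network was trained on.
    """

    kind: str
    spec: EncoderSpec
    branches: dict[str, nn.Sequential]
    n_encoder_layers: int

    def encode_array(self, values: np.ndarray, platform: str | None = None) -> np.ndarray:
        if values.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"input width {values.shape[1]} != spec input_dim {self.spec.input_dim}"
            )
        if self.kind == "cross":
            if platform not in self.branches:
                raise KeyError(
                    f"platform {platform!r} has no branch; trained on {sorted(self.branches)}"
                )
            model = self.branches[platform]
        else:
            model = next(iter(self.branches.values()))
        x = values
        for layer in model.layers[: self.n_encoder_layers]:
            x = layer.forward(x, training=False)
        return x


@dataclass
class LatentFeatures:
    """Named per-sample bottleneck feature blocks and their concatenation."""

    sample_ids: list[str]
    blocks: dict[str, np.ndarray]

    def __post_init__(self):
        for name, block in self.blocks.items():
            block = np.asarray(block, dtype=float)
            if block.shape[0] != len(self.sample_ids):
                raise ValueError(f"block {name!r} row count != number of samples")
            if not np.isfinite(block).all():
                raise ValueError(f"block {name!r} contains NaN/Inf")
            self.blocks[name] = block

    @property
    def matrix(self) -> np.ndarray:
        """Blocks concatenated column-wise in insertion order."""
        return np.concatenate(list(self.blocks.values()), axis=1)

    @property
    def width(self) -> int:
        return sum(b.shape[1] for b in self.blocks.values())

    def block_slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for name, block in self.blocks.items():
            out[name] = slice(start, start + block.shape[1])
            start += block.shape[1]
        return out

    def subset_samples(self, sample_ids) -> "LatentFeatures":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return LatentFeatures(
            list(sample_ids), {k: v[rows] for k, v in self.blocks.items()}
        )


# ---------------------------------------------------------------------------
# training


def _loss_fn(spec: EncoderSpec):
    return nn.bce_loss if spec.reconstruction_loss == "binary_cross_entropy" else nn.mse_loss


def _check_trainable(x: ExpressionMatrix, spec: EncoderSpec) -> None:
    if x.n_samples < 2:
        raise ValueError("need at least 2 samples to train")
    if x.n_genes != spec.input_dim:
        raise ValueError(f"matrix width {x.n_genes} != spec input_dim {spec.input_dim}")
    if spec.reconstruction_loss == "binary_cross_entropy" and not x.normalized:
        raise ValueError(
            "binary cross-entropy reconstruction requires [0,1]-normalized input; "
            "apply min-max normalization first"
        )


def _train_reconstruction(x: np.ndarray, spec: EncoderSpec, seed: int,
                          cross_target: np.ndarray | None = None):
    """Shared training loop for all three network kinds.

    Minimizes recon_loss(x_hat, x) and, when ``cross_target`` is given,
    adds cross_loss_weight * recon_loss(x_hat, cross_target) — the paired
    other-platform profile. With cross_loss_weight = 0 the trajectory is
    bit-identical to a plain autoencoder with the same seed.
    """
    rng = np.random.default_rng(seed)
    model, n_enc = _build_autoencoder(spec, rng)
    opt = nn.Adam(model.params(), lr=spec.learning_rate)
    loss_fn = _loss_fn(spec)
    lam = spec.cross_loss_weight if cross_target is not None else 0.0
    log = TrainLog(cross=[] if cross_target is not None else None)
    n = x.shape[0]
    for _ in range(spec.epochs):
        rec_sum = cross_sum = 0.0
        for batch in nn.iterate_minibatches(n, spec.batch_size, rng):
            xb = x[batch]
            out = model.forward(xb, training=True)
            rec, g = loss_fn(out, xb)
            rec_sum += rec * len(batch)
            if cross_target is not None:
                cl, gc = loss_fn(out, cross_target[batch])
                cross_sum += lam * cl * len(batch)
                g = g + lam * gc
            model.backward(g)
            opt.step(model.grads())
        log.reconstruction.append(rec_sum / n)
        if cross_target is not None:
            log.cross.append(cross_sum / n)
    return model, n_enc, log


def train_ae(x: ExpressionMatrix, spec: EncoderSpec) -> tuple[EncodingNetwork, TrainLog]:
    """Train a plain autoencoder on one platform's normalized matrix."""
    _check_trainable(x, spec)
    model, n_enc, log = _train_reconstruction(x.values, spec, spec.seed)
    return EncodingNetwork("ae", spec, {x.platform: model}, n_enc), log


def train_pooled(a: ExpressionMatrix, b: ExpressionMatrix,
                 spec: EncoderSpec) -> tuple[EncodingNetwork, TrainLog]:
    """Train one autoencoder on the row-wise pooled samples of both platforms.

    Both matrices must be aligned to the same mapped gene order; the pooled
    training set has a.n_samples + b.n_samples rows and the single trained
    encoder applies identically to samples from either platform.
    """
    _check_trainable(a, spec)
    _check_trainable(b, spec)
    if a.n_genes != b.n_genes:
        raise ValueError(f"gene widths differ: {a.n_genes} vs {b.n_genes}; align first")
    pooled = np.vstack([a.values, b.values])
    model, n_enc, log = _train_reconstruction(pooled, spec, spec.seed)
    return EncodingNetwork("pooled", spec, {"pooled": model}, n_enc), log


def train_cross(a: ExpressionMatrix, b: ExpressionMatrix,
                spec: EncoderSpec) -> tuple[EncodingNetwork, TrainLog]:
    """Train the cross-platform translation network.

    Requires paired samples (identical sample ids). One network with shared
    weights is trained on both translation directions: a platform-A profile
    is penalized for reconstruction error against itself and (weighted by
    ``cross_loss_weight``) for divergence from the *paired* platform-B
    profile, and symmetrically for platform-B rows. Sharing the weights
    across directions puts both platforms' bottlenecks in one coordinate
    space, which is what lets the latent code carry platform-independent
    structure. With ``cross_loss_weight = 0`` the network coincides with the
    pooled autoencoder trained at the same seed.
    """
    _check_trainable(a, spec)
    _check_trainable(b, spec)
    if a.n_genes != b.n_genes:
        raise ValueError(f"gene widths differ: {a.n_genes} vs {b.n_genes}; align first")
    if set(a.sample_ids) != set(b.sample_ids):
        raise ValueError("cross-platform training requires paired samples (same ids)")
    b = b.subset_samples(a.sample_ids)  # enforce identical row order
    pooled = np.vstack([a.values, b.values])
    paired = np.vstack([b.values, a.values])
    model, n_enc, log = _train_reconstruction(pooled, spec, spec.seed,
                                              cross_target=paired)
    net = EncodingNetwork("cross", spec,
                          {a.platform: model, b.platform: model}, n_enc)
    return net, log


def encode(net: EncodingNetwork, x: ExpressionMatrix) -> LatentFeatures:
    """Map a normalized matrix to its bottleneck block (dropout disabled)."""
    z = net.encode_array(x.values, platform=x.platform)
    return LatentFeatures(list(x.sample_ids), {net.kind: z})


def concat_features(*features: LatentFeatures) -> LatentFeatures:
    """Column-wise fusion of blocks sharing sample ids and row order."""
    if not features:
        raise ValueError("need at least one feature block")
    first = features[0]
    blocks: dict[str, np.ndarray] = {}
    for f in features:
        if f.sample_ids != first.sample_ids:
            raise ValueError("sample ids (or their order) differ between blocks")
        for name, block in f.blocks.items():
            key, k = name, 2
            while key in blocks:
                key = f"{name}{k}"
                k += 1
            blocks[key] = block
    return LatentFeatures(list(first.sample_ids), blocks)


# ---------------------------------------------------------------------------
# persistence


def save_network(net: EncodingNetwork, directory) -> None:
    """Checkpoint = config.json + one weights.npz per branch."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    config = {
        "kind": net.kind,
        "spec": asdict(net.spec),
        "n_encoder_layers": net.n_encoder_layers,
        "branches": sorted(net.branches),
    }
    (directory / "config.json").write_text(json.dumps(config, indent=2))
    for name, model in net.branches.items():
        np.savez(directory / f"weights_{name}.npz", **model.state_arrays())


def load_network(directory) -> EncodingNetwork:
    directory = Path(directory)
    config = json.loads((directory / "config.json").read_text())
    spec = EncoderSpec(**config["spec"])
    branches = {}
    for name in config["branches"]:
        model, _ = _build_autoencoder(spec, np.random.default_rng(0))
        with np.load(directory / f"weights_{name}.npz") as arrays:
            model.load_state_arrays(dict(arrays))
        branches[name] = model
    return EncodingNetwork(config["kind"], spec, branches, config["n_encoder_layers"])


def write_latent(features: LatentFeatures, path) -> None:
    """Tab-delimited export, columns named <block>.<index>."""
    cols = [f"{name}.{i:04d}" for name, block in features.blocks.items()
            for i in range(block.shape[1])]
    pd.DataFrame(features.matrix, index=features.sample_ids, columns=cols).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_latent(path) -> LatentFeatures:
    df = pd.read_csv(path, sep="\t", index_col=0)
    blocks: dict[str, list[str]] = {}
    for col in df.columns:
        blocks.setdefault(col.rsplit(".", 1)[0], []).append(col)
    return LatentFeatures(
        [str(s) for s in df.index],
        {name: df[cols].values for name, cols in blocks.items()},
    )
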