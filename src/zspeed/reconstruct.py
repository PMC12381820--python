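"""1D deep-learning reconstruction of dense Z-spectra from sparse samples.

Three small convolutional encoder-decoder networks map a masked sparse
Z-spectrum (length 101, zeros at unsampled offsets) to the dense 101-point
spectrum:

* ``autoencoder`` — 6 convolution layers, 2 max-poolings, 2 upsamplings,
  no skip connections;
* ``unet1``      — the same layer budget plus skip connections from the
  encoder to the decoder at both resolution levels;
* ``unet2``      — a deeper variant with 10 convolution layers, 2
  max-poolings, 2 upsamplings and 2 skip connections.

Training is supervised (sparse in, dense out) with Adam, mean-absolute-error
loss, a held-out validation split, and a reduce-on-plateau learning-rate
schedule floored at 1e-6.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .core import ZSpectrum
from .nn import Adam, Conv1d, Crop1d, EdgePad1d, MaxPool1d, Upsample1d
from .select import MIN_SUBSET, OffsetSubset

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "TrainedModel",
    "encode_sparse",
    "build_model",
    "train",
    "predict",
    "save_model",
    "load_model",
]

Architecture = Literal["autoencoder", "unet1", "unet2"]

# conv-channel plans per architecture: encoder blocks, bottleneck, decoder
# blocks (the final 1-channel linear output conv is added on top)
_PLANS: dict[str, dict] = {
    "autoencoder": {"enc": [[32], [64]], "bottleneck": [64],
                    "dec": [[64], [32]], "skips": False},
    "unet1": {"enc": [[32], [64]], "bottleneck": [64],
              "dec": [[64], [32]], "skips": True},
    "unet2": {"enc": [[32, 32], [64, 64]], "bottleneck": [64],
              "dec": [[64, 64], [32, 32]], "skips": True},
}


@dataclass(frozen=True)
class ModelSpec:
    """Architecture identifier plus the fixed structural counts."""

    architecture: Architecture
    input_length: int = 101
    kernel_size: int = 3
    mask_channel: bool = False

    def __post_init__(self) -> None:
        if self.architecture not in _PLANS:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.input_length < 8:
            raise ValueError("input_length too short for two pooling stages")

    @property
    def n_conv_layers(self) -> int:
        plan = _PLANS[self.architecture]
        return (sum(len(b) for b in plan["enc"]) + len(plan["bottleneck"])
                + sum(len(b) for b in plan["dec"]) + 1)

    @property
    def n_skip_connections(self) -> int:
        return 2 if _PLANS[self.architecture]["skips"] else 0

    @property
    def n_pool_layers(self) -> int:
        return 2

    @property
    def n_upsample_layers(self) -> int:
        return 2


class _ZNet:
    """Concrete encoder-decoder network built from a :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, seed: int | None):
        self.spec = spec
        rng = np.random.default_rng(seed)
        plan = _PLANS[spec.architecture]
        self.use_skips: bool = plan["skips"]
        k = spec.kernel_size

        # pad so the length is divisible by 4 (two 2x poolings)
        L = spec.input_length
        total_pad = (-L) % 4
        left = total_pad // 2
        right = total_pad - left
        self.pad = EdgePad1d(left, right)
        self.crop = Crop1d(left, right)

        c_prev = 2 if spec.mask_channel else 1
        self.enc_blocks: list[list[Conv1d]] = []
        self.pools: list[MaxPool1d] = []
        enc_out_channels: list[int] = []
        for block_plan in plan["enc"]:
            block = []
            for c in block_plan:
                block.append(Conv1d(c_prev, c, k, rng))
                c_prev = c
            self.enc_blocks.append(block)
            enc_out_channels.append(c_prev)
            self.pools.append(MaxPool1d())

        self.bottleneck: list[Conv1d] = []
        for c in plan["bottleneck"]:
            self.bottleneck.append(Conv1d(c_prev, c, k, rng))
            c_prev = c

        self.ups: list[Upsample1d] = []
        self.dec_blocks: list[list[Conv1d]] = []
        self._up_channels: list[int] = []
        for i, block_plan in enumerate(plan["dec"]):
            self.ups.append(Upsample1d())
            self._up_channels.append(c_prev)
            if self.use_skips:
                c_prev = c_prev + enc_out_channels[-(i + 1)]
            block = []
            for c in block_plan:
                block.append(Conv1d(c_prev, c, k, rng))
                c_prev = c
            self.dec_blocks.append(block)

        self.out_conv = Conv1d(c_prev, 1, k, rng, activation=None)

    # -- introspection -------------------------------------------------
    @property
    def conv_layers(self) -> list[Conv1d]:
        layers = [c for b in self.enc_blocks for c in b]
        layers += self.bottleneck
        layers += [c for b in self.dec_blocks for c in b]
        layers.append(self.out_conv)
        return layers

    def params(self):
        out = []
        for conv in self.conv_layers:
            out.extend(conv.params())
        return out

    # -- forward / backward --------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.pad.forward(x, train)
        skips: list[np.ndarray] = []
        for block, pool in zip(self.enc_blocks, self.pools):
            for conv in block:
                h = conv.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        for conv in self.bottleneck:
            h = conv.forward(h, train)
        for i, (up, block) in enumerate(zip(self.ups, self.dec_blocks)):
            h = up.forward(h, train)
            if self.use_skips:
                h = np.concatenate([h, skips[-(i + 1)]], axis=1)
            for conv in block:
                h = conv.forward(h, train)
        h = self.out_conv.forward(h, train)
        return self.crop.forward(h, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.crop.backward(dy)
        d = self.out_conv.backward(d)
        n_levels = len(self.enc_blocks)
        dskips: list[np.ndarray | None] = [None] * n_levels
        for i in reversed(range(len(self.dec_blocks))):
            for conv in reversed(self.dec_blocks[i]):
                d = conv.backward(d)
            if self.use_skips:
                c_up = self._up_channels[i]
                dskips[n_levels - 1 - i] = d[:, c_up:, :]
                d = d[:, :c_up, :]
            d = self.ups[i].backward(d)
        for conv in reversed(self.bottleneck):
            d = conv.backward(d)
        for lev in reversed(range(n_levels)):
            d = self.pools[lev].backward(d)
            if dskips[lev] is not None:
                d = d + dskips[lev]
            for conv in reversed(self.enc_blocks[lev]):
                d = conv.backward(d)
        return self.pad.backward(d)

    # -- weight access for persistence ---------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, conv in enumerate(self.conv_layers):
            out[f"conv{i}_W"] = conv.W
            out[f"conv{i}_b"] = conv.b
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, conv in enumerate(self.conv_layers):
            W, b = weights[f"conv{i}_W"], weights[f"conv{i}_b"]
            if W.shape != conv.W.shape:
                raise ValueError(f"weight shape mismatch at conv{i}")
            conv.W = W.copy()
            conv.b = b.copy()


@dataclass
class TrainConfig:
    """Supervised-training hyperparameters.

    Defaults sit inside the study's printed ranges (epochs 250-500, batch
    5-25, validation split 0.2); shorter runs are permitted for desk-scale
    experiments.  The learning rate never drops below ``min_lr``.
    """

    epochs: int = 300
    batch_size: int = 16
    validation_split: float = 0.2
    learning_rate: float = 1e-3
    plateau_factor: float = 0.5
    plateau_patience: int = 10
    min_lr: float = 1e-6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if not 0.0 <= self.validation_split < 1.0:
            raise ValueError("validation_split must be in [0, 1)")
        if self.min_lr <= 0 or self.learning_rate < self.min_lr:
            raise ValueError("need learning_rate >= min_lr > 0")


@dataclass
class TrainedModel:
    """A trained network plus its spec and per-epoch loss history."""

    spec: ModelSpec
    net: _ZNet
    history: dict[str, list[float]]
    config: TrainConfig
    seed: int | None = None
    n_train: int = 0
    n_val: int = 0

    def predict(self, masked: np.ndarray, clip: bool = False) -> np.ndarray:
        return predict(self, masked, clip=clip)


def encode_sparse(dense: ZSpectrum, subset: OffsetSubset,
                  mask_channel: bool = False) -> np.ndarray:
    """Zero-filled sparse encoding of a dense spectrum.

    Sampled positions carry the dense values, unsampled positions carry 0.
    With ``mask_channel`` a second row marks sampled positions with 1,
    giving shape (2, N) instead of (N,).
    """
    if subset.grid != dense.grid:
        raise ValueError("subset grid does not match spectrum grid")
    if len(subset) < MIN_SUBSET:
        raise ValueError(f"subset must have >= {MIN_SUBSET} offsets")
    vec = np.zeros(len(dense))
    idx = list(subset.indices)
    vec[idx] = dense.values[idx]
    if mask_channel:
        m = np.zeros(len(dense))
        m[idx] = 1.0
        return np.stack([vec, m])
    return vec


def encode_sparse_table(values: np.ndarray, subset: OffsetSubset,
                        mask_channel: bool = False) -> np.ndarray:
    """Vectorized :func:`encode_sparse` over rows of a (n, N) value array."""
    values = np.atleast_2d(values)
    masked = np.zeros_like(values)
    idx = list(subset.indices)
    masked[:, idx] = values[:, idx]
    if mask_channel:
        m = np.zeros_like(values)
        m[:, idx] = 1.0
        return np.stack([masked, m], axis=1)  # (n, 2, N)
    return masked


def build_model(spec: ModelSpec | str, seed: int | None = None) -> _ZNet:
    """Instantiate an untrained network with seed-reproducible weights."""
    if isinstance(spec, str):
        spec = ModelSpec(spec)  # type: ignore[arg-type]
    return _ZNet(spec, seed)


def _as_batches(x: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Coerce inputs to (B, C, L)."""
    x = np.asarray(x, dtype=float)
    c = 2 if spec.mask_channel else 1
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim == 2 and not spec.mask_channel:
        x = x[:, None, :]
    elif x.ndim == 2 and spec.mask_channel:
        x = x[None, :, :]
    if x.ndim != 3 or x.shape[1] != c or x.shape[2] != spec.input_length:
        raise ValueError(f"expected input of length {spec.input_length} "
                         f"with {c} channel(s), got shape {x.shape}")
    return x


def train(model: _ZNet, inputs: np.ndarray, targets: np.ndarray,
          config: TrainConfig | None = None) -> TrainedModel:
    """Train a network on (masked sparse, dense) pairs with MAE loss.

    A ``validation_split`` fraction of the pairs is held out (after a seeded
    shuffle); the learning rate halves when validation loss fails to improve
    for ``plateau_patience`` consecutive epochs, never dropping below
    ``min_lr``.  Raises on NaN loss with an epoch-tagged diagnostic.
    """
    config = config or TrainConfig()
    spec = model.spec
    X = _as_batches(inputs, spec)
    Y = np.asarray(targets, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if Y.shape != (X.shape[0], spec.input_length):
        raise ValueError("targets must be (n_pairs, input_length)")
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 training pairs")

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_val = int(round(n * config.validation_split))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, Ytr = X[tr_idx], Y[tr_idx]
    Xval, Yval = X[val_idx], Y[val_idx]

    opt = Adam(model.params(), lr=config.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    plateau = 0

    for epoch in range(config.epochs):
        order = rng.permutation(len(Xtr))
        epoch_loss = 0.0
        for start in range(0, len(Xtr), config.batch_size):
            b = order[start:start + config.batch_size]
            xb, yb = Xtr[b], Ytr[b]
            pred = model.forward(xb, train=True)[:, 0, :]
            err = pred - yb
            loss = float(np.abs(err).mean())
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            epoch_loss += loss * len(b)
            dpred = np.sign(err) / err.size
            model.backward(dpred[:, None, :])
            opt.step([g for _, g in model.params()])
        train_loss = epoch_loss / len(Xtr)

        if len(Xval):
            val_pred = model.forward(Xval, train=False)[:, 0, :]
            val_loss = float(np.abs(val_pred - Yval).mean())
        else:
            val_loss = train_loss
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")

        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            plateau = 0
        else:
            plateau += 1
            if plateau >= config.plateau_patience:
                opt.lr = max(opt.lr * config.plateau_factor, config.min_lr)
                plateau = 0

    return TrainedModel(spec=spec, net=model, history=history,
                        config=config, seed=config.seed,
                        n_train=len(tr_idx), n_val=len(val_idx))


def predict(model: TrainedModel | _ZNet, masked: np.ndarray,
            clip: bool = False) -> np.ndarray:
    """Reconstruct dense spectra from masked sparse inputs.

    Returns an array shaped like the input rows (length 101 each); with
    ``clip`` the output is clamped to the physical range [0, 1.05].
    """
    net = model.net if isinstance(model, TrainedModel) else model
    x = _as_batches(masked, net.spec)
    out = net.forward(x, train=False)[:, 0, :]
    if clip:
        out = np.clip(out, 0.0, 1.05)
    single = (np.asarray(masked).ndim == 1
              or (np.asarray(masked).ndim == 2 and net.spec.mask_channel))
    return out[0] if single else out


def save_model(model: TrainedModel, out_dir: str | Path) -> Path:
    """Persist a trained model: spec JSON, weight arrays, history CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec_d = {
        "architecture": model.spec.architecture,
        "input_length": model.spec.input_length,
        "kernel_size": model.spec.kernel_size,
        "mask_channel": model.spec.mask_channel,
        "seed": model.seed,
    }
    (out / "spec.json").write_text(json.dumps(spec_d, indent=2))
    np.savez(out / "weights.npz", **model.net.get_weights())
    with open(out / "history.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "train_loss", "val_loss", "lr"])
        for i in range(len(model.history["train_loss"])):
            w.writerow([i, model.history["train_loss"][i],
                        model.history["val_loss"][i], model.history["lr"][i]])
    return out


def load_model(model_dir: str | Path) -> TrainedModel:
    """Load a model saved by :func:`save_model`."""
    d = Path(model_dir)
    spec_d = json.loads((d / "spec.json").read_text())
    seed = spec_d.pop("seed", None)
    spec = ModelSpec(**spec_d)
    net = _ZNet(spec, seed=0)
    with np.load(d / "weights.npz") as npz:
        net.set_weights({k: npz[k] for k in npz.files})
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "lr": []}
    hist_path = d / "history.csv"
    if hist_path.exists():
        with open(hist_path) as fh:
            for row in csv.DictReader(fh):
                history["train_loss"].append(float(row["train_loss"]))
                history["val_loss"].append(float(row["val_loss"]))
                history["lr"].append(float(row["lr"]))
    return TrainedModel(spec=spec, net=net, history=history,
                        config=TrainConfig(), seed=seed)
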