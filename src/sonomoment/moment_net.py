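"""The 31-layer CNN moment regressor, its training loop, and the
leave-one-speed-out cross-validation design.

Architecture: an image input layer followed by seven sets of
convolution -> batch normalization -> ReLU, with a 2x2/stride-2 average
pooling after sets 1–6 (set 7 has none); then 20% dropout, one fully
connected unit, and a regression output — 1 + 7 + 7 + 7 + 6 + 1 + 1 + 1 =
31 layers.  Filter counts are 8, 16, 32, 32, 32, 32, 32; every convolution
is 3x3, stride 1, 'same'-padded, so pooling alone halves the spatial size.

Training is stochastic gradient descent with momentum (0.9) on the mean
squared regression loss: mini-batches of 128, up to 30 epochs, learning
rate 0.001 dropping to 0.0001 after epoch 20, data reshuffled every epoch, and
validation evaluated every floor(n_train / batch) iterations.  Images are
streamed one mini-batch at a time from their source, never materialized as
a whole, and are zero-centered by the training-set mean image (statistics
frozen for validation and prediction).

All layers, gradients and the optimizer are implemented directly on NumPy
(im2col convolutions running on BLAS); weights use He-uniform
initialization, and every random draw (init, shuffling, dropout) descends
from the configured seed, so identical seeds give identical weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .synthetic_data import substream

__all__ = [
    "CnnSpec",
    "TrainConfig",
    "DataSplit",
    "TrainedModel",
    "DivergenceError",
    "build_cnn",
    "layer_output_shapes",
    "make_splits",
    "train",
    "predict",
    "fold_frame_source",
]

_FILTERS = (8, 16, 32, 32, 32, 32, 32)


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


# ---------------------------------------------------------------------------
# Architecture spec and shape propagation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CnnSpec:
    """Static description of the 31-layer network."""

    input_hw: tuple[int, int]
    filters: tuple[int, ...] = _FILTERS
    kernel: int = 3
    pool: int = 2
    pool_stride: int = 2
    dropout_p: float = 0.20

    @property
    def layers(self) -> list[tuple[str, str]]:
        """Ordered (name, kind) pairs for all 31 layers."""
        out = [("input", "input")]
        for k in range(1, len(self.filters) + 1):
            out += [(f"conv_{k}", "conv"), (f"bn_{k}", "batchnorm"), (f"relu_{k}", "relu")]
            if k < len(self.filters):
                out.append((f"avgpool_{k}", "avgpool"))
        out += [("dropout", "dropout"), ("fc", "fc"), ("regression", "regression")]
        return out

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def fc_inputs(self) -> int:
        h, w, c = layer_output_shapes(self)[-3][1]  # shape feeding the FC
        return h * w * c

    def to_dict(self) -> dict:
        return asdict(self)


def _pool_out(n: int, pool: int, stride: int) -> int:
    return (n - pool) // stride + 1


def layer_output_shapes(spec: CnnSpec) -> list[tuple[str, tuple[int, int, int]]]:
    """(layer name, output (rows, cols, channels)) for every layer.

    'same' convolutions preserve the spatial size; each pooling maps
    n -> floor((n - pool)/stride) + 1.  The FC and regression layers report
    (1, 1, 1).
    """
    h, w = spec.input_hw
    shapes: list[tuple[str, tuple[int, int, int]]] = [("input", (h, w, 1))]
    for k, f in enumerate(spec.filters, start=1):
        shapes.append((f"conv_{k}", (h, w, f)))
        shapes.append((f"bn_{k}", (h, w, f)))
        shapes.append((f"relu_{k}", (h, w, f)))
        if k < len(spec.filters):
            h = _pool_out(h, spec.pool, spec.pool_stride)
            w = _pool_out(w, spec.pool, spec.pool_stride)
            shapes.append((f"avgpool_{k}", (h, w, f)))
    f = spec.filters[-1]
    shapes.append(("dropout", (h, w, f)))
    shapes.append(("fc", (1, 1, 1)))
    shapes.append(("regression", (1, 1, 1)))
    return shapes


def build_cnn(input_hw: tuple[int, int], **overrides) -> CnnSpec:
    """Construct the 31-layer spec, validating that the input survives all
    six spatial halvings (minimum side 64 with the default 2x2 pooling)."""
    spec = CnnSpec(input_hw=tuple(input_hw), **overrides)
    for name, (h, w, _c) in layer_output_shapes(spec):
        if h < 1 or w < 1:
            raise ValueError(
                f"input {input_hw} collapses to {h}x{w} at layer '{name}'; "
                "each side must survive six halvings (>= 64 px with defaults)"
            )
    assert spec.n_layers == 31
    return spec


# ---------------------------------------------------------------------------
# Leave-one-speed-out split
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fold:
    held_out_speed: float
    train: tuple[tuple[float, int], ...]  # (speed, cycle index) keys
    validation: tuple[tuple[float, int], ...]
    prediction: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        tr, va, pr = set(self.train), set(self.validation), set(self.prediction)
        if tr & va:
            raise ValueError("train and validation cycles overlap")
        if (tr | va) & pr:
            raise ValueError("prediction cycles leak into train/validation")


@dataclass(frozen=True)
class DataSplit:
    """One fold per held-out speed (leave-one-speed-out)."""

    folds: tuple[Fold, ...]

    def __len__(self) -> int:
        return len(self.folds)

    def fold_for(self, speed: float) -> Fold:
        for f in self.folds:
            if f.held_out_speed == speed:
                return f
        raise KeyError(f"no fold holds out speed {speed}")


def make_splits(
    cycles_by_speed: dict[float, Sequence],
    cycles_per_speed: int = 8,
    fit_cycles: int = 5,
) -> DataSplit:
    """Leave-one-speed-out folds with the 5-train / 3-predict cycle split.

    Within every speed, the first ``fit_cycles`` stance cycles are the
    model-fitting pool and the remainder the prediction pool.  For each
    held-out speed s: train = fitting cycles of all other speeds (4:1
    against validation by design), validation = fitting cycles of s,
    prediction = the remaining cycles of all speeds.
    """
    speeds = sorted(cycles_by_speed)
    for s in speeds:
        if len(cycles_by_speed[s]) < cycles_per_speed:
            raise ValueError(
                f"speed {s} has {len(cycles_by_speed[s])} cycles; "
                f"{cycles_per_speed} required"
            )
    folds = []
    for held in speeds:
        train = tuple(
            (s, k) for s in speeds if s != held for k in range(fit_cycles)
        )
        validation = tuple((held, k) for k in range(fit_cycles))
        prediction = tuple(
            (s, k) for s in speeds for k in range(fit_cycles, cycles_per_speed)
        )
        folds.append(Fold(held, train, validation, prediction))
    return DataSplit(tuple(folds))


# ---------------------------------------------------------------------------
# Layers (forward + backward), parameters, optimizer
# ---------------------------------------------------------------------------

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> (N,H,W, C*k*k) patch matrix under 'same' zero padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # win: (N, H, W, C, k, k) -> flatten trailing (C, k, k)
    n, h, w = x.shape[0], x.shape[1], x.shape[2]
    return np.ascontiguousarray(win).reshape(n, h, w, -1)


def _conv_forward(x, W, b):
    k = W.shape[0]
    cols = _im2col(x, k)  # (N,H,W,C*k*k)
    Wr = W.transpose(2, 0, 1, 3).reshape(-1, W.shape[3])  # (C*k*k, F)
    y = cols @ Wr + b
    return y, cols


def _conv_backward(dout, cols, x_shape, W):
    k, _, c_in, f = W.shape
    n, h, w, _ = x_shape
    Wr = W.transpose(2, 0, 1, 3).reshape(-1, f)
    dW_flat = cols.reshape(-1, Wr.shape[0]).T @ dout.reshape(-1, f)
    dW = dW_flat.reshape(c_in, k, k, f).transpose(1, 2, 0, 3)
    db = dout.sum(axis=(0, 1, 2))
    # dx: 'full' correlation of dout with the flipped kernels
    W_rot = W[::-1, ::-1].transpose(0, 1, 3, 2)  # (k,k,F,Cin)
    cols_d = _im2col(dout, k)  # (N,H,W,F*k*k)
    Wr_rot = W_rot.transpose(2, 0, 1, 3).reshape(-1, c_in)
    dx = cols_d @ Wr_rot
    return dx, dW, db


def _pool_forward(x, pool, stride):
    n, h, w, c = x.shape
    oh, ow = _pool_out(h, pool, stride), _pool_out(w, pool, stride)
    xc = x[:, : oh * stride, : ow * stride, :]
    y = xc.reshape(n, oh, pool, ow, pool, c).mean(axis=(2, 4))
    return y


def _pool_backward(dout, x_shape, pool, stride):
    n, h, w, c = x_shape
    oh, ow = dout.shape[1], dout.shape[2]
    dx = np.zeros(x_shape, dtype=dout.dtype)
    up = np.repeat(np.repeat(dout, pool, axis=1), pool, axis=2) / (pool * pool)
    dx[:, : oh * pool, : ow * pool, :] = up
    return dx


def _bn_forward(x, gamma, beta, running, training):
    axes = (0, 1, 2)
    if training:
        mean = x.mean(axis=axes, dtype=np.float64).astype(x.dtype)
        var = x.var(axis=axes, dtype=np.float64).astype(x.dtype)
        running["mean"] = (
            (1 - _BN_MOMENTUM) * running["mean"] + _BN_MOMENTUM * mean
        ).astype(x.dtype)
        running["var"] = (
            (1 - _BN_MOMENTUM) * running["var"] + _BN_MOMENTUM * var
        ).astype(x.dtype)
    else:
        mean, var = running["mean"], running["var"]
    inv_std = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (x - mean) * inv_std
    return gamma * xhat + beta, (xhat, inv_std)


def _bn_backward(dout, cache, gamma):
    xhat, inv_std = cache
    m = dout.shape[0] * dout.shape[1] * dout.shape[2]
    axes = (0, 1, 2)
    dgamma = (dout * xhat).sum(axis=axes)
    dbeta = dout.sum(axis=axes)
    dxhat = dout * gamma
    dx = (
        inv_std
        / m
        * (m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))
    )
    return dx, dgamma, dbeta


def _init_params(spec: CnnSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """He-uniform conv/FC weights, zero biases, identity BN affine."""
    params: dict[str, np.ndarray] = {}
    c_in = 1
    k = spec.kernel
    for i, f in enumerate(spec.filters, start=1):
        fan_in = k * k * c_in
        limit = np.sqrt(6.0 / fan_in)
        params[f"conv_{i}.W"] = rng.uniform(-limit, limit, (k, k, c_in, f)).astype(
            np.float32
        )
        params[f"conv_{i}.b"] = np.zeros(f, dtype=np.float32)
        params[f"bn_{i}.gamma"] = np.ones(f, dtype=np.float32)
        params[f"bn_{i}.beta"] = np.zeros(f, dtype=np.float32)
        c_in = f
    d = spec.fc_inputs
    limit = np.sqrt(6.0 / d)
    params["fc.W"] = rng.uniform(-limit, limit, (d, 1)).astype(np.float32)
    params["fc.b"] = np.zeros(1, dtype=np.float32)
    return params


def _init_running(spec: CnnSpec) -> dict[str, dict[str, np.ndarray]]:
    return {
        f"bn_{i}": {
            "mean": np.zeros(f, dtype=np.float32),
            "var": np.ones(f, dtype=np.float32),
        }
        for i, f in enumerate(spec.filters, start=1)
    }


def _forward(spec, params, running, x, training, drop_rng=None):
    """Forward pass; returns predictions and (in training) the tape."""
    tape = []
    n_sets = len(spec.filters)
    for i in range(1, n_sets + 1):
        x_in_shape = x.shape
        y, cols = _conv_forward(x, params[f"conv_{i}.W"], params[f"conv_{i}.b"])
        tape.append(("conv", i, cols, x_in_shape))
        y, bn_cache = _bn_forward(
            y, params[f"bn_{i}.gamma"], params[f"bn_{i}.beta"], running[f"bn_{i}"], training
        )
        tape.append(("bn", i, bn_cache))
        mask = y > 0
        y = y * mask
        tape.append(("relu", i, mask))
        if i < n_sets:
            tape.append(("pool", i, y.shape))
            y = _pool_forward(y, spec.pool, spec.pool_stride)
        x = y
    if training and spec.dropout_p > 0:
        keep = (drop_rng.random(x.shape) >= spec.dropout_p).astype(x.dtype)
        x = x * keep / (1.0 - spec.dropout_p)
        tape.append(("dropout", 0, keep))
    flat_shape = x.shape
    flat = x.reshape(x.shape[0], -1)
    pred = flat @ params["fc.W"] + params["fc.b"]
    tape.append(("fc", 0, (flat, flat_shape)))
    return pred[:, 0], tape


def _backward(spec, params, tape, dpred):
    grads = {}
    dout = dpred[:, None].astype(np.float32)
    # FC
    kind, _, (flat, flat_shape) = tape.pop()
    grads["fc.W"] = flat.T @ dout
    grads["fc.b"] = dout.sum(axis=0)
    dx = (dout @ params["fc.W"].T).reshape(flat_shape)
    if tape and tape[-1][0] == "dropout":
        _, _, keep = tape.pop()
        dx = dx * keep / (1.0 - spec.dropout_p)
    while tape:
        kind, i, *payload = tape.pop()
        if kind == "pool":
            (pre_shape,) = payload
            dx = _pool_backward(dx, pre_shape, spec.pool, spec.pool_stride)
        elif kind == "relu":
            dx = dx * payload[0]
        elif kind == "bn":
            dx, dg, db = _bn_backward(dx, payload[0], params[f"bn_{i}.gamma"])
            grads[f"bn_{i}.gamma"] = dg
            grads[f"bn_{i}.beta"] = db
        elif kind == "conv":
            cols, x_in_shape = payload
            dx, dW, db = _conv_backward(dx, cols, x_in_shape, params[f"conv_{i}.W"])
            grads[f"conv_{i}.W"] = dW
            grads[f"conv_{i}.b"] = db
    return grads


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule for one fold."""

    mini_batch: int = 128
    max_epochs: int = 30
    lr_initial: float = 0.001
    lr_late: float = 0.0001
    lr_drop_epoch: int = 20
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mini_batch < 1 or self.max_epochs < 1:
            raise ValueError("mini_batch and max_epochs must be >= 1")
        if self.lr_initial <= 0 or self.lr_late <= 0:
            raise ValueError("learning rates must be positive")


@dataclass
class TrainedModel:
    """Weights plus everything needed to reproduce and reuse the fit."""

    spec: CnnSpec
    params: dict
    running: dict
    mean_image: np.ndarray
    config: TrainConfig
    record: dict = field(default_factory=dict)

    def save(self, path) -> None:
        """Single-file checkpoint: weights, BN stats, spec, seed, record."""
        arrays = {f"param:{k}": v for k, v in self.params.items()}
        for name, st in self.running.items():
            arrays[f"running:{name}:mean"] = st["mean"]
            arrays[f"running:{name}:var"] = st["var"]
        arrays["mean_image"] = self.mean_image
        meta = {
            "spec": self.spec.to_dict(),
            "config": asdict(self.config),
            "record": self.record,
        }
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta_json"].tobytes()).decode())
            spec_d = meta["spec"]
            spec = CnnSpec(
                input_hw=tuple(spec_d["input_hw"]),
                filters=tuple(spec_d["filters"]),
                kernel=spec_d["kernel"],
                pool=spec_d["pool"],
                pool_stride=spec_d["pool_stride"],
                dropout_p=spec_d["dropout_p"],
            )
            params = {
                k.split(":", 1)[1]: z[k] for k in z.files if k.startswith("param:")
            }
            running: dict = {}
            for k in z.files:
                if k.startswith("running:"):
                    _, name, stat = k.split(":")
                    running.setdefault(name, {})[stat] = z[k]
            return cls(
                spec=spec,
                params=params,
                running=running,
                mean_image=z["mean_image"],
                config=TrainConfig(**meta["config"]),
                record=meta["record"],
            )


def _gather_batch(images, idx: np.ndarray) -> np.ndarray:
    return np.stack([np.asarray(images[int(i)], dtype=np.float32) for i in idx])


def _check_shapes(images, labels, spec):
    first = np.asarray(images[0])
    if tuple(first.shape) != tuple(spec.input_hw):
        raise ValueError(
            f"image shape {first.shape} does not match spec input {spec.input_hw}"
        )
    labels = np.asarray(labels, dtype=np.float32)
    if not np.all(np.isfinite(labels)):
        raise ValueError("labels must be finite")
    if len(images) != labels.size:
        raise ValueError("image count != label count")
    return labels


def _mean_image(images, batch: int) -> np.ndarray:
    total = np.zeros(np.asarray(images[0]).shape, dtype=np.float64)
    n = len(images)
    for s in range(0, n, batch):
        idx = np.arange(s, min(s + batch, n))
        total += _gather_batch(images, idx).sum(axis=0)
    return (total / n).astype(np.float32)


def train(
    spec: CnnSpec,
    images,
    labels,
    cfg: TrainConfig | None = None,
    val_images=None,
    val_labels=None,
) -> TrainedModel:
    """Fit the network with mini-batch SGD + momentum.

    ``images`` is any indexable source of (H, W) frames (NumPy stack,
    HDF5 dataset, concatenated stance cycles, ...); frames are fetched one
    mini-batch at a time so the full set is never materialized.  The
    training-set mean image is the only input-normalization statistic and
    is frozen into the model.  Per-iteration training loss/RMSE and the
    scheduled validation loss/RMSE are recorded.
    """
    cfg = cfg or TrainConfig()
    labels = _check_shapes(images, labels, spec)
    if val_images is not None:
        val_labels = _check_shapes(val_images, val_labels, spec)
    rng_init = substream(cfg.seed, "init")
    params = _init_params(spec, rng_init)
    running = _init_running(spec)
    velocity = {k: np.zeros_like(v) for k, v in params.items()}
    mean_img = _mean_image(images, cfg.mini_batch)

    n = len(images)
    val_every = max(n // cfg.mini_batch, 1)
    record = {"train_loss": [], "train_rmse": [], "validation": []}
    it = 0
    for epoch in range(cfg.max_epochs):
        lr = cfg.lr_initial if epoch < cfg.lr_drop_epoch else cfg.lr_late
        order = substream(cfg.seed, "shuffle", str(epoch)).permutation(n)
        drop_rng = substream(cfg.seed, "dropout", str(epoch))
        for s in range(0, n, cfg.mini_batch):
            idx = order[s : s + cfg.mini_batch]
            x = _gather_batch(images, idx) - mean_img
            x = x[..., None]
            y = labels[idx]
            pred, tape = _forward(spec, params, running, x, True, drop_rng)
            resid = pred - y
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at iteration {it}")
            record["train_loss"].append(loss)
            record["train_rmse"].append(float(np.sqrt(loss)))
            dpred = (2.0 / y.size) * resid
            grads = _backward(spec, params, tape, dpred)
            for k in params:
                velocity[k] = cfg.momentum * velocity[k] - lr * grads[k]
                params[k] = params[k] + velocity[k].astype(params[k].dtype)
            it += 1
            if val_images is not None and it % val_every == 0:
                model = TrainedModel(spec, params, running, mean_img, cfg)
                vp = predict(model, val_images, batch=cfg.mini_batch)
                vl = float(np.mean((vp - val_labels) ** 2))
                record["validation"].append(
                    {"iteration": it, "loss": vl, "rmse": float(np.sqrt(vl))}
                )
    return TrainedModel(spec, params, running, mean_img, cfg, record)


def predict(model: TrainedModel, images, batch: int = 128) -> np.ndarray:
    """One moment value (Nm) per frame; dropout inactive, BN in inference
    mode with the stored running statistics."""
    first = np.asarray(images[0])
    if tuple(first.shape) != tuple(model.spec.input_hw):
        raise ValueError(
            f"image shape {first.shape} does not match model input "
            f"{model.spec.input_hw}"
        )
    n = len(images)
    out = np.empty(n, dtype=np.float64)
    for s in range(0, n, batch):
        idx = np.arange(s, min(s + batch, n))
        x = _gather_batch(images, idx) - model.mean_image
        pred, _ = _forward(model.spec, model.params, model.running, x[..., None], False)
        out[idx] = pred
    return out


class fold_frame_source:
    """Lazy concatenation of stance-cycle frames for streaming training.

    Indexing maps a global frame index to (cycle, offset) without copying
    the cycles' image stacks.
    """

    def __init__(self, cycles: Iterable):
        self.cycles = [c for c in cycles]
        counts = [c.frames.shape[0] for c in self.cycles]
        self.offsets = np.concatenate([[0], np.cumsum(counts)])

    def __len__(self) -> int:
        return int(self.offsets[-1])

    def __getitem__(self, i: int):
        k = int(np.searchsorted(self.offsets, i, side="right") - 1)
        return self.cycles[k].frames[i - self.offsets[k]]

    @property
    def labels(self) -> np.ndarray:
        return np.concatenate([c.moment for c in self.cycles])
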