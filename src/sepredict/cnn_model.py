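"""1-D convolutional classifiers over the 36-feature table.

Three fixed architectures with 2, 3 or 4 convolutional layers. Each conv
layer uses width-3 kernels, stride 1 and same padding (so convolution never
changes the spatial length) followed by ReLU and a non-overlapping max-pool;
kernel counts double per layer (32, 64, 128, 256) and every architecture
flattens to exactly 256 inputs for the dense 256->64 layer, which feeds a
64->2 softmax output. Dropout is applied in the dense layer only.

Everything — forward pass, backprop, Adam — is implemented in numpy, in
float32, deterministically under a single seed. The input is treated as a
length-36 single-channel signal; convolving over an (arbitrary) feature
ordering is a modelling quirk inherited from the original method.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import evaluation

#: learning-rate grid used by the published hyper-parameter sweep
ALPHA_GRID: tuple[float, ...] = (1e-5, 5e-5, 1e-4, 5e-4, 1e-3, 5e-3, 1e-2, 5e-2)
#: epoch grid: 50..150 with stride 10
EPOCH_GRID: tuple[int, ...] = tuple(range(50, 151, 10))
#: conv-layer-count grid
LAYER_GRID: tuple[int, ...] = (2, 3, 4)

_EPS_CLIP = 1e-12


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # conv | pool | dense | softmax
    kernels: int | None = None       # conv output channels
    kernel_width: int = 3
    pool_width: int | None = None
    units: int | None = None         # dense/softmax output size
    stride: int = 1
    padding: str = "same"

    def __post_init__(self):
        if self.kind not in ("conv", "pool", "dense", "softmax"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv" and (self.stride != 1 or self.padding != "same"):
            raise ValueError("conv layers are stride-1 same-padding only")
        if self.kind == "pool" and self.pool_width not in (2, 3):
            raise ValueError("pool width must be 2 or 3")


@dataclass(frozen=True)
class ModelSpec:
    name: str
    layers: tuple[LayerSpec, ...]
    input_len: int = 36
    n_classes: int = 2


@dataclass
class TrainConfig:
    """Hyper-parameters of one training run."""

    alpha: float = 5e-4
    epochs: int = 100
    seed: int = 0
    dropout_rate: float = 0.5
    batch_size: int | None = 128  # None = full batch
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class TrainedModel:
    spec: ModelSpec
    params: dict[str, np.ndarray]
    config: TrainConfig
    history: dict[str, list[float]] = field(default_factory=dict)


def build_architecture(n_conv_layers: int, input_len: int = 36) -> ModelSpec:
    """Fixed architecture for 2, 3 or 4 conv layers.

    conv32-pool3-conv64-pool3 [-conv128-pool2 [-conv256-pool2]] -dense64-softmax2
    """
    if n_conv_layers not in (2, 3, 4):
        raise ValueError(f"number of conv layers must be 2, 3 or 4, got {n_conv_layers}")
    kernel_counts = (32, 64, 128, 256)[:n_conv_layers]
    pool_widths = (3, 3, 2, 2)[:n_conv_layers]
    layers: list[LayerSpec] = []
    for kernels, pw in zip(kernel_counts, pool_widths):
        layers.append(LayerSpec(kind="conv", kernels=kernels, kernel_width=3))
        layers.append(LayerSpec(kind="pool", pool_width=pw))
    layers.append(LayerSpec(kind="dense", units=64))
    layers.append(LayerSpec(kind="softmax", units=2))
    spec = ModelSpec(name=f"cnn-{n_conv_layers}l", layers=tuple(layers),
                     input_len=input_len)
    if input_len == 36 and flatten_size(spec) != 256:
        raise AssertionError("architecture must flatten to 256 dense inputs")
    return spec


def propagate_shapes(spec: ModelSpec) -> list[tuple[str, int, int]]:
    """Per-layer output shapes as (layer kind, channels, length).

    Same-padding stride-1 convolution preserves length; a width-w pool maps
    length n to floor(n/w). Dense/softmax outputs are (units, 1).
    """
    shapes: list[tuple[str, int, int]] = [("input", 1, spec.input_len)]
    channels, length = 1, spec.input_len
    for layer in spec.layers:
        if layer.kind == "conv":
            channels = layer.kernels
        elif layer.kind == "pool":
            length = length // layer.pool_width
        elif layer.kind in ("dense", "softmax"):
            channels, length = layer.units, 1
        if length < 1:
            raise ValueError(
                f"layer {layer.kind} reduces spatial length below 1 "
                f"(input_len {spec.input_len} too short for this architecture)")
        shapes.append((layer.kind, channels, length))
    return shapes


def flatten_size(spec: ModelSpec) -> int:
    """Number of inputs entering the dense layer (channels x length)."""
    channels, length = 1, spec.input_len
    for layer in spec.layers:
        if layer.kind == "conv":
            channels = layer.kernels
        elif layer.kind == "pool":
            length = length // layer.pool_width
            if length < 1:
                raise ValueError("spatial length collapsed below 1 before dense")
        else:
            break
    return channels * length


def relu(x):
    return np.maximum(0, x)


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise stable softmax (max subtraction)."""
    z = np.asarray(z, dtype=float)
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(h: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy of positive-class probabilities h vs labels y."""
    h = np.asarray(h, dtype=float)
    y = np.asarray(y, dtype=float)
    if h.size == 0:
        raise ValueError("cannot average a loss over zero samples")
    h = np.clip(h, _EPS_CLIP, 1 - _EPS_CLIP)
    return float(-np.mean(y * np.log(h) + (1 - y) * np.log(1 - h)))


# ---------------------------------------------------------------------------
# parameter init / forward / backward

def _init_params(spec: ModelSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """He-style seeded initialization, float32."""
    params: dict[str, np.ndarray] = {}
    channels = 1
    i_conv = 0
    for layer in spec.layers:
        if layer.kind == "conv":
            fan_in = layer.kernel_width * channels
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           size=(fan_in, layer.kernels))
            params[f"conv{i_conv}_W"] = w.astype(np.float32)
            params[f"conv{i_conv}_b"] = np.zeros(layer.kernels, dtype=np.float32)
            channels = layer.kernels
            i_conv += 1
        elif layer.kind == "dense":
            fan_in = flatten_size(spec)
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, layer.units))
            params["dense_W"] = w.astype(np.float32)
            params["dense_b"] = np.zeros(layer.units, dtype=np.float32)
            channels = layer.units
        elif layer.kind == "softmax":
            w = rng.normal(0.0, np.sqrt(1.0 / channels), size=(channels, layer.units))
            params["out_W"] = w.astype(np.float32)
            params["out_b"] = np.zeros(layer.units, dtype=np.float32)
    return params


def _forward(spec: ModelSpec, params: dict[str, np.ndarray], X: np.ndarray,
             dropout_rate: float = 0.0,
             rng: np.random.Generator | None = None):
    """Forward pass; returns (probs, cache) — cache is None-free only in train."""
    m = X.shape[0]
    A = X.astype(np.float32, copy=False)[:, :, None]  # (m, L, C=1)
    cache: list = []
    i_conv = 0
    probs = None
    for layer in spec.layers:
        if layer.kind == "conv":
            W = params[f"conv{i_conv}_W"]
            b = params[f"conv{i_conv}_b"]
            w = layer.kernel_width
            L, C = A.shape[1], A.shape[2]
            pad_l, pad_r = (w - 1) // 2, w // 2
            Ap = np.pad(A, ((0, 0), (pad_l, pad_r), (0, 0)))
            win = np.lib.stride_tricks.sliding_window_view(Ap, w, axis=1)
            cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(m * L, w * C)
            Z = cols @ W + b
            Aout = np.maximum(Z, 0, out=Z).reshape(m, L, layer.kernels)
            cache.append(("conv", i_conv, cols, Aout, (L, C, w, pad_l)))
            A = Aout
            i_conv += 1
        elif layer.kind == "pool":
            w = layer.pool_width
            L, C = A.shape[1], A.shape[2]
            L2 = L // w
            R = A[:, :L2 * w].reshape(m, L2, w, C)
            A2 = R.max(axis=2)
            cache.append(("pool", R, A2, (L, w, L2, C)))
            A = A2
        elif layer.kind == "dense":
            flat = A.reshape(m, -1)
            Z1 = flat @ params["dense_W"] + params["dense_b"]
            H = np.maximum(Z1, 0, out=Z1)
            if dropout_rate > 0 and rng is not None:
                mask = (rng.random(H.shape) >= dropout_rate).astype(np.float32)
                mask /= np.float32(1 - dropout_rate)
                Hd = H * mask
            else:
                mask = None
                Hd = H
            cache.append(("dense", flat, H, mask, A.shape))
            A = Hd
        elif layer.kind == "softmax":
            Z2 = A @ params["out_W"] + params["out_b"]
            probs = softmax(Z2)
            cache.append(("softmax", A, probs))
    return probs, cache


def _backward(spec: ModelSpec, params: dict[str, np.ndarray], cache: list,
              y: np.ndarray) -> dict[str, np.ndarray]:
    """Gradient of the mean binary cross-entropy wrt all parameters."""
    grads: dict[str, np.ndarray] = {}
    m = y.shape[0]
    # softmax + binary CE on the positive-class output: dJ/dz = +-(p1 - y)/m
    kind, Hd, probs = cache[-1]
    g = (probs[:, 1] - y).astype(np.float32) / np.float32(m)
    dZ2 = np.stack([-g, g], axis=1)
    grads["out_W"] = Hd.T @ dZ2
    grads["out_b"] = dZ2.sum(axis=0)
    dA = dZ2 @ params["out_W"].T

    for entry in reversed(cache[:-1]):
        if entry[0] == "dense":
            _, flat, H, mask, pre_shape = entry
            if mask is not None:
                dA = dA * mask
            dZ1 = dA * (H > 0)
            grads["dense_W"] = flat.T @ dZ1
            grads["dense_b"] = dZ1.sum(axis=0)
            dA = (dZ1 @ params["dense_W"].T).reshape(pre_shape)
        elif entry[0] == "pool":
            _, R, A2, (L, w, L2, C) = entry
            # route gradient to the first position attaining the max
            dR = np.zeros((m, L2, w, C), dtype=np.float32)
            taken = np.zeros((m, L2, C), dtype=bool)
            for k in range(w):
                sel = (R[:, :, k, :] == A2) & ~taken
                dR[:, :, k, :] = np.where(sel, dA, 0)
                taken |= sel
            dAfull = np.zeros((m, L, C), dtype=np.float32)
            dAfull[:, :L2 * w] = dR.reshape(m, L2 * w, C)
            dA = dAfull
        elif entry[0] == "conv":
            _, i_conv, cols, Aout, (L, C, w, pad_l) = entry
            dZ = (dA * (Aout > 0)).reshape(m * L, -1)
            grads[f"conv{i_conv}_W"] = cols.T @ dZ
            grads[f"conv{i_conv}_b"] = dZ.sum(axis=0)
            dcols = (dZ @ params[f"conv{i_conv}_W"].T).reshape(m, L, w, C)
            dAp = np.zeros((m, L + w - 1, C), dtype=np.float32)
            for k in range(w):
                dAp[:, k:k + L] += dcols[:, :, k]
            dA = dAp[:, pad_l:pad_l + L]
    return grads


# ---------------------------------------------------------------------------
# training

def train(spec: ModelSpec, X: np.ndarray, y: np.ndarray, config: TrainConfig,
          checkpoints: Sequence[int] | None = None,
          checkpoint_fn: Callable[[int, dict[str, np.ndarray]], None] | None = None,
          ) -> TrainedModel:
    """Train with mini-batch Adam; fully deterministic under ``config.seed``.

    ``checkpoints``/``checkpoint_fn`` allow snapshot evaluation at chosen
    epochs (used by the grid search so an e-epoch run is the prefix of a
    150-epoch run under the same seed).

    History records per-epoch mean batch loss and batch-level training
    accuracy (computed in train mode, i.e. with dropout active).
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] != spec.input_len:
        raise ValueError(f"expected (n, {spec.input_len}) features, got {X.shape}")
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree on sample count")
    if y.size and not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    propagate_shapes(spec)  # validates the architecture against input_len

    rng = np.random.default_rng(config.seed)
    params = _init_params(spec, rng)
    adam_m = {k: np.zeros_like(v) for k, v in params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in params.items()}
    t = 0
    n = X.shape[0]
    batch = config.batch_size or n
    checkpoints = set(checkpoints or ())

    loss_hist: list[float] = []
    acc_hist: list[float] = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_correct = 0
        for lo in range(0, n, batch):
            idx = order[lo:lo + batch]
            Xb, yb = X[idx], y[idx]
            probs, cache = _forward(spec, params, Xb,
                                    dropout_rate=config.dropout_rate, rng=rng)
            batch_loss = cross_entropy_loss(probs[:, 1], yb)
            epoch_loss += batch_loss * len(idx)
            n_correct += int(((probs[:, 1] > probs[:, 0]).astype(int) == yb).sum())
            grads = _backward(spec, params, cache, yb)
            t += 1
            b1c = 1 - config.beta1 ** t
            b2c = 1 - config.beta2 ** t
            for key, g in grads.items():
                adam_m[key] = config.beta1 * adam_m[key] + (1 - config.beta1) * g
                adam_v[key] = config.beta2 * adam_v[key] + (1 - config.beta2) * g * g
                step = (config.alpha * (adam_m[key] / b1c)
                        / (np.sqrt(adam_v[key] / b2c) + config.adam_eps))
                params[key] = params[key] - step.astype(np.float32)
        epoch_loss /= n
        if not np.isfinite(epoch_loss):
            raise RuntimeError(
                f"non-finite loss {epoch_loss} at epoch {epoch}; "
                f"alpha={config.alpha} likely too large")
        loss_hist.append(epoch_loss)
        acc_hist.append(n_correct / n)
        if epoch in checkpoints and checkpoint_fn is not None:
            checkpoint_fn(epoch, params)
    return TrainedModel(spec=spec, params=params, config=config,
                        history={"loss": loss_hist, "accuracy": acc_hist})


def predict_proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    return _predict_proba(model.spec, model.params, X)


def _predict_proba(spec: ModelSpec, params: dict[str, np.ndarray],
                   X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 2 or X.shape[1] != spec.input_len:
        raise ValueError(f"expected (n, {spec.input_len}) features, got {X.shape}")
    probs, _ = _forward(spec, params, X)
    return probs


def predict_label(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Argmax labels; exact ties resolve to class 0."""
    probs = predict_proba(model, X)
    return (probs[:, 1] > probs[:, 0]).astype(int)


# ---------------------------------------------------------------------------
# cross-validation and grid search

def stratified_folds(y: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold split (plain K-fold when k == n, i.e. leave-one-out)."""
    from sklearn.model_selection import KFold, StratifiedKFold

    y = np.asarray(y)
    n = y.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k exceeds sample count")
    if k == n:
        splitter = KFold(n_splits=k)
        return list(splitter.split(np.zeros(n)))
    counts = np.bincount(y, minlength=2)
    if counts[counts > 0].min() < k:
        raise ValueError(
            f"stratification impossible: smallest class has "
            f"{counts[counts > 0].min()} samples < k={k}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros(n), y))


def _fold_report(y_test: np.ndarray, probs: np.ndarray) -> "evaluation.EvalReport":
    scores = probs[:, 1]
    preds = (probs[:, 1] > probs[:, 0]).astype(int)
    return evaluation.evaluate_predictions(y_test, preds, scores=scores,
                                           strict=False)


def cross_validate(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
                   config: TrainConfig, k: int = 5
                   ) -> tuple[list["evaluation.EvalReport"], dict[str, float]]:
    """Stratified k-fold CV; returns per-fold reports and their means.

    Metrics undefined on some fold (e.g. precision when nothing is predicted
    positive) are NaN there and excluded from the mean via nanmean.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    reports = []
    for i, (train_idx, test_idx) in enumerate(stratified_folds(y, k, config.seed)):
        fold_config = TrainConfig(**{**asdict(config), "seed": config.seed + i})
        model = train(spec, X[train_idx], y[train_idx], fold_config)
        probs = predict_proba(model, X[test_idx])
        reports.append(_fold_report(y[test_idx], probs))
    mean = {}
    for metric in ("accuracy", "precision", "recall", "f1", "auc"):
        vals = np.array([getattr(r, metric) for r in reports])
        mean[metric] = (float(np.nanmean(vals))
                        if not np.isnan(vals).all() else float("nan"))
    return reports, mean


@dataclass
class GridSearchResult:
    best: tuple[int, float, int]           # (L, alpha, epochs)
    best_accuracy: float
    surface: "pd.DataFrame"                # columns: L, alpha, epochs, accuracy, f1


def grid_search(X: np.ndarray, y: np.ndarray, seed: int = 0, k: int = 5,
                layer_grid: Sequence[int] = LAYER_GRID,
                alpha_grid: Sequence[float] = ALPHA_GRID,
                epoch_grid: Sequence[int] = EPOCH_GRID,
                dropout_rate: float = 0.5,
                batch_size: int | None = 128) -> GridSearchResult:
    """CV-accuracy grid search over (layers, learning rate, epochs).

    For each (L, alpha) one run per fold is trained to max(epochs) and
    evaluated at every epoch checkpoint — equivalent to separate runs
    because an e-epoch run is the deterministic prefix of a longer one.
    Ties break toward smaller L, then fewer epochs, then smaller alpha.
    """
    import pandas as pd

    layer_grid = list(layer_grid)
    alpha_grid = list(alpha_grid)
    epoch_grid = sorted(epoch_grid)
    if not layer_grid or not alpha_grid or not epoch_grid:
        raise ValueError("empty hyper-parameter grid")
    X = np.asarray(X)
    y = np.asarray(y)
    rows = []
    for L in layer_grid:
        spec = build_architecture(L, input_len=X.shape[1])
        for alpha in alpha_grid:
            # metric accumulators: (epochs -> list over folds)
            acc: dict[int, list[float]] = {e: [] for e in epoch_grid}
            f1: dict[int, list[float]] = {e: [] for e in epoch_grid}
            for i, (tr, te) in enumerate(stratified_folds(y, k, seed)):
                config = TrainConfig(alpha=alpha, epochs=max(epoch_grid),
                                     seed=seed + i, dropout_rate=dropout_rate,
                                     batch_size=batch_size)

                def snapshot(epoch, params, _te=te, _acc=acc, _f1=f1, _spec=spec):
                    probs = _predict_proba(_spec, params, X[_te])
                    report = _fold_report(y[_te], probs)
                    _acc[epoch].append(report.accuracy)
                    _f1[epoch].append(report.f1)

                try:
                    train(spec, X[tr], y[tr], config,
                          checkpoints=epoch_grid, checkpoint_fn=snapshot)
                except RuntimeError:
                    # divergent cell (non-finite loss): record as unusable
                    for e in epoch_grid:
                        if len(acc[e]) <= i:
                            acc[e].append(np.nan)
                            f1[e].append(np.nan)
            for e in epoch_grid:
                rows.append({"L": L, "alpha": alpha, "epochs": e,
                             "accuracy": float(np.nanmean(acc[e]))
                             if not all(np.isnan(acc[e])) else np.nan,
                             "f1": float(np.nanmean(f1[e]))
                             if not all(np.isnan(f1[e])) else np.nan})
    surface = pd.DataFrame(rows)
    usable = surface.dropna(subset=["accuracy"])
    if usable.empty:
        raise RuntimeError("every grid cell diverged")
    # argmax with deterministic tie-breaking: smaller L, epochs, alpha
    ordered = usable.sort_values(["L", "epochs", "alpha"], kind="stable")
    best_row = ordered.loc[ordered["accuracy"].idxmax()]
    best_acc = usable["accuracy"].max()
    candidates = ordered[ordered["accuracy"] == best_acc]
    best_row = candidates.iloc[0]
    return GridSearchResult(
        best=(int(best_row["L"]), float(best_row["alpha"]), int(best_row["epochs"])),
        best_accuracy=float(best_acc),
        surface=surface)


# ---------------------------------------------------------------------------
# serialization

def save_model(model: TrainedModel, path: str | Path) -> None:
    payload = {
        "spec": {
            "name": model.spec.name,
            "input_len": model.spec.input_len,
            "n_classes": model.spec.n_classes,
            "layers": [asdict(l) for l in model.spec.layers],
        },
        "config": asdict(model.config),
        "history": model.history,
        "params": {k: v.tolist() for k, v in model.params.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path) -> TrainedModel:
    with open(path) as fh:
        payload = json.load(fh)
    spec = ModelSpec(
        name=payload["spec"]["name"],
        input_len=payload["spec"]["input_len"],
        n_classes=payload["spec"]["n_classes"],
        layers=tuple(LayerSpec(**l) for l in payload["spec"]["layers"]))
    config = TrainConfig(**payload["config"])
    params = {k: np.asarray(v, dtype=np.float32)
              for k, v in payload["params"].items()}
    return TrainedModel(spec=spec, params=params, config=config,
                        history=payload.get("history", {}))
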