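"""Spectral enhancement with a very-deep residual CNN (VDSR-style).

The enhancer treats a noisy 67-point visible-range reflectance spectrum as a
degraded "image" and learns the residual correction that maps it to the
reference-instrument spectrum:

1. the 1x67 spectrum is stacked into a 41x67 image (the original row plus 40
   copies), so a 2D super-resolution network can consume it;
2. a chain of N zero-padded 3x3 convolutions (default N=20: 1->64 channels,
   64->64 hidden layers with ReLU, a final 64->1 reconstruction layer) emits
   a residual image that is added back to the input.  The receptive field of
   the chain is (2N+1) x (2N+1) = 41x41 for the default depth, matching the
   41-row stacking;
3. the middle 50% of output rows (the 21 centered rows of 41) are averaged
   column-wise back to a 1x67 spectrum, damping row-wise edge artifacts.

No deep-learning framework is assumed: convolution forward/backward passes
are implemented with im2col + BLAS matmul in float32, optimized with Adam.
Training minimizes the MSE between enhanced and reference images (network
native, 2D) or optionally between the averaged 1D spectra.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .spectra_io import (
    GridMismatchError,
    ReflectanceSpectrum,
    visible_grid,
)
from .synthetic import SpectrumPair

__all__ = [
    "StackedImage",
    "EnhancerSpec",
    "EnhancerModel",
    "TrainConfig",
    "TEST_PROFILE_SPEC",
    "TEST_PROFILE_TRAIN",
    "DataError",
    "TrainingDivergenceError",
    "ModelCompatibilityError",
    "N_ROWS",
    "N_COLS",
    "MIDDLE_ROWS",
    "receptive_field_side",
    "stack_spectrum",
    "unstack_average",
    "build_model",
    "forward",
    "enhance",
    "train",
    "save_model",
    "load_model",
]

N_ROWS = 41  # 1 original row + 40 stacked copies
N_COLS = 67
# "middle 50% rows" of 41: the 21 centered rows, 0-based indices 10..30
MIDDLE_ROWS = slice(10, 31)

MODEL_FORMAT_VERSION = 1


class DataError(ValueError):
    """Empty or unusable training data."""


class TrainingDivergenceError(RuntimeError):
    """Loss became non-finite during optimization."""


class ModelCompatibilityError(ValueError):
    """A model file's declared spec does not match its stored weights."""


StackedImage = np.ndarray  # shape (41, 67), float


def receptive_field_side(n_layers: int) -> int:
    """Side length of the receptive field of ``n_layers`` stacked 3x3 convs."""
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    return 2 * n_layers + 1


def stack_spectrum(spectrum: ReflectanceSpectrum) -> StackedImage:
    """Replicate a 67-point spectrum into a 41x67 image (all rows identical)."""
    if not spectrum.on_visible67():
        raise GridMismatchError(
            "stack_spectrum requires the 67-point visible grid (400-730 nm)"
        )
    return np.tile(spectrum.values, (N_ROWS, 1))


def unstack_average(image: np.ndarray) -> ReflectanceSpectrum:
    """Average the 21 centered rows of a 41x67 image back to a spectrum.

    Negative pixels (possible after the residual addition) are clipped to 0.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != (N_ROWS, N_COLS):
        raise ValueError(
            f"expected image of shape ({N_ROWS}, {N_COLS}), got {image.shape}"
        )
    # mean of the middle rows, computed relative to a pivot row so that
    # identical rows (the no-network case) reproduce the input bitwise
    mid = image[MIDDLE_ROWS]
    vals = mid[0] + (mid - mid[0]).mean(axis=0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ReflectanceSpectrum(visible_grid(), np.clip(vals, 0.0, None))


# ---------------------------------------------------------------------------
# network definition

@dataclass(frozen=True)
class EnhancerSpec:
    """Architecture of the residual enhancement network."""

    n_layers: int = 20
    filters_per_hidden_layer: int = 64
    kernel_size: int = 3
    activation: str = "relu"
    residual: bool = True

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise ValueError("n_layers must be >= 2 (first + reconstruction)")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (shape-preserving padding)")
        if self.activation != "relu":
            raise ValueError(f"unsupported activation {self.activation!r}")

    @property
    def receptive_field(self) -> int:
        return receptive_field_side(self.n_layers)

    def layer_channels(self) -> list[tuple[int, int]]:
        """(in, out) channel counts per convolution layer."""
        f = self.filters_per_hidden_layer
        chans = [(1, f)]
        chans += [(f, f)] * (self.n_layers - 2)
        chans += [(f, 1)]
        return chans


@dataclass
class EnhancerModel:
    """Network spec + weights + provenance of the training run."""

    spec: EnhancerSpec
    weights: list[tuple[np.ndarray, np.ndarray]]  # per layer: (W, b)
    training_fingerprint: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        chans = self.spec.layer_channels()
        k = self.spec.kernel_size
        if len(self.weights) != self.spec.n_layers:
            raise ModelCompatibilityError(
                f"{len(self.weights)} weight tensors for {self.spec.n_layers} layers"
            )
        for i, ((cin, cout), (w, b)) in enumerate(zip(chans, self.weights)):
            if w.shape != (cout, cin, k, k) or b.shape != (cout,):
                raise ModelCompatibilityError(
                    f"layer {i}: weight shape {w.shape} inconsistent with spec "
                    f"({cout}, {cin}, {k}, {k})"
                )


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 1e-3
    gradient_clip_norm: float | None = 1.0
    loss: str = "mse"
    loss_domain: str = "2d"  # "2d" (stacked images) or "1d" (averaged spectra)
    seed: int = 0
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.loss != "mse":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.loss_domain not in ("2d", "1d"):
            raise ValueError("loss_domain must be '2d' or '1d'")
        if not (0 <= self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in [0, 1)")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


# reduced profile for continuous-integration runs on one CPU: a shallower,
# narrower network trained briefly on a few hundred pairs
TEST_PROFILE_SPEC = EnhancerSpec(n_layers=8, filters_per_hidden_layer=16)
TEST_PROFILE_TRAIN = TrainConfig(epochs=30, batch_size=16, learning_rate=1e-3)


def build_model(spec: EnhancerSpec = EnhancerSpec(), seed: int = 0) -> EnhancerModel:
    """Initialize a model with seeded He-scaled random weights, zero biases."""
    rng = np.random.default_rng(seed)
    k = spec.kernel_size
    weights = []
    for cin, cout in spec.layer_channels():
        std = np.sqrt(2.0 / (cin * k * k))
        w = (std * rng.standard_normal((cout, cin, k, k))).astype(np.float32)
        b = np.zeros(cout, dtype=np.float32)
        weights.append((w, b))
    return EnhancerModel(spec, weights, {"init_seed": seed})


# ---------------------------------------------------------------------------
# conv primitives (im2col + matmul)

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B*H*W, C*k*k) patch matrix with zero padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B, C, H, W, k, k)
    b, c, h, w = x.shape
    return cols.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * k * k)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    cout, cin, k, _ = w.shape
    bs, _, h, wid = x.shape
    colmat = _im2col(x, k)
    out = colmat @ w.reshape(cout, cin * k * k).T
    out += b
    return out.reshape(bs, h, wid, cout).transpose(0, 3, 1, 2)


def _conv_backward(
    x: np.ndarray, w: np.ndarray, dout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dw, db) of a shape-preserving convolution."""
    cout, cin, k, _ = w.shape
    bs, _, h, wid = x.shape
    dmat = dout.transpose(0, 2, 3, 1).reshape(bs * h * wid, cout)
    colmat = _im2col(x, k)
    dw = (dmat.T @ colmat).reshape(cout, cin, k, k)
    db = dmat.sum(axis=0)
    dcol = (dmat @ w.reshape(cout, cin * k * k)).reshape(bs, h, wid, cin, k, k)
    p = k // 2
    dxp = np.zeros((bs, cin, h + 2 * p, wid + 2 * p), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + wid] += dcol[:, :, :, :, i, j].transpose(
                0, 3, 1, 2
            )
    dx = dxp[:, :, p : p + h, p : p + wid]
    return dx, dw, db


def forward(
    model: EnhancerModel, images: np.ndarray, return_cache: bool = False
):
    """Run the network on a batch of images.

    ``images``: (B, 41, 67) or (B, 1, 41, 67).  Returns (B, 41, 67) output
    (input + residual when the residual skip is on).
    """
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[:, None, :, :]
    acts = [x]
    a = x
    n = model.spec.n_layers
    for i, (w, b) in enumerate(model.weights):
        a = _conv_forward(a, w, b)
        if i < n - 1:
            np.maximum(a, 0.0, out=a)
        acts.append(a)
    out = a + x if model.spec.residual else a
    if return_cache:
        return out[:, 0], acts
    return out[:, 0]


def _backward(
    model: EnhancerModel, acts: list[np.ndarray], dout: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Gradients of the loss w.r.t. every (W, b), given d(loss)/d(output)."""
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(model.weights)
    da = dout[:, None, :, :].astype(np.float32)
    n = model.spec.n_layers
    for i in range(n - 1, -1, -1):
        if i < n - 1:  # ReLU between hidden layers
            da = da * (acts[i + 1] > 0)
        w, _ = model.weights[i]
        dx, dw, db = _conv_backward(acts[i], w, da)
        grads[i] = (dw, db)
        da = dx
    return grads


def enhance(model: EnhancerModel, spectrum: ReflectanceSpectrum) -> ReflectanceSpectrum:
    """Enhance one spectrum: stack -> network -> middle-row average."""
    img = stack_spectrum(spectrum)
    out = forward(model, img[None])[0]
    enhanced = unstack_average(np.asarray(out, dtype=float))
    enhanced.label = spectrum.label
    return enhanced


# ---------------------------------------------------------------------------
# training

def _pairs_to_arrays(pairs: Sequence[SpectrumPair]) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for p in pairs:
        if not p.degraded.on_visible67():
            raise GridMismatchError("training pairs must be on the visible67 grid")
        xs.append(stack_spectrum(p.degraded))
        ys.append(stack_spectrum(p.reference))
    return (
        np.asarray(xs, dtype=np.float32),
        np.asarray(ys, dtype=np.float32),
    )


def _loss_and_grad(
    model: EnhancerModel, xb: np.ndarray, yb: np.ndarray, loss_domain: str
):
    out, acts = forward(model, xb, return_cache=True)
    if loss_domain == "2d":
        diff = out - yb[:, 0] if yb.ndim == 4 else out - yb
        loss = float(np.mean(diff.astype(np.float64) ** 2))
        dout = (2.0 / diff.size) * diff
    else:  # loss on the averaged 1D spectra
        mid = out[:, MIDDLE_ROWS, :].mean(axis=1)
        ymid = (yb[:, 0] if yb.ndim == 4 else yb)[:, MIDDLE_ROWS, :].mean(axis=1)
        diff1 = mid - ymid
        loss = float(np.mean(diff1.astype(np.float64) ** 2))
        n_mid = MIDDLE_ROWS.stop - MIDDLE_ROWS.start
        dout = np.zeros_like(out)
        dout[:, MIDDLE_ROWS, :] = ((2.0 / diff1.size) * diff1 / n_mid)[:, None, :]
    grads = _backward(model, acts, dout)
    return loss, grads


def _clip_gradients(grads, max_norm: float | None) -> None:
    if max_norm is None or max_norm <= 0:
        return
    total = np.sqrt(
        sum(float(np.sum(dw.astype(np.float64) ** 2)) + float(np.sum(db.astype(np.float64) ** 2))
            for dw, db in grads)
    )
    if total > max_norm:
        scale = np.float32(max_norm / (total + 1e-12))
        for dw, db in grads:
            dw *= scale
            db *= scale


def train(
    model: EnhancerModel,
    pairs: Sequence[SpectrumPair],
    config: TrainConfig = TrainConfig(),
) -> tuple[EnhancerModel, dict]:
    """Train the enhancer on (degraded, reference) pairs with Adam.

    Returns ``(trained_model, history)`` where ``history`` holds per-epoch
    training and validation loss.  Deterministic given (model, pairs, config).
    """
    if len(pairs) == 0:
        raise DataError("cannot train on an empty pair list")
    x, y = _pairs_to_arrays(pairs)
    rng = np.random.default_rng(config.seed)
    n = len(pairs)
    perm = rng.permutation(n)
    n_val = int(round(config.validation_fraction * n))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if train_idx.size == 0:
        raise DataError("validation_fraction leaves no training pairs")

    # Adam state
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m_state = [(np.zeros_like(w), np.zeros_like(b)) for w, b in model.weights]
    v_state = [(np.zeros_like(w), np.zeros_like(b)) for w, b in model.weights]
    weights = [(w.copy(), b.copy()) for w, b in model.weights]
    model = EnhancerModel(model.spec, weights, dict(model.training_fingerprint))

    history: dict = {"train_loss": [], "val_loss": []}
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        epoch_losses = []
        for start in range(0, order.size, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = _loss_and_grad(
                model, x[idx], y[idx], config.loss_domain
            )
            if not np.isfinite(loss):
                raise TrainingDivergenceError(
                    f"non-finite training loss at epoch {epoch}"
                )
            epoch_losses.append(loss)
            _clip_gradients(grads, config.gradient_clip_norm)
            step += 1
            lr_t = config.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for li, ((w, b), (dw, db)) in enumerate(zip(model.weights, grads)):
                mw, mb = m_state[li]
                vw, vb = v_state[li]
                mw += (1 - beta1) * (dw - mw)
                mb += (1 - beta1) * (db - mb)
                vw += (1 - beta2) * (dw * dw - vw)
                vb += (1 - beta2) * (db * db - vb)
                w -= np.float32(lr_t) * mw / (np.sqrt(vw) + eps)
                b -= np.float32(lr_t) * mb / (np.sqrt(vb) + eps)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if val_idx.size:
            vout = forward(model, x[val_idx])
            vloss = float(np.mean((vout - y[val_idx]) ** 2))
            if not np.isfinite(vloss):
                raise TrainingDivergenceError(
                    f"non-finite validation loss at epoch {epoch}"
                )
            history["val_loss"].append(vloss)

    model.training_fingerprint = {
        **model.training_fingerprint,
        "seed": config.seed,
        "epochs": config.epochs,
        "n_pairs": n,
        "final_train_loss": history["train_loss"][-1] if history["train_loss"] else None,
        "final_val_loss": history["val_loss"][-1] if history["val_loss"] else None,
    }
    return model, history


# ---------------------------------------------------------------------------
# persistence: npz archive with a JSON spec block and binary weight arrays

def save_model(model: EnhancerModel, path: str | Path) -> None:
    arrays = {
        "format_version": np.array(MODEL_FORMAT_VERSION),
        "spec_json": np.array(json.dumps(asdict(model.spec))),
        "fingerprint_json": np.array(json.dumps(model.training_fingerprint)),
    }
    for i, (w, b) in enumerate(model.weights):
        arrays[f"w{i}"] = w
        arrays[f"b{i}"] = b
    np.savez(path, **arrays)


def load_model(path: str | Path) -> EnhancerModel:
    with np.load(path, allow_pickle=False) as npz:
        version = int(npz["format_version"])
        if version != MODEL_FORMAT_VERSION:
            raise ModelCompatibilityError(
                f"model format version {version} != {MODEL_FORMAT_VERSION}"
            )
        spec = EnhancerSpec(**json.loads(str(npz["spec_json"])))
        fingerprint = json.loads(str(npz["fingerprint_json"]))
        weights = []
        for i in range(spec.n_layers):
            key_w, key_b = f"w{i}", f"b{i}"
            if key_w not in npz or key_b not in npz:
                raise ModelCompatibilityError(f"missing weights for layer {i}")
            weights.append(
                (npz[key_w].astype(np.float32), npz[key_b].astype(np.float32))
            )
    return EnhancerModel(spec, weights, fingerprint)
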