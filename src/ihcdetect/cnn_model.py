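"""Two-class patch CNN and dense likelihood-map inference, on numpy.

The classifier is a small convolutional network — six 3×3 convolutions
(valid padding, ReLU), 2×2 max pools after the 2nd and 4th convolution,
and two fully connected layers ending in a 2-way softmax — trained with
plain stochastic gradient descent plus Nesterov momentum (lr 0.01,
momentum 0.9, one pass over the data by default).  Forward, backward and
the optimizer are implemented directly on numpy arrays; convolutions are
evaluated as kernel-offset shifted matrix products, which keeps both
training batches and whole-image inference on the BLAS fast path without
im2col buffers.

Dense inference produces a per-pixel posterior map: the value at (y, x)
is the positive-class probability of the 46×46 window centered there.
Because the two stride-2 pools give the stacked network an output stride
of 4, a true stride-1 map is assembled by the shift-and-stitch scheme:
the network runs on the 16 (dy, dx) ∈ {0..3}² croppings of the image and
the 16 stride-4 outputs interleave into the full-resolution map.  Each
map value is algebraically identical to classifying its window alone,
which is the module's central correctness contract (checked against a
naive sliding-window oracle in the tests).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .imaging_io import ImageMetadata, RGBImage, Tile, stitch_tiles, tile_image
from .patch_pipeline import PATCH_HALF, PATCH_SIZE, LabeledPatch, patches_to_arrays


class UntrainedModelError(RuntimeError):
    """Raised when inference is requested from a model that was never trained."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CNNConfig:
    """Architecture of the patch classifier.

    ``conv_channels`` gives the output channels of the six 3×3
    convolutions; ``pool_after`` the (1-based) convolution indices
    followed by a 2×2 max pool; ``fc_sizes`` the two fully connected
    widths, the last of which must be 2 (softmax over negative/positive).
    The default stack maps a 46×46 patch to a 4×4 feature map:
    46 →44→42 →pool 21 →19→17 →pool 8 →6→4.
    """

    input_size: int = PATCH_SIZE
    conv_channels: tuple[int, ...] = (32, 32, 64, 64, 128, 128)
    kernel_size: int = 3
    pool_after: tuple[int, ...] = (2, 4)
    fc_sizes: tuple[int, ...] = (256, 2)

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 6:
            raise ValueError("exactly six convolutional layers are required")
        if len(self.pool_after) != 2:
            raise ValueError("exactly two pooling layers are required")
        if len(self.fc_sizes) != 2:
            raise ValueError("exactly two fully connected layers are required")
        if self.fc_sizes[-1] != 2:
            raise ValueError("final layer width must be 2 (two classes)")
        if any(c < 1 for c in self.conv_channels) or any(
            w < 1 for w in self.fc_sizes
        ):
            raise ValueError("layer widths must be ≥ 1")
        if not all(1 <= p <= 6 for p in self.pool_after) or len(
            set(self.pool_after)
        ) != 2:
            raise ValueError("pool_after must be two distinct indices in 1..6")
        if self.feature_size() < 1:
            raise ValueError(
                f"receptive field exceeds the {self.input_size}-px input: "
                f"the conv/pool stack consumes the whole patch"
            )

    def feature_size(self) -> int:
        """Spatial size of the conv-stack output for a full patch input."""
        s = self.input_size
        for i in range(1, 7):
            s -= self.kernel_size - 1
            if i in self.pool_after:
                s //= 2
        return s


@dataclass(frozen=True)
class TrainingConfig:
    """SGD settings: lr 0.01, Nesterov momentum 0.9, one epoch by default."""

    learning_rate: float = 0.01
    nesterov_momentum: float = 0.9
    epochs: int = 1
    batch_size: int = 256
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be ≥ 0")
        if not 0 <= self.nesterov_momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be ≥ 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be ≥ 1")


@dataclass
class LikelihoodMap:
    """Per-pixel posterior probability of 'positive cell', in [0, 1]."""

    values: np.ndarray
    metadata: ImageMetadata

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("likelihood map must be 2-D")
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError("likelihood values must lie in [0, 1]")
        self.values = v


@dataclass
class TrainingHistory:
    step_losses: list[float] = field(default_factory=list)
    epoch_mean_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# layer primitives (batch-last-channel layout: N, H, W, C)
# ---------------------------------------------------------------------------


#: Row budget per matmul block; keeps the shifted-slice copies and the
#: GEMM working set inside cache (large monolithic slabs run ~4× slower).
_ROW_BLOCK = 60_000


def _conv2d_block(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid cross-correlation via kernel-offset shifted matmuls (one block)."""
    N, H, Wd, Ci = x.shape
    kh, kw, _, Co = W.shape
    h, w = H - kh + 1, Wd - kw + 1
    out = np.empty((N, h, w, Co), dtype=x.dtype)
    out[:] = b
    acc = out.reshape(-1, Co)
    for di in range(kh):
        for dj in range(kw):
            patch = np.ascontiguousarray(x[:, di : di + h, dj : dj + w, :])
            acc += patch.reshape(-1, Ci) @ W[di, dj]
    return out


def _conv2d(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid cross-correlation, blocked over batch and image rows.

    Blocking only partitions output rows; every output element is still
    produced by a single matmul reduction, so results are identical to
    the unblocked computation.
    """
    N, H, Wd, Ci = x.shape
    kh, kw, _, Co = W.shape
    h, w = H - kh + 1, Wd - kw + 1
    rows_per_item = h * w
    if N * rows_per_item <= _ROW_BLOCK:
        return _conv2d_block(x, W, b)
    out = np.empty((N, h, w, Co), dtype=x.dtype)
    if N > 1:
        nb = max(1, _ROW_BLOCK // max(1, rows_per_item))
        for i in range(0, N, nb):
            out[i : i + nb] = _conv2d(x[i : i + nb], W, b)
        return out
    hb = max(1, _ROW_BLOCK // max(1, w))
    for i0 in range(0, h, hb):
        i1 = min(h, i0 + hb)
        out[:, i0:i1] = _conv2d_block(x[:, i0 : i1 + kh - 1], W, b)
    return out


def _conv2d_dw(x: np.ndarray, W_shape: tuple, dout: np.ndarray) -> np.ndarray:
    """Weight gradient of the valid cross-correlation, blocked like _conv2d."""
    N, H, Wd, Ci = x.shape
    kh, kw, _, Co = W_shape
    h, w = dout.shape[1], dout.shape[2]
    dW = np.zeros(W_shape, dtype=dout.dtype)
    rows_per_item = h * w
    nb = max(1, _ROW_BLOCK // max(1, rows_per_item))
    for i in range(0, N, nb):
        xs, ds = x[i : i + nb], dout[i : i + nb]
        dflat = ds.reshape(-1, Co)
        for di in range(kh):
            for dj in range(kw):
                patch = np.ascontiguousarray(xs[:, di : di + h, dj : dj + w, :])
                dW[di, dj] += patch.reshape(-1, Ci).T @ dflat
    return dW


def _conv2d_backward(
    x: np.ndarray, W: np.ndarray, dout: np.ndarray, need_dx: bool = True
) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    """Gradients of :func:`_conv2d` w.r.t. input, weights and bias."""
    N, H, Wd, Ci = x.shape
    kh, kw, _, Co = W.shape
    h, w = dout.shape[1], dout.shape[2]
    dW = _conv2d_dw(x, W.shape, dout)
    db = dout.sum(axis=(0, 1, 2))
    if not need_dx:
        return None, dW, db
    # dx = full correlation of dout with the flipped, channel-swapped kernel
    pad = np.zeros((N, h + 2 * (kh - 1), w + 2 * (kw - 1), Co), dtype=dout.dtype)
    pad[:, kh - 1 : kh - 1 + h, kw - 1 : kw - 1 + w, :] = dout
    Wflip = np.ascontiguousarray(W[::-1, ::-1].transpose(0, 1, 3, 2))
    dx = _conv2d(pad, Wflip, np.zeros(Ci, dtype=dout.dtype))
    return dx, dW, db


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple[int, ...]]:
    """2×2/stride-2 max pool; odd trailing rows/cols are dropped."""
    N, H, W, C = x.shape
    H2, W2 = H // 2, W // 2
    xr = (
        x[:, : 2 * H2, : 2 * W2, :]
        .reshape(N, H2, 2, W2, 2, C)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(N, H2, W2, 4, C)
    )
    idx = xr.argmax(axis=3)
    out = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, idx, x.shape


def _maxpool2_backward(
    dout: np.ndarray, idx: np.ndarray, x_shape: tuple[int, ...]
) -> np.ndarray:
    N, H, W, C = x_shape
    H2, W2 = H // 2, W // 2
    dxr = np.zeros((N, H2, W2, 4, C), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, : 2 * H2, : 2 * W2, :] = (
        dxr.reshape(N, H2, W2, 2, 2, C)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(N, 2 * H2, 2 * W2, C)
    )
    return dx


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class PatchCNN:
    """The patch classifier: parameters, forward/backward, persistence.

    Both fully connected layers are stored as convolution kernels (the
    first spans the full conv-stack output, the second is 1×1), so the
    identical forward code serves 46×46 patches and whole images.
    """

    def __init__(self, config: CNNConfig, params: dict[str, np.ndarray]):
        self.config = config
        self.params = params
        self.trained = False

    # -- construction ------------------------------------------------------

    @classmethod
    def build(cls, config: CNNConfig = CNNConfig(), seed: int = 0) -> "PatchCNN":
        rng = np.random.default_rng(seed)
        params: dict[str, np.ndarray] = {}
        k = config.kernel_size
        cin = 3
        for i, cout in enumerate(config.conv_channels, start=1):
            fan_in = k * k * cin
            params[f"conv{i}_W"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(k, k, cin, cout)
            ).astype(np.float32)
            params[f"conv{i}_b"] = np.zeros(cout, dtype=np.float32)
            cin = cout
        s = config.feature_size()
        fc1, fc2 = config.fc_sizes
        params["fc1_W"] = rng.normal(
            0.0, np.sqrt(2.0 / (s * s * cin)), size=(s, s, cin, fc1)
        ).astype(np.float32)
        params["fc1_b"] = np.zeros(fc1, dtype=np.float32)
        params["fc2_W"] = rng.normal(
            0.0, np.sqrt(1.0 / fc1), size=(1, 1, fc1, fc2)
        ).astype(np.float32)
        params["fc2_b"] = np.zeros(fc2, dtype=np.float32)
        return cls(config, params)

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def _param_names(self) -> list[str]:
        return [f"conv{i}_{s}" for i in range(1, 7) for s in ("W", "b")] + [
            "fc1_W", "fc1_b", "fc2_W", "fc2_b",
        ]

    # -- forward -----------------------------------------------------------

    def forward_logits(
        self, x: np.ndarray, want_cache: bool = False
    ) -> tuple[np.ndarray, list]:
        """Logit maps for a (N, H, W, 3) float input scaled to [0, 1].

        For H = W = 46 the output is (N, 1, 1, 2); larger inputs yield
        stride-4 logit maps (one entry per aligned 46×46 window).
        """
        cfg = self.config
        dtype = x.dtype
        cache: list = []
        h = x
        for i in range(1, 7):
            W = self.params[f"conv{i}_W"].astype(dtype, copy=False)
            b = self.params[f"conv{i}_b"].astype(dtype, copy=False)
            pre = _conv2d(h, W, b)
            post = np.maximum(pre, 0)
            if want_cache:
                cache.append(("conv", i, h, pre))
            h = post
            if i in cfg.pool_after:
                pooled, idx, shape = _maxpool2(h)
                if want_cache:
                    cache.append(("pool", i, idx, shape))
                h = pooled
        W = self.params["fc1_W"].astype(dtype, copy=False)
        b = self.params["fc1_b"].astype(dtype, copy=False)
        pre = _conv2d(h, W, b)
        if want_cache:
            cache.append(("fc1", 0, h, pre))
        h = np.maximum(pre, 0)
        W = self.params["fc2_W"].astype(dtype, copy=False)
        b = self.params["fc2_b"].astype(dtype, copy=False)
        logits = _conv2d(h, W, b)
        if want_cache:
            cache.append(("fc2", 0, h, None))
        return logits, cache

    def forward_probs(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities (N, 2) for a batch of 46×46 patches."""
        if x.shape[1:3] != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(
                f"expected {PATCH_SIZE}×{PATCH_SIZE} patches, got {x.shape[1:3]}"
            )
        logits, _ = self.forward_logits(x)
        return _softmax(logits[:, 0, 0, :])

    # -- backward ----------------------------------------------------------

    def backward(
        self, cache: list, dlogits: np.ndarray
    ) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        d = dlogits
        for entry in reversed(cache):
            kind, i = entry[0], entry[1]
            if kind == "fc2":
                h_in = entry[2]
                dx, dW, db = _conv2d_backward(
                    h_in, self.params["fc2_W"].astype(d.dtype), d
                )
                grads["fc2_W"], grads["fc2_b"] = dW, db
                d = dx
            elif kind == "fc1":
                h_in, pre = entry[2], entry[3]
                d = d * (pre > 0)
                dx, dW, db = _conv2d_backward(
                    h_in, self.params["fc1_W"].astype(d.dtype), d
                )
                grads["fc1_W"], grads["fc1_b"] = dW, db
                d = dx
            elif kind == "pool":
                idx, shape = entry[2], entry[3]
                d = _maxpool2_backward(d, idx, shape)
            else:  # conv
                h_in, pre = entry[2], entry[3]
                d = d * (pre > 0)
                dx, dW, db = _conv2d_backward(
                    h_in, self.params[f"conv{i}_W"].astype(d.dtype), d,
                    need_dx=(i != 1),  # no gradient needed w.r.t. the input image
                )
                grads[f"conv{i}_W"], grads[f"conv{i}_b"] = dW, db
                d = dx
        return grads

    def predict_likelihood_map(self, image: RGBImage, **kwargs) -> "LikelihoodMap":
        """Dense per-pixel inference; see :func:`predict_likelihood_map`."""
        return predict_likelihood_map(self, image, **kwargs)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Self-describing checkpoint: JSON config + parameter tensors."""
        path = Path(path)
        cfg = {
            "input_size": self.config.input_size,
            "conv_channels": list(self.config.conv_channels),
            "kernel_size": self.config.kernel_size,
            "pool_after": list(self.config.pool_after),
            "fc_sizes": list(self.config.fc_sizes),
            "trained": self.trained,
        }
        np.savez_compressed(
            path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PatchCNN":
        with np.load(Path(path)) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            params = {k: data[k] for k in data.files if k != "__config__"}
        model = cls(
            CNNConfig(
                input_size=cfg["input_size"],
                conv_channels=tuple(cfg["conv_channels"]),
                kernel_size=cfg["kernel_size"],
                pool_after=tuple(cfg["pool_after"]),
                fc_sizes=tuple(cfg["fc_sizes"]),
            ),
            params,
        )
        model.trained = bool(cfg.get("trained", False))
        return model


def build_model(config: CNNConfig = CNNConfig(), seed: int = 0) -> PatchCNN:
    """Deterministically initialized, untrained patch classifier."""
    return PatchCNN.build(config, seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _as_float32(X: np.ndarray) -> np.ndarray:
    return X.astype(np.float32) / np.float32(255.0)


def train(
    model: PatchCNN,
    patches: Sequence[LabeledPatch],
    tc: TrainingConfig = TrainingConfig(),
    val_patches: Sequence[LabeledPatch] | None = None,
) -> TrainingHistory:
    """SGD with Nesterov momentum on softmax cross-entropy.

    Performs exactly ``tc.epochs`` passes over the (shuffled) patches.
    The update follows the velocity form
    ``v ← µ·v − η·∇;  θ ← θ + µ·v − η·∇``.
    Validation accuracy is logged after each epoch when ``val_patches``
    is given.  Raises on single-class data and aborts on non-finite
    loss.
    """
    X, y = patches_to_arrays(patches)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    Xf = _as_float32(X)
    rng = np.random.default_rng(tc.seed)
    mu = np.float32(tc.nesterov_momentum)
    lr = np.float32(tc.learning_rate)
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    history = TrainingHistory()
    n = len(y)
    for epoch in range(tc.epochs):
        order = rng.permutation(n) if tc.shuffle else np.arange(n)
        epoch_losses = []
        for start in range(0, n, tc.batch_size):
            sel = order[start : start + tc.batch_size]
            xb, yb = Xf[sel], y[sel]
            logits, cache = model.forward_logits(xb, want_cache=True)
            probs = _softmax(logits[:, 0, 0, :])
            eps = np.float32(1e-12)
            loss = float(
                -np.log(probs[np.arange(len(yb)), yb] + eps).mean()
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} step {start // tc.batch_size}"
                    f" (lr={tc.learning_rate}); training aborted"
                )
            history.step_losses.append(loss)
            epoch_losses.append(loss)
            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= np.float32(len(yb))
            grads = model.backward(cache, dlogits[:, None, None, :])
            for k, p in model.params.items():
                g = grads[k].astype(np.float32, copy=False)
                v = velocity[k]
                v *= mu
                v -= lr * g
                p += mu * v - lr * g
        history.epoch_mean_loss.append(float(np.mean(epoch_losses)))
        if val_patches:
            acc = float(
                np.mean(
                    (classify_patches(model, val_patches, _allow_untrained=True)
                     >= 0.5)
                    == (patches_to_arrays(val_patches)[1] == 1)
                )
            )
            history.val_accuracy.append(acc)
    model.trained = True
    return history


def classify_patches(
    model: PatchCNN,
    patches: Sequence[LabeledPatch] | np.ndarray,
    batch_size: int = 512,
    _allow_untrained: bool = False,
) -> np.ndarray:
    """Positive-class probability for each 46×46 patch."""
    if not model.trained and not _allow_untrained:
        raise UntrainedModelError("classify_patches requires a trained model")
    if isinstance(patches, np.ndarray):
        X = patches
    else:
        X, _ = patches_to_arrays(patches)
    if X.shape[1:] != (PATCH_SIZE, PATCH_SIZE, 3):
        raise ValueError(
            f"expected (N, {PATCH_SIZE}, {PATCH_SIZE}, 3) patches, got {X.shape}"
        )
    Xf = _as_float32(X) if X.dtype == np.uint8 else X.astype(np.float32)
    out = np.empty(len(Xf), dtype=np.float64)
    for start in range(0, len(Xf), batch_size):
        probs = model.forward_probs(Xf[start : start + batch_size])
        out[start : start + len(probs)] = probs[:, 1]
    return out


# ---------------------------------------------------------------------------
# dense likelihood inference
# ---------------------------------------------------------------------------

_OUTPUT_STRIDE = 4  # product of the two stride-2 pools
_SAFETY_PAD = 8  # keeps floor-division pooling from dropping needed windows


def _dense_map_single(model: PatchCNN, pixels: np.ndarray,
                      dtype: np.dtype) -> np.ndarray:
    """Stride-1 positive-class map for one uint8 H×W×3 array."""
    H, W = pixels.shape[:2]
    x = pixels.astype(dtype) / dtype.type(255.0)
    out = np.zeros((H, W), dtype=np.float64)
    for sy in range(_OUTPUT_STRIDE):
        ky = (H - PATCH_SIZE - sy) // _OUTPUT_STRIDE
        if H - PATCH_SIZE - sy < 0:
            continue
        for sx in range(_OUTPUT_STRIDE):
            kx = (W - PATCH_SIZE - sx) // _OUTPUT_STRIDE
            if W - PATCH_SIZE - sx < 0:
                continue
            sub = x[sy:, sx:, :]
            h_s, w_s = sub.shape[:2]
            padded = np.zeros(
                (h_s + _SAFETY_PAD, w_s + _SAFETY_PAD, 3), dtype=dtype
            )
            padded[:h_s, :w_s] = sub
            logits, _ = model.forward_logits(padded[None])
            probs = _softmax(logits[0])[:, :, 1]
            req_h, req_w = ky + 1, kx + 1
            out[
                sy + PATCH_HALF : sy + PATCH_HALF + _OUTPUT_STRIDE * req_h : _OUTPUT_STRIDE,
                sx + PATCH_HALF : sx + PATCH_HALF + _OUTPUT_STRIDE * req_w : _OUTPUT_STRIDE,
            ] = probs[:req_h, :req_w]
    return out


def predict_likelihood_map(
    model: PatchCNN,
    image: RGBImage,
    tile: int | None = None,
    halo: int = PATCH_HALF,
    dtype: type = np.float64,
) -> LikelihoodMap:
    """Per-pixel positive-cell posterior for a whole image.

    The value at (y, x) equals the classifier's positive probability for
    the 46×46 window centered there; the 23-px border band, where no
    full window fits, is 0.  With ``tile`` set, the image is processed
    tile-wise (halo ≥ 23 guarantees tiling changes no value) so
    arbitrarily large images fit in memory.  Inference runs in float64
    by default so whole-image, tiled and per-window evaluation agree to
    numerical precision.
    """
    if not model.trained:
        raise UntrainedModelError("predict_likelihood_map requires a trained model")
    H, W = image.height, image.width
    if H < PATCH_SIZE or W < PATCH_SIZE:
        raise ValueError(
            f"image {H}×{W} smaller than the {PATCH_SIZE}-px patch"
        )
    dt = np.dtype(dtype)
    if tile is None:
        values = _dense_map_single(model, image.pixels, dt)
    else:
        if halo < PATCH_HALF:
            raise ValueError(f"halo must be ≥ {PATCH_HALF} for exact tiling")
        tiles = tile_image(image.pixels, tile, halo)
        out_tiles = []
        for t in tiles:
            th, tw = t.pixels.shape[:2]
            if th >= PATCH_SIZE and tw >= PATCH_SIZE:
                tv = _dense_map_single(model, t.pixels, dt)
            else:
                tv = np.zeros((th, tw), dtype=np.float64)
            out_tiles.append(Tile(pixels=tv, offset=t.offset, core=t.core))
        values = stitch_tiles(out_tiles, shape=(H, W))
    return LikelihoodMap(values=values, metadata=image.metadata)


__all__ = [
    "CNNConfig",
    "TrainingConfig",
    "LikelihoodMap",
    "TrainingHistory",
    "PatchCNN",
    "UntrainedModelError",
    "build_model",
    "train",
    "classify_patches",
    "predict_likelihood_map",
]
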