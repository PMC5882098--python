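"""A compact fully-convolutional classifier for 64x64 H&E patches.

The network alternates valid 3x3 convolutions, batch normalization, ReLU and
2x2 max-pooling, and ends in a small convolutional head to 2 channels, so it
has no fixed-size dense layer: applied to a whole ROI it emits a dense map of
failing-class probabilities (one value per 8-px stride), and applied to a
single 64x64 patch it emits exactly one.  The reference layout has 13,306
learnable parameters.

Layers, backpropagation and SGD are implemented directly on numpy arrays
(im2col convolutions backed by BLAS matrix products), in float32.  Training
is deterministic for fixed seeds under single-threaded BLAS.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import (
    DegenerateInputError,
    InvalidArchitectureError,
    InvalidArgumentError,
    InvalidDataError,
)
from .patching import PatchSet
from .slide_prep import RegionOfInterest
from .synthetic_data import is_failing_label

__all__ = [
    "StageSpec",
    "ArchitectureSpec",
    "REFERENCE_ARCHITECTURE",
    "TrainingConfig",
    "ProbabilityMap",
    "FullyConvNet",
    "build_model",
    "count_parameters",
    "train",
    "predict_probability_map",
    "image_probability",
]

# input normalization applied to 8-bit pixels before the first convolution
_NORM_OFFSET = 0.5
_NORM_SCALE = 0.25


@dataclass(frozen=True)
class StageSpec:
    kernel_px: int
    out_channels: int
    batch_norm: bool = True
    activation: bool = True
    pool: bool = False


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative layout of the fully-convolutional network."""

    stages: tuple[StageSpec, ...]
    input_px: int = 64
    input_channels: int = 3
    head_kernel_px: int = 4
    n_classes: int = 2

    def spatial_trace(self, side: int | None = None) -> list[int]:
        """Spatial size after each stage (and the head) for a given input side."""
        s = self.input_px if side is None else side
        trace = [s]
        for st in self.stages:
            s = s - st.kernel_px + 1
            if st.pool:
                s //= 2
            trace.append(s)
            if s < 1:
                raise InvalidArchitectureError("stage list collapses spatial dims to zero")
        s = s - self.head_kernel_px + 1
        trace.append(s)
        if s < 1:
            raise InvalidArchitectureError("head kernel larger than remaining spatial dims")
        return trace

    @property
    def downsample_factor(self) -> int:
        return 2 ** sum(1 for st in self.stages if st.pool)

    def parameter_count(self) -> int:
        """Closed-form learnable parameter count.

        Convolutions followed by batch norm are bias-free; BN contributes a
        scale and shift per channel (running statistics are not learnable);
        the head convolution carries a bias.
        """
        total = 0
        cin = self.input_channels
        for st in self.stages:
            total += st.kernel_px**2 * cin * st.out_channels
            total += 2 * st.out_channels if st.batch_norm else st.out_channels
            cin = st.out_channels
        total += self.head_kernel_px**2 * cin * self.n_classes + self.n_classes
        return total


#: reference layout: 64x64x3 -> [3x3 conv16,BN,ReLU,pool] x2 -> [3x3 conv24,BN,ReLU,pool]
#: -> [3x3 conv28,BN,ReLU] -> 4x4 conv to 2 + bias -> softmax; 13,306 parameters,
#: natural stride 8, and a 64x64 input maps to exactly one output location
REFERENCE_ARCHITECTURE = ArchitectureSpec(
    stages=(
        StageSpec(3, 16, pool=True),
        StageSpec(3, 16, pool=True),
        StageSpec(3, 24, pool=True),
        StageSpec(3, 28, pool=False),
    )
)


@dataclass
class TrainingConfig:
    epochs: int = 30
    batch_size: int = 64
    optimizer: str = "sgd"
    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 5e-4
    lr_step_epoch: int = 20  # learning rate x0.1 from this epoch on
    lr_step_factor: float = 0.1
    rng_seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise InvalidArgumentError("epochs and batch_size must be >= 1")
        if self.optimizer != "sgd":
            raise InvalidArgumentError("only the sgd optimizer is supported")


@dataclass
class ProbabilityMap:
    """Dense failing-class probabilities over one ROI."""

    values: np.ndarray
    downsample_factor: int
    roi_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)


# ---------------------------------------------------------------------------
# layers


class _Conv2d:
    """Valid convolution on NHWC activations.

    Computed as k*k shifted GEMM accumulations (one matrix product per kernel
    offset over the full input, added into the output at the offset): this
    keeps every memory access in long contiguous runs, which on a single CPU
    core beats an explicit im2col for these small channel counts.
    """

    def __init__(self, cin: int, cout: int, k: int, bias: bool, rng: np.random.Generator):
        std = np.sqrt(2.0 / (k * k * cin))
        self.W = rng.normal(0.0, std, (cout, cin, k, k)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32) if bias else None
        self.k = k
        self.first = False  # first layer skips input-gradient computation
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        k = self.k
        ho, wo = h - k + 1, w - k + 1
        cout = self.W.shape[0]
        xflat = x.reshape(-1, c)
        out = np.zeros((n, ho, wo, cout), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                y = (xflat @ self.W[:, :, ki, kj].T).reshape(n, h, w, cout)
                out += y[:, ki : ki + ho, kj : kj + wo, :]
        if self.b is not None:
            out += self.b
        if train:
            self._cache = x
        return out

    def backward(self, d: np.ndarray) -> np.ndarray | None:
        x = self._cache
        self._cache = None
        n, ho, wo, cout = d.shape
        k = self.k
        c = x.shape[3]
        dmat = d.reshape(-1, cout)
        if self.b is not None:
            self.gb = dmat.sum(axis=0)
        gW = np.empty_like(self.W)
        dx = None if self.first else np.zeros(x.shape, dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                xs = np.ascontiguousarray(x[:, ki : ki + ho, kj : kj + wo, :]).reshape(-1, c)
                gW[:, :, ki, kj] = dmat.T @ xs
                if dx is not None:
                    dx[:, ki : ki + ho, kj : kj + wo, :] += (dmat @ self.W[:, :, ki, kj]).reshape(
                        n, ho, wo, c
                    )
        self.gW = gW
        return dx

    def params(self):
        yield "W", self.W, self.gW
        if self.b is not None:
            yield "b", self.b, self.gb


class _BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.ggamma = np.zeros(c, dtype=np.float32)
        self.gbeta = np.zeros(c, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        c = x.shape[-1]
        if train:
            flat = x.reshape(-1, c)
            m = flat.shape[0]
            mean = flat.mean(axis=0)
            sq = np.einsum("ij,ij->j", flat, flat) / m
            var = np.maximum(sq - mean * mean, 0.0)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        mean = mean.astype(np.float32)
        a = self.gamma * ivar
        b = self.beta - mean * a
        out = x * a
        out += b
        if train:
            self._cache = (x, mean, ivar)
        return out

    def backward(self, d: np.ndarray) -> np.ndarray:
        x, mean, ivar = self._cache
        self._cache = None
        c = d.shape[-1]
        m = d.size // c
        xhat = x - mean
        xhat *= ivar
        dflat = d.reshape(-1, c)
        dsum = dflat.sum(axis=0).astype(np.float32)
        dxhat_sum = np.einsum("ij,ij->j", dflat, xhat.reshape(-1, c)).astype(np.float32)
        self.ggamma = dxhat_sum
        self.gbeta = dsum
        coef = (self.gamma * ivar / m).astype(np.float32)
        # in-place: d <- coef * (m*d - dsum - xhat*dxhat_sum); d and xhat are
        # no longer needed by the caller at this point in backprop
        d *= np.float32(m)
        d -= dsum
        xhat *= dxhat_sum
        d -= xhat
        d *= coef
        return d

    def params(self):
        yield "gamma", self.gamma, self.ggamma
        yield "beta", self.beta, self.gbeta


class _ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, d: np.ndarray) -> np.ndarray:
        d *= self._mask
        self._mask = None
        return d

    def params(self):
        return iter(())


class _MaxPool2d:
    """2x2 max pooling on NHWC; the backward pass routes the gradient to the
    first maximum of each window (deterministic subgradient on ties)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        quads = (x[:, 0::2, 0::2, :], x[:, 0::2, 1::2, :], x[:, 1::2, 0::2, :], x[:, 1::2, 1::2, :])
        ho = min(q.shape[1] for q in quads)
        wo = min(q.shape[2] for q in quads)
        quads = tuple(q[:, :ho, :wo, :] for q in quads)
        best = np.ascontiguousarray(quads[0])
        if train:
            idx = np.zeros(best.shape, dtype=np.uint8)
            for t, q in enumerate(quads[1:], start=1):
                m = q > best
                np.copyto(best, q, where=m)
                idx[m] = t
            self._cache = (idx, x.shape)
        else:
            for q in quads[1:]:
                np.maximum(best, q, out=best)
        return best

    def backward(self, d: np.ndarray) -> np.ndarray:
        idx, xshape = self._cache
        self._cache = None
        n, ho, wo, c = d.shape
        dx = np.zeros(xshape, dtype=np.float32)
        views = (dx[:, 0::2, 0::2, :], dx[:, 0::2, 1::2, :], dx[:, 1::2, 0::2, :], dx[:, 1::2, 1::2, :])
        for t, v in enumerate(views):
            np.copyto(v[:, :ho, :wo, :], d, where=(idx == t))
        return dx

    def params(self):
        return iter(())


# ---------------------------------------------------------------------------
# model


class FullyConvNet:
    """Sequential fully-convolutional network built from an ArchitectureSpec."""

    def __init__(self, spec: ArchitectureSpec, rng_seed: int = 0):
        spec.spatial_trace()  # validates the layout
        self.spec = spec
        rng = np.random.default_rng(rng_seed)
        self.layers: list = []
        cin = spec.input_channels
        for st in spec.stages:
            conv = _Conv2d(cin, st.out_channels, st.kernel_px, bias=not st.batch_norm, rng=rng)
            self.layers.append(conv)
            if st.batch_norm:
                self.layers.append(_BatchNorm2d(st.out_channels))
            if st.activation:
                self.layers.append(_ReLU())
            if st.pool:
                self.layers.append(_MaxPool2d())
            cin = st.out_channels
        self.layers.append(_Conv2d(cin, spec.n_classes, spec.head_kernel_px, bias=True, rng=rng))
        self.layers[0].first = True

    # -- plumbing -----------------------------------------------------------
    def parameters(self):
        for i, layer in enumerate(self.layers):
            for name, arr, grad in layer.params():
                yield f"layer{i}.{name}", arr, grad

    @property
    def n_parameters(self) -> int:
        return sum(arr.size for _, arr, _ in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: arr.copy() for name, arr, _ in self.parameters()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, _BatchNorm2d):
                state[f"layer{i}.running_mean"] = layer.running_mean.copy()
                state[f"layer{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, arr, _ in self.parameters():
            arr[...] = state[name]
        for i, layer in enumerate(self.layers):
            if isinstance(layer, _BatchNorm2d):
                layer.running_mean[...] = state[f"layer{i}.running_mean"]
                layer.running_var[...] = state[f"layer{i}.running_var"]

    def save(self, path) -> None:
        """Single checkpoint file with an embedded, versioned architecture header."""
        header = json.dumps({"format": 1, "spec": asdict(self.spec)})
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **self.state_dict())

    @classmethod
    def load(cls, path) -> "FullyConvNet":
        with np.load(path) as z:
            header = json.loads(bytes(z["__header__"]).decode())
            spec_d = header["spec"]
            spec = ArchitectureSpec(
                stages=tuple(StageSpec(**st) for st in spec_d.pop("stages")), **spec_d
            )
            model = cls(spec)
            model.load_state_dict({k: z[k] for k in z.files if k != "__header__"})
        return model

    # -- compute ------------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, d: np.ndarray) -> None:
        for layer in reversed(self.layers):
            d = layer.backward(d)


def normalize_patches(pixels_u8: np.ndarray) -> np.ndarray:
    """uint8 (N,H,W,3) -> float32 NHWC normalized network input."""
    x = pixels_u8.astype(np.float32)
    x *= 1.0 / (255.0 * _NORM_SCALE)
    x -= _NORM_OFFSET / _NORM_SCALE
    return x


def build_model(spec: ArchitectureSpec = REFERENCE_ARCHITECTURE, rng_seed: int = 0) -> FullyConvNet:
    """Instantiate a seeded model (He-normal convolution init, BN at identity)."""
    return FullyConvNet(spec, rng_seed=rng_seed)


def count_parameters(model: FullyConvNet) -> int:
    """Total learnable scalars (conv weights/biases, BN scale/shift;
    BN running statistics excluded)."""
    return model.n_parameters


def _labels_to_binary(y: np.ndarray) -> np.ndarray:
    if y.dtype.kind in "iub":
        return y.astype(np.int64)
    return np.array([1 if is_failing_label(str(v)) else 0 for v in y], dtype=np.int64)


def _softmax_xent(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    m = logits.max(axis=1, keepdims=True)
    z = logits - m
    logsum = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsum
    n = logits.shape[0]
    loss = float(-logp[np.arange(n), y].mean())
    p = np.exp(logp)
    d = p.copy()
    d[np.arange(n), y] -= 1.0
    return loss, d / n, p


def _patchset_to_xy(patches) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(patches, PatchSet):
        x, y = patches.as_arrays()
    else:
        x, y = patches
    return np.asarray(x), _labels_to_binary(np.asarray(y))


def train(
    model: FullyConvNet,
    train_patches,
    val_patches=None,
    config: TrainingConfig | None = None,
) -> tuple[FullyConvNet, list[dict]]:
    """Minimize softmax cross-entropy by mini-batch SGD with momentum.

    ``train_patches``/``val_patches`` are :class:`PatchSet` objects or
    ``(pixels_u8, labels)`` pairs.  Weight decay applies to convolution
    weights only.  When a validation set is given, the weights from the
    best-validation-accuracy epoch are restored at the end; otherwise the
    final weights are kept.  Returns the model and a per-epoch log.
    """
    config = config or TrainingConfig()
    x_u8, y = _patchset_to_xy(train_patches)
    if x_u8.shape[0] == 0:
        raise InvalidDataError("empty training set")
    if x_u8.shape[1] != model.spec.input_px or x_u8.shape[2] != model.spec.input_px:
        raise InvalidArgumentError(
            f"patches are {x_u8.shape[1]}x{x_u8.shape[2]}, expected {model.spec.input_px}"
        )
    if np.unique(y).size < 2:
        raise InvalidDataError("training set contains a single class")
    val = None
    if val_patches is not None:
        xv, yv = _patchset_to_xy(val_patches)
        val = (normalize_patches(xv), yv)

    rng = np.random.default_rng(config.rng_seed)
    velocity = {name: np.zeros_like(arr) for name, arr, _ in model.parameters()}
    conv_weights = {
        f"layer{i}.W" for i, l in enumerate(model.layers) if isinstance(l, _Conv2d)
    }
    n = x_u8.shape[0]
    log: list[dict] = []
    best_val, best_state = -1.0, None
    for epoch in range(config.epochs):
        lr = config.learning_rate * (
            config.lr_step_factor if epoch >= config.lr_step_epoch else 1.0
        )
        order = rng.permutation(n)
        total_loss, total_correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = normalize_patches(x_u8[idx])
            yb = y[idx]
            logits = model.forward(xb, train=True).reshape(len(idx), -1)
            loss, dlogits, probs = _softmax_xent(logits, yb)
            model.backward(dlogits.reshape(len(idx), 1, 1, model.spec.n_classes))
            for name, arr, grad in model.parameters():
                g = grad
                if config.weight_decay and name in conv_weights:
                    g = g + config.weight_decay * arr
                v = velocity[name]
                v *= config.momentum
                v -= lr * g
                arr += v
            total_loss += loss * len(idx)
            total_correct += int((probs.argmax(axis=1) == yb).sum())
        entry = {
            "epoch": epoch,
            "lr": lr,
            "train_loss": total_loss / n,
            "train_acc": total_correct / n,
        }
        if val is not None:
            vl, va = _evaluate_patches(model, *val, batch_size=config.batch_size)
            entry["val_loss"], entry["val_acc"] = vl, va
            if va > best_val:
                best_val, best_state = va, model.state_dict()
        log.append(entry)
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, log


def _evaluate_patches(model: FullyConvNet, x: np.ndarray, y: np.ndarray, batch_size: int = 256):
    losses, correct = 0.0, 0
    for start in range(0, x.shape[0], batch_size):
        xb, yb = x[start : start + batch_size], y[start : start + batch_size]
        logits = model.forward(xb, train=False).reshape(len(yb), -1)
        loss, _, probs = _softmax_xent(logits, yb)
        losses += loss * len(yb)
        correct += int((probs.argmax(axis=1) == yb).sum())
    return losses / x.shape[0], correct / x.shape[0]


def predict_probability_map(model: FullyConvNet, roi: RegionOfInterest | np.ndarray) -> ProbabilityMap:
    """Apply the network fully-convolutionally over an ROI.

    The map holds, at each location, softmax(channel failing) of the network
    applied to the corresponding 64-px window; locations are spaced by the
    network's natural stride (8 for the reference layout).
    """
    if isinstance(roi, RegionOfInterest):
        pixels, roi_id = roi.pixels, roi.roi_id
    else:
        pixels, roi_id = np.asarray(roi), ""
    if min(pixels.shape[:2]) < model.spec.input_px:
        raise InvalidArgumentError("ROI smaller than the network receptive field")
    x = normalize_patches(pixels[None])
    logits = model.forward(x, train=False)[0]  # (h, w, 2)
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e[..., 1] / e.sum(axis=-1)
    return ProbabilityMap(values=p, downsample_factor=model.spec.downsample_factor, roi_id=roi_id)


def image_probability(pmap: ProbabilityMap) -> float:
    """Image-level probability: the arithmetic mean over all map pixels."""
    if pmap.values.size == 0:
        raise DegenerateInputError("empty probability map")
    return float(pmap.values.mean())


def export_map_tiff(pmap: ProbabilityMap, path) -> None:
    """Write a probability map as a 32-bit float TIFF (one value per
    network stride step)."""
    import tifffile

    tifffile.imwrite(path, pmap.values.astype(np.float32))
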