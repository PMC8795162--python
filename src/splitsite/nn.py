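"""Minimal differentiable layer engine.

Implements exactly the layer vocabulary the split architectures need —
same-padding 2-D convolution, 2x2 max pooling, flatten, dense, and pointwise
activations — as pure-NumPy forward/backward pairs, plus Glorot-uniform
initialization and an Adam optimizer.  Everything is float64 and fully
deterministic given a :class:`numpy.random.Generator`.

The engine is deliberately small: stride-1 same-padding convolutions and
2x2/stride-2 pooling are the only spatial operators the split models use, so
nothing more general is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

VALID_ACTIVATIONS = ("sigmoid", "leaky_relu", "relu", "linear")
VALID_LAYER_KINDS = ("conv2d", "maxpool2d", "flatten", "dense", "activation")

#: negative-side slope of leaky ReLU
LEAKY_SLOPE = 0.01


class ShapeError(ValueError):
    """Raised when tensors do not satisfy a layer's shape contract."""


@dataclass(frozen=True)
class LayerDef:
    """One layer of a stack: a kind plus the parameters relevant to it.

    Only the fields relevant to ``kind`` may be set:

    - ``conv2d``: kernel_size, filters, stride (must be 1), padding ("same")
    - ``maxpool2d``: pool windows are fixed 2x2/stride 2
    - ``dense``: units
    - ``activation``: activation in {sigmoid, leaky_relu, relu, linear}
    - ``flatten``: no parameters
    """

    kind: str
    kernel_size: int | None = None
    filters: int | None = None
    stride: int = 1
    padding: str = "same"
    units: int | None = None
    activation: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}; valid: {VALID_LAYER_KINDS}")
        if self.kind == "conv2d":
            if not (self.kernel_size and self.kernel_size >= 1):
                raise ValueError("conv2d needs kernel_size >= 1")
            if not (self.filters and self.filters >= 1):
                raise ValueError("conv2d needs filters >= 1")
            if self.stride != 1:
                raise ValueError("only stride-1 convolutions are supported")
            if self.padding != "same":
                raise ValueError("only 'same' padding is supported")
        elif self.kind == "dense":
            if not (self.units and self.units >= 1):
                raise ValueError("dense needs units >= 1")
        elif self.kind == "activation":
            if self.activation not in VALID_ACTIVATIONS:
                raise ValueError(
                    f"activation must be one of {VALID_ACTIVATIONS}, got {self.activation!r}"
                )

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"kind": self.kind}
        for f in ("kernel_size", "filters", "units", "activation"):
            v = getattr(self, f)
            if v is not None:
                d[f] = v
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "LayerDef":
        return cls(**d)


@dataclass
class ParameterSet:
    """Ordered, named collection of weight arrays for one layer stack."""

    arrays: dict[str, np.ndarray] = field(default_factory=dict)

    def copy(self) -> "ParameterSet":
        return ParameterSet({k: v.copy() for k, v in self.arrays.items()})

    def validate_finite(self) -> None:
        for name, a in self.arrays.items():
            if not np.all(np.isfinite(a)):
                raise FloatingPointError(f"non-finite values in parameter {name!r}")

    def names(self) -> list[str]:
        return list(self.arrays)

    def __iter__(self) -> Iterator[tuple[str, np.ndarray]]:
        return iter(self.arrays.items())

    def __getitem__(self, name: str) -> np.ndarray:
        return self.arrays[name]

    def allclose(self, other: "ParameterSet", rtol: float = 0.0, atol: float = 0.0) -> bool:
        if self.names() != other.names():
            return False
        return all(
            np.allclose(a, other.arrays[k], rtol=rtol, atol=atol) for k, a in self.arrays.items()
        )

    def save(self, path) -> None:
        np.savez(path, **self.arrays)

    @classmethod
    def load(cls, path) -> "ParameterSet":
        with np.load(path) as z:
            return cls({k: z[k] for k in z.files})


# ---------------------------------------------------------------------------
# activations


def act_forward(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "leaky_relu":
        return np.where(z > 0, z, LEAKY_SLOPE * z)
    if name == "sigmoid":
        # numerically stable two-sided form
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out
    if name == "linear":
        return z
    raise ValueError(f"unknown activation {name!r}")


def act_backward(name: str, z: np.ndarray, dout: np.ndarray) -> np.ndarray:
    if name == "relu":
        return dout * (z > 0)
    if name == "leaky_relu":
        return dout * np.where(z > 0, 1.0, LEAKY_SLOPE)
    if name == "sigmoid":
        s = act_forward("sigmoid", z)
        return dout * s * (1.0 - s)
    if name == "linear":
        return dout
    raise ValueError(f"unknown activation {name!r}")


# ---------------------------------------------------------------------------
# layer primitives (forward returns (out, cache); backward returns (dx, grads))


def _conv2d_forward(x: np.ndarray, kernel: np.ndarray, bias: np.ndarray):
    if x.ndim != 4:
        raise ShapeError(f"conv2d expects [batch, H, W, C], got shape {x.shape}")
    b, h, w, c = x.shape
    kh, kw, cin, f = kernel.shape
    if cin != c:
        raise ShapeError(f"conv2d kernel expects {cin} input channels, got {c}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, kh - 1 - ph), (pw, kw - 1 - pw), (0, 0)))
    # windows: [b, h, w, c, kh, kw]
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))
    cols = win.reshape(b * h * w, c * kh * kw)
    kmat = kernel.transpose(2, 0, 1, 3).reshape(c * kh * kw, f)
    out = (cols @ kmat + bias).reshape(b, h, w, f)
    return out, (x.shape, cols, kmat.shape)


def _conv2d_backward(dout: np.ndarray, cache, kernel: np.ndarray):
    (b, h, w, c), cols, _ = cache
    kh, kw, _, f = kernel.shape
    dout_mat = dout.reshape(b * h * w, f)
    dkmat = cols.T @ dout_mat
    dk = dkmat.reshape(c, kh, kw, f).transpose(1, 2, 0, 3)
    db = dout_mat.sum(axis=0)
    kmat = kernel.transpose(2, 0, 1, 3).reshape(c * kh * kw, f)
    dcols = dout_mat @ kmat.T
    dwin = dcols.reshape(b, h, w, c, kh, kw)
    ph, pw = kh // 2, kw // 2
    dxp = np.zeros((b, h + kh - 1, w + kw - 1, c))
    for i in range(kh):
        for j in range(kw):
            dxp[:, i : i + h, j : j + w, :] += dwin[:, :, :, :, i, j]
    dx = dxp[:, ph : ph + h, pw : pw + w, :]
    return dx, dk, db


def _maxpool_forward(x: np.ndarray):
    if x.ndim != 4:
        raise ShapeError(f"maxpool2d expects [batch, H, W, C], got shape {x.shape}")
    b, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    if h2 < 1 or w2 < 1:
        raise ShapeError(f"spatial dims too small to pool: {x.shape}")
    xt = (
        x[:, : h2 * 2, : w2 * 2, :]
        .reshape(b, h2, 2, w2, 2, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(b, h2, w2, 4, c)
    )
    idx = xt.argmax(axis=3)
    out = np.take_along_axis(xt, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, (x.shape, idx)


def _maxpool_backward(dout: np.ndarray, cache):
    (b, h, w, c), idx = cache
    h2, w2 = h // 2, w // 2
    dxt = np.zeros((b, h2, w2, 4, c))
    np.put_along_axis(dxt, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
    dx = np.zeros((b, h, w, c))
    dx[:, : h2 * 2, : w2 * 2, :] = (
        dxt.reshape(b, h2, w2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(b, h2 * 2, w2 * 2, c)
    )
    return dx


# ---------------------------------------------------------------------------


class Stack:
    """An ordered list of :class:`LayerDef` with forward/backward passes."""

    def __init__(self, layers: list[LayerDef]):
        if not layers:
            raise ValueError("a stack needs at least one layer")
        self.layers = list(layers)

    # -- shapes ------------------------------------------------------------

    def output_shape(self, input_shape: tuple[int, ...]) -> tuple[int, ...]:
        """Per-sample output shape for a per-sample ``input_shape``."""
        shape = tuple(input_shape)
        for ld in self.layers:
            if ld.kind == "conv2d":
                if len(shape) != 3:
                    raise ShapeError(f"conv2d needs [H, W, C] input, got {shape}")
                shape = (shape[0], shape[1], ld.filters)
            elif ld.kind == "maxpool2d":
                if shape[0] // 2 < 1 or shape[1] // 2 < 1:
                    raise ShapeError(f"input too small to pool at shape {shape}")
                shape = (shape[0] // 2, shape[1] // 2, shape[2])
            elif ld.kind == "flatten":
                shape = (int(np.prod(shape)),)
            elif ld.kind == "dense":
                shape = (ld.units,)
            # activation: unchanged
        return shape

    # -- parameters --------------------------------------------------------

    def init_params(self, input_shape: tuple[int, ...], rng: np.random.Generator) -> ParameterSet:
        """Glorot-uniform kernels/weights, zero biases."""
        params = ParameterSet()
        shape = tuple(input_shape)
        for i, ld in enumerate(self.layers):
            if ld.kind == "conv2d":
                kh = kw = ld.kernel_size
                cin = shape[2]
                fan_in, fan_out = kh * kw * cin, kh * kw * ld.filters
                limit = np.sqrt(6.0 / (fan_in + fan_out))
                params.arrays[f"{i:02d}_conv2d/kernel"] = rng.uniform(
                    -limit, limit, size=(kh, kw, cin, ld.filters)
                )
                params.arrays[f"{i:02d}_conv2d/bias"] = np.zeros(ld.filters)
            elif ld.kind == "dense":
                d = shape[0]
                limit = np.sqrt(6.0 / (d + ld.units))
                params.arrays[f"{i:02d}_dense/weight"] = rng.uniform(
                    -limit, limit, size=(d, ld.units)
                )
                params.arrays[f"{i:02d}_dense/bias"] = np.zeros(ld.units)
            shape = Stack([ld]).output_shape(shape)
        return params

    # -- passes ------------------------------------------------------------

    def forward(self, x: np.ndarray, params: ParameterSet):
        """Returns (output, caches); caches feed :meth:`backward`."""
        caches: list[Any] = []
        out = x
        for i, ld in enumerate(self.layers):
            if ld.kind == "conv2d":
                out, cache = _conv2d_forward(
                    out, params[f"{i:02d}_conv2d/kernel"], params[f"{i:02d}_conv2d/bias"]
                )
            elif ld.kind == "maxpool2d":
                out, cache = _maxpool_forward(out)
            elif ld.kind == "flatten":
                cache = out.shape
                out = out.reshape(out.shape[0], -1)
            elif ld.kind == "dense":
                cache = out
                out = out @ params[f"{i:02d}_dense/weight"] + params[f"{i:02d}_dense/bias"]
            else:  # activation
                cache = out
                out = act_forward(ld.activation, out)
            caches.append(cache)
        return out, caches

    def backward(self, dout: np.ndarray, caches: list, params: ParameterSet, *, start: int | None = None):
        """Backpropagate ``dout`` from layer ``start`` (default: last) down.

        Returns (dx, grads) where grads is a :class:`ParameterSet` aligned
        with ``params``.
        """
        grads = ParameterSet({k: np.zeros_like(v) for k, v in params})
        d = dout
        first = len(self.layers) - 1 if start is None else start
        for i in range(first, -1, -1):
            ld = self.layers[i]
            cache = caches[i]
            if ld.kind == "conv2d":
                d, dk, db = _conv2d_backward(d, cache, params[f"{i:02d}_conv2d/kernel"])
                grads.arrays[f"{i:02d}_conv2d/kernel"] = dk
                grads.arrays[f"{i:02d}_conv2d/bias"] = db
            elif ld.kind == "maxpool2d":
                d = _maxpool_backward(d, cache)
            elif ld.kind == "flatten":
                d = d.reshape(cache)
            elif ld.kind == "dense":
                x = cache
                grads.arrays[f"{i:02d}_dense/weight"] = x.T @ d
                grads.arrays[f"{i:02d}_dense/bias"] = d.sum(axis=0)
                d = d @ params[f"{i:02d}_dense/weight"].T
            else:
                d = act_backward(ld.activation, cache, d)
        return d, grads

    def loss_backward(self, y: np.ndarray, out: np.ndarray, caches: list, params: ParameterSet, loss_name: str):
        """Loss + full backward pass through the stack.

        Fuses the (sigmoid, binary cross-entropy) and (linear, MSE) output
        pairs so the gradient at the output pre-activation is computed in
        closed form, avoiding the unstable d(loss)/d(probability) route.

        Returns (loss, dx_at_input, grads).
        """
        p = out.reshape(out.shape[0])
        yv = np.asarray(y, dtype=float).reshape(-1)
        if p.shape != yv.shape:
            raise ShapeError(f"predictions {p.shape} vs labels {yv.shape}")
        n = p.shape[0]
        last = self.layers[-1]
        loss = loss_value(loss_name, p, yv)
        fused = last.kind == "activation" and (
            (last.activation == "sigmoid" and loss_name == "binary_crossentropy")
            or (last.activation == "linear" and loss_name == "mse")
        )
        if fused:
            scale = 1.0 if loss_name == "binary_crossentropy" else 2.0
            dz = (scale * (p - yv) / n).reshape(out.shape)
            dx, grads = self.backward(dz, caches, params, start=len(self.layers) - 2)
        else:
            if loss_name == "binary_crossentropy":
                pc = np.clip(p, 1e-7, 1 - 1e-7)
                dp = ((pc - yv) / (pc * (1 - pc)) / n).reshape(out.shape)
            elif loss_name == "mse":
                dp = (2.0 * (p - yv) / n).reshape(out.shape)
            else:
                raise ValueError(f"unknown loss {loss_name!r}")
            dx, grads = self.backward(dp, caches, params)
        return loss, dx, grads


def loss_value(loss_name: str, p: np.ndarray, y: np.ndarray) -> float:
    """Mean loss over a batch; BCE clips probabilities at 1e-7."""
    p = np.asarray(p, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if p.shape != y.shape:
        raise ShapeError(f"length mismatch: {p.shape} vs {y.shape}")
    if loss_name == "binary_crossentropy":
        pc = np.clip(p, 1e-7, 1 - 1e-7)
        return float(np.mean(-(y * np.log(pc) + (1 - y) * np.log(1 - pc))))
    if loss_name == "mse":
        return float(np.mean((p - y) ** 2))
    raise ValueError(f"unknown loss {loss_name!r}")


class Adam:
    """Adam with bias correction; one instance owns one ParameterSet's state."""

    def __init__(self, lr: float = 3e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: ParameterSet, grads: ParameterSet) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, g in grads:
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1**self.t)
            vhat = self.v[name] / (1 - b2**self.t)
            params.arrays[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def clone_config(self) -> "Adam":
        return Adam(self.lr, self.beta1, self.beta2, self.eps)
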