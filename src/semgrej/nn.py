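"""Minimal NumPy neural-network stack: layers, manual backprop, Adam.

The networks in this package are deliberately small (a 6-layer CNN and a
7-layer mirror MLP), so a compact hand-derived backprop implementation is
both sufficient and fully deterministic under a single seed.  Conventions:
inputs are batched along axis 0; convolution inputs are [N, C, H, W];
``forward(x, train=...)`` caches what ``backward(grad)`` needs; parameter
gradients accumulate into ``layer.grads`` and are consumed by ``Adam``.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class; stateless layers leave params empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)  # He init, suited to (leaky) rectifiers
        self.params = {
            "W": rng.standard_normal((n_in, n_out)) * scale,
            "b": np.zeros(n_out),
        }

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.slope * grad)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


def conv_output_size(n: int, kernel: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - kernel) // stride + 1


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with per-axis stride and padding."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: tuple[int, int],
        stride: tuple[int, int],
        pad: tuple[int, int],
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        kh, kw = kernel
        scale = np.sqrt(2.0 / (in_ch * kh * kw))
        self.params = {
            "W": rng.standard_normal((out_ch, in_ch, kh, kw)) * scale,
            "b": np.zeros(out_ch),
        }
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        kh, kw = self.kernel
        sh, sw = self.stride
        ph, pw = self.pad
        n, c, h, w = x.shape
        ho = conv_output_size(h, kh, sh, ph)
        wo = conv_output_size(w, kw, sw, pw)
        if ho < 1 or wo < 1:
            raise ValueError(f"input {x.shape[2:]} too small for kernel {self.kernel}")
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        cols = win[:, :, ::sh, ::sw][:, :, :ho, :wo]  # [N,C,Ho,Wo,kh,kw]
        self._cols, self._xshape = cols, x.shape
        out = np.einsum("nchwij,ocij->nohw", cols, self.params["W"], optimize=True)
        return out + self.params["b"][None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        kh, kw = self.kernel
        sh, sw = self.stride
        ph, pw = self.pad
        n, c, h, w = self._xshape
        ho, wo = grad.shape[2], grad.shape[3]
        self.grads["W"] = np.einsum("nohw,nchwij->ocij", grad, self._cols, optimize=True)
        self.grads["b"] = grad.sum(axis=(0, 2, 3))
        dxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw))
        W = self.params["W"]
        for i in range(kh):
            for j in range(kw):
                patch = np.einsum("nohw,oc->nchw", grad, W[:, :, i, j], optimize=True)
                dxp[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += patch
        return dxp[:, :, ph : ph + h, pw : pw + w]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameter_layers(self) -> list[Layer]:
        out = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                out.extend(layer.parameter_layers())
            elif layer.params:
                out.append(layer)
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {
            f"layer{i}_{name}": arr
            for i, layer in enumerate(self.parameter_layers())
            for name, arr in layer.params.items()
        }

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.parameter_layers()):
            for name in layer.params:
                arr = np.asarray(state[f"layer{i}_{name}"])
                if arr.shape != layer.params[name].shape:
                    raise ValueError(
                        f"checkpoint shape {arr.shape} != model shape "
                        f"{layer.params[name].shape} for layer{i}_{name}"
                    )
                layer.params[name] = arr.astype(float)


class Adam:
    """Adaptive moment estimation over the parameter layers of a network."""

    def __init__(
        self,
        net: Sequential,
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.layers = net.parameter_layers()
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1**self.t)
                vhat = v[k] / (1 - b2**self.t)
                layer.params[k] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def softmax(logits: np.ndarray) -> np.ndarray:
    return np.exp(log_softmax(logits))
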