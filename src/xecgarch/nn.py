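"""Minimal 1-D CNN engine on numpy.

Implements exactly the layer set the architecture needs -- valid (unpadded)
1-D convolution, batch normalization, ReLU, global average pooling and a
dense softmax head -- with full forward/backward passes and an Adam
optimizer.  Keeping the engine in numpy gives the attribution code direct
access to every intermediate activation and lets ReLU backward be modified
in place (guided backpropagation) and batch-norm layers be folded into
their convolutions (relevance propagation), without fighting a framework's
autodiff.

Convolutions are evaluated as batched GEMMs over an im2col view; the
input-gradient pass scatters through the kernel taps, so cost stays
O(n_out * k * C_in * C_out) per layer.

Shapes follow the (batch, channels, length) convention.
"""

from __future__ import annotations

import copy

import numpy as np

from .architecture import CNNSpec

__all__ = ["Model", "Adam", "softmax", "cross_entropy", "one_hot"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(p: np.ndarray, y_idx: np.ndarray) -> float:
    """Mean categorical cross-entropy of probabilities vs integer labels."""
    eps = 1e-12
    return float(-np.mean(np.log(p[np.arange(len(y_idx)), y_idx] + eps)))


def one_hot(y_idx: np.ndarray, n_classes: int = 2) -> np.ndarray:
    out = np.zeros((len(y_idx), n_classes))
    out[np.arange(len(y_idx)), y_idx] = 1.0
    return out


class Conv1D:
    def __init__(self, c_in: int, c_out: int, k: int, stride: int, rng, dtype):
        self.k, self.stride = k, stride
        self.c_in, self.c_out = c_in, c_out
        std = np.sqrt(2.0 / (c_in * k))  # He init for the ReLU stack
        self.W = rng.normal(0.0, std, size=(c_out, c_in, k)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.grads: dict[str, np.ndarray] = {}
        self._cols = None
        self._in_len = 0

    def params(self):
        return {"W": self.W, "b": self.b}

    def out_len(self, n: int) -> int:
        return (n - self.k) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, length = x.shape
        if length < self.k:
            raise ValueError(
                f"input length {length} shorter than kernel {self.k}; "
                "pad the signal to at least the receptive field"
            )
        win = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=2)
        win = win[:, :, :: self.stride, :]  # (N, C_in, L_out, k)
        l_out = win.shape[2]
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            n, l_out, c * self.k
        )
        out = cols @ self.W.reshape(self.c_out, -1).T + self.b
        self._cols, self._in_len = cols, length
        return out.transpose(0, 2, 1)

    def backward(self, dout: np.ndarray, param_grads: bool = True) -> np.ndarray:
        n, _, l_out = dout.shape
        d = dout.transpose(0, 2, 1)  # (N, L_out, C_out)
        if param_grads:
            dW = d.reshape(-1, self.c_out).T @ self._cols.reshape(-1, self.c_in * self.k)
            self.grads = {"W": dW.reshape(self.W.shape), "b": d.sum(axis=(0, 1))}
        dx = np.zeros((n, self.c_in, self._in_len), dtype=dout.dtype)
        for t in range(self.k):
            # contribution of kernel tap t to input positions t, t+s, ...
            contrib = np.tensordot(d, self.W[:, :, t], axes=(2, 0))  # (N, L_out, C_in)
            dx[:, :, t : t + self.stride * l_out : self.stride] += contrib.transpose(0, 2, 1)
        return dx


class BatchNorm1D:
    def __init__(self, c: int, dtype, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.eps, self.momentum = eps, momentum
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * inv[:, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma[:, None] * xhat + self.beta[:, None]

    def backward(self, dout: np.ndarray, param_grads: bool = True) -> np.ndarray:
        xhat, inv, train, shape = self._cache
        if param_grads:
            self.grads = {
                "gamma": (dout * xhat).sum(axis=(0, 2)),
                "beta": dout.sum(axis=(0, 2)),
            }
        g = self.gamma[:, None]
        if not train:
            return dout * g * inv[:, None]
        m = shape[0] * shape[2]
        dxhat = dout * g
        return (
            inv[:, None]
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(0, 2), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
            )
        )

    def fold_into(self, conv: Conv1D) -> tuple[np.ndarray, np.ndarray]:
        """Equivalent (W, b) of conv followed by this BN in eval mode."""
        scale = self.gamma / np.sqrt(self.running_var + self.eps)
        W = conv.W * scale[:, None, None]
        b = (conv.b - self.running_mean) * scale + self.beta
        return W, b


class ReLU:
    def __init__(self):
        self._mask = None
        self.grads: dict[str, np.ndarray] = {}

    def params(self):
        return {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray, param_grads: bool = True, guided: bool = False):
        d = dout * self._mask
        if guided:
            d = d * (dout > 0)
        return d


class GlobalAveragePool:
    def __init__(self):
        self._len = 0
        self.grads: dict[str, np.ndarray] = {}

    def params(self):
        return {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._len = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout: np.ndarray, param_grads: bool = True) -> np.ndarray:
        return np.repeat(dout[:, :, None], self._len, axis=2) / self._len


class Dense:
    def __init__(self, c_in: int, c_out: int, rng, dtype):
        std = np.sqrt(1.0 / c_in)
        self.W = rng.normal(0.0, std, size=(c_out, c_in)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.grads: dict[str, np.ndarray] = {}
        self._x = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray, param_grads: bool = True) -> np.ndarray:
        if param_grads:
            self.grads = {"W": dout.T @ self._x, "b": dout.sum(axis=0)}
        return dout @ self.W


class Model:
    """GAP-CNN for binary classification, instantiated from a :class:`CNNSpec`.

    Layer stack: [Conv -> (BatchNorm) -> ReLU] per spec layer, then global
    average pooling and a dense layer of size two whose softmax gives the
    class probabilities.  Accepts any input length >= the receptive field.
    """

    def __init__(self, spec: CNNSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.seed = seed
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.layers: list = []
        self.conv_indices: list[int] = []
        self.relu_indices: list[int] = []
        c_in = 1
        for ls in spec.layers:
            self.conv_indices.append(len(self.layers))
            self.layers.append(Conv1D(c_in, ls.feature_maps, ls.kernel_size, ls.stride, rng, dtype))
            if ls.has_batch_norm:
                self.layers.append(BatchNorm1D(ls.feature_maps, dtype))
            self.relu_indices.append(len(self.layers))
            self.layers.append(ReLU())
            c_in = ls.feature_maps
        self.gap_index = len(self.layers)
        self.layers.append(GlobalAveragePool())
        self.layers.append(Dense(c_in, 2, rng, dtype))

    # -- parameter access ---------------------------------------------------
    def parameters(self) -> list[tuple[int, str, np.ndarray]]:
        out = []
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params().items():
                out.append((i, name, arr))
        return out

    def get_state(self) -> list[np.ndarray]:
        state = [arr.copy() for _, _, arr in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm1D):
                state.extend([layer.running_mean.copy(), layer.running_var.copy()])
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for (_, _, arr), new in zip(params, state[: len(params)]):
            arr[...] = new
        rest = iter(state[len(params) :])
        for layer in self.layers:
            if isinstance(layer, BatchNorm1D):
                layer.running_mean[...] = next(rest)
                layer.running_var[...] = next(rest)

    def copy(self) -> "Model":
        return copy.deepcopy(self)

    def astype(self, dtype) -> "Model":
        """Copy of the model with all parameters cast to ``dtype``."""
        m = self.copy()
        m.dtype = dtype
        for layer in m.layers:
            for name, arr in list(layer.params().items()):
                setattr(layer, name, arr.astype(dtype))
            if isinstance(layer, BatchNorm1D):
                layer.running_mean = layer.running_mean.astype(dtype)
                layer.running_var = layer.running_var.astype(dtype)
        return m

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch ``(N, 1, L)`` (or ``(N, L)``)."""
        if x.ndim == 2:
            x = x[:, None, :]
        h = x.astype(self.dtype, copy=False)
        self._acts = [h]
        for layer in self.layers:
            h = layer.forward(h, train=train)
            self._acts.append(h)
        return h

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def backward(
        self,
        dlogits: np.ndarray,
        param_grads: bool = True,
        guided: bool = False,
        to_layer: int = 0,
    ) -> np.ndarray:
        """Backpropagate from the logits to the output of ``layers[to_layer-1]``
        (i.e. the input of ``layers[to_layer]``); 0 reaches the model input."""
        d = dlogits.astype(self.dtype, copy=False)
        for layer in reversed(self.layers[to_layer:]):
            if isinstance(layer, ReLU):
                d = layer.backward(d, param_grads=param_grads, guided=guided)
            else:
                d = layer.backward(d, param_grads=param_grads)
        return d

    def loss_and_grads(self, x: np.ndarray, y_idx: np.ndarray) -> float:
        """Training step helper: CE loss; gradients left on the layers."""
        logits = self.forward(x, train=True)
        p = softmax(logits)
        loss = cross_entropy(p, y_idx)
        dlogits = (p - one_hot(y_idx, 2)) / len(y_idx)
        self.backward(dlogits.astype(self.dtype), param_grads=True)
        return loss

    def input_gradient(
        self, x: np.ndarray, class_idx: int, guided: bool = False
    ) -> np.ndarray:
        """d logit[class] / d input, eval mode, shape (N, L)."""
        if x.ndim == 1:
            x = x[None, :]
        n = x.shape[0]
        self.forward(x, train=False)
        dlogits = np.zeros((n, 2), dtype=self.dtype)
        dlogits[:, class_idx] = 1.0
        dx = self.backward(dlogits, param_grads=False, guided=guided)
        return dx[:, 0, :]

    # -- access for attribution methods --------------------------------------
    def activations(self) -> list[np.ndarray]:
        """Per-layer outputs of the most recent forward pass (acts[0] = input)."""
        return self._acts

    def layer_gradient(self, class_idx: int, layer_index: int) -> np.ndarray:
        """d logit[class] / d output of ``layers[layer_index]`` for the most
        recent forward pass."""
        n = self._acts[-1].shape[0]
        dlogits = np.zeros((n, 2), dtype=self.dtype)
        dlogits[:, class_idx] = 1.0
        return self.backward(dlogits, param_grads=False, to_layer=layer_index + 1)

    def folded_convs(self) -> list[tuple[np.ndarray, np.ndarray, int]]:
        """Per spec layer the eval-equivalent (W, b, stride) with any batch
        norm folded into the convolution weights."""
        out = []
        for idx in self.conv_indices:
            conv = self.layers[idx]
            nxt = self.layers[idx + 1]
            if isinstance(nxt, BatchNorm1D):
                W, b = nxt.fold_into(conv)
            else:
                W, b = conv.W.copy(), conv.b.copy()
            out.append((np.asarray(W, dtype=np.float64), np.asarray(b, dtype=np.float64), conv.stride))
        return out

    @property
    def dense(self) -> Dense:
        return self.layers[-1]

    @property
    def receptive_field(self) -> int:
        return self.spec.receptive_field


class Adam:
    def __init__(self, model: Model, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, name, arr in self.model.parameters():
            g = self.model.layers[i].grads.get(name)
            if g is None:
                continue
            key = (i, name)
            m = self.m.setdefault(key, np.zeros_like(arr))
            v = self.v.setdefault(key, np.zeros_like(arr))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
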