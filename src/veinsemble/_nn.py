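"""Minimal deterministic CNN engine (numpy + BLAS).

Supports exactly what the weak-classifier architectures need: 2x2 convs
with keep-size zero padding (bottom/right), 2x2/stride-2 max pooling with
floor semantics, a flatten -> ReLU -> dropout head and a dense softmax
output, trained by SGD with momentum on cross-entropy.

Activations are kept in NHWC layout so the im2col gather stays close to
contiguous; pooling uses a two-stage pairwise max (ties resolve to the
first element) instead of argmax bookkeeping.  All state is float32 so
runs are bit-reproducible under a seed.
"""

from __future__ import annotations

import numpy as np

_F32 = np.float32


class Conv2x2:
    """2x2 convolution, stride 1, zero-padded bottom/right to keep H x W.

    Weights are stored as a (4 * in_ch, out_ch) matrix whose rows follow
    the (dy, dx, channel) order of the im2col gather.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        fan_in = in_ch * 4
        # linear trunk (no inter-conv ReLU): variance-preserving init
        self.w = rng.normal(0.0, np.sqrt(1.0 / fan_in), (fan_in, out_ch)).astype(_F32)
        self.b = np.zeros(out_ch, dtype=_F32)
        self.vw = np.zeros_like(self.w)
        self.vb = np.zeros_like(self.b)
        self.in_ch = in_ch
        self.out_ch = out_ch
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (0, 1), (0, 1), (0, 0)))
        cols = np.empty((n, h, w, 4 * c), dtype=_F32)
        for k, (i, j) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
            cols[..., k * c : (k + 1) * c] = xp[:, i : i + h, j : j + w, :]
        cols = cols.reshape(n * h * w, 4 * c)
        out = cols @ self.w + self.b
        if train:
            self._cols = cols
            self._shape = (n, h, w, c)
        return out.reshape(n, h, w, self.out_ch)

    def backward(
        self, dout: np.ndarray, lr: float, momentum: float, needs_dx: bool = True
    ) -> np.ndarray | None:
        n, h, w, c = self._shape
        dm = dout.reshape(n * h * w, self.out_ch)
        dw = self._cols.T @ dm
        db = dm.sum(axis=0)
        self._cols = None
        dx = None
        if needs_dx:
            dcols = (dm @ self.w.T).reshape(n, h, w, 4, c)
            dxp = np.zeros((n, h + 1, w + 1, c), dtype=_F32)
            for k, (i, j) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, k, :]
            dx = dxp[:, :h, :w, :]
        self.vw = momentum * self.vw - lr * dw
        self.vb = momentum * self.vb - lr * db
        self.w += self.vw
        self.b += self.vb
        return dx

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"w": self.w, "b": self.b}


class MaxPool2:
    """2x2 max pooling with stride 2; odd trailing rows/cols are dropped."""

    def __init__(self) -> None:
        self._row_pick: np.ndarray | None = None
        self._col_pick: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        xc = x[:, : ho * 2, : wo * 2, :]
        r0, r1 = xc[:, 0::2], xc[:, 1::2]
        row_pick = r0 >= r1
        rows = np.where(row_pick, r0, r1)
        c0, c1 = rows[:, :, 0::2], rows[:, :, 1::2]
        col_pick = c0 >= c1
        out = np.where(col_pick, c0, c1)
        if train:
            self._row_pick = row_pick
            self._col_pick = col_pick
            self._shape = (n, h, w, c)
        return out

    def backward(self, dout: np.ndarray, lr: float, momentum: float) -> np.ndarray:
        n, h, w, c = self._shape
        ho, wo = h // 2, w // 2
        rp, cp = self._row_pick, self._col_pick
        # winner quadrant masks at output resolution
        rp0, rp1 = rp[:, :, 0::2], rp[:, :, 1::2]
        dx = np.zeros((n, h, w, c), dtype=_F32)
        dcp = dout * cp
        dncp = dout - dcp
        dx[:, 0 : ho * 2 : 2, 0 : wo * 2 : 2] = dcp * rp0
        dx[:, 1 : ho * 2 : 2, 0 : wo * 2 : 2] = dcp * ~rp0
        dx[:, 0 : ho * 2 : 2, 1 : wo * 2 : 2] = dncp * rp1
        dx[:, 1 : ho * 2 : 2, 1 : wo * 2 : 2] = dncp * ~rp1
        self._row_pick = None
        self._col_pick = None
        return dx

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {}


class ReluDropoutHead:
    """Flatten -> ReLU -> (train-time) inverted dropout."""

    def __init__(self, rate: float):
        self.rate = rate
        self._mask: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        n = x.shape[0]
        flat = x.reshape(n, -1)
        out = np.maximum(flat, 0.0)
        if train:
            self._shape = x.shape
            mask = (out > 0).astype(_F32)
            keep = (rng.random(out.shape) >= self.rate).astype(_F32)
            drop = keep / _F32(1.0 - self.rate)
            self._mask = mask * drop
            out = out * drop
        return out

    def backward(self, dout: np.ndarray, lr: float, momentum: float) -> np.ndarray:
        d = (dout * self._mask).reshape(self._shape)
        self._mask = None
        return d

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {}


class DenseSoftmax:
    """Dense projection to class logits; softmax/CE handled by the net."""

    def __init__(self, in_dim: int, n_classes: int, rng: np.random.Generator):
        # small head init keeps initial logits near zero (loss ~ log C)
        self.w = rng.normal(0.0, 0.01, (in_dim, n_classes)).astype(_F32)
        self.b = np.zeros(n_classes, dtype=_F32)
        self.vw = np.zeros_like(self.w)
        self.vb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dlogits: np.ndarray, lr: float, momentum: float) -> np.ndarray:
        dw = self._x.T @ dlogits
        db = dlogits.sum(axis=0)
        dx = dlogits @ self.w.T
        self._x = None
        self.vw = momentum * self.vw - lr * dw
        self.vb = momentum * self.vb - lr * db
        self.w += self.vw
        self.b += self.vb
        return dx

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"w": self.w, "b": self.b}


def softmax(logits: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


class Network:
    """Conv/pool trunk + head; one forward/backward per mini-batch."""

    def __init__(
        self,
        filters: tuple[int, ...],
        input_shape: tuple[int, int],
        n_classes: int,
        rng: np.random.Generator,
        dropout: float = 0.5,
    ):
        self.filters = filters
        self.input_shape = input_shape
        self.n_classes = n_classes
        self.convs: list[Conv2x2] = []
        self.pools: list[MaxPool2] = []
        h, w = input_shape
        in_ch = 1
        for f in filters:
            self.convs.append(Conv2x2(in_ch, f, rng))
            self.pools.append(MaxPool2())
            in_ch = f
            h, w = h // 2, w // 2
        self.head = ReluDropoutHead(dropout)
        self.out_dim = h * w * filters[-1]
        self.dense = DenseSoftmax(self.out_dim, n_classes, rng)

    def forward_logits(
        self, x: np.ndarray, train: bool, rng: np.random.Generator
    ) -> np.ndarray:
        if x.ndim == 3:
            x = x[..., None]  # single input channel
        out = np.ascontiguousarray(x, dtype=_F32)
        # float32 overflow marks a diverged classifier; the caller treats
        # non-finite losses/probabilities as a failed (gated-out) model
        with np.errstate(over="ignore", invalid="ignore"):
            for conv, pool in zip(self.convs, self.pools):
                out = pool.forward(conv.forward(out, train), train)
            out = self.head.forward(out, train, rng)
            return self.dense.forward(out, train)

    def predict_proba(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        outs = []
        for start in range(0, x.shape[0], batch):
            logits = self.forward_logits(x[start : start + batch], False, None)
            outs.append(softmax(logits))
        return np.concatenate(outs, axis=0)

    def train_batch(
        self,
        x: np.ndarray,
        y: np.ndarray,
        lr: float,
        momentum: float,
        rng: np.random.Generator,
    ) -> float:
        n = x.shape[0]
        logits = self.forward_logits(x, True, rng)
        with np.errstate(over="ignore", invalid="ignore"):
            probs = softmax(logits)
            loss = float(-np.log(probs[np.arange(n), y] + 1e-12).mean())
            dlogits = probs.astype(_F32)
            dlogits[np.arange(n), y] -= 1.0
            dlogits /= _F32(n)
            grad = self.dense.backward(dlogits, lr, momentum)
            grad = self.head.backward(grad, lr, momentum)
            for depth in range(len(self.convs) - 1, -1, -1):
                grad = self.pools[depth].backward(grad, lr, momentum)
                grad = self.convs[depth].backward(
                    grad, lr, momentum, needs_dx=depth > 0
                )
        return loss

    def reset_momentum(self) -> None:
        for conv in self.convs:
            conv.vw[:] = 0.0
            conv.vb[:] = 0.0
        self.dense.vw[:] = 0.0
        self.dense.vb[:] = 0.0

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for i, conv in enumerate(self.convs):
            for k, v in conv.params.items():
                out[f"conv{i}_{k}"] = v
        for k, v in self.dense.params.items():
            out[f"dense_{k}"] = v
        return out

    def load_parameters(self, arrays: dict[str, np.ndarray]) -> None:
        for i, conv in enumerate(self.convs):
            conv.w = arrays[f"conv{i}_w"].astype(_F32)
            conv.b = arrays[f"conv{i}_b"].astype(_F32)
            conv.vw = np.zeros_like(conv.w)
            conv.vb = np.zeros_like(conv.b)
        self.dense.w = arrays["dense_w"].astype(_F32)
        self.dense.b = arrays["dense_b"].astype(_F32)
        self.dense.vw = np.zeros_like(self.dense.w)
        self.dense.vb = np.zeros_like(self.dense.b)
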