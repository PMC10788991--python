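"""Minimal numpy training core for 1-D convolutional-recurrent classifiers.

Implements exactly the pieces the grading architectures need — 1-D
convolution (same padding), max pooling, squeeze-and-excitation channel
attention, stacked LSTM with input/recurrent dropout, global average
pooling, dense layers, class-weighted softmax cross-entropy, and Adam —
with explicit forward/backward passes.  Arrays are float32; the layer
convention is channels-first ``(batch, channels, time)`` except for the
LSTM, which consumes ``(batch, time, features)``.

The LSTM gate packing follows the gate equations with the recurrent state
concatenated *before* the input, i.e. each gate computes
``sigma(K @ [h_{t-1}, x_t] + Z)``; the packed kernel stacks the four gates
in order (forget, input, output, candidate).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(F32)


class Layer:
    """Base class: layers expose ``params``/``grads`` as parallel lists."""

    params: list
    grads: list

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded 1-D convolution, stride 1, odd kernel width."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel width must be odd for same padding")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.W = _glorot(rng, (out_ch, in_ch, kernel), in_ch * kernel, out_ch * kernel)
        self.b = np.zeros(out_ch, dtype=F32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        win = sliding_window_view(xp, self.kernel, axis=2)  # (N, C, T, k)
        self._win = win if train else None
        return np.einsum("nctk,fck->nft", win, self.W, optimize=True) + self.b[:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        p = self.kernel // 2
        self.grads[0][...] = np.einsum("nctk,nft->fck", self._win, dy, optimize=True)
        self.grads[1][...] = dy.sum(axis=(0, 2))
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p)))
        win2 = sliding_window_view(dyp, self.kernel, axis=2)  # (N, F, T, k)
        dx = np.einsum("nftk,fck->nct", win2, self.W[:, :, ::-1], optimize=True)
        self._win = None
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(F32)


class MaxPool1d(Layer):
    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, t = x.shape
        t_out = t // self.pool
        if t_out < 1:
            raise ValueError(f"sequence length {t} shorter than pool size {self.pool}")
        xr = x[:, :, : t_out * self.pool].reshape(n, c, t_out, self.pool)
        self._arg = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, t = self._in_shape
        t_out = dy.shape[2]
        dxr = np.zeros((n, c, t_out, self.pool), dtype=F32)
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None].astype(F32), axis=3)
        dx = np.zeros((n, c, t), dtype=F32)
        dx[:, :, : t_out * self.pool] = dxr.reshape(n, c, t_out * self.pool)
        return dx


class SEBlock1d(Layer):
    """Squeeze-and-excitation: per-channel mean -> bottleneck -> sigmoid gate."""

    def __init__(self, n_channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(1, n_channels // reduction)
        self.n_channels, self.reduction, self.hidden = n_channels, reduction, hidden
        self.W1 = _glorot(rng, (hidden, n_channels), n_channels, hidden)
        self.b1 = np.zeros(hidden, dtype=F32)
        self.W2 = _glorot(rng, (n_channels, hidden), hidden, n_channels)
        self.b2 = np.zeros(n_channels, dtype=F32)
        self.params = [self.W1, self.b1, self.W2, self.b2]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        s = x.mean(axis=2)                        # squeeze (N, C)
        z1 = s @ self.W1.T + self.b1
        a1 = np.maximum(z1, 0.0)
        w = sigmoid(a1 @ self.W2.T + self.b2)     # excitation (N, C) in (0,1)
        self._cache = (x, s, z1, a1, w)
        return (x * w[:, :, None]).astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, s, z1, a1, w = self._cache
        t = x.shape[2]
        dw = (dy * x).sum(axis=2) * w * (1.0 - w)
        self.grads[2][...] = dw.T @ a1
        self.grads[3][...] = dw.sum(axis=0)
        da1 = dw @ self.W2
        dz1 = da1 * (z1 > 0)
        self.grads[0][...] = dz1.T @ s
        self.grads[1][...] = dz1.sum(axis=0)
        ds = dz1 @ self.W1
        dx = dy * w[:, :, None] + ds[:, :, None] / t
        self._cache = None
        return dx.astype(F32)

    @property
    def excitation(self) -> np.ndarray:
        """Channel weights from the most recent forward pass."""
        return self._cache[4] if self._cache is not None else None


class GlobalAvgPool1d(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._t = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return (np.repeat(dy[:, :, None], self._t, axis=2) / self._t).astype(F32)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape).astype(F32)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.W = _glorot(rng, (out_dim, in_dim), in_dim, out_dim)
        self.b = np.zeros(out_dim, dtype=F32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = dy.T @ self._x
        self.grads[1][...] = dy.sum(axis=0)
        dx = dy @ self.W
        self._x = None
        return dx.astype(F32)


class LSTM(Layer):
    """Single LSTM layer over (batch, time, features) with BPTT.

    ``input_dropout``/``recurrent_dropout`` use one mask per sequence
    (inverted dropout), applied to the layer input x_t and to h_{t-1}
    respectively; both are active only when ``train`` is true.
    """

    def __init__(
        self,
        input_size: int,
        hidden_size: int,
        rng: np.random.Generator,
        input_dropout: float = 0.0,
        recurrent_dropout: float = 0.0,
    ):
        super().__init__()
        self.input_size, self.hidden_size = input_size, hidden_size
        h, c = hidden_size, input_size
        self.K = _glorot(rng, (4 * h, h + c), h + c, 4 * h)
        self.Z = np.zeros(4 * h, dtype=F32)
        self.Z[:h] = 1.0  # forget-gate bias init: remember by default
        self.input_dropout = float(input_dropout)
        self.recurrent_dropout = float(recurrent_dropout)
        self._rng = rng
        self.params = [self.K, self.Z]
        self.grads = [np.zeros_like(self.K), np.zeros_like(self.Z)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, t, cin = x.shape
        h = self.hidden_size
        if train and self.input_dropout > 0:
            keep = 1.0 - self.input_dropout
            in_mask = (self._rng.random((n, cin)) < keep).astype(F32) / keep
        else:
            in_mask = None
        if train and self.recurrent_dropout > 0:
            keep = 1.0 - self.recurrent_dropout
            rec_mask = (self._rng.random((n, h)) < keep).astype(F32) / keep
        else:
            rec_mask = None
        h_t = np.zeros((n, h), dtype=F32)
        c_t = np.zeros((n, h), dtype=F32)
        ys = np.empty((n, t, h), dtype=F32)
        cache = []
        for step in range(t):
            x_t = x[:, step, :]
            if in_mask is not None:
                x_t = x_t * in_mask
            h_in = h_t * rec_mask if rec_mask is not None else h_t
            concat = np.concatenate([h_in, x_t], axis=1)
            gates = concat @ self.K.T + self.Z
            f = sigmoid(gates[:, :h])
            i = sigmoid(gates[:, h : 2 * h])
            o = sigmoid(gates[:, 2 * h : 3 * h])
            g = np.tanh(gates[:, 3 * h :])
            c_prev = c_t
            c_t = f * c_prev + i * g
            tc = np.tanh(c_t)
            h_t = o * tc
            ys[:, step, :] = h_t
            cache.append((concat, f, i, o, g, c_prev, tc))
        self._cache = cache if train or self._keep_cache else None
        self._masks = (in_mask, rec_mask)
        self._in_shape = x.shape
        return ys

    _keep_cache = True  # grad-CAM needs backward after an eval forward

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, t, cin = self._in_shape
        h = self.hidden_size
        in_mask, rec_mask = self._masks
        dK = self.grads[0]
        dZ = self.grads[1]
        dK[...] = 0.0
        dZ[...] = 0.0
        dx = np.zeros((n, t, cin), dtype=F32)
        dh_next = np.zeros((n, h), dtype=F32)
        dc_next = np.zeros((n, h), dtype=F32)
        for step in range(t - 1, -1, -1):
            concat, f, i, o, g, c_prev, tc = self._cache[step]
            dh = dy[:, step, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dgates = np.concatenate(
                [
                    df * f * (1.0 - f),
                    di * i * (1.0 - i),
                    do * o * (1.0 - o),
                    dg * (1.0 - g * g),
                ],
                axis=1,
            )
            dK += dgates.T @ concat
            dZ += dgates.sum(axis=0)
            dconcat = dgates @ self.K
            dh_prev = dconcat[:, :h]
            if rec_mask is not None:
                dh_prev = dh_prev * rec_mask
            dx_t = dconcat[:, h:]
            if in_mask is not None:
                dx_t = dx_t * in_mask
            dx[:, step, :] = dx_t
            dh_next = dh_prev
            dc_next = dc * f
        self._cache = None
        return dx


# --------------------------------------------------------------------------
# Loss and optimizer
# --------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, y_idx: np.ndarray, sample_weight: Optional[np.ndarray] = None
) -> tuple[float, np.ndarray]:
    """Class-weighted categorical cross-entropy; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    if sample_weight is None:
        sample_weight = np.ones(n)
    wsum = sample_weight.sum()
    loss = -(sample_weight * np.log(p[np.arange(n), y_idx] + 1e-12)).sum() / wsum
    dlogits = p.copy()
    dlogits[np.arange(n), y_idx] -= 1.0
    dlogits *= (sample_weight / wsum)[:, None]
    return float(loss), dlogits.astype(F32)


class Adam:
    def __init__(self, params: list, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(p.dtype)


# --------------------------------------------------------------------------
# Architectures
# --------------------------------------------------------------------------

class Network:
    """One of the three ablation architectures, with explicit wiring.

    ``cnn``: three conv(+ReLU)/max-pool stages, flatten, three dense layers
    (nine counted layers).

    ``cnn_lstm`` / ``cnn_lstm_se``: three conv stages (SE attention after
    conv-2 and conv-3 in the ``_se`` variant), an LSTM stack reading the
    last stage as a time series, a global-average-pool skip from each
    stage into the dense head alongside the LSTM's final hidden state, and
    two dense layers.

    ``forward`` caches stage activations so grad-CAM can ask ``backward``
    for the gradient at the last conv stage.
    """

    def __init__(self, variant: str, input_length: int, n_classes: int,
                 conv_filters, kernel_sizes, pool_size: int,
                 n_lstm_layers: int, lstm_hidden: int, se_reduction: int,
                 lstm_input_dropout: float, lstm_recurrent_dropout: float,
                 rng: np.random.Generator):
        self.variant = variant
        self.input_length = input_length
        self.n_classes = n_classes
        f1, f2, f3 = conv_filters
        k1, k2, k3 = kernel_sizes
        t = input_length
        for i, k in enumerate((k1, k2, k3), start=1):
            if t < 1:
                raise ValueError(f"input too short: stage conv{i} receives length {t}")
            t_next = t // pool_size
            if t_next < 1:
                raise ValueError(
                    f"input too short: pool after conv{i} would reduce length {t} "
                    f"below 1 (pool size {pool_size})"
                )
            t = t_next
        self.t_final = t

        self.conv1 = Conv1d(1, f1, k1, rng)
        self.conv2 = Conv1d(f1, f2, k2, rng)
        self.conv3 = Conv1d(f2, f3, k3, rng)
        self.relu1, self.relu2, self.relu3 = ReLU(), ReLU(), ReLU()
        self.pool1 = MaxPool1d(pool_size)
        self.pool2 = MaxPool1d(pool_size)
        self.pool3 = MaxPool1d(pool_size)
        self.se2 = self.se3 = None
        self.lstms: list[LSTM] = []

        if variant == "cnn":
            self.flat = Flatten()
            self.dense1 = Dense(f3 * t, 64, rng)
            self.relu_d1 = ReLU()
            self.dense2 = Dense(64, 32, rng)
            self.relu_d2 = ReLU()
            self.dense3 = Dense(32, n_classes, rng)
        elif variant in ("cnn_lstm", "cnn_lstm_se"):
            if variant == "cnn_lstm_se":
                self.se2 = SEBlock1d(f2, se_reduction, rng)
                self.se3 = SEBlock1d(f3, se_reduction, rng)
            in_size = f3
            for _ in range(n_lstm_layers):
                self.lstms.append(
                    LSTM(in_size, lstm_hidden, rng,
                         input_dropout=lstm_input_dropout,
                         recurrent_dropout=lstm_recurrent_dropout)
                )
                in_size = lstm_hidden
            self.gap1, self.gap2, self.gap3 = (
                GlobalAvgPool1d(), GlobalAvgPool1d(), GlobalAvgPool1d())
            head_in = f1 + f2 + f3 + lstm_hidden
            self.dense1 = Dense(head_in, 64, rng)
            self.relu_d1 = ReLU()
            self.dense2 = Dense(64, n_classes, rng)
        else:
            raise ValueError(f"unknown variant {variant!r}")

    # -- bookkeeping -------------------------------------------------------
    def _layers(self) -> list[Layer]:
        layers = [self.conv1, self.conv2, self.conv3]
        if self.se2 is not None:
            layers += [self.se2, self.se3]
        layers += self.lstms
        layers += [self.dense1, self.dense2]
        if self.variant == "cnn":
            layers.append(self.dense3)
        return layers

    def params(self) -> list:
        return [p for l in self._layers() for p in l.params]

    def grads(self) -> list:
        return [g for l in self._layers() for g in l.grads]

    def census(self) -> dict:
        """Count of counted architectural components per the layer census."""
        if self.variant == "cnn":
            return {"conv": 3, "pool": 3, "dense": 3}
        c = {"conv": 3, "lstm": len(self.lstms), "gap": 3, "dense": 2}
        if self.variant == "cnn_lstm_se":
            c = {"conv": 3, "se": 2, "lstm": len(self.lstms), "gap": 3, "dense": 2}
        return c

    def n_layers(self) -> int:
        return sum(self.census().values())

    # -- forward/backward --------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, L) -> logits (N, n_classes)."""
        x = np.asarray(x, dtype=F32)[:, None, :]  # (N, 1, L)
        a1 = self.pool1.forward(self.relu1.forward(self.conv1.forward(x, train)), train)
        c2 = self.relu2.forward(self.conv2.forward(a1, train))
        s2 = self.se2.forward(c2, train) if self.se2 is not None else c2
        a2 = self.pool2.forward(s2, train)
        c3 = self.relu3.forward(self.conv3.forward(a2, train))
        s3 = self.se3.forward(c3, train) if self.se3 is not None else c3
        a3 = self.pool3.forward(s3, train)
        self.activations = {"conv3_relu": c3, "stage3_out": s3, "stage3_pooled": a3}
        if self.variant == "cnn":
            h = self.relu_d1.forward(self.dense1.forward(self.flat.forward(x=a3), train), train)
            h = self.relu_d2.forward(self.dense2.forward(h, train), train)
            return self.dense3.forward(h, train)
        seq = np.transpose(a3, (0, 2, 1))  # (N, T, C)
        for lstm in self.lstms:
            seq = lstm.forward(seq, train)
        h_last = seq[:, -1, :]
        g1 = self.gap1.forward(a1)
        g2 = self.gap2.forward(a2)
        g3 = self.gap3.forward(a3)
        self._seq_T = seq.shape[1]
        head = np.concatenate([g1, g2, g3, h_last], axis=1)
        h = self.relu_d1.forward(self.dense1.forward(head, train), train)
        return self.dense2.forward(h, train)

    def backward(self, dlogits: np.ndarray, stop_after_stage3: bool = False) -> dict:
        """Backpropagate; returns gradients at the cached stage tensors.

        With ``stop_after_stage3`` the pass ends once the gradient at the
        last conv stage is known (sufficient for grad-CAM; conv input
        caches are only retained on training-mode forwards).
        """
        grads_at = {}
        if self.variant == "cnn":
            dh = self.dense3.backward(dlogits.astype(F32))
            dh = self.dense2.backward(self.relu_d2.backward(dh))
            dh = self.dense1.backward(self.relu_d1.backward(dh))
            da3 = self.flat.backward(dh)
        else:
            dh = self.dense2.backward(dlogits.astype(F32))
            dhead = self.dense1.backward(self.relu_d1.backward(dh))
            f1 = self.conv1.out_ch
            f2 = self.conv2.out_ch
            f3 = self.conv3.out_ch
            dg1 = dhead[:, :f1]
            dg2 = dhead[:, f1 : f1 + f2]
            dg3 = dhead[:, f1 + f2 : f1 + f2 + f3]
            dh_last = dhead[:, f1 + f2 + f3 :]
            dseq = np.zeros((dlogits.shape[0], self._seq_T, self.lstms[-1].hidden_size),
                            dtype=F32)
            dseq[:, -1, :] = dh_last
            for lstm in reversed(self.lstms):
                dseq = lstm.backward(dseq)
            da3 = np.transpose(dseq, (0, 2, 1)).copy() + self.gap3.backward(dg3)
        ds3 = self.pool3.backward(da3)
        grads_at["stage3_out"] = ds3.copy()
        dc3 = self.se3.backward(ds3) if self.se3 is not None else ds3
        grads_at["conv3_relu"] = dc3.copy()
        if stop_after_stage3:
            return grads_at
        da2 = self.conv3.backward(self.relu3.backward(dc3))
        if self.variant != "cnn":
            da2 = da2 + self.gap2.backward(dhead[:, self.conv1.out_ch:
                                                 self.conv1.out_ch + self.conv2.out_ch])
        ds2 = self.pool2.backward(da2)
        dc2 = self.se2.backward(ds2) if self.se2 is not None else ds2
        da1 = self.conv2.backward(self.relu2.backward(dc2))
        if self.variant != "cnn":
            da1 = da1 + self.gap1.backward(dhead[:, : self.conv1.out_ch])
        self.conv1.backward(self.relu1.backward(self.pool1.backward(da1)))
        return grads_at
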