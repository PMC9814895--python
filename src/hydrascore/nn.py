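"""Minimal 3D convolutional network with explicit forward/backward passes.

The pose classifier is small enough (three conv/ReLU blocks with 2x max
pooling, one fully connected layer, softmax) that it is implemented directly
on NumPy arrays. Keeping the layers explicit gives the relevance-propagation
module exact access to weights, pre-activations and pooling argmaxes, and
makes training bit-reproducible per seed.

Shapes: inputs are (N, C, D, D, D); convolutions use 3^3 kernels, stride 1,
zero padding 1; pooling is 2^3 non-overlapping max. D must be divisible by 8.
"""

from __future__ import annotations

import numpy as np

KERNEL = 3
PAD = 1


def conv3d(x: np.ndarray, W: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """'Same' 3D cross-correlation. x: (N,C,D1,D2,D3), W: (F,C,3,3,3)."""
    N, C, D1, D2, D3 = x.shape
    F = W.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (PAD, PAD), (PAD, PAD), (PAD, PAD)))
    V = D1 * D2 * D3
    out = np.zeros((N, F, V), dtype=x.dtype)
    for a in range(KERNEL):
        for bb in range(KERNEL):
            for c in range(KERNEL):
                xs = xp[:, :, a:a + D1, bb:bb + D2, c:c + D3].reshape(N, C, V)
                out += np.matmul(W[:, :, a, bb, c], xs)
    out = out.reshape(N, F, D1, D2, D3)
    if b is not None:
        out += b[None, :, None, None, None]
    return out


def conv3d_input_grad(delta: np.ndarray, W: np.ndarray, x_shape) -> np.ndarray:
    """Gradient of conv3d w.r.t. its input (the transposed convolution)."""
    N, C, D1, D2, D3 = x_shape
    F = W.shape[0]
    V = D1 * D2 * D3
    dflat = delta.reshape(N, F, V)
    dxp = np.zeros((N, C, D1 + 2 * PAD, D2 + 2 * PAD, D3 + 2 * PAD),
                   dtype=delta.dtype)
    for a in range(KERNEL):
        for bb in range(KERNEL):
            for c in range(KERNEL):
                contrib = np.matmul(W[:, :, a, bb, c].T, dflat)
                dxp[:, :, a:a + D1, bb:bb + D2, c:c + D3] += contrib.reshape(
                    N, C, D1, D2, D3
                )
    return dxp[:, :, PAD:-PAD, PAD:-PAD, PAD:-PAD]


def conv3d_weight_grad(delta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Gradient of conv3d w.r.t. W. delta: (N,F,D...), x: (N,C,D...)."""
    N, C, D1, D2, D3 = x.shape
    F = delta.shape[1]
    V = D1 * D2 * D3
    xp = np.pad(x, ((0, 0), (0, 0), (PAD, PAD), (PAD, PAD), (PAD, PAD)))
    dflat = delta.reshape(N, F, V)
    dW = np.zeros((F, C, KERNEL, KERNEL, KERNEL), dtype=delta.dtype)
    for a in range(KERNEL):
        for bb in range(KERNEL):
            for c in range(KERNEL):
                xs = xp[:, :, a:a + D1, bb:bb + D2, c:c + D3].reshape(N, C, V)
                dW[:, :, a, bb, c] = np.einsum("nfv,ncv->fc", dflat, xs,
                                               optimize=True)
    return dW


class ConvReLU:
    """3^3 convolution (stride 1, pad 1) followed by ReLU.

    The forward pass caches the 27 shifted input slices in a GEMM-friendly
    (C, N*V) layout so the weight gradient is pure matrix products; the
    input layer sets ``skip_input_grad`` since nothing below it needs one.
    """

    def __init__(self, W: np.ndarray, b: np.ndarray,
                 skip_input_grad: bool = False):
        self.W = W
        self.b = b
        self.skip_input_grad = skip_input_grad
        self.dW = np.zeros_like(W)
        self.db = np.zeros_like(b)
        self.x = None
        self.pre = None
        self._xs = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        N, C, D1, D2, D3 = x.shape
        F = self.W.shape[0]
        V = D1 * D2 * D3
        if self.skip_input_grad:
            # input layer: all-zero channels (unused atom types) contribute
            # nothing to the output or the weight gradient — skip them
            self._active = np.where(x.any(axis=(0, 2, 3, 4)))[0]
        else:
            self._active = np.arange(C)
        xa = x[:, self._active] if len(self._active) < C else x
        Wa = self.W[:, self._active] if len(self._active) < C else self.W
        Ca = xa.shape[1]
        xp = np.pad(xa, ((0, 0), (0, 0), (PAD, PAD), (PAD, PAD), (PAD, PAD)))
        xpT = np.ascontiguousarray(xp.transpose(1, 0, 2, 3, 4))
        self._xs = []
        outT = np.zeros((F, N * V), dtype=x.dtype)
        for a in range(KERNEL):
            for bb in range(KERNEL):
                for c in range(KERNEL):
                    xs = np.ascontiguousarray(
                        xpT[:, :, a:a + D1, bb:bb + D2, c:c + D3]
                    ).reshape(Ca, N * V)
                    self._xs.append(xs)
                    outT += Wa[:, :, a, bb, c] @ xs
        outT += self.b[:, None]
        self.pre = outT.reshape(F, N, D1, D2, D3).transpose(1, 0, 2, 3, 4)
        return np.maximum(self.pre, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray | None:
        N, C, D1, D2, D3 = self.x.shape
        F = self.W.shape[0]
        V = D1 * D2 * D3
        delta = dout * (self.pre > 0)
        dT = np.ascontiguousarray(delta.transpose(1, 0, 2, 3, 4)).reshape(F, N * V)
        reduced = len(self._active) < C
        if reduced:
            self.dW.fill(0.0)
        k = 0
        for a in range(KERNEL):
            for bb in range(KERNEL):
                for c in range(KERNEL):
                    g = dT @ self._xs[k].T
                    if reduced:
                        self.dW[:, self._active, a, bb, c] = g
                    else:
                        self.dW[:, :, a, bb, c] = g
                    k += 1
        self.db = dT.sum(axis=1)
        if self.skip_input_grad:
            return None
        dxpT = np.zeros(
            (C, N, D1 + 2 * PAD, D2 + 2 * PAD, D3 + 2 * PAD), dtype=dout.dtype
        )
        for k, (a, bb, c) in enumerate(
            (a, bb, c) for a in range(KERNEL) for bb in range(KERNEL)
            for c in range(KERNEL)
        ):
            contrib = (self.W[:, :, a, bb, c].T @ dT).reshape(C, N, D1, D2, D3)
            dxpT[:, :, a:a + D1, bb:bb + D2, c:c + D3] += contrib
        return dxpT[:, :, PAD:-PAD, PAD:-PAD, PAD:-PAD].transpose(1, 0, 2, 3, 4)

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class MaxPool:
    """2^3 non-overlapping max pooling with tie-splitting backward."""

    def __init__(self):
        self.mask = None
        self.counts = None
        self.in_shape = None

    @staticmethod
    def _windows(x):
        N, C, D1, D2, D3 = x.shape
        return x.reshape(N, C, D1 // 2, 2, D2 // 2, 2, D3 // 2, 2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.in_shape = x.shape
        w = self._windows(x)
        out = w.max(axis=(3, 5, 7))
        self.mask = w == out[:, :, :, None, :, None, :, None]
        self.counts = self.mask.sum(axis=(3, 5, 7))
        return out

    def route(self, upper: np.ndarray) -> np.ndarray:
        """Distribute an upper-layer quantity (gradient or relevance) onto
        the winning inputs, splitting ties equally."""
        share = upper / self.counts
        w = self.mask * share[:, :, :, None, :, None, :, None]
        return w.reshape(self.in_shape)

    backward = route


class Dense:
    """Fully connected layer, no activation (heads handled by the losses)."""

    def __init__(self, W: np.ndarray, b: np.ndarray):
        self.W = W  # (out, in)
        self.b = b
        self.dW = np.zeros_like(W)
        self.db = np.zeros_like(b)
        self.x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = dout.T @ self.x
        self.db = dout.sum(axis=0)
        return dout @ self.W

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Network:
    """input(C, D^3) -> [conv3 + ReLU -> maxpool 2^3] x 3 -> FC -> heads.

    Outputs ``n_outputs`` raw values: two class logits (softmaxed by the
    loss) and, when present, one contact-score logit (sigmoided by its
    loss).
    """

    def __init__(self, blocks, dense: Dense, n_channels: int, dims: int):
        self.blocks = blocks  # list of (ConvReLU, MaxPool)
        self.dense = dense
        self.n_channels = n_channels
        self.dims = dims

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.ndim == 4:
            x = x[None]
        if x.shape[1:] != (self.n_channels, self.dims, self.dims, self.dims):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match network "
                f"({self.n_channels}, {self.dims}^3)"
            )
        for conv, pool in self.blocks:
            x = pool.forward(conv.forward(x))
        self.feature_shape = x.shape[1:]
        return self.dense.forward(x.reshape(x.shape[0], -1))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.dense.backward(dlogits)
        d = d.reshape(d.shape[0], *self.feature_shape)
        for conv, pool in reversed(self.blocks):
            d = conv.backward(pool.backward(d))
        return d

    @property
    def layers(self):
        out = []
        for conv, pool in self.blocks:
            out.extend([conv, pool])
        out.append(self.dense)
        return out

    @property
    def params(self):
        out = []
        for conv, _ in self.blocks:
            out.extend(conv.params)
        out.extend(self.dense.params)
        return out

    def check_finite(self):
        for W, _ in self.params:
            if not np.all(np.isfinite(W)):
                raise ValueError("network has non-finite weights")


def build_network(
    n_channels: int,
    dims: int = 48,
    filters=(32, 64, 128),
    n_outputs: int = 2,
    seed: int | np.random.Generator = 0,
    dtype=np.float32,
    zero_bias: bool = False,
) -> Network:
    """Deterministic He/Xavier initialization per seed."""
    if dims % 8 != 0:
        raise ValueError("dims must be divisible by 8 (three 2^3 poolings)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    blocks = []
    c_in = n_channels
    for k, f in enumerate(filters):
        fan_in = c_in * KERNEL**3
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(f, c_in, KERNEL, KERNEL, KERNEL)).astype(dtype)
        b = np.zeros(f, dtype=dtype)
        blocks.append((ConvReLU(W, b, skip_input_grad=(k == 0)), MaxPool()))
        c_in = f
    feat = c_in * (dims // 8) ** 3
    Wd = rng.normal(0.0, np.sqrt(1.0 / feat), size=(n_outputs, feat)).astype(dtype)
    bd = np.zeros(n_outputs, dtype=dtype)
    if zero_bias:
        pass  # biases are zero-initialized already; flag kept for clarity
    return Network(blocks, Dense(Wd, bd), n_channels, dims)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)
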