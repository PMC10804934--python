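"""Minimal NumPy neural-network layer with explicit reverse-mode gradients.

Provides exactly what the two training tasks and the inversion attack need:
dense and convolutional layers (2-D and 3-D, stride 1, odd kernels), ReLU,
instance normalization, 2x max pooling, nearest-neighbour upsampling, the
softmax cross-entropy and soft-Dice losses, He initialization and the Adam
optimizer.  Parameters live in flat ``{name: float64 array}`` dictionaries so
they can be encoded, shared and averaged tensor-by-tensor by the federation
layer.  Everything is float64 and deterministic given the seeds, which is what
lets an encrypted aggregation round be compared to its plaintext counterpart
at the 1e-13 level.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Adam",
    "MLPClassifier",
    "UNet3D",
    "SmallCNN2d",
    "softmax",
    "softmax_cross_entropy",
    "soft_dice_loss",
]


def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """He-scheme initialization: zero-mean normal with std sqrt(2 / fan_in)."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


# ---------------------------------------------------------------------------
# Layers.  Each layer owns its parameters and caches the last forward pass;
# backward() consumes the upstream gradient, fills self.grads and returns the
# gradient w.r.t. its input.
# ---------------------------------------------------------------------------


class _Layer:
    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def _p(self, key: str) -> str:
        return f"{self.name}.{key}"


class Linear(_Layer):
    def __init__(self, name, n_in, n_out, rng):
        super().__init__(name)
        self.params[self._p("weight")] = he_normal(rng, (n_out, n_in), n_in)
        self.params[self._p("bias")] = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        W = self.params[self._p("weight")]
        return x @ W.T + self.params[self._p("bias")]

    def backward(self, dout):
        W = self.params[self._p("weight")]
        self.grads[self._p("weight")] = dout.T @ self._x
        self.grads[self._p("bias")] = dout.sum(axis=0)
        return dout @ W


class ReLU(_Layer):
    def __init__(self):
        super().__init__("relu")

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Sigmoid(_Layer):
    def __init__(self):
        super().__init__("sigmoid")

    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class Conv(_Layer):
    """N-D convolution (cross-correlation), stride 1, symmetric zero padding."""

    def __init__(self, name, c_in, c_out, kernel, ndim, pad, rng):
        super().__init__(name)
        self.ndim = ndim
        self.pad = pad
        self.kernel = kernel
        fan_in = c_in * kernel**ndim
        self.params[self._p("weight")] = he_normal(
            rng, (c_out, c_in) + (kernel,) * ndim, fan_in
        )
        self.params[self._p("bias")] = np.zeros(c_out)
        if ndim == 2:
            self._fw = "ncxyij,ocij->noxy"
            self._bw_w = "ncxyij,noxy->ocij"
            self._bw_x = "noxyij,ocij->ncxy"
        elif ndim == 3:
            self._fw = "ncxyzijk,ocijk->noxyz"
            self._bw_w = "ncxyzijk,noxyz->ocijk"
            self._bw_x = "noxyzijk,ocijk->ncxyz"
        else:
            raise ValueError("only 2-D and 3-D convolutions are supported")

    def _windows(self, x):
        nd, p, k = self.ndim, self.pad, self.kernel
        xp = np.pad(x, [(0, 0), (0, 0)] + [(p, p)] * nd)
        return sliding_window_view(xp, (k,) * nd, axis=tuple(range(2, 2 + nd)))

    def forward(self, x):
        W = self.params[self._p("weight")]
        b = self.params[self._p("bias")]
        self._win = self._windows(x)
        out = np.einsum(self._fw, self._win, W, optimize=True)
        return out + b.reshape((1, -1) + (1,) * self.ndim)

    def backward(self, dout):
        nd, p, k = self.ndim, self.pad, self.kernel
        W = self.params[self._p("weight")]
        self.grads[self._p("weight")] = np.einsum(
            self._bw_w, self._win, dout, optimize=True
        )
        self.grads[self._p("bias")] = dout.sum(axis=(0,) + tuple(range(2, 2 + nd)))
        # Gradient w.r.t. input: full correlation of dout with the flipped kernel.
        q = k - 1 - p
        dp = np.pad(dout, [(0, 0), (0, 0)] + [(q, q)] * nd)
        dwin = sliding_window_view(dp, (k,) * nd, axis=tuple(range(2, 2 + nd)))
        wf = np.flip(W, axis=tuple(range(2, 2 + nd)))
        return np.einsum(self._bw_x, dwin, wf, optimize=True)


class InstanceNorm(_Layer):
    """Normalize each (sample, channel) over its spatial extent; affine."""

    def __init__(self, name, channels, ndim, eps=1e-5):
        super().__init__(name)
        self.ndim = ndim
        self.eps = eps
        self.params[self._p("gamma")] = np.ones(channels)
        self.params[self._p("beta")] = np.zeros(channels)

    def forward(self, x):
        axes = tuple(range(2, 2 + self.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        g = self.params[self._p("gamma")].reshape((1, -1) + (1,) * self.ndim)
        b = self.params[self._p("beta")].reshape((1, -1) + (1,) * self.ndim)
        return g * self._xhat + b

    def backward(self, dout):
        axes = tuple(range(2, 2 + self.ndim))
        red = (0,) + axes
        self.grads[self._p("gamma")] = (dout * self._xhat).sum(axis=red)
        self.grads[self._p("beta")] = dout.sum(axis=red)
        g = self.params[self._p("gamma")].reshape((1, -1) + (1,) * self.ndim)
        dxhat = dout * g
        m = np.prod([dout.shape[a] for a in axes])
        s1 = dxhat.sum(axis=axes, keepdims=True)
        s2 = (dxhat * self._xhat).sum(axis=axes, keepdims=True)
        return (dxhat - s1 / m - self._xhat * s2 / m) / self._std


class MaxPool3d(_Layer):
    """2x2x2 max pooling with stride 2; ties resolve to the first maximum."""

    def __init__(self):
        super().__init__("maxpool")

    def forward(self, x):
        n, c, d, h, w = x.shape
        self._in_shape = x.shape
        xr = (
            x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(n, c, d // 2, h // 2, w // 2, 8)
        )
        self._idx = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, d, h, w = self._in_shape
        blocks = np.zeros(dout.shape + (8,))
        np.put_along_axis(blocks, self._idx[..., None], dout[..., None], axis=-1)
        return (
            blocks.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(n, c, d, h, w)
        )


class NearestUpsample3d(_Layer):
    """Nearest-neighbour 2x upsampling in every spatial dimension."""

    def __init__(self):
        super().__init__("upsample")

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, dout):
        n, c, d, h, w = dout.shape
        return dout.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def softmax(z, axis=1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits, labels):
    """Mean cross-entropy over the batch. Returns (loss, dloss/dlogits)."""
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


def soft_dice_loss(logits, target_onehot, foreground_classes, eps=1e-5):
    """Soft Dice loss over foreground classes with channel softmax.

    ``1 - mean_c (2 sum(p_c t_c) + eps) / (sum p_c + sum t_c + eps)`` over the
    given foreground class indices.  Returns (loss, dloss/dlogits).
    """
    p = softmax(logits, axis=1)
    fg = list(foreground_classes)
    dice_terms = []
    dp = np.zeros_like(p)
    for c in fg:
        pc, tc = p[:, c], target_onehot[:, c]
        num = 2.0 * (pc * tc).sum() + eps
        den = pc.sum() + tc.sum() + eps
        dice_terms.append(num / den)
        # d(num/den)/dp_c = (2 t_c den - num) / den^2
        dp[:, c] = -(2.0 * tc * den - num) / (den**2) / len(fg)
    loss = 1.0 - float(np.mean(dice_terms))
    # chain through the channel softmax
    inner = (dp * p).sum(axis=1, keepdims=True)
    dlogits = p * (dp - inner)
    return loss, dlogits


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam with bias correction; state keyed by parameter name."""

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


class _Model:
    """Common surface: flat parameter dict, loss+grads, (de)serialization."""

    layers: list

    def parameters(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for layer in self._param_layers():
            out.update(layer.params)
        return out

    def set_parameters(self, values: dict[str, np.ndarray]) -> None:
        own = self.parameters()
        if set(own) != set(values):
            missing = set(own) ^ set(values)
            raise ValueError(f"parameter name mismatch: {sorted(missing)}")
        for k, v in values.items():
            np.copyto(own[k], v)

    def collect_grads(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for layer in self._param_layers():
            out.update(layer.grads)
        return out

    def _param_layers(self):
        return [l for l in self.layers if l.params]

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.parameters().values())


class MLPClassifier(_Model):
    """Fully connected classifier: ReLU between layers, softmax cross-entropy.

    ``widths = (512, 256, 256, 128, 2)`` reproduces the four-layer feature
    classifier head used on 512-d tile feature vectors.
    """

    def __init__(self, widths=(512, 256, 256, 128, 2), seed=0, bias=True):
        if len(widths) < 2:
            raise ValueError("need at least an input and an output width")
        rng = np.random.default_rng(seed)
        self.widths = tuple(widths)
        self.layers = []
        for i in range(len(widths) - 1):
            lin = Linear(f"fc{i + 1}", widths[i], widths[i + 1], rng)
            if not bias:
                del lin.params[lin._p("bias")]
                lin.backward = _linear_backward_nobias(lin)
            self.layers.append(lin)
            if i < len(widths) - 2:
                self.layers.append(ReLU())

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x):
        return softmax(self.forward(x), axis=1)

    def loss_and_grads(self, x, labels):
        loss, grads, _ = self.loss_grads_input(x, labels)
        return loss, grads

    def loss_grads_input(self, x, labels):
        """Loss, parameter gradients and the gradient w.r.t. the input."""
        logits = self.forward(x)
        loss, dout = softmax_cross_entropy(logits, labels)
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return loss, self.collect_grads(), dout


def _linear_backward_nobias(lin: Linear):
    def backward(dout):
        W = lin.params[lin._p("weight")]
        lin.grads[lin._p("weight")] = dout.T @ lin._x
        return dout @ W

    return backward


class _ConvBlock:
    """conv -> ReLU -> instance norm, twice (the quoted block order)."""

    def __init__(self, name, c_in, c_out, rng):
        self.seq = [
            Conv(f"{name}.conv1", c_in, c_out, 3, 3, 1, rng),
            ReLU(),
            InstanceNorm(f"{name}.norm1", c_out, 3),
            Conv(f"{name}.conv2", c_out, c_out, 3, 3, 1, rng),
            ReLU(),
            InstanceNorm(f"{name}.norm2", c_out, 3),
        ]

    def forward(self, x):
        for l in self.seq:
            x = l.forward(x)
        return x

    def backward(self, d):
        for l in reversed(self.seq):
            d = l.backward(d)
        return d


class UNet3D(_Model):
    """Volumetric U-Net: contraction/expansion with skip concatenation.

    ``levels`` contraction blocks with channel widths ``base * 2**i`` (the
    first convolution maps the input channels directly to ``base``), 2x max
    pooling between levels, nearest-neighbour upsampling and skip
    concatenation on the way up, and a final 1x1x1 convolution to
    ``out_classes`` followed by a channel softmax.  Normalization is
    instance-style, as appropriate for single-volume batches.  Trained with
    the soft Dice loss over the foreground classes.
    """

    def __init__(self, levels=4, base_channels=48, in_channels=4, out_classes=3,
                 spatial=(128, 128, 128), seed=0):
        if levels < 2:
            raise ValueError("a U-Net needs at least 2 levels")
        for s in spatial:
            if s % (2 ** (levels - 1)) != 0:
                raise ValueError(
                    f"spatial size {spatial} not divisible by 2^{levels - 1}"
                )
        rng = np.random.default_rng(seed)
        self.levels = levels
        self.out_classes = out_classes
        self.in_channels = in_channels
        self.spatial = tuple(spatial)
        ch = [base_channels * 2**i for i in range(levels)]
        self._ch = ch
        self.down = []
        c_prev = in_channels
        for i, c in enumerate(ch):
            self.down.append(_ConvBlock(f"down{i + 1}", c_prev, c, rng))
            c_prev = c
        self.pools = [MaxPool3d() for _ in range(levels - 1)]
        self.ups = [NearestUpsample3d() for _ in range(levels - 1)]
        self.up = []
        for i in range(levels - 2, -1, -1):
            # concat(skip c_i, upsampled c_{i+1}) -> c_i
            self.up.append(_ConvBlock(f"up{i + 1}", ch[i] + ch[i + 1], ch[i], rng))
        self.head = Conv("head", ch[0], out_classes, 1, 3, 0, rng)
        self.layers = (
            [l for b in self.down for l in b.seq]
            + [l for b in self.up for l in b.seq]
            + [self.head]
        )

    def forward(self, x):
        skips = []
        for i, block in enumerate(self.down):
            x = block.forward(x)
            if i < self.levels - 1:
                skips.append(x)
                x = self.pools[i].forward(x)
        for j, block in enumerate(self.up):
            x = self.ups[j].forward(x)
            skip = skips[-(j + 1)]
            x = np.concatenate([skip, x], axis=1)
            x = block.forward(x)
        return self.head.forward(x)

    def predict_proba(self, x):
        return softmax(self.forward(x), axis=1)

    def _backward(self, dout):
        d = self.head.backward(dout)
        dskip_by_level: dict[int, np.ndarray] = {}
        for j in range(len(self.up) - 1, -1, -1):
            d = self.up[j].backward(d)
            level = self.levels - 2 - j  # up[j] consumed the skip from this level
            c_skip = self._ch[level]
            dskip_by_level[level] = d[:, :c_skip]
            d = self.ups[j].backward(d[:, c_skip:])
        for i in range(self.levels - 1, -1, -1):
            if i < self.levels - 1:
                d = self.pools[i].backward(d)
                d = d + dskip_by_level[i]
            d = self.down[i].backward(d)
        return d

    def loss_and_grads(self, volume, target_onehot):
        logits = self.forward(volume)
        fg = range(1, self.out_classes)
        loss, dout = soft_dice_loss(logits, target_onehot, fg)
        self._backward(dout)
        return loss, self.collect_grads()


class SmallCNN2d(_Model):
    """Two 3x3 conv layers and a dense softmax head on 2-D patches.

    The miniature classification network used to demonstrate gradient
    inversion on single image patches.  Activations default to sigmoid:
    smooth activations keep the gradient-match landscape well-behaved (with
    ReLU the loss surface fragments into dead-unit regions and inversion
    needs many restarts); ``activation="relu"`` is available for training use.
    """

    def __init__(self, in_channels=1, hidden_channels=4, spatial=(8, 8),
                 n_classes=2, seed=0, activation="sigmoid"):
        rng = np.random.default_rng(seed)
        self.spatial = tuple(spatial)
        self.in_channels = in_channels
        self.conv1 = Conv("conv1", in_channels, hidden_channels, 3, 2, 1, rng)
        self.conv2 = Conv("conv2", hidden_channels, hidden_channels, 3, 2, 1, rng)
        act = {"sigmoid": Sigmoid, "relu": ReLU}[activation]
        self.relu1, self.relu2 = act(), act()
        flat = hidden_channels * spatial[0] * spatial[1]
        self.fc = Linear("fc", flat, n_classes, rng)
        self.layers = [self.conv1, self.relu1, self.conv2, self.relu2, self.fc]

    def forward(self, x):
        h = self.relu1.forward(self.conv1.forward(x))
        h = self.relu2.forward(self.conv2.forward(h))
        self._h_shape = h.shape
        return self.fc.forward(h.reshape(h.shape[0], -1))

    def predict_proba(self, x):
        return softmax(self.forward(x), axis=1)

    def loss_and_grads(self, x, labels):
        loss, grads, _ = self.loss_grads_input(x, labels)
        return loss, grads

    def loss_grads_input(self, x, labels):
        """Loss, parameter gradients and the gradient w.r.t. the input."""
        logits = self.forward(x)
        loss, dout = softmax_cross_entropy(logits, labels)
        d = self.fc.backward(dout).reshape(self._h_shape)
        d = self.conv1.backward(self.relu1.backward(
            self.conv2.backward(self.relu2.backward(d))))
        return loss, self.collect_grads(), d
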