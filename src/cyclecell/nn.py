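"""Minimal CNN building blocks with explicit forward/backward passes.

Everything is NumPy ``float32`` in NCHW layout. A network is a
:class:`Sequential` stack of layers; ``forward`` returns the output together
with a *tape* (per-layer caches) and ``backward`` consumes that tape, so the
same network can be run several times inside one training step (as the
cycle-consistency terms require) without clobbering state. Parameter
gradients are accumulated into ``layer.grads`` only when ``accumulate=True``,
which lets a discriminator be used purely as a differentiable critic when the
generator is being updated.

Convolutions use im2col -> matmul; the col2im backward loops over the k*k
kernel offsets only, so it stays vectorised over the image.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


# ---------------------------------------------------------------------------
# im2col / col2im


# Convolution uses the direct shift-and-add algorithm: one small matmul per
# kernel offset on a strided view of the (padded) input. This avoids
# materialising im2col patch matrices, whose memory traffic dominates at
# these network widths.


# ---------------------------------------------------------------------------
# Layers


class Layer:
    """Base layer: stateless apart from parameters and their gradients."""

    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x):  # -> (y, cache)
        raise NotImplementedError

    def backward(self, dy, cache, accumulate=True):  # -> dx
        raise NotImplementedError

    def zero_grad(self):
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv2d(Layer):
    def __init__(self, in_ch, out_ch, k, stride=1, pad=0, bias=True):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.stride, self.pad = stride, pad
        self.params["W"] = np.zeros((out_ch, in_ch, k, k), dtype=F32)
        self.grads["W"] = np.zeros_like(self.params["W"])
        if bias:
            self.params["b"] = np.zeros(out_ch, dtype=F32)
            self.grads["b"] = np.zeros_like(self.params["b"])

    @property
    def fan_in(self):
        return self.in_ch * self.k * self.k

    @property
    def fan_out(self):
        return self.out_ch * self.k * self.k

    def forward(self, x):
        k, s, pad = self.k, self.stride, self.pad
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
        oh = (xp.shape[2] - k) // s + 1
        ow = (xp.shape[3] - k) // s + 1
        W = self.params["W"]
        y = np.zeros((n, self.out_ch, oh * ow), dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i : i + oh * s : s, j : j + ow * s : s]
                y += W[:, :, i, j] @ xs.reshape(n, c, oh * ow)
        if "b" in self.params:
            y += self.params["b"][:, None]
        return y.reshape(n, self.out_ch, oh, ow), (xp, (n, c, h, w, oh, ow))

    def backward(self, dy, cache, accumulate=True):
        xp, (n, c, h, w, oh, ow) = cache
        k, s, pad = self.k, self.stride, self.pad
        W = self.params["W"]
        dyf = dy.reshape(n, self.out_ch, oh * ow)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i : i + oh * s : s, j : j + ow * s : s]
                if accumulate:
                    self.grads["W"][:, :, i, j] += np.einsum(
                        "nop,ncp->oc", dyf, xs.reshape(n, c, oh * ow))
                dxs = W[:, :, i, j].T @ dyf  # (n, c, oh*ow)
                dxp[:, :, i : i + oh * s : s, j : j + ow * s : s] += dxs.reshape(
                    n, c, oh, ow)
        if accumulate and "b" in self.params:
            self.grads["b"] += dyf.sum(axis=(0, 2))
        if pad:
            return dxp[:, :, pad:-pad, pad:-pad]
        return dxp


class NearestUpsample(Layer):
    def __init__(self, factor=2):
        super().__init__()
        self.f = factor

    def forward(self, x):
        f = self.f
        y = x.repeat(f, axis=2).repeat(f, axis=3)
        return y, x.shape

    def backward(self, dy, cache, accumulate=True):
        n, c, h, w = cache
        f = self.f
        return dy.reshape(n, c, h, f, w, f).sum(axis=(3, 5))


class InstanceNorm(Layer):
    """Per-sample, per-channel normalisation (no affine parameters)."""

    def __init__(self, eps=1e-5):
        super().__init__()
        self.eps = eps

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        y = xc * inv
        return y, (y, inv)

    def backward(self, dy, cache, accumulate=True):
        y, inv = cache
        # d/dx of (x-mu)/sqrt(var+eps)
        return (dy - dy.mean(axis=(2, 3), keepdims=True)
                - y * (dy * y).mean(axis=(2, 3), keepdims=True)) * inv


class ReLU(Layer):
    def forward(self, x):
        m = x > 0
        return x * m, m

    def backward(self, dy, cache, accumulate=True):
        return dy * cache


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        m = x > 0
        return np.where(m, x, F32(self.slope) * x), m

    def backward(self, dy, cache, accumulate=True):
        return np.where(cache, dy, F32(self.slope) * dy)


class Tanh(Layer):
    def forward(self, x):
        y = np.tanh(x)
        return y, y

    def backward(self, dy, cache, accumulate=True):
        return dy * (1.0 - cache * cache)


class Residual(Layer):
    """conv-IN-ReLU-conv-IN with an additive skip connection."""

    def __init__(self, ch):
        super().__init__()
        self.body = Sequential(
            Conv2d(ch, ch, 3, pad=1),
            InstanceNorm(),
            ReLU(),
            Conv2d(ch, ch, 3, pad=1),
            InstanceNorm(),
        )

    # expose inner parameters through the layer interface
    def layers(self):
        return self.body.layers

    def zero_grad(self):
        self.body.zero_grad()

    def forward(self, x):
        y, tape = self.body.forward(x)
        return x + y, tape

    def backward(self, dy, cache, accumulate=True):
        return dy + self.body.backward(dy, cache, accumulate=accumulate)


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        tape = []
        for layer in self.layers:
            x, cache = layer.forward(x)
            tape.append(cache)
        return x, tape

    def backward(self, dy, tape, accumulate=True):
        for layer, cache in zip(reversed(self.layers), reversed(tape)):
            dy = layer.backward(dy, cache, accumulate=accumulate)
        return dy

    def __call__(self, x):
        return self.forward(x)[0]

    # -- parameter plumbing ------------------------------------------------
    def _flat(self):
        out = []
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Residual):
                for j, inner in enumerate(layer.layers()):
                    for k in inner.params:
                        out.append((f"{i}.{j}.{k}", inner))
            else:
                for k in layer.params:
                    out.append((f"{i}.{k}", layer))
        return out

    def parameters(self):
        """List of (name, param_array, grad_array), arrays shared in place."""
        out = []
        for name, layer in self._flat():
            key = name.rsplit(".", 1)[-1]
            out.append((name, layer.params[key], layer.grads[key]))
        return out

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def conv_layers(self):
        convs = []
        for layer in self.layers:
            if isinstance(layer, Conv2d):
                convs.append(layer)
            elif isinstance(layer, Residual):
                convs.extend(l for l in layer.layers() if isinstance(l, Conv2d))
        return convs

    def state_dict(self):
        return {name: p.copy() for name, p, _ in self.parameters()}

    def load_state_dict(self, state):
        for name, p, _ in self.parameters():
            p[...] = state[name]


# ---------------------------------------------------------------------------
# Optimiser


class Adam:
    """Adaptive moment estimation; beta1 is the decay rate of the gradient
    exponential moving average."""

    def __init__(self, net: Sequential, lr=0.002, beta1=0.5, beta2=0.999, eps=1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {n: np.zeros_like(p) for n, p, _ in net.parameters()}
        self.v = {n: np.zeros_like(p) for n, p, _ in net.parameters()}

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        # bias correction degenerates when beta1 == 1 (printed value); guard it
        c1 = 1.0 - b1 ** self.t if b1 < 1.0 else 1.0
        c2 = 1.0 - b2 ** self.t
        for n, p, g in self.net.parameters():
            m = self.m[n]
            v = self.v[n]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def state_dict(self):
        return {
            "t": self.t,
            "m": {k: a.copy() for k, a in self.m.items()},
            "v": {k: a.copy() for k, a in self.v.items()},
        }


# ---------------------------------------------------------------------------
# Initialisation


def glorot_normal_(net: Sequential, rng: np.random.Generator):
    """Per-layer Glorot/Xavier normal: std = sqrt(2/(fan_in+fan_out))."""
    for conv in net.conv_layers():
        std = np.sqrt(2.0 / (conv.fan_in + conv.fan_out))
        conv.params["W"][...] = rng.normal(0.0, std, conv.params["W"].shape).astype(F32)
        if "b" in conv.params:
            conv.params["b"][...] = 0.0


def truncated_normal_(net: Sequential, rng: np.random.Generator, n_in: int, n_out: int):
    """Global truncated normal within +-sqrt(6/(n_in+n_out)).

    The bound equals sqrt(3) times the Glorot std sqrt(2/(n_in+n_out)); samples
    outside the bound are redrawn.
    """
    bound = np.sqrt(6.0 / (n_in + n_out))
    std = np.sqrt(2.0 / (n_in + n_out))
    for conv in net.conv_layers():
        w = conv.params["W"]
        samp = rng.normal(0.0, std, w.shape)
        bad = np.abs(samp) > bound
        while bad.any():
            samp[bad] = rng.normal(0.0, std, int(bad.sum()))
            bad = np.abs(samp) > bound
        w[...] = samp.astype(F32)
        if "b" in conv.params:
            conv.params["b"][...] = 0.0
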