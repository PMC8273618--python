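"""A compact numpy conv-net library for encoder–decoder segmentation.

Implements exactly the pieces the segmentation models need — 2D
convolutions (im2col), batch/instance normalization, ReLU, 2x max pooling,
nearest-neighbour upsampling, spatial (channel) dropout, residual blocks,
and the Adam optimizer — with explicit forward/backward passes. Tensors are
``(batch, channel, row, col)`` float64 arrays; gradients are exact, which
keeps training deterministic given a seed.

The public entry points are the encoder/decoder classes and
:class:`SegNet`, assembled by :func:`ccmorph.model.build_model`.
"""

from __future__ import annotations

import numpy as np

#: Compute dtype for network weights and activations. Single precision is
#: ample for segmentation probabilities and halves memory bandwidth.
DTYPE = np.float32

# ---------------------------------------------------------------------------
# parameters and optimizer


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Adam:
    """Adaptive-moment optimizer (the standard Adam update)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


# ---------------------------------------------------------------------------
# im2col helpers


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp = (x.shape[2] - k) // stride + 1
    wp = (x.shape[3] - k) // stride + 1
    cols = np.empty((n, c, k, k, hp, wp), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + stride * hp : stride, j : j + stride * wp : stride]
    return cols.reshape(n, c * k * k, hp * wp), (hp, wp, x.shape)


def _col2im(gcols: np.ndarray, xpad_shape, k: int, stride: int, hp: int, wp: int, pad: int):
    n, c, h, w = xpad_shape
    g = np.zeros(xpad_shape, dtype=gcols.dtype)
    gc = gcols.reshape(n, c, k, k, hp, wp)
    for i in range(k):
        for j in range(k):
            g[:, :, i : i + stride * hp : stride, j : j + stride * wp : stride] += gc[:, :, i, j]
    if pad:
        g = g[:, :, pad : h - pad, pad : w - pad]
    return g


# ---------------------------------------------------------------------------
# layers


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1, rng=None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in)))
        self.b = Param(np.zeros(cout))
        self.k, self.stride, self.pad = k, stride, k // 2
        self.cin, self.cout = cin, cout

    def forward(self, x, train=False):
        cols, (hp, wp, xpad_shape) = _im2col(x, self.k, self.stride, self.pad)
        self._cache = (cols, hp, wp, xpad_shape)
        y = np.matmul(self.W.value, cols) + self.b.value[:, None]
        return y.reshape(x.shape[0], self.cout, hp, wp)

    def backward(self, gy):
        cols, hp, wp, xpad_shape = self._cache
        n = gy.shape[0]
        gyf = np.ascontiguousarray(gy.reshape(n, self.cout, hp * wp), dtype=DTYPE)
        self.W.grad[...] = np.matmul(gyf, cols.transpose(0, 2, 1)).sum(axis=0)
        self.b.grad[...] = gyf.sum(axis=(0, 2))
        gcols = np.matmul(self.W.value.T, gyf)
        return _col2im(gcols, xpad_shape, self.k, self.stride, hp, wp, self.pad)

    def params(self):
        return [self.W, self.b]


class _NormBase(Layer):
    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def _normalize(self, x, axes, use_stats=None):
        if use_stats is None:
            mean = x.mean(axis=axes, keepdims=True)
            var = x.var(axis=axes, keepdims=True)
        else:
            mean, var = use_stats
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * ivstd
        g = self.gamma.value.reshape(1, -1, 1, 1)
        b = self.beta.value.reshape(1, -1, 1, 1)
        self._cache = (xhat, ivstd, axes, x.shape)
        return g * xhat + b, mean, var

    def _backward_norm(self, gy, trained_stats: bool):
        xhat, ivstd, axes, shape = self._cache
        g = self.gamma.value.reshape(1, -1, 1, 1)
        self.gamma.grad[...] = (gy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad[...] = gy.sum(axis=(0, 2, 3))
        gxhat = gy * g
        if not trained_stats:  # stats were fixed (eval mode): simple scaling
            return gxhat * ivstd
        m = np.prod([shape[ax] for ax in axes])
        return (
            ivstd
            / m
            * (m * gxhat - gxhat.sum(axis=axes, keepdims=True) - xhat * (gxhat * xhat).sum(axis=axes, keepdims=True))
        )


class BatchNorm2d(_NormBase):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__(c, eps)
        self.momentum = momentum
        self.running_mean = np.zeros((1, c, 1, 1), dtype=DTYPE)
        self.running_var = np.ones((1, c, 1, 1), dtype=DTYPE)

    def forward(self, x, train=False):
        if train:
            y, mean, var = self._normalize(x, (0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            self._train_mode = True
        else:
            y, _, _ = self._normalize(x, (0, 2, 3), use_stats=(self.running_mean, self.running_var))
            self._train_mode = False
        return y

    def backward(self, gy):
        return self._backward_norm(gy, trained_stats=self._train_mode)


class InstanceNorm2d(_NormBase):
    """Per-(sample, channel) normalization; same statistics at train and eval."""

    def forward(self, x, train=False):
        y, _, _ = self._normalize(x, (2, 3))
        return y

    def backward(self, gy):
        return self._backward_norm(gy, trained_stats=True)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False):
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._y = out
        return out

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


class MaxPool2(Layer):
    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy):
        n, c, h, w = self._inshape
        g4 = np.zeros((n, c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(g4, self._idx[..., None], gy[..., None], axis=-1)
        return g4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x, train=False):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy):
        n, c, h, w = gy.shape
        return gy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class SpatialDropout2d(Layer):
    """Zeroes whole channels during training; identity at evaluation."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = self.rng.random((x.shape[0], x.shape[1], 1, 1)) >= self.p
        self._mask = (keep / (1.0 - self.p)).astype(DTYPE)
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


# ---------------------------------------------------------------------------
# blocks


def _make_norm(kind: str, c: int) -> _NormBase:
    if kind == "batch":
        return BatchNorm2d(c)
    if kind == "instance":
        return InstanceNorm2d(c)
    raise ValueError(f"unknown normalization {kind!r}")


def double_conv(cin: int, cout: int, norm: str, rng) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, 3, rng=rng),
        _make_norm(norm, cout),
        ReLU(),
        Conv2d(cout, cout, 3, rng=rng),
        _make_norm(norm, cout),
        ReLU(),
    )


class ResidualBlock(Layer):
    """Two 3x3 convolutions with an identity (or projected) shortcut."""

    def __init__(self, cin: int, cout: int, stride: int, norm: str, rng):
        self.main = Sequential(
            Conv2d(cin, cout, 3, stride=stride, rng=rng),
            _make_norm(norm, cout),
            ReLU(),
            Conv2d(cout, cout, 3, rng=rng),
            _make_norm(norm, cout),
        )
        self.shortcut = (
            None
            if cin == cout and stride == 1
            else Sequential(Conv2d(cin, cout, 1, stride=stride, rng=rng), _make_norm(norm, cout))
        )
        self.relu = ReLU()

    def forward(self, x, train=False):
        y = self.main.forward(x, train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train)
        return self.relu.forward(y + s, train)

    def backward(self, gy):
        g = self.relu.backward(gy)
        gx = self.main.backward(g)
        gx = gx + (g if self.shortcut is None else self.shortcut.backward(g))
        return gx

    def params(self):
        ps = self.main.params()
        if self.shortcut is not None:
            ps += self.shortcut.params()
        return ps


# ---------------------------------------------------------------------------
# encoders


class SmallEncoder(Layer):
    """Three down-blocks of double convolutions; downsampling factor 8."""

    def __init__(self, in_ch: int, base: int, norm: str, rng):
        self.stages = [double_conv(in_ch, base, norm, rng)]
        ch = base
        for _ in range(3):
            self.stages.append(Sequential(MaxPool2(), *double_conv(ch, ch * 2, norm, rng).layers))
            ch *= 2
        self.channels = [base * 2**i for i in range(4)]
        self.factor = 8

    def forward(self, x, train=False):
        feats = []
        for stage in self.stages:
            x = stage.forward(x, train)
            feats.append(x)
        return feats

    def backward(self, gfeats):
        gx = None
        for stage, gf in zip(reversed(self.stages), reversed(gfeats)):
            g = gf if gx is None else gf + gx
            gx = stage.backward(g)
        return gx

    def params(self):
        return [p for s in self.stages for p in s.params()]


class ResNetEncoder(SmallEncoder):
    """Residual encoder in the 18/34-layer family; downsampling factor 16.

    ``blocks_per_stage`` is (2, 2, 2, 2) for the 18-layer preset and
    (3, 4, 6, 3) for the 34-layer one.
    """

    def __init__(self, in_ch: int, base: int, blocks_per_stage, norm: str, rng):
        stem = Sequential(Conv2d(in_ch, base, 3, rng=rng), _make_norm(norm, base), ReLU())
        self.stages = [stem]
        self.channels = [base]
        ch = base
        for i, n_blocks in enumerate(blocks_per_stage):
            cout = base * 2 ** min(i, 3)
            layers: list[Layer] = []
            if i == 0:
                layers.append(MaxPool2())
                layers.append(ResidualBlock(ch, cout, 1, norm, rng))
            else:
                layers.append(ResidualBlock(ch, cout, 2, norm, rng))
            for _ in range(n_blocks - 1):
                layers.append(ResidualBlock(cout, cout, 1, norm, rng))
            self.stages.append(Sequential(*layers))
            self.channels.append(cout)
            ch = cout
        self.factor = 16


# ---------------------------------------------------------------------------
# decoders


class UNetDecoder(Layer):
    """Full-resolution decoder with skip concatenation at every level."""

    def __init__(self, enc_channels: list[int], norm: str, dropout: float, rng):
        self.blocks = []
        self.ups = []
        self.drops = []
        ch = enc_channels[-1]
        for skip_ch in reversed(enc_channels[:-1]):
            self.ups.append(Upsample2())
            self.blocks.append(double_conv(ch + skip_ch, skip_ch, norm, rng))
            self.drops.append(SpatialDropout2d(dropout, rng=np.random.default_rng(rng.integers(2**31))))
            ch = skip_ch
        self.head = Conv2d(ch, 1, 1, rng=rng)

    def forward(self, feats, train=False):
        x = feats[-1]
        self._split = []
        for up, block, drop, skip in zip(self.ups, self.blocks, self.drops, reversed(feats[:-1])):
            x = up.forward(x, train)
            self._split.append(x.shape[1])
            x = np.concatenate([x, skip], axis=1)
            x = drop.forward(block.forward(x, train), train)
        return self.head.forward(x, train)

    def backward(self, gy):
        g = self.head.backward(gy)
        gfeats = [None] * (len(self.blocks) + 1)
        for i in range(len(self.blocks) - 1, -1, -1):
            g = self.blocks[i].backward(self.drops[i].backward(g))
            n_up = self._split[i]
            g_up, g_skip = g[:, :n_up], g[:, n_up:]
            gfeats[len(self.blocks) - 1 - i] = g_skip
            g = self.ups[i].backward(g_up)
        gfeats[-1] = g
        return gfeats

    def params(self):
        ps = []
        for up, block in zip(self.ups, self.blocks):
            ps += block.params()
        return ps + self.head.params()


class FPNDecoder(Layer):
    """Pyramid decoder: 1x1 laterals, top-down sums, merged heads, and a
    final upsampling back to input resolution."""

    def __init__(self, enc_channels: list[int], norm: str, dropout: float, rng, pyramid_ch: int | None = None):
        # pyramid levels use every encoder feature except the full-res stem
        self.n_levels = len(enc_channels) - 1
        p = pyramid_ch or max(enc_channels[1], 32)
        self.p = p
        self.laterals = [Conv2d(c, p, 1, rng=rng) for c in enc_channels[1:]]
        self.heads = [Sequential(Conv2d(p, p, 3, rng=rng), ReLU()) for _ in range(self.n_levels)]
        self.merge = Sequential(Conv2d(p, p, 3, rng=rng), _make_norm(norm, p), ReLU())
        self.drop = SpatialDropout2d(dropout, rng=np.random.default_rng(rng.integers(2**31)))
        self.final_up = Upsample2()
        self.out = Conv2d(p, 1, 1, rng=rng)

    def forward(self, feats, train=False):
        pyr = [lat.forward(f, train) for lat, f in zip(self.laterals, feats[1:])]
        # top-down pathway: upsample the coarser map and add
        self._updowns = []
        for i in range(self.n_levels - 2, -1, -1):
            up = Upsample2()
            pyr[i] = pyr[i] + up.forward(pyr[i + 1], train)
            self._updowns.append(up)
        outs = [head.forward(pz, train) for head, pz in zip(self.heads, pyr)]
        # bring every level to the finest pyramid resolution and sum
        self._level_ups = []
        acc = outs[0]
        for i in range(1, self.n_levels):
            ups = [Upsample2() for _ in range(i)]
            x = outs[i]
            for u in ups:
                x = u.forward(x, train)
            self._level_ups.append(ups)
            acc = acc + x
        x = self.merge.forward(acc, train)
        x = self.drop.forward(x, train)
        x = self.final_up.forward(x, train)
        return self.out.forward(x, train)

    def backward(self, gy):
        g = self.out.backward(gy)
        g = self.final_up.backward(g)
        g = self.drop.backward(g)
        gacc = self.merge.backward(g)
        gouts = [gacc]
        for ups in self._level_ups:
            gx = gacc
            for u in reversed(ups):
                gx = u.backward(gx)
            gouts.append(gx)
        gpyr = [head.backward(go) for head, go in zip(self.heads, gouts)]
        # reverse the top-down pathway (built from coarse to fine)
        for up, i in zip(reversed(self._updowns), range(self.n_levels - 1)):
            gpyr[i + 1] = gpyr[i + 1] + up.backward(gpyr[i])
        gfeats = [None] + [lat.backward(gp) for lat, gp in zip(self.laterals, gpyr)]
        gfeats[0] = np.zeros(self._f0_shape, dtype=DTYPE)
        return gfeats

    def params(self):
        ps = [p for lat in self.laterals for p in lat.params()]
        ps += [p for head in self.heads for p in head.params()]
        return ps + self.merge.params() + self.out.params()


# ---------------------------------------------------------------------------
# assembled network


class SegNet:
    """Encoder–decoder segmentation network emitting per-pixel probabilities."""

    def __init__(self, encoder: Layer, decoder: Layer):
        self.encoder = encoder
        self.decoder = decoder
        self.sigmoid = Sigmoid()
        self.factor = encoder.factor

    def check_input(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if h % self.factor or w % self.factor:
            raise ValueError(
                f"tile sides must be multiples of the encoder downsampling factor "
                f"{self.factor}; got {h}x{w}"
            )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        self.check_input(x.shape[2:])
        feats = self.encoder.forward(x, train)
        if isinstance(self.decoder, FPNDecoder):
            self.decoder._f0_shape = feats[0].shape
        logits = self.decoder.forward(feats, train)
        return self.sigmoid.forward(logits, train)

    def backward(self, gp: np.ndarray) -> None:
        gy = self.sigmoid.backward(np.asarray(gp, dtype=DTYPE))
        gfeats = self.decoder.backward(gy)
        self.encoder.backward(gfeats)

    def params(self) -> list[Param]:
        return self.encoder.params() + self.decoder.params()

    def predict(self, tile: np.ndarray) -> np.ndarray:
        """Probability map for a single 2D tile (evaluation mode)."""
        tile = np.asarray(tile, dtype=DTYPE)
        out = self.forward(tile[None, None], train=False)
        return out[0, 0].astype(np.float64)

    def predict_batch(self, tiles: np.ndarray) -> np.ndarray:
        """Probability maps for a stack of 2D tiles ``(n, H, W)``."""
        out = self.forward(np.asarray(tiles, dtype=DTYPE)[:, None], train=False)
        return out[:, 0].astype(np.float64)

    # -- serialization ------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.value for i, p in enumerate(self.params())}
        i = 0
        for layer in _iter_layers(self):
            if isinstance(layer, BatchNorm2d):
                state[f"running_mean_{i}"] = layer.running_mean
                state[f"running_var_{i}"] = layer.running_var
                i += 1
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"param_{i}"]
        i = 0
        for layer in _iter_layers(self):
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"running_mean_{i}"]
                layer.running_var[...] = state[f"running_var_{i}"]
                i += 1


def _iter_layers(net: SegNet):
    """Depth-first walk over every primitive layer of the network."""
    stack: list = [net.encoder, net.decoder]
    while stack:
        obj = stack.pop()
        yield obj
        for attr in ("stages", "layers", "blocks", "ups", "drops", "laterals", "heads"):
            children = getattr(obj, attr, None)
            if children:
                stack.extend(children)
        for attr in ("main", "shortcut", "relu", "head", "merge", "drop", "final_up", "out"):
            child = getattr(obj, attr, None)
            if child is not None:
                stack.append(child)
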