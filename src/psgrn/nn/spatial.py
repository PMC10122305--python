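"""Convolutional spatial-feature modules over the merged pair matrix.

Three interchangeable wirings, all mapping a one-channel image
(B, 1, H, W) to a fixed-length feature vector via global average pooling:

* ``DenseNetModule`` — dense blocks in which every layer receives the
  channel-concatenation of all preceding feature maps in its block,
  separated by 1×1-conv + 2×2-average-pool transition layers that
  compress channels and halve the spatial dimensions.
* ``VGGModule`` — plain stacked 3×3 conv/ReLU pairs with pooling.
* ``ResNetModule`` — residual blocks with identity skip connections.

The output length depends only on the channel bookkeeping of the
configuration, never on the input height/width (above the documented
minimum needed to survive the downsampling stages).
"""

from __future__ import annotations

import numpy as np

from .core import AvgPool2d, BatchNorm2d, Conv2d, GlobalAvgPool2d, Module, ReLU


class ValidationError(ValueError):
    pass


class _ConvReLU(Module):
    """Conv → batch-norm → ReLU composite unit."""

    def __init__(self, rng, in_ch, out_ch, kernel=3, stride=1, pad=1):
        self.conv = Conv2d(rng, in_ch, out_ch, kernel, stride, pad)
        self.bn = BatchNorm2d(out_ch)
        self.relu = ReLU()

    def forward(self, x):
        return self.relu.forward(self.bn.forward(self.conv.forward(x)))

    def backward(self, dout):
        return self.conv.backward(self.bn.backward(self.relu.backward(dout)))


class _DenseBlock(Module):
    """Dense connectivity: layer k sees in_ch + (k-1)·growth input channels."""

    def __init__(self, rng, in_ch: int, n_layers: int, growth: int):
        self.layers = [
            _ConvReLU(rng, in_ch + i * growth, growth) for i in range(n_layers)
        ]
        self.in_ch = in_ch
        self.growth = growth
        self.out_ch = in_ch + n_layers * growth
        self._n_inputs: list[int] = []

    @property
    def layer_input_channels(self) -> list[int]:
        return [self.in_ch + i * self.growth for i in range(len(self.layers))]

    def forward(self, x):
        feats = [x]
        for layer in self.layers:
            inp = np.concatenate(feats, axis=1) if len(feats) > 1 else feats[0]
            feats.append(layer.forward(inp))
        self._n_inputs = [f.shape[1] for f in feats]
        return np.concatenate(feats, axis=1)

    def backward(self, dout):
        sizes = self._n_inputs
        bounds = np.cumsum(sizes)
        grads = [
            dout[:, (0 if i == 0 else bounds[i - 1]) : bounds[i]].copy()
            for i in range(len(sizes))
        ]
        for k in range(len(self.layers) - 1, -1, -1):
            dinp = self.layers[k].backward(grads[k + 1])
            # dinp covers the concatenation of feats[0..k]
            off = 0
            for i in range(k + 1):
                grads[i] += dinp[:, off : off + sizes[i]]
                off += sizes[i]
        return grads[0]


class DenseNetModule(Module):
    """Initial stride-2 conv + pool, dense blocks with transitions, global pool."""

    def __init__(
        self,
        rng: np.random.Generator,
        n_blocks: int = 3,
        layers_per_block: int = 4,
        growth: int = 12,
        num_init: int = 16,
        compression: float = 0.5,
        input_width: int | None = None,
    ):
        # narrow merged matrices (short time lags) keep their width through
        # the stem; only the time axis is downsampled
        narrow = input_width is not None and input_width < 16
        self.min_input = 4 if narrow else 4 * 2 ** (n_blocks - 1)
        self.stem = _ConvReLU(rng, 1, num_init, stride=(2, 1) if narrow else 2)
        self.stem_pool = AvgPool2d((2, 1) if narrow else 2)
        self.blocks: list[Module] = []
        ch = num_init
        for b in range(n_blocks):
            block = _DenseBlock(rng, ch, layers_per_block, growth)
            ch = block.out_ch
            self.blocks.append(block)
            if b < n_blocks - 1:
                trans_ch = max(1, int(ch * compression))
                self.blocks.append(_ConvReLU(rng, ch, trans_ch, kernel=1, pad=0))
                self.blocks.append(AvgPool2d(2))
                ch = trans_ch
        self.gap = GlobalAvgPool2d()
        self.out_dim = ch

    def forward(self, x):
        if min(x.shape[2], x.shape[3]) < self.min_input:
            raise ValidationError(
                f"input spatial size {x.shape[2]}x{x.shape[3]} below the minimum "
                f"{self.min_input} required by the downsampling stages"
            )
        h = self.stem_pool.forward(self.stem.forward(x))
        for m in self.blocks:
            h = m.forward(h)
        return self.gap.forward(h)

    def backward(self, dout):
        d = self.gap.backward(dout)
        for m in reversed(self.blocks):
            d = m.backward(d)
        return self.stem.backward(self.stem_pool.backward(d))


class VGGModule(Module):
    """Two conv/conv/pool stages of 3×3 filters, then global average pooling."""

    def __init__(self, rng: np.random.Generator, width: int = 16):
        self.min_input = 8
        self.stages = [
            _ConvReLU(rng, 1, width),
            _ConvReLU(rng, width, width),
            AvgPool2d(2),
            _ConvReLU(rng, width, 2 * width),
            _ConvReLU(rng, 2 * width, 2 * width),
            AvgPool2d(2),
        ]
        self.gap = GlobalAvgPool2d()
        self.out_dim = 2 * width

    def forward(self, x):
        if min(x.shape[2], x.shape[3]) < self.min_input:
            raise ValidationError(
                f"input spatial size below the minimum {self.min_input}"
            )
        h = x
        for m in self.stages:
            h = m.forward(h)
        return self.gap.forward(h)

    def backward(self, dout):
        d = self.gap.backward(dout)
        for m in reversed(self.stages):
            d = m.backward(d)
        return d


class _ResBlock(Module):
    def __init__(self, rng, ch):
        self.c1 = _ConvReLU(rng, ch, ch)
        self.c2 = Conv2d(rng, ch, ch)
        self.bn2 = BatchNorm2d(ch)
        self.relu = ReLU()

    def forward(self, x):
        return self.relu.forward(self.bn2.forward(self.c2.forward(self.c1.forward(x))) + x)

    def backward(self, dout):
        d = self.relu.backward(dout)
        return self.c1.backward(self.c2.backward(self.bn2.backward(d))) + d


class ResNetModule(Module):
    """Stride-2 stem plus two identity-skip residual blocks with pooling."""

    def __init__(self, rng: np.random.Generator, width: int = 16):
        self.min_input = 8
        self.stem = _ConvReLU(rng, 1, width, stride=2)
        self.block1 = _ResBlock(rng, width)
        self.pool = AvgPool2d(2)
        self.block2 = _ResBlock(rng, width)
        self.gap = GlobalAvgPool2d()
        self.out_dim = width

    def forward(self, x):
        if min(x.shape[2], x.shape[3]) < self.min_input:
            raise ValidationError(
                f"input spatial size below the minimum {self.min_input}"
            )
        h = self.stem.forward(x)
        h = self.block1.forward(h)
        h = self.pool.forward(h)
        h = self.block2.forward(h)
        return self.gap.forward(h)

    def backward(self, dout):
        d = self.gap.backward(dout)
        d = self.block2.backward(d)
        d = self.pool.backward(d)
        d = self.block1.backward(d)
        return self.stem.backward(d)
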