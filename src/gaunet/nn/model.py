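"""U-shaped segmentation network assembled from an :class:`ArchitectureSpec`."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ..architecture import ArchitectureSpec
from ..errors import ShapeError
from ..genome import ACTIVATION_NAMES, POOLING_NAMES
from .layers import (
    DTYPE,
    Activation,
    BatchNorm2D,
    Conv2D,
    ConvTranspose2D,
    Dropout,
    Param,
    Pool2D,
    Sigmoid,
)

__all__ = ["UNet"]


class _Block:
    """Two convolutions, each (optionally BN then) activated, optional dropout."""

    def __init__(self, cin, cout, spec: ArchitectureSpec, rng, dtype=DTYPE):
        act = ACTIVATION_NAMES[spec.activation]
        self.layers = []
        for conv_in in (cin, cout):
            self.layers.append(Conv2D(conv_in, cout, spec.kernel_size, rng, dtype))
            if spec.use_bn:
                self.layers.append(BatchNorm2D(cout, dtype=dtype))
            self.layers.append(Activation(act))
        if spec.use_dropout:
            self.layers.append(
                Dropout(spec.dropout_rate, np.random.default_rng(rng.integers(2**31)))
            )

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def extra_state_size(self):
        return sum(layer.extra_state_size() for layer in self.layers)


class UNet:
    """Encoder-decoder network with skip connections, built from a spec.

    Weight initialization is fully determined by ``seed``.  Inputs are
    channel-last ``(N, H, W, C)`` (or ``(N, H, W)`` for single-channel)
    arrays; spatial dimensions must be divisible by ``2**depth``.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0, dtype=DTYPE):
        self.spec = spec
        rng = np.random.default_rng(seed)
        pool_kind = POOLING_NAMES[spec.pooling]
        d = spec.depth

        self.enc_blocks, self.pools = [], []
        cin = spec.in_channels
        for c in spec.encoder_channels:
            self.enc_blocks.append(_Block(cin, c, spec, rng, dtype))
            self.pools.append(Pool2D(pool_kind))
            cin = c
        self.bottleneck = _Block(cin, spec.bottleneck_channels, spec, rng, dtype)

        # decoder level l (0 = shallowest) upsamples from the next-deeper width
        self.upconvs, self.dec_blocks = [None] * d, [None] * d
        cin = spec.bottleneck_channels
        for level in reversed(range(d)):
            c = spec.encoder_channels[level]
            self.upconvs[level] = ConvTranspose2D(cin, c, rng, dtype)
            self.dec_blocks[level] = _Block(2 * c, c, spec, rng, dtype)
            cin = c
        self.out_conv = Conv2D(cin, spec.n_classes, 1, rng, dtype)
        self.sigmoid = Sigmoid()

    # -- plumbing ----------------------------------------------------------

    def _all_blocks(self):
        return self.enc_blocks + [self.bottleneck] + self.dec_blocks

    def parameters(self) -> list[Param]:
        params = []
        for block in self._all_blocks():
            params.extend(block.params())
        for up in self.upconvs:
            params.extend(up.params())
        params.extend(self.out_conv.params())
        return params

    def param_count(self) -> int:
        """Total parameters of the allocated arrays, including BN running stats."""
        trainable = sum(p.size for p in self.parameters())
        extra = sum(block.extra_state_size() for block in self._all_blocks())
        return trainable + extra

    # -- forward / backward -------------------------------------------------

    def _to_nchw(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images)
        if x.ndim == 3:
            x = x[..., None]
        if x.ndim != 4 or x.shape[-1] != self.spec.in_channels:
            raise ShapeError(
                f"expected (N, H, W, {self.spec.in_channels}) input, got {x.shape}"
            )
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2), dtype=DTYPE)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """NCHW batch -> NCHW probability maps."""
        divisor = 2**self.spec.depth
        h, w = x.shape[2], x.shape[3]
        if h % divisor or w % divisor:
            raise ShapeError(
                f"input spatial size {h}x{w} must be divisible by {divisor}"
            )
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            x = block.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.bottleneck.forward(x, training)
        for level in reversed(range(self.spec.depth)):
            x = self.upconvs[level].forward(x, training)
            x = np.concatenate([x, skips[level]], axis=1)
            x = self.dec_blocks[level].forward(x, training)
        x = self.out_conv.forward(x, training)
        return self.sigmoid.forward(x, training)

    def backward(self, dprob: np.ndarray) -> None:
        """Backpropagate d(loss)/d(probabilities); fills parameter grads."""
        d = self.sigmoid.backward(dprob)
        d = self.out_conv.backward(d)
        dskips = [None] * self.spec.depth
        for level in range(self.spec.depth):
            d = self.dec_blocks[level].backward(d)
            c = self.spec.encoder_channels[level]
            d, dskips[level] = d[:, :c], d[:, c:]
            d = self.upconvs[level].backward(d)
        d = self.bottleneck.backward(d)
        for level in reversed(range(self.spec.depth)):
            d = self.pools[level].backward(d)
            d = d + dskips[level]
            d = self.enc_blocks[level].backward(d)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Channel-last images -> (N, H, W) foreground probabilities."""
        probs = self.forward(self._to_nchw(images), training=False)
        return probs[:, 0] if self.spec.n_classes == 1 else probs.transpose(0, 2, 3, 1)

    # -- persistence ---------------------------------------------------------

    def _state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.parameters())}
        i = 0
        for block in self._all_blocks():
            for layer in block.layers:
                if isinstance(layer, BatchNorm2D):
                    arrays[f"bn_mean_{i}"] = layer.running_mean
                    arrays[f"bn_var_{i}"] = layer.running_var
                    i += 1
        return arrays

    def save_weights(self, path) -> None:
        np.savez(Path(path), **self._state_arrays())

    def load_weights(self, path) -> None:
        with np.load(Path(path)) as data:
            for key, array in self._state_arrays().items():
                if key not in data or data[key].shape != array.shape:
                    raise ShapeError(f"weights file does not match model at {key!r}")
                array[...] = data[key]
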