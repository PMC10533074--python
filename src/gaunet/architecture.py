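"""Decoding genomes into U-shaped network plans and exact parameter accounting.

A genome with ``B = 2d + 1`` blocks decodes into ``d`` encoder levels, one
bottleneck and ``d`` mirrored decoder levels.  Channel widths double on the
way down (``C, 2C, ..., C*2^(d-1)``, bottleneck ``C*2^d``) and halve on the
way up; every block holds two same-padded ``FxF`` convolutions, each
optionally followed by batch normalization and then the activation.  Skip
connections concatenate each encoder level's output into the same-level
decoder input; down/up-sampling use 2x2 stride-2 pooling and transposed
convolution; the head is a 1x1 convolution with a sigmoid.

Parameter accounting conventions (closed forms per layer):

* ``k x k`` convolution, ``cin -> cout``:     ``k*k*cin*cout + cout``
* 2x2 transposed convolution, ``cin -> cout``: ``4*cin*cout + cout``
* batch normalization over ``c`` channels:     ``4*c`` (scale, shift and the
  two running statistics)
* pooling / activation / concat / dropout:     0

The millions figures quoted for model sizes use truncation, not rounding.
"""

from __future__ import annotations

import dataclasses
import io
import math
from typing import Optional

import pandas as pd

from .errors import GenomeError
from .genome import Genome, SearchSpace, validate_genome

__all__ = [
    "ArchitectureSpec",
    "LayerDescriptor",
    "decode_architecture",
    "layer_plan",
    "count_parameters",
    "unet_baseline_spec",
    "count_parameters_unet_baseline",
    "params_in_millions",
    "percent_of_baseline",
    "percent_fewer",
    "build_network",
    "summary_text",
    "summary_dataframe",
]


@dataclasses.dataclass(frozen=True)
class ArchitectureSpec:
    """Concrete U-shaped layer plan decoded from a genome."""

    depth: int
    in_channels: int
    n_classes: int
    encoder_channels: tuple[int, ...]
    bottleneck_channels: int
    kernel_size: int
    activation: int
    pooling: int
    use_bn: bool
    use_dropout: bool
    dropout_rate: float = 0.3

    @property
    def decoder_channels(self) -> tuple[int, ...]:
        """Mirror of the encoder channel sequence (halving on the way up)."""
        return tuple(reversed(self.encoder_channels))

    @property
    def n_blocks(self) -> int:
        return 2 * self.depth + 1


@dataclasses.dataclass(frozen=True)
class LayerDescriptor:
    """One parameterizable (or structural) layer of the decoded plan."""

    kind: str  # conv | bn | activation | pool | upconv | concat | dropout | output
    kernel: int
    cin: int
    cout: int
    params: int


def decode_architecture(
    g: Genome,
    in_channels: int = 1,
    n_classes: int = 1,
    space: Optional[SearchSpace] = None,
) -> ArchitectureSpec:
    """Decode a valid genome into an :class:`ArchitectureSpec`."""
    validate_genome(g, space)
    if in_channels < 1:
        raise GenomeError(f"in_channels must be >= 1, got {in_channels}")
    if n_classes < 1:
        raise GenomeError(f"n_classes must be >= 1, got {n_classes}")
    d = g.depth
    enc = tuple(g.first_filters * 2**level for level in range(d))
    return ArchitectureSpec(
        depth=d,
        in_channels=in_channels,
        n_classes=n_classes,
        encoder_channels=enc,
        bottleneck_channels=g.first_filters * 2**d,
        kernel_size=g.kernel_size,
        activation=g.activation,
        pooling=g.pooling,
        use_bn=bool(g.batch_norm),
        use_dropout=bool(g.dropout),
    )


def _conv_params(k: int, cin: int, cout: int) -> int:
    return k * k * cin * cout + cout


def _block_layers(
    spec: ArchitectureSpec, cin: int, cout: int
) -> list[LayerDescriptor]:
    """Two convolutions, each optionally with BN, each with an activation."""
    k = spec.kernel_size
    layers: list[LayerDescriptor] = []
    for conv_in in (cin, cout):
        layers.append(
            LayerDescriptor("conv", k, conv_in, cout, _conv_params(k, conv_in, cout))
        )
        if spec.use_bn:
            layers.append(LayerDescriptor("bn", 0, cout, cout, 4 * cout))
        layers.append(LayerDescriptor("activation", 0, cout, cout, 0))
    if spec.use_dropout:
        layers.append(LayerDescriptor("dropout", 0, cout, cout, 0))
    return layers


def layer_plan(spec: ArchitectureSpec) -> list[LayerDescriptor]:
    """Flatten the spec into an ordered list of layer descriptors."""
    layers: list[LayerDescriptor] = []
    cin = spec.in_channels
    for c in spec.encoder_channels:
        layers.extend(_block_layers(spec, cin, c))
        layers.append(LayerDescriptor("pool", 2, c, c, 0))
        cin = c
    layers.extend(_block_layers(spec, cin, spec.bottleneck_channels))
    cin = spec.bottleneck_channels
    for c in spec.decoder_channels:
        layers.append(LayerDescriptor("upconv", 2, cin, c, 4 * cin * c + c))
        layers.append(LayerDescriptor("concat", 0, 2 * c, 2 * c, 0))
        layers.extend(_block_layers(spec, 2 * c, c))
        cin = c
    layers.append(
        LayerDescriptor(
            "output", 1, cin, spec.n_classes, cin * spec.n_classes + spec.n_classes
        )
    )
    return layers


def count_parameters(spec: ArchitectureSpec) -> int:
    """Total parameter count (trainable plus batch-norm running statistics)."""
    return sum(layer.params for layer in layer_plan(spec))


def unet_baseline_spec(in_channels: int = 1, n_classes: int = 1) -> ArchitectureSpec:
    """The original hand-designed U-Net: 4 levels at 64..512, bottleneck 1024,
    two 3x3 convolutions per block, no batch normalization."""
    return ArchitectureSpec(
        depth=4,
        in_channels=in_channels,
        n_classes=n_classes,
        encoder_channels=(64, 128, 256, 512),
        bottleneck_channels=1024,
        kernel_size=3,
        activation=1,
        pooling=1,
        use_bn=False,
        use_dropout=False,
    )


def count_parameters_unet_baseline(in_channels: int = 1) -> int:
    return count_parameters(unet_baseline_spec(in_channels))


def params_in_millions(count: int) -> float:
    """Parameter count in millions, truncated (floored): 3 decimals below one
    million, 2 decimals otherwise — the convention behind figures like 0.076
    and 31.03."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if count < 1_000_000:
        return (count // 1_000) / 1_000
    return (count // 10_000) / 100


def _truncate_percent(fraction: float) -> float:
    return math.floor(fraction * 100 * 100) / 100


def percent_of_baseline(count: int, baseline: int) -> float:
    """Model size as a percentage of a baseline count, truncated to 2 decimals."""
    return _truncate_percent(count / baseline)


def percent_fewer(count: int, baseline: int) -> float:
    """Parameter reduction vs. a baseline, in percent truncated to 2 decimals."""
    return _truncate_percent(1.0 - count / baseline)


def build_network(spec: ArchitectureSpec, seed: int = 0):
    """Instantiate a trainable network for the plan (see :mod:`gaunet.nn`)."""
    from .nn import UNet

    return UNet(spec, seed=seed)


def summary_dataframe(spec: ArchitectureSpec) -> pd.DataFrame:
    """One row per layer: kind, kernel, cin, cout, params."""
    return pd.DataFrame([dataclasses.asdict(layer) for layer in layer_plan(spec)])


def summary_text(spec: ArchitectureSpec) -> str:
    df = summary_dataframe(spec)
    total = int(df["params"].sum())
    buf = io.StringIO()
    buf.write(
        f"U-shaped network: depth={spec.depth}, blocks={spec.n_blocks}, "
        f"in_channels={spec.in_channels}, kernel={spec.kernel_size}x{spec.kernel_size}\n"
    )
    buf.write(df.to_string(index=False))
    buf.write(f"\ntotal parameters: {total:,} ({params_in_millions(total)} M)\n")
    return buf.getvalue()
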