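"""Convolution-layer complexity counters.

Standalone utilities scoring user-supplied layer shapes with the standard
conv-layer cost formulas: multiply-accumulate FLOPs
``2 * H * W * (C_in * K**2 + 1) * C_out`` (the ``+ 1`` is the bias term) and
weight count ``C_in * K**2 * C_out``. ``H`` and ``W`` are the height and
width of the feature map the kernel slides over. All arithmetic is integer
and exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["ConvLayerSpec", "conv_flops", "conv_params", "score_layers"]


@dataclass(frozen=True)
class ConvLayerSpec:
    """Shape of one convolutional layer."""

    H: int
    W: int
    K: int
    C_in: int
    C_out: int

    def __post_init__(self) -> None:
        for name in ("H", "W", "K", "C_in", "C_out"):
            value = getattr(self, name)
            if not isinstance(value, int) or value <= 0:
                raise ValueError(f"{name} must be a positive integer")


def conv_flops(spec: ConvLayerSpec) -> int:
    """Floating-point operations of one convolution (with bias)."""
    return 2 * spec.H * spec.W * (spec.C_in * spec.K**2 + 1) * spec.C_out


def conv_params(spec: ConvLayerSpec) -> int:
    """Weight count of one convolution (bias excluded)."""
    return spec.C_in * spec.K**2 * spec.C_out


def score_layers(layers: pd.DataFrame) -> pd.DataFrame:
    """Score a table of layer shapes (columns H, W, K, C_in, C_out)."""
    out = layers.copy()
    specs = [
        ConvLayerSpec(int(r.H), int(r.W), int(r.K), int(r.C_in), int(r.C_out))
        for r in layers.itertuples()
    ]
    out["flops"] = [conv_flops(s) for s in specs]
    out["params"] = [conv_params(s) for s in specs]
    return out
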