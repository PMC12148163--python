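"""Parameter and FLOP accounting with per-layer profiles.

Conventions (frozen after calibrating against the baseline detector's
published budget row; see docs/methods.md):

* **Parameters.**  A convolution contributes ``C_out * K_h * K_w * C_in / g``
  weights, plus ``C_out`` bias terms only when it actually carries a bias
  (convolutions followed by BatchNorm are bias-free), plus ``2 * C_out`` BN
  affine terms when BN is present.  Pooling, upsampling, concatenation and
  activations are parameter-free.
* **FLOPs.**  A convolution contributes
  ``F_h * F_w * C_out * (2 * K_h * K_w * C_in / g + bias)`` where (F_h, F_w)
  is the *output* map size -- one multiply and one add per weight, one add for
  the bias.  This is the standard profiler (thop) convention.  The textbook
  formula with ``(2k^2 - 1)`` multiply-adds is available as
  ``convention="macs-1"`` but does not reproduce the published budgets.

Totals are exact integer sums converted to MegaParams / GigaFLOPs and rounded
to 2 / 1 decimals for table comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import blocks as _blocks
from .assembly import ModelGraph


@dataclass(frozen=True)
class ConvSpec:
    """Static description of one convolution layer."""

    in_channels: int
    out_channels: int
    kernel: int = 1
    stride: int = 1
    groups: int = 1
    activation: str = "silu"
    has_bn: bool = True
    has_bias: bool = False

    def __post_init__(self):
        if self.in_channels and self.in_channels % self.groups:
            raise ValueError(
                f"in_channels {self.in_channels} not divisible by groups {self.groups}")
        if self.kernel % 2 == 0:
            raise ValueError(f"kernel must be odd, got {self.kernel}")
        if self.stride not in (1, 2):
            raise ValueError(f"stride must be 1 or 2, got {self.stride}")


def count_layer_params(spec: ConvSpec) -> int:
    """Trainable parameters of one conv layer (weights + bias + BN affine)."""
    p = spec.out_channels * (spec.kernel * spec.kernel * spec.in_channels
                             // spec.groups)
    if spec.has_bias:
        p += spec.out_channels
    if spec.has_bn:
        p += 2 * spec.out_channels
    return p


def count_layer_flops(spec: ConvSpec, out_h: int, out_w: int,
                      convention: str = "macs") -> int:
    """FLOPs of one conv layer at the given output map size.

    ``macs``   : 2 ops per weight (+1 per bias) -- the calibrated default.
    ``macs-1`` : (2k^2 - 1) per input-channel column (+1), the literal
                 textbook count of multiplies and adds.
    """
    k2cin = spec.kernel * spec.kernel * spec.in_channels // spec.groups
    if convention == "macs":
        per_px = 2 * k2cin + (1 if spec.has_bias else 0)
    elif convention == "macs-1":
        per_px = (spec.in_channels * (2 * spec.kernel ** 2 - 1)) // spec.groups + 1
    else:
        raise ValueError(f"unknown FLOP convention {convention!r}")
    return out_h * out_w * spec.out_channels * per_px


@dataclass
class LayerProfile:
    name: str
    kind: str
    in_shape: tuple
    out_shape: tuple
    params: int
    flops: int


@dataclass
class ModelProfile:
    layers: list[LayerProfile]
    input_size: int
    total_params: int = 0
    total_flops: int = 0

    def __post_init__(self):
        self.total_params = sum(l.params for l in self.layers)
        self.total_flops = sum(l.flops for l in self.layers)

    @property
    def total_params_M(self) -> float:
        return round(self.total_params / 1e6, 2)

    @property
    def total_flops_G(self) -> float:
        return round(self.total_flops / 1e9, 1)

    def as_rows(self):
        for l in self.layers:
            yield (l.name, l.kind, l.in_shape, l.out_shape, l.params, l.flops)


def _rows_to_profile(rows: list[dict], input_size: int,
                     convention: str = "macs") -> ModelProfile:
    layers = []
    for r in rows:
        spec = ConvSpec(r["cin"], r["cout"], r["k"], 1, max(r["groups"], 1),
                        has_bn=r["bn"], has_bias=r["bias"])
        params = count_layer_params(spec) if r["cin"] else 2 * r["cout"]  # BN-only
        flops = count_layer_flops(spec, r["oh"], r["ow"], convention) if r["cin"] else 0
        kind = "bn" if not r["cin"] else (f"conv{r['k']}x{r['k']}"
                                          + ("dw" if r["groups"] > 1 else ""))
        layers.append(LayerProfile(r["name"], kind,
                                   (r["cin"], r["oh"], r["ow"]),
                                   (r["cout"], r["oh"], r["ow"]), params, flops))
    return ModelProfile(layers, input_size)


def profile_model(model: ModelGraph, input_size: int | None = None,
                  convention: str = "macs") -> ModelProfile:
    """Profile a model by symbolic shape propagation (no data is computed)."""
    size = input_size or model.spec.input_size
    if size % 32:
        raise ValueError(f"input size must be a multiple of 32, got {size}")
    rows = model.profile_layers(size)
    prof = _rows_to_profile(rows, size, convention)
    return prof


def profile_by_forward(model: ModelGraph, input_size: int,
                       convention: str = "macs") -> ModelProfile:
    """Profile by executing a real forward pass with operator hooks.

    Every convolution that actually runs records its true output shape; the
    result is an independent cross-check of :func:`profile_model` (the two
    routes share no shape arithmetic).  BN-only branches and the fixed DFL
    projection are appended from the model's parameter registry so parameter
    totals are comparable.
    """
    from . import autodiff as ad
    sink: list[dict] = []
    _blocks._PROFILE_SINK = sink
    try:
        was_training = model.training
        model.eval()
        with ad.no_grad():
            model(np.zeros((1, 3, input_size, input_size), dtype=np.float32))
        if was_training:
            model.train()
    finally:
        _blocks._PROFILE_SINK = None
    prof = _rows_to_profile(sink, input_size, convention)
    # hooks only see convs; add the remaining registered parameters
    # (RepConv identity-branch BN, DFL projection) as zero-FLOP rows
    seen = prof.total_params
    rest = model.num_params() - seen
    if rest:
        prof.layers.append(LayerProfile("non-conv-params", "other", (), (), rest, 0))
        prof.total_params += rest
    return prof


def reduction(base: ModelProfile, other: ModelProfile) -> tuple[float, float]:
    """Percentage reductions (params, FLOPs) of `other` relative to `base`.

    Computed on the table-rounded M/G values, which is how the published
    percentages were derived (e.g. 3.01 -> 1.34 M gives 55.5 %).
    """
    if base.input_size != other.input_size:
        raise ValueError("profiles were taken at different input sizes")
    if base.total_params_M <= 0 or base.total_flops_G <= 0:
        raise ValueError("base profile has zero totals")
    p = 100.0 * (1.0 - other.total_params_M / base.total_params_M)
    f = 100.0 * (1.0 - other.total_flops_G / base.total_flops_G)
    return round(p, 1), round(f, 1)
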