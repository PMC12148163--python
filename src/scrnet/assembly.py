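"""Model assembly: baseline detector, ablation variants and the full network.

The detector family is organised around three independent switches applied to
a YOLOv8n-layout baseline (width multiple 0.25, depth multiple 0.33, nc
classes, anchor-free DFL head):

* ``S`` -- replace the P5 SPPF pooling block with SPPE;
* ``R`` -- replace every C2f aggregation block (backbone and neck) with RGE;
* ``C`` -- replace the PAN-FPN neck with the cross-scale feature fusion
  pyramid (CFFP): 64-channel 1x1 laterals between backbone and neck,
  channel-preserving 1x1 refinements before each upsampling, C2f fusion in
  the top-down path and plain 1x1 fusion/downsampling in the bottom-up path.

The switches compose; ``CRS`` (all three) is the full network.  Channel
widths of the CFFP stages are frozen by the budget calibration
(``scrnet.calibration``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .blocks import (RGE, SPPE, SPPF, C2f, ConfigurationError, Conv, Detect,
                     Module)

# flag triples (use_sppe, use_rge, use_cffp); composition is order-independent
VARIANTS = {
    "baseline": (False, False, False),
    "S": (True, False, False),
    "R": (False, True, False),
    "C": (False, False, True),
    "CS": (True, False, True),
    "CR": (False, True, True),
    "CRS": (True, True, True),
}
VARIANT_ALIASES = {"scrnet": "CRS", "yolov8n": "baseline", "SC": "CS",
                   "RC": "CR", "RCS": "CRS", "SRC": "CRS", "CSR": "CRS"}


@dataclass
class VariantSpec:
    """Which architectural switches are enabled, plus head/input size."""

    use_sppe: bool = False
    use_rge: bool = False
    use_cffp: bool = False
    num_classes: int = 4
    input_size: int = 640
    seed: int = 0

    @classmethod
    def from_name(cls, name: str, num_classes: int = 4, input_size: int = 640,
                  seed: int = 0) -> "VariantSpec":
        key = VARIANT_ALIASES.get(name, name)
        if key not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {name!r}; valid names: "
                f"{sorted(VARIANTS)} (aliases {sorted(VARIANT_ALIASES)})")
        s, r, c = VARIANTS[key]
        return cls(use_sppe=s, use_rge=r, use_cffp=c, num_classes=num_classes,
                   input_size=input_size, seed=seed)

    @property
    def name(self) -> str:
        for k, v in VARIANTS.items():
            if v == (self.use_sppe, self.use_rge, self.use_cffp):
                return k
        raise AssertionError("unreachable")

    def to_dict(self) -> dict:
        return dict(variant=self.name, num_classes=self.num_classes,
                    input_size=self.input_size, seed=self.seed)


class Upsample(Module):
    """Nearest-neighbour 2x upsampling (parameter-free)."""

    def forward(self, x: Tensor) -> Tensor:
        return ad.upsample_nearest2x(x)


class Concat(Module):
    """Channel concatenation of its input nodes (parameter-free)."""

    def forward(self, xs: list[Tensor]) -> Tensor:
        return ad.concat(xs, axis=1)


@dataclass
class Node:
    name: str
    module: Module
    src: list[int]  # indices of producer nodes; -1 == previous node
    out_ch: int


class ModelGraph(Module):
    """An ordered DAG of blocks with named skip/concat connections."""

    def __init__(self, spec: VariantSpec, nodes: list[Node], head_idx: list[int]):
        super().__init__()
        self.spec = spec
        self.nodes = nodes
        self.head_idx = head_idx  # indices of the three head input nodes
        for i, n in enumerate(nodes):
            setattr(self, f"n{i}_{n.name}", n.module)
        self.head: Detect = nodes[-1].module  # detect is always last

    # -- execution ------------------------------------------------------------
    def forward(self, x: Tensor):
        """Run letterboxed images (B,3,H,W) through the graph.

        Returns the raw head outputs: a list of (box_map, cls_map) per scale.
        """
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ConfigurationError(f"expected (B,3,H,W) input, got {x.shape}")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ConfigurationError(
                f"input spatial size must be a multiple of 32, got {x.shape[2:]}")
        outs: list[Tensor | None] = [None] * len(self.nodes)
        prev = x
        for i, n in enumerate(self.nodes[:-1]):
            srcs = [prev if j == -1 else outs[j] for j in n.src]
            prev = n.module(srcs if isinstance(n.module, Concat) else srcs[0])
            outs[i] = prev
        feats = [outs[j] for j in self.head_idx]
        return self.head(feats)

    # -- profiling ------------------------------------------------------------
    def profile_layers(self, input_size: int | None = None) -> list[dict]:
        """Shape-propagate and return per-convolution layer rows."""
        size = input_size or self.spec.input_size
        shapes: list[tuple[int, int]] = [None] * len(self.nodes)
        rows: list[dict] = []
        prev_shape = (size, size)
        for i, n in enumerate(self.nodes[:-1]):
            src_shapes = [prev_shape if j == -1 else shapes[j] for j in n.src]
            if isinstance(n.module, Concat):
                out_shape = src_shapes[0]
            elif isinstance(n.module, Upsample):
                out_shape = (src_shapes[0][0] * 2, src_shapes[0][1] * 2)
            else:
                out_shape, r = n.module.profile(*src_shapes[0])
                for row in r:
                    row["name"] = row["name"] or n.name
                rows.extend(r)
            shapes[i] = out_shape
            prev_shape = out_shape
        head_shapes = [shapes[j] for j in self.head_idx]
        hr = self.head.profile(head_shapes)
        for row in hr:
            row["name"] = row["name"] or "detect"
        rows.extend(hr)
        return rows

    def block_census(self) -> dict[str, int]:
        """Count block types in the graph (for structural assertions)."""
        census: dict[str, int] = {}
        for m in self.modules():
            census[type(m).__name__] = census.get(type(m).__name__, 0) + 1
        return census


def _backbone(nodes, blk, spec, rng):
    """YOLOv8n-layout backbone; returns indices of P3, P4, P5 feature nodes."""
    add = nodes.append
    add(Node("stem", Conv(3, 16, 3, 2, rng=rng), [-1], 16))          # 0 P1/2
    add(Node("down2", Conv(16, 32, 3, 2, rng=rng), [-1], 32))        # 1 P2/4
    add(Node("c1", blk(32, 32, 1, True), [-1], 32))                  # 2
    add(Node("down3", Conv(32, 64, 3, 2, rng=rng), [-1], 64))        # 3 P3/8
    add(Node("c2", blk(64, 64, 2, True), [-1], 64))                  # 4
    add(Node("down4", Conv(64, 128, 3, 2, rng=rng), [-1], 128))      # 5 P4/16
    add(Node("c3", blk(128, 128, 2, True), [-1], 128))               # 6
    add(Node("down5", Conv(128, 256, 3, 2, rng=rng), [-1], 256))     # 7 P5/32
    add(Node("c4", blk(256, 256, 1, True), [-1], 256))               # 8
    if spec.use_sppe:
        add(Node("sppe", SPPE(256, 256, rng=rng), [-1], 256))        # 9
    else:
        add(Node("sppf", SPPF(256, 256, rng=rng), [-1], 256))        # 9
    return 4, 6, 9


def build_variant(spec: VariantSpec | str, **kw) -> ModelGraph:
    """Build the model graph for a variant spec or variant name."""
    if isinstance(spec, str):
        spec = VariantSpec.from_name(spec, **kw)
    rng = np.random.default_rng(spec.seed)
    nc = spec.num_classes

    if spec.use_rge:
        def blk(c1, c2, n, shortcut=True):
            return RGE(c1, c2, n, rng=rng)
    else:
        def blk(c1, c2, n, shortcut=True):
            return C2f(c1, c2, n, shortcut, rng=rng)

    nodes: list[Node] = []
    p3, p4, p5 = _backbone(nodes, blk, spec, rng)
    add = nodes.append

    if not spec.use_cffp:
        # standard PAN-FPN neck
        add(Node("up1", Upsample(), [p5], 256))                        # 10
        add(Node("cat1", Concat(), [-1, p4], 384))                     # 11
        add(Node("td4", blk(384, 128, 1, False), [-1], 128))           # 12
        add(Node("up2", Upsample(), [-1], 128))                        # 13
        add(Node("cat2", Concat(), [-1, p3], 192))                     # 14
        add(Node("td3", blk(192, 64, 1, False), [-1], 64))             # 15 P3 out
        add(Node("bdown1", Conv(64, 64, 3, 2, rng=rng), [-1], 64))     # 16
        add(Node("cat3", Concat(), [-1, 12], 192))                     # 17
        add(Node("bu4", blk(192, 128, 1, False), [-1], 128))           # 18 P4 out
        add(Node("bdown2", Conv(128, 128, 3, 2, rng=rng), [-1], 128))  # 19
        add(Node("cat4", Concat(), [-1, p5], 384))                     # 20
        add(Node("bu5", blk(384, 256, 1, False), [-1], 256))           # 21 P5 out
        head_idx = [15, 18, 21]
        head_ch = (64, 128, 256)
    else:
        # cross-scale feature fusion pyramid (widths frozen by calibration)
        add(Node("lat3", Conv(64, 64, 1, rng=rng), [p3], 64))          # 10
        add(Node("lat4", Conv(128, 64, 1, rng=rng), [p4], 64))         # 11
        add(Node("lat5", Conv(256, 64, 1, rng=rng), [p5], 64))         # 12
        add(Node("refine5", Conv(64, 64, 1, rng=rng), [-1], 64))       # 13
        add(Node("up1", Upsample(), [-1], 64))                         # 14
        add(Node("cat1", Concat(), [-1, 11], 128))                     # 15
        add(Node("td4", blk(128, 128, 2, False), [-1], 128))           # 16
        add(Node("refine4", Conv(128, 128, 1, rng=rng), [-1], 128))    # 17
        add(Node("up2", Upsample(), [-1], 128))                        # 18
        add(Node("refine3", Conv(64, 64, 1, rng=rng), [10], 64))       # 19
        add(Node("cat2", Concat(), [18, 19], 192))                     # 20
        add(Node("td3", blk(192, 64, 2, False), [-1], 64))             # 21 P3 out
        add(Node("bdown1", Conv(64, 64, 1, 2, rng=rng), [-1], 64))     # 22
        add(Node("cat3", Concat(), [-1, 16], 192))                     # 23
        add(Node("bu4", Conv(192, 64, 1, rng=rng), [-1], 64))          # 24 P4 out
        add(Node("bdown2", Conv(64, 64, 1, 2, rng=rng), [-1], 64))     # 25
        add(Node("cat4", Concat(), [-1, 12], 128))                     # 26
        add(Node("bu5", Conv(128, 64, 1, rng=rng), [-1], 64))          # 27 P5 out
        head_idx = [21, 24, 27]
        head_ch = (64, 64, 64)

    add(Node("detect", Detect(nc, head_ch, rng=rng), head_idx, 0))
    return ModelGraph(spec, nodes, head_idx)


def forward(model: ModelGraph, images) -> list[tuple[Tensor, Tensor]]:
    """Functional alias for ``model(images)``."""
    return model(images)


def cffp_lateral(p3: Tensor, p4: Tensor, p5: Tensor, rng=None):
    """Standalone CFFP laterals: project three backbone scales to 64 channels."""
    rng = rng or np.random.default_rng(0)
    lats = [Conv(int(p.shape[1]), 64, 1, rng=rng) for p in (p3, p4, p5)]
    return tuple(lat(p) for lat, p in zip(lats, (p3, p4, p5)))


def cffp_pre_upsample_refine(x: Tensor, conv: Conv | None = None,
                             identity_init: bool = False) -> Tensor:
    """Channel-preserving 1x1 refinement applied before 2x upsampling.

    With ``identity_init=True`` the kernel is the identity matrix and BN is
    neutralised, so the refinement reproduces its input exactly (useful for
    verifying the channel contract).
    """
    c = int(x.shape[1])
    if conv is None:
        if identity_init:
            conv = Conv(c, c, 1, act="identity", bn=False)
            conv.weight.data = np.eye(c, dtype=np.float32).reshape(c, c, 1, 1)
            conv.bias.data[...] = 0.0
            conv.eval()
        else:
            conv = Conv(c, c, 1)
    if conv.c1 != c or conv.c2 != c:
        raise ConfigurationError("refinement conv must be channel-preserving")
    return conv(x)
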