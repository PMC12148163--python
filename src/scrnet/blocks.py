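"""Neural building blocks for the lightweight underwater detector.

Everything here operates on ``FeatureMap``-shaped data: float32 arrays of
shape (batch, channels, height, width) wrapped in :class:`scrnet.autodiff.Tensor`.

The block set covers the standard one-stage-detector vocabulary (Conv-BN-act,
C2f with Bottlenecks, SPPF, anchor-free decoupled head with distribution-focal
box regression) plus the three lightweight blocks this package exists for:

* :class:`SPPE` -- an ELAN-style spatial pyramid pooling block in which the
  aggregation stream opens with a 5x5 max pool instead of a 3x3 convolution,
  every activation is ReLU, and the internal width is very small (the width is
  pinned by budget calibration; see ``scrnet.calibration``).
* :class:`RepConv` -- a reparameterizable convolution trained as parallel
  3x3 + 1x1 (+ identity BN) branches and fused to a single 3x3 at deploy time.
* :class:`RGE` -- a C2f-like aggregation block whose bottlenecks are replaced
  by one RepConv stream plus cheap depthwise 3x3 convolutions that generate
  duplicate ("ghost") feature maps.

All blocks preserve spatial size at stride 1 and expose ``profile(h, w)``
returning per-convolution layer rows for the analyzer's shape-propagation
profiler.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

# Frozen by the budget-calibration search (scrnet.calibration): the internal
# hidden width of SPPE and the hidden-channel fraction of RGE are the only
# values in the enumerated design space that reproduce the published
# parameter/FLOP budgets of the ablation table.
SPPE_HIDDEN = 4
SPPE_NUM_CONVS = 3
RGE_SCALE = 25 / 64  # hidden channels = round(RGE_SCALE * out_channels)

BN_EPS = 1e-3
BN_MOMENTUM = 0.03

_ACTS = ("silu", "relu", "identity")

# when set to a list, every executed convolution appends its true spec/output
# shape here -- the operator-hook route of the dual profiling cross-check
_PROFILE_SINK: list | None = None


class ConfigurationError(ValueError):
    """Raised for invalid block configuration (bad channels, kernels, ...)."""


class StateError(RuntimeError):
    """Raised when a block is used in an inconsistent train/deploy state."""


class Parameter(Tensor):
    """A trainable (or fixed) tensor registered on a Module."""

    def __init__(self, data, trainable: bool = True):
        super().__init__(np.asarray(data, dtype=np.float32))
        self.requires_grad = trainable
        self.trainable = trainable


class Module:
    """Tiny torch-like module base: parameter registry + train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value):
        arr = np.asarray(value, dtype=np.float32)
        self._buffers[name] = arr
        object.__setattr__(self, name, arr)

    # -- traversal ------------------------------------------------------------
    def named_parameters(self, prefix: str = "",
                         _seen: set | None = None) -> Iterator[tuple[str, Parameter]]:
        _seen = set() if _seen is None else _seen
        for k, p in self._params.items():
            if id(p) not in _seen:
                _seen.add(id(p))
                yield f"{prefix}{k}", p
        for k, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{k}.", _seen)

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self, _seen: set | None = None):
        _seen = set() if _seen is None else _seen
        if id(self) in _seen:
            return
        _seen.add(id(self))
        yield self
        for m in self._modules.values():
            yield from m.modules(_seen)

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    # -- (de)serialization ----------------------------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for k, p in self._params.items():
            out[f"{prefix}{k}"] = p.data
        for k, b in self._buffers.items():
            out[f"{prefix}{k}"] = getattr(self, k)
        for k, m in self._modules.items():
            out.update(m.state_dict(f"{prefix}{k}."))
        return out

    def load_state_dict(self, sd: dict[str, np.ndarray], prefix: str = ""):
        for k, p in self._params.items():
            p.data = np.asarray(sd[f"{prefix}{k}"], dtype=np.float32).reshape(p.data.shape)
        for k in self._buffers:
            getattr(self, k)[...] = np.asarray(sd[f"{prefix}{k}"], dtype=np.float32)
        for k, m in self._modules.items():
            m.load_state_dict(sd, f"{prefix}{k}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- profiling ------------------------------------------------------------
    def profile(self, h: int, w: int) -> tuple[tuple[int, int], list]:
        """Shape-propagate a (h, w) input; return ((oh, ow), conv rows).

        Rows are dicts with keys cin, cout, k, groups, bias, bn, oh, ow
        consumed by ``scrnet.analyzer``.
        """
        raise NotImplementedError


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


def _row(cin, cout, k, groups, bias, bn, oh, ow, name=""):
    return dict(name=name, cin=cin, cout=cout, k=k, groups=groups,
                bias=bias, bn=bn, oh=oh, ow=ow)


class Conv(Module):
    """Convolution + optional BatchNorm + activation.

    ``padding`` defaults to k//2 (shape-preserving at stride 1).  When
    ``bn=False`` the convolution carries a bias (this is the deploy form of a
    fused conv and the form of the detect head's final 1x1 projections).
    """

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, g: int = 1,
                 act: str = "silu", bn: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if c1 <= 0 or c2 <= 0:
            raise ConfigurationError(f"channels must be positive, got {c1}->{c2}")
        if c1 % g:
            raise ConfigurationError(f"in_channels {c1} not divisible by groups {g}")
        if k % 2 == 0:
            raise ConfigurationError(f"kernel must be odd, got {k}")
        if act not in _ACTS:
            raise ConfigurationError(f"unknown activation {act!r}; choose from {_ACTS}")
        rng = rng or np.random.default_rng(0)
        self.c1, self.c2, self.k, self.s, self.g = c1, c2, k, s, g
        self.act = act
        self.has_bn = bn
        fan_in = c1 // g * k * k
        self.weight = Parameter(_kaiming_uniform(rng, (c2, c1 // g, k, k), fan_in))
        if bn:
            self.gamma = Parameter(np.ones(c2))
            self.beta = Parameter(np.zeros(c2))
            self.register_buffer("running_mean", np.zeros(c2))
            self.register_buffer("running_var", np.ones(c2))
            self.bias = None
        else:
            self.bias = Parameter(np.zeros(c2))

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.c1:
            raise ConfigurationError(
                f"Conv expects {self.c1} input channels, got {x.shape[1]}")
        y = ad.conv2d(x, self.weight, bias=self.bias, stride=self.s, groups=self.g)
        if _PROFILE_SINK is not None:
            _PROFILE_SINK.append(dict(
                name="", cin=self.c1, cout=self.c2, k=self.k, groups=self.g,
                bias=self.bias is not None, bn=self.has_bn,
                oh=y.shape[2], ow=y.shape[3]))
        if self.has_bn:
            y = ad.batch_norm(y, self.gamma, self.beta, self.running_mean,
                              self.running_var, self.training,
                              momentum=BN_MOMENTUM, eps=BN_EPS)
        if self.act == "silu":
            y = ad.silu(y)
        elif self.act == "relu":
            y = ad.relu(y)
        return y

    def profile(self, h, w):
        oh = (h + 2 * (self.k // 2) - self.k) // self.s + 1
        ow = (w + 2 * (self.k // 2) - self.k) // self.s + 1
        return (oh, ow), [_row(self.c1, self.c2, self.k, self.g,
                               self.bias is not None, self.has_bn, oh, ow)]


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained 5x5 stride-1 max pools.

    The four streams (input projection and the three successive poolings) are
    concatenated and expanded back by a 1x1 convolution.
    """

    def __init__(self, c1: int, c2: int, hidden: int | None = None, k: int = 5,
                 rng=None):
        super().__init__()
        hidden = c1 // 2 if hidden is None else hidden
        if hidden <= 0:
            raise ConfigurationError(f"SPPF hidden width must be positive, got {hidden}")
        self.k = k
        self.cv1 = Conv(c1, hidden, 1, rng=rng)
        self.cv2 = Conv(hidden * 4, c2, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        p1 = ad.max_pool2d(y, self.k)
        p2 = ad.max_pool2d(p1, self.k)
        p3 = ad.max_pool2d(p2, self.k)
        return self.cv2(ad.concat([y, p1, p2, p3], axis=1))

    def profile(self, h, w):
        _, r1 = self.cv1.profile(h, w)
        _, r2 = self.cv2.profile(h, w)
        return (h, w), r1 + r2


class SPPE(Module):
    """Spatial pyramid pooling ELAN block (single-branch, ReLU-activated).

    One narrow aggregation stream: a 1x1 projection to a small hidden width,
    then a 5x5 max pool standing in for the first 3x3 convolution of the ELAN
    stack, then ``n_convs`` 3x3 convolutions.  Every stage is tapped; the taps
    are concatenated and projected by a final 1x1 convolution.  The dropped
    ELAN left branch and the tiny hidden width are what make the block cheap;
    ReLU (not SiLU) keeps the per-element cost at a single threshold.
    """

    def __init__(self, c1: int, c2: int, hidden: int = SPPE_HIDDEN,
                 n_convs: int = SPPE_NUM_CONVS, pool_k: int = 5, rng=None):
        super().__init__()
        if hidden <= 0:
            raise ConfigurationError(f"SPPE hidden width must be positive, got {hidden}")
        self.pool_k = pool_k
        self.n_convs = n_convs
        self.cv1 = Conv(c1, hidden, 1, act="relu", rng=rng)
        self.convs = ModuleList(
            [Conv(hidden, hidden, 3, act="relu", rng=rng) for _ in range(n_convs)])
        self.cv2 = Conv(hidden * (2 + n_convs), c2, 1, act="relu", rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        taps = [self.cv1(x)]
        taps.append(ad.max_pool2d(taps[-1], self.pool_k))
        for conv in self.convs:
            taps.append(conv(taps[-1]))
        return self.cv2(ad.concat(taps, axis=1))

    def profile(self, h, w):
        rows = self.cv1.profile(h, w)[1]
        for conv in self.convs:
            rows += conv.profile(h, w)[1]
        rows += self.cv2.profile(h, w)[1]
        return (h, w), rows


class ModuleList(Module):
    def __init__(self, mods):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
        self._list = list(mods)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class RepConv(Module):
    """Reparameterizable 3x3 convolution (RepVGG-style).

    Training mode: act(BN(conv3x3(x)) + BN(conv1x1(x)) + BN(x)), the identity
    branch present only when in==out and stride==1.  Deploy mode (after
    ``scrnet.reparam.fuse_repconv``): act(fused 3x3 conv with bias).
    """

    def __init__(self, c1: int, c2: int, s: int = 1, act: str = "silu", rng=None):
        super().__init__()
        self.c1, self.c2, self.s = c1, c2, s
        self.act = act
        self.deployed = False
        self.conv3 = Conv(c1, c2, 3, s=s, act="identity", rng=rng)
        self.conv1 = Conv(c1, c2, 1, s=s, act="identity", rng=rng)
        self.has_identity = (c1 == c2 and s == 1)
        if self.has_identity:
            self.id_gamma = Parameter(np.ones(c2))
            self.id_beta = Parameter(np.zeros(c2))
            self.register_buffer("id_mean", np.zeros(c2))
            self.register_buffer("id_var", np.ones(c2))
        self.fused: Conv | None = None

    def _act(self, y: Tensor) -> Tensor:
        if self.act == "silu":
            return ad.silu(y)
        if self.act == "relu":
            return ad.relu(y)
        return y

    def forward(self, x: Tensor) -> Tensor:
        if self.deployed:
            if self.fused is None:
                raise StateError("RepConv marked deployed but has no fused kernel; "
                                 "call scrnet.reparam.fuse_repconv first")
            return self._act(self.fused.forward_raw(x))
        y = self.conv3(x) + self.conv1(x)
        if self.has_identity:
            y = y + ad.batch_norm(x, self.id_gamma, self.id_beta, self.id_mean,
                                  self.id_var, self.training,
                                  momentum=BN_MOMENTUM, eps=BN_EPS)
        return self._act(y)

    def num_params(self) -> int:
        if self.deployed:
            return self.fused.num_params()
        return super().num_params()

    def profile(self, h, w):
        oh = (h + 2 - 3) // self.s + 1
        ow = (w + 2 - 3) // self.s + 1
        if self.deployed:
            return (oh, ow), [_row(self.c1, self.c2, 3, 1, True, False, oh, ow)]
        rows = [_row(self.c1, self.c2, 3, 1, False, True, oh, ow),
                _row(self.c1, self.c2, 1, 1, False, True, oh, ow)]
        if self.has_identity:
            rows.append(_row(0, self.c2, 1, 1, False, True, oh, ow))  # BN only
        return (oh, ow), rows


# give Conv a BN/act-free raw path for the fused RepConv kernel
def _conv_forward_raw(self, x: Tensor) -> Tensor:
    y = ad.conv2d(x, self.weight, bias=self.bias, stride=self.s, groups=self.g)
    if _PROFILE_SINK is not None:
        _PROFILE_SINK.append(dict(
            name="", cin=self.c1, cout=self.c2, k=self.k, groups=self.g,
            bias=self.bias is not None, bn=False, oh=y.shape[2], ow=y.shape[3]))
    return y


Conv.forward_raw = _conv_forward_raw


class Bottleneck(Module):
    """Two 3x3 convs with optional residual (the C2f inner block)."""

    def __init__(self, c1: int, c2: int, shortcut: bool = True, rng=None):
        super().__init__()
        self.cv1 = Conv(c1, c2, 3, rng=rng)
        self.cv2 = Conv(c2, c2, 3, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y

    def profile(self, h, w):
        return (h, w), self.cv1.profile(h, w)[1] + self.cv2.profile(h, w)[1]


class C2f(Module):
    """Cross-stage partial block with n Bottlenecks and dense concatenation."""

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = True, rng=None):
        super().__init__()
        if n < 1:
            raise ConfigurationError(f"C2f needs n >= 1 bottlenecks, got {n}")
        self.ch = c2 // 2
        self.n = n
        self.cv1 = Conv(c1, 2 * self.ch, 1, rng=rng)
        self.m = ModuleList([Bottleneck(self.ch, self.ch, shortcut, rng=rng)
                             for _ in range(n)])
        self.cv2 = Conv((2 + n) * self.ch, c2, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        a = ad.narrow(y, 1, 0, self.ch)
        b = ad.narrow(y, 1, self.ch, self.ch)
        streams = [a, b]
        for blk in self.m:
            streams.append(blk(streams[-1]))
        return self.cv2(ad.concat(streams, axis=1))

    def profile(self, h, w):
        rows = self.cv1.profile(h, w)[1]
        for blk in self.m:
            rows += blk.profile(h, w)[1]
        rows += self.cv2.profile(h, w)[1]
        return (h, w), rows


class RGE(Module):
    """Reparameterizable ghost-ELAN feature-extraction block (replaces C2f).

    A 1x1 convolution produces 2*ch channels split into two gradient-flow
    streams.  One stream passes through a RepConv; (n-1) cheap depthwise 3x3
    convolutions then derive further duplicate feature maps from it,
    GhostNet-style.  Both split halves, the RepConv output and every cheap map
    are concatenated ((n+2) streams) and projected by a final 1x1 convolution.

    ``scale`` fixes the hidden width ch = round(scale * c2).  The default is
    the budget-calibrated 25/64; see docs/methods.md for why this deviates
    from the nominal 0.5.
    """

    def __init__(self, c1: int, c2: int, n: int = 1, scale: float = RGE_SCALE,
                 rng=None):
        super().__init__()
        if not 0.0 < scale <= 1.0:
            raise ConfigurationError(f"RGE scale must be in (0, 1], got {scale}")
        if n < 1:
            raise ConfigurationError(f"RGE needs n >= 1, got {n}")
        self.ch = max(1, round(scale * c2))
        self.n = n
        self.cv1 = Conv(c1, 2 * self.ch, 1, rng=rng)
        self.rep = RepConv(self.ch, self.ch, rng=rng)
        self.cheap = ModuleList(
            [Conv(self.ch, self.ch, 3, g=self.ch, rng=rng) for _ in range(n - 1)])
        self.cv2 = Conv((2 + n) * self.ch, c2, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        a = ad.narrow(y, 1, 0, self.ch)
        b = ad.narrow(y, 1, self.ch, self.ch)
        streams = [a, b, self.rep(b)]
        for conv in self.cheap:
            streams.append(conv(streams[-1]))
        return self.cv2(ad.concat(streams, axis=1))

    def profile(self, h, w):
        rows = self.cv1.profile(h, w)[1]
        rows += self.rep.profile(h, w)[1]
        for conv in self.cheap:
            rows += conv.profile(h, w)[1]
        rows += self.cv2.profile(h, w)[1]
        return (h, w), rows


class DFL(Module):
    """Distribution-focal decoding: expectation over reg_max softmax bins.

    The projection weight is the fixed vector (0, 1, ..., reg_max-1); it is a
    registered (non-trainable) parameter so that it shows up in parameter
    counts exactly as in the reference implementation.
    """

    def __init__(self, reg_max: int = 16):
        super().__init__()
        self.reg_max = reg_max
        self.proj = Parameter(np.arange(reg_max, dtype=np.float32), trainable=False)

    def forward(self, box: Tensor) -> Tensor:
        """box: (B, 4*reg_max, A) -> distances (B, 4, A)."""
        b, _, a = box.shape
        x = ad.reshape(box, (b, 4, self.reg_max, a))
        p = ad.softmax(x, axis=2)
        w = ad.reshape(Tensor(self.proj.data), (1, 1, self.reg_max, 1))
        return ad.tsum(p * w, axis=2)


class Detect(Module):
    """Anchor-free decoupled detection head over three scales (strides 8/16/32).

    Per scale: a box branch (two 3x3 convs then 1x1 to 4*reg_max channels) and
    a class branch (two 3x3 convs then 1x1 to num_classes channels).  Raw maps
    are returned; decoding/loss live in train_smoke and assembly.
    """

    STRIDES = (8, 16, 32)

    def __init__(self, nc: int, ch: tuple[int, int, int], reg_max: int = 16, rng=None):
        super().__init__()
        if len(ch) != 3:
            raise ConfigurationError(f"Detect expects three scale widths, got {ch}")
        self.nc = nc
        self.reg_max = reg_max
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        self.box_c, self.cls_c = c2, c3
        self.cv2 = ModuleList([
            ModuleList([Conv(c, c2, 3, rng=rng), Conv(c2, c2, 3, rng=rng),
                        Conv(c2, 4 * reg_max, 1, act="identity", bn=False, rng=rng)])
            for c in ch])
        self.cv3 = ModuleList([
            ModuleList([Conv(c, c3, 3, rng=rng), Conv(c3, c3, 3, rng=rng),
                        Conv(c3, nc, 1, act="identity", bn=False, rng=rng)])
            for c in ch])
        self.dfl = DFL(reg_max)

    def forward(self, feats: list[Tensor]) -> list[tuple[Tensor, Tensor]]:
        if len(feats) != 3:
            raise ConfigurationError(f"Detect needs 3 scales, got {len(feats)}")
        out = []
        for i, x in enumerate(feats):
            box = x
            for m in self.cv2[i]:
                box = m(box)
            cls = x
            for m in self.cv3[i]:
                cls = m(cls)
            out.append((box, cls))
        return out

    def profile(self, shapes):
        rows = []
        for i, (h, w) in enumerate(shapes):
            for m in list(self.cv2[i]) + list(self.cv3[i]):
                rows += m.profile(h, w)[1]
        rows.append(_row(self.reg_max, 1, 1, 1, False, False, 0, 0, name="dfl"))
        return rows
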