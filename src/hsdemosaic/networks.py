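"""Small convolutional backbones for demosaicking refinement.

The demosaicking pipeline is network-agnostic: the network maps the
bilinearly demosaicked C-band cube to a refined C-band cube of the same
spatial size. Three compact architecture families are provided, each a
faithful-in-spirit, configurable-width variant of a standard image
restoration design rather than a replica of any published layer count:

* ``edsr``     — a residual network: head conv, N residual blocks
                 (conv-ReLU-conv with identity skip), tail conv;
* ``unet``     — a one-level encoder/decoder with skip concatenation;
* ``res2unet`` — the same encoder/decoder with hierarchical multi-scale
                 residual blocks (channel groups convolved sequentially,
                 each group seeing the previous group's output).

Every network carries a global input skip and a zero-initialised final
convolution, so an untrained model is exactly the identity: refinement
starts from the bilinear baseline and learns a correction. All
parameters are float32 by default for training speed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .autodiff import Tensor, concat

__all__ = ["NetworkSpec", "build_network", "Conv2d", "Network"]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters.

    ``architecture`` selects the family; ``width`` the base feature
    count; ``depth`` the number of residual blocks (edsr/res2unet) or
    convolutions per stage (unet). ``n_bands`` fixes input = output = C.
    """

    architecture: Literal["edsr", "unet", "res2unet"] = "edsr"
    n_bands: int = 16
    width: int = 16
    depth: int = 2

    def __post_init__(self):
        if self.architecture not in ("edsr", "unet", "res2unet"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.n_bands < 1 or self.width < 1 or self.depth < 1:
            raise ValueError("n_bands, width and depth must be positive")

    def to_dict(self) -> dict:
        return {
            "architecture": self.architecture,
            "n_bands": self.n_bands,
            "width": self.width,
            "depth": self.depth,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(**d)


class Conv2d:
    """3×3 (or k×k) same-padding convolution layer with bias."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        k: int = 3,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
        dtype=np.float32,
    ):
        if zero_init:
            w = np.zeros((out_ch, in_ch, k, k), dtype=dtype)
        else:
            rng = rng or np.random.default_rng()
            # He fan-in scaling keeps activations O(1) through ReLU stacks
            std = np.sqrt(2.0 / (in_ch * k * k))
            w = rng.normal(0.0, std, size=(out_ch, in_ch, k, k)).astype(dtype)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias)

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class Network:
    """Base class: a parameterised map from (N,C,H,W) to (N,C,H,W)."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        self.layers: list[Conv2d] = []

    def _conv(self, in_ch, out_ch, rng, zero_init=False, k=3) -> Conv2d:
        layer = Conv2d(in_ch, out_ch, k=k, rng=rng, zero_init=zero_init)
        self.layers.append(layer)
        return layer

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, x: Tensor) -> Tensor:
        raise NotImplementedError

    # -- checkpointing ---------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            out[f"layer{i}.weight"] = layer.weight.data
            out[f"layer{i}.bias"] = layer.bias.data
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            w = state[f"layer{i}.weight"]
            b = state[f"layer{i}.bias"]
            if w.shape != layer.weight.shape or b.shape != layer.bias.shape:
                raise ValueError(f"checkpoint shape mismatch at layer {i}")
            layer.weight.data = np.asarray(w)
            layer.bias.data = np.asarray(b)


class EDSRNet(Network):
    """Residual refinement network (EDSR-style, no upsampling stage)."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        super().__init__(spec)
        C, F = spec.n_bands, spec.width
        self.head = self._conv(C, F, rng)
        self.blocks = [
            (self._conv(F, F, rng), self._conv(F, F, rng)) for _ in range(spec.depth)
        ]
        self.tail = self._conv(F, C, rng, zero_init=True)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.head(x).relu()
        for c1, c2 in self.blocks:
            h = h + c2(c1(h).relu())
        return x + self.tail(h)


class UNet(Network):
    """One-level U-Net: encode, pool, bottleneck, upsample, skip-concat."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        super().__init__(spec)
        C, F = spec.n_bands, spec.width
        self.enc = [self._conv(C if i == 0 else F, F, rng) for i in range(spec.depth)]
        self.bott = [
            self._conv(F if i == 0 else 2 * F, 2 * F, rng) for i in range(spec.depth)
        ]
        self.up = self._conv(2 * F, F, rng)
        self.dec = [self._conv(2 * F if i == 0 else F, F, rng) for i in range(spec.depth)]
        self.tail = self._conv(F, C, rng, zero_init=True)

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for conv in self.enc:
            h = conv(h).relu()
        skip = h
        h = h.avg_pool2()
        for conv in self.bott:
            h = conv(h).relu()
        h = self.up(h.upsample2()).relu()
        h = concat([h, skip], axis=1)
        for conv in self.dec:
            h = conv(h).relu()
        return x + self.tail(h)


class Res2UNet(Network):
    """U-Net scaffold whose stages use hierarchical multi-scale blocks.

    Each residual block splits its features into groups; group g is
    convolved after adding the previous group's output, widening the
    receptive field within one block at low cost (Res2-style). The
    blocks sit inside the same encode/pool/bottleneck/upsample/skip
    structure as :class:`UNet`.
    """

    n_groups = 2

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        super().__init__(spec)
        C = spec.n_bands
        # width must split evenly into groups
        F = max(self.n_groups, spec.width - spec.width % self.n_groups)
        self.width = F
        self.head = self._conv(C, F, rng)
        self.enc_blocks = [self._make_block(rng) for _ in range(spec.depth)]
        self.bott_blocks = [self._make_block(rng) for _ in range(spec.depth)]
        self.fuse = self._conv(2 * F, F, rng)
        self.dec_blocks = [self._make_block(rng) for _ in range(spec.depth)]
        self.tail = self._conv(F, C, rng, zero_init=True)

    def _make_block(self, rng) -> list[Conv2d]:
        g = self.width // self.n_groups
        return [self._conv(g, g, rng) for _ in range(self.n_groups)]

    def _res2_block(self, h: Tensor, convs) -> Tensor:
        g = self.width // self.n_groups
        parts = [h[:, i * g : (i + 1) * g, :, :] for i in range(self.n_groups)]
        outs = []
        prev = None
        for part, conv in zip(parts, convs):
            inp = part if prev is None else part + prev
            prev = conv(inp).relu()
            outs.append(prev)
        return h + concat(outs, axis=1)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.head(x).relu()
        for convs in self.enc_blocks:
            h = self._res2_block(h, convs)
        skip = h
        h = h.avg_pool2()
        for convs in self.bott_blocks:
            h = self._res2_block(h, convs)
        h = concat([h.upsample2(), skip], axis=1)
        h = self.fuse(h).relu()
        for convs in self.dec_blocks:
            h = self._res2_block(h, convs)
        return x + self.tail(h)


def build_network(spec: NetworkSpec, seed: int | np.random.Generator = 0) -> Network:
    """Instantiate a network with seeded weight initialisation."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cls = {"edsr": EDSRNet, "unet": UNet, "res2unet": Res2UNet}[spec.architecture]
    return cls(spec, rng)
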