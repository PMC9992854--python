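"""Declarative architecture specs and network instantiation.

The suite uses five networks: three segmenters (coarse S1, fine S2, cortex
parcellator S3) sharing a 3D UNet architecture, a lighter denoising UNet D,
and an encoder-only quality-control regressor R. Specs are plain data; the
builders encode the published architecture at full scale and a small "toy"
preset used throughout the test suite:

* segmenters: five levels of two 3x3x3 convolutions each, ELU activations,
  24 features at the first level doubled after each max-pooling (halved on
  the way up), skip connections at every level, softmax head;
* denoiser: one convolution per level, a constant 16 features, and the skip
  connections of the top two (finest) levels suppressed;
* regressor: the segmenter encoder with 5x5x5 convolutions, followed by two
  convolutions of one feature per QC region and a global max-pooling.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from . import nn

__all__ = [
    "NetworkSpec",
    "build_segmenter_spec",
    "build_denoiser_spec",
    "build_regressor_spec",
    "instantiate",
    "count_parameters",
    "Network",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture descriptor for segmenters, denoiser and regressor."""

    kind: str  # "segmenter" | "denoiser" | "regressor"
    n_levels: int
    convs_per_level: int
    kernel: int
    base_features: int
    feature_schedule: str  # "doubling" | "constant"
    skip_mask: tuple[bool, ...]  # per level, finest first; unused for encoder
    in_channels: int
    out_channels: int
    head: str  # "segmentation" | "regression"

    def __post_init__(self) -> None:
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        if self.feature_schedule not in ("doubling", "constant"):
            raise ValueError("feature_schedule must be doubling|constant")
        if len(self.skip_mask) != self.n_levels:
            raise ValueError("skip_mask must have one entry per level")

    def features(self, level: int) -> int:
        if self.feature_schedule == "doubling":
            return self.base_features * 2**level
        return self.base_features

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "NetworkSpec":
        d = json.loads(s)
        d["skip_mask"] = tuple(d["skip_mask"])
        return cls(**d)


def build_segmenter_spec(
    n_labels: int, in_channels: int = 1, scale: str = "full"
) -> NetworkSpec:
    """UNet spec for a segmenter.

    At full scale the contracting path has feature widths
    (24, 48, 96, 192, 384); the toy preset keeps the topology with 3 levels
    and 8 base features.
    """
    if n_labels < 2:
        raise ValueError("n_labels must be >= 2")
    n_levels = 5 if scale == "full" else 3
    base = 24 if scale == "full" else 8
    return NetworkSpec(
        kind="segmenter",
        n_levels=n_levels,
        convs_per_level=2,
        kernel=3,
        base_features=base,
        feature_schedule="doubling",
        skip_mask=(True,) * n_levels,
        in_channels=in_channels,
        out_channels=n_labels,
        head="segmentation",
    )


def build_denoiser_spec(n_coarse: int, scale: str = "full") -> NetworkSpec:
    """UNet spec for the segmentation denoiser.

    One convolution per level, constant 16 features at full scale, and skip
    connections suppressed at the top two (finest) levels — a compromise
    between a UNet (skips can reintroduce erroneous fine-scale features)
    and an auto-encoder (over-smooth bottleneck output). Input is the
    one-hot coarse segmentation including background.
    """
    if n_coarse < 2:
        raise ValueError("n_coarse must be >= 2")
    n_levels = 5 if scale == "full" else 3
    base = 16 if scale == "full" else 8
    mask = [True] * n_levels
    mask[0] = mask[1] = False  # finest two levels
    return NetworkSpec(
        kind="denoiser",
        n_levels=n_levels,
        convs_per_level=1,
        kernel=3,
        base_features=base,
        feature_schedule="constant",
        skip_mask=tuple(mask),
        in_channels=n_coarse,
        out_channels=n_coarse,
        head="segmentation",
    )


def build_regressor_spec(n_regions: int = 10, in_channels: int = 1, scale: str = "full") -> NetworkSpec:
    """Encoder-only spec for the QC regressor: segmenter encoder with 5x5x5
    kernels, then two convolutions of ``n_regions`` features and a global
    max-pooling producing one score per region."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    n_levels = 5 if scale == "full" else 3
    base = 24 if scale == "full" else 8
    return NetworkSpec(
        kind="regressor",
        n_levels=n_levels,
        convs_per_level=2,
        kernel=5,
        base_features=base,
        feature_schedule="doubling",
        skip_mask=(False,) * n_levels,
        in_channels=in_channels,
        out_channels=n_regions,
        head="regression",
    )


# ---------------------------------------------------------------------------


class _ConvBlock:
    """conv -> channel norm -> ELU."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        rng: np.random.Generator,
        need_input_grad: bool = True,
    ) -> None:
        self.conv = nn.Conv3d(c_in, c_out, k, rng, need_input_grad=need_input_grad)
        self.norm = nn.ChannelNorm(c_out)
        self.act = nn.ELU()

    def params(self) -> list[nn.Param]:
        return self.conv.params() + self.norm.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.act.forward(self.norm.forward(self.conv.forward(x)))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.norm.backward(self.act.backward(gy)))


class Network:
    """A callable network instantiated from a :class:`NetworkSpec`.

    Inputs are channels-first float32 volumes ``(C, D, H, W)``. Spatial dims
    not divisible by ``2**(n_levels-1)`` are zero-padded internally and the
    output cropped back, so segmentation heads always preserve the spatial
    shape of the input.
    """

    def __init__(self, spec: NetworkSpec, seed: int) -> None:
        self.spec = spec
        self.seed = seed
        self.frozen = False
        rng = np.random.default_rng(seed)
        L, cpl, k = spec.n_levels, spec.convs_per_level, spec.kernel

        self.enc: list[list[_ConvBlock]] = []
        c_prev = spec.in_channels
        for lvl in range(L):
            blocks = []
            for i in range(cpl):
                c_out = spec.features(lvl)
                first = lvl == 0 and i == 0
                blocks.append(
                    _ConvBlock(c_prev if i == 0 else c_out, c_out, k, rng,
                               need_input_grad=not first)
                )
                c_prev = c_out
            self.enc.append(blocks)
        self.pools = [nn.MaxPool2() for _ in range(L - 1)]

        if spec.head == "segmentation":
            self.ups = [nn.Upsample2() for _ in range(L - 1)]
            self.dec: list[list[_ConvBlock]] = []
            for lvl in range(L - 2, -1, -1):
                c_in = spec.features(lvl + 1)
                if spec.skip_mask[lvl]:
                    c_in += spec.features(lvl)
                blocks = []
                for i in range(cpl):
                    c_out = spec.features(lvl)
                    blocks.append(_ConvBlock(c_in if i == 0 else c_out, c_out, k, rng))
                self.dec.append(blocks)
            self.head_conv = nn.Conv3d(spec.features(0), spec.out_channels, 1, rng)
            self.softmax = nn.Softmax()
        else:  # regression head: two convs of n_scores features + global max
            c_last = spec.features(L - 1)
            self.head_blocks = [
                _ConvBlock(c_last, spec.out_channels, k, rng),
                None,  # placeholder, second conv has no norm/act (linear scores)
            ]
            self.head_conv = nn.Conv3d(spec.out_channels, spec.out_channels, k, rng)
            self.gmp = nn.GlobalMaxPool()

    # -- parameters ---------------------------------------------------------

    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for blocks in self.enc:
            for b in blocks:
                out += b.params()
        if self.spec.head == "segmentation":
            for blocks in self.dec:
                for b in blocks:
                    out += b.params()
            out += self.head_conv.params()
        else:
            out += self.head_blocks[0].params()
            out += self.head_conv.params()
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def checksum(self) -> str:
        return nn.params_checksum(self.params())

    def freeze(self) -> "Network":
        self.frozen = True
        return self

    def save(self, path) -> None:
        """Checkpoint: spec JSON + named parameter arrays (NumPy .npz)."""
        arrays = {f"p{i:03d}.{p.name}": p.value for i, p in enumerate(self.params())}
        np.savez(path, __spec__=np.frombuffer(self.spec.to_json().encode(), dtype=np.uint8),
                 __seed__=np.array([self.seed]), **arrays)

    @classmethod
    def load(cls, path) -> "Network":
        with np.load(path) as z:
            spec = NetworkSpec.from_json(bytes(z["__spec__"]).decode())
            net = cls(spec, int(z["__seed__"][0]))
            keys = sorted(k for k in z.files if k.startswith("p"))
            params = net.params()
            if len(keys) != len(params):
                raise ValueError("checkpoint does not match spec parameterization")
            for k, p in zip(keys, params):
                p.value[...] = z[k]
        return net

    # -- forward / backward -------------------------------------------------

    def _pad(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
        mult = 2 ** (self.spec.n_levels - 1)
        dims = np.array(x.shape[1:])
        pad = (-dims) % mult
        if pad.any():
            x = np.pad(x, ((0, 0), (0, pad[0]), (0, pad[1]), (0, pad[2])))
        return x, tuple(dims)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[0] != self.spec.in_channels:
            raise ValueError(
                f"expected input (C={self.spec.in_channels}, D, H, W), got {x.shape}"
            )
        x, self._dims = self._pad(x)
        skips = []
        for lvl, blocks in enumerate(self.enc):
            for b in blocks:
                x = b.forward(x)
            if lvl < self.spec.n_levels - 1:
                skips.append(x)
                x = self.pools[lvl].forward(x)

        if self.spec.head == "segmentation":
            self._skip_used = []
            for i, lvl in enumerate(range(self.spec.n_levels - 2, -1, -1)):
                x = self.ups[i].forward(x)
                if self.spec.skip_mask[lvl]:
                    self._skip_used.append(x.shape[0])
                    x = np.concatenate([skips[lvl], x], axis=0)
                else:
                    self._skip_used.append(None)
                for b in self.dec[i]:
                    x = b.forward(x)
            x = self.softmax.forward(self.head_conv.forward(x))
            d, h, w = self._dims
            return x[:, :d, :h, :w]
        else:
            x = self.head_blocks[0].forward(x)
            x = self.head_conv.forward(x)
            return self.gmp.forward(x)

    __call__ = forward

    def backward(self, gy: np.ndarray) -> None:
        """Accumulate parameter gradients given the loss gradient w.r.t. the
        network output (cropped shape for segmentation heads)."""
        spec = self.spec
        if spec.head == "segmentation":
            d, h, w = self._dims
            mult = 2 ** (spec.n_levels - 1)
            full = tuple(int(-(-s // mult) * mult) for s in (d, h, w))
            g = np.zeros((spec.out_channels,) + full, dtype=np.float32)
            g[:, :d, :h, :w] = gy
            g = self.head_conv.backward(self.softmax.backward(g))
            skip_grads: dict[int, np.ndarray] = {}
            for i in range(len(self.dec) - 1, -1, -1):
                lvl = spec.n_levels - 2 - i
                for b in reversed(self.dec[i]):
                    g = b.backward(g)
                if spec.skip_mask[lvl]:
                    n_skip = spec.features(lvl)
                    skip_grads[lvl] = g[:n_skip]
                    g = g[n_skip:]
                g = self.ups[i].backward(g)
            for lvl in range(spec.n_levels - 1, -1, -1):
                if lvl < spec.n_levels - 1:
                    g = self.pools[lvl].backward(g)
                    if lvl in skip_grads:
                        g = g + skip_grads[lvl]
                for b in reversed(self.enc[lvl]):
                    g = b.backward(g)
        else:
            g = self.gmp.backward(gy)
            g = self.head_conv.backward(g)
            g = self.head_blocks[0].backward(g)
            for lvl in range(spec.n_levels - 1, -1, -1):
                if lvl < spec.n_levels - 1:
                    g = self.pools[lvl].backward(g)
                for b in reversed(self.enc[lvl]):
                    g = b.backward(g)


def instantiate(spec: NetworkSpec, seed: int = 0) -> Network:
    """Build a network with reproducible weights for a spec."""
    return Network(spec, seed)


def count_parameters(spec: NetworkSpec) -> int:
    """Parameter count as a pure function of the spec."""
    return instantiate(spec, 0).n_parameters()
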