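"""Block-named 3D encoder-decoder segmentation network.

The network is a U-Net-style encoder-decoder operating on 4-channel MR
volumes and producing a single-channel voxelwise tumor-probability map.
Every learnable parameter is registered under a named *block*: encoder
blocks are numbered shallow-to-deep ("1st down" ... "Nth down") and
decoder blocks deep-to-shallow ("1st up" ... "Nth up"), so "1st up" is
the deepest decoder block. Selective fine-tuning strategies freeze or
release whole blocks by these names.

Block internals: ``convs_per_block`` shape-preserving 3x3x3 convolutions
with ReLU, one dropout layer, and a residual element-wise sum around the
block whenever the input and output channel counts agree. Resolution is
halved between encoder blocks by a strided 2x2x2 convolution and doubled
between decoder blocks by a transposed 2x2x2 convolution; mirrored
resolutions are joined by skip connections (concatenation by default,
element-wise sum optional). Resampling transitions are owned by the block
they feed into; the input stem belongs to "1st down" and the 1x1x1 output
head to the shallowest up block.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import engine as eg
from .volio import VoiMask

__all__ = [
    "NetConfig",
    "BlockRegistry",
    "SegNet3d",
    "build_network",
    "binarize",
    "ordinal",
]


def ordinal(n: int) -> str:
    if 10 <= n % 100 <= 20:
        suf = "th"
    else:
        suf = {1: "st", 2: "nd", 3: "rd"}.get(n % 10, "th")
    return f"{n}{suf}"


@dataclass(frozen=True)
class NetConfig:
    """Architecture description.

    ``depth`` is the number of down blocks (= number of up blocks); each
    spatial dimension of ``target_shape`` must be divisible by
    ``2**(depth-1)`` so the strided transitions tile exactly.
    """

    depth: int = 3
    base_channels: int = 8
    in_channels: int = 4
    convs_per_block: int = 3
    dropout_rate: float = 0.2
    skip_mode: str = "concatenate"
    target_shape: tuple[int, int, int] = (32, 32, 32)

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 2:
            raise ValueError("base_channels must be >= 2")
        if self.convs_per_block < 1:
            raise ValueError("convs_per_block must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.skip_mode not in ("concatenate", "sum"):
            raise ValueError("skip_mode must be 'concatenate' or 'sum'")
        if len(self.target_shape) != 3:
            raise ValueError("target_shape must have 3 dimensions")
        div = 2 ** (self.depth - 1)
        for ax, s in zip("xyz", self.target_shape):
            if s % div != 0:
                raise ValueError(
                    f"target_shape dimension {ax}={s} is not divisible by 2**(depth-1)={div}"
                )

    def block_names(self) -> list[str]:
        down = [f"{ordinal(i)} down" for i in range(1, self.depth + 1)]
        up = [f"{ordinal(i)} up" for i in range(1, self.depth + 1)]
        return down + up


@dataclass
class BlockRegistry:
    """Maps each block name to the learnable parameters it owns."""

    blocks: dict[str, tuple[str, ...]] = field(default_factory=dict)
    param_sizes: dict[str, int] = field(default_factory=dict)

    def param_names(self, block: str) -> tuple[str, ...]:
        return self.blocks[block]

    def count(self, block_names) -> int:
        names = set()
        for b in block_names:
            names.update(self.blocks[b])
        return sum(self.param_sizes[n] for n in names)

    @property
    def total(self) -> int:
        return sum(self.param_sizes.values())

    def manifest(self, shapes: dict[str, tuple]) -> dict:
        return {
            b: {n: {"shape": list(shapes[n]), "size": self.param_sizes[n]} for n in names}
            for b, names in self.blocks.items()
        }


class _ConvBlock:
    """convs_per_block 3x3x3 convolutions + ReLU, one dropout, residual sum."""

    def __init__(self, rng, cin, cout, n_convs, dropout_rate, name):
        self.cin, self.cout = cin, cout
        self.convs = []
        self.relus = []
        c = cin
        for i in range(n_convs):
            self.convs.append(eg.Conv3x3(rng, c, cout, f"{name}.conv{i}"))
            self.relus.append(eg.ReLU())
            c = cout
        self.dropout = eg.Dropout(dropout_rate)
        self.residual = cin == cout

    def params(self):
        return [p for conv in self.convs for p in conv.params()]

    def layers(self):
        return self.convs + self.relus + [self.dropout]

    def forward(self, x, cache, rng):
        h = x
        for conv, relu in zip(self.convs, self.relus):
            h = relu.forward(conv.forward(h, cache), cache)
        h = self.dropout.forward(h, cache, rng)
        if self.residual:
            h = h + x
        return h

    def backward(self, gy):
        g = self.dropout.backward(gy)
        if g is gy and self.residual:
            g = gy.copy()  # the chain mutates g in place; keep gy intact for the residual
        for conv, relu in zip(reversed(self.convs), reversed(self.relus)):
            g = conv.backward(relu.backward(g))
        if self.residual:
            g = g + gy
        return g


class _Transition:
    """Resampling convolution + ReLU between two blocks."""

    def __init__(self, conv):
        self.conv = conv
        self.relu = eg.ReLU()

    def params(self):
        return self.conv.params()

    def layers(self):
        return [self.conv, self.relu]

    def forward(self, x, cache):
        return self.relu.forward(self.conv.forward(x, cache), cache)

    def backward(self, gy):
        return self.conv.backward(self.relu.backward(gy))


class SegNet3d:
    """Encoder-decoder with named-block parameter registry.

    ``forward`` maps ``(in_channels, *target_shape)`` float32 arrays to a
    voxelwise probability map of spatial shape ``target_shape``; training
    entry points additionally cache intermediates and expose ``backward``.
    """

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 421]))
        d, c = config.depth, config.base_channels
        ncv, drop = config.convs_per_block, config.dropout_rate
        cat = config.skip_mode == "concatenate"

        self.stem = eg.Conv3x3(rng, config.in_channels, c, "stem", input_layer=True)
        self.stem_relu = eg.ReLU()
        self.downs, self.dtrans = [], []
        for i in range(d):
            ci = c * 2**i
            self.downs.append(_ConvBlock(rng, ci, ci, ncv, drop, f"down{i + 1}"))
            if i < d - 1:
                self.dtrans.append(_Transition(eg.DownConv(rng, ci, ci * 2, f"dtrans{i + 1}")))
        self.ups, self.utrans = [], []
        cb = c * 2 ** (d - 1)
        self.ups.append(_ConvBlock(rng, cb, cb, ncv, drop, "up1"))
        for j in range(1, d):
            co = c * 2 ** (d - 1 - j)
            self.utrans.append(_Transition(eg.UpConv(rng, co * 2, co, f"utrans{j}")))
            cin_blk = co * 2 if cat else co
            self.ups.append(_ConvBlock(rng, cin_blk, co, ncv, drop, f"up{j + 1}"))
        self.head = eg.Conv1x1(rng, c, 1, "head")

        self._build_registry()
        self._train_rng: np.random.Generator | None = None
        self._cached_prob: np.ndarray | None = None

    # ------------------------------------------------------------------ setup

    def _block_members(self) -> dict[str, list]:
        d = self.config.depth
        members: dict[str, list] = {}
        members[f"{ordinal(1)} down"] = [self.stem, self.downs[0]]
        for i in range(1, d):
            members[f"{ordinal(i + 1)} down"] = [self.dtrans[i - 1], self.downs[i]]
        members[f"{ordinal(1)} up"] = [self.ups[0]]
        for j in range(1, d):
            mem = [self.utrans[j - 1], self.ups[j]]
            if j == d - 1:
                mem.append(self.head)
            members[f"{ordinal(j + 1)} up"] = mem
        return members

    def _build_registry(self):
        self._params: dict[str, eg.Param] = {}
        blocks: dict[str, tuple[str, ...]] = {}
        for name, members in self._block_members().items():
            pnames = []
            for m in members:
                for p in m.params():
                    pnames.append(p.name)
                    self._params[p.name] = p
            blocks[name] = tuple(pnames)
        sizes = {n: p.size for n, p in self._params.items()}
        self.registry = BlockRegistry(blocks, sizes)

    # ------------------------------------------------------------ inference

    def params(self) -> list[eg.Param]:
        return list(self._params.values())

    def param_dict(self) -> dict[str, eg.Param]:
        return self._params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: p.data.copy() for n, p in self._params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, p in self._params.items():
            p.data[...] = state[n]

    def copy(self) -> "SegNet3d":
        clone = SegNet3d(self.config, seed=0)
        clone.load_state_dict(self.state_dict())
        for n, p in self._params.items():
            clone._params[n].trainable = p.trainable
        return clone

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        expect = (self.config.in_channels, *self.config.target_shape)
        if x.shape != expect:
            raise ValueError(f"input shape {x.shape} does not match expected {expect}")
        return x

    def _forward_one(self, x: np.ndarray, cache: bool, rng) -> np.ndarray:
        cat = self.config.skip_mode == "concatenate"
        d = self.config.depth
        h = self.stem_relu.forward(self.stem.forward(x, cache), cache)
        skips = []
        for i in range(d):
            h = self.downs[i].forward(h, cache, rng)
            skips.append(h)
            if i < d - 1:
                h = self.dtrans[i].forward(h, cache)
        h = self.ups[0].forward(h, cache, rng)
        for j in range(1, d):
            h = self.utrans[j - 1].forward(h, cache)
            s = skips[d - 1 - j]
            h = np.concatenate([h, s], axis=0) if cat else h + s
            h = self.ups[j].forward(h, cache, rng)
        z = self.head.forward(h, cache)[0]
        prob = eg.sigmoid(z)
        if cache:
            self._cached_prob = prob
        return prob

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Inference on one volume; dropout disabled, no caches kept."""
        return self._forward_one(self._check_input(x), cache=False, rng=None)

    def forward_batch(self, xs: np.ndarray) -> np.ndarray:
        """Inference on a batch (N, in_channels, *target_shape)."""
        return np.stack([self.forward(x) for x in xs])

    # ------------------------------------------------------------- training

    def forward_train(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Forward pass with dropout active and caches kept for backward."""
        return self._forward_one(self._check_input(x), cache=True, rng=rng)

    def backward(self, dprob: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/dprob."""
        prob = self._cached_prob
        dz = (dprob * prob * (1.0 - prob)).astype(np.float32)
        dz[np.abs(dz) < 1e-30] = 0.0  # flush denormals; they stall the fp units
        dz = dz[None]
        cat = self.config.skip_mode == "concatenate"
        d = self.config.depth
        g = self.head.backward(dz)
        skip_grads: dict[int, np.ndarray] = {}
        for j in range(d - 1, 0, -1):
            g = self.ups[j].backward(g)
            if cat:
                cu = self.utrans[j - 1].conv.cout
                gu, gs = g[:cu], g[cu:]
            else:
                gu, gs = g, g
            idx = d - 1 - j
            skip_grads[idx] = skip_grads.get(idx, 0) + gs
            g = self.utrans[j - 1].backward(np.ascontiguousarray(gu))
        g = self.ups[0].backward(g)
        for i in range(d - 1, -1, -1):
            total = g + skip_grads.get(i, 0) if i < d - 1 else g
            g = self.downs[i].backward(np.ascontiguousarray(total))
            if i > 0:
                g = self.dtrans[i - 1].backward(g)
        self.stem.backward(self.stem_relu.backward(g))
        self._cached_prob = None

    # ----------------------------------------------------------- checkpoints

    def save(self, path: str | Path) -> None:
        """Write parameters (npz) plus a JSON block manifest alongside."""
        path = Path(path)
        np.savez(path, **self.state_dict(), __depth=self.config.depth)
        shapes = {n: p.data.shape for n, p in self._params.items()}
        manifest = {
            "config": {
                "depth": self.config.depth,
                "base_channels": self.config.base_channels,
                "in_channels": self.config.in_channels,
                "convs_per_block": self.config.convs_per_block,
                "dropout_rate": self.config.dropout_rate,
                "skip_mode": self.config.skip_mode,
                "target_shape": list(self.config.target_shape),
            },
            "blocks": self.registry.manifest(shapes),
        }
        mpath = path.with_suffix(path.suffix + ".json") if path.suffix != ".npz" else path.with_suffix(".json")
        mpath.write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SegNet3d":
        path = Path(path)
        mpath = path.with_suffix(".json")
        cfg = json.loads(mpath.read_text())["config"]
        cfg["target_shape"] = tuple(cfg["target_shape"])
        model = cls(NetConfig(**cfg))
        with np.load(path) as data:
            model.load_state_dict({n: data[n] for n in model._params})
        return model


def build_network(config: NetConfig, seed: int = 0) -> tuple[SegNet3d, BlockRegistry]:
    """Construct the network and its block registry."""
    model = SegNet3d(config, seed=seed)
    return model, model.registry


def binarize(prob_map: np.ndarray, threshold: float, spacing=(1.0, 1.0, 1.0),
             identifier: str = "") -> VoiMask:
    """Threshold a probability map into a binary VOI (>= threshold is tumor)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    data = (np.asarray(prob_map) >= threshold).astype(np.uint8)
    return VoiMask(data=data, spacing=tuple(spacing), identifier=identifier)
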