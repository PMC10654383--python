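"""The small U-Net family used for just-in-time denoising.

The architecture is a symmetric encoder/decoder with concatenating skip
connections.  Each resolution level applies three 3x3 convolutions
(ReLU after each); levels are bridged by 2x2 strided convolutions going
down and 2x2 transposed convolutions going up, doubling/halving the
feature count.  The ``Standard`` network starts at 8 feature maps with
three down/upscaling levels, i.e. level widths (8, 16, 32) with a
64-wide two-convolution bridge at the bottom.  Volumetric (``Zx``) and
temporal (``Tx``) variants use 3x3x3 convolutions, treat the extra axis
like the in-plane ones (but never downsample it), and collapse it to the
middle slice/frame in the final projection.

Networks are fully convolutional: inputs of any in-plane size are
reflect-padded to the next multiple of ``2**levels`` and the output is
cropped back, so a network trained on 20x20 patches can be applied to
full slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conv_ops import ConvSame, Down2, Up2, Project, ReLU, Layer

__all__ = [
    "NetworkSpec",
    "Network",
    "build_network",
    "parameter_count",
    "PRESETS",
    "preset_spec",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters of one U-Net variant.

    ``input_shape`` is the (n_x, n_y, n_z) training patch size; it does
    not affect the weights (the network is fully convolutional) but is
    recorded because pair sampling reads it.  ``frames`` > 1 selects the
    temporal (2D+time) mode, ``input_shape[2]`` > 1 the volumetric mode.
    """

    base_features: int = 8
    levels: int = 3
    convs_per_block: int = 3
    input_shape: tuple[int, int, int] = (20, 20, 1)
    frames: int = 1
    mode: str = "2D"  # "2D" | "2D+time" | "3D"
    name: str = "custom"

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError(f"invalid levels={self.levels}: must be >= 1")
        if self.base_features < 1:
            raise ValueError(f"invalid base_features={self.base_features}")
        if self.convs_per_block < 1:
            raise ValueError(f"invalid convs_per_block={self.convs_per_block}")
        if self.frames < 1 or self.frames % 2 == 0:
            raise ValueError(f"invalid frames={self.frames}: must be odd")
        if self.mode not in ("2D", "2D+time", "3D"):
            raise ValueError(f"invalid mode={self.mode!r}")
        if self.mode == "2D" and (self.frames != 1 or self.input_shape[2] != 1):
            raise ValueError("mode='2D' requires frames=1 and n_z=1")
        if len(self.input_shape) != 3 or any(s < 1 for s in self.input_shape):
            raise ValueError(f"invalid input_shape={self.input_shape}")

    @property
    def nd(self) -> int:
        """Number of spatial dims of the convolutions (2 or 3)."""
        return 2 if self.mode == "2D" else 3

    @property
    def depth(self) -> int:
        """Extent of the third (slice or frame) input axis."""
        return self.frames if self.mode == "2D+time" else self.input_shape[2]

    @property
    def min_inplane(self) -> int:
        return 2 ** self.levels


def _table1(name, **kw) -> NetworkSpec:
    return NetworkSpec(name=name, **kw)


#: The architecture presets of the published comparison: feature-map
#: variants (Cx), training patch sizes (Vx), slice counts (Zx) and
#: timeframe counts (Tx), all deviations from ``Standard``.
PRESETS: dict[str, NetworkSpec] = {
    "standard": _table1("standard"),
    "c16": _table1("c16", base_features=16),
    "c32": _table1("c32", base_features=32),
    "v30": _table1("v30", input_shape=(30, 30, 1)),
    "v40": _table1("v40", input_shape=(40, 40, 1)),
    "v60": _table1("v60", input_shape=(60, 60, 1)),
    "v100": _table1("v100", input_shape=(100, 100, 1)),
    "v150": _table1("v150", input_shape=(150, 150, 1)),
    "z3": _table1("z3", input_shape=(20, 20, 3), mode="3D"),
    "z5": _table1("z5", input_shape=(20, 20, 5), mode="3D"),
    "z7": _table1("z7", input_shape=(20, 20, 7), mode="3D"),
    "t3": _table1("t3", frames=3, mode="2D+time"),
    "t5": _table1("t5", frames=5, mode="2D+time"),
    "t7": _table1("t7", frames=7, mode="2D+time"),
}


def preset_spec(name: str) -> NetworkSpec:
    key = name.lower()
    if key not in PRESETS:
        raise KeyError(f"unknown architecture preset {name!r}; choose from {sorted(PRESETS)}")
    return PRESETS[key]


class Network:
    """A U-Net instance: spec, weights and a step counter."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.seed = int(seed)
        self.step = 0
        rng = np.random.default_rng(np.random.SeedSequence([0x7E7, self.seed]))
        nd = spec.nd
        w = [spec.base_features * 2**i for i in range(spec.levels)]
        self.level_widths = tuple(w)
        bridge = w[-1] * 2

        def block(cin, cout):
            layers: list[Layer] = []
            for j in range(spec.convs_per_block):
                layers.append(ConvSame(cin if j == 0 else cout, cout, nd, rng))
                layers.append(ReLU())
            return layers

        self.enc_blocks = []
        self.downs = []
        cin = 1
        for i in range(spec.levels):
            self.enc_blocks.append(block(cin, w[i]))
            nxt = bridge if i == spec.levels - 1 else w[i + 1]
            self.downs.append(Down2(w[i], nxt, nd, rng))
            cin = nxt
        # Two-convolution bridge at the lowest resolution.
        self.bridge = [ConvSame(bridge, bridge, nd, rng), ReLU(), ConvSame(bridge, bridge, nd, rng), ReLU()]
        self.ups = []
        self.dec_blocks = []
        above = bridge
        for i in reversed(range(spec.levels)):
            self.ups.append(Up2(above, w[i], nd, rng))
            self.dec_blocks.append(block(2 * w[i], w[i]))
            above = w[i]
        self.final = Project(w[0], 1, nd, spec.depth)

    # -- parameter access -------------------------------------------------
    def _layers(self) -> list[Layer]:
        out: list[Layer] = []
        for blk, down in zip(self.enc_blocks, self.downs):
            out.extend(blk)
            out.append(down)
        out.extend(self.bridge)
        for up, blk in zip(self.ups, self.dec_blocks):
            out.append(up)
            out.extend(blk)
        out.append(self.final)
        return out

    def params(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self._layers() for g in layer.grads()]

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params()))

    def state_dict(self) -> dict:
        return {f"p{i}": p.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            src = state[f"p{i}"]
            if src.shape != p.shape:
                raise ValueError(f"checkpoint shape mismatch at parameter {i}")
            p[...] = src

    # -- forward / backward ------------------------------------------------
    def _check_and_pad(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        m = 2 ** self.spec.levels
        h, wdt = x.shape[-2:]
        if h < self.spec.min_inplane or wdt < self.spec.min_inplane:
            raise ValueError(
                f"input in-plane size {(h, wdt)} below minimum {self.spec.min_inplane} for levels={self.spec.levels}"
            )
        ph, pw = (-h) % m, (-wdt) % m
        if ph or pw:
            pads = [(0, 0)] * (x.ndim - 2) + [(0, ph), (0, pw)]
            x = np.pad(x, pads, mode="reflect")
        return x, (h, wdt)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Forward pass on a batch ``(B, 1, [D,] H, W)``; caches for backward."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        x, (h, wdt) = self._check_and_pad(x)
        self._pad_shape = x.shape[-2:]
        skips = []
        for blk, down in zip(self.enc_blocks, self.downs):
            for layer in blk:
                x = layer.forward(x)
            skips.append(x)
            x = down.forward(x)
        for layer in self.bridge:
            x = layer.forward(x)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            for layer in blk:
                x = layer.forward(x)
        x = self.final.forward(x)
        return np.ascontiguousarray(x[..., :h, :wdt])

    def backward(self, dy: np.ndarray) -> None:
        """Accumulate parameter gradients for the loss gradient ``dy``."""
        ph, pw = self._pad_shape
        if dy.shape[-2:] != (ph, pw):
            full = np.zeros(dy.shape[:-2] + (ph, pw), dtype=np.float32)
            full[..., : dy.shape[-2], : dy.shape[-1]] = dy
            dy = full
        dy = self.final.backward(np.ascontiguousarray(dy, dtype=np.float32))
        skip_grads = []
        # Walk the decoder in reverse order.
        for up, blk, nskip in zip(self.ups[::-1], self.dec_blocks[::-1], self._skip_channels[::-1]):
            for layer in blk[::-1]:
                dy = layer.backward(dy)
            dskip, dy = dy[:, :nskip], dy[:, nskip:]
            skip_grads.append(np.ascontiguousarray(dskip))
            dy = up.backward(np.ascontiguousarray(dy))
        for layer in self.bridge[::-1]:
            dy = layer.backward(dy)
        # skip_grads were appended shallowest level first; the encoder is
        # walked from the deepest level back, so reverse them.
        for (blk, down), dskip in zip(
            zip(self.enc_blocks[::-1], self.downs[::-1]), skip_grads[::-1]
        ):
            dy = down.backward(dy)
            dy = dy + dskip
            for layer in blk[::-1]:
                dy = layer.backward(dy)

    def apply(self, patch: np.ndarray) -> np.ndarray:
        """Denoise one image (inference; no caching kept afterwards).

        Accepts ``(H, W)`` for 2-D nets or ``(D, H, W)`` for volumetric /
        temporal nets and returns the same in-plane shape with the depth
        axis collapsed to the middle slice.
        """
        arr = np.asarray(patch, dtype=np.float32)
        nd = self.spec.nd
        if arr.ndim != nd:
            raise ValueError(f"expected a {nd}-dimensional input for mode={self.spec.mode}")
        if nd == 3 and arr.shape[0] != self.spec.depth:
            raise ValueError(
                f"expected depth {self.spec.depth} (slices/frames), got {arr.shape[0]}"
            )
        out = self.forward(arr[None, None])
        return out[0, 0, 0] if nd == 3 else out[0, 0]


def build_network(spec: NetworkSpec, seed: int = 0) -> Network:
    """Construct a network with deterministic He initialisation.

    The final projection is zero-initialised so the untrained network
    outputs a constant; identical seeds give bitwise-identical weights.
    """
    return Network(spec, seed)


def parameter_count(spec: NetworkSpec) -> int:
    """Exact number of free parameters of a spec (weights + biases)."""
    return build_network(spec, seed=0).parameter_count()
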