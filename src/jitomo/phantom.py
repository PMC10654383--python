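"""Dynamic dissolving-tablet phantom.

The scene emulates a desk-scale version of a tablet dissolving in a
liquid-filled glass cylinder: a granular bed at the bottom, a tablet
resting on it, and gas bubbles that nucleate at the tablet, rise with a
constant per-bubble velocity, and vanish at the liquid surface.  Two
named regimes mirror the qualitative difference between the imaged
experiments: regime ``A`` produces fast, large bubbles; regime ``B``
slow, small ones.  The bubble size/speed distributions of the real
experiments were never quantified, so the preset numbers are
order-of-magnitude choices, not measured values.

The state at time ``t`` is a pure function of ``(config, t)``: births
are generated block-wise (one block per second) from counter-based
seeds, so querying any time never mutates hidden state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RegimeConfig",
    "PhantomState",
    "Bubble",
    "regime_preset",
    "phantom_state",
    "render_attenuation",
    "attenuation_at",
]

#: Linear attenuation coefficients (1/length, length unit = voxel edge).
DEFAULT_ATTENUATION = {
    "liquid": 0.020,
    "gas": 0.0,
    "glass": 0.050,
    "grain": 0.035,
    "tablet": 0.045,
}


@dataclass(frozen=True)
class RegimeConfig:
    """Generative parameters of one experimental regime."""

    regime_label: str = "A"
    bubble_radius_range: tuple[float, float] = (3.0, 6.0)
    bubble_speed_range: tuple[float, float] = (25.0, 50.0)  # voxels / second
    bubble_birth_rate: float = 3.0  # bubbles / second
    container_radius: float = 24.0
    container_height: float = 64.0
    glass_thickness: float = 2.0
    granular_bed_height: float = 8.0
    tablet_center: tuple[float, float, float] = (0.0, 0.0, -18.0)
    tablet_radius: float = 6.0
    liquid_height: float = 56.0  # fill level measured from the container floor
    attenuation_map: dict = field(default_factory=lambda: dict(DEFAULT_ATTENUATION))
    seed: int = 0

    def __post_init__(self):
        if self.bubble_radius_range[0] <= 0 or self.bubble_radius_range[1] < self.bubble_radius_range[0]:
            raise ValueError(f"invalid bubble_radius_range {self.bubble_radius_range}")
        if self.bubble_birth_rate < 0:
            raise ValueError("bubble_birth_rate must be >= 0")
        if any(v < 0 for v in self.attenuation_map.values()):
            raise ValueError("attenuation values must be >= 0")

    # The container is centred on the rotation axis, spanning z in
    # [-h/2, h/2]; derived landmarks:
    @property
    def z_bottom(self) -> float:
        return -self.container_height / 2.0

    @property
    def z_top(self) -> float:
        return self.container_height / 2.0

    @property
    def liquid_surface(self) -> float:
        return self.z_bottom + self.liquid_height

    @property
    def bed_top(self) -> float:
        return self.z_bottom + self.granular_bed_height


_PRESETS = {
    "A": RegimeConfig(
        regime_label="A",
        bubble_radius_range=(3.0, 6.0),
        bubble_speed_range=(25.0, 50.0),
        bubble_birth_rate=3.0,
    ),
    "B": RegimeConfig(
        regime_label="B",
        bubble_radius_range=(1.2, 2.8),
        bubble_speed_range=(6.0, 15.0),
        bubble_birth_rate=2.0,
    ),
}


def regime_preset(label: str, seed: int = 0) -> RegimeConfig:
    """Named preset for regime ``A`` (fast/large) or ``B`` (slow/small)."""
    if label not in _PRESETS:
        raise KeyError(f"unknown regime {label!r}; choose 'A' or 'B'")
    return replace(_PRESETS[label], seed=int(seed))


@dataclass(frozen=True)
class Bubble:
    center: tuple[float, float, float]
    radius: float
    velocity: float  # vertical, voxels/second


@dataclass(frozen=True)
class PhantomState:
    """Scene snapshot: static landmarks come from ``config``."""

    time: float
    bubbles: tuple[Bubble, ...]
    config: RegimeConfig


def _births_in_block(cfg: RegimeConfig, block: int):
    """Bubble births inside second-block ``[block, block+1)``.

    Counter-based seeding keeps the state a pure function of (seed, t).
    """
    rng = np.random.default_rng(np.random.SeedSequence([0xB0B, cfg.seed & 0x7FFFFFFF, block]))
    n = rng.poisson(cfg.bubble_birth_rate)
    births = []
    for _ in range(n):
        t0 = block + rng.uniform()
        r = rng.uniform(*cfg.bubble_radius_range)
        v = rng.uniform(*cfg.bubble_speed_range)
        # nucleation: on/near the tablet, clamped inside the container wall
        ang = rng.uniform(0, 2 * np.pi)
        rad = cfg.tablet_radius * np.sqrt(rng.uniform())
        x = cfg.tablet_center[0] + rad * np.cos(ang)
        y = cfg.tablet_center[1] + rad * np.sin(ang)
        rho = np.hypot(x, y)
        rmax = cfg.container_radius - r
        if rho > rmax > 0:
            x, y = x * rmax / rho, y * rmax / rho
        z0 = cfg.tablet_center[2] + cfg.tablet_radius
        births.append((t0, x, y, z0, r, v))
    return births


def phantom_state(cfg: RegimeConfig, t: float) -> PhantomState:
    """Deterministic scene state at time ``t`` (seconds)."""
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    bubbles = []
    if cfg.bubble_birth_rate > 0:
        # A bubble born at t0 lives until its top passes the surface;
        # only blocks recent enough to matter need to be generated.
        vmin = max(cfg.bubble_speed_range[0], 1e-9)
        max_life = (cfg.liquid_surface - (cfg.tablet_center[2])) / vmin + 1.0
        first_block = max(0, int(np.floor(t - max_life)))
        for block in range(first_block, int(np.floor(t)) + 1):
            for (t0, x, y, z0, r, v) in _births_in_block(cfg, block):
                if t0 > t:
                    continue
                z = z0 + v * (t - t0)
                if z - r > cfg.liquid_surface:
                    continue  # burst at the surface
                bubbles.append(Bubble((x, y, z), r, v))
    return PhantomState(time=float(t), bubbles=tuple(bubbles), config=cfg)


def attenuation_at(state: PhantomState, pts: np.ndarray) -> np.ndarray:
    """Attenuation (1/length) at world points ``pts`` of shape (..., 3).

    Composition order (later wins): liquid/gas fill, granular bed,
    tablet, bubbles, glass wall; air (zero) outside the vessel.
    """
    cfg = state.config
    att = cfg.attenuation_map
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
    rho2 = x * x + y * y
    out = np.zeros(pts.shape[:-1], dtype=np.float64)

    in_z = (z >= cfg.z_bottom) & (z <= cfg.z_top)
    interior = (rho2 <= cfg.container_radius**2) & in_z
    liquid = interior & (z <= cfg.liquid_surface)
    out[liquid] = att["liquid"]
    out[interior & ~liquid] = att["gas"]
    out[interior & (z <= cfg.bed_top)] = att["grain"]

    tc = cfg.tablet_center
    tablet = (x - tc[0]) ** 2 + (y - tc[1]) ** 2 + (z - tc[2]) ** 2 <= cfg.tablet_radius**2
    out[tablet & interior] = att["tablet"]

    for b in state.bubbles:
        c = b.center
        d2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
        out[(d2 <= b.radius**2) & interior] = att["gas"]

    wall = in_z & (rho2 > cfg.container_radius**2) & (
        rho2 <= (cfg.container_radius + cfg.glass_thickness) ** 2
    )
    out[wall] = att["glass"]
    return out


def render_attenuation(
    state: PhantomState,
    shape: tuple[int, ...],
    voxel_size: float,
    origin: tuple[float, ...] | None = None,
    supersample: int = 2,
    slice_z: float | None = None,
) -> np.ndarray:
    """Voxelise the scene on a regular grid.

    ``shape`` is (n_x, n_y) with ``slice_z`` given (a horizontal slice)
    or (n_x, n_y, n_z) for a volume.  Voxel centres sit at
    ``origin + (i + 0.5) * h`` per axis; by default the grid is centred
    on the world origin.  Anti-aliasing: each voxel is supersampled
    ``supersample`` times per axis and the occupancy averaged.
    """
    if voxel_size <= 0:
        raise ValueError(f"voxel size must be positive, got {voxel_size}")
    if len(shape) == 2 and slice_z is None:
        raise ValueError("2-D grids need slice_z")
    ndim = len(shape)
    h = float(voxel_size)
    if origin is None:
        origin = tuple(-h * n / 2.0 for n in shape)
    s = int(supersample)
    axes = []
    for n, o in zip(shape, origin):
        # supersample offsets inside each voxel
        sub = (np.arange(s) + 0.5) / s
        centers = o + h * (np.arange(n)[:, None] + sub[None, :])
        axes.append(centers.reshape(-1))
    grids = np.meshgrid(*axes, indexing="ij")
    if ndim == 2:
        pts = np.stack([grids[0], grids[1], np.full_like(grids[0], slice_z)], axis=-1)
    else:
        pts = np.stack(grids, axis=-1)
    vals = attenuation_at(state, pts)
    # average the s**ndim subsamples back onto the voxel grid
    new_shape = []
    for n in shape:
        new_shape.extend([n, s])
    vals = vals.reshape(new_shape)
    for ax in reversed(range(1, 2 * ndim, 2)):
        vals = vals.mean(axis=ax)
    return vals
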