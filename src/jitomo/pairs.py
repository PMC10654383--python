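"""Noise2Inverse training-pair generation.

A training pair (u, v) is built from one full-rotation projection
window: the window's frames are split by the parity of their global
index, each half is reconstructed on the same random region-of-interest
patch, and the two half-reconstructions — same object, statistically
independent photon noise — become input and target.  Which half plays
which role is decided by a fair coin per pair, removing any systematic
even/odd bias (switchable for reproducing fixed-role behaviour).

Patch centres are sampled uniformly inside a cylindrical region kept
strictly inside the vessel, so no pair ever contains wall artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .phantom import RegimeConfig
from .projector import ProjectionStream
from .recon import PatchSpec, SinogramBuffer, backproject, reconstruct

__all__ = [
    "SamplingRegion",
    "TrainingPair",
    "split_even_odd",
    "sample_patch_spec",
    "make_pair",
    "PairGenerator",
]


@dataclass(frozen=True)
class SamplingRegion:
    """Cylindrical patch-sampling mask in world units.

    ``half`` optionally restricts sampling to the top or bottom half of
    the region (along the in-plane y axis for single-slice work, which
    is how a repositioned slice is emulated in the 2-D test geometry).
    """

    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 20.0
    z_range: tuple[float, float] = (0.0, 0.0)
    half: str | None = None  # None | "top" | "bottom"

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("region radius must be positive")
        if self.half not in (None, "top", "bottom"):
            raise ValueError(f"half must be None, 'top' or 'bottom', got {self.half!r}")

    def with_half(self, half: str | None) -> "SamplingRegion":
        return replace(self, half=half)


def split_even_odd(indices) -> tuple[np.ndarray, np.ndarray]:
    """Partition global frame indices by parity (even first)."""
    idx = np.asarray(list(indices), dtype=int)
    return idx[idx % 2 == 0], idx[idx % 2 == 1]


def sample_patch_spec(
    region: SamplingRegion,
    shape: tuple[int, int, int],
    voxel_size: float,
    time_index: int,
    rng: np.random.Generator,
    orientation: str = "axis",
    n_frames: int = 1,
    frame_stride: int = 60,
    subset: object = "ALL",
) -> PatchSpec:
    """Draw a patch placement uniformly over the admissible sub-region.

    The admissible set keeps the whole (possibly rotated) patch inside
    the region: centres are restricted to ``radius - circumradius``.
    ``orientation`` is ``"axis"`` (axis-aligned), ``"random"`` (uniform
    in-plane rotation), or a fixed angle in radians.
    """
    nx, ny, nz = shape
    h = float(voxel_size)
    circum = 0.5 * h * float(np.hypot(nx, ny))
    r_adm = region.radius - circum
    if r_adm < 0:
        raise ValueError(
            f"patch (circumradius {circum:.1f}) does not fit in region radius {region.radius:.1f}"
        )
    if orientation not in ("axis", "random") and not isinstance(orientation, (int, float)):
        raise ValueError(f"orientation must be 'axis', 'random' or an angle, got {orientation!r}")
    # uniform over the admissible disk (or half-disk), by rejection
    cx, cy = region.center
    for _ in range(10_000):
        x = cx + r_adm * (2 * rng.uniform() - 1)
        y = cy + r_adm * (2 * rng.uniform() - 1)
        if (x - cx) ** 2 + (y - cy) ** 2 > r_adm**2:
            continue
        # the half selector constrains the patch centre, not its extent
        if region.half == "top" and y < cy:
            continue
        if region.half == "bottom" and y > cy:
            continue
        break
    else:  # pragma: no cover - only for pathological regions
        raise RuntimeError("could not place a patch in the region")
    z0, z1 = region.z_range
    z = rng.uniform(z0, z1) if z1 > z0 else z0
    if orientation == "random":
        theta = rng.uniform(0, 2 * np.pi)
    elif orientation == "axis":
        theta = 0.0
    else:
        theta = float(orientation)
    ca, sa = np.cos(theta), np.sin(theta)
    return PatchSpec(
        center=(x, y, z),
        size=tuple(shape),
        voxel_size=h,
        time_index=int(time_index),
        axis_u=(ca, sa, 0.0),
        axis_v=(-sa, ca, 0.0),
        subset=subset,
        n_frames=n_frames,
        frame_stride=frame_stride,
    )


@dataclass
class TrainingPair:
    """One Noise2Inverse sample.

    ``u`` is the network input — shape (H, W) for 2-D patches, or
    (frames, H, W) for temporal sequences / (slices, H, W) for slabs;
    ``v`` is the single-frame target, centre-matched to ``u``.  The two
    derive from disjoint projection subsets of the same window.
    """

    u: np.ndarray
    v: np.ndarray
    creation_time: float
    time_index: int
    u_subset: str
    frame_indices: frozenset

    @property
    def shape_key(self) -> tuple:
        return (self.u.shape, self.v.shape)


def make_pair(
    source: ProjectionStream | SinogramBuffer,
    spec: PatchSpec,
    rng: np.random.Generator,
    symmetrize: bool = True,
) -> TrainingPair:
    """Reconstruct the even/odd halves of ``spec``'s window as (u, v).

    For temporal specs (``n_frames`` > 1) the input is the whole
    sequence from one half and the target the middle frame from the
    other half.  With ``symmetrize`` a fair coin decides which half is
    the input (default); otherwise even is always the input.
    """
    even_first = bool(rng.integers(2)) if symmetrize else True
    u_sub, v_sub = ("EVEN", "ODD") if even_first else ("ODD", "EVEN")

    u_spec = replace(spec, subset=u_sub)
    # target: middle frame of the sequence, single reconstruction
    mid_t = spec.time_index - (spec.n_frames // 2) * spec.frame_stride
    v_spec = replace(spec, subset=v_sub, time_index=mid_t, n_frames=1)

    if isinstance(source, SinogramBuffer):
        u_patch = backproject(source, u_spec)
        v_patch = backproject(source, v_spec)
        geom = source.geometry
    else:
        u_patch = reconstruct(source, u_spec)
        v_patch = reconstruct(source, v_spec)
        geom = source.geometry

    # network layout: (H, W) single patches, (D, H, W) slabs/sequences
    uv = u_patch.values
    if spec.n_frames > 1:  # (nx, ny, 1, frames) -> (frames, nx, ny)
        u_arr = np.moveaxis(uv[:, :, 0, :], -1, 0)
    elif spec.size[2] > 1:  # slab: (nx, ny, nz) -> (nz, nx, ny)
        u_arr = np.moveaxis(uv, -1, 0)
    else:
        u_arr = uv[:, :, 0]
    if spec.size[2] > 1:
        v_arr = v_patch.values[:, :, spec.size[2] // 2]
    else:
        v_arr = v_patch.values[:, :, 0]

    lo = spec.time_index - (spec.n_frames - 1) * spec.frame_stride - geom.m_phi + 1
    frames = frozenset(range(lo, spec.time_index + 1))
    return TrainingPair(
        u=np.ascontiguousarray(u_arr, dtype=np.float32),
        v=np.ascontiguousarray(v_arr, dtype=np.float32),
        creation_time=float(spec.time_index * geom.exposure_per_frame),
        time_index=spec.time_index,
        u_subset=u_sub,
        frame_indices=frames,
    )


class PairGenerator:
    """Draws random patches from a stream window and reconstructs pairs.

    Also keeps the production counter (``n_produced``) that the online
    trainer's buffer statistics are checked against.
    """

    def __init__(
        self,
        stream: ProjectionStream,
        region: SamplingRegion,
        patch_shape: tuple[int, int, int] = (20, 20, 1),
        voxel_size: float | None = None,
        orientation: str = "axis",
        n_frames: int = 1,
        frame_stride: int = 60,
        rng: np.random.Generator | None = None,
        symmetrize: bool = True,
    ):
        self.stream = stream
        self.region = region
        self.patch_shape = tuple(patch_shape)
        self.voxel_size = float(voxel_size if voxel_size is not None else stream.geometry.voxel_size)
        self.orientation = orientation
        self.n_frames = int(n_frames)
        self.frame_stride = int(frame_stride)
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.symmetrize = symmetrize
        self.n_produced = 0

    def earliest_time_index(self) -> int:
        """First time index with a complete (possibly temporal) window."""
        m = self.stream.geometry.m_phi
        return (self.stream.first_frame_index + m - 1
                + (self.n_frames - 1) * self.frame_stride)

    def generate(self, time_index: int, region: SamplingRegion | None = None) -> TrainingPair:
        spec = sample_patch_spec(
            region if region is not None else self.region,
            self.patch_shape,
            self.voxel_size,
            time_index,
            self.rng,
            orientation=self.orientation,
            n_frames=self.n_frames,
            frame_stride=self.frame_stride,
        )
        pair = make_pair(self.stream, spec, self.rng, symmetrize=self.symmetrize)
        self.n_produced += 1
        return pair

    @staticmethod
    def default_region(cfg: RegimeConfig, margin: float = 4.0) -> SamplingRegion:
        """Sampling mask strictly inside the glass container."""
        return SamplingRegion(center=(0.0, 0.0), radius=cfg.container_radius - margin)
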