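"""Streaming projection simulator.

Turns a dynamic phantom into the photon-count stream a detector would
record: per frame, the scene at that frame's wall time is voxelised,
line integrals are taken along the beam for the frame's rotation angle,
counts follow Beer–Lambert ``I = I0 * exp(-integral)`` with Poisson
counting noise and an additive dark level, and flat/dark fields are
emitted once at stream start.

Two beam modes are supported, mirroring the reconstruction engine:
parallel 2-D (a single horizontal slice through the vessel, the default
desk-scale test geometry) and cone-beam 3-D at small volume sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.ndimage import map_coordinates

from .geometry import AcquisitionGeometry
from .phantom import RegimeConfig, phantom_state, render_attenuation

__all__ = [
    "NoiseConfig",
    "ProjectionFrame",
    "ProjectionStream",
    "project_parallel",
    "project_cone",
    "simulate_stream",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Photon statistics of the simulated detector.

    ``i0`` is the unattenuated (flat-field) count per pixel;
    ``dark_level`` the mean additive dark count.  With ``poisson=False``
    the stream is the exact noiseless expectation (useful for oracles).
    """

    i0: float = 1000.0
    dark_level: float = 4.0
    poisson: bool = True

    def __post_init__(self):
        if self.i0 <= 0:
            raise ValueError(f"i0 must be > 0, got {self.i0}")
        if self.dark_level < 0:
            raise ValueError("dark_level must be >= 0")


@dataclass
class ProjectionFrame:
    """One radiograph: raw counts or corrected line integrals."""

    pixels: np.ndarray  # (m_y, m_x)
    frame_index: int
    angle: float
    wall_time: float
    corrected: bool = False


def project_parallel(image: np.ndarray, voxel_size: float, angle: float,
                     det_u: np.ndarray, step: float | None = None) -> np.ndarray:
    """Parallel-beam line integrals of a 2-D image at one angle.

    The detector axis is ``(cos a, sin a)``; rays run along
    ``(-sin a, cos a)``.  Integration samples the image bilinearly at
    ``step`` intervals (default half a voxel) and sums.
    """
    nx, ny = image.shape
    h = float(voxel_size)
    if step is None:
        step = h / 2.0
    half = 0.5 * h * np.hypot(nx, ny)
    ts = np.arange(-half, half + step, step)
    ca, sa = np.cos(angle), np.sin(angle)
    # world coords of sample points: s * u_hat + t * ray_hat
    X = det_u[:, None] * ca - ts[None, :] * sa
    Y = det_u[:, None] * sa + ts[None, :] * ca
    # world -> pixel index (voxel centres at origin-centred grid)
    ix = X / h + (nx - 1) / 2.0
    iy = Y / h + (ny - 1) / 2.0
    vals = map_coordinates(image, [ix.ravel(), iy.ravel()], order=1, mode="constant", cval=0.0)
    return vals.reshape(X.shape).sum(axis=1) * step


def project_cone(volume: np.ndarray, voxel_size: float, angle: float,
                 geom: AcquisitionGeometry, step: float | None = None) -> np.ndarray:
    """Cone-beam line integrals of a volume (n_x, n_y, n_z) at one angle.

    Source at ``-d_so`` along the ray axis, flat detector at ``+d_od``;
    returns an (m_y, m_x) array of integrals sampled along each ray.
    """
    nx, ny, nz = volume.shape
    h = float(voxel_size)
    if step is None:
        step = h / 2.0
    ca, sa = np.cos(angle), np.sin(angle)
    u_hat = np.array([ca, sa, 0.0])
    r_hat = np.array([-sa, ca, 0.0])
    src = -geom.source_to_origin * r_hat
    det_u = geom.detector_u()
    det_v = geom.detector_v()
    # detector pixel positions in world space
    D = (geom.origin_to_detector * r_hat[None, None, :]
         + det_u[None, :, None] * u_hat[None, None, :]
         + det_v[:, None, None] * np.array([0.0, 0.0, 1.0])[None, None, :])
    rays = D - src
    lengths = np.linalg.norm(rays, axis=-1)
    dirs = rays / lengths[..., None]
    # sample between the two sphere-bounds of the volume around the origin
    radius = 0.5 * h * float(np.sqrt(nx**2 + ny**2 + nz**2))
    t0 = geom.source_to_origin - radius
    t1 = geom.source_to_origin + radius
    ts = np.arange(t0, t1 + step, step)
    pts = src[None, None, None, :] + dirs[:, :, None, :] * ts[None, None, :, None]
    ix = pts[..., 0] / h + (nx - 1) / 2.0
    iy = pts[..., 1] / h + (ny - 1) / 2.0
    iz = pts[..., 2] / h + (nz - 1) / 2.0
    vals = map_coordinates(volume, [ix.ravel(), iy.ravel(), iz.ravel()],
                           order=1, mode="constant", cval=0.0)
    return vals.reshape(pts.shape[:-1]).sum(axis=2) * step


@dataclass
class ProjectionStream:
    """A simulated (or loaded) stream of count frames plus calibration."""

    counts: np.ndarray  # (T, m_y, m_x)
    angles: np.ndarray  # (T,)
    timestamps: np.ndarray  # (T,)
    flat: np.ndarray  # (m_y, m_x)
    dark: np.ndarray  # (m_y, m_x)
    geometry: AcquisitionGeometry
    first_frame_index: int = 0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def frame_indices(self) -> np.ndarray:
        return self.first_frame_index + np.arange(len(self))

    def frame(self, global_index: int) -> ProjectionFrame:
        i = global_index - self.first_frame_index
        if not 0 <= i < len(self):
            raise IndexError(f"frame {global_index} outside stream")
        return ProjectionFrame(
            pixels=self.counts[i],
            frame_index=global_index,
            angle=float(self.angles[i]),
            wall_time=float(self.timestamps[i]),
        )

    # -- persistence: multi-page TIFF + YAML sidecar -----------------------
    def save(self, path) -> None:
        import tifffile

        path = str(path)
        pages = np.concatenate([self.dark[None], self.flat[None], self.counts], axis=0)
        tifffile.imwrite(path, np.clip(np.rint(pages), 0, 65535).astype(np.uint16))
        sidecar = {
            "geometry": self.geometry.to_dict(),
            "dark_page": 0,
            "flat_page": 1,
            "first_frame_page": 2,
            "first_frame_index": int(self.first_frame_index),
            "timestamps": [float(t) for t in self.timestamps],
            "angles": [float(a) for a in self.angles],
            "meta": self.meta,
        }
        with open(path + ".yaml", "w") as fh:
            yaml.safe_dump(sidecar, fh)

    @classmethod
    def load(cls, path) -> "ProjectionStream":
        import tifffile

        path = str(path)
        pages = tifffile.imread(path).astype(np.float64)
        with open(path + ".yaml") as fh:
            side = yaml.safe_load(fh)
        return cls(
            counts=pages[side["first_frame_page"]:],
            angles=np.asarray(side["angles"], dtype=np.float64),
            timestamps=np.asarray(side["timestamps"], dtype=np.float64),
            flat=pages[side["flat_page"]],
            dark=pages[side["dark_page"]],
            geometry=AcquisitionGeometry.from_dict(side["geometry"]),
            first_frame_index=int(side["first_frame_index"]),
            meta=side.get("meta", {}),
        )


def simulate_stream(
    cfg: RegimeConfig,
    geom: AcquisitionGeometry,
    duration: float,
    noise: NoiseConfig | None = None,
    seed: int | None = None,
    slice_z: float | None = None,
    grid_shape: tuple[int, ...] | None = None,
) -> ProjectionStream:
    """Simulate ``duration`` seconds of projection data.

    One frame per exposure slot; frame ``k`` sees the phantom at wall
    time ``k * exposure`` under rotation angle ``2*pi*k/m_phi``.  The
    master ``seed`` (default: ``cfg.seed``) splits into independent
    phantom and noise sub-streams.  ``slice_z`` selects the imaged
    horizontal slice in parallel mode (default: tablet height, where
    the bubbles nucleate); ``grid_shape`` overrides the phantom
    voxelisation grid.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    noise = noise or NoiseConfig()
    master = int(cfg.seed if seed is None else seed)
    from dataclasses import replace

    cfg = replace(cfg, seed=master)
    noise_rng = np.random.default_rng(np.random.SeedSequence([0x4015E, master & 0x7FFFFFFF]))

    h = geom.voxel_size
    n_frames = int(round(duration / geom.exposure_per_frame))
    det_u = geom.detector_u()
    m_x, m_y = geom.detector_shape

    parallel = geom.beam_type == "parallel"
    if parallel:
        if slice_z is None:
            slice_z = cfg.tablet_center[2]
        if grid_shape is None:
            n = int(np.ceil(2 * (cfg.container_radius + cfg.glass_thickness) / h)) + 2
            grid_shape = (n, n)
    else:
        if grid_shape is None:
            n = int(np.ceil(2 * (cfg.container_radius + cfg.glass_thickness) / h)) + 2
            nz = int(np.ceil(cfg.container_height / h)) + 2
            grid_shape = (n, n, nz)

    counts = np.empty((n_frames, m_y, m_x), dtype=np.float64)
    angles = np.empty(n_frames)
    times = np.empty(n_frames)
    for k in range(n_frames):
        t_k = k * geom.exposure_per_frame
        a_k = geom.angle_of_frame(k)
        state = phantom_state(cfg, t_k)
        if parallel:
            img = render_attenuation(state, grid_shape, h, slice_z=slice_z)
            p = project_parallel(img, h, a_k, det_u)[None, :]  # (1, m_x)
        else:
            vol = render_attenuation(state, grid_shape, h)
            p = project_cone(vol, h, a_k, geom)
        expected = noise.i0 * np.exp(-p)
        if noise.poisson:
            frame = noise_rng.poisson(expected) + noise_rng.poisson(
                noise.dark_level, size=expected.shape
            )
        else:
            frame = expected + noise.dark_level
        counts[k] = frame
        angles[k] = a_k
        times[k] = t_k

    flat = np.full((m_y, m_x), noise.i0 + noise.dark_level, dtype=np.float64)
    dark = np.full((m_y, m_x), noise.dark_level, dtype=np.float64)
    return ProjectionStream(
        counts=counts,
        angles=angles,
        timestamps=times,
        flat=flat,
        dark=dark,
        geometry=geom,
        meta={
            "regime": cfg.regime_label,
            "seed": master,
            "i0": noise.i0,
            "dark_level": noise.dark_level,
            "slice_z": slice_z if parallel else None,
        },
    )
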