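"""Acquisition geometry for circular-trajectory scans.

Conventions (fixed once, since they matter for every module downstream):

* World origin sits on the rotation axis at the height of the central
  detector row; the rotation axis is ``z``.
* Projection frame ``k`` is taken at angle ``2*pi*k / m_phi +
  angle_offset``, counter-clockwise.  At angle ``theta`` the detector
  u-axis is ``(cos theta, sin theta, 0)`` and rays travel along
  ``(-sin theta, cos theta, 0)`` (parallel mode) or from a point source
  at ``-source_to_origin`` along that direction (cone mode).
* Detector pixel centres sit at ``(i - (m-1)/2) * pixel_size``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = ["AcquisitionGeometry"]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Description of a circular cone-beam or parallel-beam scan.

    ``detector_shape`` is ``(m_x, m_y)`` = (columns, rows); parallel
    2-D mode uses a single row (``m_y = 1``).  Times are seconds,
    lengths are in the same unit as ``voxel_size`` (millimetres by
    convention in the bundled presets).
    """

    beam_type: str = "parallel"  # "parallel" | "cone"
    m_phi: int = 150
    rotation_period: float = 1.8
    detector_shape: tuple[int, int] = (64, 1)
    detector_pixel_size: float = 1.0
    source_to_origin: float = 0.0
    origin_to_detector: float = 0.0
    voxel_size: float = 1.0
    angle_offset: float = 0.0

    def __post_init__(self):
        if self.beam_type not in ("parallel", "cone"):
            raise ValueError(f"beam_type must be 'parallel' or 'cone', got {self.beam_type!r}")
        if self.m_phi < 2:
            raise ValueError(f"m_phi must be >= 2, got {self.m_phi}")
        if min(self.detector_shape) < 1:
            raise ValueError(f"detector_shape must be positive, got {self.detector_shape}")
        if self.detector_pixel_size <= 0 or self.voxel_size <= 0:
            raise ValueError("pixel and voxel sizes must be positive")
        if self.beam_type == "cone" and (self.source_to_origin <= 0 or self.origin_to_detector < 0):
            raise ValueError("cone beam requires source_to_origin > 0 and origin_to_detector >= 0")

    # -- derived quantities -------------------------------------------------
    @property
    def exposure_per_frame(self) -> float:
        """Seconds per projection frame."""
        return self.rotation_period / self.m_phi

    @property
    def source_to_detector(self) -> float:
        return self.source_to_origin + self.origin_to_detector

    def angle_of_frame(self, index) -> np.ndarray | float:
        """Rotation angle (radians) of global frame ``index``."""
        return 2.0 * np.pi * (np.asarray(index) % self.m_phi) / self.m_phi + self.angle_offset

    def time_of_frame(self, index) -> np.ndarray | float:
        return np.asarray(index) * self.exposure_per_frame

    def detector_u(self) -> np.ndarray:
        """Detector column-centre coordinates (length units)."""
        m = self.detector_shape[0]
        return (np.arange(m) - (m - 1) / 2.0) * self.detector_pixel_size

    def detector_v(self) -> np.ndarray:
        """Detector row-centre coordinates (length units)."""
        m = self.detector_shape[1]
        return (np.arange(m) - (m - 1) / 2.0) * self.detector_pixel_size

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["detector_shape"] = list(self.detector_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        d = dict(d)
        d["detector_shape"] = tuple(d["detector_shape"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "AcquisitionGeometry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
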