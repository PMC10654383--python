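"""Shared fixtures: small synthetic streams built once per session."""

import numpy as np
import pytest

import jitomo
from jitomo.geometry import AcquisitionGeometry
from jitomo.projector import ProjectionStream, project_parallel


@pytest.fixture(scope="session")
def geometry64():
    return jitomo.default_geometry()


@pytest.fixture(scope="session")
def regime_a():
    return jitomo.regime_preset("A", seed=101)


@pytest.fixture(scope="session")
def stream_a(regime_a, geometry64):
    """6 s of noisy regime-A data: a few rotations past warm-up."""
    return jitomo.simulate_stream(regime_a, geometry64, duration=6.0)


def make_disk_image(n=64, radius=20.0, mu=0.02):
    xs = np.arange(n) - (n - 1) / 2.0
    x, y = np.meshgrid(xs, xs, indexing="ij")
    img = np.zeros((n, n))
    img[x**2 + y**2 <= radius**2] = mu
    return img


def make_disk_stream(m_phi=360, n_det=64, mu=0.02, radius=20.0, i0=1000.0,
                     noisy=False, rotations=1, seed=0):
    """Stream of a static uniform disk; optionally Poisson-noisy.

    With ``rotations`` > 1 the noiseless projections are tiled and each
    frame gets a fresh Poisson draw, giving many independent windows of
    the same static object.
    """
    geom = AcquisitionGeometry(beam_type="parallel", m_phi=m_phi,
                               detector_shape=(n_det, 1))
    img = make_disk_image(n_det, radius, mu)
    det_u = geom.detector_u()
    base = np.empty((m_phi, 1, n_det))
    for k in range(m_phi):
        p = project_parallel(img, 1.0, float(geom.angle_of_frame(k)), det_u)
        base[k, 0] = i0 * np.exp(-p)
    counts = np.tile(base, (rotations, 1, 1))
    if noisy:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(counts).astype(np.float64)
    total = m_phi * rotations
    return ProjectionStream(
        counts=counts,
        angles=np.asarray([geom.angle_of_frame(k) for k in range(total)]),
        timestamps=np.arange(total) * geom.exposure_per_frame,
        flat=np.full((1, n_det), i0),
        dark=np.zeros((1, n_det)),
        geometry=geom,
    )


@pytest.fixture(scope="session")
def disk_stream():
    return make_disk_stream()


@pytest.fixture(scope="session")
def disk_image():
    return make_disk_image()
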