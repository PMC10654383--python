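"""Noise-normalised accuracy metrics for self-supervised denoising.

The accuracy of a denoiser A on a pair (u, v) is

    alpha(A, u, v) = ||A(u) - v||^2 / ||u - v||^2,

a squared misfit normalised by the pair's own noise level, which makes
scores comparable across windows with fluctuating noise.  The identity
mapping scores exactly 1; a perfect denoiser on a pair built from one
clean image plus two independent zero-mean i.i.d. noise images scores
about 0.5 for large images (numerator ~ sigma^2, denominator ~
2 sigma^2).  Values below 0.5 are legal — they appear when input and
target have genuinely different underlying content (object motion,
angular-subsampling differences) that the network learns to predict —
and are flagged, not rejected.

The empirical accuracy R^alpha of an evaluation set is the arithmetic
mean of per-pair alphas (not a ratio of summed norms — the two differ).
The out-of-distribution error of a network theta on a foreign set E is

    eps = R^alpha_E[A_theta] - R^alpha_E[A_psi],

the accuracy it loses relative to a baseline psi trained on E itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegeneratePair",
    "AccuracyRecord",
    "alpha",
    "empirical_accuracy",
    "windowed_accuracy",
    "ood_error",
    "build_eval_set",
]


class DegeneratePair(ValueError):
    """u == v exactly: the accuracy denominator vanishes."""


def _input_reference(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """The slice of the input that corresponds to the target.

    For sequence/slab inputs (D, H, W) against a single-frame target,
    the middle slice is the centre-matched reference.
    """
    if u.ndim == v.ndim + 1:
        return u[u.shape[0] // 2]
    return u


def alpha(denoised: np.ndarray, u: np.ndarray, v: np.ndarray) -> float:
    """Noise-normalised accuracy of one denoised output against (u, v)."""
    denoised = np.asarray(denoised, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    u_ref = _input_reference(u, v)
    if denoised.shape != v.shape or u_ref.shape != v.shape:
        raise ValueError(
            f"shape mismatch: denoised {denoised.shape}, input {u_ref.shape}, target {v.shape}"
        )
    denom = float(np.sum((u_ref - v) ** 2))
    if denom == 0.0:
        raise DegeneratePair("input and target are identical")
    return float(np.sum((denoised - v) ** 2)) / denom


@dataclass
class AccuracyRecord:
    """An empirical-accuracy estimate and its provenance."""

    value: float
    n_pairs: int
    window: tuple[float, float] | None = None
    checkpoint_id: str | None = None
    n_degenerate: int = 0
    low_flag: bool = field(init=False)

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.value < 0:
            raise ValueError("accuracy cannot be negative")
        # below the ideal Noise2Noise floor: legal, but worth flagging
        self.low_flag = self.value < 0.5


def empirical_accuracy(denoiser, pairs, window=None, checkpoint_id=None) -> AccuracyRecord:
    """Mean per-pair accuracy of ``denoiser`` over an evaluation set.

    ``denoiser`` is any callable mapping an input patch to a denoised
    patch (e.g. a trained :class:`~jitomo.trainer.Denoiser`).
    Degenerate pairs (u == v) are excluded and counted.
    """
    values = []
    n_degenerate = 0
    for pair in pairs:
        try:
            values.append(alpha(denoiser(pair.u), pair.u, pair.v))
        except DegeneratePair:
            n_degenerate += 1
    if not values:
        raise ValueError("all pairs degenerate; empirical accuracy undefined")
    return AccuracyRecord(
        value=float(np.mean(values)),
        n_pairs=len(values),
        window=window,
        checkpoint_id=checkpoint_id,
        n_degenerate=n_degenerate,
    )


def build_eval_set(generator, time_indices, n_pairs, rng=None) -> list:
    """Fresh hold-out pairs drawn from the given window end indices.

    The pairs record which projection frames they touch, so callers can
    assert disjointness from training windows (pairs are independent
    only if generated from different projection sets).
    """
    rng = rng if rng is not None else generator.rng
    time_indices = np.asarray(time_indices, dtype=int)
    picks = rng.integers(0, len(time_indices), size=n_pairs)
    return [generator.generate(int(time_indices[i])) for i in picks]


def windowed_accuracy(
    checkpoints,
    stream,
    generator_factory,
    window_length: float,
    n_samples: int,
    rng: np.random.Generator,
    spec=None,
) -> list[AccuracyRecord]:
    """Accuracy of each checkpoint on fresh pairs near its timestamp.

    ``checkpoints`` are the trace dicts of a replay run (step, sim_time,
    state, offset/scale); ``generator_factory(rng)`` builds a fresh
    :class:`~jitomo.pairs.PairGenerator` so evaluation draws never
    perturb training reproducibility.  Windows outside the stream are
    skipped with a warning record (value ``nan`` is never emitted; the
    checkpoint is simply absent from the result).
    """
    import warnings

    from .trainer import Denoiser

    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    geom = stream.geometry
    exposure = geom.exposure_per_frame
    last = stream.first_frame_index + len(stream) - 1
    out = []
    for ck in checkpoints:
        gen = generator_factory(rng)
        t_mid = ck["sim_time"]
        t0, t1 = t_mid - window_length / 2, t_mid + window_length / 2
        lo = max(int(np.ceil(t0 / exposure)), gen.earliest_time_index())
        hi = min(int(np.floor(t1 / exposure)), last)
        if hi < lo:
            warnings.warn(f"window around t={t_mid:.2f}s outside stream; skipped")
            continue
        net = _restore(ck, spec)
        den = Denoiser(net, ck["offset"], ck["scale"])
        pairs = build_eval_set(gen, np.arange(lo, hi + 1), n_samples, rng)
        rec = empirical_accuracy(den, pairs, window=(t0, t1), checkpoint_id=ck["id"])
        out.append(rec)
    return out


def _restore(ck, spec):
    from .model import build_network

    if "network" in ck:
        return ck["network"]
    if spec is None:
        raise ValueError("pass spec= to rebuild networks from checkpoint state dicts")
    net = build_network(spec, seed=0)
    net.load_state_dict(ck["state"])
    net.step = ck["step"]
    return net


def ood_error(denoiser_theta, denoiser_psi, eval_pairs) -> float:
    """Accuracy penalty of ``theta`` on foreign data, against baseline ``psi``.

    Positive values mean the foreign-trained network is worse on this
    set than the matched baseline; zero when both are the same network.
    """
    r_theta = empirical_accuracy(denoiser_theta, eval_pairs).value
    r_psi = empirical_accuracy(denoiser_psi, eval_pairs).value
    return r_theta - r_psi
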