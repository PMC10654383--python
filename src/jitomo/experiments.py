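"""Scripted experiment templates tying the modules into reproducible runs.

Three templates mirror the evaluation programme of the method:

* :func:`run_ood_grid` — quantify out-of-distribution error for
  pipeline discontinuities (repositioning, tilting, zooming) and
  distribution drift (later time, other regime);
* :func:`run_architecture_sweep` — accuracy-versus-step curves of the
  U-Net presets trained under a fixed budget on a fixed data window;
* :func:`run_discontinuity_replay` — buffered online strategies versus
  the no-buffer and frozen-pretrained baselines across a simulated
  sampling-region jump.

Every run is a pure function of its :class:`ExperimentConfig`; reports
embed the config hash and master seed.  The default problem sizes are
desk-scale (64-pixel detector, 150 projections per 1.8 s rotation,
hundreds of training steps) so each template finishes in minutes on one
CPU core.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import AcquisitionGeometry
from .metrics import build_eval_set, empirical_accuracy
from .model import NetworkSpec, build_network, parameter_count, preset_spec
from .pairs import PairGenerator, SamplingRegion
from .phantom import regime_preset
from .projector import NoiseConfig, ProjectionStream, simulate_stream
from .trainer import (
    CapacityQueue,
    Denoiser,
    RegionEvent,
    ReplaySchedule,
    Trainer,
    TrainerConfig,
    run_replay,
)

__all__ = [
    "ExperimentConfig",
    "default_geometry",
    "train_denoiser",
    "run_ood_grid",
    "run_discontinuity_replay",
    "run_architecture_sweep",
]

OOD_SCENARIOS = ("same", "reposition", "tilt", "zoom", "later-time", "other-regime")


def default_geometry(**overrides) -> AcquisitionGeometry:
    """The desk-scale parallel test geometry: 150 projections / 1.8 s."""
    kw = dict(beam_type="parallel", m_phi=150, rotation_period=1.8,
              detector_shape=(64, 1), detector_pixel_size=1.0, voxel_size=1.0)
    kw.update(overrides)
    return AcquisitionGeometry(**kw)


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully serialisable description of one experiment run."""

    regime: str = "A"
    geometry: AcquisitionGeometry = field(default_factory=default_geometry)
    architectures: tuple[str, ...] = ("standard",)
    buffer_sizes: tuple[int, ...] = (320,)
    train_steps: int = 300
    train_duration: float = 12.0
    n_eval: int = 100
    window_length: float = 2.0
    i0: float = 1000.0
    patch_shape: tuple[int, int, int] = (20, 20, 1)
    scenarios: tuple[str, ...] = ("same", "zoom")
    schedule_n_reco: float = 30.0
    schedule_n_opt: float = 30.0
    replay_duration: float = 24.0
    switch_time: float = 12.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"] = self.geometry.to_dict()
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _sub_seed(master: int, *tags: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([master & 0x7FFFFFFF, *tags])


def _stream(config: ExperimentConfig, regime: str, duration: float, tag: int) -> ProjectionStream:
    cfg = regime_preset(regime, seed=int(_sub_seed(config.seed, tag).generate_state(1)[0] % 2**31))
    return simulate_stream(cfg, config.geometry, duration, NoiseConfig(i0=config.i0))


def train_denoiser(
    stream: ProjectionStream,
    region: SamplingRegion,
    spec: NetworkSpec,
    steps: int,
    seed: int,
    time_indices: np.ndarray,
    patch_shape=(20, 20, 1),
    voxel_size: float | None = None,
    orientation="axis",
    buffer_size: int = 320,
    config: TrainerConfig | None = None,
    eval_every: int | None = None,
    eval_pairs=None,
) -> tuple[Denoiser, pd.DataFrame]:
    """Budgeted training on pairs drawn from fixed window end indices.

    One pair is produced per optimizer step (resampling older pairs via
    the capacity queue), which keeps budgets identical across the
    networks being compared.  Returns the trained denoiser and a curve
    of (step, loss[, holdout accuracy]) rows.
    """
    config = config or TrainerConfig(seed=seed)
    gen_rng = np.random.default_rng(_sub_seed(seed, 0xA))
    n_frames = spec.frames if spec.mode == "2D+time" else 1
    shape = patch_shape
    if spec.mode == "3D":
        shape = (patch_shape[0], patch_shape[1], spec.input_shape[2])
    gen = PairGenerator(
        stream, region, patch_shape=shape, voxel_size=voxel_size,
        orientation=orientation, n_frames=n_frames,
        rng=gen_rng,
    )
    # temporal sequences need (n_frames - 1) * stride extra history
    time_indices = np.asarray(time_indices)
    time_indices = time_indices[time_indices >= gen.earliest_time_index()]
    if time_indices.size == 0:
        raise ValueError("no window end index leaves room for the requested sequences")
    queue = CapacityQueue(buffer_size)
    net = build_network(spec, seed=seed)
    trainer = Trainer(net, config)
    draw_rng = np.random.default_rng(_sub_seed(seed, 0xB))
    pick_rng = np.random.default_rng(_sub_seed(seed, 0xC))
    rows = []
    for step in range(1, steps + 1):
        t_idx = int(time_indices[pick_rng.integers(len(time_indices))])
        pair = gen.generate(t_idx)
        trainer.observe(pair)
        queue.push(pair)
        loss = trainer.train_step(queue.draw_batch(config.batch_size, draw_rng))
        row = {"step": step, "loss": loss}
        if eval_every and eval_pairs is not None and (step % eval_every == 0 or step == steps):
            row["holdout_accuracy"] = empirical_accuracy(trainer.denoiser(), eval_pairs).value
        rows.append(row)
    return trainer.denoiser(), pd.DataFrame(rows)


def _train_indices(stream: ProjectionStream, t0: float, t1: float) -> np.ndarray:
    geom = stream.geometry
    lo = max(int(np.ceil(t0 / geom.exposure_per_frame)), geom.m_phi - 1)
    hi = min(int(np.floor(t1 / geom.exposure_per_frame)), len(stream) - 1)
    if hi < lo:
        raise ValueError(f"no complete windows in [{t0}, {t1}] s")
    return np.arange(lo, hi + 1)


def run_ood_grid(config: ExperimentConfig) -> dict:
    """Out-of-distribution error for each configured scenario.

    For each scenario a network theta is trained on the base data D and
    a baseline psi on the scenario data E under identical budgets; both
    are evaluated on fresh pairs from E.  The report rows carry
    R_E[theta], R_E[psi] and their difference eps (> 0 means the
    discontinuity costs accuracy).
    """
    for s in config.scenarios:
        if s not in OOD_SCENARIOS:
            raise ValueError(f"unknown scenario {s!r}; choose from {OOD_SCENARIOS}")
    spec = preset_spec(config.architectures[0])
    base_cfg = regime_preset(config.regime)
    region = PairGenerator.default_region(base_cfg)
    need_later = "later-time" in config.scenarios
    base_duration = config.train_duration * (2 if need_later else 1) + 1.0
    stream_d = _stream(config, config.regime, base_duration, tag=1)
    idx_d = _train_indices(stream_d, 0.0, config.train_duration)

    rows = []
    for i, scenario in enumerate(config.scenarios):
        # scenario-specific E: stream, region, orientation, voxel size
        stream_e, idx_e = stream_d, idx_d
        region_d = region_e = region
        orient_d = orient_e = "axis"
        vox_d = vox_e = None
        if scenario == "reposition":
            region_d = region.with_half("top")
            region_e = region.with_half("bottom")
        elif scenario == "tilt":
            orient_e = np.pi / 2
        elif scenario == "zoom":
            vox_e = config.geometry.voxel_size / 2.0  # halved voxel size
        elif scenario == "later-time":
            idx_e = _train_indices(stream_d, config.train_duration, 2 * config.train_duration)
        elif scenario == "other-regime":
            other = "B" if config.regime == "A" else "A"
            stream_e = _stream(config, other, config.train_duration + 1.0, tag=2)
            other_cfg = regime_preset(other)
            region_e = PairGenerator.default_region(other_cfg)
            idx_e = _train_indices(stream_e, 0.0, config.train_duration)

        seed_i = int(_sub_seed(config.seed, 0xD0, i).generate_state(1)[0] % 2**31)
        theta, _ = train_denoiser(stream_d, region_d, spec, config.train_steps, seed_i,
                                  idx_d, config.patch_shape, vox_d, orient_d)
        psi, _ = train_denoiser(stream_e, region_e, spec, config.train_steps, seed_i + 1,
                                idx_e, config.patch_shape, vox_e, orient_e)
        eval_gen = PairGenerator(
            stream_e, region_e, patch_shape=config.patch_shape, voxel_size=vox_e,
            orientation=orient_e,
            rng=np.random.default_rng(_sub_seed(config.seed, 0xE0, i)),
        )
        pairs_e = build_eval_set(eval_gen, idx_e, config.n_eval)
        r_theta = empirical_accuracy(theta, pairs_e).value
        r_psi = empirical_accuracy(psi, pairs_e).value
        rows.append(
            {"scenario": scenario, "R_E_theta": r_theta, "R_E_psi": r_psi,
             "epsilon": r_theta - r_psi, "n_eval": config.n_eval}
        )
    report = pd.DataFrame(rows)
    return {
        "table": report,
        "config_hash": config.config_hash,
        "seed": config.seed,
        "architecture": spec.name,
    }


def run_architecture_sweep(config: ExperimentConfig) -> dict:
    """Accuracy-versus-step curves for the configured presets.

    Training pairs are drawn (with resampling) from a fixed data window;
    hold-out pairs come from a later, disjoint window.  Every preset
    gets the same step budget.
    """
    specs = [preset_spec(name) for name in config.architectures]
    base_cfg = regime_preset(config.regime)
    region = PairGenerator.default_region(base_cfg)
    stream = _stream(config, config.regime, 2 * config.train_duration + 1.0, tag=3)
    idx_train = _train_indices(stream, 0.0, config.train_duration)
    idx_hold = _train_indices(stream, config.train_duration + 1.0, 2 * config.train_duration)
    eval_every = max(1, config.train_steps // 5)

    curves = []
    for j, spec in enumerate(specs):
        seed_j = int(_sub_seed(config.seed, 0xF0, j).generate_state(1)[0] % 2**31)
        shape = config.patch_shape
        if spec.name.startswith("v"):
            shape = spec.input_shape  # Vx presets train on larger patches
        n_frames = spec.frames if spec.mode == "2D+time" else 1
        hold_shape = shape if spec.mode != "3D" else (shape[0], shape[1], spec.input_shape[2])
        hold_gen = PairGenerator(
            stream, region, patch_shape=hold_shape, n_frames=n_frames,
            rng=np.random.default_rng(_sub_seed(config.seed, 0xF5, j)),
        )
        hold_pairs = build_eval_set(hold_gen, idx_hold, config.n_eval)
        _, curve = train_denoiser(
            stream, region, spec, config.train_steps, seed_j, idx_train,
            patch_shape=shape, eval_every=eval_every, eval_pairs=hold_pairs,
        )
        curve["architecture"] = spec.name
        curve["parameters"] = parameter_count(spec)
        curves.append(curve)
    table = pd.concat(curves, ignore_index=True)
    return {"table": table, "config_hash": config.config_hash, "seed": config.seed}


def run_discontinuity_replay(config: ExperimentConfig) -> dict:
    """Buffered online strategies across a sampling-region discontinuity.

    Runs the replay scheduler with each configured buffer size, the
    capacity-1 (no-buffer) baseline, and an offline-pretrained baseline
    frozen at the switch; reports windowed-accuracy series and a
    recovery summary.
    """
    from .metrics import windowed_accuracy

    spec = preset_spec(config.architectures[0])
    base_cfg = regime_preset(config.regime)
    region_pre = PairGenerator.default_region(base_cfg).with_half("top")
    region_post = PairGenerator.default_region(base_cfg).with_half("bottom")
    stream = _stream(config, config.regime, config.replay_duration + 1.0, tag=4)
    schedule = ReplaySchedule(
        n_reco=config.schedule_n_reco,
        n_opt=config.schedule_n_opt,
        duration=config.replay_duration,
        events=(RegionEvent(config.switch_time, region_post),),
    )
    eval_rng = np.random.default_rng(_sub_seed(config.seed, 0x1E))

    def gen_factory_for(region):
        def factory(rng):
            return PairGenerator(stream, region, patch_shape=config.patch_shape, rng=rng)
        return factory

    series = {}
    checkpoint_ids = []
    strategies = [(f"buffer-{n}", n) for n in config.buffer_sizes] + [("no-buffer", 1)]
    tconf = TrainerConfig(seed=config.seed, checkpoint_interval=max(1, config.train_steps // 6))
    for name, cap in strategies:
        net = build_network(spec, seed=config.seed)
        gen = PairGenerator(
            stream, region_pre, patch_shape=config.patch_shape,
            rng=np.random.default_rng(_sub_seed(config.seed, 0x2E, cap)),
        )
        trace = run_replay(stream, schedule, net, tconf, gen, CapacityQueue(cap))
        recs = []
        for ck in trace.checkpoints:
            reg = region_pre if ck["sim_time"] < config.switch_time else region_post
            recs += windowed_accuracy([ck], stream, gen_factory_for(reg),
                                      config.window_length, config.n_eval, eval_rng, spec=spec)
        series[name] = recs
        checkpoint_ids += [ck["id"] for ck in trace.checkpoints]

    # offline-pretrained baseline: trained on pre-switch data, frozen
    idx_pre = _train_indices(stream, 0.0, config.switch_time)
    pre_seed = int(_sub_seed(config.seed, 0x3E).generate_state(1)[0] % 2**31)
    pretrained, _ = train_denoiser(stream, region_pre, spec, config.train_steps,
                                   pre_seed, idx_pre, config.patch_shape)
    pre_recs = []
    eval_times = [rec.window for rec in next(iter(series.values()))]
    for (t0, t1) in eval_times:
        reg = region_pre if (t0 + t1) / 2 < config.switch_time else region_post
        gen = gen_factory_for(reg)(eval_rng)
        idx = _train_indices(stream, max(t0, 0.0), t1)
        pairs = build_eval_set(gen, idx, config.n_eval, eval_rng)
        rec = empirical_accuracy(pretrained, pairs, window=(t0, t1), checkpoint_id="pretrained")
        pre_recs.append(rec)
    series["pretrained"] = pre_recs

    rows = []
    for name, recs in series.items():
        for rec in recs:
            rows.append(
                {"strategy": name, "t_mid": np.mean(rec.window), "accuracy": rec.value,
                 "n_pairs": rec.n_pairs, "checkpoint": rec.checkpoint_id}
            )
    table = pd.DataFrame(rows)

    summary = []
    for name, recs in series.items():
        pre = [r.value for r in recs if np.mean(r.window) < config.switch_time]
        post = [r.value for r in recs if np.mean(r.window) >= config.switch_time]
        summary.append(
            {"strategy": name,
             "pre_switch_mean": float(np.mean(pre)) if pre else np.nan,
             "post_switch_mean": float(np.mean(post)) if post else np.nan}
        )
    return {
        "table": table,
        "summary": pd.DataFrame(summary),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "checkpoint_ids": checkpoint_ids,
    }
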