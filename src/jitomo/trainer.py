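"""Just-in-time online training: capacity queue, optimizer loop, replay.

Training pairs produced from the live stream are pushed onto a bounded
FIFO *capacity queue*; the optimizer draws uniform random batches (with
replacement) from whatever the queue currently holds and takes gradient
steps on the mean-squared empirical risk.  If pairs are produced at
``n_reco`` per second and the optimizer consumes ``n_opt`` batches per
second, each pair is drawn about ``n_opt * batch_size / n_reco`` times
during its lifetime in the queue, independent of the queue size.

Production and training are interleaved by a deterministic
single-threaded scheduler (rates, not threads), so every run is exactly
reproducible from its seed; a real-time threaded runner could be
layered on top without touching the semantics.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .model import Network, build_network
from .optim import Adam
from .pairs import PairGenerator, SamplingRegion, TrainingPair
from .projector import ProjectionStream

__all__ = [
    "QueueStarved",
    "CapacityQueue",
    "TrainerConfig",
    "Denoiser",
    "Trainer",
    "TrainingTrace",
    "RegionEvent",
    "ReplaySchedule",
    "run_replay",
    "save_checkpoint",
    "load_checkpoint",
]


class QueueStarved(RuntimeError):
    """Batch requested from an empty queue; the consumer should wait."""


class CapacityQueue:
    """Bounded FIFO of training pairs with uniform random batch draws."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = int(capacity)
        self._entries: deque[TrainingPair] = deque(maxlen=self.capacity)
        self.push_count = 0
        self.draw_count = 0

    def __len__(self) -> int:
        return len(self._entries)

    def push(self, pair: TrainingPair) -> None:
        if self._entries and pair.shape_key != self._entries[0].shape_key:
            raise ValueError(
                f"pair shape {pair.shape_key} does not match queue contents {self._entries[0].shape_key}"
            )
        self._entries.append(pair)  # deque evicts oldest when full
        self.push_count += 1

    def draw_batch(self, batch_size: int, rng: np.random.Generator) -> list[TrainingPair]:
        if not self._entries:
            raise QueueStarved("capacity queue is empty")
        idx = rng.integers(0, len(self._entries), size=batch_size)
        self.draw_count += int(batch_size)
        return [self._entries[i] for i in idx]

    def entries(self) -> list[TrainingPair]:
        return list(self._entries)


@dataclass(frozen=True)
class TrainerConfig:
    """Optimization hyperparameters (squared-error loss, Adam)."""

    loss: str = "mse"
    learning_rate: float = 1e-4
    batch_size: int = 32
    optimizer: str = "adam"
    checkpoint_interval: int = 500
    norm_pairs: int = 100  # pairs used to freeze the affine input transform
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.loss != "mse":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")

    def to_yaml(self, path) -> None:
        import dataclasses

        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "TrainerConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class Denoiser:
    """A trained network plus its frozen input normalisation.

    Callable on raw reconstruction patches: normalises, applies the
    network, and maps back to reconstruction units.
    """

    network: Network
    offset: float
    scale: float

    def __call__(self, u: np.ndarray) -> np.ndarray:
        un = (np.asarray(u, dtype=np.float32) - self.offset) / self.scale
        return self.network.apply(un) * self.scale + self.offset


@dataclass
class TrainingTrace:
    """Per-step records and checkpoints of one (replay) run."""

    records: list = field(default_factory=list)  # dict per step
    checkpoints: list = field(default_factory=list)  # dict: step, sim_time, state, id
    events: list = field(default_factory=list)
    terminated_reason: str | None = None

    def add(self, step, sim_time, loss, buffer_fill, pushes=0, event=""):
        if self.records and step <= self.records[-1]["step"]:
            raise ValueError("trace steps must be strictly increasing")
        self.records.append(
            {"step": step, "sim_time": sim_time, "loss": loss,
             "buffer_fill": buffer_fill, "pushes": pushes, "event": event}
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class Trainer:
    """Gradient steps on the empirical risk of queued Noise2Inverse pairs.

    The input normalisation is a fixed affine transform (offset/scale)
    estimated from the first ``norm_pairs`` pairs seen and then frozen:
    per-batch statistics would drift under a non-stationary stream.
    Optimizer state persists across data-regime switches.
    """

    def __init__(self, network: Network, config: TrainerConfig | None = None):
        self.network = network
        self.config = config or TrainerConfig()
        self.opt = Adam(network.params(), lr=self.config.learning_rate)
        self.offset: float | None = None
        self.scale: float | None = None
        self._norm_buf: list[np.ndarray] = []
        self.last_batch: list[TrainingPair] | None = None

    # -- normalisation -----------------------------------------------------
    def observe(self, pair: TrainingPair) -> None:
        """Feed one pair to the (not yet frozen) normalisation estimate."""
        if self.offset is None:
            self._norm_buf.append(np.asarray(pair.u, dtype=np.float64))
            if len(self._norm_buf) >= self.config.norm_pairs:
                self._freeze_norm()

    def _freeze_norm(self):
        data = np.concatenate([a.ravel() for a in self._norm_buf])
        self.offset = float(data.mean())
        self.scale = float(max(data.std(), 1e-12))
        self._norm_buf.clear()

    def ensure_norm(self) -> None:
        """Freeze the affine transform from whatever has been observed."""
        if self.offset is None:
            if not self._norm_buf:
                raise RuntimeError("no pairs observed; cannot freeze normalisation")
            self._freeze_norm()

    def denoiser(self) -> Denoiser:
        self.ensure_norm()
        return Denoiser(self.network, self.offset, self.scale)

    # -- optimisation ------------------------------------------------------
    def _stack(self, batch: list[TrainingPair]) -> tuple[np.ndarray, np.ndarray]:
        u = np.stack([p.u for p in batch])[:, None]  # (B, 1, [D,] H, W)
        v = np.stack([p.v for p in batch])[:, None]
        if self.network.spec.nd == 3 and u.ndim == 4:
            raise ValueError("network expects slab/sequence inputs (D, H, W)")
        if self.network.spec.nd == 3:
            v = v[:, :, None]  # (B, 1, 1, H, W) to match collapsed output
        return u, v

    def train_step(self, batch: list[TrainingPair]) -> float:
        """One Adam step on the batch-mean squared error; returns the loss."""
        if not batch:
            raise ValueError("empty batch")
        self.ensure_norm()
        u, v = self._stack(batch)
        un = (u - self.offset) / self.scale
        vn = (v - self.offset) / self.scale
        y = self.network.forward(un.astype(np.float32))
        r = y - vn.astype(np.float32)
        loss = float(np.mean(r.astype(np.float64) ** 2))
        if not np.isfinite(loss):
            self.last_batch = batch
            raise RuntimeError(
                f"non-finite loss at step {self.network.step}; last batch retained on trainer.last_batch"
            )
        self.network.backward((2.0 / r.size) * r)
        self.opt.step(self.network.grads())
        self.network.step += 1
        return loss


@dataclass(frozen=True)
class RegionEvent:
    """A timestamped change of the patch-sampling region."""

    time: float
    region: SamplingRegion


@dataclass(frozen=True)
class ReplaySchedule:
    """Rates and events of a deterministic replay run.

    ``n_reco``: pairs produced per simulated second; ``n_opt``: batches
    trained per simulated second; ``events``: sampling-region switches
    that emulate discontinuities (user interaction) in the pipeline.
    """

    n_reco: float
    n_opt: float
    duration: float
    events: tuple = ()

    def __post_init__(self):
        if self.n_reco <= 0 or self.n_opt <= 0:
            raise ValueError("rates must be positive")
        times = [e.time for e in self.events]
        if times != sorted(times):
            raise ValueError("events must be sorted by time")


def save_checkpoint(path, network: Network, step: int, sim_time: float,
                    offset: float | None = None, scale: float | None = None) -> None:
    """Versioned weight archive embedding spec, seed and wall-time."""
    import json

    spec_json = json.dumps(
        {
            "base_features": network.spec.base_features,
            "levels": network.spec.levels,
            "convs_per_block": network.spec.convs_per_block,
            "input_shape": list(network.spec.input_shape),
            "frames": network.spec.frames,
            "mode": network.spec.mode,
            "name": network.spec.name,
        }
    )
    np.savez(
        path,
        __format_version__=1,
        spec=spec_json,
        seed=network.seed,
        step=step,
        sim_time=sim_time,
        offset=np.nan if offset is None else offset,
        scale=np.nan if scale is None else scale,
        **network.state_dict(),
    )


def load_checkpoint(path) -> tuple[Network, dict]:
    import json

    from .model import NetworkSpec

    with np.load(path, allow_pickle=False) as data:
        spec_d = json.loads(str(data["spec"]))
        spec_d["input_shape"] = tuple(spec_d["input_shape"])
        net = build_network(NetworkSpec(**spec_d), seed=int(data["seed"]))
        net.load_state_dict({k: data[k] for k in data.files if k.startswith("p")})
        net.step = int(data["step"])
        meta = {
            "step": int(data["step"]),
            "sim_time": float(data["sim_time"]),
            "offset": float(data["offset"]),
            "scale": float(data["scale"]),
        }
    return net, meta


def run_replay(
    stream: ProjectionStream,
    schedule: ReplaySchedule,
    network: Network,
    config: TrainerConfig,
    generator: PairGenerator,
    queue: CapacityQueue,
    trainer: Trainer | None = None,
) -> TrainingTrace:
    """Deterministic interleaving of pair production and training.

    Within every simulated second, ``n_reco`` productions and ``n_opt``
    batch steps fire at their fractional times, merged into one ordered
    event list (productions win ties so data precedes training).  Pair
    production at simulated time ``s`` reconstructs from the window
    ending at the newest frame acquired by ``s``; until a full rotation
    has been acquired, productions are skipped (warm-up).  Sampling-
    region events apply at their timestamps.  Checkpoints are taken
    every ``checkpoint_interval`` steps.  The trace (and every
    checkpoint) is a pure function of (stream, schedule, config seed).
    """
    trainer = trainer or Trainer(network, config)
    rng = np.random.default_rng(np.random.SeedSequence([0x5EED, config.seed & 0x7FFFFFFF]))
    trace = TrainingTrace()
    geom = stream.geometry
    exposure = geom.exposure_per_frame
    last_frame = stream.first_frame_index + len(stream) - 1
    ready_at = generator.earliest_time_index()

    # global event list: (time, priority, kind)
    times_prod = [(i + 1) / schedule.n_reco for i in range(int(round(schedule.n_reco * schedule.duration)))]
    times_train = [(i + 1) / schedule.n_opt for i in range(int(round(schedule.n_opt * schedule.duration)))]
    events = [(t, 0, "produce") for t in times_prod] + [(t, 1, "train") for t in times_train]
    events += [(e.time, -1, ("region", e.region)) for e in schedule.events]
    events.sort(key=lambda x: (x[0], x[1]))

    region = generator.region
    step = 0
    for (t_sim, _, kind) in events:
        if isinstance(kind, tuple) and kind[0] == "region":
            region = kind[1]
            trace.events.append({"time": t_sim, "event": "region_switch"})
            continue
        newest = stream.first_frame_index + int(np.floor(t_sim / exposure))
        if kind == "produce":
            if newest > last_frame:
                trace.terminated_reason = "end_of_stream"
                break
            if newest < ready_at:
                continue  # warm-up: window not complete yet
            pair = generator.generate(newest, region=region)
            trainer.observe(pair)
            queue.push(pair)
        else:  # train
            if len(queue) == 0:
                continue  # starved: wait for data, never train on nothing
            batch = queue.draw_batch(config.batch_size, rng)
            loss = trainer.train_step(batch)
            step += 1
            trace.add(step, t_sim, loss, len(queue), pushes=queue.push_count)
            if step % config.checkpoint_interval == 0:
                trace.checkpoints.append(
                    {
                        "step": step,
                        "sim_time": t_sim,
                        "state": network.state_dict(),
                        "id": f"ckpt-{step:06d}",
                        "offset": trainer.offset,
                        "scale": trainer.scale,
                    }
                )
    return trace
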