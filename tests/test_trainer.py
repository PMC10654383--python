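"""Capacity queue, optimisation steps, and the deterministic replay loop."""

import numpy as np
import pytest

import jitomo
from jitomo.pairs import TrainingPair
from jitomo.trainer import (
    CapacityQueue,
    QueueStarved,
    RegionEvent,
    ReplaySchedule,
    Trainer,
    TrainerConfig,
    load_checkpoint,
    run_replay,
    save_checkpoint,
)


def _pair(i, shape=(8, 8), rng=None):
    rng = rng or np.random.default_rng(i)
    u = rng.standard_normal(shape).astype(np.float32)
    v = u + 0.1 * rng.standard_normal(shape).astype(np.float32)
    return TrainingPair(u, v, float(i), i, "EVEN", frozenset({i}))


class TestCapacityQueue:
    def test_fifo_eviction_keeps_latest(self):
        q = CapacityQueue(320)
        for i in range(1, 401):
            q.push(_pair(i))
        assert len(q) == 320
        held = [p.time_index for p in q.entries()]
        assert held == list(range(81, 401))

    def test_capacity_one_is_latest_only(self):
        q = CapacityQueue(1)
        for i in range(5):
            q.push(_pair(i))
        assert len(q) == 1
        assert q.entries()[0].time_index == 4

    def test_push_into_empty(self):
        q = CapacityQueue(8)
        q.push(_pair(0))
        assert len(q) == 1 and q.push_count == 1

    def test_shape_mismatch_rejected(self):
        q = CapacityQueue(4)
        q.push(_pair(0))
        with pytest.raises(ValueError, match="shape"):
            q.push(_pair(1, shape=(6, 6)))

    def test_draw_is_uniform_with_replacement(self):
        """10^5 draws over 10 entries: each near 10% (binomial bound)."""
        q = CapacityQueue(10)
        for i in range(10):
            q.push(_pair(i))
        rng = np.random.default_rng(0)
        counts = np.zeros(10)
        for _ in range(100):
            for p in q.draw_batch(1000, rng):
                counts[p.time_index] += 1
        freq = counts / counts.sum()
        assert np.all(np.abs(freq - 0.1) < 0.005)
        assert len(q) == 10  # draws never remove entries
        assert q.draw_count == 100_000

    def test_empty_queue_signals_starvation(self):
        with pytest.raises(QueueStarved):
            CapacityQueue(4).draw_batch(8, np.random.default_rng(0))


class TestTrainStep:
    def _trainer(self, seed=0):
        net = jitomo.build_network(jitomo.preset_spec("standard"), seed=seed)
        tr = Trainer(net, TrainerConfig(seed=seed))
        return net, tr

    def test_perfect_batch_gives_zero_loss_and_frozen_weights(self):
        net, tr = self._trainer()
        rng = np.random.default_rng(0)
        pair = _pair(0, shape=(20, 20), rng=rng)
        tr.observe(pair)
        tr.ensure_norm()
        den = tr.denoiser()
        # targets = current network output -> gradient is exactly zero
        perfect = [TrainingPair(p.u, den(p.u).astype(np.float32), p.creation_time,
                                p.time_index, p.u_subset, p.frame_indices)
                   for p in [_pair(i, shape=(20, 20)) for i in range(4)]]
        before = [p.copy() for p in net.params()]
        loss = tr.train_step(perfect)
        assert loss == pytest.approx(0.0, abs=1e-12)
        assert all(np.array_equal(a, b) for a, b in zip(before, net.params()))

    def test_zero_learning_rate_freezes_weights(self):
        net = jitomo.build_network(jitomo.preset_spec("standard"), seed=1)
        tr = Trainer(net, TrainerConfig(learning_rate=0.0))
        tr.observe(_pair(0, shape=(20, 20)))
        before = [p.copy() for p in net.params()]
        tr.train_step([_pair(i, shape=(20, 20)) for i in range(3)])
        assert all(np.array_equal(a, b) for a, b in zip(before, net.params()))

    def test_overfitting_one_fixed_batch_reduces_loss(self):
        """100 repeated Adam steps on one batch: loss decreases overall."""
        net, tr = self._trainer(seed=2)
        batch = [_pair(i, shape=(20, 20)) for i in range(8)]
        tr.observe(batch[0])
        losses = [tr.train_step(batch) for _ in range(100)]
        assert losses[-1] < losses[0]
        # non-increasing trend: late average well below early average
        assert np.mean(losses[-10:]) < np.mean(losses[:10])

    def test_empty_batch_rejected(self):
        _, tr = self._trainer()
        with pytest.raises(ValueError, match="empty"):
            tr.train_step([])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainerConfig(batch_size=0)
        with pytest.raises(ValueError):
            TrainerConfig(loss="l1")


class TestReplay:
    @pytest.fixture(scope="class")
    @staticmethod
    def replay_setup(stream_a, regime_a):
        spec = jitomo.preset_spec("standard")
        region = jitomo.PairGenerator.default_region(regime_a)

        def run(capacity=64, seed=3, n_reco=8.0, n_opt=8.0, duration=6.0, events=()):
            gen = jitomo.PairGenerator(stream_a, region,
                                       rng=np.random.default_rng([seed, 0]))
            net = jitomo.build_network(spec, seed=seed)
            sched = ReplaySchedule(n_reco=n_reco, n_opt=n_opt, duration=duration,
                                   events=events)
            tconf = TrainerConfig(seed=seed, checkpoint_interval=5)
            trace = run_replay(stream_a, sched, net, tconf, gen,
                               CapacityQueue(capacity))
            return trace, net

        return run

    def test_buffer_fill_conservation(self, replay_setup):
        trace, _ = replay_setup(capacity=4)
        assert trace.records
        for rec in trace.records:
            assert rec["buffer_fill"] == min(rec["pushes"], 4)

    def test_draws_per_pair_matches_rate_ratio(self, replay_setup):
        """Each produced pair is drawn ~ n_opt * batch / n_reco times."""
        trace, _ = replay_setup(capacity=64, n_reco=10.0, n_opt=5.0)
        draws = 32 * len(trace.records)
        pushes = trace.records[-1]["pushes"]
        expected = 5.0 * 32 / 10.0
        assert draws / pushes == pytest.approx(expected, rel=0.10)

    def test_identical_seeds_give_identical_traces(self, replay_setup):
        t1, n1 = replay_setup(seed=9)
        t2, n2 = replay_setup(seed=9)
        assert [r["loss"] for r in t1.records] == [r["loss"] for r in t2.records]
        assert all(np.array_equal(a, b) for a, b in zip(n1.params(), n2.params()))
        for c1, c2 in zip(t1.checkpoints, t2.checkpoints):
            assert all(np.array_equal(c1["state"][k], c2["state"][k])
                       for k in c1["state"])

    def test_no_events_means_no_region_switches(self, replay_setup):
        trace, _ = replay_setup()
        assert trace.events == []

    def test_schedule_outrunning_stream_terminates(self, replay_setup):
        trace, _ = replay_setup(duration=10.0)  # stream is only 6 s
        assert trace.terminated_reason == "end_of_stream"

    def test_region_event_recorded(self, replay_setup, regime_a):
        region2 = jitomo.PairGenerator.default_region(regime_a).with_half("bottom")
        trace, _ = replay_setup(events=(RegionEvent(2.0, region2),))
        assert [e["event"] for e in trace.events] == ["region_switch"]

    def test_schedule_validation(self):
        with pytest.raises(ValueError, match="rates"):
            ReplaySchedule(n_reco=0.0, n_opt=1.0, duration=1.0)


def test_checkpoint_roundtrip(tmp_path):
    net = jitomo.build_network(jitomo.preset_spec("t3"), seed=4)
    rng = np.random.default_rng(0)
    for p in net.params():
        p += rng.standard_normal(p.shape).astype(np.float32) * 1e-3
    path = tmp_path / "ck.npz"
    save_checkpoint(path, net, step=17, sim_time=1.5, offset=0.1, scale=2.0)
    loaded, meta = load_checkpoint(path)
    assert meta["step"] == 17
    assert meta["scale"] == 2.0
    assert loaded.spec == net.spec
    assert all(np.array_equal(a, b) for a, b in zip(loaded.params(), net.params()))


def test_trainer_config_yaml_roundtrip(tmp_path):
    conf = TrainerConfig(learning_rate=3e-4, batch_size=8, seed=5)
    path = tmp_path / "train.yaml"
    conf.to_yaml(path)
    assert TrainerConfig.from_yaml(path) == conf
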