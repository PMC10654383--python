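"""Just-in-time learning: online training from a streaming buffer.

Replays a stream through the deterministic scheduler: pairs are pushed
onto a 320-entry capacity queue at n_reco per second while the
optimizer draws batches at n_opt per second — each produced pair is
revisited about n_opt * batch_size / n_reco times before eviction.
"""

import numpy as np

import jitomo
from jitomo.trainer import CapacityQueue, ReplaySchedule, TrainerConfig, run_replay

cfg = jitomo.regime_preset("A", seed=11)
stream = jitomo.simulate_stream(cfg, jitomo.default_geometry(), duration=6.0)
region = jitomo.PairGenerator.default_region(cfg)
gen = jitomo.PairGenerator(stream, region, rng=np.random.default_rng(2))
net = jitomo.build_network(jitomo.preset_spec("standard"), seed=1)

schedule = ReplaySchedule(n_reco=10.0, n_opt=10.0, duration=6.0)
queue = CapacityQueue(320)
trace = run_replay(stream, schedule, net, TrainerConfig(seed=3, checkpoint_interval=20),
                   gen, queue)

df = trace.to_frame()
print(df[["step", "sim_time", "loss", "buffer_fill"]].iloc[::10].to_string(index=False))
print(f"\npairs produced: {queue.push_count}, samples drawn: {queue.draw_count}")
print(f"draws per pair: {queue.draw_count / queue.push_count:.1f} "
      f"(rate argument predicts {schedule.n_opt * 32 / schedule.n_reco:.1f})")
print("Training only starts once a full rotation is buffered (warm-up),")
print("and the loss falls as the network picks up the stream's features.")
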