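# jitomo — just-in-time learning for streaming tomographic denoising

Real-time X-ray computed tomography watches a process *while it
happens*: projections arrive in a continuous stream, a filtered-
backprojection engine reconstructs user-selected slices from the last
full rotation, and short exposures leave those slices badly degraded by
photon noise.  No clean ground truth ever exists for such data, and the
imaged process itself drifts — so a denoising network must be trained
*during* the experiment, on the stream itself, and keep adapting.

`jitomo` implements that whole loop at desk scale, for method
development and testing without a beamline:

* **`jitomo.phantom` / `jitomo.projector`** — a dynamic phantom (gas
  bubbles rising from a dissolving tablet through a liquid-filled glass
  cylinder, in a fast/large-bubble regime A and a slow/small regime B)
  and a projection simulator producing Beer–Lambert photon counts with
  Poisson noise, flat/dark fields, in parallel- or cone-beam geometry.
* **`jitomo.recon`** — streaming filtered backprojection: flat/dark
  correction with clamping, discrete Ram-Lak (band-limited ramp)
  filtering, and region-of-interest backprojection of slices, slabs and
  temporal sequences from arbitrary projection subsets.  Subsets are
  normalised by `pi / n_angles`, so even-half, odd-half and full
  reconstructions share one intensity scale.
* **`jitomo.pairs`** — Noise2Inverse training pairs: the projection
  window is split by even/odd frame index, each half reconstructed on a
  random patch inside the vessel; the two reconstructions show the same
  object with independent noise and serve as input and target.
* **`jitomo.model`** — a small fully-convolutional U-Net family
  (encoder/decoder with skip connections; strided and transposed
  convolutions; 8→16→32 feature maps for the `standard` preset), with
  presets varying width (`c16`, `c32`), training patch size
  (`v30`…`v150`), input slices (`z3`–`z7`) and input timeframes
  (`t3`–`t7`).  Implemented in numpy with hand-derived gradients;
  trained with Adam (lr 1e-4, batch 32) on the mean-squared error.
* **`jitomo.trainer`** — the just-in-time engine: a bounded FIFO
  *capacity queue* of recent pairs, uniform batch draws, and a
  deterministic replay scheduler interleaving pair production
  (`n_reco`/s) and optimisation (`n_opt`/s), with checkpoints.
* **`jitomo.metrics`** — the noise-normalised accuracy

      alpha(A, u, v) = ||A(u) − v||² / ||u − v||²

  (1 = no denoising, ≈ 0.5 = ideal under i.i.d. noise), its empirical
  mean `R^alpha`, windowed accuracy over a run, and the
  out-of-distribution error `eps = R^alpha_E[A_theta] − R^alpha_E[A_psi]`.
* **`jitomo.experiments`** — reproducible templates: the OOD scenario
  grid (reposition / tilt / zoom / later-time / other-regime), the
  architecture sweep, and the discontinuity replay comparing buffer
  strategies against no-buffer and frozen-pretrained baselines.

## Worked example

```bash
python examples/02_noise2inverse_training.py
```

simulates 8 s of regime-A data, trains the `standard` U-Net for 300
steps on even/odd 20×20 pairs and evaluates on held-out windows:

```
 step     loss  holdout_accuracy
  100 0.451702          1.499917
  200 0.214004          0.731890
  300 0.175708          0.627246
identity baseline R^alpha: 1.0
```

The identity mapping scores exactly 1 by construction; the falling
hold-out `R^alpha` (1.50 → 0.63) shows the network learning to remove
noise it was never shown labelled — the even/odd split of the same
projection window supplies the supervision.  Perfect denoising of
i.i.d. noise would approach 0.5.

Other examples: `01_simulate_and_reconstruct.py` (stream + FBP slice),
`03_online_replay.py` (capacity-queue replay and the draws-per-pair
rate argument), `04_ood_scenarios.py` (zoom/same OOD errors).  A thin
CLI mirrors the common paths:
`jitomo simulate | replay | ood-grid | arch-sweep | evaluate`.

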