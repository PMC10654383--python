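# Methods

## The problem being modelled

In streaming computed tomography a detector records radiographs
`f_t ∈ R^{m_x × m_y}` while the object rotates continuously; the last
`m_phi` frames — one full rotation — determine a reconstruction `x_t`
through the X-ray transform.  Direct inversion (filtered backprojection,
or FDK for cone beams) is linear and local, so any region of interest
can be reconstructed at a cost proportional to its voxel count; this is
what makes patch-based training and slice-level inference feasible in
real time.  Short exposures make the reconstructions noisy, the imaged
process evolves, and no ground truth exists — hence a self-supervised,
continuously trained denoiser.

## Synthetic data generator

The phantom is a liquid-filled glass cylinder with a granular bed, a
tablet resting on it, and gas bubbles nucleating at the tablet that
rise with constant per-bubble velocity and vanish at the liquid
surface.  Bubble births are a Poisson process generated block-wise (one
block per second) from counter-based seeds, so the scene at time `t` is
a pure function of `(config, t)` — no hidden state, identical answers
on repeated queries.

Two regime presets set the bubble statistics: regime A draws radii in
3–6 voxels and speeds 25–50 voxels/s at 3 births/s; regime B radii
1.2–2.8, speeds 6–15, 2 births/s.  The real experiments' size and
speed distributions were never quantified; these are order-of-magnitude
choices fixed once, intended only to give the two regimes clearly
different spatio-temporal texture.  Bubble motion is deliberately
non-interacting and vertical — the simplest dynamics that reproduce the
diagonal space-time patterns that distinguish slow from fast regimes.

Attenuation values (1/mm at 1 mm voxels): liquid 0.020, glass 0.050,
grains 0.035, tablet 0.045, gas 0.  Anti-aliasing supersamples each
voxel 2× per axis and averages occupancy.  Projection integrates the
voxelised scene along rays with bilinear sampling at half-voxel steps;
counts follow `I = I0 · exp(−∫mu)` with Poisson counting noise plus a
Poisson dark level, and flat/dark fields are emitted at stream start.
The default test geometry is parallel-beam 2-D (a horizontal slice at
tablet height, 64-pixel detector, 150 projections per 1.8 s rotation,
12 ms exposure); cone-beam FDK is exercised at small volume sizes.
One master seed splits into independent phantom and noise sub-streams
via `numpy` `SeedSequence` with fixed tags.

What the generator does **not** emulate: fluid dynamics, beam
hardening, detector point-spread, scatter, ring artefacts.  Passing
tests therefore demonstrate the correctness and the qualitative
behaviour of the learning stack, not performance on any real scanner.

## Reconstruction

`preprocess` computes `−log((I − dark)/(flat − dark))`, clamping
transmittance at 1e-6 (raw streams contain zero counts) and counting
clamped pixels.  Filtering uses the discrete Ram-Lak kernel — the
sampled inverse Fourier transform of the band-limited ramp,
`h[0] = 1/(4d²)`, `h[n] = −1/(π n d)²` for odd `n` — applied by FFT
with zero-padding to the next power of two ≥ twice the row length
(linear, not circular, convolution).  This spatial-kernel construction
is used instead of a frequency-sampled `|ω|` ramp because the latter
carries a well-known O(1/N) DC bias that shifts reconstructed values by
several percent at desk-scale padding; with the kernel form a uniform
disk reconstructs to 0.2 % of its true attenuation.  The kernel's
residual DC gain is O(1/N), not exactly zero.

Backprojection evaluates each patch voxel in world coordinates
(oriented boxes: centre, orthonormal in-plane axes, voxel size), with
linear detector interpolation in parallel mode and standard FDK
weighting in cone mode (cosine pre-weight `d_sd/√(d_sd²+u²+v²)`, ramp
amplitude taken on the virtual detector at the rotation axis, depth
weight `(d_so/(d_so+p_v))²`).  Any subset of the window's frames can be
selected; the `π / n_selected` normalisation makes `ALL` exactly the
mean of `EVEN` and `ODD` and puts all subsets on one intensity scale,
so one network can train on half-reconstructions and infer on full
ones.  Exactly `m_phi` frames per window; short scans are rejected
(`WindowNotReady`), not approximated.  Temporal sequences reconstruct
`n_frames` (odd) windows at a fixed stride, newest last; the stride
default of 60 projections (0.72 s) matches the spacing used for
spatio-temporal reconstructions.

Coordinates: world origin on the rotation axis at the central detector
row; frame `k` has angle `2π k / m_phi + offset`, counter-clockwise;
detector pixel centres at `(i − (m−1)/2)·d`.

## Noise2Inverse pairs

A window's frames are split by global-index parity; both halves are
reconstructed on the same randomly placed patch, giving two images of
the same object with independent photon noise.  Which half becomes the
input is decided by a fair coin per pair (switchable), removing the
systematic even/odd asymmetry a fixed assignment would bake in.
Temporal (`Tx`) pairs use the sequence from one half as input and the
middle frame from the other half as target.  Patch centres are uniform
over a cylindrical region kept strictly inside the vessel (no wall
artefacts in training data); `top`/`bottom` half-region overrides make
repositioning scenarios scriptable, and orientation can be axis-
aligned, fixed-angle, or uniformly random.  Patch locations are drawn
with replacement within a window.

## Network family

A symmetric U-Net with three resolution levels (widths 8/16/32 for
`standard`), three 3×3 convolutions per level with ReLU, 2×2 strided
convolutions down, 2×2 transposed convolutions up, a 64-wide
two-convolution bridge, concatenating skips, and a linear 1×1 output
head.  `Zx`/`Tx` variants use 3×3×3 convolutions, never downsample the
slice/frame axis, and collapse it in the final projection so `x`
slices/frames yield the single middle-slice output.  No batch
normalisation: batch statistics are unstable under non-stationary
online streams.

Inputs of any in-plane size are reflect-padded to the next multiple of
`2^levels` and the output cropped back — a 20×20 training patch is not
divisible by 8, so "valid" convolutions cannot be meant literally; zero-
padded "same" convolutions with outer reflect padding keep the output
size equal to the input everywhere.  The output head is zero-
initialised, so an untrained network predicts the normalisation offset
(a constant) rather than amplified noise; all other layers use He
initialisation from a seed-derived generator (identical seeds give
bitwise-identical weights).

The convolution forward/backward passes are written directly in numpy
(window views + `tensordot`/`einsum`); gradients are exact and checked
against finite differences for both 2-D and 3-D variants.  Adam
(lr 1e-4, β = 0.9/0.999, eps 1e-8) optimises the batch-mean squared
error.  Input normalisation is a single affine transform (mean/std of
the first 100 pairs observed) frozen for the rest of the run — per-
batch statistics would drift with the stream.

## Online training

Pairs are pushed onto a bounded FIFO capacity queue; batches are drawn
uniformly with replacement from current entries.  At production rate
`n_reco` pairs/s and training rate `n_opt` batches/s, a pair is drawn
`n_opt · batch_size / n_reco` times on average during its queue
lifetime, independent of capacity — the tests assert this counting
argument to 10 %.  The replay scheduler is a deterministic
single-threaded interleaving of timestamped production and training
events (productions win ties, so data precedes the step that could
consume it); region-switch events apply at their timestamps, optimizer
state is never reset across switches (the transfer-learning reading of
online adaptation), and checkpoints (default every 500 steps) make any
run reproducible from its seed.  A concurrent real-time runner could be
layered on top, but bit-for-bit reproducibility requires the scheduler,
so all tests and experiments use it.  An empty queue starves the
consumer (an explicit signal; training never proceeds on nothing), and
a schedule outrunning the stream terminates with a recorded reason.

## Evaluation

`alpha = ||A(u) − v||² / ||u − v||²` normalises the misfit by the
pair's own noise level.  Aggregation is the arithmetic mean of per-pair
alphas (matching the metric's definition as written, not a ratio of
summed norms — the two differ).  Degenerate pairs (`u = v`) are
excluded and counted rather than assigned a value, since the ratio is
undefined there.  Values below 0.5 are flagged, not rejected: they
occur legitimately when input and target have genuinely different
content (motion, angular subsampling) that the network learns to
predict.  Hold-out and windowed evaluations draw fresh pairs from
projection windows disjoint from training windows; each pair records
the frames it touched so disjointness is assertable.  Windowed
accuracy draws fresh patch locations for every checkpoint.

The OOD error `eps = R^alpha_E[A_theta] − R^alpha_E[A_psi]` compares a
network trained on distribution D against a baseline trained on E under
an identical budget, both evaluated on E.  In the scenario grid,
`zoom` halves the reconstruction voxel size — the analogue of the
largest user-interaction penalty, since convolutional features are not
scale-invariant — and the tests assert its direction (`eps > 0`) on the
synthetic stream.

## Problem sizes and numerical choices

Experiments default to the 64-pixel parallel geometry, 20×20 patches,
hundreds-to-2000 training steps, and 100–500 evaluation pairs: each
template then completes in minutes on one CPU core, which is the scale
this package targets (step budgets replace wall-clock budgets
throughout, as wall-clock numbers are hardware facts).  Tolerances used
in tests: subset linearity 1e-6 (float64 backprojection), ROI-vs-crop
1e-3, finite-difference gradients 5 % at eps 1e-2 in float32, FBP disk
accuracy 3 %.  Ties in the scheduler resolve production before
training; degenerate inputs (empty subsets, short windows, non-finite
losses) raise typed errors rather than propagating NaNs — a non-finite
loss aborts with the offending batch retained for inspection.

## Known limitations

The cone-beam path is exercised only at small volumes (FDK accuracy is
verified against analytic phantoms, not a second implementation); the
simulator's physics is deliberately minimal; K-fold Noise2Inverse
splits beyond even/odd, iterative reconstruction, TV baselines, and
GPU execution are out of scope.  Accuracy numbers quoted anywhere in
this repository are properties of the synthetic streams and say nothing
quantitative about real scanner data.
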