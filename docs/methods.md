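# Methods

## Signal model and simulator

The simulator renders the IF signal of a sawtooth FMCW radar (carrier
fc = 77 GHz, bandwidth B = 3.99 GHz, 256 ADC samples per chirp, 50 Hz frame
rate).  A point target at range R contributes, at fast-time sample n,

    a * exp( j*2*pi*(2*B*R0/c) * n/N  +  j*4*pi*R(t)/lambda_c )

The two terms are deliberately decoupled: the beat frequency is pinned to the
nominal range R0 while the time-varying range R(t) = R0 + d(t) modulates only
the carrier phase.  This is the stop-and-hop approximation — chest motion
(millimetres) is two orders of magnitude below the range resolution
c/(2B) ≈ 3.76 cm, so range migration is physically negligible, and the
approximation makes the slow-time phase at the target's FFT bin *exactly*
4*pi*(R0 + d(t))/lambda_c in the noise-free case, which the test suite
verifies to 1e-6 rad.  Radars of the emulated class sweep 76–81 GHz while
chirping over a 3.99 GHz bandwidth; the bandwidth is what enters the range
mapping, so B = 3.99 GHz with fc = 77 GHz is used.  The chirp duration
(60 µs) never affects downstream processing because the bin↔range mapping
k = 2BR/c is Tc-invariant.  The multi-antenna/multi-chirp front end is
collapsed to one virtual channel per frame: slow-time processing operates at
frame granularity and no channel-combination rule is needed.

Chest displacement is

    d(t) = A_b * w(2*pi*f_b*t; s)  +  A_h * sum_k h_k * sin(2*pi*k*f_h*t + phi_k)

with w a smoothly time-warped sine, w(theta; s) = sin(theta + s/2*sin(theta)).
The warp skews inhale/exhale durations (the identity-bearing waveform shape)
while staying C-infinity, so respiration harmonics decay fast.  That matters:
breathing is 10–30x stronger than the heartbeat, and a kinked waveform would
flood the 0.8–1.5 Hz band with respiration harmonics that no real chest
produces.  Heartbeat is a three-harmonic series (default weights 1/0.4/0.15,
per-subject jittered) because the cardiac impulse is far from sinusoidal.

Cohort defaults (drawn once per subject, seeded): f_b ~ U(0.18, 0.38) Hz,
A_b ~ U(1, 3) mm, f_h ~ U(0.85, 1.45) Hz, A_h ~ U(0.1, 0.3) mm (typical
precordial motion), warp s ~ U(0, 1), subjects seated at R0 = 1 m.  Breathing
at these amplitudes wraps the 3.9 mm-wavelength phase several times over, so
the unwrapper is always exercised; the heartbeat stays sub-radian.  Between
records of one subject the rates drift (sigma 0.01 / 0.02 Hz), the range and
all phase offsets are redrawn, and amplitudes stay fixed — rates and posture
vary between sessions, anatomy does not.  The default scene adds a DC bias,
two static reflectors (one *stronger* than the subject echo, so localization
genuinely needs clutter removal), a random-walk dynamic clutter target,
per-frame oscillator phase noise (0.05 rad) and thermal noise (0.1 of the
subject amplitude per sample).

What the simulator does **not** model: antenna patterns and angle dimensions,
multi-person scenes, body micro-movements other than the random-walk clutter
target, RF nonlinearities, and real inter-subject anatomy.  Passing tests
therefore show that the pipeline recovers what this signal model encodes —
they do not certify performance on real radar captures.

## Processing chain

The chain is raw → dc_removed → static_removed → dynamic_removed, enforced by
stage tags.  The fast-time FFT uses no window and no zero-padding so that
k = 2BR/c stays exact.  Adaptive background subtraction runs the one-pole
recursion B[m,0] = Q[m,0], B[m,n] = 0.9*B[m,n-1] + 0.1*Q[m,n] along slow time
(this formulation is sometimes written with its case split over the range
index, which would leave the recursion ill-defined; initializing at the first
frame and recursing over slow time is the only consistent reading).  Note its high-pass response is far from flat in the respiration
band (|H| ≈ 0.27 at 0.25 Hz) — the respiration channel is attenuated but not
lost, and per-window z-scoring later removes the scale anyway.  The SVD step
keeps the *largest* singular triple: after DC/ABS removal the chest echo is
the dominant coherent structure, and because the simulator's target phase
factorizes into (row gain) × (temporal signal), the chest component is
exactly rank one.  Thorax localization takes the row with maximal summed
magnitude, ties broken toward the smaller bin.

Phase extraction uses the four-quadrant angle (a two-quadrant arctan(I/R)
would fold quadrants and break unwrapping), standard unwrapping,
and forward differencing.  K = 7 bins around the thorax are kept as parallel
rows; the K × T matrix is what the 2-D convolutions consume.  Zero-magnitude
samples carry the previous frame's phase forward with a warning.

Modal separation applies 2nd-order (prototype) Butterworth bandpasses — the
conventional reading of "second-order"; a 2-pole reading is possible but
non-standard in filter-design toolkits — with zero-phase forward-backward
filtering so the three modalities stay time-aligned.  Windows (default
10.24 s / 512 frames) are z-scored per window, per modality, per bin row with
the population (divide-by-n) standard deviation; per-window normalization
makes every training sample self-normalized regardless of record-level drift.

Rate validation (`estimate_rates`) reads the breath rate from the in-band
spectral peak and the heart rate from the in-band peak after masking ±0.04 Hz
around respiration harmonics k*f_b, k = 2..4 — even a smooth breath waveform
leaks harmonics into 0.8–1.5 Hz that can out-power the sub-mm cardiac line,
and harmonic masking is the standard remedy.  Orders above 4 carry too little
power to compete and are not masked.

## Network

Three architecture-identical, weight-independent branches (conv block + two
residual blocks) extract spatial features per modality.  The conv block
(3×3, 16 channels) uses time stride 4: its role is size correction, pulling
the 512-frame axis toward the 7-bin axis before square-kernel feature
extraction.  Residual blocks map 16→32→64 channels at time stride 2
(main path conv-BN-ReLU-conv-BN, 1×1 conv-BN shortcut, post-sum ReLU), so a
[1 × 7 × 512] window becomes [64 × 7 × 32].  CBAM fusion: channel attention
with a shared C→C/8→C MLP over global max/avg pools, then spatial attention
from a 7×7 conv over the channel-wise max/mean maps; both sigmoid-bounded in
(0,1).  Two homogenization-and-concatenate fusion schemes are provided for
the ablation axis.  The fused map is read as a Wt-step time series, projected
to d_model = d_k = 64, passed through single-head scaled dot-product
self-attention, flattened, embedded to 128-d (ReLU) and classified by
softmax.  Hyperparameters that the architecture description leaves open
(channel widths, reduction ratio 8, kernel sizes, d_k) follow common
ResNet/CBAM conventions and are all exposed in `NetworkConfig`.

The layers run on a small reverse-mode autograd core (`radarid.nn`) written
for this package: float32 numpy, im2col/BLAS convolutions, batched matmul,
softmax/cross-entropy, batch norm (batch statistics in training, running
averages at inference) and Adam.  Gradients of every op are tested against
central finite differences, and the stride-1 convolution against
`scipy.signal.correlate2d`.  Weight init is seeded uniform fan-in; a model
built from one seed is bit-reproducible.

## Training and evaluation

Adam (lr 1e-3), batch 32, cross-entropy, 50 epochs by default (20 in the
packaged experiments below).  The 7:3 split is stratified by subject at
*record* granularity, so overlapping windows can never straddle the split; a
leakage guard asserts the record partition on every run.  Accuracy is
window-level; confusion matrices are row-normalized by true class, with
unsupported classes flagged.  A label-permutation control (training on
shuffled labels must give chance-level held-out accuracy) is part of the
acceptance suite.

## Problem sizes of the packaged experiments

The identification experiment used by the tests and by
`scripts/acceptance.py` runs 5 subjects × 20 records of 20 s (1000 frames),
L = 512 / S = 64 windows (8 per record → 560 train / 240 test), and 20
epochs.  Record count is kept at the full 20 per subject because records are
the generalization unit (each has fresh phase offsets and rate drift);
record duration, window step and epoch count are the scaled-down dimensions —
they trade only statistics, not structure.  At seed 0 this configuration
reaches 0.92 held-out multimodal accuracy with the unimodal branches below
it (respiration < heartbeat < phase < fused).  Rate-recovery checks use the
full one-minute records (3000 frames) on 20-subject cohorts.

## Known limitations

* Separability of the synthetic cohort is governed by the profile
  distributions; real populations are harder (similar breathing patterns,
  clothing, posture), so absolute accuracies here say nothing quantitative
  about field performance.
* The ABS recursion attenuates the respiration band ~4x; the pipeline
  compensates via per-window normalization, but very shallow breathers
  (A_b < 0.5 mm) would approach the phase-noise floor.
* Single-person scenes only; exactly one thorax bin is returned.
* The label-permutation null and accuracy bounds assume balanced cohorts;
  heavily unbalanced record counts per subject would need support-weighted
  metrics.
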