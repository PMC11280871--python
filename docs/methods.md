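# Methods

This note records the modelling choices behind `beatline`, the defaults
and their rationale, what the synthetic data does and does not emulate,
and the numerical decisions a maintainer would otherwise have to reverse
engineer from the code.

## Data model and coordinate conventions

A representative beat is a 512×12 matrix of amplitudes in µV at 500 Hz
(1.024 s window), leads ordered I, II, III, aVR, aVL, aVF, V1–V6.
Fiducials are 0-based integer sample indices on the 2 ms grid — no
sub-sample interpolation, matching sample-resolution reference
annotations. Wave runs are half-open `[onset, offset)`; this convention
makes `masks_from_fiducials` and `fiducials_from_masks` exact inverses,
which the tests exploit as an oracle for the threshold reader. Beats
without a P-wave carry an explicit `p_present=False` with `None` P
fields, never zeros: downstream statistics must be able to distinguish
"no P-wave" from "P at sample 0". A consequence of the half-open
convention is that an offset equal to 512 (a wave touching the window
end) is outside the valid domain; the generator keeps fiducials at least
5 samples inside the window and the threshold reader clips to 511 and
flags the beat.

## Synthetic beats

Each wave (P, Q, R, S, T) is a Gaussian bump; each of the 12 leads is a
fixed linear combination of the five bumps via a 12×5 projection matrix
with physiologically plausible signs (aVR globally inverted, small r and
deep S in V1, amplitudes growing towards V4–V5). Ground-truth fiducials
are defined analytically at bump centre ± 3σ of the outermost relevant
bump, so reference annotations carry no measurement noise.

Defaults, chosen to land the derived intervals in normal adult ranges:

| parameter | default | resulting quantity |
|---|---|---|
| σ_P 13–20 ms, PQ gap 10–60 ms | P-duration ≈ 78–120 ms, PQ ≈ 100–220 ms |
| σ_Q, σ_R, σ_S 4–9 ms, Q/S offsets 14–26 ms | QRS ≈ 70–130 ms |
| σ_T 25–40 ms, S→T centre 140–240 ms | QT ≈ 300–460 ms |
| R amplitude 600–1800 µV (lead II scale) | typical precordial R waves |
| P-absent probability 0.135 | the 86.5%/13.5% with/without-P mix |
| neighbour-beat probability 0.1 | short-RR windows with edge intrusions |

A neighbour beat, when drawn, is a full PQRST copy placed one RR-interval
(55–110 bpm) away from the central R wave and pushed outside the zone
[QRS-onset − 350 ms, T-offset + 100 ms], so only its edge portion enters
the window — it perturbs the input without touching the annotation.

What the generator does **not** emulate: fibrillatory baselines,
pacemaker spikes, ST-segment shifts, notched/biphasic waves, inter-lead
timing skew, or any realistic baseline wander beyond the 0.3 Hz test
sinusoid. Passing the end-to-end tests therefore demonstrates that the
training/calibration/evaluation machinery recovers exact ground truth on
smooth morphologies at realistic scales — not clinical-grade performance
on pathological ECGs.

## Noise generators

* **HF**: Gaussian white noise high-pass filtered above 40 Hz
  (4th-order Butterworth, zero-phase), then rescaled per lead so the
  empirical rms is exactly 25 µV; independent across leads (sensor
  noise). The 40 Hz cut places the noise above the diagnostic wave band
  and below Nyquist; the bandwidth is our choice — the originating test
  practice specifies only "high-frequency".
* **LF**: 500 µV amplitude (1 mV p-p) sinusoid at 0.3 Hz, seed-drawn
  phase common to all leads. The window covers only 0.3072 cycles, so
  the delivered peak-to-peak is deliberately phase-dependent, bounded
  below by the partial-cycle envelope 500·(1 − cos(0.3072π)) ≈ 215 µV.
* **PL**: 50/60 Hz sinusoid, phase common to all leads (a field artifact
  is common-mode). At 500 Hz the grid strikes only 10 (50 Hz) or 25
  (60 Hz) distinct phases per cycle, so a fixed-amplitude sinusoid would
  deliver a phase-dependent sampled peak-to-peak (as low as 47.6 µV at
  50 Hz); the sampled wave is therefore rescaled so the delivered
  peak-to-peak is exactly 50 µV.

Noise never alters annotations: noise-immunity errors are defined on
paired measurements of the same beats.

## Network architecture

All convolutions are stride-1 with "same" zero padding (the extra pad
sample of an even kernel on the right) — required for the stated
512↔512 geometry. Upsampling repeats values rather than transposed
convolution. Input standardization is per-channel (all 13 channels, time
channel included) with statistics fit once on the training inputs and
frozen; it has no trainable parameters, consistent with the closed-form
parameter count, and makes inference deterministic. Dropout (0.1)
follows each hidden convolution's ReLU, training only; the output
convolution has none.

The three variant wirings are the parameter-count-consistent readings of
the architecture family:

* **lstm** — one full-sequence LSTM with Ch6 = 24 units ("one memory
  cell per channel") between the third decoder upsampling and the output
  convolution; gate parameters 4·((24+24)·24+24) = 4,704.
* **unet** — pre-pooling encoder maps concatenated onto the matching
  decoder maps ([Ch4,Ch3] at length 128, [Ch5,Ch2] at 256, [Ch6,Ch1] at
  512), doubling the input width of the last three convolutions.
* **resnet** — C2…C6 each wrapped into a residual block
  y = ReLU(W2·ReLU(W1·x + b1) + b2 + x); pooling/upsampling applies to
  the block output. Identity addition forces Ch2…Ch6 to equal their
  block's input width (validated at configuration time).

Each wiring is pinned by an equality test between the built model's
parameter store and the closed-form sum (26,259 / 30,963 / 36,051 /
49,419 at the defaults).

Weights are initialized with a seeded uniform fan-in scheme
(±(fan_in)^-1/2), biases zero. The whole stack — im2col convolutions,
pooling/upsampling adjoints, LSTM backpropagation through time, Adam —
is plain NumPy; a gradient check against central differences is part of
the development workflow (median relative error ~1e-6 away from
ReLU/pooling kinks).

## Training

Binary cross-entropy averaged jointly over all 512×3 output entries
(the natural multi-output extension of the per-channel form), with
probabilities clipped to [1e-7, 1−1e-7]. Adam with default moments;
batch size 64 with per-epoch reshuffling; each training example is
re-drawn every epoch with a fresh uniform integer time offset in
±100 ms (edge padding, not wrap-around — a representative beat is not
periodic in its window; the admissible range shrinks when fiducials sit
near the window edge). Early stopping restores the
minimum-validation-loss parameters; `patience = 0` stops at the first
non-improving epoch. All randomness (split, shuffling, augmentation,
dropout) derives from one seed, so training is bitwise reproducible.

The learning-rate sweep helper exposes {0.0001, 0.0005, 0.001, 0.005,
0.01}; 0.005 is the default.

## Threshold calibration

Onset = start of the longest run at/above the onset threshold; offset =
end of the longest run at/above the offset threshold. Defining each
fiducial through its own threshold only makes the five calibrations
separable; on unimodal maps this equals scanning outward from the map
peak, and on binary maps it reduces to reading the mask runs. Longest-run
selection is the tie-break against secondary bumps from neighbour beats.

Calibration zeroes the trimmed mean time error per fiducial by bisection
on θ ∈ [1e-4, 1−1e-4], using the monotone threshold–error relation
(onset TE non-decreasing, offset TE non-increasing in θ). Trimming keeps
beats with |TE| ≤ the 95th linear-interpolation percentile of |TE| and
is recomputed at every candidate θ (the self-consistent reading of
percentile-trimmed calibration). Convergence: |trimmed mean TE| < 0.1 ms
or θ-interval < 1e-4; ties on |mean TE| (e.g. step-like maps where many
thresholds are equivalent) resolve toward the neutral 0.5. If the mean
TE never changes sign, a 512-point grid search returns the
nearest-to-zero threshold with a warning flag. The P-detection threshold
maximizes TPR + TNR over midpoints of consecutive distinct scores plus
the two extremes; ties break by balance (min |TPR − TNR|), then by the
larger threshold. P-onset/P-offset calibrate on true-positive detections
only.

## Error statistics and protocols

Standard deviations use the n−1 denominator throughout; a single-value
list has std 0 by convention. `cap_outliers_3sd` is single-pass (band
from the raw values, not iterated). `drop_k_protocol` ranks deviations
against the mean computed once before any removal; ties remove the later
index, keeping the protocol order-stable and deterministic. The
noise-error sign convention is clean-minus-noisy: positive means the
noise shortened the measured duration. The restricted 100-record and
10-record reference sets behind the drop-8 and drop-2 protocols are not
redistributable, so the protocols run on synthetic stand-in records of
the same counts; the protocol arithmetic itself is pinned against
brute-force oracles.

## Problem sizes in the test suite

The end-to-end test trains the default plain network on 2,000 synthetic
beats (the 13.5% P-absent mix) for 25 epochs — enough for the validation
loss to flatten on this task — calibrates on the training beats as in
the two-phase scheme, and checks generalization on 300 held-out beats.
Unit and property tests use 60-beat datasets and narrow (6-channel,
kernel-4) networks.

## Known limitations

* Global (not per-lead) delineation only; no per-lead thresholds.
* The measurement module assumes essentially unimodal probability maps;
  heavily multimodal outputs fall back to longest-run selection, and
  threshold monotonicity can break across run switches.
* No significance testing between architectures, no Bland–Altman
  reporting, no attention/W-net extensions.
* Training is CPU NumPy: small models train in minutes, but the stack is
  not intended for large-scale sweeps.
* Readers for clinical waveform formats are out of scope; datasets enter
  through the delimited-text container format.
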