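# beatline

Delineation of 12-lead ECG **representative beats** with 1D convolutional
encoder–decoder networks and a calibrated threshold-crossing measurement
module.

A representative beat is the noise-reduced template heartbeat that resting
12-lead ECG systems build by averaging time-aligned cardiac cycles of
similar morphology. Clinical reports derive their interval measurements —
P-duration, PQ-interval, QRS-duration, QT-interval — from five *global*
fiducial points common to all leads: P-onset, P-offset, QRS-onset,
QRS-offset and T-offset. `beatline` measures those fiducials automatically
and evaluates the measurements the way diagnostic electrocardiographs are
evaluated: interval-error statistics with standard tolerances and
noise-immunity tests.

## Method

**Segmentation networks.** A beat enters as a 512×13 tensor (512 samples
at 500 Hz, 12 leads in µV plus a linear time channel t = 1…512) and leaves
as three per-sample probability maps: P-wave, QRS-complex, QT-interval.
Four architectures share one symmetric geometry — a three-block
convolutional encoder (feature lengths 512→256→128→64, max-pooling 2) and
a mirrored decoder (64→128→256→512, upsampling by repetition), with a
sigmoid output convolution:

| variant  | delta over the plain network                   | parameters |
|----------|------------------------------------------------|-----------:|
| `cednet` | —                                              | 26,259 |
| `lstm`   | one 24-unit full-sequence LSTM before the head | 30,963 |
| `unet`   | encoder→decoder skip concatenations            | 36,051 |
| `resnet` | five two-convolution residual blocks           | 49,419 |

With the default widths Ch1–Ch6 = 24 and kernels K1–K7 = 8 each
convolution contributes `Ch_i·(K_i·Ch_{i−1}+1)` trainable parameters; the
table totals follow in closed form and equal the built models' parameter
stores exactly. Training (phase I) minimizes binary cross-entropy against
binary segment masks on a 70/30 split with ±100 ms random time-offset
augmentation, Adam (LR 0.005), dropout 0.1 and early stopping with
best-epoch restoration. The networks, backpropagation and the optimizer
are implemented in NumPy.

**Measurement module.** Each fiducial is read off its map by a threshold
crossing: the onset is the start of the longest run at/above its onset
threshold, the offset the (half-open) end of the longest run at/above its
offset threshold; P-wave presence is decided by a sixth detection
threshold on the P-map peak. Calibration (phase II) tunes the five
boundary thresholds independently so the 95th-percentile-trimmed mean
time error against reference annotations is zero (bisection on the
monotone threshold–error relation), and picks the P-detection threshold
maximizing TPR + TNR on the calibration set.

**Evaluation protocols.** Signed time errors TE = T_meas − T_ref and
duration errors DE = D_meas − D_ref (ms, sample std with n−1) are
summarized under three outlier policies: mean ± 3σ capping for clinical
test sets, drop-8-of-100 with the standard tolerances (P ±10/±15,
PQ ±10/±10, QRS ±10/±10, QT ±25/±30 ms for mean/std), and drop-2-of-10
for paired noise-immunity tests with the three standard noises (25 µV rms
high-frequency, 1 mV p-p 0.3 Hz baseline, 50 µV p-p 50/60 Hz power line).

Because clinically annotated beats are not redistributable, the package
ships a first-class synthetic generator: Gaussian-bump PQRST beats with a
fixed 12×5 lead-projection matrix, exact ±3σ ground-truth fiducials, a
13.5% P-absent mix, and optional neighbour beats at the window edges.

## Worked example

```
$ beatline param-count
cednet: 26259
lstm: 30963
unet: 36051
resnet: 49419

$ beatline gen --n 200 --seed 7 --out work/data
wrote 200 beats to work/data
$ beatline train --data work/data --epochs 30 --patience 30 --seed 7 \
      --out work/model.npz
best epoch 30/30, val loss 0.02301
$ beatline calibrate --model work/model.npz --data work/data \
      --out work/thresholds.json
wrote thresholds to work/thresholds.json
```

`work/thresholds.json` then holds the six calibrated thresholds together
with the calibration report: the trimmed mean time error per fiducial
(zero to within 0.5 ms by construction of the calibration search), its
standard deviation in ms, and the P-detection TPR/TNR at the chosen
operating point. For this run the QRS-onset entry reads
`mean −0.01 ms, std 4.12 ms, 192 of 200 beats kept` with TPR = TNR = 1.0
— i.e. the calibrated threshold (0.376 on the QRS map) centres the
measured onsets on the reference annotations to within a hundredth of a
millisecond, and every P-wave is correctly detected on the calibration
set. `beatline evaluate --protocol cse` summarizes interval
errors under the drop-8-of-100 rule and writes the per-interval
tolerance verdicts into its report; `--protocol noise` reports the
paired clean-vs-noisy duration differences per noise type.

One shot, end to end:

```
$ beatline pipeline --out work --n 200 --epochs 30 --protocol ptb --seed 7
```

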