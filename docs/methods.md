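# Methods

## The synthetic session generator

The generator stands in for unavailable human forearm sEMG recordings. It
emulates the acquisition protocol exactly (6 s baseline; 30 cycles of 3 s
MVC + 3 s rest; 5 trials per movement; 4 movements; 4 bipolar channels;
2000 samples/s) and the two electrode types through their session-level
signal-to-noise ratios.

**Signal model.** Interference-pattern sEMG is well approximated by
amplitude-modulated, band-limited Gaussian noise. Each channel of a trial
is

    x_c(t) = n_c(t) + s · g[m, c] · e(t) · w_c(t)

- `n_c`: white Gaussian noise, RMS `baseline_noise_rms` (mV), modelling
  the electrode/amplifier noise floor that dominates rest periods.
- `w_c`: an independent unit-variance Gaussian carrier per channel,
  band-passed to 20–450 Hz with a 4th-order zero-phase Butterworth filter
  (an order-2 section run forward-backward) and renormalized to unit
  standard deviation per trial. The upper band edge is additionally capped
  by the modelled anti-aliasing low-pass (700 Hz — inert at the default
  band). The 20–450 Hz band is where surface EMG carries essentially all
  its power at this sampling rate.
- `e(t)`: trapezoidal contraction envelope — 0 at rest, 1 on the MVC
  plateau, 100 ms linear ramps placed entirely inside each contraction run
  (so rest samples are exactly noise). MVCs are treated as constant-effort
  plateaus.
- `g`: a movements × channels gain matrix. The default has each movement
  dominating a different channel (circumferential electrode placement puts
  each movement's prime mover under a different pair) and column-wise
  ordering flexion > fist > open > extension, reflecting the relative
  recruited muscle mass. Row maxima are strictly increasing in that order,
  which makes per-movement RMS medians ordered
  flexion > fist > open > extension > rest on dominant channels.

**SNR calibration.** The SNR statistic downstream is the mean per-segment
power over contraction segments divided by the same mean over rest
segments, in dB. In expectation rest power is `σ_n²` and contraction power
is `σ_n² + s²·E[e²]·mean(g²)`, so the scale `s` achieving a target ratio is
available in closed form; no iterative fitting is needed and measured
session SNRs land within ~0.05 dB of target at default problem sizes.

**Electrode profiles.** CE: 18.2 dB at a 0.01 mV noise floor. Ag/AgCl:
15.7 dB. Because the muscle signal is a property of the subject rather than
of the electrode, the two profiles are constrained to record the same
signal amplitude: the Ag/AgCl noise floor is derived as
`0.01·sqrt((10^1.82 − 1)/(10^1.57 − 1)) ≈ 0.0134 mV`. This matches the
empirical observation that feature-magnitude tables measured with both
electrode types on the same subjects show nearly equal per-movement
amplitudes despite the SNR gap, and it is what gives cross-electrode
transfer its realistic (rather than catastrophic) difficulty.

**Seeding.** A session is generated from one integer seed; trial
(movement `m`, trial `t`) uses entropy `(seed, m, t)` for NumPy's
`default_rng`, so any trial is reproducible in isolation and sessions are
bit-identical across runs.

**What the generator does not model.** No motor-unit action-potential
trains, no motion artifact, electrode drift, power-line interference, or
inter-subject anatomical variability (subjects differ only by seed). Class
geometry is stationary and cleaner than real sEMG: passing classification
results demonstrate that the pipeline is implemented correctly and behaves
sensibly under the protocol's structure and noise levels, not that these
accuracies would be obtained on real recordings.

## Preprocessing

Wavelet shrinkage per channel per trial: Haar (db1) multi-level DWT at
level `min(6, floor(log2(fs/20)))` (approximation band below ~16 Hz at
2000 S/s, i.e. below the EMG band), noise scale σ estimated as
MAD(finest detail)/0.6745, universal threshold `σ√(2 ln N)` applied with
soft thresholding to all detail levels, approximation untouched. All four
choices (wavelet, level, rule, mode) are exposed as arguments. Soft
thresholding in an orthonormal basis never increases energy, and a
zero signal maps to a zero signal.

Offset removal subtracts the per-channel mean over the whole trial
(per-trial, not global, so each recording is normalized independently).
Order of operations: denoise → offset-remove → splice. Splicing is exact
run-length parsing of the binary indicator into half-open 0-based
`[start, end)` intervals; an optional symmetric `trim` margin (default 0)
stands in for the manual per-subject splice adjustment that cannot be
automated faithfully. SNR is computed from offset-removed but *un-denoised*
segments: it characterizes the recording (and hence the electrode), not the
denoiser.

## Features

RMS, SD, VAR, MAV, WL per segment per channel, with SD and VAR taken about
zero (`√(Σx²/(N−1))`, `Σx²/(N−1)`). The zero-centred forms are deliberate:
offsets are removed beforehand, segment means are ≈ 0, and the exact
identities `VAR = SD²` and `SD = RMS·√(N/(N−1))` then hold, which the test
suite exploits. `center=True` switches to conventional mean-centred SD/VAR.
Feature columns are ordered features-outer, channels-inner; a dataset is a
pandas DataFrame with label and provenance columns alongside.

SNR uses `10·log10` (power quantities) of the unweighted mean per-segment
mean-square amplitude, averaged over segments and channels.

## Classifier

Topology (n_in, 20, 8, 5) with 4 ≤ n_in ≤ 20. Hidden activation is tanh by
default with sigmoid available; with the fixed training budgets below,
plain SGD through two sigmoid layers under-converges (the loss is still
descending when the epoch budget ends), while tanh — whose derivative is up
to four times larger — converges comfortably inside the same budgets.
Output is softmax with cross-entropy; gradients are hand-derived and
verified against central finite differences to < 1e−5 relative error.
Optimizer is plain mini-batch SGD without momentum. Weights initialize
N(0, 1/√fan_in), biases at zero, reproducibly from a seed.

Training holds out a stratified 15 % validation split, fits per-column
z-score normalization on the training rows only (stored on the model), and
checkpoints the epoch with the best validation accuracy within the fixed
epoch budget — the "stopping epoch" acts as the maximum budget. The two
default arms use (lr 0.01, batch 256, 542 epochs) for Ag/AgCl with all
five features and (lr 0.05, batch 128, 180 epochs) for CE with RMS/MAV/VAR.
Argmax ties resolve to the lowest class index; class order is (rest,
extension, open, fist, flexion).

Cross-electrode evaluation restricts the other arm's dataset to the model's
feature subset and, by default, normalizes it with the model's stored
training statistics (a config switch allows refitting on the evaluation
data instead). Both directions are reported with provenance.

## Experiment orchestration

All subjects' segments are pooled into one dataset per electrode arm
(per-subject SNR is reported separately); the last trial of every movement
is the test set and never reaches training or normalization. The default
experiment uses 4 subjects. Reports are plain JSON with CSV side-files;
rendering is presentation-only.

## Problem sizes and numerical choices

Default experiment: 2 arms × 4 subjects × 20 trials of 372 000 samples ×
4 channels; 4 880 segments per arm (3 904 train / 976 test). The SNR
calibration study uses 20 independent sessions per electrode. These sizes
run in a few minutes on one CPU; unit tests use structurally identical
reduced protocols (shorter durations, fewer cycles/trials). Degenerate
inputs are rejected explicitly: non-binary indicators, empty segments,
trims that consume a run, decomposition levels deeper than the signal,
networks outside the 4–20 input range, single-trial train/test splits, and
SNR with a missing class.

## Known limitations

- Synthetic classes are more separable than real sEMG; absolute accuracies
  here exceed what the same pipeline would achieve on human data.
- The envelope/gain model has no within-class amplitude drift, so
  per-segment feature variance is smaller than in real recordings.
- The cross-electrode asymmetry (clean-trained models degrade on noisy
  data, not vice versa) reproduces the qualitative pattern only; its
  magnitude depends on the assumed common-amplitude electrode model.
- Wavelet threshold estimation is per trial; very short custom protocols
  (< ~1 s) leave few coefficients for the MAD estimate.
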