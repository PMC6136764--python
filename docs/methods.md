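# Methods

`emgctl` implements a complete simultaneous myoelectric control system
— from raw multi-channel surface EMG to closed-loop usability metrics —
that can be exercised end to end without hardware, using a seeded
synthetic-EMG generator and a simulated user.

## Signal model and preprocessing

Eight bipolar electrode pairs are assumed equally spaced around the
forearm, sampled at 1.2 kHz. Each channel is band-pass filtered 5–500 Hz
and notch filtered at 50 Hz with eighth-order Butterworth filters,
realized as second-order sections (`scipy.signal.butter` with a
prototype order of 4, which yields order-8 band-pass/-stop transfer
functions). Offline training data are filtered zero-phase
(forward–backward); the closed-loop path uses the causal single-pass
variant of the same sections with persistent state, since a real-time
system cannot look ahead. The notch is a Butterworth band-stop with a
default ±1 Hz stop band; only its center frequency and order are fixed
by the design, so the width is configurable.

Signals are segmented into 160 ms windows (192 samples) advanced by
40 ms, never straddling trial boundaries.

## Training protocol and labeling

A training session has nine trials: 30 s of rest, then one trial per
active motion (wrist flexion, extension, pronation, supination, and the
four non-antagonist pairings, each a class of its own). Active trials
follow a trapezoidal commanded-intensity profile — 3 s rest, 3 s linear
ramp to full range, 3 s hold, 3 s ramp down — repeated four times
(48 s). Windows of active trials whose commanded intensity is below 30%
of full range are discarded to keep near-rest data out of the active
classes. The intensity of a window is referenced at its final sample
(the most recent instant, matching what a causal labeler would see); a
window-mean reference is available as an option.

## Synthetic EMG

Surface EMG is modeled as amplitude-modulated band-limited Gaussian
noise: independent per-channel Gaussian carriers band-passed to
20–450 Hz with instantaneous standard deviation
`noise_floor + intensity(t) · gain[channel, class]`. The default gain
matrix gives each primitive motion a dominant pair of adjacent channels
on the 8-electrode ring (gain 1.0) with a 0.05 cross-talk floor
elsewhere; combined motions superpose their primitives' gain columns.
The default noise floor is 0.05 (5% of a dominant channel's full-range
amplitude). These defaults were chosen once as a realistic idealization
of well-placed electrodes: distinct motions activate distinct muscle
groups, combined contractions superpose, and the rest signal is small
but nonzero.

What the generator emulates: class-dependent spatial amplitude
structure, stochastic within-class variability, the trapezoidal
training protocol, band-limited EMG-like spectra, and exact seeded
reproducibility (one seed, split into per-trial child streams). What it
does not emulate: motor-unit action potentials, electrode-shift and
limb-position effects, fatigue, crosstalk correlation between channels,
or inter-subject anatomy. Passing tests therefore demonstrate that the
pipeline is correct and that the decoders recover planted class
structure — not that they would reach any particular accuracy on human
EMG.

## Decoders

**CNN.** The raw-window decoder consumes 8×192 matrices. Its 22 layers
are: input; five convolution blocks of 16, 32, 64, 64, 16 filters (3×3,
zero-padded "same", each followed by batch normalization and ReLU);
2×2/stride-2 max pooling after blocks 1–3 (8×192 → 4×96 → 2×48 → 1×24;
blocks 4–5 run at 1×24); a fully connected layer to the 9 classes; a
softmax layer; an argmax classification layer. Pool placement follows
from the printed feature-map sizes. Training uses stochastic gradient
descent with momentum 0.9 (the conventional default; the coefficient is
configurable), initial learning rate 0.001, minibatch 128, L2 weight
decay 1e-4 on convolution/dense weights, a random 90/10
train/validation split, validation twice per epoch (every
⌊iterations-per-epoch/2⌋ minibatches), at most 40 epochs, and early
stopping after 5 consecutive validation checks without improvement on
the best validation loss, restoring the best-so-far parameters.
Weights use He initialization from an explicit seed, so a fixed seed
reproduces a run bit-for-bit on a fixed BLAS. The engine is written
directly on NumPy (im2col + BLAS matrix products, float32); inputs are
the raw filtered signal by default, with an optional per-channel
standardization flag.

**SVM.** The feature decoder consumes 40-dimensional vectors: per
channel, mean absolute value, zero crossings, waveform length, slope
sign changes, and mean frequency. The ZC/SSC dead band defaults to 0
(the synthetic noise floor is controlled; the dead band is the main
knob differing across published TD implementations and is configurable
and persisted). Mean frequency is the power-weighted mean of a single
rectangular-window periodogram with the DC bin excluded — 192-sample
windows are too short for segment averaging. Features are z-scored with
training-set statistics stored inside the model; the kernel is RBF with
γ = 1/40 (the reciprocal of the feature count; configurable) and cost
1, with one-vs-one voting.

## Velocity control

The decoded class selects the movement direction (extension/flexion →
±x, pronation/supination → ±θ, combined classes → the normalized
diagonal; all reversed for left-handed use). Speed follows

    V = G · (X/Y − TH) / (1 − TH), clipped to [0, G]

with X the channel-averaged MAV of the current window, Y the per-class
maximum of that quantity over the (post-intensity-filter) training
windows, TH = 0.2 and G = 0.6 units/s. Combined motions use a unit
direction vector scaled by V, so the speed magnitude equals V for every
class; a per-axis-V variant is available behind a flag.

## Fitts'-law bench

Targets are the 8 active classes × 6 difficulty levels (distances 1 and
0.5 units; widths 0.10, 0.15, 0.25), giving 48 targets presented in
four seeded-shuffled trials of 12. Difficulty is the Shannon–Welford
index ID = log₂((W+D)/W^k) with k = 0.5. The control loop ticks every
30 ms: the simulated user emits synthetic EMG for its intended class
and effort, the most recent 160 ms buffer (primed with rest signal and
causally filtered with persistent state) is decoded, and the command is
integrated into the cursor state. Orientation is an unbounded linear
coordinate (no 2π wrap). Acquisition requires staying within a 2-D
Euclidean distance W/2 of the goal continuously for 1 s; the dwell
timer resets on exit (the standard convention in this test family;
configurable). The 15 s timeout includes dwell time. Movement time for
metrics is the time from trial start to the start of the final
successful dwell (dwell excluded) — the definition throughput depends
on, recorded here as the implementation's convention.

The simulated user looks at the cursor state from 5 ticks earlier
(≈150 ms reaction delay), picks the active class whose direction best
aligns with the remaining error (a combined class only when both
coordinates err beyond a 0.05-unit dead zone), and sets effort to
distance/0.3 saturated at 1 plus Gaussian noise of s.d. 0.1, resting
once inside the target. An ideal variant (no delay, no noise, decoder
bypassed) provides the pure-kinematics upper bound. These defaults were
fixed from the design sketch before measuring closed-loop outcomes.

## Metrics

Completion rate: % of targets acquired. Throughput: mean of
ID/movement-time over acquired targets (failed targets contribute to
completion rate only). Path efficiency: straight-line over traveled
distance from trial start to the final dwell's start, as a %; a
zero-length path is 100% by definition. Overshoot: target re-entries
before acquisition (entries − 1). The exact throughput/overshoot
formulas follow the conventions of the virtual-target-acquisition
literature this test style comes from; they are documented constants of
this implementation. Fitts adherence is the OLS fit of per-ID mean
movement time against ID; methods are compared per metric with a
one-way ANOVA at α = 0.05 (for two groups, F = t²).

As a plausibility cross-check (not asserted anywhere): a throughput
near 0.36 bits/s at the bench's mean ID of ≈1.16 bits implies ≈3.2 s
movement times, consistent with the magnitudes this kind of test
produces for human operators.

## Problem sizes and numerical choices

The test suite and the examples run at sizes chosen to keep a full run
cheap on one CPU while still exercising every code path at the protocol
defaults: decoder parameter-recovery checks use 1-repetition training
sessions (~2,200 windows after the 30% filter) with the CNN capped at
10 epochs — the default 4-repetition session (~6,500 windows) behaves
identically but trains ~4× longer — and closed-loop checks run the full
48-target session. Balanced subsampling (equal windows per class)
makes the chance level exactly 1/9 in the indistinguishable-classes
control, since the rest trial contributes more windows than each active
trial.

Degenerate inputs are defined, not special-cased: a zero window has
MAV = WL = ZC = SSC = 0 and mean frequency 0; windows shorter than the
buffer are impossible by construction (the buffer is primed); ties in
max pooling take the first maximum; the early-stopping comparison uses
a 1e-6 improvement margin.

One printed-table nicety: the difficulty table's last row is 0.585
bits, which rounds to 0.58 at two decimals but is commonly printed as
0.59 (half-up rounding of the three-decimal 0.585); tests compare
against the printed values with a 0.0055-bit tolerance.

## Known limitations

The CNN engine is single-threaded NumPy; training the full-size session
takes minutes, not the seconds a GPU framework would need. The
synthetic generator's separability is by construction, so offline
accuracies near 100% say nothing about human EMG (the interesting
regime can be explored with the `gain_jitter` and gain-matrix knobs).
The simulated user is a proportional policy with delay and noise, not a
model of human motor learning; closed-loop metrics are meaningful for
comparing decoders under identical conditions, not as absolute human
performance predictions.
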