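# Methods

## Problem and scope

`emgkit` implements a personalized surface-EMG hand/finger gesture
recognition pipeline: three forearm channels sampled at 2000 Hz, ten
classes (rock, scissors, paper, one, three, four, good, okay, finger gun,
and rest), six time-domain features per channel, and four classifier
families (MLP, SVM, random forest, logistic regression) tuned per subject.
Because no public recordings accompany the protocol, the package ships a
synthetic generator that emulates the acquisition session; all tests and
the reproduction script run on simulated cohorts.

## Recording protocol and synthetic signals

A session consists, per non-rest gesture, of four rounds of five sets,
each set a 5-s rest followed by a 5-s gesture, with a 10-s rest between
rounds (`build_schedule`). The long inter-gesture break of a live session
carries no signal content and is represented by the same 10-s rest.

Each simulated channel is

```
x_c(t) = env_c(t) * n_c(t) + A_line * sin(2*pi*60*t + phi_c)
```

where `n_c` is unit-RMS Gaussian noise band-limited to 20-450 Hz (surface
EMG concentrates its power in roughly 20-500 Hz; the shaping filter is a
zero-phase 4th-order Butterworth, giving >= 98 % in-band power), and
`env_c` is a trapezoidal activation envelope: baseline `rest_gain` during
rest, rising to the gesture's per-channel gain after a uniformly drawn
onset latency (default U(0, 0.3) s, drawn per block per channel so the
three muscles activate asynchronously) with a 0.2-s linear ramp, and
falling back after the commanded block. Latency and ramp create the
transient windows whose misclassification is the dominant error mode in
real recordings.

Defaults: `rest_gain = 0.3` per channel, gesture gains between 1.5 and 6
arranged so every gesture activates at least one muscle at >= 5x rest and
no two gestures share a three-channel pattern; 60-Hz amplitude 0.05.
Amplitudes are arbitrary units — only ratios matter downstream — so no
attempt is made to model millivolt scale, electrode impedance, crosstalk,
or motor-unit physiology. Inter-subject variability multiplies every gain
by exp(N(0, sigma^2)) (default sigma = 0.2), keeping amplitudes positive.
All randomness flows from a single integer seed; identical inputs give
bit-identical recordings.

What the generator deliberately does not emulate: non-stationary fatigue
drift, electrode lift-off artifacts, inter-channel crosstalk, amputee
signal characteristics, and real within-class spectral differences between
gestures (all classes share one carrier spectrum, so class identity is
carried almost entirely by amplitude patterns). Passing pipeline tests
therefore demonstrates the machinery end to end — calibration, labeling,
features, training — under clean, well-separated conditions; they do not
predict accuracy on real recordings.

## Preprocessing

Two Butterworth filters, applied per channel as second-order sections: a
4th-order 20-500 Hz bandpass and a 7th-order 59.5-60.5 Hz bandstop.
Filtering is causal single-pass by default (a real-time pipeline cannot
look ahead); `zero_phase=True` switches to two-pass `sosfiltfilt` for
offline work. No startup trimming is performed; instead the threshold
calibration skips the first 0.25 s of each round so the filter transient
cannot inflate the rest baseline. Note that the 1-Hz-wide notch has
Q ~ 60 and rings for several seconds: steady-state attenuation at 60 Hz
is effectively complete (< -300 dB by frequency response), but any
time-domain measurement must allow ~10 s of settling.

## Segmentation and activation labeling

Windows are 250 ms (500 samples) advancing in 25-ms steps (90 % overlap),
half-open `[start, start + W)`, 0-based, and confined to (gesture, round)
spans — inter-round rest is not segmented, which keeps every window
attached to a round and yields the expected ~9:1 ratio of rest windows to
per-gesture windows over a full session.

Activation is detected per channel with the threshold
`lambda * Baseline_max`, where `Baseline_max` is the peak absolute
filtered amplitude over the first 4 s of each round's leading rest block
(after the 0.25-s skip), maximized over all (gesture, round) entries per
channel. `lambda` ranges from 1 to the ratio of the largest to smallest
`Baseline_max`. The sweep's selection rule — not fixed by the protocol
description — is the smallest grid value producing zero threshold
crossings anywhere in the commanded rest spans, i.e. maximum onset
sensitivity subject to no rest-state false positives; if no value
qualifies, the upper bound is returned with a warning. Crossings are
sought only from each gesture command onward, the earliest crossing among
the three channels is the activation point, and the activated state holds
for exactly 5 s from it. A window is labeled with its round's gesture iff
strictly more than 50 % of its samples are activated.

## Features and standardization

Per channel per window: RMS, VAR, MAV, SSC, ZC, WL in channel-major order
(18 columns). VAR uses the zero-mean convention (VAR = RMS^2); bandpassed
EMG has no DC component, so this equals the mean-square power. ZC counts
sign flips whose amplitude step is at least a threshold (default 0); SSC
counts interior samples where the slope product `(x_i - x_{i-1})(x_i -
x_{i+1})` strictly exceeds the threshold — a `literal` mode using `>=` is
kept for comparison, under which a constant signal scores N - 2.
Standardization to zero mean and unit (population) variance is fitted on
training data only — inside every cross-validation fold as well — to
avoid leakage; constant columns map to zero.

## Classifiers and tuning

Hyperparameters are tuned by stratified 10-fold cross-validation over the
published grids: MLP layers {2,3,4} x width {300,600,1000} x dropout
{0.2,0.3} x batch-norm {on,off}; SVM kernel {linear,rbf} x C
{1,10,100,1000} x gamma {1,...,1e-4}; RF trees {100,500,1000} x class
weight {balanced-subsample, none}; LR penalty {L1,L2,elasticnet,none} x C
{1,...,1e-4} x class weight x solver {lbfgs,saga}. Infeasible LR cells
(lbfgs with L1/elastic-net) are skipped; elastic-net uses mixing 0.5. The
best point by mean fold accuracy (ties: first in enumeration order) is
refitted on the whole training set.

The MLP is implemented directly in NumPy: equal-width hidden layers of
linear -> batch normalization (when on) -> ReLU -> inverted dropout, a
10-way softmax head, categorical cross-entropy, Adam (lr 0.001, batch
1024), He initialization, batch-norm running statistics with momentum 0.9.
The activation function, initialization and layer ordering are not fixed
by the protocol description; these are the package's documented choices.
Default training is 2000 epochs; the `FAST_RECIPE` (60 epochs) is used in
tests, where the synthetic task saturates well before that. The SVM uses
the one-vs-one multiclass decision of its underlying implementation.

Two evaluations are provided: a stratified 90/10 holdout (stratification
keeps all ten classes in the small test set), and a round-based split
(train rounds 1-3, test round 4) emulating deployment on later data. Rest
windows are under-sampled to the median non-rest class count before
splitting; both orders of balancing and splitting are reachable through
the API.

## Statistics

Per-subject accuracies of competing methods are compared with: Levene's
test (mean-centered; median centering available) for the equal-variance
assumption, Welch's heteroscedastic one-way ANOVA with Welch-Satterthwaite
denominator df, Games-Howell pairwise post-hoc tests (studentized-range
p with pairwise Welch df), and two-sided variance-ratio F-tests under
Benjamini-Hochberg FDR correction. Confusion matrices are row-normalized
per subject (per-class sensitivities) before element-wise averaging;
count-level aggregation remains available. With equal variances and group
sizes the Welch F approaches the classical one-way F from below with a
relative gap of order 1/n (about 6e-4 at n = 1000), which is why the
equivalence test asserts convergence rather than near-exact agreement.
The feature ablation fixes the classifier at the MLP and sweeps the eight
combinations of the ZC/SSC/WL base set plus subsets of {MAV, RMS, VAR};
on amplitude-coded synthetic data the base set scores lowest (WL still
carries amplitude, so the gap is modest).

## Problem sizes and numerical choices

Tests and `scripts/acceptance.py` use the full nine-gesture, four-round
protocol with one set per round and three-subject cohorts — every
structural property (round calibration, transitions, round splits,
class balance) is preserved at about one fifth of the samples — and
single-point "fast" grids with the 60-epoch MLP recipe. The package
defaults remain the full five-set protocol and full grids. Ties,
degenerate inputs and tolerances follow the rules above: all-zero
baselines raise a calibration error rather than yielding a zero
threshold; blocks with no crossing contribute no activated samples; a
window overlapping two rounds is assigned to the round owning the
majority of its span and logged.

## Known limitations

- Synthetic classes are separable by amplitude alone, so absolute
  accuracies here (≈0.97-0.99) exceed what real recordings yield and
  carry no information about real-world performance.
- The round-split evaluation shows only a mild drop on synthetic data
  because the generator is stationary across rounds; real sessions drift.
- The causal/zero-phase choice of the original acquisition filters is
  unknown; both are provided.
- Whether baseline peaks were pooled per channel or across channels in
  the original calibration is ambiguous; thresholds here are per channel
  with the lambda range pooled across all entries.
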