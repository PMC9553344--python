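# Methods

This note records the models, conventions and numerical choices behind
`eegchansel`, and what the synthetic validation does and does not establish.

## Data model

A recording is a channels × samples matrix in microvolts with a sampling
rate and an ordered electrode montage (default: the 30-electrode 10-20
layout Fp1=1 … O2=30; reference electrodes A1/A2 are dropped on load).
Analysis operates on non-overlapping 1-second epochs at 128 Hz, labeled
0 (JX, resting) or 1 (ZD, fatigued). Rate reduction uses polyphase
resampling with a zero-phase FIR anti-alias filter (`scipy.signal.resample_poly`
with the exact rational rate ratio); trailing partial epochs are dropped.

## Subband standard-deviation features

A 6-level wavelet packet decomposition splits 0–64 Hz into 64 leaves of
1 Hz. Each EEG band (Theta 4–8, Alpha 8–13, Beta1 13–20, Beta2 20–30 Hz)
is reconstructed from exactly the leaves whose natural frequency intervals
lie inside it; leaves are taken in sequency (frequency) order, not raw tree
order, since the high-pass branch mirrors the spectrum at every split. Band
edges must fall on leaf boundaries, which all defaults do at 128 Hz. The
feature is the population standard deviation (divisor N) of the
band-limited signal.

Numerical choices:

* **Wavelet `db16`, periodized extension.** Chosen over shorter filters and
  symmetric extension for two measured reasons on 1-second (128-sample)
  epochs: (i) periodization keeps the transform orthonormal, so leaf
  coefficient energy equals signal energy to machine precision — symmetric
  extension inflates it severalfold and makes energy bookkeeping
  meaningless; (ii) short filters leak badly at this epoch length (a pure
  6 Hz tone puts only ~86 % of its energy into Theta under `db4`, vs ≥ 98.7 %
  for all four band probes under `db16`). Both are configuration knobs
  (`WPDConfig`).
* The packet tree is evaluated batched over epochs × channels with
  `pywt.dwt`/`idwt` along the last axis; the test suite pins it against
  `pywt.WaveletPacket` node by node.

## Fuzzy entropy

FE(x) = ln Φ^m − ln Φ^{m+1}. Both window lengths use the same K = N − m
starting indices; Φ^w averages, over ordered pairs i ≠ j, the membership
exp(−(d_ij / r_eff)^n) of the Chebyshev distance d_ij between the length-w
windows at i and j. Conventions:

* **Same index set for m and m+1.** With shared indices the (m+1)-window
  distance dominates the m-window distance pairwise, so Φ^{m+1} ≤ Φ^m and
  FE ≥ 0 holds structurally, not just statistically. This also sets the
  minimum length at N ≥ m + 2.
* **Tolerance.** Default r = 0.25 relative to the sequence's standard
  deviation: r_eff = rσ, with membership exp(−(d/rσ)^n). This form is
  invariant under amplitude scaling for every exponent n, which is the
  property a dimensionless complexity measure should have; an absolute-r
  mode (`r_mode="absolute"`) is available where physical-unit tolerances
  are wanted.
* **Exponent** n = 2 by default (the common fuzzy-membership choice),
  configurable.
* **Windows are raw segments** (no per-window baseline removal).
* **Constant sequences** have FE defined as exactly 0 (all distances zero,
  all memberships one), avoiding a 0/0 at the tolerance.
* Implementation is vectorised over epochs × channels in chunks; the m+1
  distance matrix reuses the m matrix (one extra element-wise max). The
  suite checks equality with a literal loop-by-loop transcription at
  1e-10 on randomized short sequences.

## Fusion

A fused feature matrix interleaves two single-feature matrices
channel-major: channel c contributes adjacent columns (first feature,
second feature). Un-interleaving by the column map recovers the inputs
exactly.

## ReliefF channel weighting

Two-class ReliefF: columns are min-max scaled to [0,1]; m_iter = 80
instances are sampled uniformly without replacement; for each, the
k = 10 nearest hits and misses (Euclidean distance in the scaled space,
self excluded) update every column weight by mean |miss diff| − mean
|hit diff|; weights are averaged over sampled instances. The [0,1] scaling
doubles as the per-column range normalisation of the classical update and
makes constant columns contribute exactly zero. A channel's weight is the
mean of its columns' weights (relevant for fused features); ranking ties
break toward the lower channel index.

## Subset evaluation and search

Subsets are scored by K = 10 nearest-neighbour classification under
stratified 5-fold cross-validation with shuffling (each fold trains on 80 %
and tests on 20 %), pooling the confusion counts over folds before forming
Acc = (TP+TN)/(TP+TN+FP+FN). Pooling (rather than fold-averaging) is used
throughout; with stratified folds the difference is within CV noise.
Inside each fold, columns are min-max scaled using training-fold ranges
before the distance computation. This matters for fused features: microvolt
subband deviations and dimensionless entropies differ by an order of
magnitude in range, and an unscaled Euclidean metric collapses the fused
feature to whichever family is numerically larger (measured on planted-signal
data: fused top-6 accuracy 0.92 unscaled — indistinguishable from the Std
feature alone — vs 1.00 scaled). Scaling is fit on training folds only.
KNN voting ties (possible with even K) break toward class 0, matching
scikit-learn's lowest-label convention.

The canonical search (`ReliefFSFS`) evaluates prefixes of the ReliefF
ranking — the subset grows from the empty set by the highest-weighted
remaining channel, so the accuracy curve needs only N evaluations. The
optimal subset is the smallest size attaining the maximum accuracy.
`GreedySFS` implements classical accuracy-greedy forward selection (N²/2
evaluations) as a comparison mode.

## Synthetic generator

Each subject yields one resting and one fatigued recording (defaults:
30 channels, 1000 Hz, 300 s per state, 10 subjects). Every channel is the
sum of

* pink (1/f above 1 Hz) Gaussian noise, sd 10 µV,
* a narrowband alpha oscillation, 10 Hz centre, 2 Hz bandwidth, 8 µV
  equivalent-sine amplitude, and
* a narrowband theta oscillation, 6 Hz centre, 2 Hz bandwidth, 5 µV
  equivalent-sine amplitude.

In the fatigued state, informative channels (default T6, O1, Oz, T4, P3,
FC3) have their theta amplitude multiplied by `theta_power_shift` (default
2.0 — fatigue EEG is characterised by substantially elevated theta power)
and their background noise attenuated by `1 − complexity_shift` (default
0.5), making the signal more oscillation-dominated and hence more regular,
which lowers fuzzy entropy. The two effects are independently switchable so
power-driven (Std) and regularity-driven (FE) selection can be validated in
isolation.

Oscillations are narrowband Gaussian processes, not fixed-phase sinusoids,
and every component is normalised to its target power per recording. Both
choices remove *recording fingerprints*: a deterministic phase or a
realised-power excursion is constant within a recording, and a classifier
fed epochs from few recordings will learn recording identity instead of
state (observed as 0.83 "accuracy" on a null dataset with a fixed-phase
generator). With the narrowband design, a no-effect generator yields chance
accuracy and non-informative channels are exchangeable.

What the generator does not emulate: inter-channel correlation from volume
conduction, artifacts (EOG/EMG), non-stationarity within a state, subject
heterogeneity of spectra. Passing the planted-recovery tests therefore
shows the pipeline correctly concentrates on class-informative channels
under realistic amplitude/noise ratios — not that real fatigue EEG yields
any particular accuracy.

## Validation scales

The test suite and acceptance script run the end-to-end recovery at a
reduced scale chosen to keep a laptop run comfortable while leaving the
per-class epoch counts large enough for stable CV (2 subjects × 60 s per
state → 240 epochs, 120 per class; 20 seeds). Oracle batteries use ≥ 100
random short sequences (FE) and 30 small instances (ReliefF). The
full-scale study configuration (10 subjects × 300 s) is the generator
default and runs the identical code path.

## Known limitations

* ReliefF here is strictly two-class; multi-class extensions are out of
  scope.
* The weight-ordered search is not guaranteed to find the globally optimal
  subset of a given size (neither is greedy SFS); it inherits ReliefF's
  blindness to strictly complementary channel pairs.
* Optimal-size determination takes the literal argmax; near-ties at larger
  sizes (common once the curve saturates) are resolved toward the smaller
  subset by construction.
* EDF export is not provided (no EDF writer dependency); synthetic datasets
  are written as delimited text, and EDF input is read via mne.
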