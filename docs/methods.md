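# Methods

This note documents the models and procedures implemented in `wristbci`,
the parameter choices that matter, what the synthetic data generator does
and does not emulate, and the package's known limitations.

## Trial structure and pre-processing

A trial is 12,000 ms long: 3,000 ms of pre-cue baseline, then four stages
delimited by visual cues at fixed offsets from the GetReady cue (t = 0):
S1 get-ready [0, 2000) ms, S2 force ramp [2000, 5000) ms, S3 isometric
hold [5000, 8000) ms, S4 rest from the Stop cue at 8000 ms, with the trial
ending 1,000 ms after Stop. Segmentation cuts one trial per GetReady
marker; trials without a matching Stop, trials leaving the recording
bounds, and trials of non-nominal length are dropped with a warning so the
trial tensor stays rectangular.

Quality screening reports channels whose absolute amplitude exceeds 100 µV
(the conventional ceiling of scalp EEG) on more than 5% of samples;
flagged channels are reported, not interpolated, since the analysis keeps
all 128 channels.

Broadband filtering is a zero-phase (forward–backward) cascade: 4th-order
Butterworth high-pass at 0.5 Hz (DC drift), 4th-order low-pass at 99 Hz,
and a 2nd-order IIR notch centred at 50 Hz with 2 Hz bandwidth (AC line).
Zero-phase filtering preserves the timing of the band-power features
extracted later. The filter realisation is a package choice; corners are
configurable.

### Artifact screening

Ocular and myogenic components are identified automatically from an ICA
decomposition of the broadband trials, replacing manual inspection with
auditable indices:

* **EOG**: fraction of absolute topography mass on frontal electrodes
  (unit-sphere y > 0.55) and fraction of Welch PSD power below 5 Hz, both
  above 0.45 / 0.55;
* **EMG**: topography mass at the head's edge (|x| > 0.72) and power above
  30 Hz, same thresholds.

The thresholds were calibrated once against the generator's ground truth
(planted blink and EMG sources must be flagged, planted cortical sources
must not) and are configurable. Flagged components are zeroed and the
channel data rebuilt from the rest; with nothing flagged the
reconstruction is the identity up to numerical tolerance.

## Band decomposition and ICA spatial filtering

The 1–90 Hz spectrum is covered by four zero-phase 4th-order Butterworth
passbands: 1–7 Hz (delta–theta), 7–35 Hz (mu–beta), 35–49 Hz (low gamma)
and 51–90 Hz (high gamma). Applied to the three analysis datasets (RLI,
EFI-RH, EFI-LH) this yields 12 band-filtered datasets per participant.
Published summaries of this paradigm sometimes print the mu–beta band as
8–35 Hz; the 7–35 Hz definition is used here, and the edges are
configurable.

Each dataset is decomposed by extended Infomax ICA
(`mne.preprocessing.infomax`) on trials concatenated along time, after
average-referencing (which fixes the rank of 128-channel data at 127 and
hence the component count — the only mechanism consistent with 127
components from 128 channels) and PCA whitening to the numerical rank.
Hyperparameters: iteration cap 512, weight-change tolerance 1e-7,
seeded and bit-reproducible for a fixed seed. For long recordings the
decomposition may be *fitted* on an evenly spaced subset of time points
(`max_fit_samples`), the standard economy for Infomax; activations are
always computed for every sample.

Component topographies are the mixing-matrix columns, interpolated on an
azimuthal-equidistant projection of the scalp. The topography peak is the
electrode of maximum absolute weight; a perfectly uniform column has
focality 0 and an undefined peak. A component "matches" a region of
interest (ROI) when its peak lies within 3 cm great-circle distance
(95 mm head radius) of the ROI's scalp anchor. The seven ROIs are anchored
at fixed electrodes — M1 hand area at C3/C4, ventral premotor cortex at
FC5/FC6, prefrontal cortex at AF3/AF4, supplementary motor area at FCz —
and lateral pairs are symmetrised so that left/right ROIs are exact mirror
images. The 3 cm radius is a package choice (roughly two electrode
spacings of a 128-channel montage); matching is not a source localisation,
only a scalp-proximity heuristic, and the radius is configurable.

The packaged montage is a fixed 128-label subset of the 10-5 system:
the full 10-10 core plus intermediate 10-5 positions chosen by
farthest-point coverage, with unit-sphere coordinates taken from the
standard published positions.

## Time–frequency features

Over the isometric hold (t = 5000…8000 ms) a 300 ms rectangular window
slides in 100 ms steps: 28 windows. Each window's one-sided FFT power
spectrum (squared magnitude, DC excluded, no taper) is summed within
2.9 Hz bins tiling the analysis band upward from its lower edge; leftover
bandwidth narrower than one bin is discarded. Feature counts per trial:
2 bins × 28 = 56 (delta–theta), 9 × 28 = 252 (mu–beta), 4 × 28 = 112
(low gamma), 13 × 28 = 364 (high gamma).

At 500 Hz a 300 ms window holds 150 samples, so the FFT grid (3.33 Hz) is
coarser than the 2.9 Hz bins. Each FFT frequency is assigned to the unique
bin containing it; a bin that receives no FFT frequency contributes a
structural zero feature, keeping the count law |features| = windows × bins
exact. An optional zero-padding factor refines the FFT grid; the default
is no padding, the plainest reading of an FFT power spectrum.

## Feature selection: Bhattacharyya distance

For each feature, the two class-conditional amplitude densities are
estimated as normalised histograms on shared edges spanning the pooled
min–max range (32 bins; configurable). The Bhattacharyya distance is
BD = −ln Σ √(a_i b_i); identical samples give BD = 0 and disjoint supports
give +∞ (which sorts above any finite score). The 20 highest-BD features
are selected, ties broken toward lower feature index. A variant computing
the overlap without the square root is available for comparison
(`literal_form=True`) but is not the established Bhattacharyya
coefficient and is not used by default. The histogram estimator converges
to the Gaussian closed form ¼(Δµ)²/(σ₁²+σ₂²) + ½ln((σ₁²+σ₂²)/(2σ₁σ₂)) to
within 0.05 at 10⁵ samples.

The selected-feature count k = 20 follows the paradigm's single-dataset
optimisation; `sweep_feature_counts` reproduces the sweep over
{10, 15, 20, 30, 40}.

## Classification: Mahalanobis-distance clustering

Trials are points in the selected-feature space; each class is a cluster
summarised by its mean. A test trial joins the class with the smaller
squared Mahalanobis distance d² = (p − m_cl)ᵀ C⁻¹ (p − m_cl).

**Covariance.** C is the *pooled* within-class covariance of the training
trials (per-feature z-normalised), shrunk by the Ledoit–Wolf estimator so
the inverse exists with 20 features and on the order of 10² training
trials per class. A per-class-covariance variant is provided but not the
default, for a structural reason: comparing raw squared MDs under
different per-class metrics, without the log-determinant term of a full
Gaussian classifier, systematically favours the wider-spread cluster —
band-power features, whose class contrast is a variance/scale shift,
trigger exactly this failure, and the variant classifies near or below
chance on strongly separated data. The pooled metric makes the rule a
nearest-cluster-mean test in a common whitened space and is affine
invariant per feature.

**Outlier screen.** Before any splitting, each trial's MD to its own class
mean is computed and pooled over all trials; trials with
MD > mean(MD) + 3·SD(MD) are removed in one pass. The screen is a
three-sigma rule *on the MD distribution*: a threshold of 3·SD alone,
without the mean, would sit far below the typical MD in 20 dimensions
(within-class MDs concentrate near √k) and remove every trial, so it
cannot be the intended reading. With all MDs equal the SD is zero and
nothing is removed. Classes reduced below 2 trials raise an error.

**Cross-validation.** Accuracy (correct / total) is averaged over 100
independent seeded stratified 70/30 train/test splits. Outlier removal and
trial-order randomisation happen once up front. Two selection/
normalisation modes are provided:

* `per-fold` (default): BD selection and feature normalisation are
  recomputed inside every training fold — no test-set information leaks;
* `pre-split`: both are computed once on all trials before
  splitting, reproducing the published ordering of operations.

On chance data the two modes agree (the leak is small at these sample
sizes); both are reported so the comparison is explicit.

## Best-IC, ROI and band analyses

Every IC of a band-filtered dataset is scored by the full feature →
selection → classification chain. Candidates must reach 0.70 (RLI) or
0.59 (EFI; retried at 0.55 — five points above chance — if empty). The
best-performing IC is the highest-accuracy candidate whose topography
matches at least one ROI; if none matches, the result is flagged empty.

The ROI tallies count, per participant, the union of matched ROIs over
bands among best ICs whose accuracy exceeds the stricter screens
(> 77% RLI, > 67.5% EFI, applied to the mean CV accuracy): T1 is the
per-participant ROI count, T2 the per-ROI count across participants, and
ΣT1 = ΣT2 by construction. The band analysis assigns each participant to
the band of their maximum best-IC accuracy; ties are all reported, with
the headline count going to the first tied band in canonical order
(delta–theta, mu–beta, low gamma, high gamma) so tallies are reproducible
and auditable.

## Synthetic data generator

The generator emulates the statistical structure the pipeline consumes,
with full ground truth:

* the cue-paced protocol: marker quadruples at 0/2000/5000/8000 ms,
  four movement classes, 200 trials per movement per hand by default,
  500 Hz, 128 electrodes;
* cortical sources: band-limited Gaussian noise at ROI scalp positions,
  mixed to electrodes with isotropic Gaussian distance-decay gains
  g = exp(−d²/2λ²), λ = 2.5 cm; during S2–S3 a source's power is
  (1 + δ)× baseline for its configured classes. Source RMS defaults to
  10 µV — a typical sensorimotor-rhythm amplitude — which puts the
  nearest-electrode in-band signal-to-background ratio around 4:1, so a
  planted δ appears at the best electrode as a power ratio moderately
  diluted toward 1 (≈1.4 for δ = 0.5);
* background: per-channel 1/f (pink) noise at 10 µV RMS; common 50 Hz
  line interference with per-channel gain spread; Poisson frontal blinks
  (300 ms biphasic, 100 µV, rate 0.1/s); Poisson lateral EMG bursts
  (50–90 Hz, 500 ms, 25 µV, rate 0.05/s).

Everything is a pure function of the seed. The default source layout
mirrors the paradigm's findings: contralateral mu–beta lateralisation for
the hand contrast and a weaker prefrontal high-gamma extension/flexion
contrast.

**What it does not emulate** — and hence what passing tests do not show
about real data: realistic volume conduction (no boundary-element head
model, just distance decay), spatially correlated background EEG,
non-stationary rhythms (ERD/ERS dynamics beyond a power step),
inter-participant anatomical variability, eye-movement coupling to task
events, and force traces. Pipeline accuracies on synthetic data
demonstrate correct information flow, not expected real-data performance.

## Problem sizes and numerical choices

Tests and the acceptance script run at reduced problem sizes — tens of
trials per class, 16–32-channel montage subsets, 10–50 CV folds, ICA
fitted on ≤ 20,000 time points — chosen so the full suite runs on a
single CPU at desk scale; the structural 127-component check uses the
full 128-channel montage with a 52-trial set. The study-scale defaults
(200 trials per movement per hand, 128 channels, 100 folds) remain the
package defaults throughout.

Other numerical choices: rank detection by singular values above 1e-7 of
the largest; histogram bin membership is half-open [low, high) with the
maximum clipped into the top bin; z-normalisation guards zero-variance
features (std set to 1); argmin ties in classification go to the first
class in sorted label order; accuracy thresholds are compared with ≥ for
candidate selection and > for the ROI screens.

## Known limitations

* ROI matching is scalp-proximity only; deep or tangential sources can
  peak away from their anatomical projection.
* The Bhattacharyya estimator's histogram binning (32 bins) is a
  bias/variance compromise; very small trial counts per class make the
  BD ranking noisy.
* The per-class-covariance MD variant is unreliable without a
  log-determinant correction (see above) and is retained only for
  comparison.
* `pre-split` mode deliberately reproduces a selection-before-split
  ordering that leaks test information; use `per-fold` for unbiased
  estimates.
* The BrainVision-style reader supports only the package's own writer
  conventions (IEEE float32, multiplexed, µV) plus the marker subset it
  writes.
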