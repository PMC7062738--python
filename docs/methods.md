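# Methods

This note documents the models, numerical choices and limitations behind
`doceeg`. It describes what the code computes and why; every number it
mentions is produced by the test-suite or `scripts/acceptance.py`.

## Synthetic cohorts

The generator emulates a pre/post stimulation study in disorders of
consciousness. A cohort is a set of subjects split into responders (R+)
and non-responders (R−) by CRS-R change; each subject contributes
resting-state and auditory-oddball EEG before and after stimulation.

Signal model, per channel:

- **1/f background**: spectrally shaped Gaussian noise with exponent 1
  (default SD 5 μV), plus white sensor noise (1 μV).
- **Band components**: one jittered-phase sinusoid per band (δ 2.5, θ 6,
  α 10, β 20, γ 35 Hz; default amplitudes 4/2/2/1/0.5 μV, per-subject
  jitter SD 0.3 μV). A sinusoid of amplitude A contributes exactly A²/2
  μV² of band power, which is what makes the generator's planted power
  analytically known.
- **Coupling**: a shared 4–10 Hz narrowband latent added to a posterior
  set of carrier channels with per-channel lags (multiples of 40 ms).
  Lagging avoids identical ordinal patterns, so the coupling registers in
  wSMI rather than being weighted out as common-source.
- **Artifacts**: rectangular ≥150 μV transients at a per-second rate, and
  "noisy channels" carrying transients in most seconds — both exactly at
  the thresholds the rejection cascade tests.

R+ subjects' post sessions receive planted increments of theta/alpha
amplitude on the posterior third of channels, of coupling amplitude, and
of a sustained 300–600 ms P3-like task component on posterior channels
(an MMN-like biphasic deflection on frontal channels marks deviants in
all sessions). Two presets bracket the conditions: `null()` removes every
increment; `strong()` sets Δθ = Δα = 2.5 μV, Δcoupling = 4.5 μV,
ΔP3 = 4 μV. The coupling increment is deliberately larger because wSMI
estimates carry far more sampling noise than Welch band power at matched
recording length (see below).

All randomness derives from one integer seed through per-subject/session
substreams; identical specs reproduce cohorts bit for bit. The spatial
covariance of real patient EEG is not modeled (channels share only the
explicit latent); volume conduction, eye/muscle artifacts and
non-stationarity are likewise absent. Passing tests therefore show that
the estimators and statistics behave correctly on signals with known
structure — not that they are robust to everything clinical data does.

## Preprocessing

The cascade order is part of the contract: band-pass and notch filtering
(zero-phase Butterworth: high-pass order 6 at 0.5 Hz, low-pass order 8 at
45 Hz, 50/100 Hz notches at Q = 30; task data additionally low-passed at
20 Hz, order 8), epoching, then (a) channels with >150 μV peak-to-peak in
>50% of epochs, (b) channels with variance z > 4 across channels, twice,
(c) epochs with >150 μV peak-to-peak in >10% of retained channels,
(d) the z > 4 channel rule on 25 Hz high-passed data, twice. Epoch
windows are half-open `[start, end)` with 0-based indices; resting epochs
are 800 ms with 550–850 ms uniform jitter (default 100 placements,
averaged downstream; tests use 2–5), task epochs span [−800, +740) ms
around the fifth-tone onset and are baseline-corrected on [−800, 0).

Numerical notes: the variance z-score uses mean/SD across channels of
per-channel mean epoch variance (population SD); a single outlying
channel can only reach z > 4 when √(n−1) > 4, i.e. from 18 channels up —
at full scale (224 channels) the rule behaves as intended. Average
referencing uses retained channels only; rejected channels are rebuilt by
inverse-distance weighting over their retained adjacency neighbors (a
layout-agnostic, exactly testable choice; spherical splines would need a
real head geometry). The quality gate (≥75% channels, ≥30% epochs) flags
sets rather than raising, and failed sessions drop the subject from that
modality only.

## Markers

Welch spectra use 512 ms Hann segments with 400 ms overlap (128/100
samples at 250 Hz), density scaling; band power integrates bins over
half-open bands (γ includes its upper edge). At this resolution the bins
are 1.95 Hz wide, so θ and α each span two bins, and a line component
near a band edge leaks a bounded fraction (~13% for a 6 Hz line) into the
neighboring band; total 1–45 Hz power is conserved to numerical
precision. The calibration tests therefore check analytic power recovery
on a wide band (β) and on the total. Spectral quantiles (MSF, SEF90/95)
spread each bin's mass uniformly over its width, so a one-line spectrum
returns that bin's center. Spectral entropy is normalized by log of the
bin count; permutation entropy by log 6; wSMI by log 6 as well, so all
three live on comparable scales (the weighting makes small negative wSMI
values possible in principle; they do not occur for the diagnostic
cases tested).

Ordinal patterns use k = 3 with stable-sort rank ties (ties broken by
order of occurrence); τ must be an integer number of samples (32 ms at
250 Hz = 8 samples) and is rejected otherwise rather than rounded. τ = 64
ms and τ = 16 ms address the delta–theta and alpha–beta ranges under the
same pattern-frequency rule. The complexity proxy quantizes each trace to
32 equal-width amplitude levels and deflate-compresses the byte stream
(level 9); with a 32-symbol alphabet in 8-bit bytes the incompressible
ceiling is ≈0.65, so values are comparable within this implementation
only. The 80% trimmed mean drops the lowest and highest 10% of epochs per
channel; normalized band powers consequently sum to 1 exactly per epoch
but only approximately (±a few %) after trimming, since different epochs
are trimmed per band.

wSMI between two independent smooth (1/f) channels is positively biased:
the symbol distribution concentrates on the two monotone patterns, whose
pairings carry zero weight, leaving the estimate to rare-symbol cells.
This bias cancels in the within-subject post − pre contrasts the pipeline
uses, but single-pair comparisons need long recordings — the
planted-coupling test uses 60 s and a strong latent for that reason.

## Multivariate prediction

Features standardize (z-score) inside the CV pipeline before selection —
raw marker scales differ by orders of magnitude, and a margin classifier
would otherwise be dominated by raw delta power. Selection keeps
ceil(0.2 × 68) = 14 features by univariate F score, fitted on training
folds only; C is chosen from the deduplicated grid {1e-6 … 1e-1} by inner
stratified 5-fold search; probabilities come from sigmoid (Platt)
calibration with its own internal folds. The reference database defaults
to 75 VS / 68 MCS synthetic subjects whose MCS class carries higher
theta/alpha power and coupling; real patient-level probabilities are out
of reach without the original recordings, so all validation is
parameter-recovery-based.

## Decoding

Per train timepoint, features are the raw channel voltages at that
sample, standardized with training-fold statistics; the linear SVM's
decision values are scored as AUC at every test timepoint (rank formula),
averaged over 10 iterations of stratified 5-fold CV (tests and the
acceptance study use 2 iterations and a decimated time axis). Sustained
versus transient coding regimes are distinguished by the ratio of
off-diagonal to diagonal above-chance extent within a window.

## Cluster statistics

First-step statistics are two-sided at p < 0.05, with positive and
negative clusters formed separately; cluster mass is the summed statistic
and the null is the permutation distribution of the maximum absolute
cluster mass (10 000 label permutations by default; paired contrasts flip
condition signs within subject). p = (1 + #{null ≥ observed}) / (B + 1)
for sampled permutations; exact enumeration over all relabelings is used
when requested and feasible, in which case p is the exact proportion
including the identity. Mass comparisons carry a 1e-9 tolerance so exact
enumeration is stable to float roundoff.

Pair-space adjacency (the geometry for pairwise-connectivity clusters)
had to be defined here: pairs are neighbors when they share an electrode
and their non-shared electrodes are layout neighbors, or when disjoint
and a cross-assignment matches neighbors to neighbors. Channel × time
elements join consecutive samples within a channel and neighboring
channels at a sample; decoding matrices use the 4-neighborhood lattice.

The ART ANOVA aligns responses for each effect (stripping the cell-mean
contributions of the other effects), midranks the aligned values, and
runs a standard 2×2 mixed repeated-measures ANOVA on the ranks, keeping
only the aligned effect's row; degenerate all-tied alignments return
F = 0. Wilcoxon p-values are exact for n ≤ 25 without ties, otherwise
normal with continuity correction; the z reported for r = z/√N always
comes from the corrected normal approximation.

## Electric-field correlation

Voxels enter the analysis when their across-subject mean field magnitude
exceeds 0.5 V/m (1 V/m available as an alternative); in-mask Pearson
correlations against the per-subject prediction change are thresholded at
the analytic two-sided p = 0.01 critical r for the actual N (0.372 at
N = 47; a literal override is accepted for compatibility with earlier
reports that used 0.327). The shuffle test permutes subject outcomes and
**re-derives the signed masks on every permutation** before averaging r —
keeping the selection step inside the null, since selecting on the
observed data and testing only the selected voxels would be
anticonservative. Empty permuted masks score 0; an empty observed mask
skips that side with a log entry.

## Problem sizes and presets

Defaults mirror the study conditions (12 R+ / 48 R− subjects, 250 Hz,
100 resting placements, 10 000 permutations, 142-recording reference
database); the validation suite runs a desk-scale configuration chosen as
this package's own test geometry: 6 + 6 subjects, 16 channels, 40 s rest,
60 task trials, 2 resting placements, 300 permutations, ERP time axis
decimated ×4 and decoding ×8 with 2 CV iterations, 10 + 10 reference
subjects at separation 1.5. Full-scale (224-channel) layouts are
supported but not default.

## Known limitations

- Field maps are consumed as given arrays; no segmentation or
  current-flow modeling.
- Complexity values depend on the discretization/compressor pair and are
  not comparable across implementations.
- The generator's spatial covariance is minimal; cluster extents on real
  nets will differ from those on synthetic layouts.
- The classifier's absolute probabilities are meaningful only relative to
  its synthetic training population.
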