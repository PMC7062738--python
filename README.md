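# doceeg

Quantitative EEG analysis of consciousness and its response to
transcranial stimulation in disorders-of-consciousness (DoC) cohorts.

Patients surviving severe brain injury may remain in a vegetative state /
unresponsive wakefulness syndrome (VS/UWS) or a minimally conscious state
(MCS). Behavioral scoring with the Coma Recovery Scale-Revised (CRS-R,
0–23) defines these states and, in stimulation studies, the responder
label: **R+** if the CRS-R score increases after a stimulation session,
**R−** otherwise. `doceeg` implements the full electrophysiological side
of such a study — resting-state markers of conscious state, a multivariate
predictor of MCS-vs-VS, event-related responses to auditory novelty, and
the permutation statistics that tie them together — plus a synthetic-data
generator that emulates the responder/non-responder structure so every
component can be validated end to end on data with known ground truth.

## What it computes

**Resting-state markers** (per epoch × channel, summarized by the 80%
trimmed mean over epochs):

- raw and normalized band power in δ (1–4), θ (4–8), α (8–12), β (12–30)
  and γ (30–45 Hz), from Welch spectra (512 ms Hann segments, 400 ms
  overlap);
- spectral entropy (normalized Shannon entropy of the 1–45 Hz spectrum),
  median spectral frequency, 90th/95th spectral edge;
- Kolmogorov–Chaitin complexity proxied by the deflate-compressed size of
  the discretized signal;
- permutation entropy of k = 3 ordinal patterns at τ = 32 ms (theta–alpha
  sensitive), normalized to [0, 1];
- weighted symbolic mutual information (wSMI) at τ = 32 ms for every
  channel pair:

  wSMI(X,Y) = (1/log k!) Σ_{s,s'} w(s,s') p(s,s') log[ p(s,s') / p(s)p(s') ],

  with w = 0 for identical and sign-opposite pattern pairs (suppressing
  common-source coupling), reduced per channel by the median over its
  pairs ("degree").

**Multivariate prediction**: each of the 17 markers crossed with {trimmed
mean, SD} over epochs × {mean, SD} over channels gives 68 features; a
linear SVM with univariate-F selection of the top 20% (14 features),
C ∈ {1e-6 … 1e-1} chosen by nested stratified 5-fold CV, and Platt scaling
yields a calibrated P(MCS). The stimulation effect is ΔP(MCS) = post − pre.

**Oddball task**: trimmed-mean ERPs for standard vs deviant tones, the
double-difference contrast [(deviant − standard) post − pre], and
temporal-generalization decoding (a linear SVM per timepoint, tested at
all timepoints, AUC over 10 × stratified 5-fold CV) whose late square
pattern indexes sustained, P3b-like processing.

**Statistics**: two-step cluster-based permutation tests over all four
data geometries (channel topographies, channel pairs, channel × time,
train-time × test-time), with Welch t / Mann-Whitney z first steps
(dependent t / Wilcoxon for paired contrasts), max-mass null over
permuted group labels; Hedges' g and r = z/√N effect sizes with bootstrap
CIs; an aligned-rank-transform 2×2 mixed ANOVA; continuity-corrected χ²
for proportions; and a voxelwise electric-field correlation test that
masks voxels by mean field magnitude (> 0.5 V/m), thresholds Pearson r at
the analytic p = 0.01 cutoff, and tests each signed mask's mean r by
outcome shuffling with per-permutation mask re-derivation.

**Preprocessing** reproduces an automated artifact cascade: Butterworth
band-pass 0.5–45 Hz with 50/100 Hz notches (plus 20 Hz low-pass for task
data), 800 ms jittered resting epochs (100 placements averaged) or
[−800, +740] ms task epochs, 150 μV peak-to-peak channel/epoch rules,
repeated variance z > 4 channel rules, average reference, neighbor
interpolation, and a 75%-channels / 30%-epochs quality gate.

## Worked example

```python
from doceeg import CohortSpec, StudyConfig, run_study

spec = CohortSpec(n_rplus=6, n_rminus=6, n_channels=16,
                  rest_duration_s=40.0, n_task_trials=60, seed=0).strong()
cfg = StudyConfig(cohort=spec, seed=0, n_rest_iterations=2, n_perm=300,
                  erp_decim=4, decode_decim=8, decode_iterations=2,
                  reference_n_vs=10, reference_n_mcs=10,
                  reference_separation=1.5)
report = run_study(cfg)
print("theta cluster p:", report.marker_clusters["theta_norm"].min_p)
print("wSMI pair cluster p:", report.pair_cluster.min_p)
print("decoding cluster p:", report.decoding_cluster.min_p)
print("ART interaction p:", report.art["interaction"]["p"])
dp = report.delta_predictions
print("median ΔP(MCS) in R+:", dp[dp.response == "R+"]["delta"].median())
```

prints (seed 0):

```
theta cluster p: 0.0033222591362126247
wSMI pair cluster p: 0.013289036544850499
decoding cluster p: 0.006644518272425249
ART interaction p: 1.970152149741281e-07
median ΔP(MCS) in R+: 0.19542406376419919
```

The cohort plants post-session theta/alpha power, theta–alpha coupling
and a sustained P3-like component in the six R+ subjects only; the report
shows each effect recovered by its contrast family — significant clusters
over the planted posterior channels and pairs, a late above-chance
decoding cluster, and a positive prediction change confined to R+ (the
responder × stimulation interaction of the ART ANOVA).

A thin CLI wraps the same calls: `doceeg cohort --seed 1 --out DIR`
writes cohort metadata (optionally EDF recordings), and `doceeg run
--seed 1 --out report.json` runs the pipeline.

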