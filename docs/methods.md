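# Methods

## Analysis pipeline

### Epoch geometry and windows

Epochs are sampled at 200 Hz from −3700 ms to +3000 ms relative to the
imperative stimulus S2 (1341 samples, endpoints inclusive), with the
warning stimulus S1 at −3200 ms. Three windows drive everything
downstream: the baseline [−3700, −3200) ms, the cue-processing window
[−3200, −2700) ms (500 ms post-S1), and the response window [0, 500) ms
(post-S2). All windows are half-open in ms; a sample at time t belongs to
[a, b) iff a ≤ t < b, which makes the five 100-ms subwindows of a 500-ms
window an exact partition (window means are then averages of subwindow
means, a property the tests pin).

### Time–frequency phase

Complex Morlet wavelets are built with `mne.time_frequency.morlet`
(zero-mean correction on). The default is 5 cycles: at theta frequencies
this trades ~1 Hz spectral resolution against a ~0.2 s temporal envelope
SD, a standard compromise for event-related theta. The convolution itself
runs as one batched FFT over all channels × trials (same-mode centering);
a unit test pins the coefficients against `mne.time_frequency.
tfr_array_morlet` to ~1e−6 relative. Phase is the argument, amplitude the
modulus. Samples within half a wavelet's length of either epoch edge, or
with amplitude below 1e−10, are flagged in `PhaseTensor.valid_mask`.

A deliberate choice about the baseline: with a 5-cycle wavelet at 4 Hz the
half-support (~1 s) overlaps the baseline window, which starts at the
epoch's first sample. The baseline mean b̄ is therefore computed over all
baseline samples regardless of the edge mask — the epoch geometry leaves
no alternative, the zero-padding bias is common to both groups and
cancels in group contrasts, and the mask remains available for
diagnostics. Post-stimulus analysis windows sit far from both edges.

### PLV and rPLV

PLV is the modulus of the trial-mean unit phasor of the phase difference;
it is symmetric, bounded in [0, 1], and for ≤4 trials matches a direct
complex-sum oracle to 1e−12 (tested). The all-pairs path accumulates in
single precision (error ≪ across-trial sampling noise; a test ties it to
the double-precision single-pair route at 1e−5).

rPLV is computed per 1-Hz bin — (PLV − b̄)/b̄ with b̄ the bin's own
baseline mean — and then averaged across bins. Normalising per bin first
keeps each bin's baseline identity exact (the time-mean of rPLV over the
baseline window is 0 to float tolerance). Pairs with b̄ < 1e−6 in any bin
are flagged unusable and excluded with a warning, never divided through.

Left- and right-response conditions are processed separately (valid
trials only) and their rPLV averaged per subject before any group
statistic. The identical code path runs the alpha band (8–13 Hz) by
passing different frequencies.

### ROI networks

Six areas over 31 electrodes (DLPFC 6, SMA/PMA 5, M1 5, S1 5, PPC 5,
POC 5; 465 unordered pairs, within-area pair counts 15/10/10/10/10/10).
The area adjacency averages windowed rPLV over all within-area pairs
(diagonal) and all cross-area pairs (off-diagonal); self-pairs are
meaningless for PLV and excluded. The 21 unique entries are enumerated
row-major over the upper triangle including the diagonal — the order is
fixed so classifier feature indices are reproducible. The montage keeps
the labels PO1/PO2 (rather than the more common PO3/PO4) to match the
study montage it models; importers can relabel. Time-averaging precedes
pair-averaging (irrelevant for means, fixed for reproducibility).

### Graph metrics

Nodes are the 31 ROI electrodes; edge weights are windowed rPLV clipped
below at zero (shortest paths need nonnegative weights; a negative
event-related change is treated as no edge). Global efficiency is the
mean inverse shortest-path length over ordered pairs, disconnected pairs
contributing zero. Two modes are exposed: `binary` (hop counts on the
positive-weight skeleton — the convention of networkx's
`global_efficiency`, and the default) and `weighted` (Dijkstra under
distance 1/w; scales linearly with a global weight rescaling — tested).
Clustering is networkx's triangle fraction (binary) or geometric-mean
intensity (weighted). Both modes are kept because published analyses are
often ambiguous about which was run; the simulator's group effects come
out in the same direction in either.

### Multivariate group comparison

d(t) is the Euclidean norm of the difference of the group-mean 21-feature
vectors per sample (the 21 unique entries, not a redundant 36-entry
reshape, so off-diagonals are not double-weighted); within-group
dispersion is the variance across subjects of each subject's distance to
the group mean. PCA standardizes the concatenated group-average
timecourses with the pooled mean/SD (pooling across groups and time is
one concrete choice among the defensible ones; it is documented here
precisely because it affects score scales, not orderings), drops
zero-variance features with a warning, and reports per-group scores plus
eigenvectors reshaped to 6×6.

LDA classification: 100 folds; each fold holds out one random subject per
group (chance is then exactly 50%), z-scores the training set by its own
statistics, selects the 10 largest training-set ANOVA-F features (ties
broken toward the lower index), and fits a least-squares LDA with a 1e−6
shrinkage ridge for near-singular covariances. Per-fold accuracies lie in
{0, 0.5, 1}. The surrogate control permutes training labels within each
fold with the fold's derived RNG. Feature selection happens strictly
inside each fold — no statistic ever sees the held-out pair.

### Statistics

Pointwise increase maps: one-sample t-test across subjects of rPLV > 0
(one-sided, since the question is event-related *increase*), reported as
−log10(p); zero-variance cells get p = 1. These exploratory maps are
deliberately uncorrected; scalar group contrasts are FDR-adjusted.
Group contrasts use Mann-Whitney U (exact for small tie-free samples,
tie-corrected normal approximation otherwise); Z is reported without
continuity correction and the effect size is r = |Z|/√(n₁+n₂).
Benjamini–Hochberg adjustment comes from
`statsmodels.stats.multitest.multipletests`. Reaction times outside the
open interval (150, 1500) ms are excluded before RT statistics;
anticipatory responses are presses between S1 and S2. Efficiency–behavior
regressions are simple OLS, FDR-adjusted as one family across
group × window × outcome. The whole layer is deterministic.

## The synthetic cohort

### Generative model

Per trial: a carrier frequency f ~ U(4, 7) Hz and a random initial phase.
Each area's oscillator is the carrier plus von-Mises jitter (zero mean,
concentration κ(t)); each electrode adds its own von-Mises jitter around
its area's oscillator. The phase difference of two electrodes is thus a
sum of two (within-area) or four (between-area) independent jitter terms,
giving the built-in hierarchy of stronger within-area coupling, and its
expected PLV is monotone in κ — the property all recovery tests lean on.
Jitter is drawn independently per sample; the wavelet filter supplies the
temporal smoothing. Signals are cosines of these phases plus spectrally
shaped Gaussian noise (amplitude ∝ f^(−exponent/2), default exponent 1)
scaled to the configured oscillation-to-noise RMS ratio.

κ(t) equals `kappa_base` everywhere except the 500 ms after each
stimulus, where `kappa_event` is added; the "TS" group's post-S1
increment is reduced by the fraction `group_deficit_s1`, and each
subject's post-S2 increment is multiplied by a latent scale drawn from
`subject_scale_range`. Reaction times per trial are
`rt_intercept + rt_slope · scale + N(0, rt_sigma)`; trials are flagged
anticipatory with probability `anticipatory_rate` (no timed press) and
correct with probability `accuracy_rate`. Stimulus display duration is
not modelled as signal content — only the coupling windows matter.

All randomness descends from one root seed through per-subject spawned
streams; identical seeds give bit-identical cohorts.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| n_per_group | 20 | two-group cohort size the design models |
| n_trials_per_side | 50 | task block length per response side |
| fs / epoch | 200 Hz, (−3700, 3000) ms | epoch geometry above |
| kappa_base | 0.15 | weak resting coupling; baseline PLV near the small-sample noise floor |
| kappa_event | 1.0 | post-stimulus rPLV of ~0.2–0.5 and a non-saturated graph skeleton, the regime the analysis operates in |
| group_deficit_s1 | 0.5 | clearly detectable yet partial post-S1 deficit |
| snr | 0.7 | oscillation slightly below noise RMS, typical for single-trial theta |
| noise_exponent | 1.0 | 1/f background |
| subject_scale_range | (0.6, 1.4) | between-subject spread of post-S2 coupling |
| rt_intercept, rt_slope, rt_sigma | 430, −100, 120 ms | subject-mean RTs ~330 ms with realistic trial-level variability; R² of the RT–efficiency link lands near 0.3–0.6 |
| anticipatory_rate, accuracy_rate | 0.08, 0.92 | a few anticipatory presses and ~90% accuracy per subject |

The coupling and noise defaults were fixed once from the target operating
regime (baseline PLV, post-stimulus rPLV magnitude, graph density, and
detectability of the injected effects) and are not tuned per test.

### What the simulator does and does not emulate

It reproduces the statistical structure the pipeline consumes: epoch
geometry, event-locked pairwise theta coupling with an area hierarchy,
1/f noise, a group-level post-S1 deficit, and an RT–efficiency link. It
does **not** contain volume conduction (input is modelled as already
CSD-filtered), artifacts, eye blinks, EMG, evoked potentials, or raw
continuous EEG. Passing recovery tests therefore demonstrate that the
chain of estimators recovers known coupling structure from realistic
noise — not that any real-cohort finding is correct.

## Problem sizes used in testing

Monte-Carlo recovery checks run 20 replicate cohorts per condition at the
full 20 subjects per group but 10 trials per response side, with PLV
evaluated on the baseline and post-stimulus windows only; these sizes
keep the suite quick while leaving the injected effects comfortably
detectable (the post-S1 contrast rejects at p ≈ 1e−7 in typical effect
replicates). Coupling-monotonicity checks use single subjects with 200
trials (3-point κ sweep) and 50 trials (5-point sweep). The acceptance
script's surrogate-control computation uses 40 subjects and the full
100-fold protocol.

## Known limitations

- PLV is positively biased at small trial counts (E[PLV] = √π/(2√N) under
  independence); rPLV's baseline normalisation removes the common part of
  this bias but comparisons across very different trial counts remain
  delicate.
- The per-sample i.i.d. jitter model means the *effective* concentration
  after filtering differs from the nominal κ; only monotonicity, not the
  analytic κ→PLV map, is guaranteed or tested.
- Binary-mode global efficiency saturates at 1 when all windowed rPLVs
  are positive; the defaults deliberately avoid that regime, but strongly
  coupled configurations will hit it.
- The Mann-Whitney Z uses the tie-corrected normal approximation without
  continuity correction; for very small samples the reported p (exact)
  and Z (asymptotic) are consistent in direction but not identical in
  implied tail mass.
- The LDA protocol estimates separability, not a validated biomarker:
  with two held-out subjects per fold the fold accuracies are coarse and
  strongly correlated across folds.
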