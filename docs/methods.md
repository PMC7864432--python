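# Methods

`rseeg` implements a resting-state EEG biomarker analysis chain for
cognitive decline — spectral band power, the theta/alpha ratio, a
quantile-distance statistic between band-power distributions (PDDM),
inter-channel coherence, group statistics and a linear classifier —
together with a synthetic cohort generator that makes every stage
testable end to end without clinical data.

## Spectral estimation

Recordings (nominally 256 Hz, 20 channels in the 10-20 montage,
eyes-closed) are band-passed 1–49 Hz with a zero-phase Hamming-windowed
sinc FIR filter (transition width 1 Hz at both edges; kernel length from
the standard Hamming rule 3.3·fs/Δf, forced odd and applied as a centred
symmetric convolution, so no group delay). Channels with a flat-line run
longer than 5 s (samples equal within 1e-8 µV, a tolerance that survives
16-bit EDF quantisation) or whole-session correlation below 0.4 with an
inverse-distance-weighted average of their 4 nearest neighbours are
excluded, not interpolated. The neighbour-average predictor is a
documented simplification of the RANSAC-style reconstruction used by
common cleaning plugins; the thresholds are the conventional ones.

The PSD estimator is a modified periodogram: 1-s Kaiser windows
(shape β = 6), 256-point FFT, 1 Hz bins, segments advancing by half a
window. Each 1-s epoch is assigned the log10 of the mean of the linear
PSDs of the segment aligned with it and its two half-overlapping
neighbours; the first and last epochs average the two segments that
exist. The window normalisation U = Σw² is included (that is what
"modified periodogram" means); every downstream measure — relative PSD,
TAR, PDDM differences, coherence — is invariant to this constant, so the
choice only fixes the absolute scale of printed powers. Linear powers
below 1e-12 µV²/Hz are clamped before the log to keep degenerate epochs
finite.

Bands are Delta 1–3 Hz, Theta 3–7 Hz, Alpha 8–13 Hz on inclusive
integer-Hz bins; bin 3 belongs to both Delta and Theta and the 7–8 Hz
gap stands, because the bands are analysed independently. Band power is
the arithmetic mean of linear bin powers (log-transformed for storage);
relative PSD divides each bin by the 1–40 Hz total; the alpha peak is
the largest strict local maximum of the session-average PSD in 6–13 Hz
at 1 Hz resolution (no peak → missing value). TAR is the ratio of
epoch-mean linear theta power to epoch-mean linear alpha power
(ratio-of-means; a mean-of-ratios variant sits behind
`SpectralConfig.tar_mode` since the convention is genuinely ambiguous),
and "temporal" summaries average T3, T4, T5, T6.

## The quantile-distance statistic (PDDM)

For one channel, the per-epoch log10 band powers of band B form an
empirical distribution with CDF F_B. The power distribution difference
function between bands B1, B2 is the difference of their quantile
functions, PDDF(u) = F_B1⁻¹(u) − F_B2⁻¹(u) on u ∈ (0,1), and

PDDM_{c1,c2}(B1,B2) = ∫_{c1}^{c2} PDDF(u) du,

a raw integral (units log10-power × probability) — deliberately not
divided by (c2 − c1). PDDM95 uses [0.95, 1]: it compares only the top
5% of theta epochs against the top 5% of alpha epochs, which is why a
handful of abnormal epochs that vanish into a session mean still move
it. Quantile functions use the left-continuous generalized inverse
F⁻¹(u) = inf{p : F(p) ≥ u}, evaluated exactly from the order statistics;
the integral is computed in closed form over the order-statistic
segments (each sorted sample occupies a u-interval of width 1/n), so the
statistic is exact, antisymmetric and shift-equivariant to machine
precision. Histogram PDFs/CDFs (0.05 log10-unit bins) are kept for
reporting only — binning would add an avoidable approximation and no
canonical bin count exists. The [0.95, 1] window is a configuration
default, not a fitted quantity.

## Coherence

Sessions are cut into 20-s epochs at 50% overlap; per epoch, Welch
magnitude-squared coherence uses 2-s Kaiser (β = 6) windows at 50%
overlap, and epochs are averaged arithmetically. The native 0.5 Hz grid
is collapsed onto the shared integer 1–40 Hz axis by averaging the two
adjacent native bins (f − 0.5, f) → f. Normalised coherence subtracts
each pair's own 1–40 Hz mean (zero-mean per pair by construction), so
group maps show band-specific deviations rather than overall coupling
level. Pairs are long-range when their 2D head-plane distance exceeds
0.4 × the maximum inter-electrode distance (the fraction is
configurable; no canonical cutoff exists) and inter-hemispheric when
the members lie on opposite lateral sides — midline channels count as
intra for either side. Band-level coherence averages normalised values
over the band's bins.

## Group statistics

Welch's unequal-variance t-test with Satterthwaite degrees of freedom,
two-tailed, α = 0.05; effect sizes are Hedges' g (pooled SD,
small-sample correction J = 1 − 3/(4(n₁+n₂−2)−1)). Uncorrected flags are
primary, with Benjamini–Hochberg FDR flags reported alongside, applied
within a measure across its 20 channels (or pairs). Pearson correlations
with clinical scores carry Fisher-z 95% confidence intervals. Per-unit
comparisons with zero variance in both groups (possible for the
1-Hz-discrete alpha peak) are skipped by the pipeline rather than
reported as spurious infinities.

## Classification

Features are session-averaged relative PSDs at 30 locations
(20 channels + 10 lateralised regional averages, a region being the mean
of its member channels) × 51 frequency descriptors (40 integer bins +
11 named bands), i.e. 1530 features. PCA is fitted once on the two
groups being contrasted (unsupervised, so no label leakage) and the
smallest K components exceeding 98% cumulative explained variance are
kept; refitting PCA inside every bootstrap iteration is available behind
a flag but is not the default, trading a small bias for a stable,
interpretable basis. The classifier is a two-class LDA on the component
scores with equal priors and a ridge of 1e-6 × the mean covariance
diagonal for numerical safety.

Evaluation uses a random under-sampling bootstrap: each of 100
iterations draws minority-class-size subjects from the majority class
without replacement (every minority subject is in every iteration) and
scores the balanced set by leave-one-out cross-validation. Per-iteration
ROCs are averaged vertically on a fixed 101-point FPR grid; the reported
AUC is the area under the mean curve, and the apparent (train-on-all)
ROC is reported alongside as the overfitting reference. The final
classifier averages the per-iteration LDA coefficients; posterior
probabilities for new subjects go through the stored PCA basis and the
averaged coefficients, and a utility bins (MCI-probability,
AD-probability) pairs into quadrants split at 0.5 (Q2 both low, Q3 MCI
high only, Q4 both high, Q1 AD high only).

Two small-sample behaviours are worth knowing. Under the null,
leave-one-out posteriors are biased *against* the held-out subject's
class, so chance-level AUC sits slightly below 0.5 — a documented CV
artifact, strongest when subjects are few; calibration checks therefore
use cohorts of ≥ 16 per group. And with balanced classes the
under-sampling step is a no-op, so all bootstrap iterations coincide.

## The synthetic cohort generator

Each channel is a sum of frequency-domain-synthesised components
(amplitude shaping × random phases, inverse rFFT, unit-RMS normalised):

- **1/f^β background** (default β = 1.0, RMS 7 µV): six shared sources at
  fixed scalp anchors with distance-decaying gains (length scale 0.8 head
  radii) mixed against a private source; `spatial_mixing` ∈ [0,1]
  (default 0.5) sets the shared fraction of background power and thereby
  the coherence level.
- **Alpha oscillator**: one shared narrow-band source (Gaussian spectral
  bump, σ = 0.5 Hz) at `alpha_peak_hz`, scaled per channel by the
  montage's posterior-dominance weights × `alpha_amplitude` (default
  6 µV at a unit-weight channel).
- **Theta gains**: after background and alpha are summed, each channel's
  3–7 Hz content is split off with an FFT band mask and its linear power
  multiplied by `theta_sustained_gain` everywhere and additionally by
  `theta_burst_gain` on 1-s epochs drawn Bernoulli(`theta_burst_prob`),
  restricted to `burst_channel_mask`. Gains therefore act on the
  channel's *total* theta-band power, and bursts are aligned to the
  downstream epoch grid so "abnormal in 8% of epochs" means exactly
  that.
- **White sensor noise**, 1 µV.
- **Between-subject heterogeneity**: background, alpha and theta draw
  independent lognormal amplitude multipliers with CV 0.25
  (`subject_cv`). Real resting EEG amplitudes vary at least this much
  across individuals; without this term, session-mean measures have
  unrealistically tiny between-subject variance and any mean-based
  statistic looks spuriously sensitive.

Group recipes: healthy controls (alpha peak 9 Hz, no theta elevation);
an MCI-like group with conspicuous sparse bursts (probability 0.08 per
epoch, four-fold power, temporal channels only, alpha preserved); an
AD-like group with sustained 1.5× theta, alpha reduced to 5 µV and
slowed to 8 Hz. These defaults were chosen once to reproduce the
*qualitative* clinical picture (healthy temporal TAR near 0.9, AD-like
near 1.5, MCI-like in between and localised); no quantitative effect
sizes exist to copy, so simulated magnitudes are not comparable to any
particular clinical cohort.

What the generator does **not** emulate: ocular/EMG/cardiac artifacts
(only a flat-line injector for exercising channel screening),
non-stationary drowsiness drift, volume-conduction physics (mixing is
phenomenological), pathology beyond the theta/alpha axis, or eyes-open
activity. Passing tests therefore show that the *methods* behave as
specified on signals with realistic spectral and spatial structure — not
that clinical effect sizes will match.

## Validation experiments and problem sizes

The test suite and the reproduction script (`scripts/acceptance.py`) use
simulation scales chosen to make each check statistically meaningful:
biomarker cohorts of 25 subjects/group at 60-s sessions; the
tail-sensitivity study runs 100 replicate cohorts (burst probability
drawn uniformly in [0.05, 0.10]) on the four temporal channels, where
both summary biomarkers live; null calibration uses 250 independent
single-channel replicates (channels within a session share subject-level
amplitude draws, so multichannel sessions contribute ~1 effective test
each); classifier checks use 10–16 subjects/group at 30-s sessions.
Under these conditions the sparse-theta regime shows the intended
ordering — Hedges g of temporal PDDM95 exceeds that of temporal TAR in
~100% of replicates (mean g ≈ 0.75 vs ≈ 0.37) — and the Welch test
rejects at ≈ 5% under the null.

## Known limitations

- PDDM's inputs are log10 band powers; on other scales its
  shift-equivariance story changes.
- The alpha peak is resolved at 1 Hz; slowing smaller than a bin is
  invisible.
- The EDF writer is minimal (16-bit, 1-s records, fixed header date for
  reproducibility); it is not a general-purpose EDF+ implementation.
- Coherence bias: Welch magnitude-squared coherence has a positive bias
  floor of order 1/(number of averaged segments); normalised coherence
  removes the pair-mean component of it but absolute msc values near the
  floor should not be over-read.
- `pddm(d, d)` is exactly 0 and bootstrap evaluation is bit-reproducible
  for a given seed, but cross-platform bit-identity of the *generator*
  depends on the FFT implementation.
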