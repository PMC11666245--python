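# Methods

This note documents the models and procedures implemented in `ssveptag`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data suite does and does not show.

## Paradigm constants

Rates are stored as exact rationals so every period is an integer number of
samples at the 420 Hz analysis rate: image-update rate 30/7 ≈ 4.286 Hz
(98 samples per image), category rate 6/7 ≈ 0.857 Hz, category cycle
7/6 s = 490 samples, paired-epoch segment 7/3 s = 980 samples, hence a DFT
bin spacing of 3/7 ≈ 0.4286 Hz. A 14 s condition block holds 12 category
cycles; the first and last are the stimulus fade-in/out and are excluded
from analysis, leaving 10 analyzable epochs per block. On the 0.4286 Hz
grid, image bins sit at every 10th bin, category bins at every other even
bin, and noise bins at the odd bins.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes — not
infant EEG physiology. Each session is described by a `GroundTruthSpec`:

- **Category responses.** One waveform per category and cycle, a sum of
  Gaussian-windowed deflections (lobe width σ = 15% of the spacing to the
  nearest other peak, 60 ms for a lone peak). Faces: positive deflection at
  500 ms, negative at 900 ms, amplitude growing multiplicatively with
  log10(age); other categories: a single deflection near 500 ms (cars: a
  late positivity near 1000 ms). Each waveform is rescaled so its one-sided
  Fourier amplitude at 0.857 Hz equals the specified amplitude in µV — this
  makes amplitude-recovery tests exact rather than approximate. Default
  amplitudes are 0.6–1.2 µV, the order of magnitude of infant
  category-selective SSVEP responses.
- **Visual response.** One 233 ms cycle, two deflections (negativity then
  positivity) below 120 days of age and four at or above it, with the first
  two peak latencies linear in log10(age in days): lat₁ = 95 − 10·log10(age)
  ms and lat₂ = 182.8 − 35·log10(age) ms, chosen so latencies fall inside
  the study's analysis windows (60–90 ms; 90–160 ms young / 90–110 ms
  older) across 84–445 days. Amplitude defaults to 3 µV at the image
  fundamental.
- **Topographies.** Channel weight vectors with Gaussian falloff of planar
  distance to the nearest electrode of a focus set (occipital focus for the
  visual response, bilateral occipitotemporal for the category response),
  normalized to unit sum of squares. Falloff from the focus *set* rather
  than its centroid makes the small-spread limit concentrate equal weight on
  every focus electrode, which is the behavior the downstream tests rely
  on. The layout is the 128-channel geodesic net geometry bundled with mne,
  azimuthally projected to 2-D; only relative distances are used.
- **Noise.** 1/f^α power-spectrum noise (α = 1 by default) with random
  phases, scaled to a per-channel RMS (`noise_scale`, default 5 µV),
  independent across channels.
- **Artifacts.** Raised-cosine transients at `artifact_amplitude`
  (default 300 µV) on random channel subsets, scheduled as a Poisson process
  (default 2/min). The transient duration is 500 ms by default: the epoch
  rejection rule requires more than 15% of a 1167 ms epoch (≈175 ms) above
  threshold, which a 200 ms burst can never satisfy, so shorter transients
  would never exercise the rejection step at all.
- **Cohorts.** The default cross-sectional cohort has the study's group
  sizes — 17 (3–4 mo), 14 (4–6 mo), 15 (6–8 mo), 15 (12–15 mo), 61
  sessions — with ages evenly spread within groups; optionally 12
  participants receive a second session 90 days later. One master seed fans
  out to per-session seeds, and every session is bit-reproducible from its
  seed.

What the generator does **not** emulate: ocular/EMG spectra, non-stationary
noise, inter-sequence pauses when infants look away (sequences are
contiguous), electrode-position variability, or volume-conduction
correlations between channels (noise is channel-independent). Passing
recovery tests therefore demonstrate correctness of the *analysis*, not
robustness to every property of real infant EEG.

## Preprocessing

Fixed stage order: bandpass filter → resample → channel repair → common
average reference → epoch → channel-wise epoch rejection.

- The bandpass is realized as a zero-phase (forward–backward) Butterworth
  cascade: 2nd-order high-pass at 0.03 Hz and 8th-order low-pass at 50 Hz.
  Zero-phase filtering preserves the latency analyses. The low-pass order
  was chosen so that a 60 Hz component is attenuated by more than 20 dB
  after the forward–backward pass while the 4.286 Hz passband is flat to
  within 1%; a 4th-order design reaches only ≈14.5 dB at 60 Hz.
- Thresholds are exposed per profile. The infant profile uses the midpoints
  of the study's ranges: channel repair at 125 µV (range 100–150) on more
  than 20% of samples, epoch rejection at 175 µV (range 150–200) on more
  than 15% of samples. The adult profile uses 30 µV / 15% and 55 µV
  (range 30–80) / 10%. Both comparisons are strict ("more than"), applied to
  absolute voltage; peak-to-peak thresholding is not used.
- Channel repair replaces a flagged channel with the unweighted mean of its
  six nearest neighbors' original traces (planar Euclidean distance). More
  than half the channels flagged raises an error — the recording is
  unusable.
- Epoch rejection only edits the per-epoch-per-channel validity mask; data
  are never modified. Sessions with fewer than 20 valid epochs per category
  (configurable) are flagged and excluded by the pipeline.

## Spectral statistics

"Averaged over two consecutive epochs" is implemented as concatenating
consecutive valid-epoch pairs into 2.3334 s segments and averaging the
segments — the only reading consistent with a 0.4286 Hz resolution. A
trailing unpaired epoch is dropped. DFT amplitudes use the one-sided 2/N
convention (a unit-amplitude sinusoid at an exact bin reads 1.0), verified
by a Parseval identity; every contrast downstream is scale-invariant, so
the convention is free.

Hotelling's T² treats the per-participant (real, imaginary) coefficient at
one bin as a bivariate sample: T² = n·m̄ᵀS⁻¹m̄,
F = T²(n−2)/(2(n−1)) ~ F(2, n−2). The test input is the ROI-averaged
complex coefficient per participant (one complex sample each); the
alternative (per channel, then combined) is a known sensitivity-analysis
axis. A singular covariance (collinear coefficients) falls back to a ridge
of ε·trace(S)/2 on the diagonal and is flagged on the result. Type-I error
is verified by Monte-Carlo under circular Gaussian nulls at n ∈
{5, 14, 17, 20}.

Harmonic caps: the image response is quantified at the fundamental plus
three harmonics (4.286–17.143 Hz), the category response at the fundamental
plus first harmonic (0.857, 1.714 Hz), time-domain reconstruction keeps
category harmonics up to 30 Hz excluding image harmonics, and the noise
amplitude is the mean modulus over the first five (or ten) noise bins below
8.571 Hz. Missing channels/participants are dropped from a cell, never
imputed.

## Time-domain analysis

Band reconstruction zeroes all bins outside the selection, inverts the
DFT, splits the 2.3334 s segment into its two category cycles and averages
them. The category/image/noise reconstructions are exactly additive (their
sum equals the cycle-folded segment minus DC), and a category
reconstruction re-transformed has zero energy at image bins; both are
asserted in tests to 1e-9 relative.

The cluster permutation test computes per-point two-tailed one-sample
t-tests at α = 0.05, defines clusters as maximal runs of consecutive
significant points regardless of sign, and uses the permutation
distribution of the per-permutation maximum (and minimum) cluster mass
under participant-level sign flips (one flip per participant for the whole
waveform). A cluster is significant when its mass exceeds the 97.5th
percentile of the maxima or falls below the 2.5th percentile of the minima;
p-values use the (b+1)/(B+1) convention and are never exactly zero. The
sign-flip null is computed vectorized (second moments are flip-invariant,
so only the flipped mean is recomputed), which makes the full 10,000
permutation setting and the family-wise-error calibration cheap. No
baseline correction is applied before peak extraction — reconstructions are
zero-mean by construction.

Peak windows: first visual deflection 60–90 ms; second 90–160 ms below 120
days of age, else 90–110 ms; category peak 400–700 ms. Ties break to the
earliest sample.

## Decoding and distinctiveness

Patterns are concatenated in fixed (LOT, OCC, ROT) order. Correlation is
Pearson throughout. Winner-take-all ties (probability ~0 with continuous
data) deterministically take the lowest category index and are flagged; a
zero-variance test vector counts as a miss for every category. The
split-half RSM is *not* symmetric (odd and even halves differ), so the
between-category mean for distinctiveness uses the off-diagonal entries of
both the category's row and column (8 cells for 5 categories); a row-only
variant is available. Odd/even splitting is by within-condition epoch
order, the most literal reading of odd/even trials. Group accuracy is
tested one-tailed against the 20% chance level with FDR correction across
age groups by default (Bonferroni available — the two conventions appear
interchangeably in the literature for this test). A zero-variance accuracy
vector above chance is reported significant with p = 0 under a documented
degenerate rule.

## Developmental mixed models

All models are random-intercept LMMs on log10(age in days), fitted by REML
via statsmodels MixedLM, e.g.
`distinctiveness ~ 1 + log10(age) × category + (1 | participant)`.
Reported t-statistics are Wald tests with residual degrees of freedom
(n_obs − number of fixed-effect parameters), matching the t_(df) reporting
convention of the designs this package targets; Satterthwaite approximation
is not available in the backend and exact dof conventions are a known
source of small p-value differences. Categorical predictors use treatment
coding with a configurable reference level. When every participant
contributes one row the random intercept is unidentified and the fit
reduces explicitly to OLS; an all-zero response returns exact zero
estimates. Non-convergence is flagged on the result, never silently
replaced. Per-level post hoc fits apply Benjamini–Hochberg correction
across levels; levels with fewer than three participants are skipped and
logged.

## Problem sizes in the validation suite

The calibration and recovery suites use: 500 signal-free cohorts of 15
participants for the decoding chance level; 10,000 draws per sample size
for the T² type-I error; 1,000 outer simulations at 1,000 permutations for
the cluster-test family-wise error; six 2-sequence sessions at 0.25 µV
noise (per-channel SNR ≈ 14 at the category bin) for amplitude recovery;
and 200 simulated cohorts of the default longitudinal design for LMM slope
coverage. These sizes give sub-percent Monte-Carlo error on the quantities
checked while keeping the whole suite under a few minutes on one CPU.

## Known limitations

- The generator's noise is spatially independent; scalp EEG noise is
  correlated across channels, which would change (usually inflate) ROI
  averaging gains relative to the synthetic case.
- MixedLM residual-dof Wald inference is slightly anticonservative for
  small numbers of participants compared to Satterthwaite/Kenward–Roger.
- The EDF bridge imports continuous signals only; condition events must be
  supplied separately (the portable JSON sidecar format carries them).
- The cluster test assumes exchangeability under sign flips
  (symmetric-about-zero null), which holds for the evoked-response nulls it
  is used for here.
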