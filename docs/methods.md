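# Methods

`circatemp` analyses circadian rhythms in two telemonitored body-temperature
channels — chest-surface temperature from a wearable sensor ("chest") and
gastrointestinal core temperature from ingestible electronic pills ("core") —
together with concurrent minute accelerometry and per-subject covariates.
This note documents the models, the numerical choices, and what the
synthetic validation does and does not establish.

## Preprocessing

Raw streams are minute-resolution wall-clock time series. The fixed order is

```
mask/trim  →  stitch  →  5-min bin  →  { 1-h smooth → day profile }
                                       { hourly means (gap rules)  }
```

* **Sensor-off masking.** Chest readings strictly below 30 °C are treated as
  missing (a removed sensor reads room temperature). Comparisons are strict:
  a reading of exactly 30.0 °C is kept.
* **Pill transients.** Within the first 30 min after a pill ingestion, core
  readings above 38 °C or below 36 °C (a hot/cold drink swallowed with the
  pill) are removed; outside that window nothing is touched.
* **Pill stitching.** Pill-1 data are used strictly before the pill-1
  elimination time, pill-2 data at/after it. The elimination time is an
  input; a coverage hole between elimination and pill-2 start is flagged
  missing with a warning rather than interpolated.
* **5-min binning** averages non-missing minutes per bin; an empty bin stays
  missing.
* **1-h smoothing.** An even number of 5-min bins cannot be centered
  exactly, so the smoother is the symmetric 13-tap kernel with half weight
  at the ends (the mean of the two half-bin-offset 12-bin boxcars). This
  keeps the filter phase-neutral — an asymmetric 12-bin boxcar would shift
  every acrophase by 2.5 min. The kernel attenuates a 24-h harmonic by
  ≈ 0.997 and a 12-h harmonic by ≈ 0.989; this bias (< 1.2 % of amplitude,
  ~6 mK at typical amplitudes) is accepted as the price of noise reduction
  and is far below the recovery tolerances used in validation. When
  unbiased harmonic content matters more than smoothness,
  `preprocess_temperature(..., smooth=False)` skips the step; exactness
  checks of the cosinor stage use that path.
* **Day profile.** The smoothed 5-min series is averaged per clock bin over
  days into 288 bins anchored at clock noon (bin 0 = 12:00). After 5-min
  binning each day contributes at most one sample per bin, so
  equal-weight-per-day and pooled averaging coincide.
* **Hourly means.** Hours with any raw sample use the mean of what is
  available; fully missing hours are linearly interpolated between adjacent
  observed hourly means and flagged; a contiguous missing run longer than
  7 h drops every calendar 24-h segment (counted from the subject's first
  noon) that the run touches.

## Spectral analysis

The spectral density of the hourly series is evaluated on a fixed
480-point, log-spaced period grid on [2 h, 54 h]. Log spacing resolves the
short ultradian periods; the grid step near 24 h is ≈ 0.17 h. The point
estimate is a Lomb–Scargle periodogram evaluated directly at the grid
periods. A Fourier-grid (Welch) estimate was considered and rejected: at
the 72-h minimum record length the Fourier spacing near 24 h is several
hours, too coarse for the 24 ± 2 h / 12 ± 1 h classification windows,
whereas Lomb–Scargle evaluates at arbitrary periods and handles dropped
24-h segments naturally. Normalisation: white noise of variance σ² has
flat expected density σ²; a sinusoid of amplitude A adds a peak ≈ N·A²/4.

The 90 % confidence envelope is the pointwise 5th/95th percentile band over
block-bootstrap replicates with **day-aligned 24-h blocks** (whole days
resampled with replacement). Alignment matters: blocks starting at
arbitrary offsets carry random phases of the circadian harmonic, and the
incoherent phasor sum collapses genuine peaks in the replicates; day-aligned
blocks keep the 24-h and 12-h harmonics phase-coherent while still
scrambling the noise. The band is widened where needed so it always
contains the point estimate. The envelope is pointwise, not simultaneous.

Records shorter than three circadian cycles (72 retained hours) are
rejected — short pill records simply do not resolve the circadian band.

**Classification.** The dominant period is the grid period of largest
density (ties break toward the longer period). A peak counts as a genuine
rhythm only if it is significant — its lower envelope exceeds the median
density level (rule configurable). Significant peaks in 22–26 h classify
the record as 24-h dominant, in 11–13 h as 12-h dominant; an insignificant
peak anywhere, or a significant peak elsewhere, is non-circadian.

**Spectral gravity center.** SGC = Σₖ Tₖ I(Tₖ) / Σₖ I(Tₖ) over the whole
grid: the density-weighted mean period, a scalar locating spectral energy
between the ultradian and circadian ranges. It is invariant under positive
rescaling of the density and bounded by the grid extremes.

## Two-harmonic cosinor

With t in hours from clock noon and fixed periods T₁ = 12 h, T₂ = 24 h:

y(t) = M + a₁ sin(2πt/T₁) + b₁ cos(2πt/T₁) + a₂ sin(2πt/T₂) + b₂ cos(2πt/T₂) + e(t)

fitted by ordinary least squares to the non-missing profile bins (at least
5 bins spanning more than 12 h; a rank-deficient design is rejected).
Derived quantities:

* **Composite amplitude** A = (max ŷ − min ŷ)/2 over one 24-h cycle.
  Extrema are located on a 1-min grid and refined by bounded scalar
  optimisation of the analytic curve (tolerance 1e−10 h), so A is exact to
  well below measurement precision. Note A ≤ √(a₁²+b₁²) + √(a₂²+b₂²)
  always, with equality only when one harmonic vanishes — the 24-h and
  12-h troughs can never coincide, so the bound is strict whenever both
  amplitudes are nonzero.
* **Acrophases.** All strict local maxima of ŷ (one or two for a
  two-harmonic curve); maxima with prominence ≤ 1e−6 °C are discarded as
  numerical ghosts. When two acrophases exist (12-h-dominant subjects) the
  *reported* acrophase is the one in the clock window (20:00, 08:00] — the
  "evening" peak, which stays comparable to the ~03:00 acrophases of
  24-h-dominant subjects. The window is configurable; it is a judgement
  call, not a measured constant.
* **Bathyphase** — the global-minimum time, used for the core channel
  where the trough is the better-determined landmark.

**Bootstrap CIs.** Whole recording days (noon-anchored blocks of the 5-min
series) are resampled with replacement, preserving within-day
autocorrelation; profile and fit are recomputed per replicate. Intervals
are *expanded percentile* intervals: with n days, the bootstrap
distribution of a day-mean statistic is too narrow by √((n−1)/n) and the
normal quantile understates t₍ₙ₋₁₎, so the percentile level is widened to
α′ = Φ(−t₍ₙ₋₁,1−α/2₎·√(n/(n−1))) (≈ 1.8/98.2 % instead of 5/95 % at
n = 7). Plain percentiles are available via `expand=False`; measured
coverage of the plain interval at 7 days is ≈ 80 % against the nominal
90 %, which is why expansion is the default. Phase intervals are computed
on the circle around the point estimate.

## PCA of joint dynamics ("loops")

Each subject with both channels contributes a row
[M, a₁, b₁, a₂, b₂]_chest ⧺ [M, a₁, b₁, a₂, b₂]_core. Columns are
standardised (mean 0, sample sd with n−1) and the principal components are
the right singular vectors of the z-scored matrix. Signs are fixed
deterministically: the largest-magnitude element of each loading vector is
positive. Scores are the PC coordinates of the standardised rows;
back-transformation multiplies by column sds and adds column means.

Because ŷ(t) is linear in the parameters, any parameter vector defines a
closed planar curve {(chest ŷ(t), core ŷ(t)): t ∈ [0, 24 h]} — the "loop".
Single-PC loops use mean + score·(loading ∘ sds) on a 5-min grid (289
points, last = first so the curve closes exactly); at score 0 every PC
gives the cohort-mean loop, and a subject's full score vector reproduces
their own fitted loop.

## Activity HMM

Minute accelerometry is modelled as a homogeneous 3-state Gaussian HMM
(inactive IA, intermediate MA, high HA), fitted by Baum–Welch with random
restarts (best log-likelihood wins) and decoded retrospectively and
probabilistically via smoothed posteriors; the hard path is the per-minute
posterior mode (Viterbi is not used — the posterior mode matches the
probabilistic decoding contract). States are relabelled by ascending
emission mean, ties broken toward the more persistent state.

Emissions are Gaussian on the **raw count scale** by default. A log1p
option exists for heavily right-skewed real-world counts, but near-zero
rest counts make the log scale badly non-Gaussian: in testing, log-scale
EM split the rest state and merged MA/HA (decoding ~31 % vs > 99 % on the
raw scale). A time-of-day-modulated (harmonic) emission model is out of
scope; the interface accepts a future emission plug-in.

Missing minutes are excluded by splitting the record into contiguous
observed segments, each an independent chain in the likelihood — equivalent
to skipping them in the emission likelihood except that transitions across
gap boundaries are not counted.

**Activity strength** is the median raw activity over minutes decoded MA
or HA (intermediate-to-high activity); undefined (explicit `None`) when no
such minute exists.

## Covariate analysis

Phases are periodic, so before regression they are mapped to a line by
linearized = ((clock − 14) mod 24) − 10 — the unique linear map with unit
slope through the anchors 14:00 ↦ −10 and 10:00 ↦ +10. Clock times in
(10:00, 14:00) map beyond +10 and are flagged but included.

Each response (SGC; chest/core mesor, amplitude, linearized phase; PC
scores) is regressed by OLS on [1, sex, age, sex×age] with sex coded
0 = female / 1 = male; significance is the two-sided t-test per
coefficient. No multiple-testing correction is applied by default; a
Benjamini–Hochberg column is an explicitly marked opt-in extension.
p < 5 % is labelled significant, 5–10 % a trend. Spearman correlations
(tie-corrected) and Welch's unequal-variance t-test (Satterthwaite df,
one- or two-sided) back the correlation panel.

## Synthetic cohort generator

The generator defines the study conditions for validation:

* **Temperature signal**: mesor + 24-h and 12-h cosines (clock-hour peak
  phases) + stationary AR(1) noise at the native resolution (default
  sd 0.3 °C chest / 0.1 °C core, lag-1 correlation 0.8 at 1 min). AR(1) is
  the simplest autocorrelated model that makes the 1-h smoothing rule
  consequential.
* **Artifacts**: Poisson-count sensor-off events (default duration 30 min)
  replacing readings with room temperature 22 ± 1 °C so the < 30 °C rule
  fires; independent per-minute telemetry loss (default 4 %, the cohort's
  median missing rate); pill-ingestion transients — additive
  exponential-decay pulses whose floor offset is sized from the in-window
  readings so every affected sample clears the 36/38 °C band for the whole
  30-min window.
* **Activity**: 3-state Markov chain (persistent transitions, default
  means 5/100/180, sds 3/15/20 accelerations/min) with Gaussian emissions
  truncated at zero.
* **Cohort effects**: chest/core mesor and 24-h amplitude are linear in
  (sex, age, sex×age) with the study's regression coefficients as defaults
  (chest mesor −1.567/−0.022/+0.023 etc.) plus between-subject noise;
  intercepts are set so a 35-year-old female lands on the observed cohort
  medians (chest mesor ≈ 35.0 °C, core ≈ 37.0 °C, amplitudes ≈ 0.9/0.45 °C).
  Acrophases/bathyphases are drawn around the observed medians (03:08 chest
  acrophase, 03:30 core bathyphase). The within-subject variance
  decomposition is not reported anywhere, so those defaults are stated
  choices, not derived ones.
* All randomness flows from one seed through `SeedSequence` spawning;
  identical seeds give bit-identical outputs.

**What passing tests show — and don't.** The generator emulates harmonic
structure, autocorrelated noise, dropout artifacts and planted covariate
effects; it does not emulate transient fevers, exercise bouts, light or
feeding entrainment, daylight-saving shifts, or realistic packet loss.
Recovery and calibration results therefore validate the *pipeline
mechanics* under the stated noise model, not field performance on human
telemetry.

## Problem sizes used in validation

Recovery and calibration checks run at the study's own scales: 7-day chest
records (the cohort's median duration), 3-day core records, 33-subject
end-to-end cohorts, 50–200 subjects for error/coverage rates, 100 replicate
cohorts of n = 200 for covariate sign recovery, and 100–200 bootstrap or
envelope resamples.

## Known limitations

* The spectrum estimator and envelope are a documented substitute honouring
  the original interface (480-point grid, 90 % envelope); they are not a
  re-derivation of the cited spectrum-resampling algorithm.
* The 1-h smoother's amplitude attenuation (≤ 1.2 %) is uncorrected.
* Elimination of pill 1 is an input, not detected automatically.
* The homogeneous HMM ignores diurnal modulation of activity emissions.
* PCA variance shares depend on the cohort realisation; only the
  qualitative axis structure (chest-amplitude, joint-mesor, core-amplitude)
  is asserted.
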