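# Methods

## Scope and model

`tremorlab` implements a quantitative hand-tremor accelerometry pipeline for
a three-group occupational-neurotoxicity study design: manganese-exposed
welders with a manganism diagnosis (WELDER), de novo idiopathic Parkinson's
disease (IPD) and essential tremor (ET).  Each subject contributes four
recordings — rest and postural (arms extended) conditions on the right and
left hand — from a biaxial accelerometer.  The pipeline has four layers:

1. a generative model of tremor acceleration signals and whole cohorts,
2. the five classical spectral tremor parameters,
3. cohort statistics (summaries, fold changes, ANOVA, Fisher, regression),
4. a rule-based three-group classifier.

## Signal model

One acceleration axis is modelled as

    a(t) = A sin(2π φ(t)) + n(t),        dφ/dt = f0 + δ(t),

* `A` — amplitude of the harmonic core (m/s²); a pure sinusoid has band RMS
  A/√2 exactly.
* `f0` — center frequency (Hz), constrained to the 0.9–15 Hz analysis band.
* `δ(t)` — mean-reverting (Ornstein–Uhlenbeck) instantaneous-frequency
  wander, simulated with its exact AR(1) discretisation from a stationary
  start.  Stationary SD `freq_jitter_sd` (Hz) controls spectral-line
  broadening and hence frequency dispersion; the timescale default of 1 s is
  the simplest choice giving slow, unimodal broadening (the quasi-static
  regime, where the line shape is close to Gaussian with SD ≈ jitter SD).
* `n(t)` — Gaussian broadband noise brick-wall-limited to 0.9–15 Hz, scaled
  to an exact target RMS.  `harmonic_fraction` (hf) fixes the share of band
  power carried by the harmonic core, so the total band RMS equals the
  implied target intensity: noise power = (A²/2)(1−hf)/hf (plus an optional
  explicit noise floor).

Axes of a biaxial record are independent realisations of the same component
parameters.  Acquisition defaults are 128 Hz sampling (≥8× oversampling of
the band top) for 16 s; every draw flows from one `numpy` `SeedSequence`, so
a fixed seed reproduces signals and cohort tables bit-identically.

## Spectral metrics

Metrics are computed from a Welch power spectral density (Hann window, 4-s
segments, 50% overlap → 0.25 Hz grid on 16-s records), restricted to the
closed band [0.9, 15] Hz.  For two-axis records the per-axis densities are
averaged before any metric is taken.

The per-axis density is rescaled so its full-range integral equals the
record's sample variance exactly (a normalized power distribution).  With a
tapered window the raw Welch integral underweights segment-edge samples and
can deviate from the sample variance by several percent on 16-s records;
the rescaling removes that bias from intensity, and every other metric is a
power ratio, so normalization cancels.

* **Intensity** = sqrt(band-integrated density), m/s².
* **Center frequency (Cf)** = power-weighted mean frequency, Σ f·P(f)/Σ P(f).
* **Median frequency** = 50% point of the cumulative band power, taken as
  the midpoint of the linearly interpolated forward and backward crossings.
  The two-sided form matters for spectra whose mass splits evenly around a
  gap (two equal lines): the midpoint convention returns the central
  frequency instead of an endpoint of the ambiguous 50% plateau.
* **Frequency dispersion** = width of the narrowest window symmetric about
  the median frequency containing ≥ 68% of band power, grown over the grid
  (candidate half-widths are the distances of grid points from the median).
* **Energy distribution** = shares of band power in [3, 6.5] Hz and
  (6.5, 10] Hz.
* **Harmonic index (HI)** = share of band power within ±0.5 Hz of the modal
  (peak-density) frequency, ties broken toward the lower frequency.  This
  definition satisfies the two defining properties of the device metric — a
  single harmonic oscillation scores 1.00, and the index decreases when the
  tremor is composed of many oscillations — but the device's own formula is
  unpublished, so numeric HI values are not comparable to device output
  (see *Known limitations*).

Degenerate inputs (zero band power) raise `UndefinedMetricError`; records
shorter than one Welch segment are rejected with an explicit message.

## Group archetypes and cohort generation

The three built-in archetypes carry, per condition × side cell, published
group means and SEMs of intensity and Cf, group-mean dispersion and HI,
demographic distributions (age, age at onset, sex ratio, and for welders
exposure years) and clinical-sign Bernoulli rates.  Between-subject SDs are
recovered from SEMs as SEM·√n with the published group sizes (37/20/20).

Per-subject draws:

* **Intensity** — moment-matched lognormal.  The Table-derived SDs exceed
  the means for most intensity cells (coefficient of variation > 1), which
  no positive truncated normal can represent, and resampling a normal
  truncated at zero would inflate the cell mean by ~0.5 m/s²; the lognormal
  is always positive with the target mean and SD exact.
* **Cf** — normal truncated to the analysis band by resampling.
* **Within-subject structure** — the four cells share latent severity and
  frequency traits (equicorrelation 0.8, applied on the log scale for
  intensity).  Tremor severity and oscillator frequency are subject-level
  characteristics; the shared trait makes paired rest-vs-postural tests
  meaningful while preserving each cell's marginal mean and SD exactly.
* **Clinical signs** — independent Bernoulli per sign (no joint structure
  is published).  ET sign rates are fixed from the cohort definition
  (mono-symptomatic postural/kinetic tremor: tremor-related rates 1.0,
  parkinsonian and autonomic signs 0).
* **Demographics** — normal draws; onset is redrawn until it precedes age;
  exposure durations are folded to be non-negative.

Realized cell targets map to component parameters by
`hf = (HI − w/B)/(1 − w/B)` (w = 1 Hz HI window, B = 14.1 Hz band width;
a flat remainder contributes w/B to HI) and
`freq_jitter_sd = dispersion/2.2` (the 68% width of a near-Gaussian line is
≈ 2.2 SD once the broadband share is accounted for).

### What the generator does and does not emulate

It emulates: group-level means and spreads of intensity and Cf per
condition and side, postural intensification patterns, dispersion-scaled
line broadening, clinical-sign frequencies, and study-sized cohorts.  It
does **not** emulate: nonstationary tremor (bursts, re-emergent rest
tremor), amplitude–frequency coupling, harmonics of the fundamental,
measurement artifacts, medication state, or any joint distribution of
clinical signs.  Passing tests therefore show that the *pipeline* recovers
the population quantities it is pointed at, not that real tremor data would
behave this way.

## Statistics

* Summaries: mean ± SEM (sd/√n, ddof=1); n=1 yields SEM 0, flagged.
* Fold change: ratio of group means (postural/rest) — the published fold
  values are ratios of group means, not means of per-subject ratios — plus
  a paired t-test across subjects; identical paired samples return t=0,
  p=1 rather than the 0/0 form.
* Two-way ANOVA: ordinary fixed-effects position × side with interaction on
  the four observations per subject pooled across subjects (no
  repeated-measures structure is assumed); reported as percent of total sum
  of squares (eta-squared × 100) per factor, which sums to 100 with the
  residual.
* Fisher's exact test: two-sided by the standard point-probability
  criterion (sum of hypergeometric probabilities of all tables with point
  probability ≤ the observed one), computed with exact integer binomial
  numerators over a `Fraction` total so ties are decided exactly, never by
  floating comparison.  Odds ratios use the 0.5-per-cell substitute when a
  cell is zero (flagged); p-values never do.  No multiple-testing
  correction is applied anywhere — reports say so explicitly.
* Regression: OLS with the two-sided t-test of slope = 0; a constant
  response returns slope 0 / R² 0; a constant predictor is an error.

## Classifier

Three side-averaged features per subject: rest Cf, postural Cf, and the
postural/rest intensity ratio (mean of per-side ratios).  Decision tree:
ratio < 1.5 and postural Cf < 6.5 Hz → IPD; else rest Cf ≥ 6.5 Hz → WELDER;
else ET.  Thresholds sit in the gaps between the published group means and
are fully configurable; the side asymmetry of welder tremor is deliberately
not used.  Every classification records which branch fired, and the three
branches partition feature space.

On the archetype *means* the rule is exact (3/3).  On simulated cohorts it
is informative but far from perfect (accuracy ≈ 0.51–0.55 at 200
subjects/group): with between-subject SDs of ≈ 1.3–1.6 Hz around Cf means
separated by ≈ 0.5–1.5 Hz, the three groups overlap heavily, and no setting
of the three thresholds separates them well (a flexible classifier given
the same three features reaches only ≈ 0.68–0.83 depending on the assumed
within-subject trait correlation).  This is a property of the published
group statistics, not a defect of the rule's implementation, and it mirrors
the field's caution that tremor analysis supplements rather than replaces
clinical evaluation.

## Numerical choices

* Welch: Hann, `nperseg = 4 s × fs`, 50% overlap, per-segment mean removal,
  density scaling, then Parseval renormalization per axis.
* Band edges inclusive; the low/high energy sub-bands are [3, 6.5] and
  (6.5, 10] Hz on the grid.
* Median-frequency crossings interpolate linearly and tolerate floating
  plateaus at 0.5 (crossing searched from 0.5 − 1e-9).
* Modal-peak ties break toward the lower frequency.
* Truncated draws resample (cap 1000 iterations, then clip).
* Derived seeds flow through `SeedSequence.spawn`, keeping child streams
  independent and reproducible.

## Problem sizes used by the test-suite studies

Moment recovery and classifier evaluation use 200 subjects per group
(4 records × 2 axes each, 16 s at 128 Hz); the null-regression type-I study
uses 500 replicate cohorts of 200 subjects at the distribution level (no
signal rendering); the Fisher cross-check against the library
implementation enumerates every 2×2 table with N ≤ 30 exhaustively plus a
seeded random sample of 500 tables with 30 < N ≤ 60.

## Known limitations

* The device's harmonic-index formula is unpublished.  The windowed-power
  definition used here satisfies its two stated properties, but its numeric
  values on broadened spectra (≈ 0.4–0.7 on simulated cohorts) sit well
  below device-reported values (≈ 0.91–0.96); the published HI and
  dispersion values are in fact mutually inconsistent under any
  windowed-power definition (a line whose 68% width is 1.2 Hz cannot hold
  >≈ 0.65 of its power in a 1 Hz window).  HI targets therefore enter the
  simulator only through the harmonic band-power share.
* One published Cf SEM (welder postural-left, ±1.54) implies a
  between-subject SD of 9.4 Hz — physically impossible inside a 0.9–15 Hz
  band and 7× every other Cf SEM.  It is carried as printed; band
  truncation makes that one cell's Cf draw near-uniform.
* The source tables report group statistics only; per-subject covariance,
  missing-data patterns (per-sign denominators 29–32) and axis-level data
  are unpublished and are design choices here, as documented above.
* A contradiction in the source narrative (welders' rest Cf described once
  as lower and once as higher than ET's) is resolved by the group tables,
  which show welders higher; the classifier defaults follow the tables.
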