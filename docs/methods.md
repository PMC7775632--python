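# Methods

This note documents the generative model, the analysis conventions, the
numerical choices and the known limits of the `steadyfield` package.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Stimulus

`generate_click_train` places rectangular unit pulses of `click_duration`
(default 2 ms) at onsets 0, SOA, 2·SOA, … One click belongs to each full SOA
period, so `n_clicks = floor(train_duration / soa)` (20 with the defaults)
and the fundamental is `f0 = 1000/soa = 40 Hz`.  The periodogram of the
default train peaks at `f0` below 200 Hz, with harmonics of comparable
energy above — the spectral signature that lets the auditory system derive
periodicity either from `f0` or from the common divisor of the harmonics
(kept as the descriptive attribute `f_sp`).

## 2. Generative model of the epoched source data

Each subject contributes four epoched arrays (2 stimulated ears × 2
hemispheres), each `trials × vertices × time` at 1 kHz over −500…+1000 ms.
Per trial and vertex:

```
x(t) = gain · pol_v · [ g_A(v) · ASSR(t) + g_S(v) · SF(t) + g_T(v) · T(t) ] + n(t)
```

* **ASSR** — `a_A · sin(2π·40·t + φ_trial)` gated to 0–500 ms with 20 ms
  raised-cosine ramps; `φ_trial ~ von Mises(0, κ)`.  The von Mises family
  was chosen because its concentration κ maps monotonically onto ITPC
  (`I₁(κ)/I₀(κ)` in the noise-free limit), giving analytic recovery tests.
* **SF** — `a_S · L(t)` with `a_S < 0` (negative source current, the
  defining polarity of the sustained field) and `L` a logistic whose
  10–90 % rise spans `sf_rise_time` (100 ms), centered `rise/2` after
  `sf_onset_latency` (150 ms), held to stimulus offset and decaying
  exponentially (τ = 100 ms) afterwards.  A single differentiable
  parametric family keeps onset latency and plateau independently
  controllable.
* **Transients** — Gaussian deflections at 40 ms (σ 12 ms) and 82 ms
  (σ 16 ms), both positive: the child-typical P50m/P100m morphology (the
  adult N100m/P200m pattern is not modelled).
* **Noise** — spectrally shaped Gaussian noise with power ∝ 1/f^exponent
  (default exponent 1, per-sample SD 5 source units), independent across
  trials and vertices, scaled analytically (no data-dependent
  normalization).

**Spatial structure.** Vertices per hemisphere form an "ASSR" cluster
(fraction 0.4, `g_A = 1`), an "SF" cluster (fraction 0.4, `g_S = 1`) and
scattered background (`g = 0.2`); transient gain is the mean of the two.
Cluster centres use the canonical auditory-cortex geometry (MNI, mm): ASSR
at (−45.5, −28.5, 11.0)/(50.2, −25.3, 11.1) and SF shifted anterolaterally
to (−51.9, −20.5, 6.6)/(53.7, −17.2, 7.4); per-subject coordinates are
drawn around these centres (σ = 6 mm; background 3× wider), so
maxima-localization has recoverable ground truth and coordinate statistics
have between-subject variance.  A fraction `flip_fraction` (0.15) of
vertices is sign-inverted (`pol_v = −1`), with the hidden labels stored for
validation of the polarity-alignment stage.

**Condition and group structure.** Contralateral responses are scaled by
1.5, the right hemisphere by 1.2.  The ASD condition scales `a_S` by 0.85
bilaterally, adds 25 ms to the left-hemisphere SF onset, and shifts the
left SF cluster 5 mm medially.

**Between-subject variability.** Subjects draw a lognormal SF amplitude
factor (CV 0.3), a lognormal ASSR amplitude factor (CV 0.3) and a Gaussian
onset jitter (SD 20 ms), shared across ears and hemispheres; trials draw a
small SF amplitude factor (CV 0.1 — trial-to-trial SF variability is not
constrained by available evidence and is exposed as a free parameter).
These variability parameters are what make a standardized group effect size
finite.  The ASD-effect defaults were calibrated, by Monte Carlo on the
full measurement chain (simulation → rejection → averaging → alignment →
9 Hz filtering → interval means), so that the true standardized deficit of
the 151–250 ms left-hemisphere contralateral interval is ≈ 1.0 (measured
≈ 1.08; right hemisphere ≈ 0.37).  The calibration deliberately includes
the chain because the filter smears the rising front and the common ROI
dilutes the SF cluster with low-gain vertices, which attenuate the raw
generative effect by roughly a quarter.

**Determinism.** All randomness derives from `(seed, subject id, stream)`
via `SeedSequence`; identical parameters give bit-identical cohorts, and
subject-level latent draws are independent of which ear condition is
generated first.

**Psychometrics.** Scale scores (two IQ subscales + processing index;
three autism severity scales) are drawn per group from a 6×6 within-group
correlation structure (IQ block 0.7, severity block 0.55, cross −0.2 —
the severity-block value matching the 0.5–0.6 inter-questionnaire
correlations typical of such cohorts) with group means/SDs of a
representative pediatric sample (e.g. MPI 84.3 ± 22.0 ASD vs 121.2 ± 12.6
NT; SRS 104.8 ± 23.9 vs 45.2 ± 22.6).  A configurable fraction (default
6 %) of severity-scale entries is set missing.  With the 0.55 block
correlation the first principal component of the three severity scales
explains ≈ 0.70 of their variance.

## 3. Time–frequency analysis

A 200 ms window slides in 10 ms steps anchored at t = 0; windows whose
support would leave the epoch are dropped, not zero-padded (padding biases
phase coherence toward the edges).  The time–bandwidth product of the
requested ±4 Hz smoothing is 0.2 s × 4 Hz = 0.8, below the DPSS minimum, so
NW is clamped to 1 and `K = floor(2·NW − 1) = 1` taper is used; NW and K are
reported in the log.  Coefficients are computed per requested frequency
(default 36–44 Hz in 2 Hz steps) by direct projection onto tapered complex
exponentials; the per-trial coefficient is the taper average, and the
per-trial phase is the phase of that average (one defensible definition,
switchable in principle but not duplicated).

Zero-magnitude coefficients have no phase; they contribute a zero vector to
the ITPC mean and raise a warning.

**z-ITPC.** Raw ITPC is biased upward at small trial counts
(E[ITPC] ≈ √π/(2√N) under uniform phases — verified by Monte Carlo in the
suite), so groups differing in usable trials are not comparable on the raw
scale.  The default normalization therefore z-scores the trial-count
corrected Rayleigh statistic `Rz = N·ITPC²` — whose null expectation is 1
at every N — against its own baseline-window (−400…−100 ms) distribution;
plain z-scoring of raw ITPC is available as `z_mode="raw"`.  Zero baseline
variance marks the output NaN with a warning.

**Percent power change** uses the trial-averaged, taper-averaged squared
magnitudes against the per-frequency baseline mean; zero stimulation power
over positive baseline gives exactly −100 %.

Band–interval scalars average grid cells whose centers fall in the closed
band × interval (38–42 Hz × 200–500 ms by default).

## 4. ASSR pipeline

The common ROI is the 30 vertices with the highest pooled-sample metric
(both groups averaged together — pooling keeps selection orthogonal to the
group contrast); the individual ROI is each subject's own top 30.  Ties
break by (value desc, vertex id asc) for determinism.  Activation maxima at
or below ITPC 0.18 — the maximal baseline ITPC — are excluded from
coordinate analyses, boundary inclusive (0.18 is excluded, 0.18 + ε is
not).

Group comparisons use Mann–Whitney U between groups (medians reported) and
Wilcoxon matched pairs between hemispheres; age associations use Spearman
correlations with optional linear-age-trend residualization before
psychometric correlations.  Pointwise group tests run a two-sample rank
test at each of the 30 window centers in [200, 500) ms of each of the four
hemisphere × laterality series, with one Benjamini–Hochberg correction over
the pooled 30 × 4 family (q = 0.05).

## 5. SF pipeline

* **Jump rejection** — epochs whose 100 Hz high-passed (4th-order
  Butterworth, zero-phase) peak amplitude exceeds the across-epoch mean by
  3 SD are dropped and logged.
* **Averaging** — trial mean per vertex, baseline −200…0 ms (half-open:
  the onset sample belongs to the stimulus).
* **Polarity alignment** — the ROI grand average is the signed mean of the
  unflipped vertices; each vertex whose 0–500 ms product-moment correlation
  with it is negative is sign-flipped.  One pass, no re-iteration: the flip
  rule is a single correlation test per vertex, and iterating could
  oscillate on borderline vertices.  Zero-variance vertices stay unflipped
  with a warning.
* **Filtering** — windowed-sinc (Hamming) FIR, order 300, cutoff 9 Hz,
  applied forward and backward (`filtfilt`): zero net phase, squared
  magnitude response, > 100 dB suppression at 40 Hz.
* **Measures** — interval means over the closed windows 151–250, 251–350,
  351–450, 451–550 ms (the 1 ms-resolution partition of 151–550 without
  double-counted boundaries; the alternative 150-based boundaries would
  count 250, 350, 450 twice); `SF_max` is the most negative filtered value
  in 150–500 ms, sign retained.
* **Detectability** — whether a timecourse contains a genuine sustained
  negative deflection (traditionally judged by eye) is decided by an
  automated rule: mean over 200–500 ms negative and larger in magnitude
  than 2 baseline SDs of the filtered trace.  The
  screened sample is used only for coordinate analyses; amplitude analyses
  use the full sample (a flag can change this).

Group statistics: (a) group × ear × hemisphere rmANOVA on `SF_max`; (b)
group × hemisphere × time rmANOVA on the contralateral interval means with
Greenhouse–Geisser-adjusted p and partial eta-squared; (c) eight planned
two-sample comparisons (4 intervals × 2 hemispheres, contralateral) at
per-test alpha 0.05/8 = 0.006, with Cohen's d for the early left contrast;
(d) pointwise rank tests on the filtered timecourses over [0, 500) ms, one
FDR correction over the pooled 500 × 4 family at q = 0.01.  Coordinates of
SF maxima (largest mean |amplitude| in 200–500 ms) are compared per axis by
t tests and jointly by two-sample Hotelling T² with the exact F transform.

## 6. Statistical kernel

* Mann–Whitney U is the exceedance count of the first sample (midrank
  ties); two-sided p by exhaustive permutation enumeration when both groups
  have ≤ 8 observations (exact even under ties), else normal approximation
  with tie-corrected variance and 0.5 continuity correction.  A family in
  which every observation is tied yields p = 1 (no evidence), not NaN.
* Wilcoxon matched pairs drops zero differences, reports T (smaller
  signed-rank sum) and |Z|; exact 2ⁿ sign-flip enumeration at n ≤ 8.
* The mixed rmANOVA supports one between factor and arbitrarily many
  crossed within factors on balanced cell-means tables.  Sums of squares
  come from inclusion–exclusion over margin totals, which makes
  SS conservation exact; F ratios use the matching within-stratum error
  terms.  Greenhouse–Geisser ε is estimated per within effect from the
  covariance of orthonormalized contrasts pooled within groups (the mixed-
  design estimator; a whole-sample estimator would absorb group differences
  into apparent non-sphericity), clamped to [1/df, 1].  Huynh–Feldt is not
  implemented.  Effects whose error stratum has zero variance (possible
  only on degenerate constructed tables) report NaN rather than raising.
* Planned comparisons are pooled-variance two-sample t tests at the
  Bonferroni-adjusted alpha; Cohen's d uses the pooled SD.
* Partial correlation residualizes both variables on the control set by
  least squares; df = n − k − 2.  Collinear controls and zero residual
  variance raise/mark explicitly.
* Hotelling T² converts to F with (p, n₁+n₂−p−1) df; partial eta-squared is
  T²/(T² + n₁ + n₂ − 2); near-singular pooled covariance raises an error
  naming the most collinear axes.
* The Autism Score is the first principal component of the z-transformed
  severity scales, fitted on the ASD group only; missing entries are
  imputed with the subject's mean available z-score *after* the
  z-transform (imputing before would mix scales of different units); the
  loading sign is fixed so higher raw severity gives a higher score.

## 7. Orchestration

`run_pipeline` processes subjects one at a time and keeps only per-vertex
reductions (band scalars, band-averaged z series, trial averages), so a
full cohort never holds all raw epoch arrays simultaneously;
`simulate_cohort` also exists for in-memory use at small sizes, with
`iter_cohort_epochs` as the streaming variant.  One seed controls the run;
identical configurations produce byte-identical JSON summaries.  The
configuration round-trips losslessly through a flat-key YAML file, and
every analysis default above is the config default, so a bare run executes
the reference study design.  Stage failures abort with the stage name and
the offending subject/condition.

## 8. Problem sizes used in the test suite

The replicate-cohort properties run at reduced size — 35 + 35 subjects but
6 vertices per hemisphere, 10 trials, 5-vertex ROIs and −300…+700 ms
epochs — chosen so hundreds of replicate cohorts complete in a routine test
run while leaving every amplitude, latency, gain and variability default
untouched.  The type-I calibration runs 200 null-configuration cohorts
(group main effect within ±3 percentage points of 5 %; each planned
comparison within ±3 points of its 0.6 % level); the effect-recovery suite
runs 50 default cohorts (Bonferroni-significant early-left contrast in
≥ 90 %, mean recovered d within ±0.35 of 1.01) plus pointwise-FDR
localization on ten of them.  The κ-recovery sweep uses 5 concentration
levels × 20 single-subject replicates.

## 9. What passing tests do and do not show

The generator emulates the statistical structure the analyses assume —
phase-locked oscillation plus negative sustained current plus transients in
clustered sources with 1/f noise — not real MEG physics: no sensor array,
forward model, inverse-solution leakage, head movement, artifact topology
or heteroscedastic noise across cortex.  Passing recovery tests therefore
show that the chain measures what it claims on data whose ground truth is
known, and that its statistics are calibrated under the generator's null;
they do not show that real recordings satisfy the generator's assumptions.
ITPC laterality deserves a specific caveat: hemispheric gain differences
enter ITPC only through SNR, so the simulated right-hemisphere ITPC
advantage is much weaker than the amplitude advantage.  Localization claims
are only as sharp as the two-cluster geometry; adult response morphology is
out of scope.
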