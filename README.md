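# steadyfield

Analysis of two sustained neuromagnetic responses to 40 Hz click trains —
the **auditory steady-state response** (ASSR) and the **sustained field**
(SF) — in MEG source space, together with a ground-truth simulator of the
epoched source-current data such analyses consume.

## Who this is for

Auditory-neuroscience groups quantify the 40 Hz ASSR by inter-trial phase
coherence and the SF by polarity-aligned source-timecourse averaging, then
compare pediatric clinical groups (e.g. autistic vs neurotypical children)
with rank tests, pooled pointwise FDR and mixed repeated-measures ANOVA.
Those processing chains are long and full of conventions (baseline windows,
taper counts, flip rules, interval boundaries), and real recordings offer no
ground truth against which to validate them.  `steadyfield` implements the
complete chain as a tested library and pairs it with a generator whose every
effect — phase concentration, SF plateau and onset latency, hemispheric
gains, polarity-inverted vertices, 1/f noise — is a known parameter, so each
stage can be checked against the truth that produced its input.

## The model

**Stimulus.** A 500 ms train of 2 ms clicks at 25 ms onset asynchrony: 20
clicks, fundamental `f0 = 1000/25 = 40 Hz`, with the spectral energy below
200 Hz concentrated at `f0`.

**Generator.** Each trial of each source vertex is

```
x(t) = g · s_v · [ a_A κ-phase-jittered 40 Hz during 0–500 ms
                 + a_S · L(t; onset, rise) negative sustained plateau
                 + P50m/P100m Gaussian transients ]  +  1/f noise
```

where `L` is a logistic rise to a plateau held to stimulus offset, `g`
combines contralateral (×1.5) and right-hemisphere (×1.2) gains, `s_v` is a
per-vertex spatial gain concentrated in an "ASSR" and an anterolaterally
shifted "SF" cluster, and a minority of vertices carries inverted polarity.
The ASD condition attenuates the SF bilaterally (×0.85) and delays its onset
in the left hemisphere (+25 ms); with the default between-subject
variability this yields a true standardized deficit of ≈ 1.0 for the
151–250 ms left-hemisphere interval.

**ASSR analysis.** Sliding multitaper transform (200 ms window, 10 ms step,
±4 Hz smoothing → NW clamped to 1, a single DPSS taper), then per vertex

```
ITPC(f,t) = | mean_n  c_n(f,t) / |c_n(f,t)| |            (trials n)
z-ITPC    = baseline z-score of Rz = N·ITPC²             (−400…−100 ms)
%power    = (P − P̄_baseline) / P̄_baseline × 100
```

band-averaged over 38–42 Hz × 200–500 ms, in the 30 highest-ITPC vertices of
the pooled sample (common ROI) or per subject (individual ROI).  Activation
maxima with ITPC ≤ 0.18 (the maximal baseline value) are excluded from
coordinate analyses.

**SF analysis.** Epoch rejection (3 SD rule on the 100 Hz high-passed
peaks), trial averaging with a −200…0 ms baseline, single-pass polarity
flipping of ROI vertices anti-correlated (R < 0) with the ROI grand average
over 0–500 ms, zero-phase 9 Hz FIR low-pass (order 300, forward–backward),
interval means over 151–250 / 251–350 / 351–450 / 451–550 ms and `SF_max`
(most negative value in 150–500 ms).

**Statistics.** Mann–Whitney U / Wilcoxon matched pairs (exact enumeration
at n ≤ 8), Benjamini–Hochberg FDR over pooled pointwise families (500 × 4
SF samples, 30 × 4 ASSR window centers), mixed rmANOVA with
Greenhouse–Geisser correction built from sums of squares, eight Bonferroni
planned comparisons at per-test alpha 0.006 (= 0.05/8), Cohen's d, partial
eta-squared, Hotelling T² on source coordinates, Pearson/Spearman/partial
correlations, and a PCA "Autism Score" (first principal component of three
z-transformed severity scales, fitted on the ASD group, missing entries
imputed with the subject's mean available z-score).

## Worked example

A reduced simulated study (12 subjects per group, 20 trials, 30 vertices per
hemisphere, 15-vertex ROIs) runs in about half a minute:

```bash
python - <<'EOF'
from steadyfield import SimulationParams
from steadyfield.pipeline import PipelineConfig
cfg = PipelineConfig(
    simulation=SimulationParams(n_per_group=12, n_trials=20, n_vertices=30, seed=42),
    roi_size=15, seed=42)
cfg.to_yaml("demo.yaml")
EOF
steadyfield run-all --config demo.yaml --out demo_out
```

which prints

```
headline contrast: SF 151-250 ms, left hemisphere, contralateral, ASD vs NT: d=1.68, Bonferroni p=0.003684
report in demo_out
```

and writes the report tables.  The interval rmANOVA
(`demo_out/sf_anova_intervals.tsv`) for this run:

```
effect                      F        p          gg_epsilon  partial_eta_squared
group                       12.14    0.0021                 0.356
hemisphere                  266.79   8.7e-14    1           0.924
hemisphere x group          0.89     0.354      1           0.039
time                        137.60   2.4e-28    0.359       0.862
time x group                1.07     0.368      0.359       0.046
hemisphere x time           5.43     0.0021     0.593       0.198
hemisphere x time x group   26.60    2.1e-11    0.593       0.547
```

Reading the output: the simulated ASD group has a weaker SF overall (group
main effect), the right hemisphere carries a stronger SF than the left
(hemisphere effect, from the ×1.2 right gain), and the left-hemisphere onset
delay shows up as the hemisphere × time × group interaction and as the
large early-interval deficit in the headline planned comparison (d = 1.68
in this small cohort; the generator's true effect is ≈ 1.0 and small-sample
estimates scatter widely at n = 12).  At this cohort size the pooled
pointwise FDR at q = 0.01 flags no individual samples — single-timepoint
rank tests need the full 35-per-group design to reach the step-up
threshold.

`steadyfield simulate / tfr / assr / sf / stats` expose the individual
stages; `--null` zeroes every ASD effect for calibration runs, and
`--n-per-group` / `--seed` override the configuration.

## Layout

| module | contents |
| --- | --- |
| `steadyfield.simulate` | click train, transient kernels, subject/cohort simulator, psychometrics |
| `steadyfield.spectral` | DPSS tapers, sliding multitaper transform, ITPC / z-ITPC / power change |
| `steadyfield.assr` | ROI selection, activation maxima, ASSR group tests, pointwise FDR |
| `steadyfield.sf` | epoch rejection, averaging, polarity alignment, filtering, SF measures, SF group analyses |
| `steadyfield.stats` | rank tests, BH-FDR, Bonferroni, mixed rmANOVA + GG, correlations, Hotelling T², PCA score |
| `steadyfield.pipeline` | configuration, end-to-end orchestration, report writing |
| `steadyfield.io` | HDF5 epoch/TFR containers, TSV tables, JSON summaries |
| `steadyfield.cli` | `steadyfield` command-line entry points |

See `docs/methods.md` for the full account of the model, parameter defaults
and numerical choices.
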