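# Methods

## The extrema-points model

A beat-indexed haemodynamic parameter is treated as a discrete
sequence `x[0..n-1]` with irregular timestamps `t[0..n-1]` (one sample
per heart beat). An interior beat is a **local maximum** when it is
strictly larger than both neighbours and a **local minimum** when
strictly smaller; endpoints have one neighbour and never qualify.
Consecutive extrema — regardless of kind, so peak→trough and
trough→peak transitions both count — define

* the inter-extrema **interval** `τ_i = t[i+1] − t[i]` (s),
* the extrema **frequency** `F_i = 1/τ_i` (Hz),
* the extrema **amplitude** `a_i = |x[i+1] − x[i]|` (parameter units).

Frequencies are in true Hz because intervals use the recorded beat
timestamps, not beat counts. Amplitudes are reported as magnitudes;
the signed excursion is recoverable from the extrema kinds.

For a pure sinusoid of frequency `f` and amplitude `A`, adjacent
extrema are half a period apart and span peak to trough, so the
analysis must recover `F = 2f` and `a = 2A`. This analytic law is the
backbone of the validation suite.

### Tie handling and tolerances

Neighbour comparisons use exact floating-point inequality. A flat
plateau therefore yields no extremum, and quantised signals can
under-detect. `find_extrema(..., atol=...)` optionally requires a
point to clear both neighbours by an absolute margin, which suppresses
noise-scale wiggles; the default is `atol = 0` (exact strict
comparison) and every reported result uses it.

### Known distortions of the measured metrics

Two effects make metrics computed from beat-sampled data differ from
the dense-sampling ideal:

1. **Beat quantisation.** Extrema can only be observed at beat times,
   so intervals are sums of whole RR intervals. When the true extrema
   rate `2f` approaches the beat rate `1/RR`, the interval
   distribution collapses onto small integer multiples of `RR` and the
   *median* frequency is biased upward. At one beat per second the
   bias is negligible for `2f ≤ 0.4 Hz` (a few percent), ≈15% at
   `2f = 0.6 Hz`, and ≈20–25% at `2f = 0.8 Hz` — persisting at every
   physiological RR variability and with zero measurement noise. The
   achievable band is set by sampling theory, not by implementation.
2. **Additive noise** creates spurious extremum pairs wherever the
   underlying slope is shallow (near true turning points), adding
   short intervals (raising measured frequencies) and small
   amplitudes. Ensemble-median frequency is non-decreasing in the
   noise level. No smoothing is applied before detection — denoising
   would alter the very quantity being measured and is deliberately
   out of scope.

## Statistical layer

Each metric sample gets a normality verdict: Shapiro–Wilk at
`α = 0.05` for `n ≤ 5000`, the D'Agostino–Pearson omnibus test above
(Shapiro's p-value approximation degrades at very large n; the switch
point is conventional). Samples with `n < 3` or zero variance take the
nonparametric route. Both groups normal → independent two-sample
t-test (Welch form by default; pooled variance by flag). Otherwise →
two-sided Mann–Whitney U: exact by full enumeration of the
`C(n1+n2, n1)` group assignments when `n1 + n2 ≤ 10` (two-sided p is
twice the smaller tail probability, capped at 1 — well defined even
when ties make the permutation distribution asymmetric), normal
approximation with tie correction above. Correlations are two-tailed
Pearson (both variables normal) or Spearman. Quartiles use linear
interpolation of order statistics.

No multiple-testing correction is applied by default; an optional
Bonferroni / Benjamini–Hochberg adjustment exists
(`beatvar.stats.adjust_pvalues`). **Limitation:** consecutive extrema
pairs from one recording are serially dependent, but the comparison
treats them as independent observations. The reported p-values are
therefore anti-conservative with respect to within-recording
autocorrelation; they quantify the contrast under the model's own
convention, not a dependence-corrected inference.

## Synthetic recordings

The generator emulates beat-by-beat monitor exports:

* **Beat times**: RR intervals i.i.d. truncated-normal
  (`mean_rr`, `rr_sd`, hard floor 0.25 s ≙ 240 bpm ceiling);
  `rr_sd = 0` gives an exact grid. The profile guard
  `mean_rr > 3·rr_sd` keeps truncation marginal.
* **Pressures**: `SBP(t) = baseline + Σ sinusoids + N(0, σ)`, likewise
  DBP; a `map` oscillation is added to both, shifting MAP by exactly
  that component. Noise draws producing `SBP ≤ DBP` are redrawn
  (bounded retries; impossible configurations fail loudly).
* **Derived parameters**: `MAP = DBP + (SBP−DBP)/3` per beat;
  `HR = 60/RR`; `CO = SV·HR/1000`; `TPR = MAP/CO` by default. A
  profile with its own `tpr` oscillation/noise instead drives TPR
  independently around the baseline MAP/CO ratio — the mechanism used
  to emulate pressure/resistance dissociation.
* **Nyquist guard**: oscillation frequencies must stay below
  0.45 × mean beat rate; faster components cannot be carried by
  beat-sampled data.

Sinusoids were chosen precisely because they make the extrema ground
truth analytic. What the generator does **not** emulate: baroreflex
closed-loop dynamics, respiratory and very-low-frequency bands,
artefact beats, measurement drift, or intra-beat waveforms. Passing
tests therefore demonstrate that the pipeline measures oscillatory
structure correctly, not that real dialysis recordings contain that
structure.

### Bundled profiles and their defaults

| parameter | HD-like | NC-like (rest / stress) | why |
|---|---|---|---|
| mean RR | 0.8 s | 1.0 / 0.75 s | mild tachycardia in dialysis patients; exercise tachycardia under stress |
| RR SD | 0.04 s | 0.05 s | depressed vs normal resting heart-rate variability (SDNN scale) |
| SBP/DBP baseline | 121/75 mmHg | 118/78 mmHg | the two subjects' cuff pressures |
| MAP oscillation | 0.38 Hz, 2.5 mmHg | 0.20 / 0.23 Hz, 2.5 mmHg | designed contrast: pressure turns ~2× as often in HD; amplitude gives ~5 mmHg excursions |
| TPR oscillation | 0.42 Hz, 0.3 MU | 0.40 Hz, 1.5 MU | resistance response five-fold larger in the control |
| noise SD | 0.3 mmHg (pressures), 0.5 ml (SV), 5% of TPR amplitude | same | small relative to oscillation amplitudes |
| duration | rest 1500 s, stress 10800 s | rest 1800 s, stress 10800 s | 25/30 min rest recordings and a 3 h stress phase |

These defaults are plausibility choices at textbook physiological
scales, fixed once; they are not estimates of any particular subject.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use scaled problem
sizes chosen so each check is decisive yet quick: 1000 random
sequences (length 3–200) for oracle equivalence; 400 samples/cycle ×
10 cycles for the sinusoid law (the grid is commensurate with the
period, so discretisation error vanishes and the 1e-6 tolerance tests
pure arithmetic); 2000 null comparisons at n = 50 for type-I
calibration; 100 seeds × 30 min recordings for sinusoid recovery; and
100 seeds × 600 s recordings for the HD-vs-NC contrast (at that size
the designed contrast is detected with p < 0.0001 in every seed).

Recovery through beat sampling is asserted at ±15% of the analytic
`2f`/`2A` values for design frequencies up to 0.3 Hz at one beat per
second. The 0.4 Hz case sits in the quantisation-biased regime
described above (measured bias ≈20%) and the corresponding check
documents this as the method's sampling limit rather than a defect:
practitioners should treat extrema frequencies approaching the beat
rate as compressed toward it.

## Numerical and degenerate-input conventions

* CSV round trips are lossless: floats are written with shortest
  round-trip repr and parsed with correctly rounded conversion.
* Fewer than 3 beats → no extrema (warning, empty result); fewer than
  2 extrema → empty metric arrays; comparisons on such inputs are
  marked not-computable rather than failing the run.
* Invalid rows (SBP ≤ DBP, non-positive rates/volumes, NaN in a
  present column) are dropped with one diagnostic each; non-monotone
  beat times abort the read naming the first offending row.
* All simulation randomness flows through `numpy.random.default_rng`
  seeded per profile; identical profiles give byte-identical output
  files.
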