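# vicurve

Visual-curve indices and vision-related quality-of-life analysis for
presbyopia-correction outcomes.

## The problem

After presbyopia-correcting surgery (multifocal or extended-depth-of-focus
intraocular lenses), a patient's functional vision cannot be summarised by
visual acuity (VA) at one distance: everyday life mixes near, intermediate
and distance demands. The *visual curve* (ViC) plots VA — in Letters, on a
0–100 scale — against viewing distance, and the *Area of the Curve* (AoC)

AoC = ∫ₓₘᵢₙ^{xₘₐₓ} g(x) dx

(with g the polynomial fitted to the measured acuities) condenses the whole
curve into one scalar index of visual capacity. Splitting the integral at
50 cm gives a near-vision part (AoCN, distances ≤ 50 cm) and a
distance-vision part (AoCD, > 50 cm). The clinical question this package
operationalises: do these curve-based indices track patients' own
perception of their vision — NEI-VFQ-25 questionnaire scores — better than
single-point acuities do, and how few measured distances suffice?

The package is for biostatisticians and vision researchers who want the
full analysis as reusable, tested code: curve fitting, analytic AoC
computation, questionnaire scoring, the correlation/quartile statistical
battery, and a synthetic cohort generator so everything runs end to end
without access to patient data.

## What it computes

- **Curve fitting** (`vicurve.curves`): least-squares polynomial over
  distance in cm (a diopter axis x = 100/d is available), fitted on the
  standard distance subsets S4 = {25, 33, 66, 300}, S5 = {25, 33, 50,
  100, 300}, S6 = {25, 28, 33, 50, 100, 300} and all nine distances
  (25–300 cm). With ≤ 5 points the polynomial interpolates exactly;
  with more, the degree (3–6) is chosen by leave-one-out cross-validation
  under a one-standard-error parsimony rule with an overfit guard.
- **AoC indices**: total/near/distance areas by exact antiderivative
  (no quadrature), plus the conventional defocus-curve comparator (DCT):
  straight lines through all points, exact trapezoid areas.
- **NEI-VFQ-25 scoring** (`vicurve.scoring`): standard 0–100 linear
  recoding (bundled table), subscale means, composite = mean of the 11
  vision subscales; complete-case filtering.
- **Statistics** (`vicurve.stats`): Shapiro–Wilk-driven choice between
  Pearson and Spearman (with a 3×MAD outlier rule), Fisher-z confidence
  intervals, the full index×score correlation battery (17 rows),
  lowest-quartile versus remainder comparisons (t / Mann–Whitney /
  chi-square / Fisher), and the a-priori sample size for a correlation
  effect.
- **Synthetic cohorts** (`vicurve.simulate`): a two-factor latent model
  (near/distance ability) calibrated to printed anchor summaries
  (74.4 ± 7.74 Letters at 40 cm, 85.6 ± 4.01 at 300 cm) with QoL scores
  whose correlation with the true nine-point AoC is calibrated to a
  target (default 0.70).

## Worked example

```python
import vicurve as vc

params = vc.SimParams(n_patients=100, seed=42)   # synthetic 100-patient cohort
cohort = vc.simulate_cohort(params)
table  = vc.aoc_table(cohort.profiles())          # 15 AoC indices per patient
wide   = vc.aoc_wide(table)
va     = cohort.va.set_index(["patient_id", "distance_cm"])["va_letters"]
battery = vc.correlation_battery(
    wide, cohort.qol,
    va40=va.xs(40.0, level="distance_cm"),
    va300=va.xs(300.0, level="distance_cm"),
)
```

A few rows of the battery for this seed:

```
 index_name          score_name   method     r  ci_low  ci_high stars
   total_S9         total_score spearman 0.578   0.426    0.699   ***
  total_DCT         total_score spearman 0.614   0.471    0.726   ***
    near_S9     near_activities spearman 0.675   0.548    0.772   ***
    va_40cm     near_activities spearman 0.678   0.552    0.774   ***
distance_S9 distance_activities spearman 0.509   0.342    0.645   ***
   va_300cm distance_activities  pearson 0.566   0.416    0.686   ***
```

Each row pairs one visual-function index with one questionnaire score:
`r` is the correlation by the method the normality/outlier rules selected,
with its Fisher-z 95 % CI and significance stars (\*\*\* p < 0.001). The
nine-point AoC correlates with the total score at ~0.6–0.7 here because
the generator was calibrated to a population value of 0.70; single-cohort
values fluctuate. `vc.required_n(0.26, 0.05, 0.80, 2)` returns `114`, the
Fisher-z sample size for detecting r = 0.26 at α = 0.05 and 80 % power.

The same pipeline runs from the shell:

```bash
vicurve simulate --n 100 --seed 42 --out cohort/
vicurve analyze --va cohort/va_profiles.csv --qol cohort/qol_scores.csv --out report/
```

writing `aoc_indices.csv`, `correlations.csv`, `quartile_comparison.csv`,
`normality.csv` and a `manifest.json` recording the configuration, seed
and patient counts at every stage.

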