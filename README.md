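# ihiscale

Visual-scale assessment and population analysis of **incomplete hippocampal
inversion** (IHI, also known as hippocampal malrotation) — an atypical
anatomical pattern of the hippocampus (round, verticalized, medially
positioned body with a deep collateral sulcus) found in a substantial
fraction of healthy people, predominantly on the left.

The package is aimed at neuroimaging researchers who rate IHI on coronal
T1-weighted MRI and need the full downstream analysis to be reproducible:

* **grading** — the five-criterion ordinal scale (C1 roundness/verticality,
  C2 collateral sulcus, C3 medial positioning, C4 subiculum thickness,
  C5 fusiform-gyrus sulci), each grade on a 0.5 grid, plus geometric
  adapters for landmark measurements;
* **scoring & classification** — the composite IHI score
  `S = C1 + C2 + C3 + C4 + C5 ∈ [0, 10]`, and an accuracy-optimal
  threshold fitted against the global reference criterion C0
  (0 no / 1 partial / 2 total IHI): midpoint candidates between observed
  scores, `S > t` classified IHI;
* **reliability** — Cohen's κ (C0, C4, C5) and linearly weighted κ
  (C1–C3) with large-sample or bootstrap confidence intervals;
* **prevalence** — per-side C0 frequency tables with Wald/Wilson binomial
  CIs, left×right co-occurrence, χ² comparisons (side, sex, handedness),
  per-criterion grade distributions, threshold-based frequencies;
* **sulcal association** — pooled-variance Student's *t* and Cohen's *d*
  per (sulcus, measure, direction) over BrainVisa-style morphometry tables,
  Bonferroni-corrected over the fixed 45 × 5 × 4 = 900-test family;
* **simulation** — a calibrated synthetic cohort generator (latent-severity
  Gaussian copula over the published grade marginals) standing in for the
  access-restricted study data, so every stage is testable end to end.

See `docs/methods.md` for the model, calibration and numerical choices.

## Worked example

```python
from ihiscale import (GeneratorConfig, generate_assessments,
                      optimal_threshold, c0_frequency_table,
                      threshold_frequency_table)

cohort = generate_assessments(GeneratorConfig(n_subjects=2008), seed=42)
thr = optimal_threshold(cohort.ratings)
print("threshold:", thr)
print(c0_frequency_table(cohort.ratings, "left").round(3))
print(threshold_frequency_table(cohort.ratings, thr,
                                mode="classify_all").round(3))
```

prints

```
threshold: 3.75
             count     n  p_hat  ci_low  ci_high
category
no_ihi        1453  2008  0.724   0.704    0.743
partial_ihi    227  2008  0.113   0.099    0.127
total_ihi     328  2008  0.163   0.147    0.180
                count     n  p_hat  ci_low  ci_high
side  category
left  ihi         427  2008  0.213   0.195    0.231
      no_ihi     1581  2008  0.787   0.769    0.805
right ihi         198  2008  0.099   0.086    0.112
      no_ihi     1810  2008  0.901   0.888    0.914
```

The fitted threshold 3.75 separates scores 3.5 and 4.0: because the
generator (like the population it emulates) keeps total IHI at scores ≥ 4
and absent IHI at scores ≤ 3.5, classification by `score > 3.75` equals the
"score ≥ 4 is IHI" rule. The left C0 frequency table shows ~16% total IHI
with its 95% Wald CI; the threshold table shows the classify-all
frequencies per side (left ~21%, right ~10% at this seed), with the left
predominance the analysis is designed to quantify.

A command-line interface mirrors the library
(`ihiscale simulate | grade | threshold | reliability | prevalence |
associate | report`), with exit codes 0 success / 1 configuration /
2 data validation / 3 degenerate statistics.

```bash
ihiscale simulate --n 2008 --seed 42 --out-dir sim --sulcal
ihiscale report --config pipeline.yaml
```

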