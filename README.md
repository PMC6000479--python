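# acsnorms

Psychometrics and regression-based normative data for the **Amsterdam
Cognition Scan (ACS)**, an online self-administered neuropsychological test
battery (seven tests, twelve outcome measures including a battery composite).
The package is aimed at researchers who run the ACS — or a structurally
similar two-occasion cognitive battery — and need to turn raw score tables
into cleaned data, test-retest reliability summaries, and demographically
corrected norm scores.

## What it computes

Given a participant × occasion × measure table of raw scores and per-
participant demographics (age, gender, Verhage education level), the
pipeline:

1. **Cleans** — flags outliers on response-time measures with the median
   absolute deviation rule (median ± 3.5·MAD, per age group ≤40 / 41–59 /
   ≥60 and per occasion) and excludes raw zeros on count-based tests where
   a zero reflects a usability failure.
2. **Scales** — normalizes and direction-aligns each measure (1/x for
   completion times, −log₁₀ x, −√x, or identity), standardizes against the
   reference sample (mean 0, SD 1), and averages nine measures into the
   battery **total score** (complete cases only).
3. **Reliability** — per measure: paired *t* test for practice effects,
   intraclass correlation ICC(A,1) (two-way, absolute agreement, single
   measures) from the ANOVA mean squares, the standard error of
   measurement SEM = √MS_residual, the smallest detectable change
   SDC = 1.96·√2·SEM, and the group-level
   SDC_group = (SDC + |mean₁ − mean₂|·[practice effect]) / √n.
4. **Norms** — regresses standardized scores on centered age, age²,
   gender (0 = female) and education (0 = high), prunes nonsignificant
   predictors (p > .05) and refits; the frozen model then scores new
   individuals:

   ```
   z_pred = constant + Σ βⱼ·xⱼ          (age entered as age − 49.19)
   norm   = (z_actual − z_pred) / SD_residual
   ```

   so a norm score of −1.64 means performance 1.64 residual SDs below
   demographic expectation.
5. **Simulates** — generates two-occasion cohorts with the reference
   study's demographic mix, demographic effect sizes, practice shifts, and
   measurement-error structure (calibrated to target ICCs), so every stage
   is testable without participant data.

## Worked example

The packaged Connect the Dots I norm model (constant −.149, age β −.042,
gender β .401, residual SD .819, reference constants .0304/.00793) scores a
woman aged 55 who took 60 seconds:

```python
from acsnorms import Demographics, default_acs_norm_models, norm_score, predicted_score

model = default_acs_norm_models()["ConnectTheDotsI"]
woman = Demographics("w", age=55, gender=0)
print(round(predicted_score(model, woman), 2))   # -0.39
result = norm_score(model, 60.0, woman)
print(round(result.z_actual, 2))                 # -1.73
print(round(result.norm, 2))                     # -1.63
```

Her predicted standardized score is −0.39; her actual time standardizes to
(1/60 − .0304)/.00793 = −1.73; the norm score is the standardized
difference, ≈ −1.63 at full precision (−1.64 when the two-decimal
intermediates are chained as in the published example) — about 1.6 SD
below expectation for her age and gender.

The same machinery runs from the shell:

```bash
acsnorms simulate --n 250 --seed 5 --out-dir data
acsnorms clean --scores data/scores.csv --demographics data/demographics.csv
acsnorms reliability --scores scores_clean.csv
acsnorms fit-norms --scores scores_clean.csv --demographics data/demographics.csv
acsnorms score --models-dir models --input individual.csv --age 55 --gender 0
```

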