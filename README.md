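# actibed

Wrist actigraphy + sleep-diary analysis for community-dwelling older adults
(75+): from per-minute vector-magnitude accelerometer counts and bedtime
diaries to non-wear detection, windowed physical-activity and
sedentary-behaviour summaries, time-in-bed (TIB) categorization, and
multinomial relative-risk-ratio models of who usually, sometimes, or rarely
spends an age-appropriate 7–9 h in bed per night.

It is written for epidemiologists and movement scientists who work with
epoch-level ActiGraph-style data (60-s epochs, counts per minute in vector
magnitude) plus a wear-time diary, and who want the whole chain — cleaning
rules, cut-points, validity filters, exposure construction, and models — as
tested, scriptable code rather than point-and-click steps.

## The pipeline

1. **Non-wear detection** — runs of ≥ 30 min of continuous zero counts,
   allowing one spike below 100 counts per run, are non-wear.
2. **Diary masking** — each night's time in bed (bed time → next rise time)
   is masked; bed times between 24:00 and 05:00 belong to the previous
   night. TIB takes precedence over detected non-wear.
3. **Exposures** — wear epochs between 05:00–24:00 (max 19 h/day) are
   classified as sedentary (0–2302 cpm), mid (2303–4999) or high (≥ 5000)
   intensity. A day is valid with ≥ 10 h wear; a participant with ≥ 4 valid
   days. Person-level values pool epochs across valid days (total band
   minutes / total wear minutes); *highly sedentary* means ≥ 65 % of wear
   time sedentary (≈ 10 h/day at a typical 15.5-h wear day).
4. **TIB categories** — a night is in range when 7 h ≤ TIB ≤ 9 h; a
   participant is UTIB (≥ 80 % of diary nights in range), STIB (20–79 %) or
   RTIB (< 20 %).
5. **Models** — baseline-category (multinomial) logit of the TIB category
   with UTIB as reference. For outcome $j \in \{\text{STIB},\text{RTIB}\}$,

   $$\log \frac{P(Y=j \mid x)}{P(Y=\text{UTIB} \mid x)} = x^\top \beta_j,$$

   so $e^{\beta_{jk}}$ is the relative risk ratio (RRR) for predictor $k$.
   Model I adjusts for age, sex, average daily nap length and SPPB score
   and is used with tertile exposures (average CPM, % mid, % high; lowest
   tertile = reference). Model II additionally adjusts for % high intensity
   and is used with the binary highly-sedentary exposure. Wald 95 % CIs,
   likelihood-ratio exposure tests, predicted category probabilities
   (softmax at covariate means/modes) and probability contrasts with
   delta-method CIs are reported.
6. **Sensitivity** — the sedentary share computed after removing sleep by a
   fixed 23:00–08:00 window is compared with diary-based removal; in-bed
   minutes outside the fixed window get misclassified as (zero-count, hence
   sedentary) wear, inflating %SB.

Because person-level cohort data of this kind are not public, the package
ships a seeded synthetic cohort generator (`actibed.synthetic`) that
emulates the target population — 7-day recordings, nightly TIB near
8 h 21 min with realistic spread, ~64 % of wear time sedentary, ~13 % of
bedtimes after midnight, naps, shower gaps, and covariates correlated with
activity — so every stage is testable end to end.

## Worked example

```python
from actibed import CohortConfig, ModelSpec, fit_multinomial
from actibed.pipeline import build_analysis_table
from actibed.synthetic import generate_cohort

cohort = generate_cohort(CohortConfig(n_participants=341, seed=7))
table, excluded = build_analysis_table(cohort)
print(f"retained {len(table)} of {len(cohort)} participants")
print(table["tib_category"].value_counts().to_string())

results = fit_multinomial(table, ModelSpec(exposure="avg_cpm", model="I"))
print(results.summary())
print(results.probability_contrast("high", "low").round(3).to_string())
```

prints

```
retained 341 of 341 participants
tib_category
UTIB    152
STIB    116
RTIB     73

Multinomial logit of TIB category (reference: UTIB)
Exposure: avg_cpm   Covariates: Model I
n = 341, log-likelihood = -343.070
Exposure LR test: chi2(4) = 19.225, p = 0.0007

outcome            term   rrr ci_lower ci_upper p_value
   STIB  avg_cpm_middle 0.719    0.370    1.396  0.3298
   STIB    avg_cpm_high 0.571    0.282    1.154  0.1183
   ...
   RTIB  avg_cpm_middle 0.487    0.237    1.001  0.0502
   RTIB    avg_cpm_high 0.146    0.059    0.365  0.0000
   ...

      contrast     se  ci_lower  ci_upper
UTIB     0.250  0.075     0.103     0.397
STIB     0.011  0.074    -0.133     0.156
RTIB    -0.261  0.064    -0.386    -0.136
```

Read: in this simulated cohort the most active tertile has an RRR of 0.15
(95 % CI 0.06–0.37) for rarely achieving 7–9 h in bed, and being in the
highest rather than the lowest average-CPM tertile lowers the probability
of RTIB by 26 percentage points (CI 14–39).

The same chain is available from the shell:

```sh
actibed simulate --n 341 --seed 7 --out cohort/
actibed process --epochs cohort/epochs --diary cohort/diary.csv \
    --covars cohort/covariates.csv --out table.csv
actibed analyze --table table.csv --exposure avg_cpm --model I --out report.json
actibed sensitivity --epochs cohort/epochs --diary cohort/diary.csv --out sens.csv
actibed run --simulate 341 --seed 7 --out results/   # everything at once
```

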