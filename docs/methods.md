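# Methods

This note documents the conventions, parameters and design choices behind
`actibed`: what each stage computes, what the synthetic cohort generator
does and does not emulate, and where the design was genuinely open.

## Epochs, timestamps and diary conventions

Epochs are half-open minutes `[t, t + 60 s)`; an epoch belongs to a
calendar day, a diary interval, or the summarization window by its *start*
time, which avoids double counting at boundaries. Timestamps are naive
local clock times; no daylight-saving transitions are modelled. Missing
epochs are explicit (NaN in memory, empty field in the epoch CSV) — never
absent rows — and a gap in the minute grid is a format error naming the
first missing minute.

A diary *night* is identified by the date of the evening it starts. Bed
times with clock readings in [00:00, 05:00) are late bedtimes of the
previous night: a diary row dated `d` with bed time 00:30 produces the
night of `d − 1`. Rise times always fall on the morning after the night.
Diary clock times are assumed minute-precise.

## Non-wear detection

A non-wear run is ≥ `min_duration` (default 30) consecutive minutes of
zero counts, allowing at most `max_spikes` (default 1) epochs with a count
strictly below `spike_ceiling` (default 100) per run; a count at or above
the ceiling, or a missing epoch, always terminates a run. Choices the
verbal rule leaves open, fixed here:

* **Strict ceiling** — a count of exactly 100 breaks the run ("below 100").
* **Per-run spike budget** — one spike per run, not per 30-min window.
* **Spikes count toward duration** (the spike happens inside the period).
* **Zero endpoints** — a run starts and ends on a zero-count epoch; a spike
  cannot be the first or last epoch. Without this, overlapping qualifying
  windows have no unique resolution.
* **Greedy left-to-right maximality** — the earliest-starting qualifying
  run is taken at its maximal extent and the scan resumes after it, so
  reported intervals never overlap and detection is deterministic.
* **Edge runs qualify** — a long-enough run truncated by the start or end
  of the recording counts; wear status beyond the edge is unknowable.

Detection is verified against an independent brute-force enumeration on
randomized series. One caveat worth knowing: raising the spike ceiling is
*not* globally monotone. A former run-breaker can become a spike, merging
two runs into one whose per-run budget is exhausted earlier, shedding a
short tail (a frozen counterexample lives in the test suite). Lowering
`min_duration` only ever adds coverage.

### Composition with sleep masking

The canonical mask builder detects non-wear *within wear-candidate
segments*: diary TIB intervals break zero runs before detection, and TIB
labels take precedence over NONWEAR. This matters in one place — a short
still period adjacent to a sleep interval. With detection on the raw
series, any in-bed zeros merge with the night's run and the adjacent still
minutes are always non-wear; with boundary-broken detection, a sub-30-min
still period next to the sleep mask remains wear. The latter is what makes
the fixed-window sensitivity analysis meaningful (below): misclassified
in-bed minutes can actually land in the sedentary tally, which is the
mechanism the comparison exists to quantify.

## Exposures

Cut-points are wrist vector-magnitude values for older adults: sedentary
0–2302 cpm, mid 2303–4999, high ≥ 5000. The upper two bands describe
*relatively* higher intensity, not validated MVPA. Summaries use wear
epochs starting in 05:00–24:00 (19 h max); the night window is excluded
because counts there mostly reflect time in bed or restlessness. A day is
valid with ≥ 600 wear minutes — assessed inside the window, since the
window is the stated summation domain; a participant needs ≥ 4 valid days.

Person-level pooling divides total counts and total band minutes by total
wear minutes across valid days (equivalently, wear-minute-weighted means of
daily values); `pooling="mean_of_days"` gives the unweighted alternative.
Highly sedentary is pooled %SB ≥ 65 — evaluated on the percentage, not the
~10 h/day absolute equivalent it corresponds to at a median 15.4-h wear
day.

Tertiles use inclusive linear-interpolation quantiles at 1/3 and 2/3;
values equal to a cut go to the lower tertile, making assignment
deterministic and permutation-stable. Nights excluded for missing diary
data do not remove the day from exposure computation if the wear criterion
is met.

## TIB categorization

A night is in range when 420 ≤ TIB ≤ 540 minutes, both ends inclusive.
Category thresholds tile [0, 100] exactly: UTIB ≥ 80 %, STIB [20 %, 80 %),
RTIB < 20 % of diary nights — the printed "79" upper bound of STIB is
integer shorthand that would leave gaps for 7-night denominators. The
denominator is nights with a complete diary entry, not a fixed 7.

## Models

The three-category baseline-logit is estimated by Newton-type maximum
likelihood (statsmodels `MNLogit`; gradient tolerance 1e-8, ≤ 100
iterations). Wald CIs use standard errors from the observed information;
the per-exposure overall p-value is a likelihood-ratio test of the exposure
block (2 df per tertile pair per non-reference outcome). Sex is coded
female = 1 with male reference; tertile low and UTIB are references. Wald
rather than profile CIs is a deliberate convention. No multiple-testing
adjustment is applied to the RRR tables.

Predicted probabilities are softmax transforms of the linear predictors
with continuous covariates at cohort means and binary covariates at modes
(`categorical="mean"` switches to means). Their CIs, and those of
probability contrasts between exposure levels, use the delta method:
∂p_c/∂β_j = p_c (1{c=j} − p_j) x, with the full estimated parameter
covariance. On two-category degenerate data the model collapses exactly to
binary logistic regression, which the tests exploit as an independent
oracle for coefficients, standard errors and delta-method prediction SEs.

Small cohorts (n ≈ 50) with seven-predictor designs can genuinely separate;
the fit then raises a convergence error naming the design columns rather
than returning unstable estimates.

## Sensitivity analysis

The exposure pipeline runs twice with identical non-wear detection and
summarization, once masking diary TIB and once masking a fixed 23:00–08:00
window each night. Because the 05:00–24:00 summarization window already
excludes the night, the operative fixed exclusion is 05:00–08:00 plus
23:00–24:00. In-bed minutes outside the fixed window that are too short to
qualify as non-wear (< 30 min of zeros between the mask boundary and real
activity) are counted as sedentary wear under fixed-window removal,
inflating %SB; inflation is reported per participant and as the cohort
median (mean available). Long spills (≥ 30 min) are caught by non-wear
detection under either method and contribute nothing — so the synthetic
cohort's median inflation (~0.2 percentage points) is a qualitative
direction check, much smaller than in real data, where in-bed restlessness
counts keep zero runs short and push the misclassification higher.

## The synthetic cohort generator

The generator reproduces the statistical structure the analysis assumes,
at the epoch level, from a single integer seed (identical config + seed ⇒
bit-identical cohorts). Defaults describe the target population:

| parameter | default | meaning |
| --- | --- | --- |
| `n_participants` | 341 | cohort size |
| `n_days` | 7 | recording days (series spans `n_days` × 24 h) |
| `tib_mean` / `tib_sd` | 501 / 45 min | person-level nightly TIB centre and spread |
| `tib_irregularity` | 35 min | night-to-night TIB jitter |
| `bedtime_mean` / `bedtime_sd` | 23:15 / 40 min | bedtime centre and spread (≈ 13 % of nights start after midnight) |
| `nap_mean` | 43 min/day | expected diary nap length (12:00–16:00 window) |
| `band_mixture` | 0.64 / 0.23 / 0.13 | wear-time weights of the SB / mid / high count regimes |
| `nonwear_gap_rate` | 1 /day | shower-like daytime gaps (35–75 min of zeros) |
| `inbed_counts_zero` | true | device off in bed; optional restlessness noise |

Counts come from a three-regime mixture: SB epochs mix zeros with light
movement (gamma-tailed, clipped at 2302), the mid band is uniform on
2303–4999, the high band exponential above 5000. Two per-person latent
dimensions tilt the weights: a general activity trait (raises mid/high)
and a sedentariness dimension, anti-correlated with activity but with its
own noise (raises SB) — someone can be briefly vigorous yet otherwise very
sedentary. Person-level TIB is right-skewed via a long-sleeper tail whose
probability falls with activity, rises with sedentariness, and includes a
direct effect of being highly sedentary (SB weight ≥ 0.65). The direct
effect is needed structurally: with purely latent-mediated coupling, the
band shares are near-deterministic functions of the latents, and adjusting
for % high intensity (Model II) provably cancels any highly-sedentary
association along its level sets. SPPB is a monotone noisy function of the
activity trait (clipped to 0–12), age is 75 plus a gamma tail, and 62 % of
participants are female.

At defaults the simulated cohort lands near the population it emulates:
median nightly TIB ≈ 510 min, median %SB ≈ 64, median average CPM ≈ 2020,
≈ 14 % of bedtimes after midnight, TIB category shares ≈ 40/40/20, a
protective high-CPM tertile (RRR ≈ 0.3 for RTIB) and an adverse
highly-sedentary exposure (RRR ≈ 2–3 after Model II adjustment).

What it does **not** emulate: raw tri-axial waveforms, posture, device
noise, autocorrelated activity bouts, weekday/weekend structure, missing
diary entries, or seasonal/DST effects. Passing tests on this cohort show
the *pipeline arithmetic and model machinery* are right under the assumed
structure; they do not validate the cut-points or the behavioural model
against real recordings.

`generate_from_logit` operates at the analysis-table level: it draws
standardized exposure and covariates, computes the exact
baseline-category-logit probabilities for given true coefficients, and
draws each participant's category — the tool for parameter-recovery and
CI-coverage studies, where synthesizing epoch streams would add cost and
no information.

## Problem sizes and numerics

The default verification sizes are: 200 replicates of n = 2000 for
parameter recovery (all coefficients within 3 SE of truth in ≥ 95 % of
replicates), 500 replicates of n = 341 for 95 % Wald-CI coverage of the
exposure coefficients (observed ≈ 94–96 %), 300–1000 randomized series of
up to 2000 epochs for the non-wear oracle, and n = 50 for the end-to-end
byte-identical determinism check. Probabilities in JSON reports are
rounded to 6 decimals; tertile cuts use `numpy.quantile` linear
interpolation; the softmax subtracts the max linear predictor before
exponentiation.

## Known limitations

* The non-wear rule's spike allowance interpretation (per run) is an
  assumption; per-window readings give different results on long runs.
* Diary validity is taken at face value — no cross-checking of diary TIB
  against count patterns (by design: data-driven sleep detection is out of
  scope).
* The sensitivity comparison understates real-world inflation when in-bed
  counts are exactly zero (see above).
* Sleep efficiency is unobservable in this design; TIB includes wakeful
  lying.
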