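"""Seeded synthetic cohorts emulating 7-day wrist actigraphy in adults 75+.

Every downstream stage (non-wear detection, exposures, TIB categorization,
multinomial models) is exercised on cohorts from this module, because the
person-level study data these analyses were designed for are not publicly
available.  The generator reproduces the *statistical structure* the
analysis assumes, not raw acceleration:

* 7 nights of diary time in bed centred near 8 h 21 min with between-person
  and night-to-night spread; bed times late enough that about 13 % of
  nights begin after midnight;
* daytime counts drawn from a three-regime mixture (sedentary <= 2302 cpm,
  mid 2303–4999, high >= 5000) whose weights put roughly 64 % of wear time
  in sedentary behaviour, tilted per participant by two latent dimensions
  (general activity; sedentariness with its own idiosyncratic noise);
* naps (~43 min/day on average) placed in the 12:00–16:00 window;
* daily shower-like non-wear gaps of sustained zero counts;
* covariates (age >= 75, sex, SPPB 0–12) with SPPB a monotone noisy
  function of the activity trait.

Counts during time in bed default to zero (the device is off in bed by
protocol); optional low-level restlessness noise is available.

All randomness flows from a single integer seed: identical config and seed
give bit-identical cohorts.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .epoch_io import DiaryDay, EpochSeries

__all__ = [
    "CohortConfig",
    "Covariates",
    "Participant",
    "TrueBetas",
    "ConfigurationError",
    "generate_cohort",
    "generate_from_logit",
    "DEFAULT_TRUE_BETAS",
    "LOGIT_TERMS",
]


class ConfigurationError(ValueError):
    """A cohort configuration field is invalid; the message names it."""


@dataclass(frozen=True)
class Covariates:
    """Person-level covariates: age (years, >= 75), sex, SPPB total (0-12).

    The Short Physical Performance Battery (SPPB) scores standing balance,
    3-m gait speed and chair stands 0-4 each, summed to 0-12; higher is
    better lower-extremity function.
    """

    age: int
    sex: str
    sppb_total: int

    def __post_init__(self) -> None:
        if self.age < 75:
            raise ConfigurationError(f"age must be >= 75, got {self.age}")
        if self.sex not in ("female", "male"):
            raise ConfigurationError(f"sex must be female/male, got {self.sex!r}")
        if not 0 <= self.sppb_total <= 12:
            raise ConfigurationError(
                f"sppb_total must be in [0, 12], got {self.sppb_total}"
            )


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic cohort parameters.

    Defaults are calibrated to the population the pipeline targets:
    community-dwelling adults 75+, median nightly TIB ~8 h 21 min (501 min),
    ~64 % of wear time sedentary, naps ~43 min/day, about one non-wear gap
    per day.
    """

    n_participants: int = 341
    n_days: int = 7
    epoch_length: int = 60                      # seconds; fixed
    tib_mean: float = 501.0                     # minutes/night
    tib_sd: float = 45.0                        # between-person, minutes
    tib_irregularity: float = 35.0              # night-to-night, minutes
    bedtime_mean: dt.time = dt.time(23, 15)
    bedtime_sd: float = 40.0                    # minutes (person + night)
    nap_mean: float = 43.0                      # minutes/day
    activity_trait_sd: float = 1.0
    band_mixture: tuple[float, float, float] = (0.64, 0.23, 0.13)
    nonwear_gap_rate: float = 1.0               # events/day
    inbed_counts_zero: bool = True
    restlessness_rate: float = 0.05             # used when inbed counts not zero
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        if self.epoch_length != 60:
            raise ConfigurationError("epoch_length is fixed at 60 s")
        if self.tib_mean <= 0:
            raise ConfigurationError("tib_mean must be > 0")
        if self.tib_sd < 0 or self.tib_irregularity < 0:
            raise ConfigurationError("tib_sd/tib_irregularity must be >= 0")
        w = np.asarray(self.band_mixture, dtype=float)
        if w.size != 3 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                "band_mixture must be three non-negative weights summing to 1"
            )
        if self.nonwear_gap_rate < 0:
            raise ConfigurationError("nonwear_gap_rate must be >= 0")


class Participant(NamedTuple):
    series: EpochSeries
    diary: list[DiaryDay]
    covariates: Covariates


EPOCHS_PER_DAY = 1440
_START_DATE = dt.date(2013, 5, 6)  # arbitrary Monday; naive local time, no DST

# count regimes: SB epochs mix zeros with light movement; mid band uniform;
# high band exponential tail above the cut
_SB_ZERO_P = 0.25
_SB_GAMMA_SHAPE = 2.0
_SB_GAMMA_SCALE = 480.0
_HIGH_TAIL_MEAN = 800.0


def _participant_weights(
    base: np.ndarray, trait: float, sedentariness: float
) -> np.ndarray:
    """Tilt the band mixture by the two per-person latent dimensions.

    ``trait`` (general activity) raises the mid/high weights;
    ``sedentariness`` — only partially redundant with low activity — raises
    the sedentary weight, so the SB share carries information beyond the
    high-intensity share (as in real cohorts, where someone can be both
    briefly vigorous and otherwise very sedentary).
    """
    tilt = base * np.exp(
        np.array([0.45 * sedentariness, 0.35 * trait, 0.50 * trait])
    )
    return tilt / tilt.sum()


def _draw_wear_counts(rng: np.random.Generator, n: int, w: np.ndarray) -> np.ndarray:
    regime = rng.choice(3, size=n, p=w)
    counts = np.zeros(n)
    sb = regime == 0
    n_sb = int(sb.sum())
    if n_sb:
        vals = rng.gamma(_SB_GAMMA_SHAPE, _SB_GAMMA_SCALE, size=n_sb)
        vals = np.clip(np.round(vals), 1, 2302)
        vals[rng.random(n_sb) < _SB_ZERO_P] = 0
        counts[sb] = vals
    mid = regime == 1
    counts[mid] = rng.integers(2303, 5000, size=int(mid.sum()))
    high = regime == 2
    counts[high] = 5000 + np.round(
        rng.exponential(_HIGH_TAIL_MEAN, size=int(high.sum()))
    )
    return counts


def _simulate_participant(
    rng: np.random.Generator, pid: str, config: CohortConfig
) -> Participant:
    n_epochs = config.n_days * EPOCHS_PER_DAY
    start = pd.Timestamp.combine(_START_DATE, dt.time(0, 0))

    trait = rng.normal(0.0, config.activity_trait_sd)
    # sedentariness: anti-correlated with activity but with its own noise
    sed = -0.5 * trait + 0.87 * rng.normal(0.0, config.activity_trait_sd)
    w = _participant_weights(np.asarray(config.band_mixture, float), trait, sed)
    counts = _draw_wear_counts(rng, n_epochs, w)

    # --- covariates -------------------------------------------------------
    age = 75 + int(np.floor(rng.gamma(2.5, 2.6)))
    sex = "female" if rng.random() < 0.62 else "male"
    sppb = int(np.clip(np.round(10.0 + 1.1 * trait + rng.normal(0, 1.3)), 0, 12))
    cov = Covariates(age=age, sex=sex, sppb_total=sppb)

    # --- nights and naps --------------------------------------------------
    bed_base = (
        config.bedtime_mean.hour * 60 + config.bedtime_mean.minute
    )  # minutes from midnight of the night's date
    person_bed = rng.normal(0.0, config.bedtime_sd * 0.7)
    # person-level TIB: right-skewed (a long-sleeper tail, more likely for
    # less active participants) around a slightly sub-mean core, so the
    # cohort median sits near tib_mean while RTIB is populated
    # long-sleep propensity: lower for active people, higher for sedentary
    # ones, with a direct effect of being highly sedentary (SB weight >=
    # 0.65) so the association survives adjustment for the activity bands
    hs_latent = 1.0 if w[0] >= 0.65 else 0.0
    p_long = 1.0 / (1.0 + np.exp(1.4 + 0.3 * trait - 0.2 * sed - 1.1 * hs_latent))
    skew = rng.normal(-0.33, 0.9)
    if rng.random() < p_long:
        skew += 1.9
    person_tib = config.tib_mean + config.tib_sd * skew
    diary: list[DiaryDay] = []
    for d in range(config.n_days):
        night = _START_DATE + dt.timedelta(days=d)
        bed_offset = bed_base + person_bed + rng.normal(
            0.0, config.bedtime_sd * 0.7
        )
        tib = person_tib + rng.normal(0.0, config.tib_irregularity)
        tib = float(np.clip(tib, 240.0, 780.0))
        bed = pd.Timestamp.combine(night, dt.time(0, 0)) + pd.Timedelta(
            minutes=round(bed_offset)
        )
        rise = bed + pd.Timedelta(minutes=round(tib))
        naps: list[tuple[pd.Timestamp, pd.Timestamp]] = []
        if config.nap_mean > 0 and rng.random() < 0.70:
            length = rng.gamma(1.6, config.nap_mean / (0.70 * 1.6))
            length = int(np.clip(np.round(length), 5, 180))
            nap_start_min = 12 * 60 + int(rng.integers(0, max(1, 4 * 60 - length)))
            a = pd.Timestamp.combine(night, dt.time(0, 0)) + pd.Timedelta(
                minutes=nap_start_min
            )
            naps.append((a, a + pd.Timedelta(minutes=length)))
        diary.append(
            DiaryDay(date=night, bed_time=bed, rise_time=rise, naps=tuple(naps))
        )

    # --- overwrite in-bed epochs -----------------------------------------
    minute = pd.Timedelta(minutes=1)
    for day in diary:
        i = max(int(-((start - day.bed_time) // minute)), 0)
        j = min(int(-((start - day.rise_time) // minute)), n_epochs)
        if i >= j:
            continue
        if config.inbed_counts_zero:
            counts[i:j] = 0.0
        else:
            seg = np.zeros(j - i)
            restless = rng.random(j - i) < config.restlessness_rate
            seg[restless] = rng.integers(1, 90, size=int(restless.sum()))
            counts[i:j] = seg

    # epochs before the first diary rise are residual sleep from the
    # (unrecorded) night before the recording started
    first_bed_idx = max(int(-((start - diary[0].bed_time) // minute)), 0)
    presleep_end = int(
        np.clip(round(person_tib + bed_base - EPOCHS_PER_DAY + person_bed), 0, first_bed_idx)
    )
    counts[:presleep_end] = 0.0

    # --- shower-like non-wear gaps ---------------------------------------
    for d in range(config.n_days):
        for _ in range(rng.poisson(config.nonwear_gap_rate)):
            dur = int(rng.integers(35, 76))
            start_min = d * EPOCHS_PER_DAY + 6 * 60 + int(
                rng.integers(0, 16 * 60 - dur)
            )
            counts[start_min : start_min + dur] = 0.0

    series = EpochSeries(participant_id=pid, start=start, counts=counts)
    return Participant(series=series, diary=diary, covariates=cov)


def generate_cohort(config: CohortConfig = CohortConfig()) -> list[Participant]:
    """Generate a seeded cohort of (epoch series, diary, covariates) tuples."""
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_participants))
    return [
        _simulate_participant(rng, f"P{i + 1:0{width}d}", config)
        for i in range(config.n_participants)
    ]


# ---------------------------------------------------------------------------
# analysis-table generation from a known multinomial logit

LOGIT_TERMS = ("const", "exposure", "age_z", "sex_female", "nap_z", "sppb_z")


@dataclass(frozen=True)
class TrueBetas:
    """Baseline-category-logit coefficients for STIB and RTIB vs UTIB.

    Each mapping goes from term name (``LOGIT_TERMS``) to coefficient on
    the standardized design; omitted terms are zero.
    """

    stib: dict[str, float] = field(default_factory=dict)
    rtib: dict[str, float] = field(default_factory=dict)

    def as_matrix(self) -> np.ndarray:
        """Coefficients as a (n_terms, 2) array, columns (STIB, RTIB)."""
        unknown = (set(self.stib) | set(self.rtib)) - set(LOGIT_TERMS)
        if unknown:
            raise ConfigurationError(f"unknown logit terms {sorted(unknown)}")
        return np.column_stack(
            [
                [self.stib.get(t, 0.0) for t in LOGIT_TERMS],
                [self.rtib.get(t, 0.0) for t in LOGIT_TERMS],
            ]
        )


#: Effects used by default: exposure lowers the relative risk of RTIB
#: (strongly) and barely moves STIB; SPPB acts the same way; shares near
#: 38/39/23 % for UTIB/STIB/RTIB at covariate means.
DEFAULT_TRUE_BETAS = TrueBetas(
    stib={"const": 0.09, "exposure": -0.10, "age_z": 0.05,
          "sex_female": -0.05, "nap_z": -0.02, "sppb_z": -0.15},
    rtib={"const": -0.38, "exposure": -0.55, "age_z": 0.10,
          "sex_female": -0.10, "sppb_z": -0.35},
)


def generate_from_logit(
    true_betas: TrueBetas = DEFAULT_TRUE_BETAS,
    config: CohortConfig = CohortConfig(),
) -> pd.DataFrame:
    """Draw an analysis table whose TIB category follows a known logit.

    Exposure and standardized covariates are drawn i.i.d. standard normal
    (sex as a 62 %-female Bernoulli), the three category probabilities are
    the softmax of the linear predictors with UTIB as reference, and each
    participant's category is a single multinomial draw.  Returns a frame
    with the design columns, ``tib_category``, and the true per-category
    probabilities (``p_utib``/``p_stib``/``p_rtib``) for calibration
    checks.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    beta = true_betas.as_matrix()
    X = np.column_stack(
        [
            np.ones(n),
            rng.normal(size=n),                       # exposure
            rng.normal(size=n),                       # age_z
            (rng.random(n) < 0.62).astype(float),     # sex_female
            rng.normal(size=n),                       # nap_z
            rng.normal(size=n),                       # sppb_z
        ]
    )
    eta = np.column_stack([np.zeros(n), X @ beta])    # UTIB reference
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    assert np.allclose(p.sum(axis=1), 1.0), "category probabilities must normalize"
    u = rng.random(n)
    codes = (u[:, None] >= np.cumsum(p, axis=1)).sum(axis=1)
    categories = np.array(["UTIB", "STIB", "RTIB"])[codes]
    df = pd.DataFrame(X, columns=LOGIT_TERMS)
    df["tib_category"] = pd.Categorical(
        categories, categories=["UTIB", "STIB", "RTIB"]
    )
    df[["p_utib", "p_stib", "p_rtib"]] = p
    return df


def write_cohort(cohort: Sequence[Participant], out_dir) -> None:
    """Write a cohort to epoch/diary/covariate CSVs under ``out_dir``."""
    from pathlib import Path

    from . import epoch_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    epochs_dir = out / "epochs"
    epochs_dir.mkdir(exist_ok=True)
    diaries = {}
    rows = []
    for p in cohort:
        epoch_io.write_epochs(p.series, epochs_dir / f"{p.series.participant_id}.csv")
        diaries[p.series.participant_id] = p.diary
        rows.append(
            {
                "participant_id": p.series.participant_id,
                "age": p.covariates.age,
                "sex": p.covariates.sex,
                "sppb_total": p.covariates.sppb_total,
            }
        )
    epoch_io.write_diary(diaries, out / "diary.csv")
    epoch_io.write_covariates(pd.DataFrame(rows), out / "covariates.csv")
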