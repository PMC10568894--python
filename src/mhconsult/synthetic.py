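"""Synthetic consultation-level registry generator with known ground truth.

The national registry data behind this kind of surveillance analysis are
closed; this module generates consultation and population extracts with
the statistical structure the analysis pipeline assumes, so every
downstream statistic has a computable expected value.

Mechanism.  Each patient draws a gender, a birth year (uniform within an
age-group band) and a habitual consultation-timing profile: a gamma
multiplier with shape ``frailty_shape`` (mean 1) per ISO week-of-year,
persisting from one year to the next with probability ``persistence``
(otherwise redrawn).  Weekly consultations per diagnosis then arise from a
Poisson process with intensity

    profile x lambda0 x seasonal(w) x holiday_dip(w) x effect(year, w)

where seasonal(w) = 1 + amplitude x cos(2*pi*(w - phase)/52).  The shared
week-of-year profile is what makes one year's weekly totals predict the
next year's — the positive between-year correlation the forecast model
relies on — and its persistence decay makes that correlation fall with
the year gap.  Stronger heterogeneity (smaller shape) increases the
between-year correlation; with amplitude 0 and no heterogeneity the
correlation vanishes.

Symptom-code mixing: a fraction of depressive-disorder and anxiety
consultations carry the corresponding symptom code (P03 feeling depressed,
P01 feeling anxious) instead of the disorder code, so cohort inclusion and
the analysis-code filter are both exercised.  Multiplicative pandemic
shocks are injected per diagnosis and week window via ``effect_schedule``;
``registration_loss`` optionally drops a fraction of December consultations
in the final year, emulating late registration at the year boundary.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .registry_io import CONTACT_TYPES, write_consultations, write_population
from .weekly import iso_weeks_in_year

logger = logging.getLogger(__name__)

_EPOCH_ORDINAL = dt.date(1970, 1, 1).toordinal()

#: Realistic mix of the eight reimbursement contact categories.
CONTACT_WEIGHTS = (0.60, 0.05, 0.03, 0.02, 0.20, 0.05, 0.03, 0.02)

MAX_EXPECTED_CONSULTATIONS = 50_000_000


@dataclass(frozen=True)
class DiagnosisParams:
    """Weekly consultation process for one ICPC-2 diagnosis."""

    lambda0: float  # baseline weekly intensity per patient
    amplitude: float = 0.2  # seasonal amplitude, in [0, 1)
    phase: float = 2.0  # week-of-year of the seasonal peak
    symptom_code: str | None = None  # e.g. P03 for P76
    symptom_prob: float = 0.0  # fraction of consultations symptom-coded

    def __post_init__(self):
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if not 0 <= self.amplitude < 1:
            raise ValueError("amplitude must be in [0, 1)")
        if not 0 <= self.symptom_prob <= 1:
            raise ValueError("symptom_prob must be in [0, 1]")


def default_diagnoses() -> dict[str, DiagnosisParams]:
    """The five disorder processes, volumes ordered like real primary care:
    depression and anxiety dominate, eating disorders are rare."""
    return {
        "P76": DiagnosisParams(0.060, 0.20, 2.0, symptom_code="P03", symptom_prob=0.25),
        "P74": DiagnosisParams(0.050, 0.20, 2.0, symptom_code="P01", symptom_prob=0.25),
        "P79": DiagnosisParams(0.012, 0.15, 4.0),
        "P82": DiagnosisParams(0.012, 0.15, 6.0),
        "P86": DiagnosisParams(0.008, 0.15, 2.0),
    }


@dataclass(frozen=True)
class EffectWindow:
    """A multiplicative shock on one diagnosis over a week window."""

    diagnosis: str
    start: tuple[int, int]  # (iso_year, iso_week), inclusive
    end: tuple[int, int]
    multiplier: float

    def __post_init__(self):
        if self.multiplier <= 0:
            raise ValueError("effect multiplier must be positive")
        object.__setattr__(self, "start", tuple(self.start))
        object.__setattr__(self, "end", tuple(self.end))


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_patients: int = 20_000
    years: tuple[int, ...] = (2017, 2018, 2019, 2020, 2021)
    gender_split: float = 0.62  # fraction female
    age_group_weights: tuple[float, float, float] = (0.15, 0.35, 0.50)
    diagnoses: Mapping[str, DiagnosisParams] = field(default_factory=default_diagnoses)
    holiday_dip_weeks: tuple[int, ...] = (1, 13, 28, 29, 30, 31, 52)
    dip_factor: float = 0.55
    frailty_shape: float = 2.0
    persistence: float = 0.8
    effect_schedule: tuple[EffectWindow, ...] = ()
    registration_loss: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "years", tuple(self.years))
        object.__setattr__(self, "effect_schedule", tuple(self.effect_schedule))
        if not 0 <= self.gender_split <= 1:
            raise ValueError("gender_split must be in [0, 1]")
        w = self.age_group_weights
        if len(w) != 3 or any(x < 0 for x in w) or abs(sum(w) - 1) > 1e-9:
            raise ValueError("age_group_weights must be 3 non-negative fractions summing to 1")
        if self.frailty_shape <= 0:
            raise ValueError("frailty_shape must be positive")
        if not 0 <= self.persistence <= 1:
            raise ValueError("persistence must be in [0, 1]")
        if not 0 < self.dip_factor <= 1:
            raise ValueError("dip_factor must be in (0, 1]")
        if not 0 <= self.registration_loss < 1:
            raise ValueError("registration_loss must be in [0, 1)")
        expected = (
            self.n_patients
            * len(self.years)
            * 53
            * sum(p.lambda0 for p in self.diagnoses.values())
        )
        if expected > MAX_EXPECTED_CONSULTATIONS:
            raise ValueError(
                f"infeasible config: ~{expected:.0f} expected consultations"
            )

    def seasonal_profile(self, diagnosis: str, n_weeks: int = 53) -> np.ndarray:
        """Week-of-year intensity factor including holiday dips."""
        p = self.diagnoses[diagnosis]
        w = np.arange(1, n_weeks + 1)
        s = 1.0 + p.amplitude * np.cos(2 * np.pi * (w - p.phase) / 52.0)
        dip = np.isin(w, self.holiday_dip_weeks)
        return np.where(dip, s * self.dip_factor, s)

    def effect_multipliers(self, diagnosis: str, year: int, n_weeks: int) -> np.ndarray:
        mult = np.ones(n_weeks)
        for eff in self.effect_schedule:
            if eff.diagnosis != diagnosis:
                continue
            for i, w in enumerate(range(1, n_weeks + 1)):
                if eff.start <= (year, w) <= eff.end:
                    mult[i] *= eff.multiplier
        return mult


@dataclass(frozen=True)
class GroundTruth:
    """Expected values of everything downstream of the generator.

    ``expected_weekly[diag][(year, week)]`` is the expected number of
    disorder-coded consultations in that week across the full population
    (cohort filtering thins follow-year counts by the small probability
    that a patient has no inclusion-year consultation).
    ``theoretical_r[diag][gap]`` is the model-implied Pearson correlation
    between the weekly totals of two pre-effect years ``gap`` years apart.
    """

    expected_weekly: Mapping[str, Mapping[tuple[int, int], float]]
    effect_schedule: tuple[EffectWindow, ...]
    theoretical_r: Mapping[str, Mapping[int, float]]
    config: SyntheticConfig

    def constant_multiplier(self, diagnosis: str, window: Sequence[tuple[int, int]]) -> float:
        """The injected multiplier over a window, which must be constant."""
        values = set()
        for year, week in window:
            m = 1.0
            for eff in self.effect_schedule:
                if eff.diagnosis == diagnosis and eff.start <= (year, week) <= eff.end:
                    m *= eff.multiplier
            values.add(round(m, 12))
        if len(values) != 1:
            raise ValueError(f"multiplier not constant over window: {sorted(values)}")
        return values.pop()

    def to_json(self) -> dict:
        return {
            "expected_weekly": {
                d: {f"{y}-W{w:02d}": v for (y, w), v in weekly.items()}
                for d, weekly in self.expected_weekly.items()
            },
            "effect_schedule": [
                {
                    "diagnosis": e.diagnosis,
                    "start": list(e.start),
                    "end": list(e.end),
                    "multiplier": e.multiplier,
                }
                for e in self.effect_schedule
            ],
            "theoretical_r": {
                d: {str(g): r for g, r in rs.items()} for d, rs in self.theoretical_r.items()
            },
        }


def expected_deviation(truth, r_mean: float, diagnosis: str | None = None, window=None) -> float:
    """Analytic oracle for the mean-deviation percentage.

    With observed ~ m x inclusion-year counts and predicted =
    r_mean x inclusion-year counts, the deviation is 100|m - r|/r.  Note a
    no-effect scenario (m = 1) still yields a positive deviation whenever
    r_mean < 1 — a structural property of correlation-scaled forecasts.
    Accepts either a bare multiplier or a GroundTruth plus diagnosis/window.
    """
    if r_mean <= 0:
        raise ValueError("r_mean must be positive")
    if isinstance(truth, GroundTruth):
        if diagnosis is None or window is None:
            raise ValueError("diagnosis and window required with a GroundTruth")
        m = truth.constant_multiplier(diagnosis, window)
    else:
        m = float(truth)
    return 100.0 * abs(m - r_mean) / r_mean


def theoretical_correlation(config: SyntheticConfig, diagnosis: str, gap: int) -> float:
    """Model-implied between-year Pearson correlation of weekly totals.

    Decomposes the across-week variance of a year's totals into the shared
    seasonal/holiday component, the patient-profile component (shared with
    decay persistence^gap), and unshared Poisson noise.
    """
    p = config.diagnoses[diagnosis]
    lam_eff = p.lambda0 * (1.0 - p.symptom_prob)
    s = config.seasonal_profile(diagnosis, 52)
    m = config.n_patients * lam_eff * s
    v_season = float(np.var(m))
    v_profile = config.n_patients * lam_eff**2 * float(np.mean(s**2)) / config.frailty_shape
    poisson = float(np.mean(m))
    rho = config.persistence**gap
    cov = v_season + rho * v_profile
    var = v_season + v_profile + poisson
    return cov / var


def _draw_profiles(rng, prev: np.ndarray | None, shape: float, persistence: float, size) -> np.ndarray:
    fresh = rng.gamma(shape, 1.0 / shape, size=size)
    if prev is None:
        return fresh
    keep = rng.random(size) < persistence
    return np.where(keep, prev, fresh)


def simulate(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (population frame, consultations frame, ground truth).

    Deterministic given ``config.seed``; the frames pass registry_io
    validation when round-tripped through the writers.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ref_year = config.years[0]

    ids = np.array([f"S{i:06d}" for i in range(1, n + 1)])
    female = rng.random(n) < config.gender_split
    group = rng.choice(3, size=n, p=np.asarray(config.age_group_weights))
    bounds = [(18, 24), (25, 39), (40, 65)]
    age = np.empty(n, dtype=int)
    for g, (lo, hi) in enumerate(bounds):
        mask = group == g
        age[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    population = pd.DataFrame(
        {
            "patient_id": ids,
            "gender": np.where(female, "female", "male"),
            "birth_year": ref_year - age,
        }
    )

    # shared habitual week-of-year profile per patient, persisting across years
    profiles: dict[int, np.ndarray] = {}
    prev = None
    for year in config.years:
        prev = _draw_profiles(rng, prev, config.frailty_shape, config.persistence, (n, 53))
        profiles[year] = prev

    pid_col, date_col, code_col = [], [], []
    expected: dict[str, dict[tuple[int, int], float]] = {}
    for diag, params in config.diagnoses.items():
        season = config.seasonal_profile(diag, 53)
        expected[diag] = {}
        for year in config.years:
            n_weeks = iso_weeks_in_year(year)
            effect = config.effect_multipliers(diag, year, n_weeks)
            rate_week = params.lambda0 * season[:n_weeks] * effect
            counts = rng.poisson(profiles[year][:, :n_weeks] * rate_week)
            pat_idx, week_idx = np.nonzero(counts)
            reps = counts[pat_idx, week_idx]
            pat_idx = np.repeat(pat_idx, reps)
            week_idx = np.repeat(week_idx, reps)
            mondays = np.array(
                [dt.date.fromisocalendar(year, w, 1).toordinal() for w in range(1, n_weeks + 1)]
            )
            ordinals = mondays[week_idx] + rng.integers(0, 7, size=len(week_idx))
            # extracts are delivered per calendar year: boundary ISO weeks only
            # contribute the days falling inside `year`
            ordinals = np.clip(
                ordinals,
                dt.date(year, 1, 1).toordinal(),
                dt.date(year, 12, 31).toordinal(),
            )
            n_events = len(pat_idx)
            if params.symptom_code is not None and params.symptom_prob > 0:
                symptom = rng.random(n_events) < params.symptom_prob
                codes = np.where(symptom, params.symptom_code, diag)
            else:
                codes = np.full(n_events, diag)
            pid_col.append(ids[pat_idx])
            date_col.append(ordinals)
            code_col.append(codes)
            for i, w in enumerate(range(1, n_weeks + 1)):
                expected[diag][(year, w)] = float(
                    n * rate_week[i] * (1.0 - params.symptom_prob)
                )

    pid = np.concatenate(pid_col) if pid_col else np.empty(0, dtype=str)
    ordinals = np.concatenate(date_col) if date_col else np.empty(0, dtype=int)
    codes = np.concatenate(code_col) if code_col else np.empty(0, dtype=str)
    dates = pd.to_datetime(ordinals - _EPOCH_ORDINAL, unit="D")
    contact = rng.choice(CONTACT_TYPES, size=len(pid), p=CONTACT_WEIGHTS)
    consultations = pd.DataFrame(
        {
            "patient_id": pid,
            "date": dates,
            "diagnosis_codes": codes,
            "contact_type": contact,
        }
    )
    consultations = consultations.sort_values(
        ["date", "patient_id", "diagnosis_codes"], kind="stable"
    ).reset_index(drop=True)

    if config.registration_loss > 0:
        last = config.years[-1]
        december = (consultations["date"].dt.year == last) & (
            consultations["date"].dt.month == 12
        )
        drop = december & (rng.random(len(consultations)) < config.registration_loss)
        n_drop = int(drop.sum())
        if n_drop:
            logger.info("registration_loss: dropping %d December-%d consultations", n_drop, last)
        consultations = consultations[~drop].reset_index(drop=True)

    truth = GroundTruth(
        expected_weekly=expected,
        effect_schedule=config.effect_schedule,
        theoretical_r={
            d: {gap: theoretical_correlation(config, d, gap) for gap in (1, 2)}
            for d in config.diagnoses
        },
        config=config,
    )
    return population, consultations, truth


def generate(config: SyntheticConfig, outdir) -> tuple[Path, Path, GroundTruth]:
    """Generate and write population.csv, consultations.csv and a
    ground-truth JSON sidecar; returns the two file paths and the truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    population, consultations, truth = simulate(config)
    pop_path = outdir / "population.csv"
    cons_path = outdir / "consultations.csv"
    write_population(population, pop_path)
    write_consultations(consultations, cons_path)
    (outdir / "ground_truth.json").write_text(json.dumps(truth.to_json(), indent=1))
    return pop_path, cons_path, truth


def deterministic_mode(
    ratios: Mapping[int, float],
    diagnoses: Sequence[str] = ("P76", "P74", "P79", "P82", "P86"),
    years: Sequence[int] = (2017, 2018, 2019, 2020, 2021),
    n_patients: int = 60,
    outdir=None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Exact-oracle fixtures: weekly counts are known multiples by construction.

    Every year's week-w count for a diagnosis is ``ratio[year] x base_w``
    with a fixed base pattern that is a multiple of 10, so ratios such as
    1.2 or 1.5 give exact integer counts; years absent from ``ratios`` get
    ratio 1.0.  Pre-pandemic years left at ratio 1 are exact copies of the
    inclusion year, which forces a bootstrap r_mean of exactly 1.  Weeks
    beyond 52 (ISO week 53) reuse the week-52 base, mirroring the
    forecaster's carry-forward rule so injected ratios survive the whole
    pipeline unchanged.

    ``ratios`` maps year -> multiplier, or diagnosis -> {year: multiplier}.
    """
    per_diag: dict[str, dict[int, float]] = {}
    for d in diagnoses:
        if d in ratios and isinstance(ratios[d], Mapping):
            per_diag[d] = {int(y): float(m) for y, m in ratios[d].items()}
        else:
            per_diag[d] = {
                int(y): float(m) for y, m in ratios.items() if not isinstance(m, Mapping)
            }

    ref_year = years[0]
    ids = [f"D{i:04d}" for i in range(1, n_patients + 1)]
    population = pd.DataFrame(
        {
            "patient_id": ids,
            "gender": ["female" if i % 2 else "male" for i in range(n_patients)],
            "birth_year": [ref_year - (30 + i % 20) for i in range(n_patients)],
        }
    )

    pid_col, date_col, code_col = [], [], []
    counter = 0
    for offset, diag in enumerate(diagnoses):
        for year in years:
            m = per_diag[diag].get(year, 1.0)
            for w in range(1, iso_weeks_in_year(year) + 1):
                base = 10 * (4 + (min(w, 52) + offset) % 4)
                count = m * base
                if abs(count - round(count)) > 1e-9:
                    raise ValueError(
                        f"ratio {m} x base {base} is not an integer count"
                    )
                monday = dt.date.fromisocalendar(year, w, 1).toordinal()
                lo = dt.date(year, 1, 1).toordinal()
                hi = dt.date(year, 12, 31).toordinal()
                for _ in range(int(round(count))):
                    pid_col.append(ids[counter % n_patients])
                    date_col.append(min(max(monday + counter % 7, lo), hi))
                    code_col.append(diag)
                    counter += 1

    consultations = pd.DataFrame(
        {
            "patient_id": pid_col,
            "date": pd.to_datetime(np.asarray(date_col) - _EPOCH_ORDINAL, unit="D"),
            "diagnosis_codes": code_col,
            "contact_type": "gp_day",
        }
    ).sort_values(["date", "patient_id"], kind="stable").reset_index(drop=True)

    info = {"ratios": per_diag, "n_patients": n_patients, "years": list(years)}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_population(population, outdir / "population.csv")
        write_consultations(consultations, outdir / "consultations.csv")
    return population, consultations, info
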