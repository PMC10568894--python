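"""Aggregate an analysis dataset to weekly consultation totals.

Weeks follow ISO-8601 week numbering (Monday start), the Norwegian
administrative standard, so "week 11 of 2020" is the calendar week
2020-03-09 .. 2020-03-15.  Every consultation counts: a patient with three
consultations in one week contributes three to that week's total, and a
consultation carrying two analysis codes contributes one count to each
code's series.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AGE_GROUPS = ("18-24", "25-39", "40-65")

STRATUM_MODES = ("overall", "by_gender", "by_age_group")


def iso_weeks_in_year(iso_year: int) -> int:
    """Number of ISO weeks (52 or 53) in an ISO year."""
    return dt.date(iso_year, 12, 28).isocalendar()[1]


@dataclass(frozen=True)
class Stratifier:
    """A population stratum: overall, one gender, or one age group."""

    mode: str = "overall"
    level: str = "all"

    def __post_init__(self):
        if self.mode not in STRATUM_MODES:
            raise ValueError(f"mode must be one of {STRATUM_MODES}")
        if self.mode == "overall" and self.level != "all":
            raise ValueError("overall stratum has level 'all'")
        if self.mode == "by_gender" and self.level not in ("female", "male"):
            raise ValueError("by_gender level must be 'female' or 'male'")
        if self.mode == "by_age_group" and self.level not in AGE_GROUPS:
            raise ValueError(f"by_age_group level must be one of {AGE_GROUPS}")

    def __str__(self) -> str:
        return "overall" if self.mode == "overall" else f"{self.mode}:{self.level}"

    @classmethod
    def parse(cls, text: str) -> "Stratifier":
        if text == "overall":
            return cls()
        mode, _, level = text.partition(":")
        return cls(mode, level)

    def mask(self, patients: pd.DataFrame) -> pd.Series:
        """Boolean membership over a patients frame (gender, age_group columns)."""
        if self.mode == "overall":
            return pd.Series(True, index=patients.index)
        column = "gender" if self.mode == "by_gender" else "age_group"
        return patients[column] == self.level


OVERALL = Stratifier()


def default_strata() -> list[Stratifier]:
    """Overall plus both genders plus the three age groups."""
    return (
        [OVERALL]
        + [Stratifier("by_gender", g) for g in ("male", "female")]
        + [Stratifier("by_age_group", a) for a in AGE_GROUPS]
    )


@dataclass(frozen=True)
class WeeklyCountSeries:
    """Total consultations per ISO week for one diagnosis and stratum."""

    diagnosis: str
    stratum: Stratifier
    points: tuple = ()
    complete_grid: bool = True

    def __post_init__(self):
        pts = tuple((int(y), int(w), int(c)) for y, w, c in self.points)
        object.__setattr__(self, "points", pts)
        keys = [(y, w) for y, w, _ in pts]
        if keys != sorted(keys) or len(set(keys)) != len(keys):
            raise ValueError("points must be strictly ordered by (iso_year, iso_week)")
        for y, w, c in pts:
            if not (1 <= w <= 53):
                raise ValueError(f"iso_week {w} outside 1..53")
            if c < 0:
                raise ValueError("counts must be non-negative")
        if self.complete_grid and pts:
            expected = [
                (y, w)
                for y in range(pts[0][0], pts[-1][0] + 1)
                for w in range(1, iso_weeks_in_year(y) + 1)
            ]
            expected = [k for k in expected if pts[0][:2] <= k <= pts[-1][:2]]
            if keys != expected:
                raise ValueError("complete_grid series must cover every ISO week in span")

    @property
    def counts(self) -> np.ndarray:
        return np.array([c for _, _, c in self.points], dtype=float)

    @property
    def weeks(self) -> list[tuple[int, int]]:
        return [(y, w) for y, w, _ in self.points]

    @property
    def iso_years(self) -> list[int]:
        return sorted({y for y, _, _ in self.points})

    def total(self) -> int:
        return int(sum(c for _, _, c in self.points))

    def __len__(self) -> int:
        return len(self.points)


def _explode_codes(consultations: pd.DataFrame) -> pd.DataFrame:
    parts = consultations["diagnosis_codes"].str.split(";")
    out = consultations.loc[
        consultations.index.repeat(parts.str.len()),
        [c for c in consultations.columns if c != "diagnosis_codes"],
    ].copy()
    out["code"] = np.concatenate(parts.to_numpy()) if len(parts) else []
    return out


def weekly_counts(ds, diagnosis: str, stratum: Stratifier = OVERALL) -> WeeklyCountSeries:
    """Weekly totals of consultations carrying ``diagnosis`` within a stratum.

    The grid is zero-filled over the dataset's ISO-year span
    (inclusion year through last follow year); the handful of boundary dates
    whose ISO year falls outside that span are not representable on the grid
    and are excluded.
    """
    spec = ds.spec
    if diagnosis not in spec.codes.analysis_codes:
        raise ValueError(
            f"{diagnosis} is not an analysis code ({sorted(spec.codes.analysis_codes)})"
        )
    frame = ds.consultations
    # exact on canonical cells: codes are fixed-width, ';'-joined
    keep = frame["diagnosis_codes"].str.contains(diagnosis, regex=False)
    frame = frame[keep]
    member_ids = ds.patients.index[stratum.mask(ds.patients)]
    frame = frame[frame["patient_id"].isin(member_ids)]

    years = list(range(spec.inclusion_year, spec.follow_years[-1] + 1))
    iso = pd.to_datetime(frame["date"]).dt.isocalendar() if len(frame) else None
    grid: dict[tuple[int, int], int] = {
        (y, w): 0 for y in years for w in range(1, iso_weeks_in_year(y) + 1)
    }
    if iso is not None:
        tallies = (
            pd.DataFrame({"iso_year": iso["year"], "iso_week": iso["week"]})
            .value_counts()
            .to_dict()
        )
        for (y, w), n in tallies.items():
            if (y, w) in grid:
                grid[(y, w)] += int(n)
    points = [(y, w, grid[(y, w)]) for y in years for w in range(1, iso_weeks_in_year(y) + 1)]
    return WeeklyCountSeries(diagnosis=diagnosis, stratum=stratum, points=points)


def slice_years(series: WeeklyCountSeries, years) -> WeeklyCountSeries:
    """Restrict a series to the given ISO year(s)."""
    if isinstance(years, int):
        years = [years]
    years = set(years)
    points = [(y, w, c) for y, w, c in series.points if y in years]
    if not points:
        logger.warning(
            "slice_years: no overlap between %s and series span %s",
            sorted(years), series.iso_years,
        )
    return WeeklyCountSeries(
        diagnosis=series.diagnosis,
        stratum=series.stratum,
        points=points,
        complete_grid=series.complete_grid,
    )


def concat_series(*parts: WeeklyCountSeries) -> WeeklyCountSeries:
    """Concatenate year-contiguous slices back into one series."""
    points = [p for s in parts for p in s.points]
    return WeeklyCountSeries(
        diagnosis=parts[0].diagnosis, stratum=parts[0].stratum, points=points,
        complete_grid=parts[0].complete_grid,
    )


def align_weeks(series_a: WeeklyCountSeries, series_b: WeeklyCountSeries):
    """Pair two single-ISO-year series by week number over weeks 1..min length.

    Returns two equal-length count vectors; with a 52-week and a 53-week
    year, week 53 is left unpaired.
    """
    for s in (series_a, series_b):
        if len(s) == 0:
            raise ValueError("cannot align an empty series")
        if len(s.iso_years) != 1:
            raise ValueError(f"series must cover exactly one ISO year, got {s.iso_years}")
    a = {w: c for _, w, c in series_a.points}
    b = {w: c for _, w, c in series_b.points}
    n = min(len(a), len(b))
    weeks = range(1, n + 1)
    return (
        np.array([a[w] for w in weeks], dtype=float),
        np.array([b[w] for w in weeks], dtype=float),
    )
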