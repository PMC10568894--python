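"""Cohort construction for the pre-pandemic and pandemic analysis datasets.

A patient has a pre-existing mental health problem when they have at least
one GP consultation in the inclusion year carrying any inclusion code —
the five disorder codes or the two symptom codes P03/P01, since the
symptoms may develop into the corresponding disorders later.  Cohort
members are then followed through the two subsequent years, but only
consultations carrying a disorder (analysis) code are retained: a
symptom-only consultation can establish membership yet never appears in
the analysed counts.

Age is computed as inclusion_year - birth_year and the 18-65 eligibility
window and age-group assignment (18-24, 25-39, 40-65) are fixed at the
inclusion year, so patients cannot migrate between strata mid-series and
patients aging past 65 during follow-up remain in the cohort.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .registry_io import (
    CodeSet,
    DEFAULT_CODES,
    as_consultation_frame,
    as_population_frame,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortSpec:
    """Inclusion year, follow years, age window and code sets for one dataset."""

    inclusion_year: int
    follow_years: tuple[int, int]
    min_age: int = 18
    max_age: int = 65
    codes: CodeSet = field(default_factory=CodeSet)

    def __post_init__(self):
        object.__setattr__(self, "follow_years", tuple(self.follow_years))
        if any(y < self.inclusion_year for y in self.follow_years):
            raise ValueError("follow_years must not precede the inclusion year")
        if list(self.follow_years) != sorted(self.follow_years):
            raise ValueError("follow_years must be ordered")
        if not self.min_age < self.max_age:
            raise ValueError("min_age must be below max_age")

    @property
    def years(self) -> list[int]:
        return list(range(self.inclusion_year, self.follow_years[-1] + 1))


PRE_PANDEMIC_SPEC = CohortSpec(inclusion_year=2017, follow_years=(2018, 2019))
PANDEMIC_SPEC = CohortSpec(inclusion_year=2019, follow_years=(2020, 2021))


def assign_age_group(age: pd.Series) -> pd.Series:
    return pd.cut(
        age, bins=[17, 24, 39, 65], labels=["18-24", "25-39", "40-65"]
    ).astype(object)


@dataclass(frozen=True)
class AnalysisDataset:
    """Cohort membership plus the retained analysis-coded consultations.

    ``consultations`` holds, for cohort members only, the consultations dated
    from the inclusion year through the last follow year that carry at least
    one analysis code.  ``patients`` is indexed by patient_id and carries
    gender, birth_year, age (at inclusion) and age_group for every cohort
    member.
    """

    label: str
    spec: CohortSpec
    cohort_ids: frozenset[str]
    consultations: pd.DataFrame
    patients: pd.DataFrame

    @property
    def n_consultations(self) -> int:
        return len(self.consultations)

    @property
    def n_unique_patients(self) -> int:
        """Cohort members with at least one retained consultation."""
        return int(self.consultations["patient_id"].nunique())


def _carries_any(frame: pd.DataFrame, codes: frozenset[str]) -> pd.Series:
    # exact on canonical cells: codes are fixed-width, ';'-joined
    pattern = "|".join(sorted(codes))
    return frame["diagnosis_codes"].str.contains(pattern, regex=True)


def identify_cohort(consultations, population, spec: CohortSpec) -> frozenset[str]:
    """Patients with >=1 inclusion-coded consultation in the inclusion year,
    aged within the eligibility window at that year."""
    frame = as_consultation_frame(consultations)
    pop = as_population_frame(population)
    if frame.empty:
        return frozenset()
    in_year = pd.to_datetime(frame["date"]).dt.year == spec.inclusion_year
    inclusion = _carries_any(frame, spec.codes.inclusion_codes)
    qualifying = frame[in_year & inclusion]
    ids = set(qualifying["patient_id"])
    known = set(pop["patient_id"])
    missing = ids - known
    if missing:
        raise ValueError(
            "patients present in consultations but absent from population: "
            + ", ".join(sorted(missing)[:20])
        )
    ages = spec.inclusion_year - pop.set_index("patient_id")["birth_year"]
    eligible = ages[(ages >= spec.min_age) & (ages <= spec.max_age)].index
    return frozenset(ids & set(eligible))


def build_dataset(consultations, population, spec: CohortSpec, label: str = "pandemic") -> AnalysisDataset:
    """Construct an analysis dataset: cohort membership then follow-period
    consultations restricted to analysis codes."""
    frame = as_consultation_frame(consultations)
    pop = as_population_frame(population)
    cohort = identify_cohort(frame, pop, spec)
    if not cohort:
        logger.warning("empty cohort for inclusion year %s", spec.inclusion_year)

    if frame.empty:
        retained = frame
    else:
        years = pd.to_datetime(frame["date"]).dt.year
        in_span = (years >= spec.inclusion_year) & (years <= spec.follow_years[-1])
        analysed = _carries_any(frame, spec.codes.analysis_codes)
        member = frame["patient_id"].isin(cohort)
        retained = frame[in_span & analysed & member].reset_index(drop=True)

    patients = (
        pop[pop["patient_id"].isin(cohort)]
        .set_index("patient_id")[["gender", "birth_year"]]
        .copy()
    )
    patients["age"] = spec.inclusion_year - patients["birth_year"]
    patients["age_group"] = assign_age_group(patients["age"])
    return AnalysisDataset(
        label=label, spec=spec, cohort_ids=cohort,
        consultations=retained, patients=patients,
    )


def dataset_summary(ds: AnalysisDataset) -> dict:
    """Unique-patient counts, % women, and consultation counts per code,
    gender and age group (patients counted among those with retained
    consultations)."""
    cons = ds.consultations
    active = ds.patients.loc[ds.patients.index.isin(cons["patient_id"].unique())]
    n_active = len(active)
    pct_women = 100.0 * (active["gender"] == "female").mean() if n_active else 0.0

    per_code: dict[str, int] = {c: 0 for c in sorted(ds.spec.codes.analysis_codes)}
    if len(cons):
        exploded = cons["diagnosis_codes"].str.split(";").explode()
        for code, n in exploded.value_counts().items():
            if code in per_code:
                per_code[code] = int(n)

    def _by(column: str) -> dict[str, int]:
        if not len(cons):
            return {}
        attr = ds.patients[column].reindex(cons["patient_id"])
        return {str(k): int(v) for k, v in attr.value_counts().items()}

    return {
        "label": ds.label,
        "n_cohort": len(ds.cohort_ids),
        "n_unique_patients": ds.n_unique_patients,
        "n_consultations": ds.n_consultations,
        "pct_women": float(pct_women),
        "consultations_per_code": per_code,
        "consultations_per_gender": _by("gender"),
        "consultations_per_age_group": _by("age_group"),
    }


def dataset_manifest(ds: AnalysisDataset) -> dict:
    """JSON-serialisable manifest with a checksum of retained consultations,
    for reproducibility audits."""
    payload = ds.consultations.copy()
    payload["date"] = pd.to_datetime(payload["date"]).dt.strftime("%Y-%m-%d")
    digest = hashlib.sha256(
        payload.to_csv(index=False).encode("utf-8")
    ).hexdigest()
    return {
        "label": ds.label,
        "inclusion_year": ds.spec.inclusion_year,
        "follow_years": list(ds.spec.follow_years),
        "min_age": ds.spec.min_age,
        "max_age": ds.spec.max_age,
        "inclusion_codes": sorted(ds.spec.codes.inclusion_codes),
        "analysis_codes": sorted(ds.spec.codes.analysis_codes),
        "n_cohort": len(ds.cohort_ids),
        "n_unique_patients": ds.n_unique_patients,
        "n_consultations": ds.n_consultations,
        "consultations_sha256": digest,
    }
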