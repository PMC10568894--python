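"""Correlation-scaled forecasting of pandemic-period weekly counts.

The forecasting model treats the between-year Pearson correlation of weekly
consultation totals, estimated on the pre-pandemic dataset by a pairs
bootstrap, as a fixed scaling ratio: with r(2017, 2018) estimated from the
pre-pandemic cohort, the predicted weekly counts for the first pandemic
year are r x the observed weekly counts of the pandemic inclusion year
(2019), week by ISO week; the second pandemic year uses r(2017, 2019).
The model assumes consultation counts are at most as high as in the
inclusion year (correlations decay with year gap), so a forecast never
exceeds its source when 0 <= r <= 1.

The bootstrap resamples week-index pairs with replacement (the classic
pairs bootstrap over the ~52 weekly totals); a patient-level bootstrap is
available as a sensitivity mode.  Resamples where either resampled vector
is constant leave Pearson r undefined and are excluded from the average;
the number of valid resamples is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .weekly import (
    OVERALL,
    Stratifier,
    WeeklyCountSeries,
    align_weeks,
    iso_weeks_in_year,
    slice_years,
    weekly_counts,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForecastConfig:
    """Tunables for the bootstrap correlation estimate."""

    n_boot: int = 10_000
    bootstrap_mode: str = "weeks"  # "weeks" (default) or "patients"
    seed: int = 0

    def __post_init__(self):
        if self.bootstrap_mode not in ("weeks", "patients"):
            raise ValueError("bootstrap_mode must be 'weeks' or 'patients'")
        if self.n_boot < 1:
            raise ValueError("n_boot must be positive")


@dataclass(frozen=True)
class CorrelationEstimate:
    """Bootstrap mean Pearson correlation between two years' weekly totals."""

    r_mean: float
    r_sd: float
    n_boot: int
    n_valid: int
    seed: int
    year_pair: tuple[int, int]

    def __post_init__(self):
        if not -1.0 <= self.r_mean <= 1.0 + 1e-12:
            raise ValueError(f"r_mean {self.r_mean} outside [-1, 1]")
        if self.r_sd < 0:
            raise ValueError("r_sd must be non-negative")
        if self.n_valid > self.n_boot:
            raise ValueError("n_valid cannot exceed n_boot")


@dataclass(frozen=True)
class ForecastSeries:
    """Predicted weekly counts for one target year (r_mean x source counts)."""

    diagnosis: str
    stratum: Stratifier
    target_year: int
    predicted: np.ndarray
    source: WeeklyCountSeries
    estimate: CorrelationEstimate

    def __post_init__(self):
        object.__setattr__(
            self, "predicted", np.asarray(self.predicted, dtype=float)
        )
        if len(self.predicted) != iso_weeks_in_year(self.target_year):
            raise ValueError(
                f"predicted length {len(self.predicted)} != weeks in ISO year "
                f"{self.target_year}"
            )

    @property
    def weeks(self) -> list[tuple[int, int]]:
        return [(self.target_year, w) for w in range(1, len(self.predicted) + 1)]


def _rowwise_pearson(xs: np.ndarray, ys: np.ndarray):
    """Pearson r along axis 1; rows where either side is constant -> NaN."""
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", xc, xc)
    syy = np.einsum("ij,ij->i", yc, yc)
    sxy = np.einsum("ij,ij->i", xc, yc)
    valid = (sxx > 0) & (syy > 0)
    r = np.full(len(xs), np.nan)
    r[valid] = sxy[valid] / np.sqrt(sxx[valid] * syy[valid])
    return np.clip(r, -1.0, 1.0, out=r)


def bootstrap_mean_correlation(
    x, y, n_boot: int = 10_000, seed: int = 0, year_pair: tuple[int, int] = (0, 0)
) -> CorrelationEstimate:
    """Pairs-bootstrap estimate of the mean Pearson correlation.

    Draws ``n_boot`` resamples of (x, y) index pairs with replacement,
    computes Pearson r on every non-degenerate resample, and averages.
    Deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length vectors with >= 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: input vector is constant")

    rng = np.random.default_rng(seed)
    n = len(x)
    r_all = np.empty(0)
    # draw in batches to bound memory at large n_boot
    batch = max(1, min(n_boot, 200_000 // n))
    chunks = []
    done = 0
    while done < n_boot:
        m = min(batch, n_boot - done)
        idx = rng.integers(0, n, size=(m, n))
        chunks.append(_rowwise_pearson(x[idx], y[idx]))
        done += m
    r_all = np.concatenate(chunks)
    valid = r_all[~np.isnan(r_all)]
    if len(valid) == 0:
        raise ValueError("all bootstrap resamples were degenerate")
    r_mean = float(valid.mean())
    r_sd = float(valid.std(ddof=1)) if len(valid) > 1 else 0.0
    return CorrelationEstimate(
        r_mean=r_mean, r_sd=r_sd, n_boot=n_boot, n_valid=int(len(valid)),
        seed=seed, year_pair=tuple(year_pair),
    )


def enumerate_mean_correlation(x, y) -> tuple[float, int]:
    """Exhaustive enumeration over all n^n ordered resamples (tiny n only).

    Independent oracle for the Monte-Carlo bootstrap: returns the mean
    Pearson r over all non-degenerate resamples and the count of valid ones.
    """
    import itertools

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n > 6:
        raise ValueError("enumeration is exponential; use n <= 6")
    rs = []
    for idx in itertools.product(range(n), repeat=n):
        xi, yi = x[list(idx)], y[list(idx)]
        if np.ptp(xi) == 0 or np.ptp(yi) == 0:
            continue
        rs.append(np.corrcoef(xi, yi)[0, 1])
    return float(np.mean(rs)), len(rs)


def patient_bootstrap_mean_correlation(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    year_pair: tuple[int, int] = (0, 0),
) -> CorrelationEstimate:
    """Sensitivity mode: resample patients, recompute both years' weekly
    totals, and correlate.

    ``counts_a`` / ``counts_b`` are patient x week count matrices (same
    patient index).
    """
    patients = counts_a.index.union(counts_b.index)
    A = counts_a.reindex(patients, fill_value=0).to_numpy(dtype=float)
    B = counts_b.reindex(patients, fill_value=0).to_numpy(dtype=float)
    n_pat = len(patients)
    rng = np.random.default_rng(seed)
    rs = []
    batch = 200
    done = 0
    while done < n_boot:
        m = min(batch, n_boot - done)
        # multinomial draw = number of times each patient is resampled
        w = rng.multinomial(n_pat, np.full(n_pat, 1.0 / n_pat), size=m).astype(float)
        xs = w @ A
        ys = w @ B
        rs.append(_rowwise_pearson(xs, ys))
        done += m
    r_all = np.concatenate(rs)
    valid = r_all[~np.isnan(r_all)]
    if len(valid) == 0:
        raise ValueError("all bootstrap resamples were degenerate")
    return CorrelationEstimate(
        r_mean=float(valid.mean()),
        r_sd=float(valid.std(ddof=1)) if len(valid) > 1 else 0.0,
        n_boot=n_boot, n_valid=int(len(valid)), seed=seed,
        year_pair=tuple(year_pair),
    )


def scale_forecast(
    source: WeeklyCountSeries, estimate: CorrelationEstimate, target_year: int
) -> ForecastSeries:
    """Predicted week w of the target year = r_mean x source count at week w.

    Weeks are paired by ISO week number.  When the target ISO year has one
    more week than the source (week 53 of 2020), the final source week's
    value is carried forward; a negative r_mean is refused because a
    negative forecast of counts is meaningless under this model.
    """
    if estimate.r_mean < 0:
        raise ValueError(
            f"r_mean = {estimate.r_mean:.4f} < 0: scaling counts by a negative "
            "correlation would forecast negative consultation counts"
        )
    if len(source.iso_years) != 1:
        raise ValueError("source series must cover exactly one ISO year")
    src = source.counts
    n_target = iso_weeks_in_year(target_year)
    predicted = np.empty(n_target)
    n_pair = min(len(src), n_target)
    predicted[:n_pair] = estimate.r_mean * src[:n_pair]
    if n_target > len(src):
        predicted[len(src):] = estimate.r_mean * src[-1]
    return ForecastSeries(
        diagnosis=source.diagnosis, stratum=source.stratum,
        target_year=target_year, predicted=predicted,
        source=source, estimate=estimate,
    )


def _patient_week_matrix(ds, diagnosis: str, stratum: Stratifier, iso_year: int) -> pd.DataFrame:
    frame = ds.consultations
    keep = frame["diagnosis_codes"].str.contains(diagnosis, regex=False)
    frame = frame[keep]
    member_ids = ds.patients.index[stratum.mask(ds.patients)]
    frame = frame[frame["patient_id"].isin(member_ids)]
    iso = pd.to_datetime(frame["date"]).dt.isocalendar()
    frame = frame[iso["year"] == iso_year]
    weeks = iso.loc[frame.index, "week"]
    table = (
        pd.crosstab(frame["patient_id"], weeks)
        .reindex(columns=range(1, iso_weeks_in_year(iso_year) + 1), fill_value=0)
    )
    return table


def fit_forecasts(
    pre_ds,
    pan_ds,
    diagnosis: str,
    stratum: Stratifier = OVERALL,
    config: ForecastConfig = ForecastConfig(),
) -> tuple[ForecastSeries, ForecastSeries]:
    """Estimate both year-pair correlations on the pre-pandemic dataset and
    forecast both pandemic years from the pandemic inclusion year.

    r(inclusion, inclusion+1) drives the first pandemic-year forecast and
    r(inclusion, inclusion+2) the second; each estimate records the derived
    seed that produced it.
    """
    pre_year = pre_ds.spec.inclusion_year
    pan_year = pan_ds.spec.inclusion_year
    pre_series = weekly_counts(pre_ds, diagnosis, stratum)
    source = slice_years(weekly_counts(pan_ds, diagnosis, stratum), pan_year)

    estimates = []
    for gap, sub_seed in ((1, 0), (2, 1)):
        year_pair = (pre_year, pre_year + gap)
        seed = int(
            np.random.SeedSequence([config.seed, sub_seed]).generate_state(1)[0]
            % (2**31)
        )
        if config.bootstrap_mode == "patients":
            est = patient_bootstrap_mean_correlation(
                _patient_week_matrix(pre_ds, diagnosis, stratum, pre_year),
                _patient_week_matrix(pre_ds, diagnosis, stratum, pre_year + gap),
                n_boot=config.n_boot, seed=seed, year_pair=year_pair,
            )
        else:
            x, y = align_weeks(
                slice_years(pre_series, pre_year),
                slice_years(pre_series, pre_year + gap),
            )
            est = bootstrap_mean_correlation(
                x, y, n_boot=config.n_boot, seed=seed, year_pair=year_pair
            )
        estimates.append(est)
        logger.info(
            "%s %s r%s = %.4f (sd %.4f, %d/%d valid)",
            diagnosis, stratum, year_pair, est.r_mean, est.r_sd,
            est.n_valid, est.n_boot,
        )

    return (
        scale_forecast(source, estimates[0], pan_year + 1),
        scale_forecast(source, estimates[1], pan_year + 2),
    )


def forecast_frame(*forecasts: ForecastSeries) -> pd.DataFrame:
    """Tabular form of one or more forecasts (forecast.csv layout)."""
    rows = []
    for f in forecasts:
        for (year, week), value in zip(f.weeks, f.predicted):
            rows.append(
                {
                    "diagnosis": f.diagnosis,
                    "stratum": str(f.stratum),
                    "target_year": year,
                    "iso_week": week,
                    "predicted": value,
                    "r_mean": f.estimate.r_mean,
                    "r_sd": f.estimate.r_sd,
                    "seed": f.estimate.seed,
                }
            )
    return pd.DataFrame(rows)
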