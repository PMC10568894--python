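"""Local regression smoothing, pointwise confidence bands, and the
observed-vs-forecast comparison.

``loess_fit`` is a direct (exact) implementation of locally weighted
polynomial regression with the tricube kernel: at every design point the
nearest ``floor(span * n)`` neighbours are fitted by weighted least squares
of the given degree, the fitted value is the intercept of the local fit,
and the pointwise standard error is s * ||l(x)|| where l(x) is the
equivalent-kernel row and s^2 = RSS / tr[(I-L)(I-L)'] is the residual
scale of the smoothing operator L.  This reproduces the classic
direct-surface, exact-statistics local-regression computation.

The comparison smooths both the observed and the forecast weekly series
over the full pandemic span on one consecutive week index (no reset at the
year boundary), places a 99.9% pointwise band around the forecast trend,
and restricts results to the analysis window (2020-W11 onward, the week
of the first strict confinement measures) so the window start suffers no
smoothing edge effect.  The mean-deviation percentage — the headline
effect measure, 100 * sum|observed - predicted| / sum(predicted) — is
computed on raw weekly counts over the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .forecast import ForecastSeries
from .weekly import Stratifier, WeeklyCountSeries

DEFAULT_SPAN = 0.17
DEFAULT_LEVEL = 0.999
DEFAULT_WINDOW_START = (2020, 11)


@dataclass(frozen=True)
class LoessFit:
    """A local-regression fit with pointwise standard errors."""

    x: np.ndarray
    fitted: np.ndarray
    se: np.ndarray
    span: float
    degree: int
    residual_scale: float

    def __post_init__(self):
        for name in ("x", "fitted", "se"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not 0 < self.span <= 1:
            raise ValueError("span must be in (0, 1]")
        if (self.se < 0).any():
            raise ValueError("standard errors must be non-negative")


def loess_fit(y, span: float = DEFAULT_SPAN, degree: int = 2, x=None) -> LoessFit:
    """Locally weighted polynomial regression at every design point.

    Exact on polynomials up to ``degree``; deterministic.  Requires at
    least max(4, ceil(span * n)) points and no NaN input.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    x = np.arange(1.0, n + 1) if x is None else np.asarray(x, dtype=float)
    if len(x) != n:
        raise ValueError("x and y must have equal length")
    if np.isnan(y).any() or np.isnan(x).any():
        raise ValueError("NaN in loess input")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if n < max(4, int(np.ceil(span * n))):
        raise ValueError(f"too few points (n={n}) for span {span}")

    q = int(np.floor(span * n + 1e-9))
    q = min(n, max(q, degree + 1))

    L = np.zeros((n, n))
    for i in range(n):
        d = np.abs(x - x[i])
        h = np.sort(d)[q - 1]
        if h <= 0:
            h = np.finfo(float).tiny
        u = np.minimum(d / h, 1.0)
        w = (1.0 - u**3) ** 3
        w[d >= h] = 0.0
        idx = np.flatnonzero(w > 0)
        X = np.vander(x[idx] - x[i], degree + 1, increasing=True)
        XtW = X.T * w[idx]
        beta_rows = np.linalg.solve(XtW @ X, XtW)
        L[i, idx] = beta_rows[0]

    fitted = L @ y
    resid = y - fitted
    IL = np.eye(n) - L
    delta1 = float(np.einsum("ij,ij->", IL, IL))
    s = float(np.sqrt((resid @ resid) / delta1)) if delta1 > 0 else 0.0
    se = s * np.sqrt(np.einsum("ij,ij->i", L, L))
    return LoessFit(x=x, fitted=fitted, se=se, span=span, degree=degree, residual_scale=s)


def pointwise_band(
    fit: LoessFit, level: float = DEFAULT_LEVEL, quantile: str = "normal", dof: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise band fitted -/+ q * se at the two-sided ``level``.

    ``quantile`` selects the normal quantile (default; q ~ 3.2905 at 99.9%)
    or a t quantile keyed to ``dof`` degrees of freedom.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    p = 0.5 + level / 2.0
    if quantile == "normal":
        q = stats.norm.ppf(p)
    elif quantile == "t":
        if dof is None or dof <= 0:
            raise ValueError("t quantile requires positive dof")
        q = stats.t.ppf(p, dof)
    else:
        raise ValueError("quantile must be 'normal' or 't'")
    return fit.fitted - q * fit.se, fit.fitted + q * fit.se


def mean_deviation(observed_raw, predicted_raw) -> float:
    """Mean deviation percentage: 100 * sum|obs - pred| / sum(pred).

    The absolute value prevents excess and deficit weeks from cancelling.
    """
    obs = np.asarray(observed_raw, dtype=float)
    pred = np.asarray(predicted_raw, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    total = pred.sum()
    if total <= 0:
        raise ValueError("predicted total must be positive")
    return float(100.0 * np.abs(obs - pred).sum() / total)


@dataclass(frozen=True)
class FlaggedPeriod:
    """A maximal run of consecutive weeks flagged in one direction."""

    start: tuple[int, int]
    end: tuple[int, int]
    direction: str  # "above" or "below"


@dataclass(frozen=True)
class ComparisonResult:
    """Per-week observed/forecast comparison over the analysis window."""

    diagnosis: str
    stratum: Stratifier
    window: tuple  # ordered (iso_year, iso_week) pairs
    observed_raw: np.ndarray
    predicted_raw: np.ndarray
    observed_smooth: np.ndarray
    predicted_smooth: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    significant: tuple  # per-week flag: "above" | "below" | "none"
    periods: tuple
    mean_deviation_pct: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "diagnosis": self.diagnosis,
                "stratum": str(self.stratum),
                "iso_year": [w[0] for w in self.window],
                "iso_week": [w[1] for w in self.window],
                "observed": self.observed_raw,
                "predicted": self.predicted_raw,
                "obs_smooth": self.observed_smooth,
                "pred_smooth": self.predicted_smooth,
                "ci_lo": self.ci_lower,
                "ci_hi": self.ci_upper,
                "flag": list(self.significant),
            }
        )

    def periods_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "diagnosis": self.diagnosis,
                    "stratum": str(self.stratum),
                    "start_week": f"{p.start[0]}-W{p.start[1]:02d}",
                    "end_week": f"{p.end[0]}-W{p.end[1]:02d}",
                    "direction": p.direction,
                }
                for p in self.periods
            ],
            columns=["diagnosis", "stratum", "start_week", "end_week", "direction"],
        )


def flag_periods(weeks: Sequence[tuple[int, int]], flags: Sequence[str]) -> tuple:
    """Collapse per-week flags into maximal consecutive runs per direction."""
    periods = []
    start = None
    current = "none"
    for i, flag in enumerate(flags):
        if flag != current:
            if current != "none":
                periods.append(FlaggedPeriod(start=weeks[start], end=weeks[i - 1], direction=current))
            current = flag
            start = i
    if current != "none":
        periods.append(FlaggedPeriod(start=weeks[start], end=weeks[-1], direction=current))
    return tuple(periods)


def compare(
    observed: WeeklyCountSeries,
    forecasts: Sequence[ForecastSeries],
    window_start: tuple[int, int] = DEFAULT_WINDOW_START,
    span: float = DEFAULT_SPAN,
    level: float = DEFAULT_LEVEL,
    degree: int = 2,
    quantile: str = "normal",
) -> ComparisonResult:
    """Smoothed observed-vs-forecast comparison with a pointwise band.

    ``observed`` must cover (at least) the forecast years; both series are
    smoothed over the full forecast span before restriction to the window
    so the displayed window start is free of edge effects.  A week is
    flagged "above" when the observed trend exceeds the band's upper limit
    and "below" when it undercuts the lower limit.
    """
    forecasts = sorted(forecasts, key=lambda f: f.target_year)
    weeks: list[tuple[int, int]] = []
    predicted: list[float] = []
    for f in forecasts:
        weeks.extend(f.weeks)
        predicted.extend(f.predicted)
    predicted = np.asarray(predicted)

    obs_map = {(y, w): c for y, w, c in observed.points}
    missing = [wk for wk in weeks if wk not in obs_map]
    if missing:
        raise ValueError(f"observed series does not cover forecast weeks {missing[:5]}")
    obs = np.array([obs_map[wk] for wk in weeks], dtype=float)

    obs_fit = loess_fit(obs, span=span, degree=degree)
    pred_fit = loess_fit(predicted, span=span, degree=degree)
    lo, hi = pointwise_band(pred_fit, level=level, quantile=quantile)

    in_window = np.array([wk >= window_start for wk in weeks])
    if not in_window.any():
        raise ValueError(f"window start {window_start} not covered by forecasts")
    w_weeks = tuple(wk for wk, keep in zip(weeks, in_window) if keep)

    obs_s = obs_fit.fitted[in_window]
    pred_s = pred_fit.fitted[in_window]
    lo_w, hi_w = lo[in_window], hi[in_window]
    flags = tuple(
        "above" if o > u else "below" if o < l else "none"
        for o, l, u in zip(obs_s, lo_w, hi_w)
    )
    return ComparisonResult(
        diagnosis=observed.diagnosis,
        stratum=observed.stratum,
        window=w_weeks,
        observed_raw=obs[in_window],
        predicted_raw=predicted[in_window],
        observed_smooth=obs_s,
        predicted_smooth=pred_s,
        ci_lower=lo_w,
        ci_upper=hi_w,
        significant=flags,
        periods=flag_periods(w_weeks, flags),
        mean_deviation_pct=mean_deviation(obs[in_window], predicted[in_window]),
    )
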