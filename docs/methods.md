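# Methods

## The model

The pipeline is an observed-vs-expected surveillance design for weekly
event counts. Expected (counterfactual, no-pandemic) weekly consultation
counts for 2020 and 2021 are obtained by scaling the last pre-pandemic
year's observed weekly counts by the mean between-year Pearson
correlation of weekly totals, estimated on an earlier, undisturbed
period:

    pred_{2020,w} = r̄(2017, 2018) · y_{2019,w}
    pred_{2021,w} = r̄(2017, 2019) · y_{2019,w}

r̄ is a pairs-bootstrap mean: B index-resamples (with replacement) of the
~52 (x_w, y_w) week pairs, Pearson r on each non-degenerate resample,
averaged. Resamples in which either resampled vector is constant leave r
undefined; they are excluded from the average rather than redrawn, and
the number of valid resamples is reported. The estimate, its bootstrap
SD, B, and the RNG seed are recorded in every `CorrelationEstimate`.

Model assumptions, stated plainly:

* the between-year association of weekly totals is stable across
  three-year periods, so correlations estimated on 2017–2019 transfer to
  2019–2021;
* counts in a later year are at most at the inclusion-year level
  (correlations in [0, 1] scale the forecast downward); a negative r̄ is
  refused rather than silently producing negative count forecasts;
* a correlation coefficient — a scale-free quantity — is used directly as
  a multiplicative ratio. This is the method implemented, taken as given;
  it is not a regression slope, and the package documents rather than
  repairs its statistical quirks. The most important quirk: under a true
  no-effect scenario the expected mean deviation is 100·|1 − r̄|/r̄ > 0
  whenever r̄ < 1, so measured deviations must always be read against the
  reported r̄ (rare diagnoses ⇒ noisier weekly totals ⇒ smaller r̄ ⇒
  larger baseline deviation).

Open choices resolved as package policy:

* **Bootstrap unit.** Week-index pairs (the classic pairs bootstrap on
  the aggregated series). A patient-level bootstrap — resample patients,
  rebuild both years' totals — is available as `bootstrap_mode:
  "patients"` for sensitivity analysis.
* **Per-stratum estimation.** Correlations are estimated per
  diagnosis × stratum, consistent with a fully stratified analysis.
* **Week 53.** ISO year 2020 has 53 weeks while the 2019 source has 52;
  the forecast carries the last paired source week forward. Alignment of
  two years pairs weeks 1..min(n_a, n_b), leaving week 53 unpaired.

## Smoothing and the band

`loess_fit` is a direct (exact) locally weighted polynomial regression:
at each design point the nearest floor(span·n) neighbours are weighted by
the tricube kernel and fitted by weighted least squares of degree 2
(default). The pointwise standard error is s·‖l(x)‖ with l(x) the
equivalent-kernel row of the smoothing matrix L and
s² = RSS / tr[(I−L)(I−L)ᵀ]. This reproduces R's
`loess(..., surface="direct", statistics="exact")`; the committed
96-point fixture (`tests/data/loess_reference_96pt.csv`) pins agreement
to 1e-6 (measured ~5e-11, limited by the fixture's printed precision).

Defaults: span 0.17 (17% of points per local fit — small enough to show
seasonal irregularities, large enough for an overall trend), degree 2,
99.9% two-sided pointwise band using the normal quantile
(q ≈ 3.2905); a t-quantile option keyed to user-supplied degrees of
freedom exists. The high level reflects that only one observation period
backs the forecast.

Both series are smoothed over the full pandemic span (2020-W01 onward)
on one consecutive week index (no reset at the year boundary), then
restricted to the analysis window, default 2020-W11 (the week containing
the first strict confinement measures, 2020-03-09/15) through 2021-W52.
Fitting before windowing means the displayed window start carries no
smoothing edge effect. Significance flags compare the observed *smoothed*
line with the band around the forecast trend; maximal runs of equal flags
form the reported periods.

The mean-deviation percentage is computed on **raw** weekly counts over
the window (100·Σ|obs−pred|/Σpred); a smoothed-input variant can be
computed by passing the smoothed vectors to `mean_deviation` directly.
It is invariant to common rescaling of both series and zero iff they
coincide on the window.

## Cohort and aggregation conventions

* Age is inclusion_year − birth_year; the 18–65 eligibility window and
  the age-group assignment (18–24, 25–39, 40–65) are fixed at the
  inclusion year, so nobody migrates between strata mid-series and
  patients aging past 65 during follow-up stay in the cohort.
* Membership needs ≥1 inclusion-year consultation with any of the seven
  inclusion codes, any of the eight contact types. Symptom-only (P03/P01)
  consultations can establish membership but are never analysed; a
  consultation carrying both a symptom and a disorder code is analysed.
* Weeks are ISO-8601. The weekly grid spans the dataset's ISO years and
  is zero-filled; a consultation carrying k analysis codes contributes
  one count to each of the k series.
* Re-filtering an already-filtered dataset is a fixed point except in one
  corner: a patient whose membership rested solely on a symptom-coded
  row (which filtering removed) drops out on the second pass. A second
  re-filtering is always a fixed point.

## The synthetic registry

The generator emulates the data-generating context the analysis assumes,
with known ground truth:

* **Patients.** n (default 20,000) patients draw gender (62% female),
  an age group (weights 0.15/0.35/0.50) and a uniform age within the
  band.
* **Consultation process.** Per diagnosis, weekly counts per patient are
  Poisson with intensity profile·λ₀·seasonal(w)·dip(w)·effect(y, w),
  where seasonal(w) = 1 + a·cos(2π(w − φ)/52) and dip(w) multiplies
  holiday weeks (default weeks 1, 13, 28–31, 52) by 0.55. Default λ₀ per
  week: P76 0.060, P74 0.050, P79 0.012, P82 0.012, P86 0.008 — common
  codes dominate and eating disorders are rare, as in primary care.
  25% of P76/P74 consultations carry the symptom code (P03/P01) instead
  of the disorder code, exercising the inclusion/analysis split.
* **Heterogeneity and persistence.** Each patient carries a habitual
  week-of-year profile: gamma multipliers (shape k = 2, mean 1) per ISO
  week, persisting to the next year with probability ρ = 0.8, else
  redrawn. Because the profile is shared across years, it (together with
  the shared seasonal shape) creates the positive between-year
  correlation the forecast model needs; its persistence decay makes
  r(y, y+1) > r(y, y+2); smaller k (stronger heterogeneity) raises the
  correlation; with a = 0 and k → ∞ the correlation vanishes. A
  time-constant patient multiplier cannot produce these behaviours —
  it only rescales the shared level — which is why the frailty is a
  week-of-year profile.
* **Ground truth.** Expected disorder-coded weekly counts, the injected
  effect schedule, and the model-implied between-year correlation
  r_g = (V_season + ρ^g·V_profile) / (V_season + V_profile + mean count)
  are stored with every generated dataset.
* **Effects.** Multiplicative shocks per (diagnosis, week window);
  `registration_loss` optionally drops a fraction of final-December
  consultations to emulate late registration at the year boundary
  (off by default, documented, not corrected for).
* **Dates.** Events in a boundary ISO week are dated only on the days
  falling inside that calendar year, matching registries delivered as
  per-calendar-year extracts; without this, calendar-year dataset spans
  would truncate ISO boundary weeks inconsistently.

What the generator does **not** emulate: real Norwegian demography or GP
practice structure, diagnostic drift, infection dynamics, care-seeking
behaviour change, or the actual dependence structure of registry counts.
Passing tests therefore demonstrate that the pipeline recovers effects
under the stated stochastic model — not that the model matches any real
registry.

`deterministic_mode` builds exact-oracle fixtures: weekly counts are a
fixed base pattern (multiples of 10) with 2018/2019 exact copies of 2017
(forcing r̄ = 1 with zero bootstrap SD) and pandemic years exact rounded
multiples m of 2019, so the pipeline must return mean deviations of
exactly 100·(m − 1).

## Problem sizes and numerical choices

* Stochastic validation runs use the default 20,000-patient, five-
  diagnosis configuration; effect recovery averages 10 seeds and null
  calibration 20 seeds in the test suite (5 and 8 in the acceptance
  script, which favours a quick single command). These sizes give
  binomial/Poisson noise well inside the ±5-percentage-point check
  bands.
* Bootstrap resampling is vectorised and batched (~200k draws per
  batch); Pearson r is clipped to [−1, 1] against rounding.
  Degenerate-resample exclusion is exact (zero variance test).
* Loess solves one small weighted least-squares system per design point
  (n ≈ 105 per comparison); the smoothing matrix is kept dense, fine at
  these sizes but quadratic in n.
* Mean-deviation requires Σpred > 0; bootstrap requires ≥3 pairs and
  non-constant inputs; empty cohorts yield valid empty datasets with a
  warning.

## Known limitations

* The forecast treats r̄ as fixed; bootstrap uncertainty in r̄ is
  reported but not propagated into the band.
* No multiplicity control across weeks or strata — band exceedance is a
  visual/descriptive criterion, as in the surveillance design itself.
* The structural no-effect deviation 100·|1 − r̄|/r̄ inflates effect
  estimates for low-count series; compare against the reported r̄.
* December-of-final-year undercounts from late registration are
  documented (and optionally simulated) but not corrected.
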