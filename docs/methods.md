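# Methods

## Model

Every parameter is modelled as a fixed-period 24-h sinusoid on a time axis
of hours relative to the individual's habitual sleep time (HST):

    y(t) = M + A · sin(2π (t + φ) / 24),   A ≥ 0.

The period is fixed by design; no period estimation is attempted. The
acrophase (peak time relative to HST) is `wrap(6 − φ)` with the wrap into
(−12, 12]. Because the period is fixed, the model is exactly linear in the
basis `1, sin(ωt), cos(ωt)` with ω = 2π/24: `A = hypot(b_s, b_c)` and
`φ = atan2(b_c, b_s)/ω`. Linearized estimation is therefore used
throughout — it is convex, deterministic, and identical to nonlinear
least squares for this model.

Melatonin is fitted on the natural-log pg/mL scale, which matches the
roughly log-sinusoidal shape of salivary melatonin profiles; all melatonin
MESOR/amplitude values in this package are on that scale. With the
reference winter values this puts peak melatonin at e^(0.87+3.155) ≈ 56
pg/mL, a physiologically plausible nocturnal peak, and reproduces the
published onset clock times — a base-10 logarithm does neither, which is
why natural logs are used everywhere.

### Individual and population fits

Individual series (≥ 4 observations at ≥ 3 distinct times mod 24) are
fitted by ordinary least squares. The population fit for one
parameter-season is a linear mixed model on the same basis with
independent per-subject random effects on intercept, sin and cos
coefficients (REML, `statsmodels` MixedLM with a variance-component
parameterisation); the fixed-effect vector is transformed back to polar
(M, A, acrophase). Whether the original analyses placed random effects on
(M, A, φ) directly or on linearized coefficients is not documented; the
linearized choice is verified by parameter recovery rather than by
matching published interval estimates. If the mixed model fails to
converge — or the data are exactly noise-free, where REML is ill-posed —
the two-stage estimator (mean of individual coefficient vectors) is used
and flagged `two_stage`. A single-participant "population" degenerates to
that participant's individual fit.

Confidence intervals, when requested, are nonparametric percentile
bootstrap over participants (default 1000 resamples, seeded) of the
two-stage estimator; for a balanced design its fixed effects track the
mixed model closely while being orders of magnitude faster, and the
acrophase resamples are wrapped around the point estimate before taking
percentiles. Intervals are flagged with their method; they are not meant
to reproduce any published intervals, whose construction is unstated.

Degenerate amplitudes (< 1e−12 in value units) have no defined phase; the
acrophase is then reported as 6 with a `degenerate` flag — a deterministic
tie-break, never fed into circular statistics.

### Diurnal-variation test

The presence of any diurnal variation is tested per parameter-season with
a subject-blocked two-way layout: subject as block, measurement epoch as a
repeated fixed factor, F computed from the residual-sum-of-squares
comparison of the dummy-coded models with and without epoch (for the
balanced design this is the classical repeated-measures epoch F with
(k−1, N−n−k+1) degrees of freedom). An optional permutation p-value
permutes epoch labels within subject (default 999 permutations, seeded).
Under the generating model the analytic test is exact, which the
calibration study confirms (rejection rate 0.05 at α = 0.05 over 1000
rhythm-free cohorts).

### Melatonin onset (DLMO)

The onset is the rising solution of `log y(t) = log(3 pg/mL)`:

    DLMO = (24/2π) · asin((ln 3 − M)/A) − φ.

The principal asin branch lands the solution on the rising limb, in the
half-period before the acrophase, which is what an onset must be. The
onset is undefined when the curve never crosses the threshold
(|ln 3 − M| > A) or the amplitude is zero. A dense-scan reference
(`dlmo_scan`, grid + bisection) exists purely as an independent
cross-check; the analytic and scanned crossings agree to ~1e−9 h over
randomized fits.

φ in this formula is the sine-phase parameter reconstructed from a
reported acrophase as φ = 6 − acrophase. Only this reading makes the
published relative acrophases, onset clock times and HST anchor mutually
consistent.

### Season comparison

Per-parameter seasonal contrasts are paired per-participant differences of
the individual-fit MESOR, amplitude and acrophase, the latter wrapped into
(−12, 12] (negative = advance, positive = delay). Wrapped differences are
compared with a one-sample t-test, falling back to the Wilcoxon
signed-rank test when Shapiro–Wilk rejects normality at 0.05 (zeros
dropped, the standard signed-rank convention); observed phase spreads are
well below the 12-h wrap radius, so linear tests on wrapped differences
are valid and full circular statistics are unnecessary. p-values are
Holm-adjusted across parameters within each quantity. Degenerate contrasts
(identical seasons) report p = 1 with a flag rather than NaN.

Phase relationships between two parameters are summarised by the signed
circular acrophase separation, with `antiphase_distance = 12 − |separation|`
so 0 means exact antiphase.

### Growth classification

Interval ΔAL is the difference of *time-matched* model AL: each season's
fitted sinusoid evaluated at a common set of HST-relative reference times
(default: the six evening epochs, averaged). This removes the diurnal
component from between-season differences; when two fits share a phase,
the time-matched difference equals the MESOR difference at every reference
time, and that invariance is tested. ΔChT uses the MESOR difference
directly, matching how choroidal seasonal change is conventionally
reported; the AL phase shift is the circular acrophase difference.

The coordinated-growth band (axial elongation without refractive change)
is 0.030 < ΔAL ≤ 0.089 mm per 12 months; for an interval of *m* months the
bounds scale by m/12 and are quantized to 3 decimals with exact halves
rounded *down*, because 0.030 × 7/12 = 0.0175 must give the published
7-month lower bound 0.017 (truncation would corrupt the upper bound,
0.051916… → 0.051 instead of the published 0.052). The 7-month scheme has
three categories (decelerated < 0.017 ≤ coordinated < 0.052 ≤ accelerated);
the annual scheme four (shortening ≤ 0 < no-growth ≤ 0.030 < coordinated
≤ 0.089 < accelerated). At exactly 0.017 the published category ranges
overlap; this package treats 0.017 and 0.052 as the cut points with the
inclusivities above.

Associations are ordinary least-squares regressions of ΔAL on ΔChT and on
the AL phase shift, plus a one-way ANOVA of ΔAL across growth categories
with Tukey HSD pairwise comparisons (α = 0.05); a category with fewer than
two members degenerates the ANOVA and is flagged instead of tested.

## Time conventions

Clock times are 24-h `HH:MM` (fractional minutes accepted on input),
decimal hours internally, rendered by rounding to the nearest minute.
Evening epoch labels encode their HST offset literally; morning labels are
anchored to habitual wake time wrapped into the waking day, so HWT+1 with
wake 07:30 / sleep 23:30 is −15 h. The group HST anchor used to render
HST-relative times as clock times, 00:07.6, is recovered from the
published melatonin row (clock acrophase 04:07 minus relative acrophase
3.99 h); HST did not differ between seasons, so one anchor serves both.
Whether morning epochs should be timed against self-reported or
actigraphy-derived wake times is unresolved in the source design;
`t_rel` is accepted as given in the input table.

Retinal and choroidal thicknesses are stored in µm (and converted on use,
e.g. inside the VCD identity AL − (ACD + LT + RT)); all other distances in
mm, IOP in mm Hg, melatonin in pg/mL on disk and log pg/mL in fits.

## Synthetic cohort generator

The generator is the package's study-design emulator: n = 24 participants
(configurable), HST drawn around 00:08 (SD 0.9 h), waking span 16 ± 0.6 h,
eight epochs placed by the same epoch-timing rule the analysis uses
(melatonin sampled at seven: morning HWT+4 has no saliva sample). Each
parameter-season has a true population (M, A, acrophase) defaulting to the
published estimates; subjects get independent normal effects on each
(amplitude truncated at 0, acrophase wrapped), drawn **once** per subject
and shared across seasons — rhythm traits are persistent within a person,
and seasonal change enters through the season-specific population truth.
Residual noise is i.i.d. normal per observation; melatonin is generated on
the log scale and exponentiated. A single `numpy` Generator seeded from
one integer drives everything, so cohorts are bit-reproducible.

Variance components are not published, so the defaults are this package's
choices, stored in `DEFAULT_VARIABILITY` (and in YAML configs), chosen
once as follows:

- **MESOR between-subject SD**: back-calculated from the published
  population 95% CIs as SE·√24. This reproduces the printed cohort
  spreads (e.g. 1.37 mm for AL against a reported cohort SD of 1.4 mm).
- **Amplitude between-subject SD**: the same back-calculation capped at
  A/3. The CI-implied value conflates estimation error with heterogeneity
  and, taken at face value, would leave several subjects per cohort with
  essentially no rhythm and an undefined phase — a qualitative feature
  real cohorts do not show.
- **Acrophase between-subject SD**: 0.5 h for every parameter. Anchoring
  the time axis to each individual's HST removes chronotype, the dominant
  source of inter-individual phase variance; the published phase-contrast
  t-statistics imply per-subject phase spreads of this order.
- **Residual SD**: instrument/assay repeatability scale (e.g. 4 µm for
  IOLMaster axial length, 0.35 log-units for melatonin ELISA, 1 mm Hg for
  rebound tonometry).

The growth generator adds known per-participant interval ΔAL (W1→S and
S→W2, additive by construction, so annual change is exactly their sum),
with ΔChT and the AL phase shift generated as linear functions of ΔAL plus
noise sized to hit target structural R² values (defaults 0.54 and 0.81).

What the generator does *not* emulate: non-sinusoidal waveforms,
season-specific subject effects, missing epochs, correlated random effects
across parameters (each parameter's subject effects are independent, so
cross-parameter phase relations are population-level only), assay
nonlinearity, and measurement-time jitter around the scheduled epochs.
Passing tests therefore demonstrate that the estimators recover the truth
under the stated design and noise model — not that real data satisfy that
model.

## Validation studies and problem sizes

The simulation studies (module `oculorhythm.studies`, shared by the test
suite and `scripts/acceptance.py`) use these sizes, chosen to give stable
Monte-Carlo summaries:

- melatonin parameter recovery: 500 cohorts of n = 24 (observed MESOR and
  amplitude bias ≲ 1%, acrophase MAE ≈ 0.09 h). A known property of the
  linearized population estimator is a small downward amplitude
  attenuation of (ωσ_phase)²/2 from between-subject phase dispersion —
  ≈ 0.9% at σ_phase = 0.5 h;
- diurnal-test calibration: 1000 rhythm-free cohorts for size, 500 at the
  published axial-length amplitude for power;
- oracle equivalence: 10 random series against a 0.01-h acrophase grid
  search with profiled M and A, and 1000 random melatonin fits against the
  dense-scan onset;
- seasonal-shift recovery: 200 two-season cohorts with a −1.0 h
  axial-length acrophase shift injected; the mean detected shift is
  −1.01 h and is Holm-significant in every replicate;
- growth associations: 100 cohorts; the fitted ΔAL∼ΔChT R² distribution
  covers its structural target (0.54). The fitted ΔAL∼phase-shift R²
  sits well below its structural 0.81 because per-subject phase estimates
  carry substantial noise relative to the true shift spread — a classical
  errors-in-variables attenuation that is reported, not hidden.

## Known limitations

- The published lens-thickness row is internally inconsistent (its
  relative acrophases imply a −28-minute change, its clock times +16
  minutes); LT is excluded from clock-time cross-checks and the
  discrepancy simply recorded. Likewise the published onset
  seasonal-change cell (−00:47) disagrees with its own clock times
  (22:20 → 21:17 is −63 min); the clock times are reproduced, not the
  change cell.
- Published group-level quantities that depend on the unavailable raw
  cohort (interval estimates, exact F statistics, the observed 9/10/5
  seven-month category split) cannot be recomputed and are not targets;
  the package validates against synthetic truth instead.
- Bootstrap CIs use the two-stage estimator within resamples; with few
  participants they can undercover, as subject-level bootstraps do.
- The Wilcoxon fallback is triggered per contrast by a normality pretest,
  a pragmatic mirror of the original analysis strategy rather than a
  recommendation for pretest-based inference.
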