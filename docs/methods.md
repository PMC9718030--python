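# Methods

## Scope and pipeline

`pmhia` computes the mortality burden attributable to annual-mean PM2.5
above a counterfactual concentration for a set of administrative units, each
described by (a) one exposure value (optionally aggregated from grid cells)
and (b) an all-age mortality schedule on 5-year bands with an open terminal
interval. Per unit and 5-year adult age group it reports the attributable
fraction (AF), attributable deaths (AD), years of life lost (YLL) and, per
unit, the loss of life expectancy at birth (LLE), with 95% intervals, and
rolls districts up to provinces and the study region.

## Risk models

**GEMM NCD+LRI.** The packaged hazard-ratio parameters are the age-specific
NCD+LRI table of Burnett et al. (2018, PNAS 115:9592), 41-cohort fit
including the Chinese cohort: shared α = 1.6, μ = 15.5, ν = 36.8 µg/m³ and
θ falling from 0.1585 (SE 0.01477) at 25–29 to 0.1141 (SE 0.01071) at 80+.
The published table ends at an open 80+ band; here both 80–84 and 85+ carry
those values so the schedule's bands are covered one-to-one. The curve's
internal counterfactual (z = max(0, C − 2.4)) is retained regardless of the
policy counterfactual, which enters only through
AF = 1 − HR(C₀)/HR(C). Exposures at or below the policy counterfactual give
AF = 0 (no negative burden); such units stay in every output with a
`below_counterfactual` flag so maps and sums remain total.

**Log-linear comparison.** The AirQ+-style alternative uses
RR = rr₁₀^(ΔC/10) with rr₁₀ = 1.062 (95% CI 1.040–1.083) by default,
configurable, and applies to ages 30+ only, with AF = 1 − 1/RR. The
comparison table reports the log-linear AD rate per 100,000 of the 30+
population and the GEMM AD rate per 100,000 of the standard reporting
denominator (total population by default) — deliberately different base
populations, mirroring how the two tools are conventionally reported. This
denominator difference, not the AFs themselves, is what makes the log-linear
column exceed the GEMM column uniformly across the packaged province range
(15.8–40.8 µg/m³): at the low end of that range the GEMM AF is actually the
larger of the two.

## Life tables

Abridged period construction on the schedule's bands:
nqx = n·nMx/(1 + (n − nax)·nMx) with nax = n/2 = 2.5 years for every closed
interval (the inputs are sex-aggregated 5-year counts, which cannot support
infant-separation refinements; an `a0` override is exposed for
Coale–Demeny-style choices). The open interval assumes a constant hazard:
nqx = 1, nLx = lx/nMx, hence ex(open) = 1/nMx. nqx values above 1 are
clamped with a logged warning. YLL weights use the ex of the band as
constructed (band start). LLE is the difference in e0 between the observed
schedule and the counterfactual schedule with each adult band's deaths
scaled by (1 − AF); it is computed in days internally and reported in years
(÷365.25). The headline LLE is at birth; per-band ex of both schedules is
available through the life-table API.

## Uncertainty

Intervals evaluate the entire pipeline (AF → AD → YLL → LLE) at θ and
θ ± 1.96·SE(θ) per age group, treating the θ uncertainty as perfectly
correlated across ages — the conventional deterministic GEMM practice, and
exactly reproducible. A Monte-Carlo alternative (`ci_method="montecarlo"`)
draws one standard-normal deviate per replicate shared across ages, with a
fixed seed, and reports 2.5/97.5 percentiles. Baseline rates and populations
are treated as fixed. For the log-linear model the bounds come from the RR
confidence limits. All triplets satisfy low ≤ point ≤ high by construction
(AF is monotone in θ and in RR).

## Aggregation

Counts (AD, YLL) sum over districts; rates are recomputed from summed counts
over summed denominators, never averaged. Province and study-region LLE is
recomputed from the pooled schedule (band-wise summed populations and
deaths) with pooled per-band AFs (ΣAD/Σdeaths); a population-weighted mean
of member LLEs is available via `province_lle="weighted"`. The default rate
denominator is the total all-age population — chosen because published
rate-per-100,000 figures for this kind of assessment are typically quoted
against total population even when the exposed group is adults — with an
`adults-only` option.

## Exposure aggregation

District exposure is the mean of member grid-cell annual means — uniform by
default (a cell-centroid reading of "aggregated per district"), optionally
weighted by a supplied cell weight (area fraction or population). Monthly
cell values collapse to annual means unweighted by default, with a
calendar-day-weighted option (non-leap year). The canonical interchange is a
flat CSV of cells; no GIS dependency is required.

## Synthetic data

The generator emulates the study conditions of the packaged 2019 table:
11 provinces (3 districts each by default), province adult (25+)
populations log-uniform on 0.29–5.8 M, crude adult death rates uniform on
4.1–8.3 per 1,000, district exposure means spanning 15.8–40.8 µg/m³. When a
province summary table is passed, those marginals are pinned to its values
instead and only the age structure remains synthetic.

* **Age pyramid:** stable-population shares, share(x) ∝ S₀(x)·e^(−g·x),
  where S₀ is the survivorship of the default hazard and g = 0.008/yr. This
  yields a 61% adult share — consistent with the ratio of the packaged
  adult populations to the total-population denominators implied by
  published rates — and an old-age (85+) share of ~2.5%.
* **Hazard:** Gompertz–Makeham μ(x) = a·e^(bx) + c with a = 3.5×10⁻⁵,
  b = 0.095, c = 5×10⁻⁴ (1/yr), scaled multiplicatively per district so the
  realized crude 25+ rate hits its target exactly before death-count
  rounding. Unattainable targets (band rates ≥ 0.95/yr) are rejected with
  the achievable range. Deaths are rounded expectations by default;
  a seeded Poisson mode draws from a dedicated stream so it perturbs only
  the counts, not the structural draws.
* **Exposure field:** per-district g×g Gaussian noise smoothed with a
  normalized exponential kernel (periodic boundaries), recentred on the
  district target mean; district targets are the province mean ± an evenly
  spaced jitter (default ≤1.5 µg/m³). Larger correlation lengths drive the
  within-district variance toward zero.

Because crude adult rates near 4–8 per 1,000 with a 61% adult share imply
genuinely low mortality, the calibrated synthetic life tables have high life
expectancies; the same property is latent in the published marginals
(registry under-coverage is one plausible cause). Passing tests on synthetic
data therefore demonstrates the arithmetic and its invariants, not the
realism of any specific province's age structure — the synthetic pyramid is
smooth, sex-aggregated and free of migration, cohort bulges and infant
mortality concentration.

## Numerical choices and verification

* The life-table implementation is verified against an independent
  discrete-time cohort microsimulation (10⁶ persons, yearly Bernoulli
  survival with q = 1 − e^(−m), half-year credit in the death year, run to
  extinction): e0 and every ex agree within 0.5% relative error across 25
  randomized Gompertz–Makeham schedules. Problem sizes throughout the suite
  (10⁶-person cohorts, 33-district regions, 6×6 cell grids) were chosen to
  keep the full run in seconds while leaving sampling error well below the
  tolerances checked.
* Closed-form reference values for the GEMM hazard ratio and AF were frozen
  from a stand-alone evaluation before the implementation and are asserted
  to 12 significant digits.
* Report tables round AD to integers and rates/YLL/LLE to one decimal;
  all internal computation is full precision. Writers are deterministic
  (stable column order and rounding), and every run emits a manifest with
  input SHA-256 digests, the parameter-file version and the config echo.

## Known limitations

* Only the NCD+LRI GEMM outcome is packaged; the 5-COD split and IER/GBD
  curves are out of scope, as are morbidity endpoints and economic
  valuation.
* LLE uses period life tables (no cohort projection) and the perturbation
  removes attributable deaths proportionally within bands.
* The raster (GeoTIFF/polygon) exposure path is not implemented; grid cells
  arrive pre-assigned to districts in the flat CSV. Cells straddling
  borders must be resolved upstream (centroid assignment is the assumed
  rule).
* Exact reproduction of published province-level burden tables requires the
  underlying age-stratified counts, which are not public; the calibrated
  synthetic runs match marginals only.
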