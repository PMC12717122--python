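# Methods

This note documents the statistical model behind `modefire`, the choices
made where the design was genuinely open, what the synthetic generator
does and does not emulate, and the numerical conventions that affect
results.

## Study design

The package targets the large-ensemble design for teleconnection
analysis: many independent realizations (members) of a decade of climate
under fixed forcing, so that member-years can be pooled as exchangeable
samples of internal variability. The canonical configuration is 160
members × 10 years = 1600 member-years per time slice, with two time
slices (a recent climate and a +2 °C climate) processed separately —
climatologies, anomalies and mode indices are never mixed across slices.
Within-member year-to-year autocorrelation is ignored when pooling; for
modes with modest annual autocorrelation and a 10-year member length this
is a small effect, but it is a known limitation, not a theorem.

## Mode indices

Anomalies are computed per calendar month against the climatology pooled
over all members and years of the slice; "standardised anomalies" divide
by the pooled per-calendar-month standard deviation (per cell for box
recipes). The pooling choice maximizes sample size and is appropriate
because a fixed-forcing decade is stationary by construction.

Box means weight cells by cos(latitude). EOF indices weight the anomaly
matrix by √cos(latitude) so the decomposed covariance is area-weighted;
one decomposition pools all member-months of a slice. The PNA-style
recipe averages anomalies over DJF (December from the previous calendar
year) per member-year *before* the decomposition, so its index is
directly annual and the first year of each member is undefined. The PC of
the configured rank is standardized to unit variance. Near-degenerate
leading eigenvalues (relative gap < 1e-6) are flagged in the output
metadata rather than rejected.

EOF orientation: the eigendecomposition's sign is arbitrary, so each PC
recipe carries a reference box and an expected regression sign; the PC is
flipped until the regression of the field on the index over that box has
the expected sign. This makes the index a deterministic function of the
field. Note what it cannot do: the PC is a linear functional of the data,
so negating the entire input field negates the index exactly (and leaves
the loading map unchanged); no orientation convention can make the series
itself invariant under a global field flip.

Tropical-Atlantic box indices (TNA/TSA) are left in physical units
(anomaly K) rather than standardized: the downstream regression is
scale-free, so only sign conventions matter. The SOI-style recipe
standardizes each box series before differencing; the DMI-style recipe
standardizes the differenced series.

Annual windows that start in the previous calendar year (NDJFM, DJF, NDJ)
leave the first year of each member missing; missing values are never
imputed, and the affected member-years are dropped pairwise from any
analysis using that index. The same applies to one-year-lagged indices;
member boundaries never mix.

Phases use the half-standard-deviation rule with strict inequalities:
values exactly at ±0.5σ are neutral. The σ is pooled over all non-missing
member-years of the slice. For a Gaussian index this leaves ≈38.3% of
years neutral and ≈30.9% in each active phase.

Longitudes are normalized to [−180, 180); boxes crossing the antimeridian
(North Pacific recipes) are handled as the union of the two segments, so
0–360 and ±180 input encodings give identical results.

## Fire association

The per-cell model is ordinary least squares of annual fire counts on the
raw index value, with a two-sided t-test for zero slope. OLS on counts
(rather than a Poisson GLM) matches the scale-free questions being asked
— sign, significance, and relative effect — and at the ensemble's sample
sizes the t-test is robust to the mild non-normality of Poisson annual
totals. The implementation is vectorized closed-form across cells and is
cross-checked against a conventional per-cell OLS fit in the tests.

Field significance uses the Benjamini–Hochberg step-up across all
analysed cells of one mode and lag at α_FDR = 0.01 (a configuration
knob). The family is per mode per lag; modes are not jointly corrected,
because each mode's map is reported separately. No inflation of α_FDR for
spatial correlation is applied: the synthetic tests verify control under
independence, and the empirical false-discovery proportion under the
global null is ≈ α_FDR because any rejection under the null is false.

Phase-ratio maps divide the phase-conditional mean annual count by the
all-year mean at the same cell, using only member-years with a defined
phase label; this makes the phase-frequency-weighted sum of the three
ratios exactly 1 at every cell with nonzero mean (an identity the tests
check to machine precision). Cells with zero all-year mean are undefined
and omitted.

The multimode regression standardizes each index (pooled mean/SD over its
non-missing member-years) and takes the response as annual count divided
by the cell's all-year mean, so coefficients are comparable across cells
and modes. The design's condition number is reported; condition numbers
above 1e8 are rejected with the worst offending index correlation named.
Coefficient standard errors come from the homoskedastic OLS covariance.

Cross-phase tables condition domain-total annual fires on one mode's
phase (rows) and report the percentage deviation of the conditional mean
under a second mode's phase (columns) from the row baseline, with
conditional sample sizes; empty cells are reported missing, never zero.

Climate-change comparisons divide phase ratios (future ÷ recent) only
where the association is significant in both slices; every cell also
receives sign codes in both slices from which extent transitions
(e.g. not-significant → significant-positive) are read.

## Seasonality

Months sit on the annual circle at θ_m = 2π(m−1)/12 (January at angle 0).
The convention is arbitrary but harmless: all reported quantities are
either rotation-equivariant (mean phase) or rotation-invariant
(concentration, season length), so phase *differences* are
convention-independent. Phase-conditional mean phases are computed from
composite profiles (counts summed over the phase's member-years), which
is robust when individual years have few fires; differences are wrapped
to (−6, +6] months. Cells with all-year concentration below 0.15 have no
distinct seasonal peak and are excluded from shift maps.

Season length counts months whose counts *strictly* exceed half the
climatological peak (the ensemble-mean count of the maximum month); ties
at exactly half-peak are excluded, and peak-month ties resolve to the
earliest month (affecting only reporting, not length). Each member-year
is counted separately and averaged, optionally within a phase.

## Small-sample diagnostics

Subsample correlation distributions draw year sets of size 30 at random
(without replacement within a draw, ignoring member boundaries — the
member-year pool is exchangeable by design; a contiguous-block option
exists for sensitivity). The phase-mean bootstrap resamples *with*
replacement from all years at the phase's sample size, 10,000 replicates
by default; with-replacement is the standard bootstrap and a
without-replacement switch is provided. Reported box statistics are
exactly the {2.5, 25, 50, 75, 97.5} percentiles of the stored replicate
vector. The outside-95%-band flag is calibrated (≈5% under random labels)
when the phase sample is small relative to the pool, which is the
intended use case — positioning a ~30-year reanalysis phase against a
1600-year ensemble; when the phase occupies a large fraction of the pool
the comparison is conservative.

## Synthetic generator

Latent modes are stationary AR(1) series with unit variance; declared
cross-mode correlations are realized exactly in expectation by setting
the innovation covariance to R·(1 − a_i·a_j), and the sampled series are
then standardized exactly (pooled mean 0, SD 1), which preserves Pearson
correlations. Fields embed each mode as loading(cell) × latent(year),
constant within the year, plus iid Gaussian noise — so at zero noise
every recipe recovers its latent up to sign/scale, and recovery degrades
smoothly with the noise-to-loading ratio.

Fire counts are Poisson with log-rate = log(base profile) + Σ β·latent:
annual counts of rare events are approximately Poisson, and the log link
makes β a relative-risk coefficient per unit index. Under this law the
OLS slope of annual counts on a unit-variance index has expectation
μ·β·exp(β²/2), which the recovery tests use. Over-dispersion is available
as a gamma-Poisson (negative-binomial) switch, off by default. Seasonal
phase shifts rotate the 12-month profile by fractional months via
circular linear interpolation; concentration modulation tilts the profile
(p^(1+amp·latent), renormalized to conserve the annual total). Lagged
effects pair year-t counts with the year-(t−1) latent; the first year of
each member has no lagged predictor and receives the climatological rate.

What the generator does **not** emulate: real atmospheric dynamics,
spatial autocorrelation of weather noise, teleconnection nonstationarity,
the fire-occurrence process's dependence on fuel/human factors, or
spatially correlated count residuals. Passing tests therefore demonstrate
that the *statistical machinery* is correct and calibrated under the
stated assumptions — not that those assumptions hold for any particular
real ensemble.

## Problem sizes and defaults

The canonical recovery configuration mirrors the study design: 1600
member-years, a 20×30-cell fire grid (600 cells), effect sizes β ∈
{0, 0.2}, base rate 5 fires/month/cell. At these sizes the per-cell test
has overwhelming power (t ≈ 30 at β = 0.2), so sensitivity ≥ 0.95 and
empirical FDR ≤ 0.02 are comfortable margins, and the whole suite runs in
well under a minute of compute for this stage. Default thresholds: phase
½σ, α_FDR 0.01, concentration cut 0.15, bootstrap 10,000 replicates —
all exposed in `RunConfig`. Demonstration worlds (docs, CLI smoke runs)
use 25 members × 10 years to keep examples instant; nothing in the code
depends on that size.

## Known limitations

* Exchangeability ignores within-member autocorrelation (indices with
  high AR(1), e.g. decadal modes, mildly overstate effective sample size).
* No spatial model for residuals; α_FDR is applied uncorrected for
  spatial dependence of the tests.
* Seasonality statistics assume a unimodal season; bimodal regimes fold
  into a single resultant and lose structure.
* OLS on counts, not a count GLM: adequate for sign/significance/ratio
  questions at large n, not for rate prediction.
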