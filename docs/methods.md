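# Methods

This note documents the models, numerical choices and synthetic study
design behind `frostring`, and what the validation experiments do and do
not demonstrate.

## Leaf-out forcing model

Daily forcing is `R_i = (L_i/10)^k · (T_i − T_b)` for `T_i > T_b`, else 0,
accumulated from calendar day `t0`; predicted leaf-out is the first day the
accumulated forcing reaches `F_crit`. With `k = 0` the model collapses to a
plain growing-degree-day model. Parameters, units and defaults:

| parameter | meaning | unit | default box |
|---|---|---|---|
| `t0` | start of forcing accumulation | DOY | [1, 90] |
| `T_b` | base temperature | °C | (0, 10] |
| `k` | photoperiod response exponent | – | [0, 10] |
| `F_crit` | forcing threshold | forcing units | [1, 5000] |

The box endpoints enforce two biological constraints — forcing cannot start
before 1 January and the base temperature must be positive — and enclose
published optima for European beech (`t0 = 3`, `T_b = 0.29` °C, `k = 4.76`,
`F_crit = 1248`), which the synthetic generator uses as ground truth.

**Daylength.** The model needs `L_i` but no single formula is canonical;
we use the CBM model (Forsythe et al. 1995) with the refraction-corrected
sunrise/sunset angle (0.8333° below the horizon). The angle is a single
module constant (`TWILIGHT_ANGLE_DEG`) and can be swapped for, e.g., the
civil-twilight definition (6°); `F_crit` values are only comparable across
studies using the same convention. Values are clamped to the open interval
(0, 24) h because at the edge of the supported latitude band (|lat| ≤
66.5°) the midsummer sun never crosses the twilight horizon. Day of year is
computed per calendar; no leap-day adjustment is applied (≤ 1 d effect,
below the model's precision).

**Calibration.** The objective is the RMSE between predicted and observed
leaf-out DOY over all site-years. Site-years where the threshold is never
reached are scored as DOY 250, which bounds the objective and pushes the
optimiser out of non-emerging parameter regions. The objective is piecewise
constant (integer-day predictions), so the default engine is generalised
simulated annealing (`scipy.optimize.dual_annealing`, local search
disabled), seeded and therefore deterministic; defaults follow the common phenology
calibration protocol (initial temperature 10 000, up to 40 000 model
calls). The contract is only "seeded global minimiser of the RMSE within
the box", so any derivative-free global method is conforming. Internally a
precomputed (site-year × DOY) temperature matrix and per-site log-
photoperiod table make one objective evaluation a handful of vectorised
array operations.

Recovery is judged on *predictions*, not parameter values: the objective is
nearly flat along correlated ridges (e.g. `F_crit` against `k` and `t0`),
so predictively equivalent optima with very different parameter vectors are
expected and unproblematic.

**Cross-validation.** Site-years are sorted by (site, year) and permuted
with a seeded generator before being dealt into folds, making folds
invariant to input ordering. Each fold is calibrated on the remainder at a
reduced optimiser budget. The fixed-mean-date null model is evaluated under
the identical folds.

## Frost risk

A frost is any day with `tmin ≤ −1.0` °C. The threshold is deliberately
inclusive (and configurable): on clear calm nights radiative cooling drives
bud tissue several degrees below screened 2-m air temperature, so a
stricter threshold misses damaging events. The vulnerability window is
[leaf-out − 5 d, leaf-out + 14 d], inclusive on both ends — buds are
hardier before swelling, while young leaves harden only gradually after
emergence. The last spring frost is searched in DOY 1–181 (through June);
the cutoff is configurable since the margin statistics never reference
later dates. Years without a leaf-out prediction yield absent margins and
are excluded from trend sample sizes.

Trends are Theil–Sen slopes (reported per decade) with the rank-based 95 %
CI from `scipy.stats.theilslopes` and a two-sided Mann–Kendall test with
tie-corrected variance and continuity correction, implemented in-package
and cross-checked in the tests against a brute-force enumeration of the S
statistic. No autocorrelation correction is applied, matching standard
usage for these annual series. The plotted margin summary uses a 10-yr
centered moving average requiring ≥ 6 non-missing years.

## Ring-width processing

Ring widths are read from Tucson/RWL decadal files; the series stop marker
(999 vs −9999) selects 0.01 vs 0.001 mm precision, and only the *final*
value of a series is treated as a marker so a genuine 0.999 mm ring
survives a round trip.

**Detrending.** Each core is divided by a cubic smoothing spline whose
frequency response is 50 % at a 30-yr wavelength — the standard compromise
that removes age/size trends and disturbance while keeping interannual
climate signal. The spline solves `min Σ(y−g)² + λ∫g″²`
(`scipy.interpolate.make_smoothing_spline`), whose equivalent filter on
unit-spaced data is `H(f) = 1/(1 + λ(2πf)⁴)`; setting `H = 0.5` at
`f = 1/30` gives `λ = (30/2π)⁴ ≈ 520`. An FFT oracle test confirms the
fitted curve retains 50 ± 5 % of a 30-yr sinusoid's amplitude. Division
(ratio) indices are used, keeping RWI dimensionless around 1. If a fitted
curve dips to ≤ 0 (possible in strongly suppressed segments) the series
falls back to a linear fit, then to the series mean, with the fallback
logged and recorded in the series notes.

**Chronologies.** Cores are averaged per tree (single-core years pass
through, flagged in the metadata); trees are combined per site and species
with Tukey's biweight robust mean (tuning constant 9, median/MAD start,
iterated to 1e−8 or 50 iterations; the median is returned when MAD = 0).
Sample depth is recorded per year and shallow years (< 6 trees) logged.
Quality statistics follow convention: `rbar` is the mean pairwise Pearson
correlation over pairs overlapping ≥ 20 yr and
`EPS = n·rbar/(n·rbar + 1 − rbar)`; first-order autocorrelation and mean
sensitivity are averaged over the individual tree series. Crossdating is
assumed done upstream; a discarded tree is expressed as an exclusion list
in the pipeline config, not detected automatically.

## Residual frost indicator

For each sensitive-species tree, the raw residual is tree RWI minus the
reference-species *site chronology* (an integrative reference that carries
the shared climate signal), standardised to z-scores with the mean and SD
of the tree's full overlap period (≥ 20 yr required). The site "residual
chronology" is the plain per-year mean of the z series — robust averaging
is unnecessary after standardisation and keeps the chronology's units
interpretable as mean z.

A year is called a frost year when the fraction of contributing trees with
z < −1.0 reaches 0.60 ("severe" when the fraction below −1.5 also does).
The threshold is implemented as ≥ 0.60: with 12 trees the supermajority
boundary (7.2 trees) is unattainable, so ≥ and > differ only at exactly
60 %, and ≥ is the safer reading of "at least 60 %". Years with fewer than
3 contributing trees are not evaluated, avoiding spurious fractions at low
sample depth. All thresholds are configurable.

Tree-ring calls are then cross-tabulated against the climate/phenology
window rule; for discordant years the record keeps the last-frost date as
an out-of-window candidate for manual inspection.

## Growth–climate response

The daywise correlation grid aggregates a daily variable per year over
every (start DOY, window length) combination — mean for temperatures, sum
for precipitation — and computes Pearson r against the chronology across
years (prefix sums make the grid linear in total cell count; the tests pin
the implementation to a per-cell loop oracle exactly). Default grid:
starts 1–270, lengths 15–90 in steps of 5. Windows extending past DOY 365
and zero-variance aggregates are skipped. Correlations are masked at raw
p < 0.05 when plotted; no multiple-testing correction is applied across
the grid, so isolated significant cells must be interpreted with caution.

Superposed epoch analysis measures the mean chronology departure from its
overall mean at lags 0..+4 around event years. The null distribution draws
`n_boot` (default 999) pseudo-event sets of equal size, with replacement,
from all years with full lag coverage; a lag is significant when the
observed anomaly falls outside the null's central 95 % interval. Reported
intervals are of (observed − null), so "0 outside the interval" is the
significance criterion. Events lacking lag coverage are dropped with a
warning. Because the test level is 5 %, isolated false positives (e.g. a
reference-species lag-0 call in one replicate) are expected at that rate.

## Synthetic study design

The generator emulates a two-site, two-species mountain design: 12 trees ×
2 cores per species per site over 92 years (1930–2021). Defaults represent
the high site: mean annual temperature 4.7 °C, seasonal half-amplitude
8.5 °C with the coldest day in mid-January, AR(1) daily anomalies
(ρ = 0.7, SD 3 °C), diurnal range 8 °C (the low site uses 6.3 °C mean
temperature). Frost events are dips applied to `tmin` only, emulating
radiative-cooling nights with large daily amplitude. Leaf-out observations
are the true model's predictions plus rounded Gaussian noise (SD 7.5 d by
default, matching the typical uncertainty of volunteer phenology networks).

Ring widths are `w₀·exp(−λ·age) · exp(β·z + ε) · m` with initial width
3 mm, decay 0.01 yr⁻¹, a shared standardised summer index z (mean tmax of
DOY 160–220) with β = 0.3, lognormal tree noise (SD 0.2) plus smaller core
noise (SD 0.05), and `m = 0.4` in frost years for the sensitive species
only. The damage multiplier is a modelling choice — extreme frost years
leave indices around 0.4 — not an empirically fitted value. An optional
common-stress multiplier applies to *both* species, used to verify that a
shared drought cannot produce a frost flag.

Fixture frost events are placed 3 days after each year's predicted
leaf-out with a 12 °C dip: leaf-out deterministically follows warm spells,
so the realized `tmin` near leaf-out is warm-biased under AR(1) persistence
and a shallow dip would not reliably cross the −1 °C threshold — itself a
faithful miniature of the false-spring phenomenon.

What the generator does *not* emulate: spatial interpolation error and
elevation lapse physics, masting-induced growth reductions, drought–frost
co-occurrence, measurement/crossdating error, and within-population
phenological spread. Passing tests therefore demonstrate correctness of
the algorithms and their power under idealised signal structure, not field
performance on real archives.

## Validation problem sizes

Chosen to represent the study conditions at desk scale: phenology recovery
uses 40 sites × 30 yr (1200 site-years, zero observation noise, optimiser
budget 4000 calls); cross-validation uses 12 sites × 30 yr with 5 d
observation noise, 10 folds at 1500 calls each; indicator power uses 50
replicates of 90-yr sites with 3 randomly placed frost years each; SEA
uses the standard two-site fixture (six injected events after lag
filtering). `scripts/acceptance.py` reruns all of these from scratch in
about a minute.

## Known limitations

- No chilling/dormancy sub-model: the forcing model is appropriate for
  high-elevation populations where temperature dominates, not lowlands.
- The concordance computation treats the window rule and the indicator as
  independent; in the field both inherit errors from the same climate data.
- The Mann–Kendall test assumes serial independence of the annual series.
- The RWL writer emits one layout (decadal rows, 6-character fields); it
  round-trips with the reader but is not a general archival writer.
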