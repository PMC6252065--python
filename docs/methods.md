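# Methods notes

This note records the statistical model behind `camtrapdiel`, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Detection events

A detection table has one row per capture: species, site, camera,
timestamp (local civil time, minute resolution), coordinates and an
optional group size. A multi-animal image is one event. Captures of the
same species at the same camera within the *independence interval*
(default 1 h) are treated as re-triggers of a single activity bout: a
greedy forward scan keeps the first capture and then every capture at
least one interval after the most recently *kept* one. Scanning against
the last kept (not last raw) capture is the standard camera-trap
convention and is the only variant that guarantees all retained
consecutive events are ≥ 1 h apart. Same-minute captures (bursts)
collapse to one record first. The filter is idempotent, the identity at
interval 0, and retains weakly fewer events as the interval grows.

Pair analyses are restricted to locations where both species were
detected; "location" defaults to the site (broad study area) rather
than the individual camera, which is the appropriate scale when cameras
within a site sample the same animal community.

Timestamps are taken at face value as camera clock time with a fixed
per-site UTC offset used only for solar computations. No daylight-saving
reinterpretation is attempted; if cameras recorded civil time with DST,
users should supply the matching seasonal offset or pre-convert.

## Solar geometry

Sunrise/sunset use the NOAA solar-position equations (the spreadsheet
form of Meeus' algorithm) with zenith 90.833° (refraction plus solar
radius). Agreement with an independently coded NOAA fractional-year
formulation is ~1 minute over the year at 55° N — two orders of
magnitude below the 1-h resolution of the analysis. Latitudes beyond
±66.5° are rejected rather than mishandled (no polar day/night logic).

**Offsets.** Detections with clock time before 12:00 are anchored to
that day's sunrise, later ones to sunset. The offset magnitude is the
time to the anchor; the sign is positive iff the detection falls between
sunrise and sunset. Offsets keep minute precision and enter statistics
in decimal hours.

**Diel periods.** Dawn = [sunrise−1 h, sunrise+1 h), day = [sunrise+1 h,
sunset−1 h), dusk = [sunset−1 h, sunset+1 h), night = the rest. The four
half-open intervals tile the 24-h circle exactly; the offset sign and
the period labels agree about what counts as night. Seasons are
meteorological (spring = March–May, etc.).

**Diel classification.** Events are tallied by period with dawn+dusk
pooled as crepuscular (without pooling, a bimodal dawn/dusk species
could never win any single period). Counts are converted to rates per
hour of period, since period durations differ by many hours across
seasons at 55° N; the label is the period with the highest rate. If the
leading rate does not exceed the runner-up by the dominance factor
(default 1.25), activity is judged spread enough to be cathemeral. The
factor is a package convention — there is no field-standard threshold —
and is exposed as a parameter; 1.25 keeps an exactly-even split
cathemeral while letting a modest preference through.

## Circular densities and overlap

Clock times map to angles (24 h = 2π). The density estimate is a von
Mises kernel average; the kernel concentration follows the
Ridout–Linkie plug-in rule

ν = ( 3 n κ̂² I₂(2κ̂) / (4 √π I₀(κ̂)²) )^{2/5} / adjust,

computed stably with exponentially scaled Bessel functions. The
reference concentration κ̂ solves I_k(κ)/I₀(κ) = R̄_k for each sample
trigonometric moment R̄_k up to harmonic k = 3, keeping the largest
solution. The harmonic search matters: for a crepuscular species with
peaks ~12 h apart the first moment cancels to ≈ 0, and a first-moment-only
κ̂ flattens the density to uniform, grossly inflating overlap with any
other species. `adjust` > 1 smooths more (0.8 is a common small-sample
choice in the overlap literature; default 1). Densities are evaluated on
a 128-point grid, renormalised so the periodic trapezoid integral is
exactly 1; the plug-in concentration is capped at 2000 so a degenerate
point-mass sample still resolves on the grid.

The coefficient of overlapping Δ = ∫ min(f₁, f₂) is estimated two ways:
Δ̂₁ integrates the pointwise minimum of the two fitted densities on the
grid; Δ̂₄ averages min(1, f̂_other/f̂_own) over the observed points of
both samples. Following the reference estimator literature, Δ̂₁ is used
when the smaller sample has < 50 events and Δ̂₄ otherwise ("auto");
both are available explicitly. Confidence intervals are percentile
bootstrap (detection times resampled with replacement per species,
default 1,000 replicates, seeded). Percentile rather than BCa keeps the
procedure simple and exactly reproducible; the CI type is a pluggable
choice. Category labels: Δ < 0.5 low, 0.5 ≤ Δ ≤ 0.75 moderate
(both boundaries inclusive), Δ > 0.75 high.

Measured behaviour on analytic von Mises pairs: both estimators land
within ±0.02 of the quadrature truth at n = 2,000 per sample, and carry
a positive bias of roughly +0.02–0.04 at n ≈ 200 for dissimilar pairs
(kernel smoothing spreads mass into the overlap region). The 1-h
independence filter adds a further small upward nudge (~+0.02 at high
detection rates) by thinning events preferentially at activity peaks.
Bootstrap CIs at n = 200 nevertheless cover the generating truth at
≈ 95% in simulation because the bias is comfortably inside the
interval width at such sample sizes.

## Cross-correlation of diel profiles

Hourly profiles (24 bins starting at the hour mark) are correlated at
integer lags −12…+11 with circular (wrap-around) shifting, so all 24 bin
pairs contribute at every lag and the degrees of freedom are constant at
n − 2 = 22. A positive lag h correlates predator activity at hour a+h
with prey activity at hour a. Raw counts enter the CCF; Pearson
correlation is location/scale invariant, so min–max normalisation of
profiles (used for plotting) cannot change r.

Each per-lag r is transformed to t = r√((n−2)/(1−r²)) and compared as
|t| against the one-tailed Student-t critical value at p = 0.05, df = 22
(1.72), so strong correlations of either sign are flagged (a two-tailed
option is available). Significant lags are reported as maximal
consecutive runs plus a peak lag — the significant lag of largest |r|,
ties broken to the smallest |lag| and then to the negative lag (a
package convention). Runs are reported on the linear lag axis; −12 and
+11 are not merged across the wrap.

## Seasonal offset ANOVA

Signed solar offsets (decimal hours) are compared across seasons with
one-way ANOVA; seasons with fewer than two observations are dropped
with a warning. Post-hoc comparisons use Tukey HSD in its unequal-n
(Tukey–Kramer) form via statsmodels, since seasonal detection counts in
camera-trap data differ by an order of magnitude. No
normality/heteroscedasticity gatekeeping is applied; group means, SDs
and ns are reported so users can judge. The null rejection rate at
α = 0.05 sits at the nominal 5% in simulation.

## Synthetic data generator

Each species template is a von Mises mixture on the 24-h circle whose
component means are anchored to *solar events of the detection date*:
nocturnal = one component at solar midnight (κ 2–3), diurnal = solar
midday (κ 2–3), crepuscular = equal components at sunrise and sunset
(κ 4–5), cathemeral = circular uniform. Anchoring to per-date sun times
(rather than fixed clock hours) reproduces the seasonal drift of
activity relative to the clock that the offset ANOVA is designed to
detect. Event counts per camera-day are Poisson with per-season rates.

The default scene is four sites at 54.3–55.1° N, five cameras each, one
14-day window per season (280 camera-days per season), and ten species
across three guilds whose per-season rates mirror a real Irish
multi-survey assemblage (squirrels most detected with a strong spring
peak; hares nearly absent in winter; deer and foxes sparse). Expected
totals are ~8,700 detections. Congeneric hare and squirrel species are
generated separately and pooled by the pipeline's species-group map.

Ground truth accompanies every simulation: the resolved mixture per
species and season, and exact pairwise Δ by 4,096-point quadrature at
each window's midpoint date. The midpoint-date truth is adequate
because sun times drift only minutes within a 14-day window (pooled
window truth and midpoint truth agree to < 0.001 in Δ).

What the generator does **not** emulate: imperfect/distance-dependent
detection (detection rates are taken as activity, as the analysis
itself assumes), camera failure, weather, animal movement and spatial
autocorrelation between cameras, lunar effects, or behavioural
interactions beyond a fixed activity schedule. Passing tests therefore
demonstrate the estimators recover *schedules that really have the
assumed shape*, not that real detection data are unbiased samples of
activity.

## Problem sizes in the test and acceptance runs

Oracle-equivalence checks use n = 2,000 samples per species;
overlap recovery uses 50 replicates at n = 1,000; guild classification
100 datasets per guild at n = 200; bootstrap coverage 100 replicates of
n = 200 at 1,000 bootstrap resamples. Peak-lag recovery is assessed at
n = 1,000 events per species: with a broad nocturnal density (κ = 2)
the correlations at the true lag and its hour-neighbours are nearly
equal, and the exact-hit rate crosses 90% right around n = 500, so the
check is run where the property holds stably rather than on its knife
edge.

## Known limitations

* Kernel overlap estimates are biased upward for dissimilar schedules
  at small n; report CIs, not point estimates, below ~200 events.
* The CCF treats the 24 hourly bins as 24 independent observations when
  computing df = 22; adjacent bins of a smooth activity profile are
  correlated, so per-lag significance is anti-conservative. This is the
  field's standard reporting convention and is kept as such.
* No multiple-testing correction across lags or species pairs.
* Solar computations assume a fixed UTC offset per site; DST-recorded
  timestamps must be handled by the user.
* The diel classifier uses each event's own date's sun times but one
  label per species; species that switch guild seasonally should be
  classified per season by filtering events first.
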