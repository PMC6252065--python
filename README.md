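# camtrapdiel

Diel (24-hour) activity analysis for camera-trap detection data.

Camera traps record *when* animals are active, not just where. Given a
table of time-stamped detections, `camtrapdiel` answers the standard
questions of temporal wildlife ecology:

* Which detections are **independent activity events**? (captures of the
  same species at the same camera within 1 h are re-triggers of one event)
* Is a species **nocturnal, diurnal, crepuscular or cathemeral**, judged
  against each detection date's actual sunrise and sunset?
* Does activity shift **seasonally relative to the sun** — earlier or
  later than sunrise/sunset — and is the shift statistically detectable?
* How much do two species' activity schedules **overlap**, and do
  predator and prey activity peaks **lead or lag** one another?

It is aimed at ecologists analysing multi-season camera-trap surveys at
mid-latitudes, where day length varies strongly through the year and
clock-time summaries are misleading.

## Methods in brief

**Solar anchoring.** Sunrise and sunset are computed from the NOAA solar
position equations (zenith 90.833°). Each detection gets a signed
*solar offset*: detections before noon are offset from sunrise, after
noon from sunset; daylight offsets are positive, night-time negative
(e.g. a 22:10 detection with sunset at 20:00 → −2 h 10 min). Dawn and
dusk are the hour before/after sunrise and sunset; day and night are the
remainder. Seasonal differences in offsets are tested with one-way
ANOVA plus Tukey–Kramer post-hoc comparisons.

**Activity profiles and overlap.** Clock times are treated as angles on
the circle. Densities are von Mises kernel estimates with the
Ridout–Linkie plug-in concentration ν = (3nκ̂²I₂(2κ̂)/(4√π I₀(κ̂)²))^{2/5},
where κ̂ matches sample trigonometric moments up to harmonic 3 (robust
to bimodal, crepuscular schedules). The coefficient of overlapping

Δ = ∫ min(f̂₁(t), f̂₂(t)) dt ∈ [0, 1]

is estimated on a 128-point grid (Δ̂₁) or from densities at the observed
points (Δ̂₄, used when both samples have ≥ 50 events), with percentile
bootstrap 95% CIs from 1,000 resamples. Δ < 0.5 is labelled low overlap,
0.5–0.75 moderate, > 0.75 high.

**Predator–prey lags.** Hourly (24-bin) profiles are cross-correlated
with circular shifts at lags −12…+11 h; each per-lag Pearson r is tested
with t = r√((n−2)/(1−r²)) against the one-tailed Student-t critical
value at p = 0.05 with 22 df (1.72). The report lists maximal runs of
significant lags and the peak lag (largest |r| among significant lags).
Pair analyses are restricted to locations where both species occur.

**Synthetic data.** `camtrapdiel.synthetic_data` generates detection
datasets from von Mises mixtures anchored to each date's sun times
(nocturnal = solar midnight, diurnal = solar midday, crepuscular =
sunrise + sunset peaks), with Poisson counts per camera-day. Because the
generating densities are analytic, every estimate has an exact
quadrature ground truth.

## Worked example

```python
from datetime import date
from camtrapdiel import synthetic_data as syn
from camtrapdiel.activity import times_to_radians, classify_diel
from camtrapdiel.overlap_analysis import estimate_overlap
from camtrapdiel.records_io import filter_independent
from camtrapdiel.solar import sun_times, offset_from_sun

full = syn.default_plan()
plan = syn.DeploymentPlan(full.sites, full.cameras_per_site,
                          {"spring": full.windows["spring"]})
sim = syn.simulate(seed=42, plan=plan, pairs=[("fox", "rabbit")])
events = filter_independent(sim.detections).records
print(f"{len(sim.detections)} raw detections -> {len(events)} independent events")

fox = events[events.species == "fox"]
ts0 = fox.iloc[0]["timestamp"]
sd0 = sun_times(ts0.date(), fox.iloc[0]["latitude"], fox.iloc[0]["longitude"], 0.0)
off = offset_from_sun(ts0.to_pydatetime(), sd0)
print(f"first fox detection {ts0:%H:%M} -> offset {off.hours:+.2f} h (anchor: {off.anchor})")

guild = classify_diel(fox["timestamp"].tolist(),
                      [sun_times(t.date(), la, lo, 0.0)
                       for t, la, lo in zip(fox["timestamp"], fox["latitude"], fox["longitude"])])
print(f"fox diel class: {guild}  (n = {len(fox)})")

rabbit = events[events.species == "rabbit"]
res = estimate_overlap(times_to_radians(fox["timestamp"]),
                       times_to_radians(rabbit["timestamp"]),
                       pair=("fox", "rabbit"), season="spring", reps=1000, seed=42)
truth = sim.ground_truth["true_overlap"]["fox|rabbit"]["spring"]
print(f"fox-rabbit overlap: Delta = {res.delta:.2f} "
      f"(95% CI {res.ci95[0]:.2f}-{res.ci95[1]:.2f}, {res.category}; generating truth {truth:.2f})")
```

Output:

```
4178 raw detections -> 3389 independent events
first fox detection 01:07 -> offset -4.50 h (anchor: sunrise)
fox diel class: nocturnal  (n = 171)
fox-rabbit overlap: Delta = 0.58 (95% CI 0.49-0.64, moderate; generating truth 0.49)
```

Reading the numbers: the 1-h independence filter removed ~19% of raw
captures as re-triggers; the first fox event fell 4.5 h before sunrise
(night, hence the negative sign); fox activity is classified nocturnal;
and fox–rabbit spring overlap is moderate, with the bootstrap interval
covering the generating model's true Δ of 0.49 (kernel overlap
estimates carry a small positive bias at these sample sizes — see
`docs/methods.md`).

The same analysis is available from the shell:

```sh
camtrapdiel simulate --seed 42 --out-dir simulated
camtrapdiel analyse --detections simulated/detections.csv \
    --sites simulated/sites.csv --out-dir reports --seed 42
camtrapdiel report reports
```

which writes Table-style CSVs: a species × season detection summary,
per-species diel classes with seasonal offset ANOVAs, and per-pair
overlap and cross-correlation reports.

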