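# Methods

## The problem

Temperate fruit trees pass the winter in dormancy and will not resume
growth until they have experienced a genotype-specific amount of cold —
the chilling requirement (CR).  Estimating CR for every seedling in a
breeding progeny by the classical forcing method (cutting shoots weekly
and forcing budbreak in a warm chamber) does not scale to hundreds of
genotypes.  `chillreq` instead estimates CR statistically from two
long-term records that breeders already keep: one full-bloom date (day of
year, DOY) per genotype and season, and daily temperature extremes from
the orchard's weather station.

The estimation runs in two stages, per genotype:

1. **Delineate the effective chilling period** by partial least squares
   (PLS) regression of bloom DOY on the season-aligned daily chill (and
   heat) accumulation series.
2. **Accumulate chill over that period** in every season under three
   models — Chilling Hours (CH), Utah Chill Units (CU) and Dynamic-Model
   Chill Portions (CP) — giving a per-season CR table.

## Hourly temperatures from daily extremes

Chill models need hourly temperatures.  These are reconstructed from
Tmin/Tmax with the standard idealized diurnal course: daytime follows
`T(h) = Tmin + (Tmax − Tmin)·sin(π (h − sunrise) / (daylength + 4))`
(the +4 h stretch places the maximum in mid-afternoon and leaves a
non-zero sunset temperature), and the night cools logarithmically from
the sunset temperature to the next morning's Tmin.  Sunrise and sunset
come from latitude and solar declination (7-term Fourier series in the
day angle), with the hour-angle cosine clipped to [−1, 1] so polar
day/night degrade to 24 h/0 h daylength; degenerate daylengths fall back
to a flagged linear ramp.  Hours are evaluated on the integer clock grid
0–23, and `ln(max(1, ·))` guards the first post-sunset hour.  The first
and last days of a record use their own Tmin where a neighbouring day's
minimum would be required.

Daily records are quality-checked (missing calendar days, missing
extremes, gap-run lengths) and gap-filled by linear interpolation between
the nearest valid neighbours; boundary gaps take the nearest valid value
and gaps longer than `max_gap` (default 30 d) are filled but flagged.
These QC policies are the package's own documented choices.

## Chill and heat models

All four kernels consume hourly temperature (°C) and emit per-hour
increments:

* **CH**: 1 per hour with 0 ≤ T ≤ 7.2.
* **CU**: piecewise weights 0 / 0.5 / 1 / 0.5 / 0 / −0.5 / −1 over the
  bands (−∞,1.4], (1.4,2.4], (2.4,9.1], (9.1,12.4], (12.4,15.9],
  (15.9,18], (18,∞); upper bounds inclusive.
* **CP (Dynamic Model)**: two-step kinetics.  With `TK = T + 273`, a
  precursor `x` relaxes towards its temperature-dependent equilibrium
  `xs = (a0/a1)·exp((e1−e0)/TK)` at rate `ak1 = a1·exp(−e1/TK)`; when
  `x ≥ 1` the fraction `xi = sr/(1+sr)`, `sr = exp(slp·tetmlt·(TK−tetmlt)/TK)`,
  is banked irreversibly as a portion.  Constants (slp 1.6, tetmlt 277 K,
  a0 1.395×10⁵, a1 2.567×10¹⁸, e0 4153.5, e1 12888.8) are the literature
  values; they live in a config dataclass, not in the code.
* **GDH**: Anderson-type half-sine between base 4 °C, optimum 25 °C and
  critical 36 °C.

An optimized (vectorized precomputation + single recurrence loop)
implementation of CP is checked against a literal scalar recurrence to
1×10⁻¹⁰ in the tests.

## The PLS delineation

For each genotype, bloom DOY per season is regressed on the smoothed
daily increments of the chosen chill metric (default CP) and, by default,
a parallel heat block of daily GDH, over a season-relative window from
Nov 1 (`split_month=11`; at mild-winter Mediterranean sites the first
chill portions fall in early November) to DOY 120 (Apr 30).  Days are
indexed relative to Jan 1 = +1, with Dec 31 = 0 and Nov 1 = −60, so all
seasons share one column grid regardless of leap years.  Daily series are
smoothed by an 11-day centred running mean (truncated at the edges);
columns are z-scored (sample sd), constant columns are excluded and
reported, and a 2-component PLS is fitted (with ≤ 8 seasons per genotype,
cross-validating the component count is unstable, so it is fixed but
configurable).  Coefficients are mapped back to the original predictor
scale; VIP scores follow
`VIP_j = sqrt(p · Σ_a SS_a (w_aj/‖w_a‖)² / Σ_a SS_a)` with
`SS_a = q_a² t_aᵀt_a`, so the mean squared VIP over included predictors
is exactly 1.

A day belongs to the chilling period when its VIP is ≥ 0.8 **and** its
model coefficient is negative (more chill that day → earlier bloom),
restricted to the chill block — the heat block participates in the fit
but never contributes qualifying days.  Two robustness rules shape the
window:

* **Consecutive-run requirement (`min_run`, default 3).**  The
  endodormancy phase is a sustained span of negative-coefficient days.
  With 11-day-smoothed predictors, adjacent noise columns are strongly
  correlated, so spurious qualifiers arrive in short clusters — often
  after bloom, where no causal signal can exist.  Requiring runs of at
  least 3 consecutive qualifying days removes most of them;
  `min_run=1` restores the permissive reading in which every qualifying
  day counts.
* **Median-bloom cap.**  Chill accumulation cannot meaningfully extend
  past flowering, so qualifying days after `floor(median_bloom − 1)` are
  discarded (a fractional median of 71.5 caps at day 70).  The run
  pruning is applied before the cap so a genuine run straddling the cap
  is kept up to the cap.

The window spans the first to the last remaining qualifying day.  A
genotype with no qualifying day is reported, not fatal.  Raising the VIP
threshold can only shrink the qualifying set, so the window never widens
with a stricter threshold.

## CR estimation and outputs

For every season with a bloom record, CH, CU and CP are accumulated from
00:00 of the window's start day to 23:00 of its end day (day indices map
to calendar dates per season; season "2012" runs from autumn 2011).  The
CR table holds one row per genotype and one column per season × metric;
missing genotype-season cells stay empty.  Because breeders usually want
a single number per genotype, across-season mean and sd columns are
appended per metric, clearly derived from the per-season values.  A run
manifest records every parameter and library version; identical inputs
and configuration give byte-identical CSV outputs.

## Synthetic data and what the tests show

The generators provide inputs with known ground truth:

* **Weather**: daily mean = `annual_mean − annual_amplitude·cos(2π(doy −
  coldest_doy)/365)` plus a stationary AR(1) anomaly; Tmin/Tmax sit half
  the diurnal range below/above.  Defaults emulate an inland
  Mediterranean orchard at latitude 38.11°: annual mean 17.5 °C,
  amplitude 7.6 °C (mid-winter daily mean ≈ 9.9 °C, coldest ≈ Jan 15),
  diurnal range 11.9 °C, anomaly sd 1.7 °C with autocorrelation 0.65.
  These settings yield roughly 60–75 CP per dormant season, the chill
  supply typical of the mild-winter sites where Dynamic-Model accounting
  matters most.
* **Progeny**: sequential chill-then-heat phenology, the same conceptual
  model the PLS delineation assumes.  Per genotype, CR ~ N(30, 8²) CP
  (the span of apricot crosses between low- and high-chill parents) and
  a heat requirement ~ N(5500, 800²) GDH; chill counts from Nov 1.  The
  day the running CP total reaches CR is the true dormancy-release day;
  GDH then accumulate until the heat requirement is met (bloom, never
  earlier than the day after release), plus optional Gaussian
  observation noise (default sd 1.5 d).  Seasons in which CR or heat is
  never met receive the invalid marker `*`, exercising the same
  filtering pathway as field data.

What the synthetic data do **not** emulate: weather measurement error and
station relocations, chill–heat overlap during the transition
(endo/ecodormancy is a hard switch here), genotype × environment
interaction beyond the threshold parameters, and frost damage to
flowers.  Recovery results on these data therefore bound what the method
can do under its own assumptions, not under field conditions.

On noise-free progenies (20 genotypes × 8 seasons) the pipeline recovers
the chill-onset day within ±10 days for most genotypes in typical weather
realizations; in realizations with unusually warm autumns the first chill
portions fall only in mid-November, early-November predictor columns
carry no interannual signal, and delineated starts shift 2–3 weeks late.
Per-genotype CR magnitudes are recovered only partially: the delineated
window end localizes the *population's* dormancy-release transition
rather than each genotype's, because week-scale warm spells around the
turn of the year both delay release and depress the smoothed chill
predictors in the same columns, giving genuinely negative coefficients up
to roughly the latest seasonal release plus the smoothing half-width.
Per-genotype CP estimates consequently compress towards the population
value (itself within ~10 % of the population-mean CR), and genotypes
whose CR sits well below the progeny mean are overestimated.  This is an
inherent resolution limit of PLS-delineated chilling windows with ~8
seasons of data, and it is why per-season CR values should be read as a
ranking/selection phenotype rather than as absolute physiological
thresholds for individual seedlings.

## Numerical and policy choices

* Invalid-marker policy: the default `drop-genotype` removes the whole
  wide row (a marker casts doubt on the genotype's record);
  `drop-observation` keeps the genotype's other seasons.  Empty cells are
  treated like the marker.  The `BDyy` → `20yy` century mapping is a
  config key.
* Median bloom with an even season count is the midpoint of the two
  central values.
* Fewer than 4 usable seasons refuses the PLS fit; seasons without
  complete weather coverage are dropped with a warning.
* Problem sizes in the tests (6–20 genotypes, 6–8 seasons, 7–9 weather
  years) are chosen to exercise every code path at desk scale while
  matching the season counts of real progeny records.
* All randomness flows through `numpy.random.default_rng(seed)`; the
  pipeline itself is deterministic.
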