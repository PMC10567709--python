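# Methods

## The estimation model

Termite CH₄ emission at a grid cell is the product of termite biomass
density and an emission factor, summed over the natural-vegetation and
cropland portions of the cell and converted from an hourly to an annual
rate:

    E = [(1 − f) · ρ_nat · EF_nat + f · ρ_crop · EF_crop] · 8760 · 10⁻⁶

with E in g CH₄ m⁻² yr⁻¹, ρ in g dry weight m⁻², EF in
µg CH₄ g⁻¹ termite h⁻¹, f the cropland areal fraction, 8760 = 24 × 365
(leap days ignored) and 10⁻⁶ converting µg to g. Global and regional
totals are area-weighted sums on a sphere of radius 6371.0 km, reported
in Tg CH₄ yr⁻¹; a cell in latitude band [φ₀, φ₁] with longitude width
Δλ has area R²·Δλ·(sin φ₁ − sin φ₀), so cell areas tile the sphere
exactly (tested to < 10⁻⁶ relative).

The model chain makes three structural assumptions:

* **Cold-limited habitat.** Termites persist wherever the coldest
  climatological month stays strictly above −8 °C; no rainfall or
  dispersal constraint. The envelope is evaluated on a trailing 20-year
  mean of monthly temperatures (window configurable; truncated at the
  start of a series), so interannual weather noise does not flicker the
  mask. A cell at exactly −8.0 °C is excluded — the boundary test pins
  this. Habitat responds to warming instantaneously, i.e. termites are
  assumed mobile enough to track the moving envelope.
* **Land-cover density with a productivity response in the tropics.**
  Outside tropical forests, ρ is a fixed per-class value (packaged
  table; 0 for tundra and polar desert, which is also what keeps those
  classes emission-free inside the envelope). In tropical evergreen and
  deciduous forest, ρ = a·exp(b·GPP) with a = 1.21 g m⁻²,
  b = 0.0008 (g C m⁻² yr⁻¹)⁻¹, uncapped — at a synthetic tropical GPP
  of 3000 this gives ≈ 13.3 g m⁻², close to the tabulated 11, and we
  found no basis for a ceiling. The two tropical classes are exactly
  the ones the land-use-only variant replaces with fixed 11 and
  8 g m⁻²; whether savanna/shrubland should also respond is left as a
  config switch (`gpp_responsive_classes`), default off. The units of
  the exponential relationship are taken as g m⁻² by dimensional
  consistency with the class table. Cropland density is constant
  (3.815 g m⁻²) in every variant.
* **Per-class-per-member EF sampling.** Each ensemble member draws one
  EF per land-cover class (uniformly, with replacement, from the raw
  observation list — no smoothing) and applies it to every cell of the
  class; natural classes and cropland draw independently. Per-cell
  i.i.d. draws would average the EF variance away over ~10⁵ cells and
  shrink the ensemble spread of the global total toward zero, which
  contradicts the observed spread being of the same order as the mean
  (EF coefficient of variation ≈ 108 %). The granularity is isolated
  behind `EFScheme` so sensitivity runs can revisit it.

Because habitat and density are EF-independent, the ensemble is
computed from per-class biomass-area integrals; a test pins the
equivalence of this shortcut to the full gridded member computation
(10⁻⁹ relative), and a brute-force per-cell scalar loop serves as an
independent oracle for the vectorized engine.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| habitat threshold | −8 | °C (min monthly mean) | empirical envelope bounding observed colony records |
| climatology window | 20 | years | matches the 2001–2020 averaging used to fit the threshold |
| EF targets | 3.81 / 4.10 / [0, 25.26] | µg CH₄ g⁻¹ h⁻¹ | published summary of the observational EF dataset |
| EF zero fraction | 0.05 | — | supplies the printed 0.0 lower bound as exact zeros |
| GPP–density a, b | 1.21, 0.0008 | g m⁻², (g C m⁻² yr⁻¹)⁻¹ | empirical productivity–biomass relationship |
| ensemble size | 1000 | members | standard for a stable mean/s.d. of the skewed totals |
| GWP (20 / 100 yr) | 79.7 / 27.0 | — | IPCC AR6 mass-basis values, stored in config |
| soil sink total | 31.6 | Tg CH₄ yr⁻¹ | prescribed uptake of the termite-inhabited area; input, not simulated |

## The synthetic world

The generator replaces four external data streams (observed climate,
land-use reconstruction, simulated GPP, the EF compilation) with pure
functions of a config and seed:

* **Temperature**: zonal annual mean 27·cos φ − 2 °C, seasonal
  amplitude 15·sin²φ with opposite hemispheric phase (peak July in the
  north), a linear warming trend (default 0.1 °C decade⁻¹), and bounded
  uniform noise (±0.5 °C). The construction guarantees equatorial cells
  in [20, 30] °C and polar minima below −8 °C, so the envelope filter
  always has work to do; the latitude band near 72.5° sits within a
  degree of the threshold, which is what lets warming scenarios move
  the habitat edge on a 5° grid.
* **Land cover**: a static zonal mosaic over all fifteen natural
  classes (tropical forest belts, savanna/shrubland, temperate and
  boreal forest, tundra, polar desert), some belts split at longitude 0
  so every class is present on the default 36 × 72 grid.
* **Cropland**: a deterministic subtropical/temperate belt (peak
  fraction 0.25 near |φ| = 32.5°) plus a secular trend per decade
  weighted toward low latitudes, clipped to [0, 1] — emulating
  conversion of tropical natural vegetation.
* **GPP**: per-class baseline (2500 g C m⁻² yr⁻¹ in tropical evergreen
  forest, chosen so the exponential density relationship lands near the
  tabulated tropical densities) × a temperature ramp (0 at −5 °C annual
  mean, 1 at 25 °C) × a CO₂-fertilization multiplier
  (1 + rate·decades) × multiplicative ±5 % noise, truncated at zero.
  Multiplicative noise makes the fertilization ratio between same-seed
  runs exact, which the tests exploit.
* **Emission factors**: a zero-inflated lognormal truncated to
  (0, 25.26]. The point mass at zero (5 %) reproduces the printed lower
  bound; (µ, σ) of the underlying normal are root-found (tolerance
  10⁻⁶) so the *mixture* mean and s.d. hit 3.81 and 4.10. A lognormal
  is the simplest family consistent with a positive, right-skewed
  sample whose s.d. exceeds its mean; infeasible target combinations
  raise.
* **Soil sink**: a smooth positive field over land normalized so its
  global total equals a prescribed value (default 31.6 Tg CH₄ yr⁻¹).
  It is bookkeeping input for net-flux maps and offset percentages; no
  oxidation process is modelled.
* **Geography**: one supercontinent (|lon| < 60°), giving an earth-like
  land third of the sphere, with bounding-box "Africa" and "South
  America" tropical blocks for regional partitions. Ocean cells are NaN
  everywhere — never 0 — so zeros stay meaningful fluxes.

What the synthetic world does **not** emulate: spatial autocorrelation
beyond zonal structure, realistic coastlines and continental layout,
ENSO-like interannual covariance, co-located climate–land-use
correlation, or the actual frequency histogram of the EF compilation
(only its first two moments, range and zero mass). Passing tests
therefore demonstrate correctness of the pipeline's arithmetic,
bookkeeping and statistical machinery under controlled conditions — not
agreement with real-world emission magnitudes, which depend on the real
drivers. On the synthetic world the global total is ~26 Tg CH₄ yr⁻¹
simply because its warm land area is larger than Earth's actual termite
habitat.

## Scenario machinery and statistics

Per-year ensemble seeds derive from (base seed, year) via a seed
sequence, so extending a run never perturbs existing years, and every
scenario is bit-reproducible from its config (tested). Four variants
switch the two methodological axes: EF source (sampled vs prescribed
per-class table) × density source (GPP-responsive vs land-use-only).
With prescribed EFs and deterministic density there is no stochastic
spread, and the reported ensemble s.d. is exactly 0 — which is also how
the code distinguishes the two published spread types structurally.

Two different uncertainties are reported and never mixed: the ensemble
standard deviation across EF draws within one year, and the interannual
standard deviation of annual means across a decadal window
(`decadal_stats`). Scenario deltas are differences of decadal means.
Future presets (`mitigation_like`, `high_end_like`) encode
mild-vs-strong warming and fertilization; they are WorldConfig presets,
not climate-model output, and file-driven runs use the same interface.

## Numerical choices and degenerate inputs

* Missing data: any missing month poisons a cell's minimum temperature,
  and such cells are never habitat; missing GPP at a responsive
  tropical cell falls back to the tabulated density with a warning;
  missing cropland inside habitat is an error (it would silently bias
  areas).
* Aggregations skip missing cells; region labels partition land
  exactly, and regional totals are tested to sum to the global total
  (< 10⁻⁹ relative).
* Sample s.d. uses the n−1 denominator everywhere; a single-observation
  dataset reports s.d. 0 with a warning rather than NaN.
* A single-member ensemble reports s.d. 0; a single-value EF dataset
  gives a degenerate (zero-spread) ensemble.
* NetCDF I/O goes through xarray's scipy backend (NetCDF3), keeping the
  on-disk format dependency-light; round trips are bit-exact including
  NaN missing cells. Files with no units attribute load as "unknown"
  with a warning instead of failing.
* Test-scale runs use the 5° (36 × 72) grid; the 0.5° grid is a config
  change only and shares all code paths.

## Known limitations

* Soil-feeding vs wood-feeding termites are not separated, and no
  within-mound CH₄ oxidation correction is applied, so fluxes represent
  emission at the measurement convention of the underlying EF data.
* The EF sample is global: no regional or taxonomic stratification.
* Habitat tracks the envelope with no migration lag and no upper
  temperature or moisture limit.
* The GPP–density relationship is extrapolated wherever GPP exceeds the
  range it was fitted on (it is uncapped by design).
* Regional totals use bounding-box regions of the synthetic world;
  real-continent masks must be supplied by the user.
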