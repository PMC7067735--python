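# Methods

## The model chain

The package treats scenario analysis of coastal predatory fish as a
fixed pipeline over rasters on a projected square grid:

**Habitat availability.** Given a binary recruitment-habitat map and a
land/water mask, availability at a water cell is

x = (habitat cells within radius r) / (water cells within radius r),

with r the species' typical maximum migration distance (perch
10 000 m, pikeperch 15 000 m, from tagging recapture distances). The
window is a Euclidean disc of centre-to-centre distance ≤ r; no
geodesic correction, and no cost-distance around land barriers — the
disc crosses islands, a deliberate simplification whose local bias is
documented rather than corrected. Land cells and cells beyond the grid
edge are excluded from numerator *and* denominator, so x is always a
proportion of observable water; grid-edge cells are treated like land,
not like zero-habitat water, keeping x unbiased near edges. The fast
path convolves 0/1 indicators with the disc kernel by FFT and rounds
the results to integers before dividing; since the true counts are
integers far below 2⁵³, the output is bit-identical to the double-loop
counting oracle that the tests run against it.

**Habitat productivity functions.** Adult CPUE in a standardized
gill-net night is log-linear in availability:

CPUE = a·ln(x + c) + b, clamped at 0,

with perch a = 2.03 (SE 0.69), b = 9.39 (SE 1.27), c = 0 (n = 12,
p = 0.015, r² = 0.46) and pikeperch a = 0.05 (SE 0.02), b = 0.21
(SE 0.04), c = 0.02 (n = 12, p = 0.013, r² = 0.48). The perch form
diverges to −∞ as x → 0; the clamp activates exactly below
x = exp(−b/a) ≈ 0.0098 and is asserted at that threshold in the tests.
The clamp is a modelling choice (the source regressions are silent
about x near 0), preserving non-negativity and monotonicity.

**CPUE → biomass.** The original conversion functions' internals are
not published; conversion is implemented as a per-species linear
factor k (kg ha⁻¹ per CPUE unit), a config knob defaulting to the
ratio of published study-area means: k_perch = 9.4/5.4 ≈ 1.741,
k_pikeperch = 0.65/0.16 ≈ 4.063. This reproduces the published
aggregate pair by construction but is not the original (possibly
nonlinear) function; any analysis depending on absolute biomass at
extreme CPUE should treat k as calibratable. An optional length-class
expansion divides biomass above the species cutoff (> 20 cm perch,
> 30 cm pikeperch) by the proportion p of that class among all fish
> 10 cm (defaults back-solved from the published pairs 9.4 → 16 and
0.65 → 1.5 kg ha⁻¹: p = 0.5875 and 0.4333).

**Depth limit.** Perch is restricted to 0–10 m depth: CPUE/biomass
maps and area summaries blank deeper cells; pikeperch has no limit.

**Ensemble and scenarios.** Each (species, scenario) carries three
technique maps. The ensemble is the cellwise mean; uncertainty is 1
standard error across techniques — sample SD with n−1 denominator over
√n, n = 3 (configurable to plain SD, since "1 SE" admits either
reading). Nodata propagates if any member is nodata. Scenario effect =
100 × (scenario mean − baseline mean)/baseline mean, computed on the
ensemble-mean area summaries (mean first, then ratio); per-technique
ratios averaged afterwards are available for sensitivity checks but
are not the default. Scenario levels are percent Secchi-depth change
{−10, 0, +11, +20, +30, +40, +48}; +11 is the policy target and +48
the reference level.

**Validation.** Observed monitoring CPUE is regressed on predicted
CPUE (observed = a·predicted + b) by OLS, reporting slope and
intercept with SEs, r², F(1, n−2) and p. The orientation is
deliberately observed-on-predicted with no errors-in-variables
correction, mirroring how such evaluations are reported. Sites are
assumed pre-averaged over years; site exclusions (e.g. a fishing-ban
area) are a config list. If observed values are exactly constant, r²,
F and p are reported as 0, 0, 1 by convention instead of the undefined
0/0.

**Economics.** WTP for +1 kg h⁻¹ of catch comes from a travel-cost
site-choice model estimated elsewhere; its outputs are parameters
here: SEK 71.6 (perch) and SEK 153 (pikeperch) in 2002 prices,
EUR 8.29 and 18.0 in 2018 prices at SEK 10.2567 per EUR. The deflator
default 1.1875 is back-solved from the perch pair because the CPI
series is not part of the parameter set; the pikeperch published pair
implies a slightly different deflator (153 × 1.1875/10.2567 = 17.71 ≠
18.0) — both published EUR values are kept as defaults and the
inconsistency is noted, not resolved. Assuming linearity of biomass →
WPUE → WTP: ΔWPUE = baseline WPUE × relative change; value = ΔWPUE ×
WTP. *Published-rounding mode* (default) rounds ΔWPUE to 2 decimals and
EUR to 1 decimal at each step so chained worked examples reproduce
digit-for-digit; full precision differs in the second decimal
(0.8 × 0.13 × 8.29 = 0.862 vs the chained 0.829 → 0.8). The species
preference ratio r = effort_perch/effort_pike (gear days; 505 000 ±
124 000 over 83 000 ± 64 000, 95% CIs) gets a first-order delta-method
CI: half-width 1.96·r·√((σ₁/E₁)² + (σ₂/E₂)²), σ = CI/1.96, giving
6.08 ± 4.92. The delta method is exact only for small relative errors;
at the pikeperch effort's 39% relative error it understates the spread
of the actual ratio distribution, so the CI is indicative. Net index =
r × value_perch + value_pike (EUR per pikeperch-equivalent fishing
hour); only its sign is interpreted.

## The synthetic-data generator

The generator emulates the *statistical structure* the pipeline
assumes, not any real geography:

* **Landscape** — a connected mainland margin along the west edge with
  a smoothed random coastline, 2–4 random elliptical islands, water
  fraction kept in [0.5, 0.95]; depth = 2 + 18·(distance to land,
  normalized) + smooth relief, clipped positive, so depth correlates
  with distance from shore and straddles the 10 m perch limit; a
  smooth positive Secchi baseline field.
* **Habitat** — one latent Gaussian field per species (white noise
  smoothed at the autocorrelation range, default 1 500 m on a 250 m
  grid), plus an independent noise field per technique (sd = 0.3 of
  the latent sd), thresholded at the empirical quantile matching the
  target prevalence. Prevalence follows a logistic response:
  logit(p) = logit(base) + response × (Secchi change as a fraction),
  base 0.30/0.15 and response +2.0/−3.0 for perch/pikeperch. Keying
  the latent field by species only (not by scenario) makes one
  technique's maps nested across scenario levels, so prevalence — and
  hence availability and biomass — is exactly monotone in the
  scenario, which is the property the scenario sweep is meant to
  exhibit. The uniform log-odds shift is a stand-in: no claim is made
  about the spatial grain at which real habitat responds to clarity.
* **Monitoring** — observed CPUE at randomly sampled water cells =
  slope·predicted + intercept + N(0, sd), truncated at 0; defaults
  slope 1, intercept 0 give an unbiased noisy copy of the map, and the
  slope/intercept hooks support parameter-recovery simulations.
  Default 11 sites; noise sd 1.5 (perch) and 0.05 (pikeperch), scaled
  to each species' CPUE magnitude.

All randomness derives from one master seed via SHA-256 hashes of
(seed, labels), so adding a scenario, species or technique never
perturbs the others, and every generator is bit-reproducible.

What passing tests on synthetic data do **not** show: that the real
habitat models are right, that the log-odds response magnitudes match
any real basin, or that absolute biomass levels transfer — the
quantitative headline percentages of any real study area require its
original habitat rasters. The synthetic results demonstrate the
machinery: exact focal statistics, correct function evaluation,
correct ensemble algebra, correct direction of effect, and an economic
chain that reproduces its published worked example digit-for-digit.

## Numerical and design choices

* Counts before division in focal statistics are rounded to nearest
  integer to remove FFT noise; equality with the brute-force oracle is
  asserted exactly, not approximately.
* Ensemble SE uses ddof = 1; with n = 3 the SE of {1, 2, 3} is 1/√3.
* TIFF I/O keeps float64 bands so values round-trip bit-exactly; cell
  size and free-form metadata travel in a JSON ImageDescription tag.
  CRS handling is out of scope — grids are assumed projected metres.
* The demo problem size is a 64 × 64 grid at 250 m cells (16 km side):
  large enough for spatial structure and a meaningful depth mask,
  small enough that the full 206-artifact pipeline runs in under a
  second; the migration radii then span a large fraction of the grid,
  which flattens availability — realistic archipelago-scale runs
  should use larger grids.
* Pipeline runs are manifest-checksummed; a rerun with an identical
  config hash and intact artifacts is skipped wholesale (coarse-grained
  on purpose — per-stage staleness tracking is not implemented).
* Scenario tags, species and technique labels are opaque strings;
  techniques in particular carry no model semantics here.

## Known limitations

* No barrier-aware (cost-distance) availability; discs cross land.
* The linear CPUE→biomass factor is a calibration, not the original
  conversion function.
* Only technique spread enters the uncertainty bands; propagation of
  the productivity-function coefficient SEs is not implemented.
* The delta-method ratio CI degrades for large relative effort errors.
* Synthetic landscapes are stylized: no bathymetric charts, no real
  coastline, no temporal dimension.
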