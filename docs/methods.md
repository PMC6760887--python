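# Methods

This note documents the statistical machinery, the synthetic study system
used to validate it, the numerical choices, and the limitations a user
should know about before trusting output on real data.

## Study design being modeled

The package targets a before–after–control–impact telemetry design: ten
grassland sites in two hunting-access classes ("high-risk" open to public
hunting, "low-risk" restricted), radio-tagged individuals of both sexes
located 3–7 days per week from 1 October to 15 December, and a hunting
season opening 27 October. Because regulations restrict harvest to males,
females experience only *perceived* risk — the design separates
behavioral responses from mortality effects. The season calendar is
pre (1–25 Oct), early (27 Oct–23 Nov), late (24 Nov–15 Dec); 26 October
falls in no defined window and is excluded rather than guessed into a
season.

## Triangulation

A bearing set is k ≥ 2 azimuths θᵢ taken from stations sᵢ within a short
span. Bearing errors are von Mises; the location estimate maximizes
Σ cos(θᵢ − μᵢ(z)) where μᵢ(z) is the azimuth from sᵢ to z. Fisher scoring
starts at the least-squares intersection of the bearing lines and iterates
z ← z + (Σ gᵢgᵢᵀ)⁻¹ Σ sin(rᵢ)gᵢ with gᵢ = ∇μᵢ and rᵢ the wrapped residual
(tolerance 1e-8 m, max 100 iterations; parallel bearings are flagged
non-converged and excluded). The covariance is σ²(Σ gᵢgᵢᵀ)⁻¹ and the 95%
error ellipse area π·√det(Σ̂)·χ²₂,₀.₉₅. The bearing SD σ defaults to 3°
(receiver systems rarely publish theirs; the value is configurable), or
can be estimated from the circular residuals (`bearing_sd_deg=None`,
needs k ≥ 3) so ellipses track observed scatter. Quality gates: daytime
(foraging/loafing) fixes pass at ≤ 2000 m² (≈ a 25 m radius), roost fixes
at ≤ 1000 m² because roosts are revisited on foot; direct observations
always pass. The filter is idempotent and order-preserving.

## Hunting pressure

Pressure is hunters per photo per site per day. Multiple cameras on a
site-day are pooled by summing hunters and photos *before* the ratio, so
every photo carries equal weight; a mean of per-camera ratios would not.
Site-days with zero photos are missing, not zero. Days before the season
opening carry pressure 0 (no legal hunting), which keeps pre-season
moving windows in the analysis.

## Kernel home ranges

The UD is a bivariate Gaussian fixed-kernel density with the ad-hoc
reference bandwidth h = ½(sd_x + sd_y)·n^(−1/6) (sample SDs, ddof 1).
Grids default to the point bounding box padded by 3h (anything less is
rejected — truncation would corrupt normalization), 200×200 cells for
seasonal estimates and 100×100 for the much more numerous windows; at
these resolutions refining the grid 2× moves the 95% area by well under
2%. Isopleths accumulate raw cell mass in descending density order; the
truncated tail (< 0.6% at 3h padding) lies entirely outside interior
isopleths, so renormalizing by the grid total would bias regions small —
we deliberately do not. The core (50%) center is the density-weighted
centroid of the region; the density mode is also computed for users who
prefer it. Seasonal estimates require ≥ 10 fixes per individual-season;
eligibility is per season, so an individual may appear in some seasons
only. Center shifts are Euclidean distances from the pre-season core
center, defined only for individuals with both members of a pair.

Moving windows take the focal fix plus its five predecessors and five
successors (11 fixes), advanced one fix at a time: n relocations yield
max(0, n−10) windows. Each window gets its own h_ref (recomputed per
window; a per-individual variant is a one-line change), areas, core
center, and window length in days. The assigned site is the one whose
polygon overlaps the window's 95% region with the greatest area (cell-
center counting; ties broken by site id); windows overlapping no site take
the mean pressure across low-risk sites for their date range — a
conservative offsite estimate. Missing pressure days are dropped from the
mean, never imputed as zero; a window with no pressure data at all is
flagged and excluded from models.

## Mixed-model inference

All responses are modeled with Gaussian LMMs fit by REML (statsmodels
MixedLM behind a thin model/results layer). Random structure is intercept
only: site for the risk model; site and individual for space-use models
(fitted as nested when individuals belong to one site, as crossed
variance components otherwise). "Log" means natural log throughout.
Treatment coding fixes each model's reference cell: high-risk/early for
the risk model, low-risk/pre for seasonal size and shift models (fit per
sex), female for the pooled moving-window models. A year term enters only
when the data span more than one year. The moving-window covariate is
log(pressure + 0.001); the offset is needed because pre-season windows
have zero pressure, and results are insensitive to its exact value at the
pressure scales involved.

Inference is posterior simulation under flat priors: draw
σ²⁽ᵏ⁾ ~ σ̂²·df/χ²_df, then β⁽ᵏ⁾ ~ N(β̂, V̂·σ²⁽ᵏ⁾/σ̂²), 5000 draws by
default; report each coefficient's posterior mean and 2.5/97.5% quantiles
and call it significant when the interval excludes zero. Group-mean
contrasts are computed per draw from the fitted design row of each factor
cell (continuous covariates at their data means). At large residual df
the quantiles converge to Wald intervals within 1%. Two numerical
fallbacks matter: at the REML boundary (all random-effect variances ≈ 0)
MixedLM's profiled fixed effects are unreliable, and the model there *is*
OLS, so the OLS fit replaces it; and the covariance square root is taken
by eigendecomposition with negative eigenvalues clipped at zero, which
handles degenerate (zero-variance) fits cleanly.

## Roost-site PERMANOVA

Vegetation responses (warm/cool-season grass %, bare ground %, litter %,
litter depth, visual obstruction) mix units, so the default distance is
Euclidean on column-standardized variables; Bray–Curtis on raw
non-negative values is available. From the distance matrix D, Gower's
centered G = −½JD²J is partitioned sequentially (Type I) over the term
order risk, sex, risk:sex, date (date as a day-of-study integer): term SS
is tr(H_k G) − tr(H_{k−1} G) for the nested design hat matrices, each
pseudo-F tests against the full-model residual, and p-values come from
999 free row permutations with the add-one convention (p is never 0).
One-term models reproduce classical one-way ANOVA F exactly, and the
permutation p matches exhaustive enumeration on small fixtures.

Roost plots are sampled unevenly per individual, so each of the three
models (pre-season roosts; within-season roosts; non-use plots) is run on
a random one-plot-per-individual-per-season subsample, repeated 1000
times; we report each term's median F with 2.5/97.5% bounds and median p,
and call a term significant when the median p < 0.05.

## Survival

Surviving proportions are product-limit estimates anchored at the season
opening (day 0 = onset, proportion 1); collar losses are right-censored
by default (an exclusion mode exists, since field studies rarely state
their handling). With no censoring the estimate reduces exactly to the
naive alive-count ratio. The early-mortality table is
100·(1 − S(10)) per sex × risk group.

## The synthetic study system

`SimulationTruth` holds every generator parameter. Defaults describe the
study regime the package targets: 5 sites per risk group with areas
29–155 ha (rectangles — polygon realism is irrelevant to the tested
computations), 43/36 females and 31/35 males on high/low-risk sites,
daily hunter rates of 0.0061 (high, early), 0.0014 (high, late) and
0.0007 (low) hunters per photo, 120 photos per site-day split over two
cameras, and a behavioral response in which high-risk individuals (both
sexes by default; configurable via `risk_response_sexes`) shift their
activity center 500 m and inflate movement spread by exp(0.77/2) during
the early season, reverting in the late season.

Movement is a discrete-day mean-reverting walk
x_{t+1} = c_t + e^{−φ}(x_t − c_t) + N(0, σ_t²(1−e^{−2φ})) with φ = 0.6/day
and stationary SD σ = 230 m, chosen because the stationary spread maps
directly onto expected kernel area (95% area ≈ π σ² χ²₂,₀.₉₅ ≈ 100 ha
before smoothing, matching the observed scale of such studies). Hunter
counts are Poisson per photo with a mean-corrected lognormal day effect
(SD 0.5) — a mixture assumption, flagged in `truth.yaml`, since no count
model is published for camera-trap hunter data. Vulnerable males
(high-risk sites) die daily with hazard 5.8 × that day's realized site
pressure (≈ 30% expected mortality in the first ten days at the default
rates) on top of a 0.0015/day natural hazard for everyone. Vegetation is
multivariate normal around a baseline with a high-risk group offset and a
date trend, and no sex effect. Relocation error is isotropic Gaussian
with per-fix SD drawn so that most fixes pass the ellipse gates and
~10% fail them; a 15% subsample of fixes is also emitted as raw
three-bearing sets (3° noise) to exercise the triangulation stage.

What the generator does *not* emulate: habitat selection within sites,
weather, non-hunter predators, multi-year turnover, and hunter movement
within a site. Passing tests therefore demonstrate that the estimators
recover the truths of this generative model, not that the model captures
every feature of real field data.

## Problem sizes

The test suite and the acceptance script run the full chain at 12
individuals per sex × risk group (48 birds, ~2000 relocations, ~1300
windows), grids of 64–100 cells for windows and 80–200 for seasonal
estimates, 1500–5000 posterior draws, and 200 bootstrap iterations ×
199 permutations for the PERMANOVA summaries; the parameter-recovery
check uses 50 effect and 50 null replicate datasets. These sizes give
Monte-Carlo error comfortably inside every tolerance asserted.

## Known limitations

- **Overlapping-window inference is anticonservative.** Successive
  moving windows share 10 of their 11 fixes, so both log area and
  window-mean pressure are strongly autocorrelated within an individual.
  Random intercepts do not absorb this, and the model's SEs are too small
  by roughly the square root of the effective overlap (~2.5–3× in our
  simulations): under a zero-effect truth the log-pressure CI excludes
  zero in ~half of replicate datasets rather than 5%. Point estimates are
  unbiased (null estimates center on zero; effect estimates recover the
  simulated magnitudes), and power under real effects is excellent, but
  the *significance* of moving-window coefficients should be read as
  descriptive, not calibrated. The package retains the standard model
  because overlap-aware corrections change the estimator being studied;
  the dedicated recovery test documents the miscalibration rather than
  hiding it.
- Seasonal (non-overlapping) models show no such inflation; their null
  false-positive rates sit at the nominal 5%.
- The bearing-error model is von Mises with a single concentration; no
  signal-strength or antenna physics, and no bias from animal movement
  within a bearing session.
- Kernel estimates at 10–25 fixes carry substantial sampling error; as in
  the underlying design, the analyses compare relative change between
  groups and seasons rather than asserting true home-range sizes.
- PERMANOVA uses free permutation (no strata) and sequential SS in the
  fixed order risk, sex, risk:sex, date; reordering terms changes SS
  attribution, as in any Type-I decomposition.
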