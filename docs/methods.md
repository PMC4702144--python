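# Methods

This note documents the models, the synthetic study design, the numerical
choices and the known limitations of the `sympatry` pipeline.

## The scientific procedure

The pipeline asks whether two sympatric central-place foragers partition
their foraging niche. Its stages, in dependency order:

1. **Dive analysis.** Depth traces are corrected for sensor drift, split
   into surface-to-surface dives, measured for foraging signatures and
   classified.
2. **Foraging ranges.** Location fixes are speed-filtered, each dive gets
   the nearest-in-time fix (≤ 1 h), foraging-dive locations enter a 2-D
   kernel utilization distribution per species (and per tide regime for the
   area report), and every dive is labelled by region — species-only,
   overlap (inside both 95% contours) or outside.
3. **Acoustics.** Each monotone leg of the AUV see-saw is one vertical
   profile with nine water-column features; aggregations are detected in
   the Sv grid, classified dense/diffuse, measured, and attached to
   profiles as presence/absence flags.
4. **Statistics.** Dense-vs-diffuse morphometrics (Mann–Whitney), dive-depth
   comparisons gated by ICC, signature GLMMs, the overlap-contrast LMM, and
   presence/absence model sets with repeated cross-validation.

## Dive model and thresholds

All thresholds are configuration keys with these defaults, chosen from
common biologging practice: dive threshold 1 m (wet/dry), minimum dive
depth 3 m and duration 10 s, bottom band 80% of maximum depth, bottom time
counts as a signature at ≥ 5 s, wiggle excursion 2 m, plateau ≥ 5 s at
|vertical speed| ≤ 0.25 m/s deeper than 3 m, transit/search split at 10 m.
Vertical speed is a centred difference over ±3 s of a 3-point-smoothed
trace, which keeps planted plateaus detectable at 0.3 m depth noise while
leaving ramp speeds (≥ 0.7 m/s) unambiguous.

A consequence of these definitions worth knowing: any dive deeper than
about 19 m at a realistic 1.5 m/s descent spends ≥ 5 s inside the 80% band,
so a deep dive cannot avoid bottom time, and wiggles (which live inside the
band) always imply it. Foraging dives without bottom time are therefore
necessarily shallow, and the generator plants them as shallow plateau-only
dives (12–18 m).

Drift correction estimates the modal near-surface depth (0.1 m histogram
below 6 m, refined by the mean within ±0.3 m) in 30-minute windows and
subtracts the interpolated offset; traces shorter than one window fall back
to a single global offset with a warning. Residual negative depths are set
to zero.

The foraging-depth mode is the argmax of a 1-D Gaussian KDE
(normal-reference bandwidth 1.06·min(sd, IQR/1.34)·n^(−1/5)) on a 0.5 m
grid; ties break to the shallowest depth.

## Range estimation

The kernel is an axis-aligned product Gaussian with per-axis Scott
bandwidths (σ̂·n^(−1/6)); the grid has 250 m cells padded by three
bandwidths, and degenerate axes floor the bandwidth at one cell. The
highest-density region at mass α is the superlevel set found by descending
grid-cell accumulation; contour polygons come from marching squares on the
zero-padded surface, with ring nesting resolved by even-odd containment.
The "overall range" contour is 95% (standard utilization-distribution
convention; configurable), the "core" 50%. Region labels for dives use
tide-pooled ranges: per-tide surfaces built from only a couple of days are
too unstable for labelling, while pooled contours are; per-tide surfaces
are still used for the overlap-area report. Areas are planar km² — the
study frame is a local metric plane, appropriate over tens of kilometres.

## Acoustic detection

Background Sv defaults to the global cell median (aggregations are sparse).
Detection threshold is background + 6 dB, components are 8-connected with a
4-cell minimum; both sit between sensible operating points and are
configuration keys, as is the dense/diffuse split at −64 dB linear-domain
mean Sv, which lies between the planted type means (−62 / −66 dB).
Edge-touching components are retained but flagged truncated. All Sv
averaging is dB → linear → mean → dB, so a mean can never exceed the
maximum input.

Water-column features are computed on 1 m-binned profiles: gradients
(mixed layer depth, thermocline) by centred differences; the 1 W/m²
isolume by the shallowest log-linear PAR crossing (light decays
exponentially); surface PAR as the mean over the upper 2 m of sampled
water; integrated CHL by trapezoid over 0–50 m, flagged missing below 40 m
of coverage rather than extrapolated. "Within 3 m of the vehicle" is
interpreted as vertical range from the vehicle depth in the same along-track
column.

## Statistics

* Mann–Whitney U reports a tie-corrected normal Z; for n + m ≤ 18 the
  p-value is exact by full enumeration of the permutation distribution of U
  (midranks), two-sided p = min(1, 2·min(tails)). K-S tests use the exact
  small-sample distribution where available, with one-sided alternatives
  for directional questions.
* The distribution-comparison gate computes a one-way ANOVA ICC per sample
  (negative variance components truncate to zero); if every ICC is below
  0.30 the simpler K-S test is used, otherwise a random-intercept LMM on
  square-root depth. The cutoff is a configuration key.
* Gaussian mixed models are ML (not REML) fits; binomial mixed models are
  fitted by maximising the exact marginal likelihood with 21-node
  Gauss–Hermite quadrature over the random intercept, with standard errors
  from the numerical Hessian. The fit is validated against `glmer`
  (adaptive quadrature) in the test suite.
* ΔAIC model sets flag substantial support strictly below 2.0. Candidate
  sets are hypothesis-style combinations of water-column predictors;
  predictors are z-standardized (population SD) and screened by VIF < 4.
* Cross-validation is stratified 10-fold, repeated 10 times; out-of-fold
  population-level probabilities are pooled per repeat, thresholded at 0.5
  for kappa/PCC/sensitivity/specificity, with rank-based AUC; the report is
  the mean ± SD over repeats. Pooling (rather than per-fold averaging) and
  the 0.5 threshold are deliberate, documented choices.
* Convention throughout: p < 0.05 significant, 0.05 ≤ p < 0.10 marginal.

## The synthetic study

Defaults describe a plausible two-colony campaign: 5 individuals per
species, colonies 16 km apart in a local planar frame, per-day tide labels
in alternating two-day blocks, 1 s TDR sampling, 0.15 m depth noise and a
linear sensor drift bounded by ±2 m. Foraging-dive depth distributions
differ by species (bottom-dive means 35 m vs 53 m), signature probabilities
follow the observed proportions (bottom time 0.84/0.73, wiggles 0.17/0.28),
and gentoo plateau probability is 0.27 — tied to 1 − p(bottom) by the
geometric constraint above, deeper than field-reported but preserving the
interspecific direction. Durations emerge from depth, descent rate
(1.5 m/s) and planted bottom time (25 s / 45 s means), landing near 75 s
and 115 s respectively.

Individuals have home foraging centres in their species' area; a
configurable fraction are overlap users whose days split between the shared
zone (a 2.5 km disk midway between the colonies) and home — always at least
one day of each, so the within-individual contrast the LMM needs exists by
design. Dive sites follow a mean-reverting random walk around the trip
target so successive fixes imply realistic swim speeds. Gentoo foraging
dives whose true site lies inside the zone receive the configured additive
depth shift (default 30 m) — the planted vertical-partitioning effect.

AUV missions are triangular see-saws (1–88 m, 300 m legs) over a two-layer
column (tanh transitions at the mixed layer and thermocline, Gaussian CHL
bump, exponential light). The depth scales vary sinusoidally along track
(±15%, 3 km wavelength), and aggregation placement weights windows by the
local isolume depth, so presence models have a real gradient to recover.
Aggregations are ellipses with lognormal morphometrics: diffuse layers
(height median 2.6 m, length median 15 m); dense patches a 70/30 mixture of
compact swarms (height shifted +0.6 in log, length anti-correlated with
height) and thin elongated layers (height ×0.35, length ×1.2). This mixture
was calibrated once, at design time, so that rank tests on per-study samples
reproduce the qualitative pattern observed in the field — heights, areas
and internal Sv separate the types while depths, lengths and length:height
ratios mostly do not. The length:height row is the structurally hardest:
its median shift is algebraically tied to the height shift whenever lengths
are type-neutral, and the achievable "correctly non-significant" rate
plateaus near 75–85%; 1 m depth-cell quantisation of detected heights eats
further into it. Tests assert the pattern row-wise at an 80% reproduction
rate, and the length:height row is expected to sit at that boundary.

What the generator does **not** emulate: provider-specific location error
classes (only a speed filter is modelled), sea ice, bathymetry, prey
mobility or depletion, diel vertical migration, accelerometry, and
fluorescence quenching. Passing tests therefore demonstrate that the
pipeline recovers what it is designed to measure under a faithful but
idealised rendering of the campaign, not that it is robust to every field
artefact.

## Problem sizes

The test suite and the acceptance script run the study at desk scale,
chosen as the smallest sizes at which the statistical checks are stable:
2–4 days, 12–35 dives per trip for unit and end-to-end tests (50 effect
replicates and 100 null replicates for the recovery checks), 200/100/100
replicates for the mixed-model calibration batteries, and one long mission
(26 km, 70 dense + 105 diffuse patches) per replicate for the morphometric
pattern check. The acceptance script runs one full 4-day study.

## Known limitations

* Wald inference for the LMM contrasts (no small-sample df correction, by
  design); measured null false-positive rate ≈ 6% at 5 individuals per
  species.
* Repeated-CV AUC under a null model is biased slightly below 0.5 at small
  n; the calibration check uses n large enough that the bias is negligible.
* The overlap region is the intersection of two estimated 95% contours, so
  region labels near the zone boundary are noisy; the planted depth effect
  attenuates accordingly (≈ 23 m observed for 30 m planted at defaults).
* Random slopes, model averaging and Bayesian fitting are out of scope.
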