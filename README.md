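# sympatry

Do two closely related diving seabirds breeding in newly overlapping ranges
compete for the same prey, or do they partition their foraging niche?
`sympatry` is an analysis pipeline for exactly this question in the
Adélie / gentoo penguin – Antarctic krill system: it classifies foraging
behaviour from time-depth-recorder (TDR) traces, detects krill aggregations
in AUV echograms and measures their morphometrics, extracts water-column
structure from vehicle profiles, estimates kernel-density foraging ranges
and their overlap, and runs the mixed-model statistics that test for
vertical habitat partitioning — the signature result being that gentoo
penguins dive *deeper* where their range overlaps the Adélie range.

Because raw at-sea telemetry of this kind is rarely public, the package
ships a first-class synthetic-data generator that emulates the whole field
campaign — central-place foraging trips around two colonies, dive profiles
with planted bottom-time / wiggle / plateau signatures, and see-saw AUV
missions over a stratified water column with planted elliptical prey
aggregations — with a ground-truth record for every generated entity, so
every stage of the pipeline is testable end to end.

## The models at the core

* **Dive classification.** A dive's bottom phase is the interval between
  the first and last sample within 80% of its maximum depth; wiggles are
  complete vertical oscillations ≥ 2 m inside that phase; plateaus are
  shelves ≥ 5 s with |vertical speed| ≤ 0.25 m/s outside it. A dive is a
  foraging dive iff it has any signature; otherwise transit (< 10 m) or
  search.
* **Utilization distributions.** Foraging locations enter a product-Gaussian
  kernel density with per-axis normal-reference bandwidths; the 50% and 95%
  highest-density regions are the core and overall ranges, and interspecific
  overlap is their polygon intersection (areas in km²).
* **Aggregation detection.** Echogram cells exceeding background Sv by 6 dB
  form 8-connected components; components are dense or diffuse by their
  linear-domain mean Sv (split at −64 dB) and measured for depth, height,
  length, area, length:height and mean Sv.
* **Statistics.** Two-sample Kolmogorov–Smirnov tests (exact for small
  samples, with one-sided alternatives), Mann–Whitney U with exact
  enumeration for small samples, intraclass-correlation gating (ICC < 0.30
  → K-S, otherwise a linear mixed model), ML-fitted linear and binomial
  random-intercept mixed models (the binomial GLMM is fitted by
  Gauss–Hermite quadrature), ΔAIC model sets (ΔAIC < 2 = substantial
  support), VIF screening, and repeated stratified 10-fold cross-validation
  reporting Cohen's kappa, AUC, PCC, sensitivity and specificity.

## Worked example

```python
from sympatry.config import SimConfig
from sympatry.pipeline import RunConfig, run_pipeline

res = run_pipeline(RunConfig(sim=SimConfig(seed=1, days=4)))
c = res.summary["gentoo_overlap_contrast"]
print(f"gentoo deeper-in-overlap LMM: t = {c['stat']:.2f}, p = {c['p']:.2g}")
print(res.overlap_areas[["tide", "overlap_km2"]])
```

prints

```
gentoo deeper-in-overlap LMM: t = 3.98, p = 6.8e-05
           tide  overlap_km2
0       diurnal     3.667954
1  semidiurnal     2.591300
```

The contrast is a random-intercept LMM on square-root maximum dive depth of
gentoo foraging dives, inside vs outside the estimated interspecific
overlap region: the planted 30 m "dive deeper where the ranges overlap"
effect is recovered as a strongly significant positive contrast, and the
per-tide overlap areas quantify how much of the two species' 95% ranges
intersect. `res.tables` holds the full report surfaces: the dense-vs-diffuse
morphometrics table with Mann–Whitney columns, region × tide depth
comparisons, behaviour-signature GLMMs, ΔAIC model sets and cross-validation
metrics for aggregation presence/absence.

The same run is available from a shell:

```sh
sympatry run --seed 1 --days 4 --out runs/demo
sympatry report runs/demo
```

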