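# Methods

`uelshift` asks whether a species' observed upper elevational limit (UEL)
on a mountain gradient is in equilibrium with its climate — that is,
whether the species occurs as high as its global climatic niche says it
could. The package implements the full chain from occurrence records to an
equilibrium verdict, together with a synthetic-data generator whose true
limits are known in closed form, so every stage can be validated.

## The model chain

**1. Environmental space.** A global background sample of available
climates (10,000 points by default, each carrying 19 collinear bioclim-like
variables) is centred, scaled to unit variance, and reduced to its first
two principal axes. All subsequent geometry lives in this two-dimensional
environmental plane. Axis signs are fixed (largest-magnitude loading
positive) so runs are reproducible across platforms.

**2. Niche delineation.** The species' global occurrences are projected
into the plane and smoothed with a diagonal Gaussian kernel (Scott's rule
per axis) on an R x R lattice (R = 100) spanning the background envelope
padded by one bandwidth. The *niche region* is the smallest set of densest
cells containing 99% of the occurrence density mass; ties at the cut are
all included. We read "leaving out the most extreme 1%" as 1% of density
mass, not 1% of occupied area: mass-quantile contouring is the standard
convention of gridded-environment niche analysis and is the reading with a
closed-form check (for bivariate-normal occurrences the mask area must
approach pi * chi2_2(0.99) * sd1 * sd2). An availability-corrected density
(occurrence / background) is available behind a flag but is off by
default; the classification step below intersects the niche with the
regional envelope explicitly, so correction is not needed there.

**3. Suitability classification.** Regional points (a systematic sample of
the study area's climates, each with an elevation) are projected into the
same plane, calibrated on the global background only. A point is *zone A*
(climatically suitable) iff its enclosing grid cell is in the niche mask;
points outside the grid envelope are zone B by definition, since the
global background spans realizable climates. Sorting the 0/1 labels by
elevation yields a presence/absence-along-elevation series.

**4. Response curves.** The seven Huisman–Olff–Fresco (HOF) shapes — flat,
monotone sigmoid, plateaued sigmoid, symmetric and skewed unimodal, and
two bimodal forms — are fitted to the series by maximum Bernoulli
likelihood on the gradient rescaled to [0, 1]. Published parameterizations
of the bimodal types vary; here the second hump shares the first hump's
shape parameters, shifted by f, with type VII adding a height ratio.
Free-parameter counts are 1/2/3/3/4/4/5 for types I–VII, the plateau M is
fixed at 1 for presence/absence data, and the best type is chosen by AIC
(ties go to the simpler model). Fitting uses 10 seeded Latin-hypercube
starts per type, all polished simultaneously by one bounded L-BFGS-B run
on a stacked (separable) objective with analytic gradients; probabilities
are clipped to [1e-9, 1 - 1e-9] so separable data stay finite. Bounds are
b, d in (0, 200] and |a|, |c| <= 250 — the offset bound must reach the
steepness bound, because a type-II inflection at scaled position u sits at
a = -b u. Starting points are drawn from the informative core of the box
(|a|, |c| <= 30, b, d <= 60); the optimizer may leave it.

**5. Outer border and the predicted limit.** The *outer border* (OB) is
the highest elevation at which the fitted response still reaches exp(-2)
of its maximum — the predicted UEL on the descending side. It is located
on a 1 m lattice and refined by bisection to 0.1 m; a response still above
the threshold at the top of the gradient is censored there. The predicted
UEL is the mean OB over 100 replicates, each refitting the whole family to
a stratified subsample of 25% of the presences and 25% of the absences
(without replacement; sampling the strata separately keeps sparse
presences represented). Censored replicates are retained at the gradient
top and counted — dropping them would bias the interval downward. The 95%
CI is the 2.5–97.5 percentile of the replicate OBs (a normal-theory
mean ± 1.96 SD interval is also reported). A species is *in equilibrium*
when its observed UEL falls inside the CI, *below* when under it, *above*
when over it.

**6. Comparative statistics.** Temporal change in observed UELs between
two survey epochs is tested with rank-based Wilcoxon tests (unpaired
rank-sum by default, matching a reported W of the Mann–Whitney form;
paired signed-rank available), with exact null enumeration for samples of
at most 10 and a tie-corrected, continuity-corrected normal approximation
otherwise. Observed is regressed on predicted UEL by OLS; equilibrium
predicts the identity line, so alongside the correlation test the package
reports t = (1 - b)/se(b) against slope 1 with df = n - 2. Trait effects
(residence time, dispersal mode, life span) on either UEL change or the
standardized mismatch dUEL = |UELo - UELp| / UELp are assessed with a
sequential (Type-I) ANOVA in that term order (Df pattern 1/2/2), rows with
missing traits dropped listwise. The printed formula for dUEL is read as a
ratio: "standardized difference" semantics.

## The synthetic generator

The generator emulates the statistical structure the method assumes, with
analytic ground truth:

* **World.** Climate variables are noisy linear mixtures of a few latent
  gradients (temperature tied to |latitude|, moisture to longitude), so
  they are strongly collinear and two or three principal components carry
  nearly all variance, as with real bioclim layers.
* **Region.** A road gradient (1900–3600 m by default) whose temperature
  latent falls at 6.1 degC/km from 7.1 degC at the base — the adiabatic
  lapse rate and span of a Mediterranean-Andean roadside study system.
  Elevation → climate is deterministic by default (a microclimate-noise
  flag exists), which is what makes limits exactly known.
* **Species.** Gaussian niches in latent space. The true UEL is the
  highest elevation whose regional climate lies inside the 99%
  chi-square ellipsoid of the niche — a closed form, because only the
  temperature latent varies along the road. A *dispersal deficit* places
  the realized limit a fixed distance below the climatic one;
  detection probability thins survey presences.
* **Survey.** Two-epoch roadside plot presences every 100 m, observed UEL
  = highest detected plot; categorical traits drawn independently of the
  dynamics (an effect-size knob exists for power studies). Coordinate
  uncertainties are lognormal with median 300 m, so the strict <1 km
  filter removes a seed-stable, nontrivial fraction.

What the generator does *not* emulate: real geography and land masks,
spatial autocorrelation of records, sampling bias in occurrence archives,
niche asymmetry, and biotic interactions. Passing recovery tests therefore
demonstrate the internal consistency of the chain, not field validity.

## Recovery experiments and a known limitation

The recovery experiments (`uelshift.experiments`) run the full pipeline in
independent synthetic worlds and compare the predicted limit and its CI
with the analytic truth. Their fixed conditions: two latent gradients with
two-dimensional species niches (the analysis retains two PCA axes, so
latent variation a species ignores would otherwise inflate its apparent
niche and make truth and estimate different quantities); occurrences drawn
from a large independent pool (occurrence archives are far denser than the
10,000-point background); 240 regional points as a desk-scale stand-in for
a ~3,000-pixel regional grid; 100 resampling replicates; the equilibrium
verdict compared against the exact realized limit.

Across 100 worlds the 500 m-deficit species is classified "below" in 100%
of worlds, but the zero-deficit species is classified "in equilibrium" in
only ~45%, and the 95% CI covers the analytic limit in ~45% — not the
~95% a calibrated interval would give. The package computes these rates
honestly rather than hiding them, because they reveal a structural
property of the method: the predicted limit carries a small upward bias
(median ~+35 m here) that the resampling CI cannot see. The bias has three
sources: (i) kernel smoothing widens the 99% density surface beyond the
true niche edge by a factor ~sqrt(1 + n^(-1/3)) (about +40 m for niche sd
of 1–2 degC at a 6.1 degC/km lapse and ~2,500 records); (ii) the R = 100
grid over the whole global envelope quantizes the niche edge by about half
a cell (~25 m along the thermal axis); (iii) the exp(-2) border lies
2.035/b of the gradient span above the fitted step (+17 m at the
steepness bound). The resampler refits only the response-curve stage on a
*fixed* suitability labelling, so its CI (median width ~68 m) measures
subsample noise alone. Consequence for practice: equilibrium verdicts are
conservative in a specific direction — a genuinely equilibrial species
with a sharp niche edge can be misclassified as "below" by a few tens of
metres, while large deficits (hundreds of metres) are detected reliably.
Interpreting "below" calls that are within ~100 m of the CI requires
caution; calls below by several hundred metres do not.

## Numerical choices and degenerate inputs

* AIC ties broken toward fewer parameters, then the lower type number.
* All-presence or all-absence suitability series are flagged and excluded
  from limit prediction (a flat response has no interior border).
* Species with fewer than 5 presences (configurable) are skipped with a
  log entry, never a crash; replicates that fail inside the resampler are
  counted, and a species with >50% failures is reported "unstable" with no
  CI.
* A degenerate occurrence cloud (zero spread on an axis) falls back to a
  one-cell kernel bandwidth.
* Every random draw flows from an explicit seed; reruns are byte-identical
  including written artifacts.
* Problem sizes in the shipped tests (30-world recovery study; 40 in the
  acceptance script) are desk-scale choices; a 100-world reference run
  gave the same rates.

## Interpreting the two open layout questions

Where two roads overlap in elevation, observed UELs are pooled across
roads into a single per-species maximum (the generator can also emit
per-road tables). The regional climate is taken at pixel centres, for
determinism. Both choices are logged in the run manifest.
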