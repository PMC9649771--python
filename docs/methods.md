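# Methods

## Model

Each trait decile is modeled as a presence–background SDM. The fit is the
weighted-logistic (infinitely weighted logistic regression) formulation of
maximum entropy: presence weights sum to 1, background weights to a
constant `bg_weight` (default 100), so the solution approaches the maxent
density estimate as the background weight grows, and duplicating presence
rows leaves the fit unchanged. Coefficients carry an L2 penalty λ (default
1.0) on features standardized by the mean/sd of the training stack's valid
cells. The optimizer is L-BFGS with an iteration cap of 500; hitting the
cap raises a convergence error with diagnostics rather than returning a
silently unconverged model.

Logistic output uses an assumed prevalence of 0.5: the class-imbalance term
`log(w_presence/w_background)` is removed from the fitted intercept, so a
model with zero coefficients scores 0.5 everywhere. Feature classes default
to linear + quadratic — at ~40 presences per decile richer classes overfit,
and a quadratic response is exactly what a banded (unimodal) niche needs —
with product and hinge classes available through `FeatureSpec`. Projection
onto any other stack reuses the stored normalization constants verbatim;
nothing is re-standardized at prediction time.

Two conventions follow standard maxent practice and are configurable:
background sampling does not exclude presence cells, and the per-layer
"percent contribution" is permutation importance (mean training-AUC drop
over shuffles of one layer across the evaluation points, floored at zero,
normalized to 100) — a model-agnostic replacement for the path-dependent
contribution of the original maxent software.

### Threshold

τ₁₀ is the largest training-presence suitability whose strictly-below
fraction of training presences is ≤ 10%, guaranteeing training omission
≤ 0.10 (with ties, possibly less). It is computed once on the training
stack, stored on the model, and reused for every projection; recomputing it
on a projection stack would silently re-anchor the threshold to the shifted
climate and corrupt every change map.

### Evaluation

5-fold cross-validation partitions presences at random (seeded); each
fold's held-out presences are scored against the full background sample
(presence–background AUC, rank-based with half credit for ties). The
reported mean ± sd is across folds; the final model is refitted on all
presences for the training AUC, threshold and omission rate.

## Stacking and change

Richness is the cell-wise sum of the ten binary maps; nodata propagates if
any input is nodata. Change maps are `future − current` with a separate
mask for cells of zero baseline richness, because a zero delta there means
"unsuitable throughout", not "stable". Loss/gain percentages count changed
cells regardless of magnitude; the magnitude distribution is kept as a
histogram over delta values −10…10. Two denominators are reported side by
side: `all-valid` (every valid cell in the extent — "percent of the
landscape modeled") and `suitable-only` (cells suitable for ≥ 1 decile at
baseline). GCM-averaged summaries use a normal-theory mean ± 95% CI over
the three GCM values; with n = 3 this is deliberately approximate and
summarizes between-GCM spread only.

## Trait communities, similarity, ordination

Suitable cells are encoded as 10-bit decile masks (1…1023). Community
matrices count cells per (population, scenario) row and mask column. The
similarity of a cell's set is `1 − d̄/9` with d̄ the mean pairwise |i−j|
over present deciles (singletons: 1; only {1,10} reaches 0). Scenario
similarity is the count-weighted mean over combinations — weighting by cell
counts rather than averaging over distinct combinations is a choice; the
alternative would up-weight rare combinations. Positive baseline deltas
mean convergence (narrowing trait distributions).

RDA column-centers the raw count matrix and regresses it on dummy-coded
factors; the constrained fraction is SS(fitted)/SS(total) and p-values come
from seeded row permutations (999 by default). A Hellinger transform is
available but off by default, mirroring the default behavior of standard
vegetation-analysis RDA. Stepwise selection alternates forward additions
(smallest permutation p < α = 0.05, 199 permutations) with backward drops
of terms whose marginal contribution is no longer significant, to a fixed
point. Rank-deficient constraint sets are rejected with the aliased levels
named.

## Synthetic landscape

The generator emulates the statistical structure the analysis assumes, not
any real geography:

- **Climate layers**: a linear latitudinal gradient per layer (defaults:
  `cmi` 8→2 and `ppt_wt` 7→3 south-to-north; `rh` and `td` 3→7) plus
  spatially smoothed Gaussian noise (sd 0.6, smoothing radius 3 cells,
  periodic boundaries so the field is stationary). Units are arbitrary but
  consistent; each layer spans roughly [2, 8].
- **Streams**: a random spanning tree on a coarse lattice (spacing 3
  cells), rasterized, with Strahler orders computed from the tree; ~33% of
  cells are stream cells. Occurrences are confined to streams (riparian
  habitat), and stream order enters the models like any other layer.
- **Populations**: 57/157/186 genotypes (southern/central/northern) sampled
  without replacement from stream cells of three latitude bands; the bands
  stand in for the watershed extents of the real study. Leaf-out day =
  round(98 − 1.8·cmi − 0.6·ppt_wt + 0.8·rh + 1.0·td + population offset
  (−6/0/+6) + N(0, 8²)), clipped to Julian 71–125. The coefficient signs
  fix the trait–environment correlations (earlier leaf-out with higher
  moisture/winter precipitation, lower humidity/continentality); the trait
  noise sd of 8 days and the stream density were set so the fitted decile
  models evaluate at a mean test AUC of ~0.86 (per-decile 0.81–0.91),
  inside the 0.79–0.89 band of the reference analysis.
- **Future scenarios**: additive per-layer shifts, `base × rcp-factor ×
  period-factor × GCM-factor`, applied to the identical baseline field (the
  noise is not resimulated), so analytic truth is preserved. The default
  signs (`cmi`/`ppt_wt` +, `rh`/`td` −) push every layer beyond its current
  southern-edge values — trailing-edge conditions intensify. Under these
  defaults the species range shows net losses of ~17–26% across scenarios
  and all population × scenario similarity deltas are positive
  (convergence).
- **Seeding**: one master seed spawns named substreams (environment,
  stream, populations, background, CV folds, permutations), so regenerating
  one stage never perturbs another; everything is bit-reproducible.

What the generator does **not** emulate, and hence what passing tests do
not show about real data: climate layers are collinear along a single
gradient, so a directional shift largely *redistributes* suitable
conditions within the map rather than destroying them — per-population
loss ordering is flatter than the strongly south-dominant pattern of real
trailing-edge dynamics. There is no topography, no spatial autocorrelation
beyond the smoothing radius, no gene flow (population offsets stand in for
genetic structure), and GCM factors are scalar multipliers, not climate
fields.

## Planted-niche recovery

`recovery_config()` defines a harder, verifiable variant: the trait depends
on one driver (`cmi`, −5 days/unit, noise sd 1 day), populations occupy
only rows 18–82% of the grid so both range edges hold background-only
climates (without this the edge-decile models are monotone in the driver
and cells leaving the range never lose suitability), and environmental
noise is reduced to 0.2. `plant_decile_niches` then splits the driver's
distribution over occupied stream cells into ten quantile bands — aligned
by construction with the equal-count trait deciles, and identical to
equal-width bands for a uniform driver — each widened by 0.5 band widths,
with band order reversed when the trait decreases with the driver.

The recovery experiment fits the pipeline (λ = 0.05 here: tight planted
bands need weak shrinkage) and checks two things against band arithmetic:
(1) the fraction of (stream cell, decile) suitability states matching the
truth, and (2) the net-loss percentage under a *coherent climate
displacement* — every gradient layer shifted by 1.5 tenths of its occupied
span, signed by its gradient direction — versus the analytically shifted
truth. The displacement must be coherent: shifting the driver alone leaves
the correlated co-gradient layers behind, an off-manifold scenario the
single-driver oracle cannot represent.

## Numerical choices and problem sizes

- Grid default 160 × 100 (16,000 cells) at 0.05°; background 10,000 cells
  (all valid cells when fewer). These sizes keep a full 13-scenario run
  under ~10 s while leaving every statistical property measurable.
- Percent-area rounding is decimal half-up to one decimal place.
- Ties in thinning keep the first genotype in (leaf-out day, id) order;
  tie groups in decile assignment collapse into the earlier decile, so no
  trait value spans two deciles. With heavy ties a bin can end up empty;
  only fewer than ten distinct trait values is an error.
- AUC ties get half credit; empty score lists are errors, as are empty
  extents, zero-denominator percentages, and constant layers (degenerate
  normalization).
- Permutation p-values use the add-one estimator (1 + #{≥ obs})/(1 + n).

## Known limitations

- Raster I/O is ESRI ASCII grid only (text); georeferencing is taken as
  given and never reprojected — co-registered inputs are a precondition.
- The logistic-output prevalence, background-inclusion and permutation-
  importance conventions approximate, but do not replicate, the original
  Java maxent implementation; exact parity is a non-goal.
- The RDA operates on raw centered counts; published variance fractions
  from differently transformed matrices are not comparable targets.
- Small-n permutation tests (few rows, 2-level factors) are conservative
  because the permutation group is discrete.
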