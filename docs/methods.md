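# Methods

This note documents the models and procedures implemented in
`insularity`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not show about real data.

## The system being modelled

The package targets edaphic habitat-island archipelagos: patches (here,
quartz-gravel islands) whose soil contrasts sharply with a surrounding
vegetation matrix. Island biogeography predicts richness from area and
isolation; habitat-island work adds within-island heterogeneity and the
permeability of the matrix. The pipeline quantifies five predictors per
island and relates them to three responses — generalist richness (GR),
habitat-specialist richness (QS), and the specialist percentage (QS%).

## Spatial predictors

**Island area and perimeter** come straight from the polygon geometry in
a projected, metre-unit CRS. All distances are planar Euclidean;
geographic (lon/lat) input is rejected rather than silently reprojected,
because a metre is load-bearing in every index below.

**Nearest-neighbour distance** is the minimum edge-to-edge distance to
any other island, sampled or not — isolation is a property of the whole
archipelago, so unsampled islands must be present in the polygon input.

**Target effect** is `log10(max(DMI, ε)/√A)`, with DMI the edge-to-edge
distance to the archipelago's largest island (the "mainland
equivalent"). High values mean a small island far from the species pool.
Choices: the logarithm base is 10 (configurable), consistent with the
log10 transforms used elsewhere in the chain; for the main island itself
DMI = 0, and a configurable floor ε (default 2 m, one image cell) keeps
it in the models instead of dropping it — the alternative, excluding the
largest island, would silently change every model's n. Area ties for
"largest" break to the lexicographically smallest id so pipelines are
deterministic.

**Habitat diversity index.** Each island is partitioned into five main
habitat types by ordered per-cell rules on DEM derivatives
(Horn slope/aspect, topographic position index, D8 flow accumulation):
drainage if flow accumulation ≥ 50 cells, else valley/ridge if
TPI ≤ −0.5 m / ≥ +0.5 m (50 m TPI window), else slope if ≥ 5°, else
plain; slope cells split into four aspect-quadrant sub-habitats. The
thresholds are not canonical — they are defaults that produce all five
classes on realistic synthetic terrain, and every one is configurable.
Patches under 4 cells merge into their largest neighbour to suppress
single-cell raster artefacts. The index is

    HDI = TP / (2·√(π·A)),

where TP = island exterior perimeter (vector) + the length of all
internal habitat boundaries. Internal boundaries are the shared edges
between 4-adjacent cells with different sub-habitat labels, each counted
once (the total enumerates *boundaries*, not patch perimeters, which
would double-count); boundary lengths use the raster staircase with no
smoothing so an edge-enumeration oracle can check them exactly. A
homogeneous circular island scores exactly 1 (isoperimetric minimum);
internal boundaries and shape complexity raise it; the index is
scale-invariant.

**Matrix contrast.** NDVI = (NIR−red)/(NIR+red) over the scene is
classified into five ordinal units by Jenks natural breaks (exact
Fisher optimal 1-D partitioning, implemented as a dynamic programme and
checked against exhaustive search in tests). For each island, the class
values of all cells whose centres fall inside a 50 m buffer ring
(dilation minus the island itself) are summed and divided by the ring
area. Choices, both exposed as options: class ranks 1–5 are summed
rather than raw NDVI (classification immediately precedes the sum in the
procedure being implemented, and rank sums are robust to sensor
scaling; `--raw-ndvi` switches); pixels of neighbouring islands inside a
ring are kept — they are part of the focal island's surroundings — with
a mask option to exclude them. Breaks are computed once over the whole
scene (subsampled with a fixed seed to 10 000 cells when larger) so the
index is comparable across islands; cell membership is a
centre-in-polygon test, deterministic and oracle-checkable.

An optional proximity-type index (Σ areaⱼ/dⱼ² within a search radius) is
provided as an explicitly reconstructed fragmentation-analysis measure
and excluded from the default predictor table.

## Responses

From the island × species incidence matrix and per-species specialist
flags: total richness, QS (specialist incidence sum), GR = total − QS,
and QS% stored as a proportion *with its (successes, trials) pair* —
a percentage modelled by a binomial GLM needs trial counts, and island
total richness is the only coherent trial count. Species without a trait
entry are an error, never silently generalist. Empty islands leave QS%
undefined (missing, with a warning).

## Statistical chain

**SAR.** The power model S = cA^z is fitted as OLS of log10 S on
log10 A, reporting z, the intercept, R², F(1, n−2) and a t-based 95% CI
on z. Zero-richness islands are dropped (their log is undefined; a +1
shift would bias z). Constant richness returns the flat degenerate fit
(z = 0, R² = 0) rather than 0/0.

**GLM families.** Counts (GR, QS) use a negative binomial with log link;
the dispersion θ is estimated by maximum likelihood, alternating IRLS
for the coefficients with 1-D profile optimisation of θ (the classic
glm.nb scheme). The fitter reproduces statsmodels' independent
full-ML discrete NB estimates to ~1e-6 and is checked in tests against a
direct joint-likelihood optimiser. QS% uses a binomial with logit link
on (QS, total). A Poisson family is retained for the overdispersion
check (Pearson χ²/df > 1.5 flags it, and counts here are essentially
always overdispersed).

**Chain order.** (1) Shapiro–Wilk at α = 0.05 per predictor; rejected
columns become log10(x + 0.01). A predictor that is non-normal but has
values ≤ −0.01 (the target effect is already a log) is left untransformed
with a warning in the pipeline; the low-level function treats it as an
error by default. (2) z-standardisation (sample SD); squared terms are
built *after* standardisation as z². (3) Single-predictor models, linear
and quadratic; a predictor's squared term enters the full model only if
it is significant here. (4) Exhaustive AICc search over all term subsets
respecting marginality (x² never without x), intercept-only included —
at most 7 candidate terms, ≤ 2⁷ subsets; θ is re-estimated per candidate
model, matching the default behaviour of dredge-over-glm.nb workflows
(AICc ordering depends on this, hence it is fixed here). AICc counts θ
as a parameter for NB models. Non-converged subsets stay in the table,
ranked last. (5) Backward pruning: repeatedly drop the least significant
droppable term with Wald p ≥ 0.05 (never a linear term whose square
remains) and refit; then, while any VIF > 5, drop the collinear term
whose removal minimises the refit AICc. Intercept-only is a legal
endpoint. (6) Explained variance is the deviance pseudo-R² =
(null − residual)/null deviance, with the null deviance computed under
the fitted model's own θ.

Numerical notes: θ profiling converges on |Δ log-likelihood| < 1e-6 with
θ ∈ [1e-4, 1e8]; because θ is re-estimated per model, residual deviance
is not strictly monotone across nested NB models (it is under a shared
θ, and the monotonicity test uses the Poisson family where the property
is exact). The AICc→AIC gap is 2k(k+1)/(n−k−1) exactly, which tests
assert in closed form.

## Synthetic archipelago generator

The generator exists so every stage can be tested end to end with known
truth. It emulates: a 47-island archipelago with areas log-uniform over
2.5×10³–8.3×10⁶ m² (one island pinned at the maximum as the mainland
equivalent, all islands ≥ 1000 m², plus ~10 small unsampled islands);
rejection-placed star-convex polygons with ≥ 100 m edge gaps, rescaled
exactly to their drawn areas; terrain as two-scale smoothed Gaussian
fields plus per-island ridge/valley tents so large islands classify into
several habitats; and imagery back-solved from a target NDVI field —
matrix ≈ N(0.35, 0.05) with 60 m spatial correlation, scaled per island
by a density multiplier mᵢ ∈ [0.3, 1.5] within a 100 m halo, island
interiors ≈ N(0.08, 0.03) over bright (quartz-like) ground.

Communities are generated top-down from richness: the analysis consumes
only richness, so NB counts are drawn first (truth bookkeeping stays
exact) and species identities follow, sampled without replacement under
exponential rank-decay weights, which yields nested composition.
Latent log-means use z-scored predictors *computed from the scene by the
real predictor modules* (the loop is closed):

    η_GR = β₀ + β_logA·z(log10 A) + β_mc·z(MC) + β_mc2·z(MC)²
    η_QS = β₀' + β_logA·z(log10 A) + β_hdi·z(HDI)
           + β_mc·z(MC) + β_mc2·z(MC)² + β_te·z(TE) + β_te2·z(TE)²

Default effects (β_logA = 0.55, β_hdi = 0.4, β_mc = 0.15, β_mc2 = −0.2,
β_te = 0.15, β_te2 = −0.3, θ = 6, β₀ = 3.7/1.9) are invented calibration
knobs chosen once to produce the qualitative pattern the pipeline is
meant to detect: strong area and habitat-diversity effects, hump-shaped
matrix-contrast and target-effect responses, and no nearest-neighbour
effect. One consequence worth noting: with log-uniform areas over the
stated range, sd(log10 A) ≈ 1.02, so β_logA = 0.55 on the z-scored
log-area under a natural-log link implies a SAR exponent
z ≈ 0.55/(ln 10 · 1.02) ≈ 0.24 — the generator's defaults and the
classic habitat-island z-value are mutually consistent rather than
independently tuned.

For repeated simulation studies (type-I error, coverage, dredge
selection rates) a predictor-level shortcut draws the five predictors
directly from distributions matching the full scene — the target effect
built structurally from a lognormal DMI so its negative correlation with
area is automatic — skipping terrain/imagery synthesis. The full raster
loop is exercised by the single-scene tests and the acceptance run; the
repeated studies test the statistical layer, which only sees the
predictor table.

**What the generator does not emulate:** real quartz-field soil
gradients, spatially autocorrelated community composition, observation
error in the floristic survey, image misregistration or atmospheric
effects, and non-stationary matrix structure. Passing tests therefore
demonstrate correctness of the computational chain and recoverability of
planted effects under the stated noise model — not that the effect sizes
themselves generalise to any particular field system.

## Problem sizes

Raster stages default to the 2 m imagery resolution of the emulated
system; the test suite and the acceptance script run the same generator
at 10 m cells over a 25 km scene (47 islands) and 10–20 m cells over
1.5–6 km scenes (6–12 islands) for unit tests — the indices under test
are resolution-aware but their contracts are resolution-free, and these
sizes keep a full run in tens of seconds. Simulation studies use 100
seeds; the type-I-error check uses 200 replicates at n = 47.

## Known limitations

- D8 flow accumulation has no pit filling; drainage classes on noisy
  flat terrain are conservative.
- Jenks breaks from a 10 000-cell subsample are not the exact
  full-scene optimum (they are exact for the subsample; the subsample is
  seeded and documented).
- The binomial QS% model ignores any extra-binomial dispersion.
- The habitat rule thresholds are a calibration, not an inference; HDI
  values depend on them and on raster resolution, so comparisons are
  only meaningful within one configuration.
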