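# Methods

This note documents the models, the synthetic world, the numerical choices
and the known limitations of `invadiv`.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Analysis model

The unit of analysis is a plot community: the set of tree species recorded
in one inventory plot, each with a native/non-native status and a basal
area (π·(DBH/200)²·TPH per stem, in m²/ha).  Preparation applies, in
order: per-plot latest census; size filter DBH ≥ 5 cm and height ≥ 1.3 m
(both read as inclusive minima; a missing height passes, since a recorded
DBH implies breast height was reached); consensus native status between
two independent registers, dropping any plot containing a species on which
the registers conflict; a ≥ 3-species plot floor; collapse of replicate
plots at exactly identical coordinates to the replicate with the most
stems (ties broken by plot-id order); and optional down-sampling to biome
land-area proportions.  Species found in neither register are "unknown":
they count toward whole-community metrics but never toward non-native
counts, so entire-community diversity uses all recorded species.

Down-sampling apportions the target plot count by largest-remainder
(Hamilton) quotas over biome area weights, capped at availability.  Within
a biome, invaded plots are retained first, but never beyond half the
quota; the remainder is filled with uninvaded plots.  When either stratum
runs short the biome simply returns fewer plots — the half-cap is treated
as a hard constraint rather than redistributing the shortfall, so the
invaded fraction can only exceed one half by integer slack (≤ 1/quota).  A
flag can exempt named (e.g. tropical) biomes from down-sampling entirely.

### Diversity metrics

Faith's PD is the branch-length sum of the minimal spanning subtree of the
community, including the path to the root by default (configurable); MNTD
is the unweighted (presence-based) mean nearest-taxon distance.  Both are
computed twice per plot — native community and entire community — on two
trees: the phylogeny, and a functional dendrogram built by average-linkage
(UPGMA) clustering of Euclidean distances over eight traits (wood density,
root depth, leaf nitrogen, leaf phosphorus, leaf area, tree height, seed
dry mass, bark thickness), each natural-log transformed and z-scored over
the species pool.  Nonpositive raw trait values are a validation error,
never silently offset.  UPGMA is delegated to
`scipy.cluster.hierarchy.linkage`, whose merge order is deterministic for
a fixed input order; exact distance ties can make the dendrogram depend on
species order, which we accept because tie configurations have measure
zero under continuous traits (the order-invariance test uses tie-free
fixtures).

Redundancy is reported as (reference maximum MNTD − MNTD), with the
reference computed over the native communities of the post-down-sampling
analysis set, separately for the phylogenetic and functional families.
The invasion-strategy statistic is (entire MNTD − native MNTD) / native
MNTD on **raw** MNTD — the sign convention (negative = similarity) only
works on the untransformed scale.  It is undefined when native MNTD is 0
(a community of exact duplicates), and bounded below by −1.

Taxa missing from the phylogeny but with congeneric tips are grafted at
the most recent common ancestor of their congeners, with pendant length
half that node's age (its height above the tips), so grafted tips stay
inside the tree's time span; with a single congener the graft attaches at
that tip's parent.  Taxa with no congeners are reported unplaced, and
plots whose communities cannot be placed on both trees are excluded and
counted, not errored.

### Regression battery

Continuous predictors are z-scored before fitting, so coefficients are
comparable across predictors and models.  Four families:

* presence — binomial GLM, logit link;
* severity, richness — binomial GLM on (non-native count, native-side
  count), which weights plots by community size and avoids the
  denominator bias of modelling the raw proportion;
* severity, abundance — beta regression (logit mean link, log-linked
  constant precision, direct maximum likelihood via
  `statsmodels.othermod.betareg.BetaModel`); proportions of exactly 0 or
  1 are squeezed by (y·(n−1)+0.5)/n before fitting;
* strategy — ordinary least squares with MAT, MAT² (the square of
  standardized MAT), the other covariates, and the MAT×MAP, MAT×ports,
  MAP×ports interactions.  Backward elimination removes the
  least-significant interaction (largest p ≥ 0.05) one at a time,
  refitting after each removal; main effects and the quadratic term are
  never removed.  Native redundancy is excluded from strategy models
  because it is a component of the response.

Every model is fitted in two stages: the first stage omits the residual
autocovariate (RAC); its response-scale residuals (observed minus fitted
mean) are converted to RAC values — the inverse-distance weighted mean of
neighbouring residuals within 250 km, with coincident-point distances
floored at 1 m and isolated points assigned 0 — and the second stage
includes RAC as a covariate.  The 250 km radius follows the range beyond
which residual correlation is negligible in this setting; a correlogram
helper (25 km bins by default) and permutation Moran's I (inverse-distance
weights, one-sided p for positive autocorrelation) are provided as
diagnostics.

Random-forest importance uses 500 trees, bootstrap resampling, √p
variables per split and a minimum node size of 5.  Shapley values are
estimated by the permutation-sampling scheme (random feature orderings;
features switched one at a time from a random reference observation to
the explained one; telescoping prediction differences attributed to the
switched feature), 100 orderings by default.  Importance is the
per-variable sum of absolute SHAP values; the mean additivity gap
(|f(x) − base − Σφ|) is reported as a diagnostic rather than asserted,
since the sampled estimate is additive only in expectation.  The
explanation can be restricted to a row subsample to bound cost.

### Cross-validation

Spatially buffered leave-one-out CV samples focal plots uniformly without
replacement, drops all plots within the buffer (250 km default) from the
training set, fits, and predicts the focal plot; the metric (AUC for
binary outcomes, VEcv = 1 − Σ(o−p)²/Σ(o−ō)² for continuous ones) is
computed on the pooled out-of-fit predictions.  With buffer 0 and as many
repeats as observations this reduces exactly to classical LOO.  Repeats
whose training set would be empty are skipped and logged.

### Pre-invasion sensitivity

Observed native diversity on invaded plots may already be depressed by the
invasion itself, inflating apparent biotic resistance.  Plots with two
censuses whose first census is fully native identify the effect: a
Gaussian model of the fractional richness change ΔS/S₁ on final invasion
status (plus covariates) yields a coefficient c, and invaded plots'
richness is restored to S_pre = S·(1 − c) (a flag switches to S/(1+c);
the two differ at O(c²)).  The severity model is refitted with the
restored richness and the relative change |β_orig − β_upd|/|β_orig| of the
richness coefficient is reported at c and at both confidence bounds.  For
these refits the richness predictor stays on its **raw** scale: the update
is a uniform multiplicative shift across the (invaded-only) severity data,
which z-scoring would absorb exactly, making the statistic identically
zero by construction.

## Synthetic world

The generator emulates every input the analysis consumes, with recorded
ground truth.  Defaults are the study conditions used throughout the
tests; all randomness flows from one root seed through named child
streams (SHA-256 of the stage name → spawn key), so stages are
independently reproducible and the full dataset is byte-identical under a
fixed config.

* **Phylogeny** — pure-birth (Yule) tree conditioned on tip count, made
  ultrametric by extending tips to an extra exponential waiting time.
  Genera are the clades below a cut at 20% of the root depth (halved until
  ≥ 20% of tips have congeners), so congeners are clades and
  genus-placement is exercisable.
* **Traits** — geometric Brownian motion (Brownian on the log scale,
  exponentiated) with rate 0.05 per trait around realistic baselines, so
  raw traits are strictly positive with log-normal marginals.
* **Landscape** — a 3,000 km square near the equator; MAT a 20 °C
  latitudinal gradient plus smooth noise, MAP an independent longitudinal
  gradient; 5 random ports with great-circle nearest-port distances;
  log-normal population density; four soil covariates; biomes as MAT
  quantile bands sized by the configured area weights (default
  0.4/0.3/0.2/0.1 over four biomes).  Smooth fields are sums of Gaussian
  kernels at random centres with the configured range (250 km default) —
  cheaper than an exact Gaussian random field and sufficient to exercise
  the RAC machinery.
* **Native communities** — each species gets a thermal optimum (uniform
  over the MAT range) and is "native" to the biome band holding it (bands
  are topped up to ≥ 3 resident species by moving the closest-optimum
  species, so every plot can reach the 3-species floor).  Plot richness is
  3 + Poisson(9), sampled from the resident pool with weights
  exp(−(optimum − MAT)²/(2τ²)) at filtering strength 1 (0 disables
  filtering); stems get log-normal DBH ≥ 5 cm and uniform expansion
  factors.
* **Invasion** — presence ~ Bernoulli(logit⁻¹(α + β_port·z(log(dist+1)) +
  spatially correlated noise)) with α = −1, β_port = −0.8; for invaded
  plots each of 8 foreign candidates establishes with probability
  logit⁻¹(−1.5 + β_div·z(native PD)), β_div = −0.8, with at least one
  establishment forced (presence is defined by outcome); the donor for
  each establishment is the phylogenetically nearest candidate with
  probability logit⁻¹(−γ_T2·z(MAT)²) and uniform otherwise, so with
  γ_T2 = −1 similarity-invasion concentrates at temperature extremes and
  the strategy statistic is concave in MAT with a quadratic coefficient
  sharing γ_T2's sign.  The strategy effect is injected only through
  donor choice — MNTD is always computed, never assumed.
* **Two-census plots** — a separate simulator plants a fractional
  richness-change effect c of invasion (default −0.05, noise SD 0.05) for
  the sensitivity machinery.
* **Status registers** — two tables derived from the species' home
  biomes; a configurable fraction of species (default 0) gets one
  deliberately flipped region in the second register to exercise the
  conflict-dropping logic.

What the generator does **not** emulate: realistic biogeography, dispersal
limitation, demography, observation error in coordinates or taxonomy, and
any particular real-world inventory's spatial distribution.  Passing
recovery tests therefore demonstrate that the estimators are consistent
with their own model families at realistic scales, not that the effects
are identifiable in any particular real dataset.

## Problem sizes and numerical choices

Monte-Carlo validation uses 20 replicate seeds of 2,000 plots per model
family, 1,000-plot replicates for the RAC-efficacy check, 200 repeats for
null cross-validation, and a 500-plot end-to-end pipeline run — sizes at
which the checked properties are stable while the whole suite stays fast
on one CPU.  Other choices: Earth radius 6371 km; distances floored at
0.001 km in inverse-distance weights; collinearity screening drops one of
each |r| ≥ 0.7 covariate pair (MAT, MAP, ports, population density and the
diversity terms are never dropped); interaction-pruning α = 0.05;
delimited outputs use %.12g floats so reruns are byte-identical;
rank-deficient design matrices and constant predictors are rejected with
named errors rather than silently dropped.

Backward elimination at α = 0.05 retains at least one null interaction in
roughly the type-I range (the minimum of three null p-values falls below
0.05 about 14% of the time), so validation tracks the per-interaction
pruning fraction, whose expectation (~95%) is well separated from the 90%
requirement; an "all interactions pruned" event is intrinsically a
near-coin-flip at this α and is not a stable acceptance property.

## Known limitations

* Genus-graft pendant length (half the congener-MRCA age) is a documented
  convention; alternatives shift grafted tips' distances proportionally.
* The beta regression uses constant precision; dispersion covariates are
  out of scope.
* The RAC is a pragmatic autocorrelation absorber, not a generative
  spatial model (no CAR/SAR/kriging); buffered CV is the corresponding
  honest accuracy estimate.
* Status consensus treats a species listed by only one register as having
  that register's status; only explicit disagreements drop plots.
* The pipeline's "replicate plot" definition is exact coordinate
  identity; fuzzy-coordinate deduplication is out of scope.
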