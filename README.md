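# invadiv

Drivers of non-native tree invasion in plot-level forest inventories:
phylogenetic and functional diversity metrics, spatially corrected
regression models, and a ground-truthed synthetic-data generator.

## The problem

Forest-inventory plots joined to native-status registers let us ask three
questions about tree invasions:

1. **Presence** — what predicts whether a plot contains any non-native
   tree?  The leading hypothesis is anthropogenic propagule pressure,
   proxied by distance to shipping ports.
2. **Severity** — once invaded, what limits the non-natives' share of
   species and basal area?  The biotic-resistance hypothesis says diverse
   native communities fill more niches and resist spread.
3. **Strategy** — do successful invaders resemble the native community
   (environmental filtering, expected in harsh climates) or differ from it
   (limiting similarity, expected in mild ones)?

The package implements the full analysis chain for these questions and, in
place of access-restricted global inventory data, a synthetic world with
planted, recoverable effects so that every stage can be validated.

## The statistics

For a community of species on a rooted tree (a phylogeny, or a UPGMA
dendrogram over eight log-transformed, z-scored traits):

* **Faith's PD** — the branch length of the minimal subtree spanning the
  community ("phylogenetic richness"; the functional analogue is
  "functional richness");
* **MNTD** — the mean, over members, of the distance to the nearest other
  member; reported as **redundancy** = (dataset-maximum MNTD − MNTD), so
  larger means more tightly packed;
* **invasion strategy** = (MNTD_entire − MNTD_native) / MNTD_native —
  negative when non-natives nest inside the native community (similarity),
  positive when they extend it (dissimilarity);
* **invasion metrics** — presence of any non-native; relative non-native
  richness; relative non-native basal area, with basal area
  π·(DBH/200)²·TPH in m²/ha.

Models: binomial-logit GLM for presence; binomial GLM on (non-native count
out of total species) for richness severity; beta regression for abundance
severity; a Gaussian model with MAT² and backward-pruned climate×ports
interactions for strategy.  Every model is fitted twice: the first fit's
response residuals become a **residual autocovariate** (inverse-distance
weighted neighbour residuals within 250 km) included in the second fit to
absorb spatial autocorrelation.  Accuracy uses **spatially buffered
leave-one-out cross-validation** (training points within 250 km of the
focal plot are dropped), scored by AUC or VEcv.  Random forests (500
trees, √p variables per split, minimum node size 5) provide variable
importance as the sum of absolute sampled Shapley values.

## Worked example

`examples/05_severity_strategy.py` simulates 2,000 invaded plots from known
coefficients and refits them:

```
richness severity: diversity coefficient -0.793 (planted -0.8; higher native diversity -> fewer non-natives)
abundance severity: beta-regression slope +0.628 (planted +0.6 on the latent mean)

strategy: MAT^2 coefficient -0.302 (planted -0.3; concave = similarity-invasion at temperature extremes)
interactions surviving pruning: none (none were planted)
```

The severity coefficient is the planted biotic-resistance effect on the
standardized diversity scale; the negative MAT² term reproduces the
concave temperature response — invaders succeed by resembling natives at
climatic extremes.  `examples/04_spatial_models.py` shows the spatial
machinery on the presence model:

```
residual Moran's I without RAC: +0.1740
residual Moran's I with RAC:    -0.0411
buffered LOO-CV AUC over 100 repeats: 0.563
```

The other examples cover the diversity metrics on a hand-checkable
three-species tree (`01`), the synthetic world and its ground truth (`02`),
inventory preparation and biome down-sampling (`03`), and the end-to-end
pipeline (`06`).

## Pipeline

The pipeline is driven by one YAML config and runs
simulate → prepare → diversity → fit → cv → sensitivity → report, writing
delimited artifacts under a config-hashed directory (identical config ⇒
byte-identical outputs):

```bash
invadiv run-all --config examples/config_synthetic.yml
invadiv report runs/run-<hash>
```

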