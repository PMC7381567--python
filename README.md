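# tropholink

Do phylogeny and morphology predict trophic niches? `tropholink` is a
Python package for testing niche conservatism in species assemblages: it
builds inter-species dissimilarity matrices from a time-calibrated
phylogeny, morphological traits, stomach contents and stable isotope
ratios, and quantifies how strongly the four agree.

It was built for community ecologists working with assemblage-level
trophic data — the kind of dataset where each species contributes a few
dozen dissected stomachs, a handful of measured specimens and two isotope
axes, and the question is whether relatedness or morphology can stand in
for direct diet data.

## What it computes

Four dissimilarity matrices over the same species set:

* **phylogeny** — cophenetic distances `d(i,j) = Σ branch lengths` on the
  tip-to-tip path (with sister-grafting for species missing from the
  source tree);
* **morphology** — Gower distance over 26 size-standardised traits (ratios
  to standard length, plus ordinal mouth orientation and nominal tooth and
  gill-raker shapes);
* **diet** — a hierarchical rarefied Bray–Curtis distance: stomach
  contents aggregated to each of 7 nested food-category levels, specimen
  numbers equalised by rarefaction (16 per species, 1,000 draws),
  Bray–Curtis on species means per level, averaged across levels;
* **isotopes** — Euclidean distance on z-scored species means of
  (δ¹³C, δ¹⁵N).

and four ways of comparing them:

* **Spearman Mantel / partial Mantel** tests with joint row–column
  permutation (10,000 draws), the binary site contrast as covariable:
  `r_AB·C = (r_AB − r_AC r_BC)/√((1−r_AC²)(1−r_BC²))` on ranked
  off-diagonal entries;
* **dendrogram comparison** — UPGMA (selected among 8 linkages by
  cophenetic correlation) and an exact optimal branch-matching topology
  score in [0, 1];
* **phylogenetic signal** — Brownian states simulated along each
  dendrogram (σ² = 0.1, root 0, 10,000 replicates) and scored against the
  phylogeny with Abouheif's C_mean (row-normalised nodal-path proximity);
* **constrained ordination** — (db-)RDA of each response on
  forward-selected PCoA axes of each predictor, conditioned on site, with
  pseudo-F, Ezekiel-adjusted R² and ANOVA-like permutation p-values.

A synthetic community generator (`tropholink.synthetic_data`) produces
complete input bundles — Yule tree, Ornstein–Uhlenbeck traits,
trait-linked softmax diets over a nested food hierarchy, trophic-level
isotopes with noisy baselines, two sites with disjoint species — so the
entire pipeline is verifiable without any field data.

## Worked example

```python
import tropholink as tl

bundle = tl.simulate_community(tl.CommunitySimConfig(n_species=20, seed=7))
opts = tl.PipelineOptions(seed=7, rarefaction_iterations=100,
                          mantel_permutations=999, signal_reps=1000,
                          ordination_permutations=499, per_site=False)
report = tl.TrophicNicheAnalysis.from_bundle(bundle, opts).run()
print(report.summary())
```

prints (excerpt):

```
Partial Mantel (site-conditioned):
                pair        r     p  n_perm  n_species
phylogeny~morphology 0.626491 0.001     999         20
      phylogeny~diet 0.313733 0.009     999         20
   phylogeny~isotope 0.140909 0.109     999         20
     morphology~diet 0.437830 0.001     999         20
  morphology~isotope 0.000664 0.497     999         20
        diet~isotope 0.140010 0.079     999         20

Phylogenetic signal (Abouheif C_mean of BM tip states):
dendrogram scope  cmean_mean      q2.5    q97.5  n_reps
morphology   all    0.037054 -0.259869 0.405158    1000
      diet   all    0.015638 -0.264456 0.368581    1000
   isotope   all    0.001025 -0.257122 0.311612    1000
```

Reading it: morphology correlates with diet (partial Mantel r = 0.44,
p = 0.001 given site) more strongly than phylogeny does (r = 0.31), and the
phylogenetic signal carried by the dendrograms decays from morphology to
diet to isotopes — the pattern expected when diet is driven by realised
morphology and isotopes add baseline noise on top. At this small example
size (20 species) the isotope associations are not significant, and for
three ordination pairs forward selection retains no axis (reported as an
empty selection, not an error). `report.to_directory("out/")` writes every
table as CSV, the dendrograms as Newick, and a manifest with all seeds.

The same analysis runs from the shell:

```bash
tropholink simulate bundle/ --n-species 20 --seed 7
tropholink run bundle/ out/ --seed 7
tropholink dist diet bundle/ diet.csv --rarefy-n 16 --iterations 1000
tropholink mantel diet.csv morpho.csv --permutations 9999
```

Pre-computed dissimilarity matrices (e.g. archived ones) can drive the
pipeline directly via `TrophicNicheAnalysis.from_matrix_files(...)`,
skipping matrix construction; downstream results are identical to building
from raw data.

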