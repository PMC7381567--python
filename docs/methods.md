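# Methods

`tropholink` asks a comparative-ecology question: in a species assemblage,
how well do phylogenetic relatedness and morphological similarity predict
the trophic niche, as described by stomach contents and by stable isotope
ratios (δ¹³C, δ¹⁵N)? The package turns each data type into an inter-species
dissimilarity matrix and then interrogates the four matrices with
complementary statistics: matrix correlation (Spearman Mantel and partial
Mantel), dendrogram topology comparison, Brownian-simulation phylogenetic
signal, and constrained ordination. A synthetic community generator with a
known causal structure makes every stage testable end to end.

## Dissimilarity construction

**Phylogeny.** Cophenetic (patristic) distances on a time-calibrated,
ultrametric tree: d(i,j) is the sum of branch lengths on the tip-to-tip
path. Species absent from a source tree can be grafted as sisters to a
named host tip; the host's terminal branch is split at a configurable
fraction (default 0.5), which preserves ultrametricity and all pre-existing
pairwise distances.

**Morphology.** Specimen linear measurements (mm) are divided by that
specimen's standard length (SL), ratios are averaged per species, SL itself
is retained as the single absolute-size trait, and categorical traits take
the specimen modal value (lexicographic tie-break). Species profiles enter
a Gower distance: quantitative and ordinal traits contribute
range-normalised absolute differences (ordinal on integer ranks), nominal
traits a 0/1 mismatch, averaged over traits observed in both species.
Ranges are the observed ranges in the analysis set, recomputed per run;
zero-range traits are dropped with a warning. Mouth orientation is typed
ordinal (superior → terminal → subterminal → inferior is a gradient); tooth
shape and gill-raker shape are nominal.

**Diet.** The centrepiece is a hierarchical, rarefied Bray–Curtis distance.
Stomach items live at the leaves of a pyramid-shaped food hierarchy
(L = 7 levels by default; broad categories on top). For each level,
per-specimen item proportions are summed into their level-ℓ ancestor
categories; items flagged unresolvable at that level are dropped and the
remainder renormalised per specimen. Then, per level: `n_iterations`
(default 1,000) times, subsample `target_n` (default 16, the smallest
specimen sample) individuals per species without replacement, average them
into species-mean composition vectors, and compute pairwise Bray–Curtis
`1 − 2Σmin(xᵢ,yᵢ)/Σ(xᵢ+yᵢ)`; average the iteration matrices. The unified
matrix is the elementwise mean across levels, for each pair using only the
levels where both species retain specimens. When every species' sample
already fits `target_n`, every iteration is identical and a single
deterministic pass is taken (seed-independent by construction). Averaging
across resolutions makes the distance robust to the identification depth of
prey taxa: coarse levels rescue badly digested material, fine levels keep
discriminating power.

**Isotopes.** Species means of (δ¹³C, δ¹⁵N) are z-scored — globally, or
within site when between-site baseline differences must be absorbed — and
compared by Euclidean distance.

**Site contrast.** 0 for same-site pairs, 1 for different-site pairs. The
coding is kept verbatim from the field convention (which calls it a
"similarity" matrix despite 0 = same site); here it is simply the binary
covariable for the partial tests and the conditioning variable for
ordination.

**Trophic guilds.** Species are classified from their mean diet at the
broadest level: piscivore (fish > 70%), herbivore/detritivore
(plants/detritus > 70%), invertivore (invertebrates > 70%), omnivore 2
(invertebrates > 30% and fish > 30%), omnivore 1 (plants/detritus > 30% and
invertebrates > 30%); the > 70% rules are checked first because they are the
more specific, and a composition firing no rule is left `unclassified`
rather than forced into a nearest guild.

## Matrix correlation

The Mantel statistic is the Spearman correlation of the n(n−1)/2
off-diagonal entries; the partial version applies the first-order
partial-correlation formula `(r_AB − r_AC r_BC)/√((1−r_AC²)(1−r_BC²))` on
the same ranks. The null distribution jointly permutes rows and columns of
one matrix (A by convention; a flag switches to B), recomputing the full
statistic each draw; p = (#{r* ≥ r} + 1)/(n_perm + 1), one-sided (greater)
by default to match directional hypotheses. Controlling B for itself is a
0/0 limit and returns r = 0 by convention. Because ranks are invariant
under joint permutation, the implementation standardises the rank matrix
once and reduces each permutation draw to a gather plus a dot product.
Note the ranks are tie-sensitive: ultrametric matrices have many exact
ties, which is why matrix CSVs are parsed with round-trip float precision.

## Dendrograms and topology

Agglomerative clustering is implemented via the Lance–Williams update for
eight linkages (UPGMA, WPGMA, UPGMC, WPGMC, single, complete, Ward D,
Ward D2). Two conventions are fixed for bit-for-bit reproducibility: node
height = inter-cluster distance / 2 (so the cophenetic distance between
tips equals the merge distance), and ties in the minimum distance merge the
lexicographically smallest label pair. Centroid and median linkage can
produce inversions; the merge-trace cophenetic matrix is kept exact and
negative edge lengths are clamped to zero only in the exported tree.
The representative linkage for a matrix is the one maximising the Pearson
correlation between the original distances and the dendrogram's cophenetic
distances (ties go to UPGMA first).

Topological agreement between two trees on the same tips is scored by
optimal one-to-one branch matching: each internal branch bipartitions the
tips into two clades; a candidate branch pair scores
`max(min(J(A₁,A₂), J(B₁,B₂)), min(J(A₁,B₂), J(B₁,A₂)))` with J the Jaccard
overlap; the assignment is solved exactly (Hungarian algorithm), and the
score is the total matched weight divided by the larger internal-branch
count, so unmatched branches (different resolutions) count as zeros and the
score stays in [0,1] regardless of tree size. Branch lengths play no role.
Tanglegram leaf orders come from a two-sided untangling heuristic that
alternately sorts each node's children by the mean tip position in the
other tree's order, keeping the best (fewest-crossings) configuration seen,
so the crossing count never increases.

## Phylogenetic signal of a dendrogram

To measure how much phylogenetic structure a dendrogram (e.g. the diet
UPGMA tree) carries, a quantitative state is evolved along the dendrogram
under Brownian motion — root state 0, variance 0.1 × branch length per
branch, heights converted to branch lengths first — and the tip states are
scored against the *reference phylogeny* with Abouheif's C_mean: the
Moran-type statistic x_c'Wx_c / x_c'x_c, where W is the row-normalised
Abouheif proximity matrix, proximity(i,j) = 1/∏(direct-descendant counts of
the internal nodes on the nodal path through the MRCA; the root enters only
when it lies on that path). Repeating the simulation (10,000 draws at full
scale) gives a distribution summarised by its mean and 2.5/97.5% quantiles.
For an uninformative (star-like) dendrogram the states are i.i.d. and the
statistic's expectation is −1/(n−1), not exactly zero — the tests assert
that value. No per-draw permutation p-value is attached: the distribution
itself is the summary.

## Ordination

PCoA double-centres −D²/2 and eigen-decomposes; axes are scaled by √λ so
Euclidean-embeddable distances are reproduced exactly. Negative eigenvalues
(non-Euclidean input) are reported but excluded from predictor embeddings
by default; Lingoes and Cailliez corrections are available by flag. Axis
choice is either explicit (the full-scale analysis used 4 phylogeny / 14
morphology / 10 diet axes) or a documented largest-drop scree elbow.

RDA centres the response, optionally partials out a conditioning block
(site indicator), projects onto an orthonormal basis of the residualised
predictors, and reports pseudo-F = (SS_constr/p)/(SS_resid/(n−p−q−1)),
R² = SS_constr/SS_total, and Ezekiel-adjusted R²; for partial models the
adjusted value follows the variation-partitioning convention
adjR²(condition+predictors) − adjR²(condition). db-RDA embeds a response
distance matrix by PCoA (keeping ≥ 99.9% of positive variance) and is
exactly equivalent to RDA when the distance is Euclidean — that equivalence
is the standing cross-check between the two code paths. Significance uses
an ANOVA-like permutation test: rows of the reduced-model residuals are
permuted and the pseudo-F recomputed (the conditioned projection is
permutation-invariant, so only the constrained numerator varies). Forward
selection greedily adds the candidate axis with the largest added
constrained variance whose marginal permutation p ≤ α (default 0.05),
stopping otherwise; an empty selection is a valid, reported outcome.
Phylomorphospace coordinates place tree tips at their first two ordination
coordinates and every internal node at the unweighted mean of its
children, computed tips-to-root.

## The synthetic community generator

The generator emulates the statistical regime of a two-site Neotropical
stream fish study: two assemblages with disjoint species sets (65 species
at full scale, split ≈ 65/35), a time-calibrated ultrametric phylogeny,
26 morphological traits, ≥ 16 diet specimens per species over a 7-level
food hierarchy, and 3 isotope specimens per species.

* **Tree** — pure-birth (Yule) with depth normalised to 1; the clock runs
  one extra exponential interval past the n-th speciation so pendant
  branches have positive length.
* **Traits** — log size ratios evolve by an Ornstein–Uhlenbeck process
  (stationary variance 0.1, reversion α = 3, i.e. a phylogenetic half-life
  of ~0.23 tree depths), plus an independent species-specific deviation
  (sd 0.1) for measurement error and plasticity. OU rather than plain
  Brownian motion is deliberate: empirical assemblages show solid *local*
  phylogenetic signal in morphology together with weak *global*
  distance correlations, which is the OU signature (under BM the global
  correlation would be much stronger than observed). Setting α = 0 recovers
  BM. Categorical traits switch by a symmetric Markov process (rate 0.7).
* **Diets** — species preferences over the hierarchy leaves are
  softmax(λ·(guild + fine)) with λ = 3: the guild part orders species along
  the plant/detritus ↔ fish axis by relative gut length (the classic
  structured trait–guild relationship), the fine part maps the 12
  feeding-related traits through a random linear map (within-guild prey
  choice), plus species-level noise (sd 0.5). λ = 0 severs the trait–diet
  link entirely (the null-calibration configuration). Each specimen is a
  Dirichlet-multinomial stomach: Dirichlet(50·preference) proportions
  discretised over ~11 items.
* **Isotopes** — species trophic level TL = 1 + Σ proportion × prey TL with
  prey TLs fixed at plants/detritus = 1, invertebrates = 2, fish = 3;
  δ¹⁵N = basal + 2.8‰·(TL−1), δ¹³C = proportion-weighted basal source +
  0.5‰·(TL−1); per-species *baseline* deviations (sd 3.5‰ for carbon,
  2.5‰ for nitrogen) represent unmeasured basal-source variation and
  decades-long preservation effects, plus 1.0‰ per-specimen noise. The
  enrichment default sits inside the empirical 2–3.4‰ band and is validated
  at construction.

The generator's parameters were calibrated once against the published
values of the study regime it emulates (Mantel r's ≈ .19/.33/.03/.31 for
phylogeny–morphology / morphology–diet / phylogeny–diet / diet–isotope, and
signal means ≈ .22/.13/.04 for the morphology/diet/isotope dendrograms) and
then frozen. On 50 fresh communities the frozen defaults give mean signals
≈ .20/.06/.01 and reproduce the orderings signal(morphology) >
signal(diet) > signal(isotope) and r(morphology, diet) > r(phylogeny, diet)
in ≈ 90–95% of runs. The generator is a statistical stand-in, not a feeding
model: it does not emulate seasonality, individual diet specialisation,
ontogenetic diet shifts, or within-site spatial structure, so passing tests
demonstrate that the *pipeline* recovers plantings of known structure, not
that real fish behave this way.

## Numerical and procedural choices

* Canonical species order is lexicographic; every matrix is stored and
  written in that order so matrices of different kinds align positionally.
* All matrices are dissimilarities internally, even those the literature
  calls similarity matrices.
* Empty stomachs are excluded with a logged count; diet rows must sum to 1
  within 1e−6 at load and are renormalised to exact unit mass.
* Matrix CSVs are parsed with round-trip float precision because Spearman
  ranks are sensitive to 1-ulp perturbation of tied distances.
* The pipeline derives one RNG child stream per stage (diet rarefaction,
  Mantel, signal, ordination) from the master seed, so reports are
  bit-for-bit reproducible and stages are insensitive to each other's draw
  counts; building matrices from raw data and loading the same matrices
  from CSV yield identical downstream reports.
* Per-site analyses re-cluster within-site matrices (with isotopes
  re-standardised within site) rather than pruning global dendrograms.
* Scaled-down problem sizes in the test suite and the acceptance script
  (e.g. 2,000 signal replicates, 999–2,000 permutations, 65-species
  communities) were chosen so each statistic's Monte-Carlo error is small
  against the effects being checked; the full-scale defaults (10,000
  replicates/permutations) remain the library defaults.

## Known limitations

* The Nye-style topology score's treatment of unequal branch counts (zeros
  for unmatched branches) is one of several published conventions; scores
  are comparable within this package, not across implementations.
* Forward selection permutes reduced-model residuals; software differs on
  raw vs residual permutation and small p-values can differ accordingly.
* The untangling heuristic is a local search; it guarantees no increase in
  crossings, not a global minimum.
* Grafting missing species as sisters to a named host is a topological
  convenience; downstream cophenetic distances inherit whatever error the
  placement carries.
* The species/site bookkeeping assumes each species occurs at exactly one
  site, which is true of the emulated study design but not of assemblages
  generally.
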