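"""Construction of the inter-species dissimilarity matrices.

Four biological matrices are built here — cophenetic (phylogeny), Gower
(morphology), rarefied hierarchical Bray-Curtis (diet) and z-scored Euclidean
(stable isotopes) — plus the binary site contrast matrix used as a covariable
throughout, and the threshold classification of species into trophic guilds.

The diet distance is the centrepiece: stomach-content data are aggregated to
each level of a pyramid-shaped food-item hierarchy (broad categories at the
top, fine ones at the bottom), specimen counts are equalised by rarefaction
(default 16 individuals per species, matching the smallest sample, repeated
1,000 times), Bray-Curtis dissimilarity is computed on species-mean
proportion vectors at every level, and the per-level averages are averaged
again across levels into a single matrix that is robust to the taxonomic
resolution of prey identification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .data_model import (
    CATEGORICAL_TRAITS,
    LINEAR_MEASUREMENTS,
    DietRecordTable,
    DissimilarityMatrix,
    FoodHierarchy,
    PhylogeneticTree,
    ValidationError,
    validate_morpho_table,
)

__all__ = [
    "RarefactionPlan",
    "TrophicGroup",
    "TROPHIC_GROUPS",
    "graft_missing_taxa",
    "cophenetic_distance",
    "size_standardize",
    "default_trait_typing",
    "gower_distance",
    "isotope_distance",
    "species_isotope_means",
    "aggregate_diet_to_level",
    "hierarchical_diet_distance",
    "classify_trophic_group",
    "site_contrast_matrix",
]


# ---------------------------------------------------------------------------
# Phylogeny: grafting and cophenetic distances
# ---------------------------------------------------------------------------

def graft_missing_taxa(tree: PhylogeneticTree, placements: dict,
                       attachment_fraction: float = 0.5) -> PhylogeneticTree:
    """Add species absent from the source tree as sisters to a named host tip.

    Each entry of ``placements`` maps ``new_species -> host_tip``.  The host's
    terminal branch is split at ``attachment_fraction`` of its length
    (measured from the host tip upward) and the new species is attached there
    with a pendant branch of the same length, so an ultrametric tree stays
    ultrametric and ``d(new, host) = 2 * fraction * host_branch``.

    Grafting onto a tip that was itself grafted is allowed but warned about.
    """
    if not 0 <= attachment_fraction <= 1:
        raise ValidationError("attachment_fraction must be in [0, 1]")
    t = tree.dendropy_tree.clone(depth=1)
    grafted = set(tree.grafted)
    for new, host in sorted(placements.items()):
        node = None
        for lf in t.leaf_node_iter():
            if lf.taxon.label == host:
                node = lf
                break
        if node is None:
            raise ValidationError(f"graft host {host!r} is not a tip of the tree")
        if host in grafted:
            warnings.warn(f"grafting {new!r} onto already-grafted tip {host!r}", stacklevel=2)
        bl = node.edge.length or 0.0
        split = attachment_fraction * bl
        parent = node.parent_node
        joint = parent.new_child(edge_length=bl - split)
        parent.remove_child(node)
        joint.add_child(node)
        node.edge.length = split
        taxon = t.taxon_namespace.new_taxon(label=new)
        joint.new_child(taxon=taxon, edge_length=split)
        grafted.add(new)
    return PhylogeneticTree(t, grafted=tuple(sorted(grafted)))


def cophenetic_distance(tree: PhylogeneticTree) -> DissimilarityMatrix:
    """Pairwise sum of branch lengths along tip-to-tip paths."""
    return tree.cophenetic_matrix(kind="phylogeny")


# ---------------------------------------------------------------------------
# Morphology: size standardization and Gower distance
# ---------------------------------------------------------------------------

def size_standardize(morpho: pd.DataFrame) -> pd.DataFrame:
    """Specimen measurements -> species trait profiles.

    Every linear measurement (and gut length) is divided by that specimen's
    standard length; SL itself is kept as the single absolute-size trait.
    Quantitative ratios are averaged per species; categorical traits take the
    specimen modal value with a lexicographic tie-break.  A warning is issued
    for any trait missing in more than 30% of a species' specimens.
    """
    morpho = validate_morpho_table(morpho)
    quant = list(LINEAR_MEASUREMENTS) + ["gut_length"]
    df = morpho.copy()
    for col in quant:
        df[col] = df[col] / df["standard_length"]
    rows = []
    for sp, grp in df.groupby("species_id"):
        row = {"species_id": str(sp), "standard_length": grp["standard_length"].mean()}
        for col in quant:
            vals = grp[col].dropna()
            frac_missing = 1 - len(vals) / len(grp)
            if frac_missing > 0.3:
                warnings.warn(f"{sp}: {col} missing in {frac_missing:.0%} of specimens",
                              stacklevel=2)
            row[col] = vals.mean() if len(vals) else np.nan
        for col in CATEGORICAL_TRAITS:
            counts = grp[col].dropna().value_counts()
            if len(counts) == 0:
                row[col] = np.nan
                continue
            top = counts.max()
            row[col] = sorted(counts.index[counts == top])[0]
        rows.append(row)
    out = pd.DataFrame(rows).set_index("species_id").sort_index()
    return out


def default_trait_typing() -> dict:
    """Trait -> 'quantitative' | 'ordinal' | 'nominal' for the standard trait set."""
    typing = {"standard_length": "quantitative", "gut_length": "quantitative"}
    typing.update({c: "quantitative" for c in LINEAR_MEASUREMENTS})
    for col, (knd, _) in CATEGORICAL_TRAITS.items():
        typing[col] = knd
    return typing


def gower_distance(profiles: pd.DataFrame, trait_typing: dict | None = None,
                   ordinal_levels: dict | None = None) -> DissimilarityMatrix:
    """Gower distance over a mixed quantitative/ordinal/nominal trait table.

    Quantitative and ordinal traits contribute range-normalised absolute
    differences (ordinal on integer ranks); nominal traits contribute a 0/1
    mismatch.  The per-pair distance averages over traits observed in both
    species.  Ranges are the observed ranges over the analysis species set.
    Zero-range traits carry no information and are dropped with a warning.
    """
    if trait_typing is None:
        trait_typing = default_trait_typing()
    if ordinal_levels is None:
        ordinal_levels = {c: v for c, (k, v) in CATEGORICAL_TRAITS.items() if k == "ordinal"}
    traits = [c for c in profiles.columns if c in trait_typing]
    if not traits:
        raise ValidationError("no typed traits found in profile table")
    labels = [str(x) for x in profiles.index]
    n = len(labels)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for col in traits:
        knd = trait_typing[col]
        if knd in ("quantitative", "ordinal"):
            if knd == "ordinal":
                levels = list(ordinal_levels.get(col) or sorted(profiles[col].dropna().unique()))
                x = profiles[col].map({v: float(i) for i, v in enumerate(levels)}).to_numpy(dtype=float)
            else:
                x = profiles[col].to_numpy(dtype=float)
            ok = np.isfinite(x)
            rng = np.nanmax(x) - np.nanmin(x) if ok.any() else 0.0
            if not rng > 0:
                warnings.warn(f"trait {col!r} has zero range; dropped from Gower", stacklevel=2)
                continue
            diff = np.abs(x[:, None] - x[None, :]) / rng
            valid = ok[:, None] & ok[None, :]
            num += np.where(valid, np.nan_to_num(diff), 0.0)
            den += valid
        elif knd == "nominal":
            x = profiles[col].to_numpy(dtype=object)
            ok = pd.notna(x)
            mism = (x[:, None] != x[None, :]).astype(float)
            valid = ok[:, None] & ok[None, :]
            num += np.where(valid, mism, 0.0)
            den += valid
        else:
            raise ValidationError(f"unknown trait type {knd!r} for {col!r}")
    if (den == 0).any():
        raise ValidationError("some species pairs share no observed traits")
    d = num / den
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(d, labels, kind="morphology")


# ---------------------------------------------------------------------------
# Isotopes
# ---------------------------------------------------------------------------

def species_isotope_means(records: pd.DataFrame) -> pd.DataFrame:
    """Per-species mean (d13C, d15N)."""
    return (records.groupby("species_id")[["d13C", "d15N"]].mean().sort_index())


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1)
    zero = sd.index[~(sd > 0)].tolist()
    if zero:
        raise ValidationError(f"zero variance in isotope axis: {zero}")
    return (df - df.mean()) / sd


def isotope_distance(records: pd.DataFrame, per_site_standardize: bool = False,
                     sites: pd.Series | None = None) -> DissimilarityMatrix:
    """Euclidean distance between species-mean (d13C, d15N) after z-scoring.

    With ``per_site_standardize`` the z-scores are taken within each site
    (``sites`` maps species_id -> site_id), which absorbs between-site
    differences in baseline isotopic enrichment.
    """
    means = species_isotope_means(records)
    if len(means) < 2:
        raise ValidationError("need at least 2 species for isotope distances")
    if per_site_standardize:
        if sites is None:
            raise ValidationError("per-site standardization requires a species->site map")
        z = means.copy()
        for site in sorted(set(sites)):
            idx = [sp for sp in means.index if sites.get(sp) == site]
            if not idx:
                continue
            z.loc[idx] = _zscore(means.loc[idx])
    else:
        z = _zscore(means)
    x = z.to_numpy()
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    return DissimilarityMatrix(d, list(means.index.astype(str)), kind="isotope")


# ---------------------------------------------------------------------------
# Diet: level-wise aggregation, rarefaction, Bray-Curtis
# ---------------------------------------------------------------------------

@dataclass
class RarefactionPlan:
    """How many specimens per species to subsample, how often, and the seed."""

    target_n: int = 16
    n_iterations: int = 1000
    seed: int | None = None
    with_replacement: bool = False

    def __post_init__(self):
        if self.target_n < 1:
            raise ValidationError("target_n must be >= 1")
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")


def aggregate_diet_to_level(diet: DietRecordTable, hierarchy: FoodHierarchy,
                            level: int) -> pd.DataFrame:
    """Sum raw item proportions into their level-``level`` ancestor categories.

    Items excluded at this level (or not resolved this deep) are dropped and
    the remaining proportions renormalised to 1 per specimen; specimens left
    with nothing at this level are excluded from this level.
    """
    cats = hierarchy.categories(level)
    mapping = {item: hierarchy.ancestor_at_level(item, level)
               for item in diet.proportions.columns}
    out = pd.DataFrame(0.0, index=diet.proportions.index, columns=cats)
    for item, cat in mapping.items():
        if cat is not None:
            out[cat] += diet.proportions[item]
    totals = out.sum(axis=1)
    keep = totals > 1e-12
    out = out.loc[keep].div(totals[keep], axis=0)
    return out


def _bray_curtis_matrix(x: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis for rows of a non-negative composition matrix."""
    mins = np.minimum(x[:, None, :], x[None, :, :]).sum(axis=2)
    sums = x.sum(axis=1)
    tot = sums[:, None] + sums[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - 2.0 * mins / tot
    np.fill_diagonal(d, 0.0)
    return d


def hierarchical_diet_distance(diet: DietRecordTable, hierarchy: FoodHierarchy,
                               plan: RarefactionPlan | None = None,
                               rng: np.random.Generator | None = None,
                               return_levels: bool = False):
    """Rarefied, level-averaged Bray-Curtis diet distance.

    For each hierarchy level: ``n_iterations`` times, subsample
    ``min(target_n, available)`` specimens per species (without replacement by
    default), average their category proportions into a species-mean vector,
    and compute pairwise Bray-Curtis; average the iteration matrices.  The
    final matrix is the elementwise mean across levels, using for each pair
    only the levels where both species retain specimens (a warning names
    species missing anywhere).

    When every species has at most ``target_n`` specimens the subsample is the
    full sample, each iteration is identical, and a single pass is taken — the
    result is then exactly deterministic and seed-independent.
    """
    plan = plan or RarefactionPlan()
    if rng is None:
        rng = np.random.default_rng(plan.seed)
    species = diet.species_ids
    n = len(species)
    level_mats = np.full((hierarchy.n_levels, n, n), np.nan)
    warned_missing = set()
    for li, level in enumerate(range(1, hierarchy.n_levels + 1)):
        table = aggregate_diet_to_level(diet, hierarchy, level)
        sp_of = diet.species.loc[table.index]
        groups = {sp: table.loc[sp_of.index[sp_of == sp]].to_numpy()
                  for sp in species}
        present = [sp for sp in species if len(groups[sp])]
        warned_missing |= set(species) - set(present)
        if len(present) < 2:
            continue
        x_all = {sp: groups[sp] for sp in present}
        deterministic = (not plan.with_replacement and
                         all(len(v) <= plan.target_n for v in x_all.values()))
        iters = 1 if deterministic else plan.n_iterations
        acc = np.zeros((len(present), len(present)))
        for _ in range(iters):
            means = np.empty((len(present), table.shape[1]))
            for i, sp in enumerate(present):
                arr = x_all[sp]
                if len(arr) <= plan.target_n and not plan.with_replacement:
                    sub = arr
                else:
                    idx = rng.choice(len(arr), size=plan.target_n,
                                     replace=plan.with_replacement)
                    sub = arr[idx]
                means[i] = sub.mean(axis=0)
            acc += _bray_curtis_matrix(means)
        acc /= iters
        pidx = [species.index(sp) for sp in present]
        level_mats[li][np.ix_(pidx, pidx)] = acc
    if warned_missing:
        warnings.warn("species with no retained specimens at some level: "
                      f"{sorted(warned_missing)}", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        unified = np.nanmean(level_mats, axis=0)
    if np.isnan(unified).any():
        raise ValidationError("some species pair shares no hierarchy level with data")
    np.fill_diagonal(unified, 0.0)
    result = DissimilarityMatrix(unified, species, kind="diet")
    if return_levels:
        per_level = {hierarchy.levels[li]: level_mats[li] for li in range(hierarchy.n_levels)}
        return result, per_level
    return result


# ---------------------------------------------------------------------------
# Trophic guilds
# ---------------------------------------------------------------------------

TROPHIC_GROUPS = ("herbivore_detritivore", "omnivore1", "invertivore",
                  "omnivore2", "piscivore", "unclassified")
TrophicGroup = str


def classify_trophic_group(proportions: dict) -> TrophicGroup:
    """Threshold classification over {plant_detritus, invertebrate, fish}.

    Rules (applied in order of specificity): piscivore if fish > 0.70;
    herbivore/detritivore if plant/detritus > 0.70; invertivore if
    invertebrates > 0.70; omnivore 2 if invertebrates > 0.30 and fish > 0.30;
    omnivore 1 if plant/detritus > 0.30 and invertebrates > 0.30; otherwise
    unclassified.
    """
    p = float(proportions.get("plant_detritus", 0.0))
    i = float(proportions.get("invertebrate", 0.0))
    f = float(proportions.get("fish", 0.0))
    if min(p, i, f) < 0 or p + i + f > 1 + 1e-9:
        raise ValidationError("trophic proportions must be >= 0 and sum to <= 1")
    if f > 0.70:
        return "piscivore"
    if p > 0.70:
        return "herbivore_detritivore"
    if i > 0.70:
        return "invertivore"
    if i > 0.30 and f > 0.30:
        return "omnivore2"
    if p > 0.30 and i > 0.30:
        return "omnivore1"
    return "unclassified"


def classify_species_trophic_groups(diet: DietRecordTable, hierarchy: FoodHierarchy,
                                    group_of_category: dict | None = None,
                                    level: int = 1) -> pd.Series:
    """Classify every species from its mean diet at the broad-category level.

    ``group_of_category`` maps level-``level`` categories onto
    {plant_detritus, invertebrate, fish}; categories left out (e.g. rare
    "other" items) simply count toward no group.  By default the category
    name itself is used when it already is one of the three group keys.
    """
    table = aggregate_diet_to_level(diet, hierarchy, level)
    mapping = group_of_category or {c: c for c in table.columns}
    out = {}
    for sp in diet.species_ids:
        rows = table.loc[[s for s in table.index if diet.species[s] == sp]]
        if rows.empty:
            out[sp] = "unclassified"
            continue
        mean = rows.mean(axis=0)
        agg = {}
        for cat, grp in mapping.items():
            if cat in mean.index and grp in ("plant_detritus", "invertebrate", "fish"):
                agg[grp] = agg.get(grp, 0.0) + float(mean[cat])
        out[sp] = classify_trophic_group(agg)
    return pd.Series(out).sort_index()


# ---------------------------------------------------------------------------
# Site contrast
# ---------------------------------------------------------------------------

def site_contrast_matrix(species_table: pd.DataFrame) -> DissimilarityMatrix:
    """Binary matrix: 0 for same-site pairs, 1 for different-site pairs.

    Kept verbatim as the original coding (named a "similarity" matrix in the
    field yet coding 0 = same site); treated as a contrast/distance here.
    """
    sp = species_table["species_id"].astype(str).to_numpy()
    site = species_table["site_id"].to_numpy()
    d = (site[:, None] != site[None, :]).astype(float)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(d, sp, kind="site")
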