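"""Domain types, readers/writers, and validation shared by every analysis stage.

The common currency of the package is the :class:`DissimilarityMatrix` — a
labelled, symmetric, zero-diagonal matrix of inter-species distances.  All
matrices are stored as *dissimilarities* even where the literature speaks of
"similarity matrices" (Bray-Curtis, Gower, Euclidean and cophenetic distances
are all distances); bounded metrics can be presented as ``1 - d`` at the
reporting layer.  Labels are kept in canonical (lexicographically sorted)
order so that matrices of different kinds align positionally.

Tabular inputs (species/site table, per-specimen morphology, stomach
contents, stable isotopes) are plain :class:`pandas.DataFrame` objects with
module-level validators; trees are :class:`PhylogeneticTree`, a thin wrapper
around :class:`dendropy.Tree`.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from skbio.stats.distance import DistanceMatrix as _SkbioDistanceMatrix

logger = logging.getLogger("tropholink")

__all__ = [
    "DissimilarityMatrix",
    "PhylogeneticTree",
    "FoodHierarchy",
    "DietRecordTable",
    "MatrixKind",
    "align_matrices",
    "read_newick",
    "read_species_table",
    "read_morpho_table",
    "read_isotope_table",
    "read_tables",
    "validate_species_table",
    "validate_morpho_table",
    "validate_isotope_table",
    "MOUTH_ORIENTATION_LEVELS",
    "TOOTH_SHAPE_LEVELS",
    "GILL_RAKER_LEVELS",
    "LINEAR_MEASUREMENTS",
    "CATEGORICAL_TRAITS",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class FormatError(ValueError):
    """Raised when a file cannot be parsed."""


MatrixKind = str  # one of: phylogeny | morphology | diet | isotope | site | generic

# Closed vocabularies for the three categorical feeding traits.  Mouth
# orientation is an ordered dorsoventral gradient; the other two are nominal.
MOUTH_ORIENTATION_LEVELS = ("superior", "terminal", "subterminal", "inferior")
TOOTH_SHAPE_LEVELS = ("absent", "unicuspid", "multicuspid", "conical", "triangular_serrated")
GILL_RAKER_LEVELS = ("absent", "short_blunt", "intermediate_sparse", "long_comblike")

#: Linear body/fin dimensions measured in mm on each specimen (besides SL and
#: gut length).  Each is converted to a proportion of standard length before
#: any inter-species comparison.
LINEAR_MEASUREMENTS = (
    "body_depth",
    "body_width",
    "caudal_peduncle_length",
    "caudal_peduncle_height",
    "caudal_peduncle_width",
    "body_depth_below_midline",
    "head_length",
    "head_depth",
    "eye_position",
    "eye_diameter",
    "mouth_width",
    "snout_length",
    "dorsal_fin_height",
    "dorsal_fin_length",
    "pectoral_fin_length",
    "pectoral_fin_height",
    "caudal_fin_length",
    "caudal_fin_height",
    "pelvic_fin_length",
    "anal_fin_length",
    "anal_fin_height",
)

CATEGORICAL_TRAITS = {
    "mouth_orientation": ("ordinal", MOUTH_ORIENTATION_LEVELS),
    "tooth_shape": ("nominal", TOOTH_SHAPE_LEVELS),
    "gill_raker_shape": ("nominal", GILL_RAKER_LEVELS),
}


# ---------------------------------------------------------------------------
# DissimilarityMatrix
# ---------------------------------------------------------------------------

class DissimilarityMatrix:
    """Symmetric, hollow, non-negative inter-species distance matrix.

    Parameters
    ----------
    values : (n, n) array-like
        Symmetric distances with a zero diagonal.
    labels : sequence of str
        Species identifiers, one per row.  Stored in canonical sorted order;
        the matrix is permuted accordingly on construction.
    kind : str
        Provenance tag (``phylogeny``, ``morphology``, ``diet``, ``isotope``,
        ``site`` or ``generic``).
    """

    def __init__(self, values, labels, kind: MatrixKind = "generic"):
        values = np.asarray(values, dtype=float)
        labels = [str(x) for x in labels]
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValidationError("distance matrix must be square")
        if len(labels) != values.shape[0]:
            raise ValidationError("label count does not match matrix size")
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate labels in distance matrix")
        if not np.all(np.isfinite(values)):
            raise ValidationError("non-finite entries in distance matrix")
        if np.any(values < 0):
            raise ValidationError("negative entries in distance matrix")
        if not np.allclose(values, values.T, atol=1e-9):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-9):
            raise ValidationError("distance matrix diagonal is not zero")
        order = np.argsort(labels)
        self._labels = tuple(labels[i] for i in order)
        v = 0.5 * (values + values.T)
        np.fill_diagonal(v, 0.0)
        self._values = v[np.ix_(order, order)]
        self._values.setflags(write=False)
        self.kind = kind

    # -- basic accessors ----------------------------------------------------
    @property
    def labels(self) -> tuple:
        return self._labels

    @property
    def values(self) -> np.ndarray:
        return self._values

    @property
    def n(self) -> int:
        return len(self._labels)

    def __len__(self):
        return self.n

    def __repr__(self):
        return f"<DissimilarityMatrix kind={self.kind!r} n={self.n}>"

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in :func:`scipy.spatial.distance.squareform` order."""
        return squareform(self._values, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self._values, index=self._labels, columns=self._labels)

    def to_skbio(self) -> _SkbioDistanceMatrix:
        return _SkbioDistanceMatrix(np.array(self._values), ids=self._labels)

    # -- restriction / alignment -------------------------------------------
    def restrict(self, labels) -> "DissimilarityMatrix":
        """Return the sub-matrix for ``labels`` (canonical order restored)."""
        labels = [str(x) for x in labels]
        missing = sorted(set(labels) - set(self._labels))
        if missing:
            raise ValidationError(f"labels not in matrix: {missing}")
        idx = [self._labels.index(l) for l in sorted(set(labels))]
        return DissimilarityMatrix(self._values[np.ix_(idx, idx)],
                                   [self._labels[i] for i in idx], kind=self.kind)

    # -- I/O ----------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="species_id")

    @classmethod
    def from_csv(cls, path, kind: MatrixKind = "generic") -> "DissimilarityMatrix":
        # round_trip parsing: rank-based statistics downstream are sensitive to
        # 1-ulp perturbations of tied (e.g. ultrametric) distances
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise FormatError("matrix CSV row and column labels differ")
        return cls(df.to_numpy(dtype=float), df.index.astype(str), kind=kind)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kind: MatrixKind = "generic"):
        return cls(df.to_numpy(dtype=float), df.index.astype(str), kind=kind)


def align_matrices(*matrices: DissimilarityMatrix) -> list[DissimilarityMatrix]:
    """Restrict two or more matrices to their common species, common order.

    Raises if fewer than three species are shared — downstream tests are
    meaningless below that.
    """
    if len(matrices) < 2:
        raise ValidationError("need at least two matrices to align")
    common = set(matrices[0].labels)
    for m in matrices[1:]:
        common &= set(m.labels)
    if len(common) < 3:
        raise ValidationError(f"only {len(common)} species shared between matrices (need >= 3)")
    common = sorted(common)
    return [m.restrict(common) for m in matrices]


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class PhylogeneticTree:
    """Rooted tree with branch lengths, tips labelled by species id.

    Wraps a :class:`dendropy.Tree`.  Used both for the reference phylogeny
    and (via the :class:`~tropholink.dendrograms.Dendrogram` subclass) for
    cluster trees.
    """

    def __init__(self, tree: dendropy.Tree, grafted: tuple = ()):
        self._tree = tree
        #: species placed by proxy (sister-grafted), not present in the source tree
        self.grafted = tuple(grafted)
        self._validate()

    def _validate(self):
        labels = self.tip_labels
        if len(labels) < 2:
            raise ValidationError("tree must have at least 2 tips")
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate tip labels in tree")
        for e in self._tree.preorder_edge_iter():
            if e.length is not None and e.length < 0:
                raise ValidationError("negative branch length in tree")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def copy(self) -> "PhylogeneticTree":
        return type(self)(self._tree.clone(depth=1), grafted=self.grafted)

    # -- distances ----------------------------------------------------------
    def cophenetic_matrix(self, kind: MatrixKind = "phylogeny") -> DissimilarityMatrix:
        """Tip-to-tip path-length (patristic/cophenetic) distances."""
        labels = sorted(self.tip_labels)
        index = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))
        pdm = self._tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self._tree.taxon_namespace if index.get(t.label) is not None}
        for i, li in enumerate(labels):
            for lj in labels[i + 1:]:
                j = index[lj]
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[li], taxa[lj])
        return DissimilarityMatrix(d, labels, kind=kind)

    def depths(self) -> dict:
        """Root-to-node path length for every node (keyed by id(node))."""
        out = {}
        for nd in self._tree.preorder_node_iter():
            pl = 0.0 if nd.parent_node is None else out[id(nd.parent_node)]
            out[id(nd)] = pl + (nd.edge.length or 0.0)
        return out

    def prune_to(self, labels) -> "PhylogeneticTree":
        labels = set(labels)
        missing = labels - set(self.tip_labels)
        if missing:
            raise ValidationError(f"tips not in tree: {sorted(missing)}")
        t = self._tree.clone(depth=1)
        t.retain_taxa_with_labels(sorted(labels))
        return type(self)(t, grafted=tuple(g for g in self.grafted if g in labels))

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_newick(cls, source: str) -> "PhylogeneticTree":
        """Parse Newick from a string or file path."""
        data = source
        if "(" not in source:  # looks like a path
            with open(source) as fh:
                data = fh.read()
        try:
            tree = dendropy.Tree.get(data=data, schema="newick",
                                     preserve_underscores=True)
        except Exception as exc:  # dendropy raises several parse error types
            if "Duplicate taxon" in str(exc) or "Multiple occurrences" in str(exc):
                raise ValidationError(f"duplicate tip labels in Newick: {exc}") from exc
            raise FormatError(f"could not parse Newick: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True,
                                    unquoted_underscores=True).strip()

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def read_newick(path) -> PhylogeneticTree:
    """Read a Newick file into a validated :class:`PhylogeneticTree`."""
    return PhylogeneticTree.from_newick(str(path))


# ---------------------------------------------------------------------------
# Food hierarchy
# ---------------------------------------------------------------------------

@dataclass
class FoodHierarchy:
    """Pyramid of food categories: broad at the top, narrow at the bottom.

    The hierarchy maps every raw stomach item to one category at each of the
    ``L`` vertical levels (level 1 = broadest).  Items whose identification is
    too coarse for a given level carry an exclusion flag ``(item_id, level)``
    and are dropped (with renormalization) when diets are aggregated to that
    level.

    Attributes
    ----------
    levels : list of str
        Ordered level names, top first.  ``L = len(levels)`` (7 by default in
        the shipped example hierarchy).
    parent : dict
        ``node_id -> parent_id`` (parent of a level-1 node is ``None``).
    node_level : dict
        ``node_id -> level index`` (1-based).
    leaf_map : dict
        ``raw item_id -> deepest node_id``.
    exclusions : set of (item_id, level)
        Pairs dropped at that level.
    """

    levels: list
    parent: dict
    node_level: dict
    leaf_map: dict
    exclusions: set = field(default_factory=set)

    def __post_init__(self):
        self.exclusions = set(map(tuple, self.exclusions))
        for node, lvl in self.node_level.items():
            if not 1 <= lvl <= self.n_levels:
                raise ValidationError(f"node {node!r} has level {lvl} outside 1..{self.n_levels}")
            par = self.parent.get(node)
            if lvl == 1:
                if par is not None:
                    raise ValidationError(f"level-1 node {node!r} has a parent")
            else:
                if par not in self.node_level or self.node_level[par] != lvl - 1:
                    raise ValidationError(f"node {node!r} (level {lvl}) lacks a level-{lvl-1} parent")
        for item, node in self.leaf_map.items():
            if node not in self.node_level:
                raise ValidationError(f"item {item!r} maps to unknown node {node!r}")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def ancestor_at_level(self, item_id: str, level: int):
        """Category of ``item_id`` at ``level`` or ``None`` if excluded/too shallow."""
        if not 1 <= level <= self.n_levels:
            raise ValidationError(f"level {level} outside 1..{self.n_levels}")
        if (item_id, level) in self.exclusions:
            return None
        node = self.leaf_map[item_id]
        lvl = self.node_level[node]
        if lvl < level:
            return None  # the item is not resolved this deep
        while lvl > level:
            node = self.parent[node]
            lvl -= 1
        return node

    def categories(self, level: int) -> list:
        return sorted(n for n, l in self.node_level.items() if l == level)

    def items(self) -> list:
        return sorted(self.leaf_map)

    # -- I/O: 3-column edge list + 2-column exclusion list -------------------
    @classmethod
    def from_csv(cls, nodes_path, exclusions_path=None, levels=None) -> "FoodHierarchy":
        nodes = pd.read_csv(nodes_path)
        need = {"node_id", "level", "parent_id"}
        if not need <= set(nodes.columns):
            raise FormatError(f"hierarchy CSV needs columns {sorted(need)}")
        node_level, parent = {}, {}
        for row in nodes.itertuples(index=False):
            node_level[str(row.node_id)] = int(row.level)
            parent[str(row.node_id)] = (None if pd.isna(row.parent_id)
                                        else str(row.parent_id))
        L = max(node_level.values())
        levels = list(levels) if levels is not None else [f"level{i}" for i in range(1, L + 1)]
        # leaves: deepest node naming each raw item is the node itself
        leaf_map = {}
        children = set(parent.values())
        for node in node_level:
            if node not in children:
                leaf_map[node] = node
        excl = set()
        if exclusions_path is not None:
            edf = pd.read_csv(exclusions_path)
            for row in edf.itertuples(index=False):
                excl.add((str(row.item_id), int(row.level)))
        return cls(levels, parent, node_level, leaf_map, excl)

    def to_csv(self, nodes_path, exclusions_path=None) -> None:
        rows = [{"node_id": n, "level": l, "parent_id": self.parent.get(n)}
                for n, l in sorted(self.node_level.items(), key=lambda kv: (kv[1], kv[0]))]
        pd.DataFrame(rows).to_csv(nodes_path, index=False)
        if exclusions_path is not None:
            pd.DataFrame(sorted(self.exclusions),
                         columns=["item_id", "level"]).to_csv(exclusions_path, index=False)


# ---------------------------------------------------------------------------
# Diet records
# ---------------------------------------------------------------------------

class DietRecordTable:
    """Per-specimen food-item volume proportions.

    ``proportions`` is a wide specimen x item table; each retained row is
    non-negative and sums to 1 (within 1e-9 after renormalization at load).
    Rows summing to 0 are flagged empty and excluded with a logged count.
    """

    def __init__(self, proportions: pd.DataFrame, species: pd.Series,
                 hierarchy: FoodHierarchy | None = None, _tol: float = 1e-6):
        proportions = proportions.astype(float)
        if (proportions.to_numpy() < -1e-12).any():
            raise ValidationError("negative diet proportions")
        sums = proportions.sum(axis=1)
        empty = sums[np.abs(sums) < 1e-9].index
        if len(empty):
            logger.warning("excluding %d empty-stomach specimens", len(empty))
            warnings.warn(f"excluding {len(empty)} empty-stomach specimens", stacklevel=2)
            proportions = proportions.drop(index=empty)
            sums = sums.drop(index=empty)
        bad = sums[(sums - 1.0).abs() > _tol]
        if len(bad):
            raise ValidationError(
                "diet proportions do not sum to 1 for specimens: "
                + ", ".join(map(str, bad.index[:10])))
        self.proportions = proportions.div(sums, axis=0)
        self.species = species.loc[self.proportions.index].astype(str)
        self.n_excluded_empty = len(empty)
        if hierarchy is not None:
            unknown = sorted(set(proportions.columns) - set(hierarchy.leaf_map))
            if unknown:
                raise ValidationError(f"diet items absent from hierarchy: {unknown}")

    @property
    def specimen_ids(self):
        return list(self.proportions.index)

    @property
    def species_ids(self):
        return sorted(self.species.unique())

    def specimens_of(self, species_id: str) -> list:
        return list(self.species.index[self.species == species_id])

    def counts_per_species(self) -> pd.Series:
        return self.species.value_counts().sort_index()

    # -- I/O: long CSV (specimen_id, species_id, item_id, proportion) --------
    @classmethod
    def from_csv(cls, path, hierarchy: FoodHierarchy | None = None) -> "DietRecordTable":
        df = pd.read_csv(path)
        need = {"specimen_id", "species_id", "item_id", "proportion"}
        if not need <= set(df.columns):
            raise FormatError(f"diet CSV needs columns {sorted(need)}")
        wide = df.pivot_table(index="specimen_id", columns="item_id",
                              values="proportion", aggfunc="sum", fill_value=0.0)
        species = df.drop_duplicates("specimen_id").set_index("specimen_id")["species_id"]
        return cls(wide, species, hierarchy=hierarchy)

    def to_csv(self, path) -> None:
        long = (self.proportions.stack().rename("proportion").reset_index())
        long.columns = ["specimen_id", "item_id", "proportion"]
        long = long[long["proportion"] > 0]
        long.insert(1, "species_id", self.species.loc[long["specimen_id"]].to_numpy())
        long.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Tabular validators & readers
# ---------------------------------------------------------------------------

def validate_species_table(df: pd.DataFrame) -> pd.DataFrame:
    """Species/site table: one row per species, one site each, counts >= 1."""
    need = {"species_id", "site_id"}
    if not need <= set(df.columns):
        raise ValidationError(f"species table needs columns {sorted(need)}")
    df = df.copy()
    df["species_id"] = df["species_id"].astype(str)
    if df["species_id"].duplicated().any():
        dups = sorted(df.loc[df["species_id"].duplicated(), "species_id"])
        raise ValidationError(f"duplicate species_id: {dups}")
    for col in df.columns:
        if col.startswith("n_") and (df[col] < 1).any():
            raise ValidationError(f"{col} has entries < 1")
    return df.sort_values("species_id").reset_index(drop=True)


def validate_morpho_table(df: pd.DataFrame) -> pd.DataFrame:
    need = {"specimen_id", "species_id", "standard_length", "gut_length"} | set(LINEAR_MEASUREMENTS) | set(CATEGORICAL_TRAITS)
    missing = sorted(need - set(df.columns))
    if missing:
        raise ValidationError(f"morphology table missing columns: {missing}")
    if (df["standard_length"] <= 0).any():
        raise ValidationError("standard_length must be > 0")
    for col in LINEAR_MEASUREMENTS + ("gut_length",):
        if (df[col].dropna() < 0).any():
            raise ValidationError(f"{col} has negative measurements")
    for col, (_, vocab) in CATEGORICAL_TRAITS.items():
        bad = sorted(set(df[col].dropna()) - set(vocab))
        if bad:
            raise ValidationError(f"{col} values outside vocabulary: {bad}")
    return df


def validate_isotope_table(df: pd.DataFrame) -> pd.DataFrame:
    need = {"specimen_id", "species_id", "d13C", "d15N"}
    missing = sorted(need - set(df.columns))
    if missing:
        raise ValidationError(f"isotope table missing columns: {missing}")
    if not np.isfinite(df[["d13C", "d15N"]].to_numpy()).all():
        raise ValidationError("non-finite isotope values")
    small = df.groupby("species_id").size()
    small = small[small < 2]
    if len(small):
        warnings.warn(f"species with < 2 isotope specimens: {sorted(small.index)}", stacklevel=2)
    return df


def read_species_table(path) -> pd.DataFrame:
    return validate_species_table(pd.read_csv(path))


def read_morpho_table(path) -> pd.DataFrame:
    return validate_morpho_table(pd.read_csv(path))


def read_isotope_table(path) -> pd.DataFrame:
    return validate_isotope_table(pd.read_csv(path))


def read_tables(species_path, morpho_path=None, isotope_path=None,
                diet_path=None, hierarchy_nodes_path=None,
                hierarchy_exclusions_path=None) -> dict:
    """Load and cross-validate the full tabular bundle.

    Every specimen's species must appear in the species table; diet items must
    appear in the food hierarchy.  Returns a dict with keys ``species``,
    ``morpho``, ``isotopes``, ``diet``, ``hierarchy`` (absent inputs omitted).
    """
    out = {"species": read_species_table(species_path)}
    known = set(out["species"]["species_id"])

    def _check_refs(df, name):
        unknown = sorted(set(df["species_id"].astype(str)) - known)
        if unknown:
            raise ValidationError(f"{name} references unknown species: {unknown}")

    if hierarchy_nodes_path is not None:
        out["hierarchy"] = FoodHierarchy.from_csv(hierarchy_nodes_path,
                                                  hierarchy_exclusions_path)
    if morpho_path is not None:
        out["morpho"] = read_morpho_table(morpho_path)
        _check_refs(out["morpho"], "morphology table")
    if isotope_path is not None:
        out["isotopes"] = read_isotope_table(isotope_path)
        _check_refs(out["isotopes"], "isotope table")
    if diet_path is not None:
        diet = DietRecordTable.from_csv(diet_path, hierarchy=out.get("hierarchy"))
        unknown = sorted(set(diet.species) - known)
        if unknown:
            raise ValidationError(f"diet table references unknown species: {unknown}")
        out["diet"] = diet
    return out
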