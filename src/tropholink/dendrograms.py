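"""Hierarchical clustering, objective linkage selection, and tree comparison.

Agglomeration is implemented explicitly via the Lance-Williams update so that
two reproducibility conventions can be fixed:

* node height = inter-cluster distance / 2, so the cophenetic distance
  between two tips equals the distance at which their clusters merged;
* ties in the minimum inter-cluster distance are broken by merging the
  lexicographically smallest label pair, making merge traces bit-for-bit
  reproducible across platforms.

Eight linkage methods are supported (UPGMA, WPGMA, UPGMC, WPGMC, single,
complete, Ward D, Ward D2); the most faithful one for a given matrix is
chosen by cophenetic correlation.  Topological agreement between two trees
is scored by the branch-matching method of Nye and colleagues: every
internal branch splits the tips into two clades, candidate branch pairs are
scored by the worse of the two clade Jaccard overlaps, and an optimal
one-to-one assignment over branches is solved exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .data_model import DissimilarityMatrix, PhylogeneticTree, ValidationError

__all__ = [
    "Dendrogram",
    "LINKAGE_METHODS",
    "linkage_cluster",
    "cophenetic_correlation",
    "select_linkage",
    "TopologicalSimilarityResult",
    "nye_topological_similarity",
    "untangle_order",
    "count_crossings",
]


class Dendrogram(PhylogeneticTree):
    """Rooted ultrametric-style tree produced by clustering (or a phylogeny).

    Carries a provenance tag (which matrix + linkage produced it) and, when
    built by :func:`linkage_cluster`, the exact merge-trace cophenetic matrix
    (robust to the edge-length clamping needed by non-monotone linkages).
    """

    def __init__(self, tree: dendropy.Tree, provenance: str = "",
                 cophenetic: DissimilarityMatrix | None = None):
        self.provenance = provenance
        self._cophenetic = cophenetic
        super().__init__(tree)

    def _validate(self):
        labels = self.tip_labels
        if len(labels) < 2:
            raise ValidationError("dendrogram must have at least 2 tips")
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate tip labels in dendrogram")
        # negative edges are clamped at build time; nothing further to check

    @classmethod
    def from_tree(cls, tree: PhylogeneticTree, provenance: str = "phylogeny"):
        return cls(tree.dendropy_tree.clone(depth=1), provenance=provenance)

    def cophenetic_matrix(self, kind: str = "generic") -> DissimilarityMatrix:
        if self._cophenetic is not None:
            return self._cophenetic
        return super().cophenetic_matrix(kind=kind)


#: Lance-Williams coefficients.  ``squared`` methods run the update on
#: squared distances and report sqrt at the end (the convention under which
#: UPGMC/WPGMC/Ward D2 match their textbook definitions); Ward D applies the
#: Ward update to the raw dissimilarities (R's ``ward.D``).
LINKAGE_METHODS = ("UPGMA", "WPGMA", "UPGMC", "WPGMC", "single", "complete",
                   "wardD", "wardD2")


def _lw_update(method, d_ik, d_jk, d_ij, ni, nj, nk):
    if method == "single":
        return 0.5 * d_ik + 0.5 * d_jk - 0.5 * abs(d_ik - d_jk)
    if method == "complete":
        return 0.5 * d_ik + 0.5 * d_jk + 0.5 * abs(d_ik - d_jk)
    if method == "UPGMA":
        return (ni * d_ik + nj * d_jk) / (ni + nj)
    if method == "WPGMA":
        return 0.5 * d_ik + 0.5 * d_jk
    if method == "UPGMC":
        s = ni + nj
        return (ni * d_ik + nj * d_jk) / s - ni * nj * d_ij / s**2
    if method == "WPGMC":
        return 0.5 * d_ik + 0.5 * d_jk - 0.25 * d_ij
    if method in ("wardD", "wardD2"):
        s = ni + nj + nk
        return ((ni + nk) * d_ik + (nj + nk) * d_jk - nk * d_ij) / s
    raise ValidationError(f"unknown linkage method {method!r}")


def linkage_cluster(matrix: DissimilarityMatrix, method: str = "UPGMA") -> Dendrogram:
    """Agglomerative clustering of a dissimilarity matrix.

    Returns a :class:`Dendrogram` whose node heights follow the d/2
    convention (tips at height 0).  Deterministic: ties are merged smallest
    label pair first.
    """
    if method not in LINKAGE_METHODS:
        raise ValidationError(f"method must be one of {LINKAGE_METHODS}")
    if not np.all(np.isfinite(matrix.values)):
        raise ValidationError("non-finite entries in distance matrix")
    squared = method in ("UPGMC", "WPGMC", "wardD2")
    labels = list(matrix.labels)
    n = len(labels)
    work = {}  # (ci, cj) sorted-id pair -> working distance
    d0 = matrix.values ** 2 if squared else matrix.values.copy()
    clusters = {i: {"label": labels[i], "size": 1, "height": 0.0,
                    "node": dendropy.Node()} for i in range(n)}
    taxa = dendropy.TaxonNamespace()
    for i in range(n):
        clusters[i]["node"].taxon = taxa.new_taxon(label=labels[i])
    for i in range(n):
        for j in range(i + 1, n):
            work[(i, j)] = d0[i, j]
    coph = np.zeros((n, n))
    members = {i: [i] for i in range(n)}
    next_id = n
    while len(clusters) > 1:
        # minimum working distance; ties -> lexicographically smallest label pair
        best = min(work.items(),
                   key=lambda kv: (kv[1],
                                   tuple(sorted((clusters[kv[0][0]]["label"],
                                                 clusters[kv[0][1]]["label"])))))
        (ci, cj), wd = best
        dist = float(np.sqrt(max(wd, 0.0))) if squared else float(wd)
        height = dist / 2.0
        a, b = clusters[ci], clusters[cj]
        node = dendropy.Node()
        node.add_child(a["node"])
        node.add_child(b["node"])
        new = {"label": min(a["label"], b["label"]), "size": a["size"] + b["size"],
               "height": height, "node": node}
        for x in members[ci]:
            for y in members[cj]:
                coph[x, y] = coph[y, x] = dist
        # heights attached to nodes for later edge-length assignment
        a["node"].height = a["height"]
        b["node"].height = b["height"]
        node.height = height
        # update distances to the remaining clusters
        for ck in list(clusters):
            if ck in (ci, cj):
                continue
            d_ik = work[tuple(sorted((ci, ck)))]
            d_jk = work[tuple(sorted((cj, ck)))]
            work[tuple(sorted((next_id, ck)))] = _lw_update(
                method, d_ik, d_jk, wd, a["size"], b["size"], clusters[ck]["size"])
        for key in [k for k in work if ci in k or cj in k]:
            del work[key]
        members[next_id] = members.pop(ci) + members.pop(cj)
        del clusters[ci], clusters[cj]
        clusters[next_id] = new
        next_id += 1
    root_id = next(iter(clusters))
    root = clusters[root_id]["node"]
    root.height = clusters[root_id]["height"]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    clamped = False
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            nd.edge.length = None
            continue
        bl = nd.parent_node.height - nd.height
        if bl < 0:
            clamped = True
            bl = 0.0
        nd.edge.length = bl
    if clamped:
        warnings.warn(f"{method}: non-monotone merge heights; negative edges clamped to 0",
                      stacklevel=2)
    coph_m = DissimilarityMatrix(coph, labels, kind=matrix.kind)
    return Dendrogram(tree, provenance=f"{matrix.kind}:{method}", cophenetic=coph_m)


def cophenetic_correlation(matrix: DissimilarityMatrix, dendrogram: Dendrogram) -> float:
    """Pearson correlation of original vs dendrogram-implied distances."""
    coph = dendrogram.cophenetic_matrix()
    if set(coph.labels) != set(matrix.labels):
        raise ValidationError("matrix and dendrogram label sets differ")
    x = matrix.condensed()
    y = coph.condensed()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("cophenetic correlation undefined for constant distances")
    return float(pearsonr(x, y).statistic)


def select_linkage(matrix: DissimilarityMatrix):
    """Fit all eight linkages, keep the one whose dendrogram best preserves
    the matrix (highest cophenetic correlation; ties go to the earlier method
    in :data:`LINKAGE_METHODS`, i.e. UPGMA first).

    Returns ``(best_method, best_dendrogram, table)`` where ``table`` is a
    DataFrame of the eight correlations.
    """
    rows, dendros = [], {}
    for method in LINKAGE_METHODS:
        dend = linkage_cluster(matrix, method)
        rows.append({"method": method,
                     "cophenetic_correlation": cophenetic_correlation(matrix, dend)})
        dendros[method] = dend
    table = pd.DataFrame(rows)
    best = max(range(len(rows)),
               key=lambda i: (rows[i]["cophenetic_correlation"], -i))
    best_method = rows[best]["method"]
    return best_method, dendros[best_method], table


# ---------------------------------------------------------------------------
# Topological similarity (Nye-style branch matching)
# ---------------------------------------------------------------------------

@dataclass
class TopologicalSimilarityResult:
    score: float
    #: (bipartition1, bipartition2, pair score) for each matched branch pair
    mapping: list = field(default_factory=list)


def _internal_bipartitions(tree: PhylogeneticTree) -> list:
    """Non-trivial tip bipartitions (A, B) induced by internal branches."""
    tips = frozenset(tree.tip_labels)
    seen, out = set(), []
    for nd in tree.dendropy_tree.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        clade = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        other = tips - clade
        if len(clade) < 2 or len(other) < 2:
            continue
        key = frozenset((clade, other))
        if key in seen:
            continue
        seen.add(key)
        out.append((clade, other))
    return out


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def _pair_score(bp1, bp2) -> float:
    (a1, b1), (a2, b2) = bp1, bp2
    straight = min(_jaccard(a1, a2), _jaccard(b1, b2))
    flipped = min(_jaccard(a1, b2), _jaccard(b1, a2))
    return max(straight, flipped)


def nye_topological_similarity(tree1: PhylogeneticTree,
                               tree2: PhylogeneticTree) -> TopologicalSimilarityResult:
    """Best one-to-one matching of internal branches between two trees.

    The score is the mean matched-pair score with unmatched branches (when
    the trees have different internal branch counts) counted as zeros, which
    keeps the result in [0, 1] regardless of resolution.  Branch lengths play
    no role.  Identical topologies score exactly 1.
    """
    if set(tree1.tip_labels) != set(tree2.tip_labels):
        raise ValidationError("trees must share an identical tip set")
    bps1 = _internal_bipartitions(tree1)
    bps2 = _internal_bipartitions(tree2)
    if not bps1 or not bps2:
        return TopologicalSimilarityResult(score=0.0, mapping=[])
    S = np.array([[_pair_score(b1, b2) for b2 in bps2] for b1 in bps1])
    rows, cols = linear_sum_assignment(-S)
    mapping = [(bps1[i], bps2[j], float(S[i, j])) for i, j in zip(rows, cols)]
    score = float(S[rows, cols].sum() / max(len(bps1), len(bps2)))
    return TopologicalSimilarityResult(score=score, mapping=mapping)


# ---------------------------------------------------------------------------
# Tanglegram untangling
# ---------------------------------------------------------------------------

def _leaf_order(tree: dendropy.Tree) -> list:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def count_crossings(order1, order2) -> int:
    """Crossings of a tanglegram = pairs of tips in opposite relative order."""
    pos2 = {l: i for i, l in enumerate(order2)}
    seq = [pos2[l] for l in order1]
    return sum(1 for i in range(len(seq)) for j in range(i + 1, len(seq))
               if seq[i] > seq[j])


def _reorder_against(tree: dendropy.Tree, reference_order) -> None:
    """Rotate internal nodes so descendant tips follow the reference order."""
    pos = {l: i for i, l in enumerate(reference_order)}
    mean_pos = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            mean_pos[id(nd)] = pos[nd.taxon.label]
        else:
            kids = nd.child_nodes()
            kids = sorted(kids, key=lambda c: mean_pos[id(c)])
            nd.set_child_nodes(kids)
            mean_pos[id(nd)] = float(np.mean([mean_pos[id(c)] for c in kids]))


def untangle_order(tree1: PhylogeneticTree, tree2: PhylogeneticTree,
                   n_passes: int = 3):
    """Two-sided heuristic rotation to reduce tanglegram crossings.

    Alternately fixes the leaf order of one tree and rotates the internal
    nodes of the other so that each node's children are sorted by the mean
    position of their tips in the fixed order, for ``n_passes`` rounds each
    way.  The best (fewest-crossings) pair of orders seen — including the
    input orders — is returned, so the crossing count never increases.
    """
    if set(tree1.tip_labels) != set(tree2.tip_labels):
        raise ValidationError("trees must share an identical tip set")
    t1 = tree1.dendropy_tree.clone(depth=1)
    t2 = tree2.dendropy_tree.clone(depth=1)
    best = (_leaf_order(t1), _leaf_order(t2))
    best_x = count_crossings(*best)
    for _ in range(n_passes):
        _reorder_against(t2, _leaf_order(t1))
        _reorder_against(t1, _leaf_order(t2))
        o1, o2 = _leaf_order(t1), _leaf_order(t2)
        x = count_crossings(o1, o2)
        if x < best_x:
            best, best_x = (o1, o2), x
        if x == 0:
            break
    return best
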