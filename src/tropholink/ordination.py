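"""PCoA, (distance-based) redundancy analysis, forward selection, phylomorphospace.

Distance matrices enter constrained ordination through principal coordinates:
the doubly-centred Gower transform of -D^2/2 is eigen-decomposed and axes are
scaled by sqrt(eigenvalue), so Euclidean-embeddable distances are reproduced
exactly by the coordinates.  Negative eigenvalues (non-Euclidean input) are
dropped from predictor embeddings by default, with Lingoes and Cailliez
corrections available.

RDA regresses a centred multivariate response on predictor columns (after
partialling out an optional conditioning block) and reports the pseudo-F,
the coefficient of determination, and Ezekiel's adjusted R^2; for partial
models the adjusted R^2 follows the variation-partitioning convention
(adjusted R^2 of condition+predictors minus adjusted R^2 of the condition
alone).  db-RDA first embeds the response distance matrix (keeping axes for
>= 99.9% of the positive variance) and is exactly equivalent to RDA whenever
the distance is Euclidean.  Inference is by permutation: response rows (the
reduced-model residuals when conditioning) are shuffled and the pseudo-F
recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DissimilarityMatrix, PhylogeneticTree, ValidationError

__all__ = [
    "PcoaEmbedding",
    "ConstrainedOrdinationResult",
    "PhylomorphospaceProjection",
    "pcoa",
    "select_axes",
    "rda_fit",
    "db_rda_fit",
    "forward_select",
    "anova_permutation",
    "phylomorphospace_coords",
]


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PcoaEmbedding:
    labels: tuple
    coordinates: pd.DataFrame          # species x positive axes, sqrt(eig)-scaled
    eigenvalues: np.ndarray            # all eigenvalues, descending
    proportion_explained: np.ndarray   # over positive eigenvalues
    cumulative_explained: np.ndarray
    correction: str = "none"

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(matrix: DissimilarityMatrix, correction: str = "none") -> PcoaEmbedding:
    """Principal coordinates analysis of a dissimilarity matrix.

    ``correction`` is one of ``none`` (negative eigenvalues reported but no
    axes built from them), ``lingoes`` (add 2c to squared off-diagonal
    distances, c = |smallest eigenvalue|) or ``cailliez`` (add a constant to
    the off-diagonal distances, found from the companion eigenproblem).
    """
    d = matrix.values.copy()
    if not d.any():
        raise ValidationError("all-zero distance matrix")
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    if correction not in ("none", "lingoes", "cailliez"):
        raise ValidationError(f"unknown correction {correction!r}")
    if correction != "none":
        evals = np.linalg.eigvalsh(_gower_center(d))
        if evals.min() < -1e-8:
            if correction == "lingoes":
                c = -evals.min()
                d2 = d**2
                d2[off] += 2 * c
                d = np.sqrt(d2)
            else:  # cailliez
                z = np.zeros((n, n))
                comp = np.block([[z, 2 * _gower_center(d)],
                                 [-np.eye(n), -4 * _gower_center_linear(d)]])
                c = float(np.max(np.real(np.linalg.eigvals(comp))))
                d = d.copy()
                d[off] += c
    g = _gower_center(d)
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-10, 1e-10 * abs(evals[0]) if evals[0] > 0 else 1e-10)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    prop = evals[pos] / evals[pos].sum()
    cols = [f"PCoA{i + 1}" for i in range(coords.shape[1])]
    cdf = pd.DataFrame(coords, index=list(matrix.labels), columns=cols)
    return PcoaEmbedding(labels=matrix.labels, coordinates=cdf, eigenvalues=evals,
                         proportion_explained=prop,
                         cumulative_explained=np.cumsum(prop), correction=correction)


def _gower_center_linear(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def select_axes(embedding: PcoaEmbedding, n_axes: int | None = None,
                method: str = "scree") -> list:
    """Choose a prefix of the PCoA axes.

    With explicit ``n_axes``, the first that many axes.  Otherwise the scree
    elbow: keep every axis before the largest drop between consecutive
    positive eigenvalues (at least one axis).
    """
    avail = embedding.n_axes
    if n_axes is not None:
        if n_axes < 1:
            raise ValidationError("n_axes must be >= 1")
        if n_axes > avail:
            raise ValidationError(f"requested {n_axes} axes but only {avail} available")
        k = n_axes
    elif method == "scree":
        ev = embedding.eigenvalues[:avail]
        if avail == 1:
            k = 1
        else:
            drops = ev[:-1] - ev[1:]
            k = int(np.argmax(drops)) + 1
    else:
        raise ValidationError(f"unknown selection method {method!r}")
    return list(embedding.coordinates.columns[:k])


# ---------------------------------------------------------------------------
# RDA / db-RDA
# ---------------------------------------------------------------------------

@dataclass
class ConstrainedOrdinationResult:
    F: float
    df: tuple
    R2: float
    adj_R2: float
    p: float | None
    selected_axes: list
    conditioned_on: list
    ss_total: float
    ss_conditioned: float
    ss_constrained: float
    ss_residual: float
    # internals needed by the permutation test
    _Y_res: np.ndarray = field(repr=False, default=None)
    _Qx: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        df1, df2 = self.df
        p = "n/a" if self.p is None else f"{self.p:.4g}"
        return (f"F_{df1},{df2} = {self.F:.3f}, R2 = {self.R2:.3f}, "
                f"adj R2 = {self.adj_R2:.3f}, p = {p}; "
                f"axes: {', '.join(self.selected_axes) or 'none'}")


def _as_matrix(x, name: str) -> tuple[np.ndarray, list]:
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), [str(c) for c in x.columns]
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"{name}{i + 1}" for i in range(arr.shape[1])]


def _orth_basis(x: np.ndarray, names: list, tol: float = 1e-9) -> np.ndarray:
    """Orthonormal basis of the column space; errors naming collinear columns."""
    if x.shape[1] == 0:
        return np.empty((x.shape[0], 0))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > tol * max(s[0], 1.0)))
    if rank < x.shape[1]:
        bad, r = [], 0
        for k in range(x.shape[1]):
            if np.linalg.matrix_rank(x[:, : k + 1], tol=tol) == r:
                bad.append(names[k])
            else:
                r += 1
        raise ValidationError(f"predictors are rank deficient; collinear columns: {bad}")
    return u[:, :rank]


def _ezekiel(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def rda_fit(response, predictors, condition=None, n_perm: int = 0,
            seed: int | None = None, rng: np.random.Generator | None = None) -> ConstrainedOrdinationResult:
    """Redundancy analysis of a multivariate response on predictor columns.

    Rows must be aligned across all three tables.  With ``n_perm > 0`` an
    ANOVA-like permutation p-value is attached (see :func:`anova_permutation`).
    """
    Y, _ = _as_matrix(response, "Y")
    X, xnames = _as_matrix(predictors, "X")
    n = Y.shape[0]
    if X.shape[0] != n:
        raise ValidationError("response and predictors have different row counts")
    Y = Y - Y.mean(axis=0)
    X = X - X.mean(axis=0)
    ss_total = float((Y**2).sum())
    znames: list = []
    if condition is not None:
        Z, znames = _as_matrix(condition, "Z")
        if Z.shape[0] != n:
            raise ValidationError("condition has a different row count")
        Z = Z - Z.mean(axis=0)
        Qz = _orth_basis(Z, znames)
        proj = Qz @ (Qz.T @ Y)
        ss_cond = float((proj**2).sum())
        Y_res = Y - proj
        X_res = X - Qz @ (Qz.T @ X)
        qz = Qz.shape[1]
    else:
        Y_res, X_res, ss_cond, qz = Y, X, 0.0, 0
    Qx = _orth_basis(X_res, xnames)
    p = Qx.shape[1]
    fit = Qx @ (Qx.T @ Y_res)
    ss_constr = float((fit**2).sum())
    ss_resid = float((Y_res**2).sum()) - ss_constr
    df2 = n - p - qz - 1
    if df2 <= 0:
        raise ValidationError("not enough residual degrees of freedom")
    F = (ss_constr / p) / (ss_resid / df2)
    R2 = ss_constr / ss_total
    if condition is not None:
        r2_full = (ss_cond + ss_constr) / ss_total
        adj = _ezekiel(r2_full, n, p + qz) - _ezekiel(ss_cond / ss_total, n, qz)
    else:
        adj = _ezekiel(R2, n, p)
    res = ConstrainedOrdinationResult(
        F=float(F), df=(p, df2), R2=float(R2), adj_R2=float(adj), p=None,
        selected_axes=list(xnames), conditioned_on=znames,
        ss_total=ss_total, ss_conditioned=ss_cond, ss_constrained=ss_constr,
        ss_residual=ss_resid, _Y_res=Y_res, _Qx=Qx)
    if n_perm > 0:
        res.p = anova_permutation(res, n_perm=n_perm, seed=seed, rng=rng)
    return res


def anova_permutation(fit: ConstrainedOrdinationResult, n_perm: int = 10000,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None) -> float:
    """Permutation test of a fitted constrained ordination.

    Rows of the (reduced-model-residualised) response are permuted and the
    pseudo-F recomputed; p = (#{F_perm >= F_obs} + 1) / (n_perm + 1).
    """
    if fit._Y_res is None or fit._Qx is None:
        raise ValidationError("fit does not carry permutation internals")
    if rng is None:
        rng = np.random.default_rng(seed)
    Y, Qx = fit._Y_res, fit._Qx
    n = Y.shape[0]
    p, df2 = fit.df
    ss_within = float((Y**2).sum())  # invariant under row permutation
    hits = 0
    for _ in range(n_perm):
        Yp = Y[rng.permutation(n)]
        ssc = float(((Qx.T @ Yp)**2).sum())
        Fp = (ssc / p) / ((ss_within - ssc) / df2)
        if Fp >= fit.F - 1e-12:
            hits += 1
    return float((hits + 1) / (n_perm + 1))


def db_rda_fit(response: DissimilarityMatrix, predictors, condition=None,
               n_perm: int = 0, seed: int | None = None,
               rng: np.random.Generator | None = None,
               variance_kept: float = 0.999) -> ConstrainedOrdinationResult:
    """Distance-based RDA: PCoA the response distance, then RDA the coordinates.

    Axes are kept until ``variance_kept`` of the positive variance is
    covered.  Exactly equivalent to plain RDA when the distances are
    Euclidean distances of some coordinate table.
    """
    emb = pcoa(response)
    k = int(np.searchsorted(emb.cumulative_explained, variance_kept) + 1)
    k = min(k, emb.n_axes)
    coords = emb.coordinates.iloc[:, :k]
    if isinstance(predictors, pd.DataFrame):
        predictors = predictors.loc[list(response.labels)]
    if isinstance(condition, pd.DataFrame):
        condition = condition.loc[list(response.labels)]
    return rda_fit(coords, predictors, condition=condition, n_perm=n_perm,
                   seed=seed, rng=rng)


def forward_select(response, candidate_axes: pd.DataFrame, alpha: float = 0.05,
                   n_perm: int = 10000, seed: int | None = None,
                   condition=None,
                   rng: np.random.Generator | None = None) -> list:
    """Greedy forward selection of predictor axes by permutation tests.

    At each step the candidate adding the most constrained variance (given
    the condition block and the axes already selected) is tested with a
    marginal permutation F-test; it is admitted when p <= alpha and selection
    stops otherwise.  An empty selection is a legitimate outcome.

    ``response`` may be a coordinate table/array or a
    :class:`DissimilarityMatrix` (embedded via PCoA as in db-RDA).
    """
    if isinstance(response, DissimilarityMatrix):
        emb = pcoa(response)
        k = int(np.searchsorted(emb.cumulative_explained, 0.999) + 1)
        response = emb.coordinates.iloc[:, : min(k, emb.n_axes)]
        candidate_axes = candidate_axes.loc[response.index]
        if isinstance(condition, pd.DataFrame):
            condition = condition.loc[response.index]
    if candidate_axes.shape[1] < 1:
        raise ValidationError("need at least one candidate axis")
    if rng is None:
        rng = np.random.default_rng(seed)
    selected: list = []
    remaining = list(candidate_axes.columns)
    while remaining:
        base_cols = selected
        cond_block = []
        if condition is not None:
            cond_df, _ = _as_matrix(condition, "Z")
            cond_block.append(cond_df)
        if base_cols:
            cond_block.append(candidate_axes[base_cols].to_numpy(dtype=float))
        cond_arr = np.hstack(cond_block) if cond_block else None
        best, best_ss = None, -np.inf
        for cand in remaining:
            try:
                f = rda_fit(response, candidate_axes[[cand]], condition=cond_arr)
            except ValidationError:
                continue
            if f.ss_constrained > best_ss:
                best, best_ss, best_fit = cand, f.ss_constrained, f
        if best is None:
            break
        pval = anova_permutation(best_fit, n_perm=n_perm, rng=rng)
        if pval <= alpha:
            selected.append(best)
            remaining.remove(best)
        else:
            break
    return selected


# ---------------------------------------------------------------------------
# Phylomorphospace
# ---------------------------------------------------------------------------

@dataclass
class PhylomorphospaceProjection:
    #: node label/id -> (x, y); tips keep their embedding coordinates
    node_coordinates: dict
    #: (parent_key, child_key) pairs, one per tree edge
    edges: list
    tip_labels: tuple


def phylomorphospace_coords(tree: PhylogeneticTree,
                            embedding: PcoaEmbedding) -> PhylomorphospaceProjection:
    """Project the tree into the first two ordination axes.

    Tips sit at their embedding coordinates; every internal node is placed at
    the unweighted mean of its children's coordinates, computed tips-to-root.
    """
    coords = embedding.coordinates
    missing = sorted(set(tree.tip_labels) - set(coords.index.astype(str)))
    if missing:
        raise ValidationError(f"tips without embedding coordinates: {missing}")
    if coords.shape[1] < 2:
        raise ValidationError("need at least two ordination axes")
    xy = coords.iloc[:, :2]
    node_xy, edges = {}, []
    counter = [0]

    def key_of(nd):
        if nd.is_leaf():
            return nd.taxon.label
        if not hasattr(nd, "_pms_key"):
            counter[0] += 1
            nd._pms_key = f"node{counter[0]}"
        return nd._pms_key

    for nd in tree.dendropy_tree.postorder_node_iter():
        k = key_of(nd)
        if nd.is_leaf():
            node_xy[k] = tuple(float(v) for v in xy.loc[nd.taxon.label])
        else:
            kids = nd.child_nodes()
            pts = np.array([node_xy[key_of(c)] for c in kids])
            node_xy[k] = tuple(pts.mean(axis=0))
            edges.extend((k, key_of(c)) for c in kids)
    return PhylomorphospaceProjection(node_coordinates=node_xy, edges=edges,
                                      tip_labels=tuple(sorted(tree.tip_labels)))
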