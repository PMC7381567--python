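"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately written by a different route than the
package code (explicit loops, enumeration, naive linear algebra) so that
agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.distance import braycurtis, squareform
from scipy.stats import rankdata


def gower_brute(profiles: dict, typing: dict, ordinal_levels: dict | None = None):
    """Pairwise Gower by per-trait loops over a dict of {species: {trait: val}}."""
    ordinal_levels = ordinal_levels or {}
    species = sorted(profiles)
    traits = sorted(typing)
    ranges = {}
    for t in traits:
        if typing[t] in ("quantitative", "ordinal"):
            vals = []
            for s in species:
                v = profiles[s][t]
                if typing[t] == "ordinal":
                    v = ordinal_levels[t].index(v)
                vals.append(v)
            ranges[t] = max(vals) - min(vals)
    d = np.zeros((len(species), len(species)))
    for i, si in enumerate(species):
        for j, sj in enumerate(species):
            if i >= j:
                continue
            tot, cnt = 0.0, 0
            for t in traits:
                vi, vj = profiles[si][t], profiles[sj][t]
                if typing[t] == "nominal":
                    tot += 0.0 if vi == vj else 1.0
                    cnt += 1
                else:
                    if typing[t] == "ordinal":
                        vi = ordinal_levels[t].index(vi)
                        vj = ordinal_levels[t].index(vj)
                    if ranges[t] == 0:
                        continue
                    tot += abs(vi - vj) / ranges[t]
                    cnt += 1
            d[i, j] = d[j, i] = tot / cnt
    return species, d


def bray_curtis_brute(x: dict, y: dict) -> float:
    keys = set(x) | set(y)
    num = sum(min(x.get(k, 0.0), y.get(k, 0.0)) for k in keys)
    den = sum(x.get(k, 0.0) + y.get(k, 0.0) for k in keys)
    return 1.0 - 2.0 * num / den


def cophenetic_brute(newick_like: dict, labels) -> np.ndarray:
    """Cophenetic from an explicit parent/branch-length description.

    ``newick_like`` maps node -> (parent, branch_length); root parent None.
    """
    def path_to_root(n):
        out = []
        while n is not None:
            out.append(n)
            n = newick_like[n][0]
        return out

    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i >= j:
                continue
            pa, pb = path_to_root(a), path_to_root(b)
            common = set(pa) & set(pb)
            mrca = next(x for x in pa if x in common)
            dist = 0.0
            for node in pa[:pa.index(mrca)]:
                dist += newick_like[node][1]
            for node in pb[:pb.index(mrca)]:
                dist += newick_like[node][1]
            d[i, j] = d[j, i] = dist
    return d


def abouheif_cmean_brute(states: dict, parents: dict, children: dict) -> float:
    """Double-sum C_mean from an explicit tree description.

    ``parents``: node -> parent (root -> None); ``children``: node -> list.
    Proximity = 1/prod(#children of internal nodes on the nodal path),
    row-normalised; statistic on centred states.
    """
    tips = sorted(states)

    def path_internal_nodes(a, b):
        pa = []
        n = parents[a]
        while n is not None:
            pa.append(n)
            n = parents[n]
        pb = []
        n = parents[b]
        while n is not None:
            pb.append(n)
            n = parents[n]
        mrca = next(x for x in pa if x in pb)
        return pa[:pa.index(mrca)] + [mrca] + pb[:pb.index(mrca)]

    n = len(tips)
    A = np.zeros((n, n))
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            if i == j:
                continue
            prod = 1.0
            for node in path_internal_nodes(a, b):
                prod *= len(children[node])
            A[i, j] = 1.0 / prod
    W = A / A.sum(axis=1, keepdims=True)
    x = np.array([states[t] for t in tips], dtype=float)
    xc = x - x.mean()
    return float(sum(W[i, j] * xc[i] * xc[j] for i in range(n) for j in range(n))
                 / sum(xc[i] ** 2 for i in range(n)))


def nye_brute(bps1, bps2) -> float:
    """Exhaustive best one-to-one branch assignment (small trees only)."""
    def jac(a, b):
        return len(a & b) / len(a | b) if (a or b) else 1.0

    def pair(b1, b2):
        (a1, c1), (a2, c2) = b1, b2
        return max(min(jac(a1, a2), jac(c1, c2)), min(jac(a1, c2), jac(c1, a2)))

    small, large = (bps1, bps2) if len(bps1) <= len(bps2) else (bps2, bps1)
    best = 0.0
    for perm in itertools.permutations(range(len(large)), len(small)):
        tot = sum(pair(small[i], large[perm[i]]) for i in range(len(small)))
        best = max(best, tot)
    return best / max(len(bps1), len(bps2))


def spearman_mantel_brute(da: np.ndarray, db: np.ndarray) -> float:
    a = rankdata(squareform(da, checks=False))
    b = rankdata(squareform(db, checks=False))
    return float(np.corrcoef(a, b)[0, 1])


def mantel_exact_p(da: np.ndarray, db: np.ndarray, tail="greater") -> float:
    """Exact permutation p over all n! relabelings of A (tiny n only)."""
    n = da.shape[0]
    obs = spearman_mantel_brute(da, db)
    stats = []
    for perm in itertools.permutations(range(n)):
        pi = list(perm)
        stats.append(spearman_mantel_brute(da[np.ix_(pi, pi)], db))
    stats = np.array(stats)
    if tail == "greater":
        return float(np.mean(stats >= obs - 1e-12))
    raise ValueError(tail)


def partial_spearman_brute(da, db, dc) -> float:
    ra = rankdata(squareform(da, checks=False))
    rb = rankdata(squareform(db, checks=False))
    rc = rankdata(squareform(dc, checks=False))
    rab = np.corrcoef(ra, rb)[0, 1]
    rac = np.corrcoef(ra, rc)[0, 1]
    rbc = np.corrcoef(rb, rc)[0, 1]
    return float((rab - rac * rbc) / np.sqrt((1 - rac**2) * (1 - rbc**2)))


def pcoa_eigvals_brute(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    g = np.empty((n, n))
    a = -0.5 * d**2
    for i in range(n):
        for j in range(n):
            g[i, j] = a[i, j] - a[i].mean() - a[:, j].mean() + a.mean()
    return np.sort(np.linalg.eigvalsh(g))[::-1]


def rda_brute(Y: np.ndarray, X: np.ndarray):
    """R^2 and pseudo-F by explicit hat-matrix arithmetic (no conditioning)."""
    Y = Y - Y.mean(axis=0)
    X = X - X.mean(axis=0)
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    Yhat = H @ Y
    ss_fit = (Yhat**2).sum()
    ss_tot = (Y**2).sum()
    p = np.linalg.matrix_rank(X)
    n = Y.shape[0]
    F = (ss_fit / p) / ((ss_tot - ss_fit) / (n - p - 1))
    return ss_fit / ss_tot, float(F)
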