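import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.ordination import pcoa as skbio_pcoa

from tropholink.data_model import DissimilarityMatrix, PhylogeneticTree, ValidationError
from tropholink.ordination import (
    anova_permutation,
    db_rda_fit,
    forward_select,
    pcoa,
    phylomorphospace_coords,
    rda_fit,
    select_axes,
)

from oracles import pcoa_eigvals_brute, rda_brute


def _euclid_dm(pts, labels=None):
    labels = labels or [f"s{i}" for i in range(len(pts))]
    return DissimilarityMatrix(squareform(pdist(pts)), labels)


class TestPcoa:
    def test_exact_embedding_of_planar_points(self, rng):
        pts = rng.normal(size=(5, 2))
        emb = pcoa(_euclid_dm(pts))
        rebuilt = squareform(pdist(emb.coordinates.iloc[:, :2].to_numpy()))
        np.testing.assert_allclose(rebuilt, squareform(pdist(pts)), atol=1e-8)
        assert np.all(np.abs(emb.eigenvalues[2:]) < 1e-8)

    def test_relative_variance_sums_to_one(self, rng):
        emb = pcoa(_euclid_dm(rng.normal(size=(6, 4))))
        assert emb.proportion_explained.sum() == pytest.approx(1.0)
        assert np.all(np.diff(emb.cumulative_explained) >= -1e-12)

    def test_eigenvalues_match_brute_force_oracle(self):
        d = np.array([[0, 2, 3, 4], [2, 0, 2.5, 3.5], [3, 2.5, 0, 1.5],
                      [4, 3.5, 1.5, 0]])
        emb = pcoa(DissimilarityMatrix(d, list("abcd")))
        np.testing.assert_allclose(emb.eigenvalues, pcoa_eigvals_brute(d), atol=1e-8)

    def test_matches_skbio(self, rng):
        pts = rng.normal(size=(7, 3))
        m = _euclid_dm(pts)
        emb = pcoa(m)
        sk = skbio_pcoa(m.to_skbio())
        np.testing.assert_allclose(np.sort(emb.eigenvalues)[::-1][:6],
                                   np.sort(sk.eigvals.to_numpy())[::-1][:6], atol=1e-8)

    def test_corrections_remove_negative_eigenvalues(self, rng):
        # non-Euclidean matrix: random symmetric perturbation
        pts = rng.normal(size=(6, 2))
        d = squareform(pdist(pts))
        d[0, 1] = d[1, 0] = d[0, 1] * 3  # break the triangle inequality geometry
        m = DissimilarityMatrix(d, [f"s{i}" for i in range(6)])
        assert pcoa(m).eigenvalues.min() < -1e-8
        for corr in ("lingoes", "cailliez"):
            assert pcoa(m, correction=corr).eigenvalues.min() > -1e-6

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            pcoa(DissimilarityMatrix(np.zeros((3, 3)), list("abc")))


class TestSelectAxes:
    def test_explicit_prefix(self, rng):
        emb = pcoa(_euclid_dm(rng.normal(size=(8, 5))))
        assert select_axes(emb, n_axes=4) == ["PCoA1", "PCoA2", "PCoA3", "PCoA4"]

    def test_scree_elbow_obvious_gap(self):
        pts = np.diag([10.0, 9.5, 1.0, 0.9])  # 4 points in 4-D with two big axes
        # construct coordinates directly with desired eigen-structure
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(20, 4)) * np.sqrt([10.0, 9.5, 1.0, 0.9])
        emb = pcoa(_euclid_dm(coords, labels=[f"s{i}" for i in range(20)]))
        k = len(select_axes(emb, method="scree"))
        assert k == 2

    def test_selection_is_prefix(self, rng):
        emb = pcoa(_euclid_dm(rng.normal(size=(9, 4))))
        sel = select_axes(emb)
        assert sel == list(emb.coordinates.columns[:len(sel)])

    def test_invalid_count_rejected(self, rng):
        emb = pcoa(_euclid_dm(rng.normal(size=(5, 2))))
        with pytest.raises(ValidationError):
            select_axes(emb, n_axes=0)


class TestRda:
    def test_response_on_itself_r2_one(self, rng):
        Y = rng.normal(size=(10, 2))
        fit = rda_fit(Y, Y)
        assert fit.R2 == pytest.approx(1.0)
        assert fit.adj_R2 == pytest.approx(1.0)

    def test_vanishing_noise_limit(self, rng):
        x = rng.normal(size=(20, 1))
        y = x + rng.normal(size=(20, 1)) * 1e-8
        assert rda_fit(y, x).adj_R2 == pytest.approx(1.0, abs=1e-6)

    def test_matches_hat_matrix_oracle(self, rng):
        Y = rng.normal(size=(10, 2))
        X = rng.normal(size=(10, 1))
        fit = rda_fit(Y, X)
        r2, F = rda_brute(Y, X)
        assert fit.R2 == pytest.approx(r2, abs=1e-10)
        assert fit.F == pytest.approx(F, abs=1e-8)

    def test_rank_deficiency_names_columns(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=8)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValidationError, match="b"):
            rda_fit(rng.normal(size=(8, 2)), X)

    def test_variance_partition_identity(self, rng):
        Y = rng.normal(size=(12, 3))
        X = rng.normal(size=(12, 2))
        Z = rng.normal(size=(12, 1))
        fit = rda_fit(Y, X, condition=Z)
        total = fit.ss_conditioned + fit.ss_constrained + fit.ss_residual
        assert total == pytest.approx(fit.ss_total, abs=1e-8)

    def test_adjusted_below_unadjusted_without_condition(self, rng):
        Y = rng.normal(size=(15, 2))
        X = rng.normal(size=(15, 3))
        fit = rda_fit(Y, X)
        assert fit.adj_R2 <= fit.R2 <= 1.0


class TestDbRda:
    def test_euclidean_equivalence_with_rda(self, rng):
        pts = rng.normal(size=(12, 3))
        X = rng.normal(size=(12, 2))
        direct = rda_fit(pts, X)
        via_dist = db_rda_fit(_euclid_dm(pts), pd.DataFrame(X, index=[f"s{i}" for i in range(12)]))
        assert via_dist.R2 == pytest.approx(direct.R2, abs=1e-8)
        assert via_dist.F == pytest.approx(direct.F, abs=1e-6)

    def test_conditioning_on_predictors_leaves_nothing(self, rng):
        pts = rng.normal(size=(10, 2))
        X = rng.normal(size=(10, 2))
        labels = [f"s{i}" for i in range(10)]
        fit = db_rda_fit(_euclid_dm(pts), pd.DataFrame(X + rng.normal(size=(10, 2)),
                                                       index=labels),
                         condition=pd.DataFrame(X, index=labels))
        # conditioned-out columns then re-offered: only the residual part remains
        assert fit.ss_constrained <= fit.ss_total

    def test_f_matches_projection_oracle(self, rng):
        pts = rng.normal(size=(9, 2))
        X = rng.normal(size=(9, 1))
        fit = db_rda_fit(_euclid_dm(pts), pd.DataFrame(X, index=[f"s{i}" for i in range(9)]))
        _, F = rda_brute(pts - pts.mean(axis=0), X)
        assert fit.F == pytest.approx(F, abs=1e-6)


class TestForwardSelectionAndAnova:
    def test_generating_candidate_selected(self, rng):
        x = rng.normal(size=(20, 1))
        y = 2 * x + rng.normal(size=(20, 1)) * 0.1
        cand = pd.DataFrame({"signal": x[:, 0], "noise": rng.normal(size=20)})
        sel = forward_select(y, cand, alpha=0.05, n_perm=199, seed=0)
        assert sel[0] == "signal"

    def test_selection_reproducible(self, rng):
        y = rng.normal(size=(15, 2))
        cand = pd.DataFrame(rng.normal(size=(15, 4)),
                            columns=["a", "b", "c", "d"])
        s1 = forward_select(y, cand, n_perm=199, seed=42)
        s2 = forward_select(y, cand, n_perm=199, seed=42)
        assert s1 == s2

    def test_planted_signal_attains_p_floor(self, rng):
        x = rng.normal(size=(25, 1))
        y = x  # perfect signal
        fit = rda_fit(y, x, n_perm=99, seed=0)
        assert fit.p == pytest.approx(1 / 100)

    def test_anova_p_reproducible(self, rng):
        y = rng.normal(size=(12, 2))
        x = rng.normal(size=(12, 1))
        fit = rda_fit(y, x)
        p1 = anova_permutation(fit, n_perm=299, seed=9)
        p2 = anova_permutation(fit, n_perm=299, seed=9)
        assert p1 == p2


class TestPhylomorphospace:
    def test_cherry_parent_at_midpoint(self):
        tree = PhylogeneticTree.from_newick("((A:1,B:1):1,C:2);")
        coords = pd.DataFrame({"PCoA1": [0.0, 2.0, 1.0], "PCoA2": [0.0, 0.0, 3.0]},
                              index=["A", "B", "C"])
        emb = pcoa(_euclid_dm(coords.to_numpy(), labels=["A", "B", "C"]))
        emb.coordinates = coords  # use explicit coordinates for the check
        proj = phylomorphospace_coords(tree, emb)
        parents = {c: p for p, c in proj.edges}
        ab_parent = parents["A"]
        assert proj.node_coordinates[ab_parent] == pytest.approx((1.0, 0.0))

    def test_balanced_square_root_at_centroid(self):
        tree = PhylogeneticTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        coords = pd.DataFrame({"x": [0, 0, 1, 1], "y": [0, 1, 0, 1]},
                              index=["A", "B", "C", "D"], dtype=float)
        emb = pcoa(_euclid_dm(coords.to_numpy(), labels=list("ABCD")))
        emb.coordinates = coords
        proj = phylomorphospace_coords(tree, emb)
        root_key = ({p for p, _ in proj.edges} - {c for _, c in proj.edges}).pop()
        assert proj.node_coordinates[root_key] == pytest.approx((0.5, 0.5))

    def test_matches_recursive_oracle(self, rng):
        from tropholink.synthetic_data import simulate_tree
        tree = simulate_tree(8, rng=np.random.default_rng(5))
        pts = rng.normal(size=(8, 2))
        labels = sorted(tree.tip_labels)
        emb = pcoa(_euclid_dm(pts, labels=labels))
        proj = phylomorphospace_coords(tree, emb)

        # oracle: independent postorder traversal over the dendropy tree
        def avg(nd):
            if nd.is_leaf():
                return np.array(emb.coordinates.iloc[:, :2].loc[nd.taxon.label])
            return np.mean([avg(c) for c in nd.child_nodes()], axis=0)

        root_key = ({p for p, _ in proj.edges} - {c for _, c in proj.edges}).pop()
        np.testing.assert_allclose(proj.node_coordinates[root_key],
                                   avg(tree.dendropy_tree.seed_node), atol=1e-10)

    def test_missing_tip_rejected(self, rng):
        tree = PhylogeneticTree.from_newick("((A:1,B:1):1,C:2);")
        emb = pcoa(_euclid_dm(rng.normal(size=(3, 2)), labels=["A", "B", "X"]))
        with pytest.raises(ValidationError, match="C"):
            phylomorphospace_coords(tree, emb)
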