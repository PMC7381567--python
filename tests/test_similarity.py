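import numpy as np
import pandas as pd
import pytest

from tropholink.data_model import (
    DietRecordTable,
    FoodHierarchy,
    PhylogeneticTree,
    ValidationError,
)
from tropholink.similarity import (
    RarefactionPlan,
    aggregate_diet_to_level,
    classify_trophic_group,
    cophenetic_distance,
    default_trait_typing,
    gower_distance,
    graft_missing_taxa,
    hierarchical_diet_distance,
    isotope_distance,
    site_contrast_matrix,
    size_standardize,
)

from oracles import bray_curtis_brute, gower_brute


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

class TestGraft:
    tree = "((A:1,B:1):1,C:2);"

    def test_graft_splits_host_branch(self):
        t = PhylogeneticTree.from_newick(self.tree)
        g = graft_missing_taxa(t, {"X": "A"}, attachment_fraction=0.5)
        d = g.cophenetic_matrix()
        i, j = d.labels.index("X"), d.labels.index("A")
        assert d.values[i, j] == pytest.approx(1.0)  # A's branch length, split 0.5/0.5
        assert "X" in g.grafted

    def test_zero_fraction_gives_zero_distance(self):
        t = PhylogeneticTree.from_newick(self.tree)
        g = graft_missing_taxa(t, {"X": "C"}, attachment_fraction=0.0)
        d = g.cophenetic_matrix()
        assert d.values[d.labels.index("X"), d.labels.index("C")] == pytest.approx(0.0)

    def test_preserves_existing_distances_and_ultrametricity(self):
        t = PhylogeneticTree.from_newick(self.tree)
        before = cophenetic_distance(t)
        g = graft_missing_taxa(t, {"X": "B"}, attachment_fraction=0.3)
        after = cophenetic_distance(g).restrict(["A", "B", "C"])
        np.testing.assert_allclose(after.values, before.values, atol=1e-9)
        dep = g.depths()
        tip_depths = [dep[id(lf)] for lf in g.dendropy_tree.leaf_node_iter()]
        assert np.ptp(tip_depths) < 1e-9  # input was ultrametric, graft keeps it

    def test_missing_host_rejected(self):
        t = PhylogeneticTree.from_newick(self.tree)
        with pytest.raises(ValidationError, match="host"):
            graft_missing_taxa(t, {"X": "ZZZ"})


class TestCophenetic:
    def test_hand_computed_three_tips(self):
        d = cophenetic_distance(PhylogeneticTree.from_newick("((A:1,B:1):1,C:2);"))
        df = d.to_dataframe()
        assert df.loc["A", "B"] == pytest.approx(2.0)
        assert df.loc["A", "C"] == pytest.approx(4.0)
        assert df.loc["B", "C"] == pytest.approx(4.0)

    def test_star_tree_constant(self):
        d = cophenetic_distance(PhylogeneticTree.from_newick("(A:3,B:3,C:3,D:3);"))
        off = d.values[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 6.0)

    def test_ultrametric_three_point_condition(self):
        t = PhylogeneticTree.from_newick("((A:1,B:1):2,(C:2,D:2):1);")
        v = cophenetic_distance(t).values
        n = v.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    trio = sorted([v[i, j], v[i, k], v[j, k]])
                    assert trio[2] <= trio[1] + 1e-9


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def _morpho_frame(specs):
    """specs: list of dicts with overrides; fills every required column."""
    from tropholink.data_model import LINEAR_MEASUREMENTS
    rows = []
    for s in specs:
        row = {"specimen_id": s["id"], "species_id": s["sp"],
               "standard_length": s.get("sl", 100.0), "gut_length": s.get("gut", 120.0),
               "mouth_orientation": s.get("mouth", "terminal"),
               "tooth_shape": s.get("tooth", "conical"),
               "gill_raker_shape": s.get("raker", "absent")}
        for m in LINEAR_MEASUREMENTS:
            row[m] = s.get(m, 20.0)
        rows.append(row)
    return pd.DataFrame(rows)


class TestSizeStandardize:
    def test_ratio_and_mean(self):
        df = _morpho_frame([
            {"id": "a1", "sp": "A", "sl": 100.0, "body_depth": 25.0},
            {"id": "a2", "sp": "A", "sl": 200.0, "body_depth": 60.0},
        ])
        prof = size_standardize(df)
        assert prof.loc["A", "body_depth"] == pytest.approx((0.25 + 0.30) / 2)

    def test_scale_invariance(self):
        from tropholink.data_model import LINEAR_MEASUREMENTS
        base = _morpho_frame([{"id": "a1", "sp": "A"}])
        doubled = base.copy()
        for col in LINEAR_MEASUREMENTS + ("gut_length", "standard_length"):
            doubled[col] *= 2
        p1, p2 = size_standardize(base), size_standardize(doubled)
        for col in LINEAR_MEASUREMENTS + ("gut_length",):
            assert p1.loc["A", col] == pytest.approx(p2.loc["A", col])

    def test_categorical_mode_with_lexicographic_tiebreak(self):
        df = _morpho_frame([
            {"id": "a1", "sp": "A", "tooth": "conical"},
            {"id": "a2", "sp": "A", "tooth": "unicuspid"},
        ])
        assert size_standardize(df).loc["A", "tooth_shape"] == "conical"


class TestGower:
    def test_identical_profiles_zero(self):
        prof = size_standardize(_morpho_frame(
            [{"id": "a1", "sp": "A"}, {"id": "b1", "sp": "B"}]))
        d = gower_distance(prof)
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_single_nominal_mismatch_is_one_over_traits(self):
        prof = size_standardize(_morpho_frame(
            [{"id": "a1", "sp": "A", "tooth": "conical"},
             {"id": "b1", "sp": "B", "tooth": "absent"}]))
        with pytest.warns(UserWarning, match="zero range"):
            d = gower_distance(prof)
        # every quantitative/ordinal trait is constant -> zero range -> dropped;
        # the two nominal traits remain, one of which mismatches
        assert d.values[0, 1] == pytest.approx(1 / 2)

    def test_matches_brute_force_oracle(self):
        profiles = {
            "A": {"len": 1.0, "depth": 0.2, "tooth": "conical"},
            "B": {"len": 2.0, "depth": 0.5, "tooth": "conical"},
            "C": {"len": 1.5, "depth": 0.8, "tooth": "absent"},
        }
        typing = {"len": "quantitative", "depth": "quantitative", "tooth": "nominal"}
        species, expected = gower_brute(profiles, typing)
        df = pd.DataFrame(profiles).T
        df["len"] = df["len"].astype(float)
        df["depth"] = df["depth"].astype(float)
        got = gower_distance(df, trait_typing=typing)
        assert list(got.labels) == species
        np.testing.assert_allclose(got.values, expected, atol=1e-8)

    def test_ordinal_uses_integer_ranks(self):
        levels = ("superior", "terminal", "subterminal", "inferior")
        df = pd.DataFrame({"mouth": ["superior", "terminal", "inferior"]},
                          index=["A", "B", "C"])
        d = gower_distance(df, trait_typing={"mouth": "ordinal"},
                           ordinal_levels={"mouth": levels})
        assert d.to_dataframe().loc["A", "B"] == pytest.approx(1 / 3)
        assert d.to_dataframe().loc["A", "C"] == pytest.approx(1.0)

    def test_bounded_unit_interval(self, small_bundle):
        d = gower_distance(size_standardize(small_bundle.morpho))
        assert d.values.min() >= 0 and d.values.max() <= 1 + 1e-12


# ---------------------------------------------------------------------------
# isotopes
# ---------------------------------------------------------------------------

def _iso_frame(means):
    rows = []
    for sp, (c, n) in means.items():
        for k, (dc, dn) in enumerate([(c - 0.0, n), (c + 0.0, n)]):
            rows.append({"specimen_id": f"{sp}{k}", "species_id": sp,
                         "d13C": dc, "d15N": dn})
    return pd.DataFrame(rows)


class TestIsotopeDistance:
    def test_identical_means_zero(self):
        d = isotope_distance(_iso_frame({"A": (-25, 8), "B": (-25, 8), "C": (-20, 4)}))
        assert d.to_dataframe().loc["A", "B"] == pytest.approx(0.0)

    def test_equally_spaced_species_double_distance(self):
        d = isotope_distance(_iso_frame({"A": (-30, 6), "B": (-25, 8), "C": (-20, 10)}))
        df = d.to_dataframe()
        assert df.loc["A", "C"] == pytest.approx(2 * df.loc["A", "B"], rel=1e-9)

    def test_translation_invariance(self):
        base = {"A": (-30, 6), "B": (-25, 8), "C": (-20, 10)}
        shifted = {k: (c + 7.5, n - 3.25) for k, (c, n) in base.items()}
        d1 = isotope_distance(_iso_frame(base))
        d2 = isotope_distance(_iso_frame(shifted))
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-9)

    def test_zero_variance_axis_named(self):
        with pytest.raises(ValidationError, match="d13C"):
            isotope_distance(_iso_frame({"A": (-25, 6), "B": (-25, 8), "C": (-25, 10)}))

    def test_per_site_standardization_changes_result(self):
        recs = _iso_frame({"A": (-30, 6), "B": (-25, 8), "C": (-20, 10), "D": (-18, 12)})
        sites = pd.Series({"A": "s1", "B": "s1", "C": "s2", "D": "s2"})
        d_global = isotope_distance(recs)
        d_site = isotope_distance(recs, per_site_standardize=True, sites=sites)
        assert not np.allclose(d_global.values, d_site.values)


# ---------------------------------------------------------------------------
# diet
# ---------------------------------------------------------------------------

def _two_level_hierarchy():
    """Level 1 = {food}; level 2 = {seeds, chironomidae} under it."""
    return FoodHierarchy(
        levels=["broad", "fine"],
        parent={"food": None, "seeds": "food", "chironomidae": "food"},
        node_level={"food": 1, "seeds": 2, "chironomidae": 2},
        leaf_map={"seeds": "seeds", "chironomidae": "chironomidae"},
    )


def _diet(rows):
    wide = pd.DataFrame(rows).T.fillna(0.0)
    species = pd.Series({s: s.split("_")[0] for s in wide.index})
    return DietRecordTable(wide, species)


class TestAggregate:
    def test_merges_into_parent_category(self):
        h = FoodHierarchy(
            levels=["broad", "fine"],
            parent={"algae": None, "diatom": "algae", "filamentous": "algae"},
            node_level={"algae": 1, "diatom": 2, "filamentous": 2},
            leaf_map={"diatom": "diatom", "filamentous": "filamentous"},
        )
        diet = _diet({"A_1": {"diatom": 0.5, "filamentous": 0.5}})
        out = aggregate_diet_to_level(diet, h, 1)
        assert out.loc["A_1", "algae"] == pytest.approx(1.0)

    def test_exclusion_renormalizes(self):
        h = FoodHierarchy(
            levels=["broad", "fine"],
            parent={"animal": None, "fish_unid": "animal", "chironomidae": "animal"},
            node_level={"animal": 1, "fish_unid": 2, "chironomidae": 2},
            leaf_map={"fish_unid": "fish_unid", "chironomidae": "chironomidae"},
            exclusions={("fish_unid", 2)},
        )
        diet = _diet({"A_1": {"fish_unid": 0.4, "chironomidae": 0.6}})
        out = aggregate_diet_to_level(diet, h, 2)
        assert out.loc["A_1", "chironomidae"] == pytest.approx(1.0)

    def test_mass_conserved_at_every_level(self, small_bundle):
        for level in range(1, small_bundle.hierarchy.n_levels + 1):
            out = aggregate_diet_to_level(small_bundle.diet, small_bundle.hierarchy, level)
            np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)


class TestHierarchicalDietDistance:
    def test_identical_diets_zero(self):
        h = _two_level_hierarchy()
        diet = _diet({"A_1": {"seeds": 1.0}, "A_2": {"seeds": 1.0},
                      "B_1": {"seeds": 1.0}, "B_2": {"seeds": 1.0}})
        d = hierarchical_diet_distance(diet, h, RarefactionPlan(target_n=2, n_iterations=5))
        assert d.to_dataframe().loc["A", "B"] == pytest.approx(0.0)

    def test_disjoint_at_fine_level(self):
        h = _two_level_hierarchy()
        diet = _diet({"A_1": {"seeds": 1.0}, "B_1": {"chironomidae": 1.0}})
        d, levels = hierarchical_diet_distance(
            diet, h, RarefactionPlan(target_n=16), return_levels=True)
        # level 1 merges everything -> 0; level 2 disjoint -> 1; unified 0.5
        assert d.to_dataframe().loc["A", "B"] == pytest.approx(0.5)

    def test_two_level_toy_hand_computed(self):
        h = _two_level_hierarchy()
        diet = _diet({"A_1": {"seeds": 1.0}, "A_2": {"seeds": 1.0},
                      "B_1": {"seeds": 0.5, "chironomidae": 0.5},
                      "B_2": {"seeds": 0.5, "chironomidae": 0.5}})
        for seed in (0, 99):
            d = hierarchical_diet_distance(
                diet, h, RarefactionPlan(target_n=16, n_iterations=3, seed=seed))
            # level 1: all mass in one category -> 0; level 2: BC({1,0},{.5,.5}) = .5
            assert d.to_dataframe().loc["A", "B"] == pytest.approx(0.25, abs=1e-12)

    def test_deterministic_when_sample_fits_target(self, small_bundle):
        plan_a = RarefactionPlan(target_n=16, n_iterations=1, seed=1)
        plan_b = RarefactionPlan(target_n=16, n_iterations=50, seed=2024)
        da = hierarchical_diet_distance(small_bundle.diet, small_bundle.hierarchy, plan_a)
        db = hierarchical_diet_distance(small_bundle.diet, small_bundle.hierarchy, plan_b)
        np.testing.assert_array_equal(da.values, db.values)

    def test_rarefaction_converges_with_iterations(self, small_bundle):
        plan_small = RarefactionPlan(target_n=8, n_iterations=30, seed=3)
        plan_large = RarefactionPlan(target_n=8, n_iterations=600, seed=4)
        da = hierarchical_diet_distance(small_bundle.diet, small_bundle.hierarchy, plan_small)
        db = hierarchical_diet_distance(small_bundle.diet, small_bundle.hierarchy, plan_large)
        assert np.abs(da.values - db.values).max() < 0.05

    def test_matches_per_level_bray_curtis_oracle(self):
        h = FoodHierarchy(
            levels=["broad", "fine"],
            parent={"plant": None, "animal": None, "seed": "plant", "leaf": "plant",
                    "worm": "animal", "midge": "animal"},
            node_level={"plant": 1, "animal": 1, "seed": 2, "leaf": 2,
                        "worm": 2, "midge": 2},
            leaf_map={c: c for c in ["seed", "leaf", "worm", "midge"]},
        )
        diets = {
            "A": {"seed": 0.6, "worm": 0.4},
            "B": {"leaf": 0.3, "seed": 0.2, "midge": 0.5},
            "C": {"worm": 0.9, "midge": 0.1},
        }
        diet = _diet({f"{sp}_1": v for sp, v in diets.items()})
        got = hierarchical_diet_distance(diet, h, RarefactionPlan(target_n=16))
        def level1(v):
            return {"plant": v.get("seed", 0) + v.get("leaf", 0),
                    "animal": v.get("worm", 0) + v.get("midge", 0)}
        for a in "ABC":
            for b in "ABC":
                if a >= b:
                    continue
                expected = 0.5 * (bray_curtis_brute(level1(diets[a]), level1(diets[b]))
                                  + bray_curtis_brute(diets[a], diets[b]))
                assert got.to_dataframe().loc[a, b] == pytest.approx(expected, abs=1e-8)

    def test_bounded_unit_interval(self, small_bundle):
        d = hierarchical_diet_distance(small_bundle.diet, small_bundle.hierarchy,
                                       RarefactionPlan(target_n=16))
        assert d.values.min() >= 0 and d.values.max() <= 1 + 1e-9


class TestTrophicGroups:
    @pytest.mark.parametrize("props,expected", [
        ({"plant_detritus": 0.8, "invertebrate": 0.2}, "herbivore_detritivore"),
        ({"fish": 1.0}, "piscivore"),
        ({"invertebrate": 0.75}, "invertivore"),
        ({"invertebrate": 0.4, "fish": 0.45}, "omnivore2"),
        ({"plant_detritus": 0.4, "invertebrate": 0.5}, "omnivore1"),
        ({"plant_detritus": 0.45, "invertebrate": 0.1, "fish": 0.45}, "unclassified"),
        ({"plant_detritus": 0.71, "invertebrate": 0.29}, "herbivore_detritivore"),
    ])
    def test_threshold_rules(self, props, expected):
        assert classify_trophic_group(props) == expected

    def test_rules_exhaustive_on_grid(self):
        # no rule region should silently overlap: rule order is fixed, so the
        # classifier must be a total function on the simplex
        for p in np.linspace(0, 1, 11):
            for i in np.linspace(0, 1 - p, 6):
                f = 1 - p - i
                g = classify_trophic_group(
                    {"plant_detritus": p, "invertebrate": i, "fish": f})
                assert g in ("herbivore_detritivore", "omnivore1", "invertivore",
                             "omnivore2", "piscivore", "unclassified")


class TestSiteContrast:
    def test_coding(self):
        st = pd.DataFrame({"species_id": ["A", "B", "C"],
                           "site_id": ["s1", "s1", "s2"]})
        d = site_contrast_matrix(st).to_dataframe()
        assert d.loc["A", "B"] == 0 and d.loc["A", "C"] == 1 and d.loc["B", "C"] == 1

    def test_single_site_all_zero(self):
        st = pd.DataFrame({"species_id": list("ABCD"), "site_id": ["s"] * 4})
        assert site_contrast_matrix(st).values.sum() == 0

    def test_binary_values_only(self, small_bundle):
        vals = site_contrast_matrix(small_bundle.species).values
        assert set(np.unique(vals)) <= {0.0, 1.0}
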