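"""Three-channel ingredient screening on the He Shou Wu fixture."""

import numpy as np
import pytest

import hepatoscreen as hs
from hepatoscreen.featurize import FeatureMatrix
from hepatoscreen.screen import (
    HerbIngredientNetwork,
    HILIDataset,
    cluster_ingredients,
    integrate,
    screen_subgroup1,
    screen_subgroup2,
    screen_subgroup3,
)
from hepatoscreen.synthetic import make_stub_bases, stacked_from_stubs


def fixture_stub_model(pmt):
    """Stacked model whose 8 stub bases replay the fixture's channel-1 calls."""
    ids = [r.compound_id for r in pmt.ingredients]
    name_of = {r.compound_id: hs.normalize_name(r.name) for r in pmt.ingredients}
    col = np.array([1 if name_of[i] in pmt.expected.subgroup1 else 0 for i in ids])
    stubs = make_stub_bases(np.tile(col[:, None], (1, 8)), row_ids=ids,
                            families=["f"] * 8)
    fm = FeatureMatrix(ids, ["x"], np.zeros((len(ids), 1)), "f", "continuous")
    return stacked_from_stubs(stubs, {"f": fm}, col), fm


class TestSubgroup1:
    def test_fixture_yields_21_flagged_ingredients(self, pmt):
        model, fm = fixture_stub_model(pmt)
        s1, probs, notices = screen_subgroup1(pmt.ingredients, model, {"f": fm})
        assert s1 == pmt.expected.subgroup1
        assert len(s1) == 21
        assert all(probs[name] > 0.5 for name in s1)

    def test_all_negative_model_flags_nothing(self, pmt):
        ids = [r.compound_id for r in pmt.ingredients]
        stubs = make_stub_bases(np.zeros((len(ids), 8), dtype=int),
                                row_ids=ids, families=["f"] * 8)
        fm = FeatureMatrix(ids, ["x"], np.zeros((len(ids), 1)), "f", "continuous")
        model = stacked_from_stubs(stubs, {"f": fm},
                                   np.r_[np.ones(11, int), np.zeros(11, int)])
        s1, _, _ = screen_subgroup1(pmt.ingredients, model, {"f": fm})
        assert s1 == set()

    def test_probability_exactly_half_excluded(self, pmt):
        class HalfModel:
            decision_threshold = 0.5

            def predict_proba_pos(self, fms):
                return np.full(len(next(iter(fms.values())).row_ids), 0.5)

        ids = [r.compound_id for r in pmt.ingredients]
        fm = FeatureMatrix(ids, ["x"], np.zeros((len(ids), 1)), "f", "continuous")
        s1, probs, _ = screen_subgroup1(pmt.ingredients, HalfModel(), {"f": fm})
        assert s1 == set() and all(p == 0.5 for p in probs.values())

    def test_structureless_ingredients_get_notices(self, pmt):
        model, fm = fixture_stub_model(pmt)
        # drop one ingredient from the featurized rows
        short = fm.subset_rows(np.arange(len(fm.row_ids) - 1))
        ids = short.row_ids
        name_of = {r.compound_id: hs.normalize_name(r.name) for r in pmt.ingredients}
        col = np.array([1 if name_of[i] in pmt.expected.subgroup1 else 0 for i in ids])
        stubs = make_stub_bases(np.tile(col[:, None], (1, 8)), row_ids=ids,
                                families=["f"] * 8)
        model = stacked_from_stubs(stubs, {"f": short}, col)
        _, _, notices = screen_subgroup1(pmt.ingredients, model, {"f": short})
        assert len(notices) == 1 and "no usable structure" in notices[0]


class TestSubgroup2:
    def test_fixture_yields_six_hili_matches(self, pmt):
        s2 = screen_subgroup2(pmt.ingredients, pmt.hili)
        assert s2 == pmt.expected.subgroup2 and len(s2) == 6

    def test_empty_hili_set(self, pmt):
        assert screen_subgroup2(pmt.ingredients, HILIDataset()) == set()

    def test_case_variant_names_match(self, pmt):
        from hepatoscreen.chem_io import CompoundRecord, Dataset

        ds = Dataset([CompoundRecord("x", name="EMODIN")])
        assert screen_subgroup2(ds, pmt.hili) == {"emodin"}

    def test_never_invents_names(self, pmt):
        s2 = screen_subgroup2(pmt.ingredients, pmt.hili)
        queried = {hs.normalize_name(r.name) for r in pmt.ingredients}
        assert s2 <= queried


class TestSubgroup3:
    def test_he_shou_wu_has_seven_network_ingredients(self, pmt):
        s3, notices = screen_subgroup3("He Shou Wu", pmt.network)
        assert s3 == {
            "emodin", "chrysophanol", "chrysarobin", "rhein", "danthron",
            "polygonumnolide c2", "emodin dianthrone",
        }
        assert notices == []

    def test_query_normalization_insensitive(self, pmt):
        a, _ = screen_subgroup3("he shou wu", pmt.network)
        b, _ = screen_subgroup3("He-Shou-Wu", pmt.network)
        assert a == b

    def test_absent_herb_gives_notice_not_error(self, pmt):
        s3, notices = screen_subgroup3("chamomile", pmt.network)
        assert s3 == set() and "not found" in notices[0]

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            HerbIngredientNetwork([("emodin", "Emodin")])


class TestIntegrate:
    def test_fixture_union_and_unique_counts(self, pmt):
        e = pmt.expected
        result = integrate(e.subgroup1, e.subgroup2, e.subgroup3)
        assert len(result.union) == 25
        assert result.unique_counts == (15, 1, 3)

    def test_three_empty_sets(self):
        result = integrate(set(), set(), set())
        assert result.union == set() and result.unique_counts == (0, 0, 0)

    def test_commutative_and_idempotent_in_sets(self, pmt):
        e = pmt.expected
        r1 = integrate(e.subgroup1, e.subgroup2, e.subgroup3)
        r2 = integrate(set(e.subgroup1), set(e.subgroup2), set(e.subgroup3))
        assert r1.union == r2.union and r1.provenance == r2.provenance

    def test_provenance_consistent_with_membership(self, pmt):
        e = pmt.expected
        result = integrate(e.subgroup1, e.subgroup2, e.subgroup3)
        for name, channels in result.provenance.items():
            assert channels  # non-empty for every union member
            assert ("classifier" in channels) == (name in result.subgroup1)
            assert ("hili" in channels) == (name in result.subgroup2)
            assert ("network" in channels) == (name in result.subgroup3)
        total = sum(len(c) for c in result.provenance.values())
        assert total == len(e.subgroup1) + len(e.subgroup2) + len(e.subgroup3)

    def test_table_mirrors_membership(self, pmt):
        e = pmt.expected
        table = integrate(e.subgroup1, e.subgroup2, e.subgroup3).to_table()
        assert len(table) == 25
        assert int(table["in_s1"].sum()) == 21
        assert int(table["in_s2"].sum()) == 6
        assert int(table["in_s3"].sum()) == 7


class TestClustering:
    def test_identical_rows_merge_first_at_zero_distance(self):
        values = np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]])
        fm = FeatureMatrix(["a", "b", "c"], ["x", "y"], values, "f", "continuous")
        labels, Z = cluster_ingredients(fm, 2)
        assert Z[0, 2] == 0.0  # first merge joins the duplicates
        assert labels["a"] == labels["b"] != labels["c"]

    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(0)
        values = np.vstack([rng.standard_normal((10, 3)) + 8,
                            rng.standard_normal((10, 3)) - 8])
        fm = FeatureMatrix([f"i{k}" for k in range(20)], ["a", "b", "c"],
                           values, "f", "continuous")
        labels, _ = cluster_ingredients(fm, 2)
        first = {labels[f"i{k}"] for k in range(10)}
        second = {labels[f"i{k}"] for k in range(10, 20)}
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_n_groups_equal_n_gives_singletons(self):
        values = np.arange(8, dtype=float).reshape(4, 2)
        fm = FeatureMatrix(list("abcd"), ["x", "y"], values, "f", "continuous")
        labels, _ = cluster_ingredients(fm, 4)
        assert sorted(labels.values()) == [1, 2, 3, 4]

    def test_too_many_groups_rejected(self):
        fm = FeatureMatrix(["a", "b"], ["x"], np.zeros((2, 1)), "f", "continuous")
        with pytest.raises(ValueError, match="exceeds"):
            cluster_ingredients(fm, 3)
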