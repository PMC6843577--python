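"""Selection cascade: Boruta, correlation pruning, RFE ranking, subset sweep."""

import numpy as np
import pandas as pd
import pytest

import hepatoscreen as hs
from hepatoscreen.learners import LearnerSpec
from hepatoscreen.selection import (
    FeatureRanking,
    SelectionConfig,
    boruta_select,
    correlation_prune,
    find_correlation,
    load_reference_selection_widths,
    rfe_rank,
    subset_sweep,
    sweep_evaluation_count,
)

from conftest import fast_selection_config


class TestFindCorrelation:
    def test_duplicated_column_keeps_exactly_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.standard_normal(50)})
        retained = correlation_prune(df, 0.90)
        assert "c" in retained and len(retained) == 2

    def test_mean_abs_correlation_rule_drops_hub_feature(self):
        # |r| matrix with r(1,2)=0.95, r(1,3)=0.96, r(2,3)=0.10:
        # feature 1 has the larger mean |r| in both offending pairs
        corr = np.array([[1.0, 0.95, 0.96], [0.95, 1.0, 0.10], [0.96, 0.10, 1.0]])
        keep = find_correlation(corr, 0.90)
        assert keep.tolist() == [False, True, True]

    def test_postcondition_max_pairwise_r_below_cutoff(self):
        rng = np.random.default_rng(42)
        for trial in range(5):
            base = rng.standard_normal((60, 4))
            mix = rng.standard_normal((4, 12))
            data = base @ mix + 0.3 * rng.standard_normal((60, 12))
            df = pd.DataFrame(data, columns=[f"f{i}" for i in range(12)])
            retained = correlation_prune(df, 0.90)
            if len(retained) >= 2:
                sub = np.abs(np.corrcoef(df[retained].to_numpy(), rowvar=False))
                np.fill_diagonal(sub, 0.0)
                assert sub.max() <= 0.90 + 1e-12

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="constant"):
            correlation_prune(df, 0.9)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(80)
        df = pd.DataFrame({
            "a": x, "b": x + 0.05 * rng.standard_normal(80),
            "c": rng.standard_normal(80),
        })
        r1 = set(correlation_prune(df, 0.9))
        r2 = set(correlation_prune(df[["c", "b", "a"]], 0.9))
        assert r1 == r2


class TestBoruta:
    def test_planted_informative_features_confirmed(self):
        fm, y, roles = hs.make_classification_set(
            hs.SynthSpec(n=200, p_informative=5, p_redundant=0, p_noise=15,
                         effect_size=2.0, seed=3)
        )
        result = boruta_select(fm, y, fast_selection_config(seed=1))
        informative = {n for n, r in roles.items() if r == "informative"}
        assert informative <= result["confirmed"]

    def test_sets_partition_the_features(self):
        fm, y, _ = hs.make_classification_set(
            hs.SynthSpec(n=80, p_informative=2, p_redundant=0, p_noise=6, seed=0)
        )
        result = boruta_select(fm, y, fast_selection_config())
        union = result["confirmed"] | result["rejected"] | result["tentative"]
        assert union == set(fm.feature_names)
        assert not (result["confirmed"] & result["rejected"])
        assert not (result["confirmed"] & result["tentative"])

    def test_shuffled_labels_confirm_nothing(self):
        fm, y, _ = hs.make_classification_set(
            hs.SynthSpec(n=100, p_informative=3, p_redundant=0, p_noise=7,
                         effect_size=2.0, seed=5)
        )
        rng = np.random.default_rng(11)
        result = boruta_select(fm, rng.permutation(y), fast_selection_config(seed=11))
        assert result["confirmed"] == set()

    def test_single_class_rejected(self):
        fm, y, _ = hs.make_classification_set(hs.SynthSpec(n=40, seed=0))
        with pytest.raises(ValueError, match="both classes"):
            boruta_select(fm, np.ones_like(y), fast_selection_config())


class TestRFE:
    def test_single_feature_gets_rank_one(self):
        fm, y, _ = hs.make_classification_set(
            hs.SynthSpec(n=40, p_informative=1, p_redundant=0, p_noise=0, seed=0)
        )
        ranking = rfe_rank(fm, y, fast_selection_config())
        assert ranking.names_by_rank == ["inf_0"]

    def test_informative_among_noise_ranked_first(self):
        fm, y, _ = hs.make_classification_set(
            hs.SynthSpec(n=150, p_informative=1, p_redundant=0, p_noise=9,
                         effect_size=3.0, seed=4)
        )
        ranking = rfe_rank(fm, y, fast_selection_config(seed=4))
        assert ranking.names_by_rank[0] == "inf_0"

    def test_ranking_is_permutation_with_elimination_rounds(self):
        fm, y, _ = hs.make_classification_set(
            hs.SynthSpec(n=60, p_informative=2, p_redundant=0, p_noise=4, seed=1)
        )
        ranking = rfe_rank(fm, y, fast_selection_config(seed=1))
        assert sorted(ranking.names_by_rank) == sorted(fm.feature_names)
        p = len(ranking)
        last = ranking.names_by_rank[-1]
        assert ranking.elimination_round[last] == 1  # lowest rank leaves first

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="permutation"):
            FeatureRanking(["a", "a"], {"a": 1})


@pytest.fixture(scope="module")
def swept():
    fm, y, _ = hs.make_classification_set(
        hs.SynthSpec(n=60, p_informative=2, p_redundant=0, p_noise=3,
                     effect_size=2.5, seed=6)
    )
    ranking = rfe_rank(fm, y, fast_selection_config(seed=6))
    spec = LearnerSpec("decision_tree", seed=0)
    return subset_sweep(fm, y, ranking, spec, k_folds=3, seed=0)


class TestSubsetSweep:
    def test_evaluation_count_equals_feature_count(self, swept):
        assert swept.n_evaluations == 5
        assert sorted(swept.table["k"]) == [1, 2, 3, 4, 5]

    def test_chosen_subset_is_ranking_prefix(self, swept):
        assert len(swept.best_features) == swept.best_k
        best_score = swept.table["score"].max()
        ties = swept.table.loc[np.isclose(swept.table["score"], best_score), "k"]
        assert swept.best_k == ties.min()  # ties break toward fewer features

    def test_missing_ranking_names_rejected(self):
        fm, y, _ = hs.make_classification_set(
            hs.SynthSpec(n=40, p_informative=1, p_redundant=0, p_noise=1, seed=0)
        )
        ranking = FeatureRanking(["ghost"], {"ghost": 1})
        with pytest.raises(ValueError, match="absent"):
            subset_sweep(fm, y, ranking, LearnerSpec("knn"), k_folds=2)


class TestSweepBookkeeping:
    def test_reference_widths_sum_to_published_totals(self):
        widths = load_reference_selection_widths()
        assert len(widths) == 13
        per_learner = sweep_evaluation_count(widths["pruned"])
        assert per_learner == 677
        assert sweep_evaluation_count(widths["pruned"], n_learners=8) == 5416

    def test_pruned_never_exceeds_all_relevant(self):
        widths = load_reference_selection_widths()
        assert (widths["pruned"] <= widths["all_relevant"]).all()
        assert (widths["all_relevant"] <= widths["raw"]).all()


def test_selection_config_validation():
    with pytest.raises(ValueError):
        SelectionConfig(correlation_cutoff=1.5)
    with pytest.raises(ValueError):
        SelectionConfig(rfe_step=0)
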