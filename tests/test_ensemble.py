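"""Stacked combined classifier: meta-features, Naive Bayes fusion, symmetry."""

import numpy as np
import pytest

import hepatoscreen as hs
from hepatoscreen.ensemble import (
    BaseRecipe,
    StackedDILIClassifier,
    build_meta_features,
    fit_stacked,
    load_stacked,
    majority_vote,
    predict_stacked,
    save_stacked,
)
from hepatoscreen.evaluate import cross_validate
from hepatoscreen.featurize import FeatureMatrix
from hepatoscreen.learners import LearnerRecipe, LearnerSpec
from hepatoscreen.synthetic import make_stub_bases, stacked_from_stubs

from conftest import aligned_family_views


def dummy_fm(n, family="f", ids=None):
    ids = ids or [f"c{i}" for i in range(n)]
    return FeatureMatrix(ids, ["x"], np.zeros((n, 1)), family, "continuous")


class TestMetaFeatures:
    def test_stub_truth_table_replayed_exactly(self):
        rng = np.random.default_rng(0)
        table = rng.integers(0, 2, size=(10, 8))
        stubs = make_stub_bases(table, families=["f"] * 8)
        meta = build_meta_features(stubs, {"f": dummy_fm(10)})
        np.testing.assert_array_equal(meta, table)
        assert meta.shape == (10, 8)
        assert np.isin(meta, (0, 1)).all()

    def test_unanimous_positive_row(self):
        stubs = make_stub_bases(np.ones((3, 8), dtype=int), families=["f"] * 8)
        meta = build_meta_features(stubs, {"f": dummy_fm(3)})
        assert (meta == 1).all()

    def test_row_id_mismatch_rejected(self):
        fms = {"a": dummy_fm(4, "a"), "b": dummy_fm(4, "b", ids=list("wxyz"))}
        stubs = make_stub_bases(np.zeros((4, 2), dtype=int), families=["a", "b"])
        with pytest.raises(ValueError, match="row ids"):
            build_meta_features(stubs, fms)

    def test_majority_vote_reference_rule(self):
        meta = np.array([[1, 1, 0], [0, 1, 0], [1, 1, 1]])
        np.testing.assert_array_equal(majority_vote(meta), [1, 0, 1])


class TestMetaNaiveBayes:
    def test_identity_stubs_reach_resubstitution_100(self):
        y = np.array([1, 0, 1, 0, 1, 1, 0, 0, 1, 0])
        table = np.tile(y[:, None], (1, 8))
        stubs = make_stub_bases(table, families=["f"] * 8)
        fm = dummy_fm(10)
        model = stacked_from_stubs(stubs, {"f": fm}, y)
        assert (model.predict({"f": fm}) == y).all()

    def test_posterior_matches_hand_computed_bernoulli_nb(self):
        # 3 bases, 8 compounds: oracle is closed-form NB with +1 smoothing
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        table = np.array([
            [1, 1, 0], [1, 0, 1], [1, 1, 1], [0, 1, 1],
            [0, 0, 0], [0, 1, 0], [1, 0, 0], [0, 0, 1],
        ])
        stubs = make_stub_bases(table, families=["f"] * 3)
        fm = dummy_fm(8)
        model = stacked_from_stubs(stubs, {"f": fm}, y)
        got = model.predict_proba_pos({"f": fm})

        def hand_posterior(x):
            post = []
            for c in (0, 1):
                rows = table[y == c]
                prior = len(rows) / len(y)
                theta = (rows.sum(axis=0) + 1) / (len(rows) + 2)
                lik = np.prod(np.where(x == 1, theta, 1 - theta))
                post.append(prior * lik)
            return post[1] / (post[0] + post[1])

        expected = np.array([hand_posterior(x) for x in table])
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_inverted_base_learns_reversed_likelihood(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=200)
        table = np.column_stack([y, y, 1 - y])  # third base is inverted
        stubs = make_stub_bases(table, families=["f"] * 3)
        fm = dummy_fm(200)
        model = stacked_from_stubs(stubs, {"f": fm}, y)
        theta = np.exp(model.meta_model_.feature_log_prob_)  # [class, base]
        pos = list(model.meta_model_.classes_).index(1)
        assert theta[pos, 0] > 0.9  # faithful base fires with the positives
        assert theta[pos, 2] < 0.1  # inverted base almost never does


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(5)
    y = rng.integers(0, 2, size=80)
    y[:10], y[10:20] = 1, 0  # ensure both classes are populous
    fms = aligned_family_views(y, n_families=3, effect_size=1.3, seed_base=50)
    recipes = [
        BaseRecipe(LearnerSpec("naive_bayes"), "fam0",
                   tuple(fms["fam0"].feature_names)),
        BaseRecipe(LearnerSpec("knn", {"K": 3}), "fam1",
                   tuple(fms["fam1"].feature_names)),
        BaseRecipe(LearnerSpec("decision_tree"), "fam2",
                   tuple(fms["fam2"].feature_names)),
    ]
    model = fit_stacked(recipes, fms, y, mode="out_of_fold", seed=0)
    return model, fms, y, recipes


class TestStackedClassifier:
    def test_probabilities_normalized(self, fitted):
        model, fms, y, _ = fitted
        proba = model.predict_proba(fms)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert ((proba >= 0) & (proba <= 1)).all()

    def test_prediction_table_shape(self, fitted):
        model, fms, y, _ = fitted
        table = predict_stacked(model, fms)
        assert list(table.columns) == ["id", "probability", "label"]
        assert len(table) == len(y)

    def test_base_order_permutation_symmetry(self, fitted):
        model, fms, y, recipes = fitted
        permuted = fit_stacked(recipes[::-1], fms, y, mode="out_of_fold", seed=0)
        np.testing.assert_allclose(
            model.predict_proba_pos(fms), permuted.predict_proba_pos(fms)
        )

    def test_missing_family_reported(self, fitted):
        model, fms, y, recipes = fitted
        partial = {k: v for k, v in fms.items() if k != "fam1"}
        with pytest.raises(ValueError, match="fam1"):
            fit_stacked(recipes, partial, y)

    def test_save_load_roundtrip(self, fitted, tmp_path):
        model, fms, y, _ = fitted
        save_stacked(model, tmp_path / "stacked")
        back = load_stacked(tmp_path / "stacked")
        np.testing.assert_allclose(
            back.predict_proba_pos(fms), model.predict_proba_pos(fms)
        )

    def test_resubstitution_mode_supported(self, fitted):
        _, fms, y, recipes = fitted
        model = fit_stacked(recipes, fms, y, mode="resubstitution", seed=0)
        assert model.training_meta_.shape == (len(y), 3)

    def test_unknown_mode_rejected(self, fitted):
        _, fms, y, recipes = fitted
        with pytest.raises(ValueError, match="meta_feature_mode"):
            fit_stacked(recipes, fms, y, mode="bootstrap")


def test_stack_tracks_best_base_on_diverse_weak_bases():
    """With diverse individually-weak bases, the stack should not fall more
    than one accuracy point behind the best single base in CV."""
    rng = np.random.default_rng(9)
    n = 120
    y = np.r_[np.ones(60, int), np.zeros(60, int)][rng.permutation(n)]
    fms = aligned_family_views(y, n_families=4, effect_size=1.0,
                               p_informative=2, p_noise=4, seed_base=200)
    algs = ["naive_bayes", "knn", "decision_tree", "svm_rbf"]
    recipes = [
        BaseRecipe(LearnerSpec(a, {"K": 5} if a == "knn" else {}),
                   f"fam{i}", tuple(fms[f"fam{i}"].feature_names))
        for i, a in enumerate(algs)
    ]
    single_accs = [
        cross_validate(
            lambda r=r: LearnerRecipe(r.spec, list(r.subset)),
            fms[r.family], y, k=5, seed=0,
        ).report.acc
        for r in recipes
    ]
    stacked_acc = cross_validate(
        lambda: StackedDILIClassifier(base_recipes=recipes, seed=0, oof_folds=5),
        fms, y, k=5, seed=0,
    ).report.acc
    assert stacked_acc >= max(single_accs) - 1.0
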