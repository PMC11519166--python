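"""Boruta selection, RF training, abstention, proximity, embedding, importance."""

import numpy as np
import pandas as pd
import pytest

import t2dsub as t
from t2dsub.subtyper import encode_features


@pytest.fixture(scope="module")
def boruta_toy(cohort_default, kmeans_default):
    """5 informative clustering variables + 20 pure-noise candidates."""
    df = cohort_default.cohort.baseline()
    _, labels = kmeans_default
    rng = np.random.default_rng(42)
    n = 600
    toy = df[["id", "sex", *t.AHLQVIST_VARIABLES]].head(n).copy()
    noise_cols = [f"noise_{i:02d}" for i in range(20)]
    for c in noise_cols:
        toy[c] = rng.normal(size=n)
    return toy, labels, tuple(t.AHLQVIST_VARIABLES) + tuple(noise_cols)


class TestBoruta:
    def test_informative_confirmed_noise_rejected(self, boruta_toy):
        toy, labels, candidates = boruta_toy
        res = t.select_features_boruta(toy, labels, candidates=candidates,
                                       max_rounds=60, n_estimators=150, seed=1)
        assert set(t.AHLQVIST_VARIABLES) <= set(res.confirmed)
        noise = [c for c in candidates if c.startswith("noise_")]
        assert len(set(res.rejected) & set(noise)) >= 18
        assert not set(res.confirmed) & set(noise)

    def test_constant_candidate_rejected(self, boruta_toy):
        toy, labels, candidates = boruta_toy
        toy = toy.copy()
        toy["flatline"] = 1.0
        res = t.select_features_boruta(
            toy, labels, candidates=tuple(t.AHLQVIST_VARIABLES) + ("flatline",),
            max_rounds=40, n_estimators=100, seed=2)
        assert "flatline" in res.rejected

    def test_alpha_one_confirms_any_shadow_beater(self, boruta_toy):
        toy, labels, candidates = boruta_toy
        res = t.select_features_boruta(toy, labels, candidates=candidates,
                                       max_rounds=1, alpha=1.0,
                                       n_estimators=100, seed=3)
        hist = res.history
        beat_once = set(hist.loc[hist["hit"], "feature"])
        assert set(res.confirmed) == beat_once

    def test_unknown_candidate_is_error(self, boruta_toy):
        toy, labels, _ = boruta_toy
        with pytest.raises(ValueError, match="absent"):
            t.select_features_boruta(toy, labels, candidates=("nope",), seed=4)


class TestTuneAndTrain:
    def test_oob_accuracy_high_on_separable_cohort(self, cohort_clean,
                                                   kmeans_clean):
        df = cohort_clean.cohort.baseline()
        _, labels = kmeans_clean
        clf = t.tune_and_train(df, labels,
                               grid={"n_estimators": (200,),
                                     "max_features": ("sqrt",)}, seed=5)
        assert clf.notes["oob_accuracy"] >= 0.9

    def test_identical_seed_identical_record_and_predictions(self, cohort_clean,
                                                             kmeans_clean):
        df = cohort_clean.cohort.baseline()
        _, labels = kmeans_clean
        grid = {"n_estimators": (100,), "min_samples_leaf": (1, 5)}
        a = t.tune_and_train(df, labels, grid=grid, seed=6)
        b = t.tune_and_train(df, labels, grid=grid, seed=6)
        pd.testing.assert_frame_equal(a.tuning_record, b.tuning_record)
        pa = t.predict_with_abstention(a, df)
        pb = t.predict_with_abstention(b, df)
        pd.testing.assert_frame_equal(pa, pb)

    def test_single_stump_bounded_by_one_split_ceiling(self, cohort_clean,
                                                       kmeans_clean):
        df = cohort_clean.cohort.baseline()
        _, labels = kmeans_clean
        clf = t.tune_and_train(df, labels,
                               grid={"n_estimators": (1,),
                                     "max_leaf_nodes": (2,)}, seed=7)
        pred = clf.forest.predict(
            encode_features(df, clf.features).to_numpy())
        acc = (pred == labels.loc[df["id"]].to_numpy()).mean()
        shares = labels.value_counts(normalize=True)
        ceiling = shares.nlargest(2).sum()   # one split separates two groups
        assert acc <= ceiling + 1e-9

    def test_empty_grid_and_missing_class_rejected(self, cohort_clean,
                                                   kmeans_clean):
        df = cohort_clean.cohort.baseline()
        _, labels = kmeans_clean
        with pytest.raises(ValueError, match="grid"):
            t.tune_and_train(df, labels, grid={"n_estimators": ()}, seed=8)
        only_two = labels[labels.isin(["MARD", "MOD"])]
        sub = df[df["id"].isin(only_two.index)]
        with pytest.raises(ValueError, match="absent"):
            t.tune_and_train(sub, only_two, grid={"n_estimators": (10,)}, seed=8)


class TestAbstention:
    def test_probabilities_sum_to_one_and_tau_rule(self, classifier_default,
                                                   cohort_default):
        clf, _, test_ids = classifier_default
        df = cohort_default.cohort.baseline()
        pred = t.predict_with_abstention(clf, df[df["id"].isin(test_ids)])
        probs = pred[[f"p_{c}" for c in t.SUBTYPES]].to_numpy()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        undec = pred["label"] == t.UNDECIDABLE
        assert (pred.loc[undec, "max_prob"] < clf.tau).all()
        assert (pred.loc[~undec, "max_prob"] >= clf.tau).all()

    def test_unanimous_vote_is_decided(self, classifier_default, cohort_default):
        clf, train_ids, _ = classifier_default
        df = cohort_default.cohort.baseline()
        pred = t.predict_with_abstention(clf, df[df["id"].isin(train_ids)])
        unanimous = pred[pred["max_prob"] == 1.0]
        assert len(unanimous) > 0
        assert (unanimous["label"] != t.UNDECIDABLE).all()

    def test_exactly_tau_counts_as_decided(self, classifier_default,
                                           cohort_default):
        clf, _, _ = classifier_default
        df = cohort_default.cohort.baseline()
        pred = t.predict_with_abstention(clf, df)
        at_tau = pred[np.isclose(pred["max_prob"], clf.tau)]
        if len(at_tau):   # threshold is "less than", so equality decides
            assert (at_tau["label"] != t.UNDECIDABLE).all()

    def test_tau_zero_never_abstains(self, classifier_default, cohort_default):
        clf, _, _ = classifier_default
        df = cohort_default.cohort.baseline()
        pred = t.predict_with_abstention(clf, df, tau=0.0)
        assert (pred["label"] != t.UNDECIDABLE).all()
        probs = pred[[f"p_{c}" for c in t.SUBTYPES]].to_numpy()
        argmax = np.array(t.SUBTYPES)[probs.argmax(axis=1)]
        assert (pred["label"].to_numpy() == argmax).all()

    def test_raising_tau_shrinks_decided_set(self, classifier_default,
                                             cohort_default):
        clf, _, _ = classifier_default
        df = cohort_default.cohort.baseline()
        decided_prev = None
        for tau in (0.0, 0.4, 0.6, 0.8, 1.0):
            pred = t.predict_with_abstention(clf, df, tau=tau)
            decided = set(pred.loc[pred["label"] != t.UNDECIDABLE, "id"])
            if decided_prev is not None:
                assert decided <= decided_prev
            decided_prev = decided

    def test_missing_feature_named_in_error(self, classifier_default,
                                            cohort_default):
        clf, _, _ = classifier_default
        df = cohort_default.cohort.baseline().drop(columns=["homa2ir"])
        with pytest.raises(ValueError, match="homa2ir"):
            t.predict_with_abstention(clf, df)


class TestProximity:
    def test_matches_brute_force_leaf_comparison(self, classifier_default,
                                                 cohort_default):
        clf, _, _ = classifier_default
        df = cohort_default.cohort.baseline().head(20)
        P = t.proximity_matrix(clf, df)
        leaves = clf.forest.apply(encode_features(df, clf.features).to_numpy())
        # oracle: explicit double loop over recorded leaf ids
        for i in range(len(df)):
            for j in range(len(df)):
                assert P[i, j] == pytest.approx(
                    (leaves[i] == leaves[j]).mean())
        assert np.allclose(np.diag(P), 1.0)
        assert np.allclose(P, P.T)

    def test_duplicated_record_has_unit_proximity(self, classifier_default,
                                                  cohort_default):
        clf, _, _ = classifier_default
        row = cohort_default.cohort.baseline().head(1)
        pair = pd.concat([row, row], ignore_index=True)
        P = t.proximity_matrix(clf, pair)
        assert P[0, 1] == 1.0


class TestEmbedding:
    def test_two_blobs_separate_and_deterministic(self):
        n = 30
        P = np.zeros((n, n))
        P[:15, :15] = 1.0
        P[15:, 15:] = 1.0
        emb = t.embed_proximity(P, seed=3)
        from sklearn.metrics import silhouette_score
        assert silhouette_score(emb, [0] * 15 + [1] * 15) > 0.9
        emb2 = t.embed_proximity(P, seed=3)
        assert np.allclose(emb, emb2)

    def test_single_record_is_fine(self):
        assert t.embed_proximity(np.ones((1, 1)), seed=1).shape == (1, 2)

    def test_non_symmetric_rejected(self):
        P = np.eye(3)
        P[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            t.embed_proximity(P, seed=1)


class TestFeatureImportance:
    def test_noise_feature_has_null_importance(self, cohort_clean,
                                               kmeans_clean):
        df = cohort_clean.cohort.baseline().copy()
        rng = np.random.default_rng(11)
        df["noise"] = rng.normal(size=len(df))
        _, labels = kmeans_clean
        clf = t.tune_and_train(df, labels,
                               features=tuple(t.AHLQVIST_VARIABLES) + ("noise",),
                               grid={"n_estimators": (200,)}, seed=12)
        imp = t.feature_importance(clf, df, labels, repeats=5, seed=13)
        row = imp.set_index("feature").loc["noise"]
        z = row["importance"] / max(row["importance_sd"], 1e-12)
        assert abs(z) < 3

    def test_hba1c_leads_sidd_one_vs_rest(self, cohort_clean, kmeans_clean):
        df = cohort_clean.cohort.baseline()
        _, labels = kmeans_clean
        clf = t.tune_and_train(df, labels, features=t.AHLQVIST_VARIABLES,
                               grid={"n_estimators": (200,)}, seed=14)
        imp = t.feature_importance(clf, df, labels, repeats=5, seed=15,
                                   per_class=True)
        ranked = imp.set_index("feature")["importance_SIDD"].sort_values(
            ascending=False)
        assert ranked.index[0] == "hba1c_ifcc"

    def test_duplicated_feature_splits_impurity_credit(self, cohort_clean,
                                                       kmeans_clean):
        df = cohort_clean.cohort.baseline().copy()
        df["hba1c_twin"] = df["hba1c_ifcc"]
        _, labels = kmeans_clean
        base = t.tune_and_train(df, labels, features=t.AHLQVIST_VARIABLES,
                                grid={"n_estimators": (300,)}, seed=16)
        dup = t.tune_and_train(
            df, labels, features=tuple(t.AHLQVIST_VARIABLES) + ("hba1c_twin",),
            grid={"n_estimators": (300,)}, seed=16)
        base_imp = dict(zip(base.features, base.forest.feature_importances_))
        dup_imp = dict(zip(dup.features, dup.forest.feature_importances_))
        pair_sum = dup_imp["hba1c_ifcc"] + dup_imp["hba1c_twin"]
        assert pair_sum == pytest.approx(base_imp["hba1c_ifcc"], rel=0.2)
        # credit genuinely shared: each twin alone carries less than the original
        assert dup_imp["hba1c_ifcc"] < base_imp["hba1c_ifcc"]

    def test_repeats_below_one_rejected(self, classifier_default,
                                        cohort_default, kmeans_default):
        clf, _, _ = classifier_default
        _, labels = kmeans_default
        with pytest.raises(ValueError):
            t.feature_importance(clf, cohort_default.cohort.baseline(), labels,
                                 repeats=0)


def test_decided_subset_accuracy_beats_overall(classifier_default,
                                               cohort_default, kmeans_default):
    """Abstention helps: accuracy among decided >= accuracy forcing everyone."""
    clf, _, test_ids = classifier_default
    df = cohort_default.cohort.baseline()
    _, labels = kmeans_default
    pred = t.predict_with_abstention(clf, df[df["id"].isin(test_ids)])
    decided = t.classification_metrics(labels, pred, exclude_undecidable=True)
    forced = t.classification_metrics(labels,
                                      t.predict_with_abstention(
                                          clf, df[df["id"].isin(test_ids)],
                                          tau=0.0),
                                      exclude_undecidable=True)
    assert decided.accuracy >= forced.accuracy


def test_end_to_end_macro_f1_on_clean_cohort(cohort_clean, kmeans_clean):
    """Train on 70%, test on 30%: macro-F1 >= 0.85 with no boundary blends."""
    df = cohort_clean.cohort.baseline()
    _, labels = kmeans_clean
    train_ids, test_ids = t.train_test_split_ids(df["id"].to_numpy(), 0.7,
                                                 seed=17)
    clf = t.tune_and_train(df[df["id"].isin(train_ids)], labels,
                           grid={"n_estimators": (300,),
                                 "max_features": ("sqrt",)}, seed=18)
    pred = t.predict_with_abstention(clf, df[df["id"].isin(test_ids)])
    rep = t.classification_metrics(labels, pred, exclude_undecidable=True)
    assert rep.macro_f1 >= 0.85
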