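"""Metrics arithmetic, migration/consistency, Kaplan-Meier and Cox."""

import numpy as np
import pandas as pd
import pytest

import t2dsub as t


def _pred_frame(ids, labels, probs=None):
    """Build a prediction frame like predict_with_abstention returns."""
    out = pd.DataFrame({"id": ids, "label": labels})
    if probs is None:
        probs = np.zeros((len(ids), 4))
        for i, lab in enumerate(labels):
            if lab in t.SUBTYPES:
                probs[i, t.SUBTYPES.index(lab)] = 1.0
            else:
                probs[i] = 0.25
    for j, c in enumerate(t.SUBTYPES):
        out[f"p_{c}"] = probs[:, j]
    out["max_prob"] = probs.max(axis=1)
    return out


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        ids = [f"i{k}" for k in range(40)]
        labels = [t.SUBTYPES[k % 4] for k in range(40)]
        truth = pd.Series(labels, index=ids)
        rep = t.classification_metrics(truth, _pred_frame(ids, labels))
        assert rep.accuracy == 1.0
        assert (rep.per_class["f1"] == 1.0).all()
        assert (rep.per_class["auc"] == 1.0).all()
        assert rep.macro_f1 == 1.0

    def test_two_class_confusion_hand_arithmetic(self):
        # confusion [[8,2],[1,9]] between MARD (class 0) and MOD (class 1)
        truth_labels = ["MARD"] * 10 + ["MOD"] * 10
        pred_labels = (["MARD"] * 8 + ["MOD"] * 2) + (["MARD"] * 1 + ["MOD"] * 9)
        ids = [f"i{k}" for k in range(20)]
        truth = pd.Series(truth_labels, index=ids)
        rep = t.classification_metrics(truth, _pred_frame(ids, pred_labels))
        # oracle: hand-computed confusion-matrix identities
        assert rep.per_class.loc["MARD", "recall"] == pytest.approx(8 / 10)
        assert rep.per_class.loc["MARD", "precision"] == pytest.approx(8 / 9)
        assert rep.per_class.loc["MOD", "recall"] == pytest.approx(9 / 10)
        assert rep.per_class.loc["MOD", "precision"] == pytest.approx(9 / 11)
        f1 = 2 * (8 / 9) * 0.8 / ((8 / 9) + 0.8)
        assert rep.per_class.loc["MARD", "f1"] == pytest.approx(f1)
        assert rep.accuracy == pytest.approx(17 / 20)
        assert rep.confusion.loc["MARD", "MOD"] == 2

    def test_micro_accuracy_equals_trace_over_total(self, classifier_default,
                                                    cohort_default,
                                                    kmeans_default):
        clf, _, test_ids = classifier_default
        df = cohort_default.cohort.baseline()
        _, labels = kmeans_default
        pred = t.predict_with_abstention(clf, df[df["id"].isin(test_ids)])
        rep = t.classification_metrics(labels, pred)
        assert rep.accuracy == pytest.approx(
            np.trace(rep.confusion.to_numpy()) / rep.confusion.to_numpy().sum())
        assert rep.n_decided + int(
            round(rep.undecidable_fraction * rep.n_total)) == rep.n_total

    def test_label_free_probabilities_give_null_auc(self):
        rng = np.random.default_rng(31)
        n = 2000
        ids = [f"i{k}" for k in range(n)]
        truth = pd.Series(rng.choice(t.SUBTYPES, size=n), index=ids)
        probs = rng.dirichlet(np.ones(4), size=n)
        labels = np.array(t.SUBTYPES)[probs.argmax(axis=1)]
        rep = t.classification_metrics(truth, _pred_frame(ids, labels, probs),
                                       exclude_undecidable=False)
        assert np.allclose(rep.per_class["auc"], 0.5, atol=0.05)

    def test_undecidable_excluded_by_default_but_reported(self):
        ids = [f"i{k}" for k in range(10)]
        labels = ["SIDD"] * 6 + [t.UNDECIDABLE] * 4
        truth = pd.Series(["SIDD"] * 10, index=ids)
        rep = t.classification_metrics(truth, _pred_frame(ids, labels))
        assert rep.accuracy == 1.0
        assert rep.undecidable_fraction == pytest.approx(0.4)
        rep_all = t.classification_metrics(truth, _pred_frame(ids, labels),
                                           exclude_undecidable=False)
        assert rep_all.accuracy == pytest.approx(0.6)

    def test_roc_points_span_the_unit_square(self):
        rng = np.random.default_rng(40)
        ids = [f"i{k}" for k in range(100)]
        truth = pd.Series(rng.choice(t.SUBTYPES, size=100), index=ids)
        probs = rng.dirichlet(np.ones(4), size=100)
        labels = np.array(t.SUBTYPES)[probs.argmax(axis=1)]
        pts = t.roc_points(truth, _pred_frame(ids, labels, probs))
        assert set(pts["subtype"]) == set(t.SUBTYPES)
        for col in ("fpr", "tpr"):
            assert pts[col].between(0, 1).all()
            g = pts.groupby("subtype")[col]
            assert (g.first() == 0).all() and (g.last() == 1).all()

    def test_empty_decided_subset_is_error(self):
        ids = ["a", "b"]
        truth = pd.Series(["SIDD", "MOD"], index=ids)
        pred = _pred_frame(ids, [t.UNDECIDABLE, t.UNDECIDABLE])
        with pytest.raises(ValueError, match="decided"):
            t.classification_metrics(truth, pred)


class TestConsistency:
    def test_identical_labels_are_fully_consistent(self):
        ids = [f"i{k}" for k in range(20)]
        labels = pd.Series([t.SUBTYPES[k % 4] for k in range(20)], index=ids)
        rep = t.consistency_over_time(labels, labels.copy())
        assert (rep.per_subtype == 100.0).all()
        assert rep.mean_consistency == 100.0

    def test_hand_counted_toy_migration(self):
        # 10 baseline SIDD of whom 7 stay SIDD, 2 -> MARD, 1 -> MOD
        ids = [f"i{k}" for k in range(16)]
        t0 = pd.Series(["SIDD"] * 10 + ["MARD"] * 6, index=ids)
        t5 = pd.Series(["SIDD"] * 7 + ["MARD", "MARD", "MOD"] + ["MARD"] * 6,
                       index=ids)
        rep = t.consistency_over_time(t0, t5)
        assert rep.per_subtype["SIDD"] == pytest.approx(70.0)
        assert rep.per_subtype["MARD"] == pytest.approx(100.0)
        assert rep.migration.loc["SIDD", "MARD"] == 2
        assert rep.mean_consistency == pytest.approx(
            (70.0 * 10 + 100.0 * 6) / 16)

    def test_row_sums_conserve_baseline_counts(self):
        rng = np.random.default_rng(32)
        ids = [f"i{k}" for k in range(200)]
        space = list(t.SUBTYPES) + [t.UNDECIDABLE]
        t0 = pd.Series(rng.choice(space, size=200), index=ids)
        t5 = pd.Series(rng.choice(space, size=200), index=ids)
        rep = t.consistency_over_time(t0, t5)
        counts = t0.value_counts()
        for s in space:
            assert rep.migration.loc[s].sum() == counts.get(s, 0)
        assert rep.migration.to_numpy().sum() == 200

    def test_complete_relabelling_to_one_class(self):
        ids = [f"i{k}" for k in range(12)]
        t0 = pd.Series(["SIDD"] * 4 + ["SIRD"] * 4 + ["MARD"] * 4, index=ids)
        t5 = pd.Series(["MARD"] * 12, index=ids)
        rep = t.consistency_over_time(t0, t5)
        assert rep.per_subtype["SIDD"] == 0.0
        assert rep.per_subtype["MARD"] == 100.0
        off_diag = rep.migration.to_numpy().sum() - np.trace(
            rep.migration.to_numpy())
        assert off_diag == 8

    def test_undecidable_tracked_separately(self):
        ids = [f"i{k}" for k in range(8)]
        t0 = pd.Series(["SIDD"] * 4 + [t.UNDECIDABLE] * 4, index=ids)
        t5 = pd.Series(["SIDD", "SIDD", "SIDD", t.UNDECIDABLE,
                        t.UNDECIDABLE, t.UNDECIDABLE, "MOD", "MARD"], index=ids)
        rep = t.consistency_over_time(t0, t5)
        # the SIDD who became undecidable is excluded from the denominator
        assert rep.per_subtype["SIDD"] == pytest.approx(100.0)
        assert rep.undecidable_consistency == pytest.approx(50.0)

    def test_disjoint_ids_rejected(self):
        a = pd.Series(["SIDD"], index=["x"])
        b = pd.Series(["SIDD"], index=["y"])
        with pytest.raises(ValueError, match="disjoint"):
            t.consistency_over_time(a, b)

    def test_sankey_export_conserves_flow(self, tmp_path):
        ids = [f"i{k}" for k in range(30)]
        rng = np.random.default_rng(33)
        t0 = pd.Series(rng.choice(t.SUBTYPES, size=30), index=ids)
        t5 = pd.Series(rng.choice(t.SUBTYPES, size=30), index=ids)
        rep = t.consistency_over_time(t0, t5)
        payload = rep.sankey()
        assert sum(l["value"] for l in payload["links"]) == 30
        rep.sankey_json(tmp_path / "sankey.json")
        import json
        assert json.loads((tmp_path / "sankey.json").read_text()) == payload


def _toy_events(times, statuses, subtype="MARD"):
    ids = [f"i{k}" for k in range(len(times))]
    events = pd.DataFrame({"id": ids, "event_type": "retinopathy",
                           "time": times, "status": statuses})
    baseline = pd.DataFrame({"id": ids, "age": 60.0, "sex": "male",
                             "subtype": subtype})
    return events, baseline


class TestSurvival:
    def test_km_flat_at_one_without_events(self):
        events, baseline = _toy_events([5.0] * 6, ["censored"] * 6)
        res = t.survival_by_subtype(events, baseline)
        km = res.km["retinopathy"]["MARD"]
        assert (km["survival"] == 1.0).all()
        assert res.cox["retinopathy"] is None
        assert "skipped" in res.flags["retinopathy"]

    def test_km_matches_hand_product_limit_on_six_observations(self):
        # times 1..6, events at 1,2,4,6; censored at 3,5
        events, baseline = _toy_events(
            [1, 2, 3, 4, 5, 6],
            ["occurred", "occurred", "censored", "occurred", "censored",
             "occurred"])
        res = t.survival_by_subtype(events, baseline)
        km = res.km["retinopathy"]["MARD"].set_index("time")["survival"]
        # oracle: hand-computed product-limit
        assert km.loc[1.0] == pytest.approx(5 / 6)
        assert km.loc[2.0] == pytest.approx(5 / 6 * 4 / 5)      # = 2/3
        assert km.loc[4.0] == pytest.approx(2 / 3 * 2 / 3)      # = 4/9
        assert km.loc[6.0] == pytest.approx(0.0)

    def test_km_monotone_and_bounded(self, spec):
        lab = t.generate_cohort(spec, 800, seed=34)
        events = t.generate_events(lab, spec, horizon=12.0, seed=35)
        baseline = lab.cohort.baseline()[["id", "age", "sex"]].copy()
        baseline["subtype"] = lab.true_subtype.loc[baseline["id"]].to_numpy()
        baseline = baseline[baseline["subtype"] != t.BLENDED]
        res = t.survival_by_subtype(events[events["id"].isin(baseline["id"])],
                                    baseline)
        for ev_tables in res.km.values():
            for tbl in ev_tables.values():
                surv = tbl["survival"].to_numpy()
                assert (np.diff(surv) <= 1e-12).all()
                assert ((0 <= surv) & (surv <= 1)).all()
                assert (tbl["ci_lower"] <= tbl["survival"] + 1e-12).all()
                assert (tbl["survival"] <= tbl["ci_upper"] + 1e-12).all()

    def test_cox_recovers_generating_hazard_ratio(self):
        """Parameter recovery: HR(SIDD vs MARD) = 2.08 inside its 95% CI."""
        spec = t.GeneratorSpec.default()
        lab = t.generate_cohort(spec, 5000, seed=36)
        events = t.generate_events(lab, spec, horizon=12.0, seed=37)
        baseline = lab.cohort.baseline()[["id", "age", "sex"]].copy()
        baseline["subtype"] = lab.true_subtype.loc[baseline["id"]].to_numpy()
        baseline = baseline[baseline["subtype"] != t.BLENDED]
        res = t.survival_by_subtype(
            events[events["id"].isin(baseline["id"])], baseline)
        ret = res.cox["retinopathy"].set_index("subtype")
        assert ret.loc["SIDD", "ci_lower"] <= 2.08 <= ret.loc["SIDD", "ci_upper"]
        ckd = res.cox["ckd"].set_index("subtype")
        assert ckd.loc["SIRD", "ci_lower"] <= 1.58 <= ckd.loc["SIRD", "ci_upper"]

    def test_logrank_p_uniform_under_null(self):
        """Two groups with identical hazard: log-rank p is uniform (KS, 1%)."""
        from lifelines.statistics import logrank_test
        from scipy.stats import kstest
        rng = np.random.default_rng(38)
        pvals = []
        for _ in range(40):
            t1 = rng.exponential(10.0, size=120)
            t2 = rng.exponential(10.0, size=120)
            e1 = t1 <= 12.0
            e2 = t2 <= 12.0
            res = logrank_test(np.minimum(t1, 12.0), np.minimum(t2, 12.0),
                               event_observed_A=e1, event_observed_B=e2)
            pvals.append(res.p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01
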