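"""Shared fixtures: small synthetic cohorts and fitted models.

Everything is generated programmatically with fixed seeds; session scope
keeps the expensive fits (forest training, imputation) to one run each.
"""

from __future__ import annotations

import pytest

import t2dsub as t


@pytest.fixture()
def spec():
    """Fresh default generator spec (function-scoped: specs are mutable)."""
    return t.GeneratorSpec.default()


@pytest.fixture(scope="session")
def cohort_default():
    """n=2000 baseline cohort under the shipped study conditions (14% blend)."""
    return t.generate_cohort(t.GeneratorSpec.default(), 2000, seed=101)


@pytest.fixture(scope="session")
def cohort_clean():
    """n=2000 cohort with boundary_blend=0 (linearly separable four clusters)."""
    spec = t.GeneratorSpec.default()
    spec.boundary_blend = 0.0
    return t.generate_cohort(spec, 2000, seed=102)


@pytest.fixture(scope="session")
def kmeans_default(cohort_default):
    df = cohort_default.cohort.baseline()
    model, labels = t.fit_kmeans_by_sex(df, seed=103, restarts=100)
    return model, labels


@pytest.fixture(scope="session")
def kmeans_clean(cohort_clean):
    df = cohort_clean.cohort.baseline()
    model, labels = t.fit_kmeans_by_sex(df, seed=103, restarts=100)
    return model, labels


@pytest.fixture(scope="session")
def classifier_default(cohort_default, kmeans_default):
    """RF subtyper trained on the 70% split of the default cohort."""
    df = cohort_default.cohort.baseline()
    _, labels = kmeans_default
    train_ids, test_ids = t.train_test_split_ids(df["id"].to_numpy(), 0.7, seed=104)
    clf = t.tune_and_train(
        df[df["id"].isin(train_ids)], labels,
        grid={"max_features": ("sqrt",), "n_estimators": (300,),
              "min_samples_leaf": (1, 5)},
        seed=104)
    return clf, train_ids, test_ids


@pytest.fixture(scope="session")
def mask_recover():
    """Insulin block masked for 50% of a n=6000 cohort, chained-RF recovered.

    Returns the per-variable quality report (R^2, |diff| summaries) against
    the pre-masking truth.
    """
    spec = t.GeneratorSpec.default()
    lab = t.generate_cohort(spec, 6000, seed=105)
    truth = lab.cohort.baseline()[["cpeptide", "homa2b", "homa2ir"]]
    spec_m = t.GeneratorSpec.default()
    spec_m.insulin_block_fraction = 0.5
    masked = t.inject_missingness(lab.cohort, spec_m, seed=106).df
    observed = masked.dropna(subset=["cpeptide", "homa2b", "homa2ir"])
    imputer = t.fit_imputer(observed, seed=107)
    filled, report = t.impute(imputer, masked, truth=truth)
    return report.set_index("variable")
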