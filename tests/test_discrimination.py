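"""Cross-validated discrimination protocol: folds, selection, PCA, metrics."""

import numpy as np
import pandas as pd
import pytest

from eegmci.discrimination import (
    CLASSIFIER_NAMES,
    apply_transform,
    auc_rank,
    confusion_metrics,
    fit_transform,
    make_classifier,
    run_cv,
    select_features,
    subject_kfold,
    train_and_predict,
)
from eegmci.features import FeatureMatrix, assemble_features
from eegmci.stats import cohort_statistics, group_difference_map, top_connections
from .oracles import auc_oracle


def make_matrix(n_pos=12, n_neg=15, epochs_per_subject=4, n_features=30,
                effect=0.0, seed=0, n_informative=10):
    """Random feature matrix with subject structure and an optional
    group mean shift on the first ``n_informative`` features."""
    rng = np.random.default_rng(seed)
    rows, keys, labels = [], [], []
    for g, n_subj in (("PMCI", n_pos), ("SMCI", n_neg)):
        for s in range(n_subj):
            sid = f"{g}{s:03d}"
            subject_effect = rng.normal(0, 0.5, n_features)  # within-subject clustering
            for e in range(epochs_per_subject):
                x = rng.standard_normal(n_features) + subject_effect
                if g == "PMCI":
                    x[:n_informative] += effect
                rows.append(x)
                keys.append((sid, e))
                labels.append(g)
    index = pd.MultiIndex.from_tuples(keys, names=["subject_id", "epoch_index"])
    values = pd.DataFrame(rows, index=index,
                          columns=[f"f{i}" for i in range(n_features)])
    return FeatureMatrix(values=values, labels=pd.Series(labels, index=index))


# -------------------------------------------------------------------- folding

def test_fold_sizes_for_default_cohort():
    m = make_matrix(n_pos=42, n_neg=65, epochs_per_subject=1, n_features=3)
    plan = subject_kfold(m, k=10, seed=0)
    for _, test in plan.folds:
        n_pos = sum(s.startswith("PMCI") for s in test)
        n_neg = sum(s.startswith("SMCI") for s in test)
        assert n_pos in (4, 5) and n_neg in (6, 7)


def test_folds_partition_subjects():
    m = make_matrix()
    plan = subject_kfold(m, k=5, seed=3)
    seen = [s for _, test in plan.folds for s in test]
    assert sorted(seen) == sorted(set(m.subject_ids))
    assert subject_kfold(m, k=5, seed=3).folds == plan.folds  # deterministic


def test_too_few_subjects_per_class():
    m = make_matrix(n_pos=3, n_neg=12)
    with pytest.raises(ValueError, match="at least k"):
        subject_kfold(m, k=5)


# ------------------------------------------------------------------ selection

def test_strong_effect_always_retained():
    retained = 0
    for rep in range(20):
        m = make_matrix(n_pos=100, n_neg=150, epochs_per_subject=1,
                        n_features=5, effect=2.0, n_informative=1, seed=rep)
        mask = select_features(m.values, m.y)
        retained += bool(mask["f0"])
    assert retained == 20


@pytest.mark.filterwarnings("ignore:Precision loss")
def test_constant_feature_dropped():
    m = make_matrix(effect=3.0)
    m.values["f0"] = 7.7
    mask = select_features(m.values, m.y)
    assert not mask["f0"]


def test_single_class_rejected():
    m = make_matrix(n_pos=5, n_neg=5)
    with pytest.raises(ValueError, match="both classes"):
        select_features(m.values, np.ones(len(m), dtype=int))


# ------------------------------------------------------------------ transform

def test_k95_on_rank2_data(rng):
    latent = rng.standard_normal((200, 2))
    mixing = rng.standard_normal((2, 10))
    values = pd.DataFrame(
        latent @ mixing,
        index=pd.MultiIndex.from_tuples(
            [(f"S{i}", 0) for i in range(200)], names=["subject_id", "epoch_index"]
        ),
        columns=[f"f{i}" for i in range(10)],
    )
    mask = pd.Series(True, index=values.columns)
    model, reduced = fit_transform(values, mask)
    assert model.k95 == 2
    assert reduced.shape == (200, 2)


def test_k95_on_isotropic_data(rng):
    values = pd.DataFrame(
        rng.standard_normal((3000, 10)),
        index=pd.MultiIndex.from_tuples(
            [(f"S{i}", 0) for i in range(3000)], names=["subject_id", "epoch_index"]
        ),
        columns=[f"f{i}" for i in range(10)],
    )
    model, _ = fit_transform(values, pd.Series(True, index=values.columns))
    assert model.k95 == 10


def test_training_projection_centered():
    m = make_matrix(effect=1.0, seed=5)
    mask = select_features(m.values, m.y, alpha=0.5)
    model, reduced = fit_transform(m.values, mask)
    assert np.abs(reduced.mean(axis=0)).max() < 1e-8


def test_empty_mask_raises():
    m = make_matrix()
    mask = pd.Series(False, index=m.values.columns)
    with pytest.raises(ValueError, match="relax alpha"):
        fit_transform(m.values, mask)


def test_transform_is_a_function_of_training_rows_only():
    """Corrupting held-out rows must not change the fitted transform."""
    m = make_matrix(effect=1.0, seed=9)
    plan = subject_kfold(m, k=5, seed=9)
    train_subjects, test_subjects = plan.folds[0]
    train_mask = m.rows_for(train_subjects)
    train_values = m.values[train_mask]
    y_train = m.y[train_mask]

    mask1 = select_features(train_values, y_train)
    model1, _ = fit_transform(train_values, mask1)

    corrupted = m.values.copy()
    corrupted.loc[~train_mask, :] = 1e6  # garbage in the test rows
    mask2 = select_features(corrupted[train_mask], y_train)
    model2, _ = fit_transform(corrupted[train_mask], mask2)

    assert mask1.equals(mask2)
    np.testing.assert_array_equal(model1.components, model2.components)
    np.testing.assert_array_equal(model1.means, model2.means)


# ---------------------------------------------------------------- classifiers

def test_all_classifiers_solve_separable_blobs(rng):
    x_train = np.vstack([rng.normal(-5, 0.3, (40, 2)), rng.normal(5, 0.3, (40, 2))])
    y_train = np.r_[np.zeros(40, int), np.ones(40, int)]
    x_test = np.vstack([rng.normal(-5, 0.3, (10, 2)), rng.normal(5, 0.3, (10, 2))])
    y_test = np.r_[np.zeros(10, int), np.ones(10, int)]
    for name in CLASSIFIER_NAMES:
        scores, hard = train_and_predict(name, x_train, y_train, x_test)
        assert np.array_equal(hard, y_test), name
        assert auc_rank(scores, y_test) == 1.0, name


def test_unknown_classifier_lists_names():
    with pytest.raises(ValueError, match="SVM"):
        make_classifier("MLP")


def test_permuted_labels_give_chance_accuracy():
    m = make_matrix(n_pos=10, n_neg=15, epochs_per_subject=3,
                    n_features=20, effect=2.0, seed=2)
    rng = np.random.default_rng(0)
    subjects = sorted(set(m.subject_ids))
    permuted_groups = dict(zip(subjects, rng.permutation(
        [m.labels[m.subject_ids == s].iloc[0] for s in subjects]
    )))
    labels = pd.Series([permuted_groups[s] for s in m.subject_ids],
                       index=m.values.index)
    shuffled = FeatureMatrix(values=m.values, labels=labels)
    result = run_cv(shuffled, classifiers=("LDA",), alpha=0.5, k=5, seed=0)
    majority = max(np.mean(shuffled.y), 1 - np.mean(shuffled.y))
    acc = result.reports["LDA"].per_fold["ACC"]
    assert abs(acc.mean() - majority) <= 3 * acc.std()


# -------------------------------------------------------------------- metrics

def test_confusion_metrics_worked_example():
    pred = np.r_[np.ones(40), np.zeros(2), np.ones(5), np.zeros(60)].astype(int)
    truth = np.r_[np.ones(42), np.zeros(65)].astype(int)
    m = confusion_metrics(pred, truth)
    assert (m["TP"], m["FN"], m["FP"], m["TN"]) == (40, 2, 5, 60)
    assert m["ACC"] == pytest.approx(100 / 107)
    assert m["SEN"] == pytest.approx(40 / 42)
    assert m["SPE"] == pytest.approx(60 / 65)
    assert m["PPV"] == pytest.approx(40 / 45)
    assert m["F1"] == pytest.approx(80 / 87)
    # identities
    assert m["ACC"] * 107 == pytest.approx(m["TP"] + m["TN"])
    assert m["F1"] == pytest.approx(
        2 / (1 / m["PPV"] + 1 / m["SEN"])
    )


def test_confusion_metrics_degenerate_cases():
    perfect = confusion_metrics(np.array([1, 1, 0]), np.array([1, 1, 0]))
    assert all(perfect[k] == 1.0 for k in ("ACC", "SEN", "SPE", "PPV", "F1"))
    all_neg = confusion_metrics(np.zeros(5, int), np.array([1, 1, 0, 0, 0]))
    assert all_neg["SEN"] == 0.0
    assert np.isnan(all_neg["PPV"])


def test_auc_closed_forms():
    assert auc_rank([0.9, 0.8, 0.7, 0.6], [1, 1, 0, 0]) == 1.0
    assert auc_rank([0.9, 0.6, 0.8, 0.7], [1, 1, 0, 0]) == 0.5
    assert np.isnan(auc_rank([0.5, 0.6], [1, 1]))


@pytest.mark.parametrize("seed", range(10))
def test_auc_matches_pairwise_oracle_with_ties(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 60))
    scores = rng.integers(0, 8, n).astype(float)  # ties guaranteed
    labels = rng.integers(0, 2, n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    assert auc_rank(scores, labels) == pytest.approx(
        auc_oracle(scores, labels), abs=1e-12
    )


# --------------------------------------------------------------------- run_cv

def test_run_cv_recovers_strong_effect_and_reports_log():
    m = make_matrix(n_pos=12, n_neg=15, epochs_per_subject=4,
                    n_features=30, effect=1.5, seed=4)
    result = run_cv(m, classifiers=("KNN", "LDA"), k=5, seed=4)
    assert result.reports["KNN"].mean["AUC"] > 0.8
    for log, (_, test_subjects) in zip(result.fold_logs, None or
                                       subject_kfold(m, k=5, seed=4).folds):
        assert log["k95"] >= 1
        assert set(log["test_subjects"]) == set(test_subjects)


def test_run_cv_leakage_audit():
    m = make_matrix(seed=6)
    plan = subject_kfold(m, k=5, seed=6)
    for train_subjects, test_subjects in plan.folds:
        assert not (set(train_subjects) & set(test_subjects))
    train_union = set()
    for train_subjects, test_subjects in plan.folds:
        train_union |= set(test_subjects)
    assert train_union == set(m.subject_ids)


# ------------------------------------------------------- assembly and mapping

def test_assemble_rejects_mismatched_keys():
    m = make_matrix(n_pos=2, n_neg=2, epochs_per_subject=2, n_features=4)
    t1 = m.values.iloc[:, :2]
    t2 = m.values.iloc[1:, 2:]  # one key missing
    with pytest.raises(ValueError, match="keys differ"):
        assemble_features([t1, t2], {s: "SMCI" for s in set(m.subject_ids)})


def test_assemble_drops_high_missingness_rows():
    m = make_matrix(n_pos=2, n_neg=2, epochs_per_subject=2, n_features=10)
    values = m.values.copy()
    values.iloc[0, :5] = np.nan  # 50% missing in row 0
    groups = {s: ("PMCI" if s.startswith("PMCI") else "SMCI")
              for s in set(m.subject_ids)}
    fm = assemble_features([values], groups)
    assert len(fm) == len(values) - 1


def test_cohort_statistics_identical_groups():
    table = cohort_statistics(
        continuous={"age": (70.0, 5.0, 30, 70.0, 5.0, 30)},
        categorical={"sex": [[15, 15], [15, 15]]},
    )
    assert table.loc["age", "statistic"] == pytest.approx(0.0)
    assert table.loc["sex", "statistic"] == pytest.approx(0.0)


def test_group_difference_map_finds_injected_feature():
    m = make_matrix(n_pos=25, n_neg=25, epochs_per_subject=2,
                    n_features=40, effect=1.5, n_informative=1, seed=8)
    pmap = group_difference_map(m)
    assert pmap.index[0] == "f0"
    top = top_connections(pmap, n=15)
    assert len(top) == 15
    assert (top["p"].diff().dropna() >= 0).all()
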