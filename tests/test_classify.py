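"""Tomek links, resampling, linear-margin training, evaluation and markers."""

import numpy as np
import pytest

from sdmstylo.classify import (
    EvalReport,
    LinearModel,
    ResamplingStrategy,
    cross_validate,
    evaluate,
    resample,
    stratified_folds,
    tomek_links,
    top_markers,
    train,
)
from sdmstylo.features import FeatureMatrix, normalize


def matrix_of(values, labels, ids=None):
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(
        sample_ids=ids or [f"s{i:02d}" for i in range(len(labels))],
        feature_names=[f"f{j}" for j in range(values.shape[1])],
        values=values,
        labels=list(labels),
    )


def two_clusters(rng, n_a=10, n_b=10, sep=4.0, dim=3):
    a = rng.normal(0.0, 0.5, size=(n_a, dim))
    b = rng.normal(sep, 0.5, size=(n_b, dim))
    return matrix_of(np.vstack([a, b]), ["ADHD"] * n_a + ["control"] * n_b)


# ------------------------------------------------------------- Tomek links
def test_tomek_well_separated_clusters_have_no_links():
    rng = np.random.default_rng(0)
    assert tomek_links(two_clusters(rng)) == set()


def test_tomek_boundary_pair_found():
    m = matrix_of([[0.0], [1.0], [1.1], [5.0]], ["control", "control", "ADHD", "ADHD"])
    assert tomek_links(m) == {("s01", "s02")}


def brute_force_tomek(m):
    X, labels, ids = m.values, m.labels, m.sample_ids
    n = len(ids)
    links = set()
    for i in range(n):
        for j in range(n):
            if i == j or labels[i] == labels[j]:
                continue
            di = sorted(
                (np.linalg.norm(X[i] - X[k]), ids[k]) for k in range(n) if k != i
            )
            dj = sorted(
                (np.linalg.norm(X[j] - X[k]), ids[k]) for k in range(n) if k != j
            )
            if di[0][1] == ids[j] and dj[0][1] == ids[i]:
                links.add(tuple(sorted((ids[i], ids[j]))))
    return links


def test_tomek_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(1)
    for _ in range(5):
        n = int(rng.integers(10, 40))
        values = rng.normal(size=(n, 2))
        labels = ["ADHD" if rng.random() < 0.4 else "control" for _ in range(n)]
        if len(set(labels)) < 2:
            labels[0] = "ADHD" if labels[0] == "control" else "control"
        m = matrix_of(values, labels)
        assert tomek_links(m) == brute_force_tomek(m)


# --------------------------------------------------------------- resampling
def test_resample_size_arithmetic():
    rng = np.random.default_rng(2)
    m = matrix_of(rng.normal(size=(13, 2)), ["control"] * 9 + ["ADHD"] * 4)
    under = resample(m, ResamplingStrategy("undersample_majority", seed=0))
    assert sorted(under.labels).count("control") == 4 and len(under.labels) == 8
    over = resample(m, ResamplingStrategy("oversample_minority", seed=0))
    assert sorted(over.labels).count("ADHD") == 9 and len(over.labels) == 18
    assert resample(m, ResamplingStrategy("none")) is m


def test_tomek_resampling_removes_only_majority_members():
    m = matrix_of(
        [[0.0], [1.0], [1.1], [5.0], [6.0]],
        ["control", "control", "ADHD", "ADHD", "control"],
    )
    links = tomek_links(m)
    assert links == {("s01", "s02"), ("s03", "s04")}
    cleaned = resample(m, ResamplingStrategy("tomek_links"))
    removed = set(m.sample_ids) - set(cleaned.sample_ids)
    label_of = dict(zip(m.sample_ids, m.labels))
    # only the majority-class ("control") member of each link is dropped
    assert removed == {a if label_of[a] == "control" else b for a, b in links}
    assert all(label_of[s] == "control" for s in removed)
    assert {s for s in m.sample_ids if label_of[s] == "ADHD"} <= set(cleaned.sample_ids)


def test_resample_balanced_classes_is_identity():
    """With equal class counts there is no majority: under/oversampling
    must leave the matrix unchanged (never collapse it to one class)."""
    rng = np.random.default_rng(12)
    m = matrix_of(rng.normal(size=(12, 3)), ["ADHD"] * 6 + ["control"] * 6)
    for kind in ("undersample_majority", "oversample_minority"):
        out = resample(m, ResamplingStrategy(kind, seed=0))
        assert sorted(out.labels) == sorted(m.labels)


def test_resample_single_class_is_rejected():
    m = matrix_of([[0.0], [1.0]], ["ADHD", "ADHD"])
    with pytest.raises(ValueError):
        resample(m, ResamplingStrategy("undersample_majority"))


# ----------------------------------------------------------------- training
def test_separable_clusters_train_to_perfect_accuracy():
    rng = np.random.default_rng(3)
    m = normalize(two_clusters(rng))
    model = train(m, seed=0)
    report = evaluate(model, m)
    assert report.accuracy == 1.0


def test_label_flip_negates_weights():
    rng = np.random.default_rng(4)
    m = normalize(two_clusters(rng))
    flipped = FeatureMatrix(
        sample_ids=list(m.sample_ids),
        feature_names=list(m.feature_names),
        values=m.values,
        labels=["control" if lab == "ADHD" else "ADHD" for lab in m.labels],
        normalization_state=m.normalization_state,
    )
    w1 = train(m, seed=0).weights
    w2 = train(flipped, seed=0).weights
    assert w1 == pytest.approx(-w2, abs=1e-2)  # solver tolerance


def test_balanced_weights_match_minority_duplication_on_separable_data():
    """Doubling a class's hinge-loss weight equals duplicating its rows."""
    rng = np.random.default_rng(5)
    vals = np.vstack([rng.normal(0, 0.4, (4, 2)), rng.normal(3, 0.4, (8, 2))])
    m = matrix_of(vals, ["ADHD"] * 4 + ["control"] * 8)
    weighted = train(m, class_weights={"ADHD": 2.0, "control": 1.0}, seed=0)
    dup = matrix_of(
        np.vstack([vals, vals[:4]]),
        ["ADHD"] * 4 + ["control"] * 8 + ["ADHD"] * 4,
    )
    duplicated = train(dup, seed=0)
    assert weighted.weights == pytest.approx(duplicated.weights, abs=1e-6)
    assert weighted.bias == pytest.approx(duplicated.bias, abs=1e-6)


def test_single_class_training_is_rejected():
    m = matrix_of([[0.0], [1.0]], ["ADHD", "ADHD"])
    with pytest.raises(ValueError):
        train(m)


# --------------------------------------------------------------- evaluation
def eval_oracle(y_true, y_pred, order):
    out = {}
    for label in order:
        tp = sum(t == label and p == label for t, p in zip(y_true, y_pred))
        fp = sum(t != label and p == label for t, p in zip(y_true, y_pred))
        fn = sum(t == label and p != label for t, p in zip(y_true, y_pred))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[label] = (prec, rec, f1, sum(t == label for t in y_true))
    acc = sum(t == p for t, p in zip(y_true, y_pred)) / len(y_true)
    return out, acc


def test_eval_report_matches_from_scratch_oracle_on_random_predictions():
    rng = np.random.default_rng(6)
    order = ("ADHD", "control")
    for _ in range(25):
        n = int(rng.integers(2, 30))
        y_true = [order[i] for i in rng.integers(2, size=n)]
        y_pred = [order[i] for i in rng.integers(2, size=n)]
        report = EvalReport.from_predictions(y_true, y_pred, order)
        expected, acc = eval_oracle(y_true, y_pred, order)
        assert report.accuracy == pytest.approx(acc)
        for label in order:
            m = report.per_class[label]
            assert (m.precision, m.recall, m.f1, m.support) == pytest.approx(expected[label])
        assert report.confusion.sum() == n
        assert [report.per_class[c].support for c in order] == list(report.confusion.sum(axis=1))


def test_macro_recall_invariant_under_relabeling():
    rng = np.random.default_rng(7)
    order = ("ADHD", "control")
    y_true = [order[i] for i in rng.integers(2, size=40)]
    y_pred = [order[i] for i in rng.integers(2, size=40)]
    r1 = EvalReport.from_predictions(y_true, y_pred, order)
    swap = {"ADHD": "control", "control": "ADHD"}
    r2 = EvalReport.from_predictions([swap[t] for t in y_true], [swap[p] for p in y_pred], order)
    macro1 = np.mean([r1.per_class[c].recall for c in order])
    macro2 = np.mean([r2.per_class[c].recall for c in order])
    assert macro1 == pytest.approx(macro2)


def test_f1_fixed_point_when_precision_equals_recall():
    report = EvalReport.from_confusion([[3, 1], [1, 3]], ("ADHD", "control"))
    for label in ("ADHD", "control"):
        m = report.per_class[label]
        assert m.precision == m.recall == pytest.approx(m.f1)


# --------------------------------------------------------- cross-validation
def test_stratified_folds_partition_and_balance():
    labels = ["ADHD"] * 5 + ["control"] * 7
    folds = stratified_folds(labels, k=10, seed=0)
    flat = sorted(i for f in folds for i in f)
    assert flat == list(range(12))
    sizes = sorted(len(f) for f in folds)
    assert max(sizes) - min(sizes) <= 1
    with pytest.raises(ValueError):
        stratified_folds(labels, k=13)


def test_cross_validation_pools_every_sample_and_is_deterministic():
    rng = np.random.default_rng(8)
    m = two_clusters(rng, n_a=8, n_b=12)
    reports1, pooled1 = cross_validate(m, k=5, class_weights="balanced", seed=42)
    reports2, pooled2 = cross_validate(m, k=5, class_weights="balanced", seed=42)
    assert pooled1.confusion.sum() == 20
    assert np.array_equal(pooled1.confusion, pooled2.confusion)
    for r1, r2 in zip(reports1, reports2):
        assert np.array_equal(r1.confusion, r2.confusion)
    assert pooled1.accuracy == 1.0  # trivially separable


def test_cross_validation_requires_raw_matrix():
    rng = np.random.default_rng(9)
    m = normalize(two_clusters(rng))
    with pytest.raises(ValueError):
        cross_validate(m, k=2)


# ------------------------------------------------------------------ markers
def test_marker_ranking_by_signed_weight():
    model = LinearModel(
        feature_names=["on", "je", "et", "mais"],
        weights=np.array([-2.0, 2.0, -1.0, 0.0]),
        bias=0.0,
        class_order=("ADHD", "control"),
        class_weights=None,
        scaling=None,
    )
    neg, pos = top_markers(model, k=3)
    assert [n for n, _ in neg] == ["on", "et"]  # zero weight never ranks
    assert [n for n, _ in pos] == ["je"]


def test_all_zero_weights_warn_and_return_empty():
    model = LinearModel(
        feature_names=["a", "b"],
        weights=np.zeros(2),
        bias=0.0,
        class_order=("ADHD", "control"),
        class_weights=None,
        scaling=None,
    )
    with pytest.warns(UserWarning, match="zero"):
        assert top_markers(model, k=2) == ([], [])


def test_model_json_roundtrip(tmp_path):
    rng = np.random.default_rng(10)
    m = normalize(two_clusters(rng))
    model = train(m, class_weights="balanced", seed=1)
    model.save(tmp_path / "model.json")
    back = LinearModel.load(tmp_path / "model.json")
    assert back.weights == pytest.approx(model.weights)
    assert back.class_order == model.class_order
    assert evaluate(back, m).accuracy == evaluate(model, m).accuracy
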