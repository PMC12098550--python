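"""Chunking, function-word and character 3-gram features, normalization."""

import numpy as np
import pytest

from sdmstylo.annotation import Token
from sdmstylo.features import (
    FeatureMatrix,
    Sample,
    apply_scaling,
    char3_features,
    char3_matrix,
    chunk,
    default_fw_lexicon,
    fw_features,
    fw_matrix,
    normalize,
)


def words(forms, upos="NOUN"):
    return [Token(form=f, upos=("PUNCT" if f in ".,!?" else upos)) for f in forms]


def sample_of(forms, sid="s0", group="ADHD"):
    toks = tuple(words(forms))
    return Sample(id=sid, group=group, tokens=toks, source_span=(0, len(toks)))


# ------------------------------------------------------------------ chunk
@pytest.mark.parametrize(
    "total, n, expected_samples, expected_last",
    [
        (3000, 1500, 2, 1500),
        (3200, 1500, 2, 1500),  # 200-token remainder < n/2: discarded
        (2400, 1500, 2, 900),   # 900-token remainder >= n/2: kept short
        (0, 1500, 0, None),
        (749, 1500, 0, None),   # whole stream below n/2 yields nothing
        (750, 1500, 1, 750),
    ],
)
def test_chunk_remainder_rule(total, n, expected_samples, expected_last):
    stream = words([f"w{i}" for i in range(total)])
    samples = chunk(stream, n, group="g")
    assert len(samples) == expected_samples
    if expected_last is not None:
        assert len(samples[-1].tokens) == expected_last


def test_chunk_conserves_tokens_and_spans_are_disjoint():
    stream = words([f"w{i}" for i in range(3456)])
    samples = chunk(stream, 1000, group="g")
    spans = [s.source_span for s in samples]
    assert spans == sorted(spans)
    covered = sum(b - a for a, b in spans)
    discarded = len(stream) - covered
    assert covered + discarded == len(stream)
    assert 0 <= discarded < 500
    assert [s.id for s in samples] == [f"g-{i:04d}" for i in range(len(samples))]


def test_chunk_rejects_bad_n():
    with pytest.raises(ValueError):
        chunk([], 0)


# ----------------------------------------------------------- function words
def test_fw_relative_frequencies():
    vec = fw_features(sample_of(["le", "le", "la"]), ["le", "la", "et"])
    assert vec == pytest.approx([2 / 3, 1 / 3, 0.0])


def test_fw_ignores_punctuation_in_numerator_and_denominator():
    vec = fw_features(sample_of(["le", ".", ".", "chat"]), ["le"])
    assert vec == pytest.approx([1 / 2])


def test_fw_no_hits_gives_zero_vector():
    vec = fw_features(sample_of(["chat", "dort"]), ["le", "la"])
    assert not vec.any()


def test_fw_rows_sum_to_at_most_one():
    rng = np.random.default_rng(0)
    lex = default_fw_lexicon()
    forms = [lex[rng.integers(len(lex))] if rng.random() < 0.6 else f"c{rng.integers(50)}" for _ in range(400)]
    vec = fw_features(sample_of(forms), lex)
    assert vec.sum() <= 1 + 1e-12
    all_fw = fw_features(sample_of(list(lex[:30])), lex)
    assert all_fw.sum() == pytest.approx(1.0)


# ----------------------------------------------------------- character 3-grams
def test_char3_anchor_first_five_grams():
    s = sample_of(["During", "the", "night"])
    grams = char3_features(s)
    text = "during_the_night"
    ordered = [text[i : i + 3] for i in range(len(text) - 2)]
    assert ordered[:5] == ["dur", "uri", "rin", "ing", "ng_"]
    assert set(ordered) == set(grams)


def test_char3_tiny_inputs():
    assert char3_features(sample_of(["abc"])) == {"abc": 1.0}
    assert char3_features(sample_of(["ab"])) == {}
    assert char3_features(sample_of(["on", "a"])) == {"on_": 0.5, "n_a": 0.5}


def test_char3_frequencies_sum_to_one():
    rng = np.random.default_rng(1)
    forms = [f"mot{rng.integers(30)}" for _ in range(200)]
    grams = char3_features(sample_of(forms))
    assert sum(grams.values()) == pytest.approx(1.0)


def test_char3_matrix_respects_imposed_vocabulary():
    s1, s2 = sample_of(["abc"], "a"), sample_of(["xyz"], "b", group="control")
    m = char3_matrix([s1, s2], vocabulary=["abc"])
    assert m.feature_names == ["abc"]
    assert m.values[:, 0] == pytest.approx([1.0, 0.0])  # unseen gram 'xyz' ignored


# ------------------------------------------------------------- normalization
def raw_matrix(values, labels=None):
    values = np.asarray(values, dtype=float)
    n, f = values.shape
    return FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        feature_names=[f"f{j}" for j in range(f)],
        values=values,
        labels=labels or ["ADHD"] * (n // 2) + ["control"] * (n - n // 2),
    )


def test_zscore_then_l2_closed_form():
    m = normalize(raw_matrix([[1.0], [3.0]]))
    assert m.values == pytest.approx(np.array([[-1.0], [1.0]]))
    assert m.normalization_state == "zscored+L2"


def test_fitted_columns_have_zero_mean_unit_sd_and_unit_rows():
    rng = np.random.default_rng(2)
    raw = raw_matrix(rng.random((12, 5)))
    m = normalize(raw)
    means, sds = m.scaling
    z = (raw.values - means) / sds  # the z-scores before the L2 step
    assert z.mean(axis=0) == pytest.approx(np.zeros(5), abs=1e-9)
    assert z.std(axis=0) == pytest.approx(np.ones(5), abs=1e-9)
    norms = np.linalg.norm(m.values, axis=1)
    assert norms == pytest.approx(np.ones(12), abs=1e-9)


def test_all_zero_row_stays_zero():
    # first row z-scores to (0, 0): the norm-0 convention must keep it zero
    with pytest.warns(UserWarning, match="zero-variance"):
        m = normalize(raw_matrix([[0.0, 7.0], [1.0, 7.0], [-1.0, 7.0]]))
    assert m.values[0] == pytest.approx(np.zeros(2))
    assert np.all(m.values[:, 1] == 0.0)  # zero-variance feature kept but scaled to 0
    assert set(np.round(np.linalg.norm(m.values, axis=1), 9)) <= {0.0, 1.0}


def test_scaling_fitted_on_train_rows_only_no_leakage():
    """Scaling parameters must be identical whether or not the held-out
    rows are present in the matrix."""
    rng = np.random.default_rng(3)
    train_vals = rng.random((8, 4))
    test_vals = rng.random((3, 4)) + 5.0  # shifted: would distort stats if leaked
    full = FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(11)],
        feature_names=list("abcd"),
        values=np.vstack([train_vals, test_vals]),
        labels=["ADHD"] * 6 + ["control"] * 5,
    )
    train_ids = [f"s{i}" for i in range(8)]
    with_test = normalize(full, fit_on=train_ids)
    without_test = normalize(full.subset(train_ids))
    assert with_test.scaling[0] == pytest.approx(without_test.scaling[0])
    assert with_test.scaling[1] == pytest.approx(without_test.scaling[1])
    # and rows scale identically through the held-out path
    reapplied = apply_scaling(full.subset(train_ids), with_test.scaling)
    assert reapplied.values == pytest.approx(without_test.values)


def test_normalize_twice_is_rejected():
    m = normalize(raw_matrix([[1.0], [2.0]]))
    with pytest.raises(ValueError):
        normalize(m)


def test_matrix_tsv_roundtrip(tmp_path):
    import pandas as pd

    m = raw_matrix([[0.1, 0.2], [0.3, 0.4]])
    m.save(tmp_path / "m.tsv")
    df = pd.read_csv(tmp_path / "m.tsv", sep="\t", index_col="sample_id")
    assert list(df.columns) == ["group", "f0", "f1"]
    assert df[["f0", "f1"]].to_numpy() == pytest.approx(m.values)
    assert (tmp_path / "m.scaling.json").exists()
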