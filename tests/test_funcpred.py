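"""Feature extraction, class selection, BCE classifier, and prediction rules."""

import dataclasses
import warnings

import numpy as np
import pytest

from gocapgan import tensor as T
from gocapgan.funcpred import (ClassifierConfig, ClassifierModel, FeatureMatrix,
                               LabelMatrix, bce_loss, build_label_matrix,
                               extract_features, predict_labels, select_classes,
                               train_classifier)
from gocapgan.gan import build_discriminator
from gocapgan.seqio import AnnotationTable, ProteinRecord, encode_batch


def _table(counts):
    pairs = set()
    for go, c in counts.items():
        for i in range(c):
            pairs.add((f"{go}_P{i}", go))
    return AnnotationTable(pairs=pairs)


# -- class selection ----------------------------------------------------------


def test_select_classes_boundary_inclusive():
    table = _table({"GO:0000001": 20, "GO:0000002": 16, "GO:0000003": 15})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel = select_classes(table, min_count=16, top_k=25)
    assert sel.classes == ["GO:0000001", "GO:0000002"]
    assert sel.n_eligible == 2


def test_select_classes_all_below_threshold_warns_empty():
    table = _table({"GO:0000001": 3})
    with pytest.warns(UserWarning, match="eligible"):
        sel = select_classes(table, min_count=16, top_k=5)
    assert sel.classes == [] and sel.n_eligible == 0


def test_select_classes_orders_by_count_then_go_id():
    table = _table({"GO:0000002": 20, "GO:0000001": 20, "GO:0000003": 30})
    sel = select_classes(table, min_count=16, top_k=3)
    assert sel.classes == ["GO:0000003", "GO:0000001", "GO:0000002"]


def test_select_classes_matches_manifest_top_counts():
    counts = {f"GO:{k:07d}": c for k, c in
              enumerate([40, 35, 30, 28, 25, 22, 20, 18, 17, 16, 15, 10, 3])}
    table = _table(counts)
    sel = select_classes(table, min_count=16, top_k=10)
    expected = sorted((go for go, c in counts.items() if c >= 16),
                      key=lambda go: (-counts[go], go))[:10]
    assert sel.classes == expected
    assert sel.n_eligible == 10


def test_select_classes_invariant_to_row_order(rng, tiny_corpus):
    _, table, _ = tiny_corpus
    shuffled = AnnotationTable(pairs=set(
        [tuple(p) for p in rng.permutation(sorted(table.pairs))]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = select_classes(table, min_count=2, top_k=4)
        b = select_classes(shuffled, min_count=2, top_k=4)
    assert a.classes == b.classes


# -- label matrix -------------------------------------------------------------


def test_label_matrix_zero_rows_and_column_sums(tiny_corpus):
    records, table, manifest = tiny_corpus
    classes = sorted(manifest.motifs)
    lm = build_label_matrix(records, table, classes)
    counts = table.class_counts
    for j, go in enumerate(classes):
        assert lm.Y[:, j].sum() == counts.get(go, 0)
    planted = {(p["accession"], go) for p in manifest.proteins
               for go in p["classes"]}
    for i, rec in enumerate(records):
        for j, go in enumerate(classes):
            assert lm.Y[i, j] == ((rec.accession, go) in planted)


def test_label_matrix_unannotated_protein_is_all_zero():
    recs = [ProteinRecord("A", "MK"), ProteinRecord("B", "MK")]
    table = AnnotationTable(pairs={("A", "GO:0000001")})
    lm = build_label_matrix(recs, table, ["GO:0000001", "GO:0000002"])
    assert lm.Y[1].sum() == 0
    assert lm.Y[0].tolist() == [1.0, 0.0]


# -- binary cross-entropy -----------------------------------------------------


def test_bce_hand_value_and_perfect_limit():
    assert bce_loss([1.0, 0.0], [0.5, 0.5]) == pytest.approx(np.log(2))
    assert bce_loss([1.0, 0.0], [1.0, 0.0]) == pytest.approx(0.0, abs=1e-5)


def test_bce_matches_scalar_loop_oracle(rng):
    y = (rng.uniform(size=(6, 4)) > 0.5).astype(float)
    h = rng.uniform(0.01, 0.99, size=(6, 4))
    acc = 0.0
    for i in range(6):
        for j in range(4):
            acc += -(y[i, j] * np.log(h[i, j]) + (1 - y[i, j]) * np.log(1 - h[i, j]))
    assert bce_loss(y, h) == pytest.approx(acc / 24, abs=1e-9)


def test_bce_permutation_symmetry(rng):
    y = (rng.uniform(size=12) > 0.5).astype(float)
    h = rng.uniform(0.01, 0.99, size=12)
    perm = rng.permutation(12)
    assert bce_loss(y, h) == pytest.approx(bce_loss(y[perm], h[perm]))


def test_bce_clamps_exact_zero_and_one():
    v = bce_loss([1.0], [0.0])
    assert np.isfinite(v) and v == pytest.approx(-np.log(1e-7))


# -- classifier ---------------------------------------------------------------


def _separable(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 4))
    Wt = rng.normal(size=(4, 2)) * 3
    Y = (X @ Wt > 0).astype(float)
    return (FeatureMatrix(X, [f"P{i}" for i in range(n)]),
            LabelMatrix(Y, ["GO:0000001", "GO:0000002"]))


def test_training_halves_loss_on_separable_data():
    feats, labels = _separable()
    hist = []
    train_classifier(feats, labels, ClassifierConfig(epochs=40, seed=1),
                     history=hist)
    assert hist[-1] <= 0.5 * hist[0]


def test_training_is_deterministic_given_seed():
    feats, labels = _separable()
    m1 = train_classifier(feats, labels, ClassifierConfig(epochs=5, seed=3))
    m2 = train_classifier(feats, labels, ClassifierConfig(epochs=5, seed=3))
    assert np.array_equal(m1.W, m2.W) and np.array_equal(m1.b, m2.b)


def test_constant_features_converge_to_label_prevalence():
    rng = np.random.default_rng(0)
    n = 200
    X = np.ones((n, 1))
    Y = (rng.uniform(size=(n, 3)) < [0.2, 0.5, 0.8]).astype(float)
    prev = Y.mean(axis=0)
    feats = FeatureMatrix(X, [str(i) for i in range(n)])
    labels = LabelMatrix(Y, ["GO:0000001", "GO:0000002", "GO:0000003"])
    model = train_classifier(feats, labels,
                             ClassifierConfig(epochs=600, learning_rate=0.05,
                                              batch_size=n, seed=0))
    pred = model.predict_proba(X)
    assert np.allclose(pred[0], prev, atol=0.03)


def test_all_zero_labels_warn_but_train():
    feats, labels = _separable(n=20)
    zeros = LabelMatrix(np.zeros_like(labels.Y), labels.classes)
    with pytest.warns(UserWarning, match="no positive"):
        train_classifier(feats, zeros, ClassifierConfig(epochs=2, seed=0))


# -- prediction ---------------------------------------------------------------


def test_threshold_rules_and_monotonicity(rng):
    model = ClassifierModel(W=np.zeros((2, 3)), b=np.zeros(3),
                            classes=["a", "b", "c"], threshold=0.5)
    X = rng.normal(size=(5, 2))
    # zero weights -> probability exactly 0.5 everywhere -> ">=" gives 1
    assert predict_labels(model, X).Y.all()
    model2 = dataclasses.replace(model, b=np.full(3, -0.05))  # p ~ 0.4875
    assert not predict_labels(model2, X).Y.any()
    # lowering the threshold never turns a positive into a negative
    W = rng.normal(size=(2, 3))
    model3 = ClassifierModel(W=W, b=np.zeros(3), classes=["a", "b", "c"])
    hi = predict_labels(model3, X, threshold=0.7).Y
    lo = predict_labels(model3, X, threshold=0.3).Y
    assert np.all(lo >= hi)


# -- feature extraction -------------------------------------------------------


def test_extract_features_deterministic_and_correct_width(tiny_gan_config):
    disc = build_discriminator(tiny_gan_config)
    recs = [ProteinRecord("A", "MKVLLA"), ProteinRecord("A2", "MKVLLA"),
            ProteinRecord("B", "ACDEFGHIK")]
    batch = encode_batch(recs, seq_len=tiny_gan_config.seq_len)
    feats = extract_features(disc, batch)
    assert feats.n_features == tiny_gan_config.out_capsules
    assert np.array_equal(feats.values[0], feats.values[1])  # same sequence
    assert feats.accessions == ["A", "A2", "B"]
    resid = extract_features(disc, batch, tap="residual")
    assert resid.n_features == tiny_gan_config.channels


def test_feature_tsv_round_trip(tmp_path, tiny_gan_config):
    disc = build_discriminator(tiny_gan_config)
    recs = [ProteinRecord(f"P{i}", "MKVLLAQ") for i in range(3)]
    feats = extract_features(disc, encode_batch(recs, seq_len=tiny_gan_config.seq_len))
    feats.write_tsv(tmp_path / "f.tsv")
    back = FeatureMatrix.read_tsv(tmp_path / "f.tsv")
    assert back.accessions == feats.accessions
    assert np.allclose(back.values, feats.values)


def test_critic_features_linearly_separate_motif_classes():
    """Features from a briefly trained critic separate two planted motif
    classes better than chance under a held-out linear probe."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score

    from gocapgan.gan import GanConfig, build_discriminator, build_generator, train_gan
    from gocapgan.synthetic import SyntheticDesign, generate_corpus

    design = SyntheticDesign(n_classes=2, n_proteins=120, min_len=24, max_len=32,
                             labels_min=1, labels_max=1, motif_len_min=6,
                             motif_len_max=7, seed=3)
    records, table, manifest = generate_corpus(design)
    cfg = GanConfig(batch_size=16, seq_len=32, noise_dim=16, epochs=2, channels=8,
                    capsule_conv_channels=8, primary_capsule_dim=8, out_capsules=8,
                    out_capsule_dim=4, n_critic=3, seed=3)
    gen, disc = build_generator(cfg), build_discriminator(cfg)
    train_gan(gen, disc, encode_batch(records, seq_len=cfg.seq_len), cfg)

    feats = extract_features(disc, encode_batch(records, seq_len=cfg.seq_len))
    labels = build_label_matrix(records, table, sorted(manifest.motifs))
    train_idx = np.arange(0, 120, 2)
    test_idx = np.arange(1, 120, 2)
    aucs = []
    for j in range(2):
        probe = LogisticRegression(max_iter=2000).fit(
            feats.values[train_idx], labels.Y[train_idx, j])
        aucs.append(roc_auc_score(labels.Y[test_idx, j],
                                  probe.decision_function(feats.values[test_idx])))
    assert np.mean(aucs) > 0.5
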