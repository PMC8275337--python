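"""Skip-gram embedding and CNN encoder."""

import numpy as np
import pytest

from phagraph import (
    CNNEncoder,
    Contig,
    ContigTooShortError,
    cnn_forward,
    cnn_predict_contig,
    embed_segment,
    encode_contig,
    train_cnn,
    train_embedding,
)
from phagraph.encoder import kmer_ids


def _random_dna(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))


class TestEmbedding:
    def test_homopolymer_trains(self):
        emb = train_embedding(["A" * 50], seed=0, epochs=1)
        assert emb.table.shape == (64, 100)

    def test_too_short_corpus_raises(self):
        with pytest.raises(ValueError, match="too short"):
            train_embedding(["ACG"], m=2, seed=0)

    def test_determinism(self):
        corpus = ["ACGTAGCTAGGATCCA" * 10]
        a = train_embedding(corpus, seed=3, epochs=2)
        b = train_embedding(corpus, seed=3, epochs=2)
        np.testing.assert_array_equal(a.table, b.table)

    def test_cooccurring_kmers_more_similar(self, rng):
        # two disjoint sub-alphabets never co-occur within a sequence
        corpus = [_random_dna(rng, 300, "AC") for _ in range(20)]
        corpus += [_random_dna(rng, 300, "GT") for _ in range(20)]
        emb = train_embedding(corpus, seed=1, epochs=5)

        def kid(kmer):
            return int(kmer_ids(kmer)[0])

        ac_kmers = [a + b + c for a in "AC" for b in "AC" for c in "AC"]
        gt_kmers = [a + b + c for a in "GT" for b in "GT" for c in "GT"]
        t = emb.table / np.linalg.norm(emb.table, axis=1, keepdims=True)
        within = np.mean(
            [t[kid(x)] @ t[kid(y)] for x in ac_kmers for y in ac_kmers if x != y]
        )
        across = np.mean([t[kid(x)] @ t[kid(y)] for x in ac_kmers for y in gt_kmers])
        assert within > across


class TestEmbedSegment:
    def test_shape_and_padding(self, tiny_embedding):
        seq = "ACGT" * 500
        M = embed_segment(seq, tiny_embedding)
        assert M.shape == (2000, tiny_embedding.dim)
        # 1998 k-mer rows, final two rows zero-padded
        assert np.any(M[1997] != 0)
        assert np.all(M[1998:] == 0)

    def test_all_n_is_zero(self, tiny_embedding):
        assert np.all(embed_segment("N" * 2000, tiny_embedding) == 0)

    def test_wrong_length_raises(self, tiny_embedding):
        with pytest.raises(ValueError, match="length"):
            embed_segment("ACGT", tiny_embedding)

    def test_deterministic(self, tiny_embedding):
        seq = "ACGTTGCA" * 250
        np.testing.assert_array_equal(
            embed_segment(seq, tiny_embedding), embed_segment(seq, tiny_embedding)
        )


def _tiny_model(tiny_embedding, n_label=2):
    """Hand-sized CNN: d1=2, 1 filter, 2-unit dense layers."""
    return CNNEncoder(
        embedding=tiny_embedding,
        w_conv=np.arange(1 * 2 * 8, dtype=np.float32).reshape(2, 8, 1) / 16.0,
        b_conv=np.array([0.1], dtype=np.float32),
        w0=np.array([[0.5, -1.0]], dtype=np.float32),
        b0=np.array([0.0, 0.2], dtype=np.float32),
        w1=np.array([[1.0, 0.3], [-0.2, 0.4]], dtype=np.float32),
        b1=np.array([0.05, -0.05], dtype=np.float32),
        w2=np.array([[0.7, -0.7], [0.1, 0.2]], dtype=np.float32),
        b2=np.zeros(n_label, dtype=np.float32),
        class_names=[f"c{i}" for i in range(n_label)],
        window=2000,
    )


class TestCnnForward:
    def test_probability_vector(self, tiny_embedding, rng):
        model = _tiny_model(tiny_embedding)
        M = rng.normal(size=(10, 8))
        out = cnn_forward(M, model)
        assert out.shape == (2,)
        assert np.all(out >= 0)
        assert np.isclose(out.sum(), 1.0, atol=1e-6)

    def test_zero_input_uniform(self, tiny_embedding):
        model = _tiny_model(tiny_embedding)
        model.b_conv[:] = 0
        model.b0[:] = 0
        model.b1[:] = 0
        out = cnn_forward(np.zeros((10, 8)), model)
        np.testing.assert_allclose(out, [0.5, 0.5], atol=1e-7)

    def test_matches_scalar_arithmetic(self, tiny_embedding):
        # independent forward pass with explicit python loops
        model = _tiny_model(tiny_embedding)
        M = np.arange(4 * 8, dtype=np.float64).reshape(4, 8) / 10.0
        conv_vals = []
        for t in range(3):  # 4 rows, filter height 2 -> 3 windows
            acc = float(model.b_conv[0])
            for o in range(2):
                for d in range(8):
                    acc += M[t + o, d] * float(model.w_conv[o, d, 0])
            conv_vals.append(max(acc, 0.0))
        pooled = max(conv_vals)
        h1 = [max(pooled * float(model.w0[0, j]) + float(model.b0[j]), 0.0) for j in range(2)]
        h2 = [
            max(sum(h1[i] * float(model.w1[i, j]) for i in range(2)) + float(model.b1[j]), 0.0)
            for j in range(2)
        ]
        logits = [sum(h2[i] * float(model.w2[i, j]) for i in range(2)) for j in range(2)]
        exps = [np.exp(l - max(logits)) for l in logits]
        expected = np.array(exps) / sum(exps)
        np.testing.assert_allclose(cnn_forward(M, model), expected, rtol=1e-5)

    def test_dimension_mismatch_raises(self, tiny_embedding):
        with pytest.raises(ValueError):
            cnn_forward(np.zeros((10, 5)), _tiny_model(tiny_embedding))


@pytest.fixture(scope="module")
def separable_cnn():
    """CNN trained on two classes with disjoint nucleotide composition."""
    rng = np.random.default_rng(42)
    segs, labels = [], []
    for _ in range(60):
        segs.append(_random_dna(rng, 2000, "AC"))
        labels.append("fam_ac")
        segs.append(_random_dna(rng, 2000, "GT"))
        labels.append("fam_gt")
    emb = train_embedding(segs[:20], seed=5, epochs=1, dim=16)
    model = train_cnn(
        segs, labels, emb, d1=4, n_conv=4, feature_dim=16, hidden2=8,
        epochs=8, lr=3e-3, seed=5,
    )
    return model, segs, labels


class TestTrainCnn:
    def test_loss_decreases(self, separable_cnn):
        model, _, _ = separable_cnn
        assert model.history[-1] < model.history[0]

    def test_training_accuracy(self, separable_cnn):
        model, segs, labels = separable_cnn
        correct = 0
        for seq, label in zip(segs, labels):
            M = embed_segment(seq, model.embedding)
            pred = model.class_names[int(np.argmax(cnn_forward(M, model)))]
            correct += pred == label
        assert correct / len(segs) >= 0.95

    def test_single_class_raises(self, tiny_embedding):
        with pytest.raises(ValueError, match="classes"):
            train_cnn(["A" * 2000], ["only"], tiny_embedding)

    def test_determinism(self, rng):
        segs = [_random_dna(rng, 2000) for _ in range(8)]
        labels = ["a", "b"] * 4
        emb = train_embedding(segs[:2], seed=1, epochs=1, dim=8)
        kwargs = dict(d1=4, n_conv=2, feature_dim=8, hidden2=4, epochs=2, seed=9)
        m1 = train_cnn(segs, labels, emb, **kwargs)
        m2 = train_cnn(segs, labels, emb, **kwargs)
        np.testing.assert_array_equal(m1.w_conv, m2.w_conv)
        np.testing.assert_array_equal(m1.w2, m2.w2)


class TestEncodeContig:
    def test_single_window_equals_mean_of_one(self, separable_cnn):
        model, segs, _ = separable_cnn
        contig = Contig("x", segs[0])
        feat = encode_contig(contig, model)
        assert feat.shape == (model.feature_dim,)
        np.testing.assert_allclose(feat, encode_contig(contig, model), atol=0)

    def test_identical_windows_equal_single(self, separable_cnn):
        model, segs, _ = separable_cnn
        single = encode_contig(Contig("x", segs[0]), model)
        triple = encode_contig(Contig("y", segs[0] * 3), model)
        np.testing.assert_allclose(single, triple, rtol=1e-5)

    def test_nonnegative_fixed_dim(self, separable_cnn, rng):
        model, _, _ = separable_cnn
        for length in (2000, 3503, 6000):
            feat = encode_contig(Contig(f"c{length}", _random_dna(rng, length)), model)
            assert feat.shape == (model.feature_dim,)
            assert np.all(feat >= 0)

    def test_too_short_rejected(self, separable_cnn):
        model, _, _ = separable_cnn
        with pytest.raises(ContigTooShortError):
            encode_contig(Contig("short", "ACGT" * 100), model)

    def test_linear_probe_separates_families(self, separable_cnn, rng):
        model, _, _ = separable_cnn
        feats, ys = [], []
        for y, alphabet in enumerate(["AC", "GT"]):
            for _ in range(10):
                feats.append(
                    encode_contig(Contig(f"{alphabet}{_}", _random_dna(rng, 4000, alphabet)), model)
                )
                ys.append(y)
        X = np.array(feats)
        ys = np.array(ys)
        # nearest-centroid probe: better than chance on separable families
        c0, c1 = X[ys == 0].mean(0), X[ys == 1].mean(0)
        pred = (np.linalg.norm(X - c1, axis=1) < np.linalg.norm(X - c0, axis=1)).astype(int)
        assert (pred == ys).mean() > 0.5


class TestCheckpoint:
    def test_save_load_roundtrip(self, separable_cnn, tmp_path):
        model, segs, _ = separable_cnn
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = CNNEncoder.load(path)
        assert loaded.class_names == model.class_names
        contig = Contig("x", segs[0])
        np.testing.assert_allclose(
            encode_contig(contig, model), encode_contig(contig, loaded), atol=0
        )
        np.testing.assert_allclose(
            cnn_predict_contig(contig, model), cnn_predict_contig(contig, loaded), atol=0
        )
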