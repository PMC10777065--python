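import math

import numpy as np
import pytest

from spbcmi import seq_lm
from spbcmi.seq_lm import (
    EncoderConfig, MaskedBatch, OptimizerSettings, attention_head,
    encoder_forward, extract_feature, init_model, loss_and_grads,
    make_masked_batch, masked_softmax, mlm_loss, multi_head, train_mlm,
)
from spbcmi.tokenizer import CLS_ID, MASK_ID, PAD_ID, SEP_ID, Vocabulary, tokenize_document

VOCAB = Vocabulary.build(3)


def tiny_config(**kw):
    defaults = dict(vocab_size=len(VOCAB), n_layers=1, n_heads=2,
                    d_model=8, d_ff=16, d_out=8, dropout=0.0)
    defaults.update(kw)
    return EncoderConfig(**defaults)


def loop_attention_oracle(M, Wq, Wk, Wv, attn_mask):
    """Independent loop-based single-head attention (brute force)."""
    T, _ = M.shape
    dk = Wq.shape[1]
    q, k, v = M @ Wq, M @ Wk, M @ Wv
    out = np.zeros((T, Wv.shape[1]))
    valid = [j for j in range(T) if attn_mask[j]]
    for i in range(T):
        scores = {j: float(q[i] @ k[j]) / math.sqrt(dk) for j in valid}
        mx = max(scores.values())
        exps = {j: math.exp(s - mx) for j, s in scores.items()}
        z = sum(exps.values())
        for j in valid:
            out[i] += (exps[j] / z) * v[j]
    return out


class TestAttention:
    def test_single_token_identity_projection(self, rng):
        M = rng.normal(size=(1, 4))
        out = attention_head(M, np.eye(4), np.eye(4), np.eye(4))
        np.testing.assert_allclose(out, M, atol=1e-12)

    def test_rows_are_probability_vectors(self, rng):
        scores = rng.normal(size=(3, 2, 6, 6)) * 5
        mask = np.ones((3, 2, 6, 6))
        mask[..., 4:] = 0  # last two positions padded
        w = masked_softmax(scores, mask)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-8)
        assert (w[..., 4:] == 0).all()
        assert (w >= 0).all()

    def test_matches_loop_oracle(self, rng):
        for _ in range(5):
            M = rng.normal(size=(4, 6))
            Wq, Wk, Wv = (rng.normal(size=(6, 3)) for _ in range(3))
            mask = np.array([1, 1, 1, 0])
            ours = attention_head(M, Wq, Wk, Wv, mask)
            oracle = loop_attention_oracle(M, Wq, Wk, Wv, mask)
            np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_output_is_convex_combination_of_values(self, rng):
        M = rng.normal(size=(5, 4))
        Wv = rng.normal(size=(4, 4))
        out = attention_head(M, np.eye(4), np.eye(4), Wv)
        v = M @ Wv
        lo, hi = v.min(axis=0), v.max(axis=0)
        assert (out >= lo - 1e-12).all() and (out <= hi + 1e-12).all()

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            attention_head(rng.normal(size=(3, 4)), np.eye(5), np.eye(5), np.eye(5))


class TestMultiHead:
    def test_one_head_identity_wo_equals_single_head(self, rng):
        M = rng.normal(size=(5, 6))
        Wq, Wk, Wv = (rng.normal(size=(1, 6, 6)) for _ in range(3))
        weights = {"Wq": Wq, "Wk": Wk, "Wv": Wv, "Wo": np.eye(6)}
        np.testing.assert_allclose(
            multi_head(M, weights),
            attention_head(M, Wq[0], Wk[0], Wv[0]),
            atol=1e-12,
        )

    def test_block_preserves_shape(self, rng):
        cfg = tiny_config(n_layers=3)
        model = init_model(cfg, 0)
        ids = np.array([[CLS_ID, 10, 20, 30, SEP_ID, PAD_ID]])
        mask = np.array([[1, 1, 1, 1, 1, 0]])
        h, _ = encoder_forward(model, ids, mask)
        assert h.shape == (1, 6, cfg.d_model)

    def test_permutation_equivariance_without_positions(self, rng):
        # zero position embeddings: permuting content tokens permutes outputs
        cfg = tiny_config(n_layers=2)
        model = init_model(cfg, 1)
        model.params["pos_emb"][:] = 0.0
        ids = np.array([[CLS_ID, 10, 20, 30, 40, SEP_ID]])
        mask = np.ones((1, 6), dtype=np.int64)
        h1, _ = encoder_forward(model, ids, mask)
        ids2 = ids.copy()
        ids2[0, [1, 3]] = ids[0, [3, 1]]  # swap two content positions
        h2, _ = encoder_forward(model, ids2, mask)
        np.testing.assert_allclose(h2[0, 1], h1[0, 3], atol=1e-10)
        np.testing.assert_allclose(h2[0, 3], h1[0, 1], atol=1e-10)
        np.testing.assert_allclose(h2[0, 0], h1[0, 0], atol=1e-10)


class TestMaskedBatch:
    def test_span_count_and_disjointness(self):
        doc = tokenize_document("A" * 102, VOCAB, "x")  # 100 content tokens
        cfg = tiny_config(mask_rate=0.15, k=3)
        batch = make_masked_batch(doc, cfg, seed=0)
        masked = np.flatnonzero(batch.labels[0] >= 0)
        assert len(masked) == 15  # floor(0.15 * 100 / 3) = 5 runs of 3
        # disjoint length-3 runs; maximal stretches are multiples of 3
        # (two runs may abut without overlapping)
        runs = np.split(masked, np.where(np.diff(masked) != 1)[0] + 1)
        assert all(len(r) % 3 == 0 for r in runs)
        assert sum(len(r) // 3 for r in runs) == 5
        assert (batch.input_ids[0][masked] == MASK_ID).all()

    def test_specials_never_masked(self):
        doc = tokenize_document("ACGT" * 30, VOCAB, "x")
        cfg = tiny_config()
        for seed in range(5):
            batch = make_masked_batch(doc, cfg, seed)
            assert batch.labels[0, 0] == -1  # [CLS]
            sep_pos = doc.attention_masks[0].sum() - 1
            assert batch.labels[0, sep_pos] == -1
            assert (batch.input_ids[0, [0, sep_pos]] == [CLS_ID, SEP_ID]).all()

    def test_deterministic_under_seed(self):
        doc = tokenize_document("ACGT" * 30, VOCAB, "x")
        cfg = tiny_config()
        b1 = make_masked_batch(doc, cfg, seed=4)
        b2 = make_masked_batch(doc, cfg, seed=4)
        np.testing.assert_array_equal(b1.input_ids, b2.input_ids)
        np.testing.assert_array_equal(b1.labels, b2.labels)

    def test_vanishing_mask_rate_is_error(self):
        doc = tokenize_document("ACGTACGTAC", VOCAB, "x")
        cfg = tiny_config(mask_rate=0.01)
        with pytest.raises(ValueError, match="no masked positions"):
            make_masked_batch(doc, cfg, seed=0)


class TestMlmLoss:
    def test_uniform_logits_give_log_vocab(self):
        V = 37
        logits = np.zeros((4, V))
        assert mlm_loss(logits, np.array([0, 5, 7, 36])) == pytest.approx(
            math.log(V), abs=1e-9
        )

    def test_hand_computed_three_class(self):
        logits = np.log(np.array([[0.7, 0.2, 0.1]]))
        assert mlm_loss(logits, np.array([0])) == pytest.approx(-math.log(0.7), abs=1e-12)

    def test_confident_correct_prediction_approaches_zero(self):
        logits = np.array([[50.0, 0.0, 0.0]])
        assert mlm_loss(logits, np.array([0])) < 1e-12

    def test_zero_masked_positions_is_error(self):
        with pytest.raises(ValueError):
            mlm_loss(np.zeros((0, 5)), np.zeros(0, dtype=int))


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        doc = tokenize_document("ATGCATGGCCATAGCTAGCATCGATCGGG", VOCAB, "x")
        cfg = tiny_config(n_layers=2)
        model = init_model(cfg, 0)
        # scale weights so attention is far from uniform and gradients are
        # well above finite-difference noise
        for name, p in model.params.items():
            if p.ndim >= 2:
                model.params[name] = p * 20.0
        batch = make_masked_batch(doc, cfg, seed=3)
        _, grads = loss_and_grads(model, batch)
        names = ["tok_emb", "pos_emb", "mlm_W", "mlm_b",
                 "l0.Wq", "l0.Wk", "l0.Wv", "l0.Wo", "l0.bq", "l0.b1",
                 "l0.ln1_g", "l1.W1", "l1.W2", "l1.ln2_b"]
        for name in names:
            p = model.params[name]
            for _ in range(2):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                eps = 1e-6
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = loss_and_grads(model, batch)
                p[idx] = orig - eps
                lm, _ = loss_and_grads(model, batch)
                p[idx] = orig
                fd = (lp - lm) / (2 * eps)
                g = grads[name][idx]
                assert abs(fd - g) <= 1e-4 * max(1e-4, abs(fd), abs(g)), name


class TestTraining:
    def _corpus(self, n=16):
        seq = "ATGCGTACGGATCCATTGCAAGCTTACGTG"  # one 30-mer
        return [tokenize_document(seq, VOCAB, f"s{i}") for i in range(n)]

    def test_epochs_zero_returns_initialized_model(self):
        cfg = tiny_config()
        model = train_mlm(self._corpus(2), cfg, epochs=0, seed=0)
        ref = init_model(cfg, 0)
        for name in ref.params:
            np.testing.assert_array_equal(model.params[name], ref.params[name])
        assert not model.trained and model.loss_trace == []

    def test_same_seed_identical_loss_traces(self):
        cfg = tiny_config()
        opt = OptimizerSettings(batch_size=8)
        m1 = train_mlm(self._corpus(8), cfg, opt, epochs=2, seed=9)
        m2 = train_mlm(self._corpus(8), cfg, opt, epochs=2, seed=9)
        assert m1.loss_trace == m2.loss_trace
        for name in m1.params:
            np.testing.assert_array_equal(m1.params[name], m2.params[name])

    def test_memorizes_repeated_sequence(self):
        # a single repeated 30-mer is fully predictable from context
        cfg = tiny_config(n_layers=1, d_model=16, d_ff=32)
        opt = OptimizerSettings(learning_rate=3e-3, batch_size=8)
        model = train_mlm(self._corpus(16), cfg, opt, epochs=40, seed=0)
        assert model.loss_trace[-1] < model.loss_trace[0]
        acc = seq_lm.mlm_accuracy(model, self._corpus(4), seed=1)
        assert acc > 0.9

    def test_empty_corpus_raises(self):
        with pytest.raises(ValueError):
            train_mlm([], tiny_config(), epochs=1, seed=0)


class TestExtractFeature:
    def _trained(self, **cfg_kw):
        cfg = tiny_config(**cfg_kw)
        corpus = [tokenize_document("ACGTTGCA" * 8, VOCAB, f"s{i}") for i in range(4)]
        return train_mlm(corpus, cfg, OptimizerSettings(batch_size=4), epochs=1, seed=0)

    def test_untrained_model_is_error(self):
        model = init_model(tiny_config(), 0)
        doc = tokenize_document("ACGTACGT", VOCAB, "x")
        with pytest.raises(ValueError, match="trained"):
            extract_feature(model, doc)

    def test_output_width_follows_d_out(self):
        doc = tokenize_document("ACGTACGTGGCC", VOCAB, "x")
        m1 = self._trained()  # d_out == d_model: final hidden state directly
        assert extract_feature(m1, doc).shape == (8,)
        m2 = self._trained(d_out=5)  # projection head
        assert extract_feature(m2, doc).shape == (5,)

    def test_invariant_to_right_padding(self):
        model = self._trained()
        doc = tokenize_document("ACGTTGCAACGT", VOCAB, "x")
        # same content, twice the padding
        wide = tokenize_document("ACGTTGCAACGT", VOCAB, "x")
        n = wide.attention_masks[0].sum()
        h_crop, _ = encoder_forward(model, doc.chunks[:1, :n], doc.attention_masks[:1, :n])
        h_full, _ = encoder_forward(model, wide.chunks[:1], wide.attention_masks[:1])
        np.testing.assert_allclose(h_crop[0, :n], h_full[0, :n], atol=1e-10)
        np.testing.assert_allclose(
            extract_feature(model, doc), extract_feature(model, wide), atol=1e-12
        )

    def test_single_chunk_aggregation_is_identity(self):
        model = self._trained()
        doc = tokenize_document("ACGTTGCAACGT", VOCAB, "x")
        feat = extract_feature(model, doc)
        h, _ = encoder_forward(
            model,
            doc.chunks[:1, : doc.attention_masks[0].sum()],
            doc.attention_masks[:1, : doc.attention_masks[0].sum()],
        )
        np.testing.assert_allclose(feat, h[0, 0], atol=1e-12)

    def test_duplicated_chunk_gives_same_vector(self):
        model = self._trained()
        doc = tokenize_document("ACGTTGCAACGT", VOCAB, "x")
        doubled = tokenize_document("ACGTTGCAACGT", VOCAB, "x")
        doubled.chunks = np.vstack([doc.chunks, doc.chunks])
        doubled.attention_masks = np.vstack([doc.attention_masks, doc.attention_masks])
        np.testing.assert_allclose(
            extract_feature(model, doc), extract_feature(model, doubled), atol=1e-12
        )
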