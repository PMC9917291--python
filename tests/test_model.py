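import numpy as np
import pytest

from thermoseq.encoders import encode_pair
from thermoseq.io import ProteinRecord
from thermoseq.model import (
    ModelConfig,
    ThermoNetClassifier,
    bilstm_summaries,
    forward,
    forward_batch,
    init_params,
    predict_batch,
    self_attention,
)

from conftest import random_sequence

TINY = dict(embed_dim=6, conv_filters=(8, 6, 6), lstm_hidden=4, attention_dim=4,
            mlp_hidden=(8, 6, 4), dropout=0.0)


def tiny_cfg(**over):
    kw = {**TINY, **over}
    return ModelConfig(**kw)


def make_batch(rng, n=4, lmax=48, n_bio=5):
    seqs = [random_sequence(rng, int(rng.integers(8, lmax))) for _ in range(n)]
    comp = np.stack([encode_pair(s, lmax).comp_tokens for s in seqs])
    phys = np.stack([encode_pair(s, lmax).phys_tokens for s in seqs])
    lengths = np.array([len(s) for s in seqs])
    bio = rng.normal(size=(n, n_bio))
    return comp, phys, lengths, bio


class TestForward:
    def test_score_in_open_unit_interval(self, rng):
        cfg = tiny_cfg(biofeature_dim=5, seed=1)
        pair = encode_pair(random_sequence(rng, 40), lmax=64)
        res = forward(pair, rng.normal(size=5), cfg)
        assert 0.0 < res.score < 1.0

    def test_bilstm_summaries_are_128_dim_at_defaults(self, rng):
        cfg = ModelConfig(use_biofeatures=False)
        params = init_params(cfg, np.random.default_rng(0))
        pair = encode_pair(random_sequence(rng, 35), lmax=40)
        h = bilstm_summaries(params, cfg, pair)
        assert h["comp"].shape == (128,) and h["phys"].shape == (128,)

    @pytest.mark.parametrize("flags", [
        dict(use_comp_channel=True, use_phys_channel=False, use_biofeatures=False),
        dict(use_comp_channel=False, use_phys_channel=True, use_biofeatures=False),
        dict(use_comp_channel=True, use_phys_channel=True, use_biofeatures=False),
        dict(use_comp_channel=False, use_phys_channel=False, use_biofeatures=True),
        dict(use_comp_channel=True, use_phys_channel=True, use_biofeatures=True),
        dict(use_attention=False, use_biofeatures=True),
        dict(use_attention=False, use_biofeatures=False),
        dict(scaled_attention=True, use_biofeatures=False),
    ])
    def test_ablation_arms_all_score(self, flags, rng):
        """Every encoding/biofeature/attention arm runs without code changes."""
        cfg = tiny_cfg(biofeature_dim=5, seed=2, **flags)
        pair = encode_pair(random_sequence(rng, 30), lmax=40)
        bio = rng.normal(size=5) if cfg.use_biofeatures else None
        res = forward(pair, bio, cfg)
        assert 0.0 < res.score < 1.0

    def test_no_input_source_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            tiny_cfg(use_comp_channel=False, use_phys_channel=False,
                     use_biofeatures=False)

    def test_padding_invariance(self, rng):
        """Appending padding never changes the forward-pass score."""
        cfg = tiny_cfg(biofeature_dim=3, seed=5)
        params = init_params(cfg, np.random.default_rng(5))
        seq = random_sequence(rng, 21)
        bio = rng.normal(size=3)
        scores = []
        for lmax in (21, 32, 64, 301):
            res = forward(encode_pair(seq, lmax), bio, cfg, params)
            scores.append(res.score)
        assert max(scores) - min(scores) == 0.0

    def test_all_padding_rejected(self, rng):
        cfg = tiny_cfg(use_biofeatures=False)
        params = init_params(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="all-padding"):
            forward_batch(params, cfg, np.zeros((1, 4), dtype=int),
                          np.zeros((1, 4), dtype=int), np.array([0]), None)

    def test_biofeature_dim_mismatch_raises(self, rng):
        cfg = tiny_cfg(biofeature_dim=5)
        pair = encode_pair(random_sequence(rng, 30), lmax=40)
        with pytest.raises(ValueError, match="dimension"):
            forward(pair, rng.normal(size=4), cfg)

    def test_gradient_sanity_on_random_batch(self, rng):
        from thermoseq.nn import bce_with_logits

        cfg = tiny_cfg(biofeature_dim=5, seed=3)
        params = init_params(cfg, np.random.default_rng(3))
        comp, phys, lengths, bio = make_batch(rng)
        logits = forward_batch(params, cfg, comp, phys, lengths, bio)
        loss = bce_with_logits(logits, np.array([1.0, 0.0, 1.0, 0.0]))
        loss.backward()
        for name, p in params.items():
            assert p.grad is not None and np.all(np.isfinite(p.grad)), name


class TestSelfAttention:
    def test_weights_sum_to_one_over_unmasked(self, rng):
        hm = rng.normal(size=(8, 6))
        mask = np.array([1, 1, 1, 1, 1, 0, 0, 0], dtype=float)
        _, weights = self_attention(hm, mask=mask, seed=0)
        sums = weights[:5, :].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)
        assert np.all(weights[:, 5:] == 0.0)

    def test_identical_rows_give_uniform_weights(self, rng):
        row = rng.normal(size=6)
        hm = np.tile(row, (4, 1))
        _, weights = self_attention(hm, seed=1)
        np.testing.assert_allclose(weights, 0.25, atol=1e-9)

    def test_single_unmasked_position_gets_weight_one(self, rng):
        hm = rng.normal(size=(5, 6))
        mask = np.array([0, 0, 1, 0, 0], dtype=float)
        wv = rng.normal(size=(6, 4))
        pooled, weights = self_attention(hm, mask=mask, wv=wv, seed=2)
        assert weights[2, 2] == pytest.approx(1.0)
        np.testing.assert_allclose(pooled, hm[2] @ wv, atol=1e-12)

    def test_empty_mask_raises(self, rng):
        with pytest.raises(ValueError, match="unmasked"):
            self_attention(rng.normal(size=(3, 4)), mask=np.zeros(3))


@pytest.fixture(scope="module")
def fitted(small_corpus):
    y = np.array([1 if r.label == "thermophilic" else 0 for r in small_corpus])
    clf = ThermoNetClassifier(
        **TINY, use_biofeatures=False, epochs=3, batch_size=16,
        lr=3e-3, seed=4, validation_fraction=0.2)
    return clf.fit(small_corpus, y), small_corpus, y


class TestTraining:
    def test_history_has_train_and_val_loss(self, fitted):
        clf, _, _ = fitted
        assert len(clf.history_["train_loss"]) == len(clf.history_["val_loss"])
        assert all(np.isfinite(v) for v in clf.history_["train_loss"])

    def test_predictions_partition_by_threshold(self, fitted):
        clf, corpus, _ = fitted
        proba = clf.predict_proba(corpus[:10])[:, 1]
        pred = clf.predict(corpus[:10])
        np.testing.assert_array_equal(pred, (proba >= 0.5).astype(int))

    def test_repeat_scoring_is_identical(self, fitted):
        clf, corpus, _ = fitted
        s1 = clf.predict_proba(corpus[:6])[:, 1]
        s2 = clf.predict_proba(corpus[:6])[:, 1]
        np.testing.assert_array_equal(s1, s2)

    def test_single_class_training_set_raises(self, small_corpus):
        pos = [r for r in small_corpus if r.label == "thermophilic"]
        clf = ThermoNetClassifier(**TINY, use_biofeatures=False, epochs=1)
        with pytest.raises(ValueError, match="both classes"):
            clf.fit(pos, np.ones(len(pos), dtype=int))

    def test_same_seed_reproduces_loss_curves(self, small_corpus):
        y = np.array([1 if r.label == "thermophilic" else 0
                      for r in small_corpus])
        histories = []
        for _ in range(2):
            clf = ThermoNetClassifier(**TINY, use_biofeatures=False, epochs=2,
                                      batch_size=16, seed=9)
            clf.fit(small_corpus[20:40], y[20:40])
            histories.append(clf.history_)
        assert histories[0] == histories[1]

    def test_standardization_fitted_on_training_split(self, small_corpus, rng):
        y = np.array([1 if r.label == "thermophilic" else 0
                      for r in small_corpus])
        bio = rng.normal(size=(len(small_corpus), 6)) * 10 + 3
        clf = ThermoNetClassifier(**TINY, epochs=1, batch_size=16, seed=0,
                                  validation_fraction=0.2)
        clf.fit(small_corpus, y, biofeatures=bio)
        assert clf.scaler_mean_.shape == (6,)
        assert np.all(clf.scaler_std_ > 0)


def test_functional_train_wrapper_on_encoded_triples(small_corpus):
    from thermoseq.descriptors import aac
    from thermoseq.model import train

    def triples(records):
        out = []
        for r in records:
            pair = encode_pair(r.sequence, lmax=1500, id=r.id)
            out.append((pair, aac(r.sequence, id=r.id),
                        1 if r.label == "thermophilic" else 0))
        return out

    cfg = tiny_cfg(biofeature_dim=20, epochs=2, batch_size=8, seed=3)
    clf, history = train(triples(small_corpus[20:36]),
                         triples(small_corpus[36:44]), cfg)
    assert len(history["train_loss"]) == len(history["val_loss"]) >= 1
    scores = clf.predict_proba(
        [r.sequence for r in small_corpus[44:48]],
        biofeatures=np.vstack([aac(r.sequence).values
                               for r in small_corpus[44:48]]))[:, 1]
    assert np.all((scores > 0) & (scores < 1))


class TestCheckpoint:
    def test_save_load_round_trip(self, small_corpus, tmp_path):
        y = np.array([1 if r.label == "thermophilic" else 0
                      for r in small_corpus])
        clf = ThermoNetClassifier(**TINY, use_biofeatures=False, epochs=2,
                                  batch_size=16, seed=6)
        clf.fit(small_corpus[20:40], y[20:40])
        path = tmp_path / "model.npz"
        clf.save(path)
        loaded = ThermoNetClassifier.load(path)
        s1 = clf.predict_proba(small_corpus[:8])[:, 1]
        s2 = loaded.predict_proba(small_corpus[:8])[:, 1]
        np.testing.assert_array_equal(s1, s2)

    def test_predict_batch_reports_per_record_errors(self, small_corpus, tmp_path):
        y = np.array([1 if r.label == "thermophilic" else 0
                      for r in small_corpus])
        # biofeature route exercises descriptor preconditions per record
        clf = ThermoNetClassifier(
            **TINY, use_biofeatures=True, epochs=1, batch_size=16, seed=6,
            descriptor_families=("aac",))
        clf.fit(small_corpus[20:40], y[20:40])
        path = tmp_path / "model.npz"
        clf.save(path)
        batch = list(small_corpus[:3]) + [ProteinRecord("short", "M")]
        results, errors = predict_batch(batch, path)
        assert len(results) == 3 and len(errors) == 1
        assert errors[0][0] == "short"
        for r in results:
            assert 0.0 < r.score < 1.0
            assert r.label in ("thermophilic", "mesophilic")
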