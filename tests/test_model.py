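"""Network architecture, gradients, training contract, persistence."""

import numpy as np
import pytest

from ontorel.corpus import CandidatePair
from ontorel.model import (
    ConfigurationError,
    ModelConfig,
    Vocabulary,
    build_model,
    build_vocabularies,
    embed_concept,
    load_model,
    predict,
    save_model,
    train,
)
from ontorel.preprocess import InstanceFeatures


def tiny_instances(n=12, seed=0):
    """Hand-sized instances over a 3-concept vocabulary; labels alternate."""
    rng = np.random.default_rng(seed)
    toks = ["entity", "raises", "level", "of", "with"]
    classes = ["0", "verb.change", "noun.attribute", "0", "0"]
    insts = []
    for i in range(n):
        k = 2 + int(rng.integers(0, 3))
        pair = CandidatePair(
            e1=f"a{i}", e2=f"b{i}", label="effect" if i % 2 else "negative",
            provenance="gold", doc_id="d", sentence_id=f"s{i}",
        )
        onto = ["C:1", "C:2", "C:3"][: 1 + i % 3]
        insts.append(
            InstanceFeatures(pair, toks[:k], classes[:k], onto, onto[:1] if i % 2 else [])
        )
    return insts


def tiny_config(**kw):
    base = dict(
        channels=("words", "wordnet", "concat_ancestors", "common_ancestors"),
        word_dim=5, wordnet_dim=4, ontology_dim=3, lstm_units=4, dense_units=3,
        dropout_rate=0.0, batch_size=4, max_epochs=5, patience=2, seed=3,
        train_word_embeddings=True,
    )
    base.update(kw)
    return ModelConfig(**base)


@pytest.fixture()
def tiny_model():
    insts = tiny_instances()
    cfg = tiny_config(max_len={"words": 5, "wordnet": 5, "concat_ancestors": 3, "common_ancestors": 2})
    vocabs = build_vocabularies(insts, cfg.channels)
    return build_model(cfg, vocabs), insts


class TestArchitecture:
    def test_shapes(self, tiny_model):
        model, _ = tiny_model
        H = model.config.lstm_units
        V = model.vocabs["concat_ancestors"].size
        assert model.params["concat_ancestors:E"].shape == (V, 3)
        assert model.params["concat_ancestors:Wx"].shape == (3, 4 * H)
        assert model.params["dense:W"].shape == (4 * H, 3)
        assert model.params["out:W"].shape == (3, 5)

    def test_vocabulary_counts_concepts_plus_pad_and_unk(self, tiny_model):
        model, insts = tiny_model
        n_concepts = len({t for i in insts for t in i.concat_ancestor_seq})
        assert model.vocabs["concat_ancestors"].size == n_concepts + 2

    def test_empty_channel_set_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(channels=())

    def test_words_only_baseline_builds(self):
        insts = tiny_instances()
        cfg = tiny_config(channels=("words",))
        model = build_model(cfg, build_vocabularies(insts, cfg.channels))
        assert set(model.params) == {"words:E", "words:Wx", "words:Wh", "words:b",
                                     "dense:W", "dense:b", "out:W", "out:b"}


class TestEmbedding:
    def test_one_hot_identity_and_padding(self, tiny_model):
        model, _ = tiny_model
        E = model.params["wordnet:E"]
        assert np.array_equal(embed_concept(E, 2), E[2])
        assert not np.any(embed_concept(E, 0))  # padding index -> zero vector
        with pytest.raises(IndexError):
            embed_concept(E, E.shape[0])

    def test_distinct_concepts_get_distinct_vectors(self, tiny_model):
        model, _ = tiny_model
        E = model.params["concat_ancestors:E"]
        assert not np.allclose(E[2], E[3])


class TestForward:
    def test_gradients_match_numeric_differentiation(self, tiny_model):
        model, insts = tiny_model
        batch = model.encode(insts[:6])
        y = model.encode_labels([i.pair for i in insts[:6]])
        probs, cache = model.forward(batch)
        grads = model.backward(batch, cache, y)
        rng = np.random.default_rng(1)
        eps = 1e-5
        for name, P in model.params.items():
            for _ in range(4):
                ix = tuple(rng.integers(0, s) for s in P.shape)
                orig = P[ix]
                P[ix] = orig + eps
                lp = model.loss(model.forward(batch)[0], y)
                P[ix] = orig - eps
                lm = model.loss(model.forward(batch)[0], y)
                P[ix] = orig
                assert (lp - lm) / (2 * eps) == pytest.approx(grads[name][ix], abs=1e-6)

    def test_probabilities_sum_to_one(self, tiny_model):
        model, insts = tiny_model
        for _, _, probs in predict(model, insts):
            assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_extending_padding_never_changes_pooled_output(self, tiny_model):
        model, insts = tiny_model
        batch = model.encode(insts)
        p1, _ = model.forward(batch)
        model.config.max_len = {ch: model.config.max_len[ch] + 7 for ch in model.config.channels}
        p2, _ = model.forward(model.encode(insts))
        assert np.allclose(p1, p2)

    def test_initial_loss_near_log_n_classes(self, tiny_model):
        model, insts = tiny_model
        rng = np.random.default_rng(0)
        y = rng.integers(0, 5, size=len(insts))
        probs, _ = model.forward(model.encode(insts))
        assert model.loss(probs, y) == pytest.approx(np.log(5), rel=0.1)

    def test_prediction_is_deterministic(self, tiny_model):
        model, insts = tiny_model
        a = predict(model, insts)
        b = predict(model, insts)
        for (_, la, pa), (_, lb, pb) in zip(a, b):
            assert la == lb and np.array_equal(pa, pb)

    def test_auto_negative_bypasses_network(self, tiny_model):
        model, insts = tiny_model
        auto = InstanceFeatures(
            insts[0].pair.relabeled("negative", "auto_negative"),
            insts[0].sdp_tokens, insts[0].wordnet_classes, [], [],
        )
        (_, label, probs) = predict(model, [auto])[0]
        assert label == "negative" and probs[0] == 1.0


class TestTraining:
    def test_loss_log_and_early_stopping_contract(self):
        insts = tiny_instances(n=40)
        cfg = tiny_config(max_epochs=30, patience=2)
        model = build_model(cfg, build_vocabularies(insts, cfg.channels))
        log = train(model, insts, seed=5)
        assert 1 <= len(log) <= 30
        val = [e["val_loss"] for e in log]
        if len(log) < 30:  # stopped early: the last `patience` epochs failed to improve
            assert min(val) < min(val[-2:]) + 1e-6
        # best weights restored: current validation loss equals the best seen
        rng = np.random.default_rng(5)
        order = rng.permutation(len(insts))
        cut = int(round(0.8 * len(insts)))
        val_set = [insts[i] for i in order[cut:]]
        probs, _ = model.forward(model.encode(val_set))
        y = model.encode_labels([i.pair for i in val_set])
        assert model.loss(probs, y) == pytest.approx(min(val), abs=1e-9)

    def test_too_few_instances_rejected(self):
        insts = tiny_instances(n=4)
        cfg = tiny_config()
        model = build_model(cfg, build_vocabularies(insts, cfg.channels))
        with pytest.raises(ValueError):
            train(model, insts)

    def test_detection_mode_collapses_positives(self):
        insts = tiny_instances()
        cfg = tiny_config(n_classes=2)
        model = build_model(cfg, build_vocabularies(insts, cfg.channels))
        y = model.encode_labels([i.pair for i in insts])
        assert set(y) <= {0, 1}
        assert model.config.labels == ("negative", "positive")


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, tiny_model):
        model, insts = tiny_model
        train(model, tiny_instances(n=20), seed=2)
        before = predict(model, insts)
        save_model(model, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        after = predict(loaded, insts)
        for (_, la, pa), (_, lb, pb) in zip(before, after):
            assert la == lb
            assert np.allclose(pa, pb)

    def test_missing_metadata(self, tmp_path):
        with pytest.raises(ConfigurationError):
            load_model(tmp_path / "nothing")

    def test_requesting_absent_channel(self, tmp_path):
        insts = tiny_instances()
        cfg = tiny_config(channels=("words",))
        model = build_model(cfg, build_vocabularies(insts, cfg.channels))
        save_model(model, tmp_path / "m")
        with pytest.raises(ConfigurationError, match="lacks"):
            load_model(tmp_path / "m", channels=("words", "common_ancestors"))

    def test_version_mismatch(self, tmp_path, tiny_model):
        import json

        model, _ = tiny_model
        save_model(model, tmp_path / "m")
        meta = json.loads((tmp_path / "m" / "model.json").read_text())
        meta["format_version"] = 99
        (tmp_path / "m" / "model.json").write_text(json.dumps(meta))
        with pytest.raises(ConfigurationError, match="version"):
            load_model(tmp_path / "m")


def test_vocabulary_encode_unknown_to_unk():
    v = Vocabulary(["a", "b"])
    assert v.encode(["a", "zz"]) == [2, 1]
    assert v.size == 4
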