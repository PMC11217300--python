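import numpy as np
import pytest

from spinegrader import nn
from spinegrader.cast import (AUGMENT_BOUNDS, CastConfig, CastModel,
                              GradingTaskSpec, UNKNOWN, augment_volume,
                              balanced_accuracy, binarize_ccs, grading_loss,
                              read_labels_csv, sample_augmentation,
                              sequence_dropout)

TASKS = [GradingTaskSpec("degeneration", 2), GradingTaskSpec("pfirrmann", 5)]


@pytest.fixture(scope="module")
def model():
    return CastModel(TASKS, np.random.default_rng(0), CastConfig.tiny())


def _volume(rng, h=28, w=56, s=3):
    return rng.random((h, w, s))


class TestSlicePooling:
    def test_single_slice_gets_weight_one(self, model, rng):
        token = model.slice_encode_and_pool(_volume(rng, s=1), 17, "T2w")
        assert token.slice_weights.shape == (1,)
        assert token.slice_weights[0] == pytest.approx(1.0)

    def test_weights_sum_to_one(self, model, rng):
        token = model.slice_encode_and_pool(_volume(rng, s=5), 17, "T2w")
        assert token.slice_weights.min() >= 0
        assert token.slice_weights.sum() == pytest.approx(1.0)

    def test_slice_permutation_equivariance(self, model, rng):
        vol = _volume(rng, s=4)
        perm = [2, 0, 3, 1]
        t1 = model.slice_encode_and_pool(vol, 17, "T2w")
        t2 = model.slice_encode_and_pool(vol[:, :, perm], 17, "T2w")
        assert np.allclose(t1.slice_weights[perm], t2.slice_weights, atol=1e-9)
        assert np.allclose(t1.embedding.data, t2.embedding.data, atol=1e-9)

    def test_duplicated_slice_gets_equal_weights(self, model, rng):
        vol = _volume(rng, s=1)
        dup = np.concatenate([vol, vol], axis=2)
        token = model.slice_encode_and_pool(dup, 17, "T2w")
        assert token.slice_weights[0] == pytest.approx(token.slice_weights[1])


class TestTransformer:
    def test_single_token_forward(self, model, rng):
        tok = model.slice_encode_and_pool(_volume(rng), 17, "T2w")
        out = model.transformer_contextualize([tok])
        assert out[0].embedding.shape == (model.cfg.dim,)
        assert np.all(np.isfinite(out[0].embedding.data))

    def test_variable_token_and_sequence_counts(self, model, rng):
        for n_tokens, seqs in [(1, ["T1w"]), (5, ["T1w", "T2w"]),
                               (24, ["T1w", "T2w", "STIR", "FLAIR"])]:
            tokens = [model.slice_encode_and_pool(_volume(rng), i % 23,
                                                  seqs[i % len(seqs)])
                      for i in range(n_tokens)]
            out = model.transformer_contextualize(tokens)
            assert len(out) == n_tokens

    def test_unknown_sequence_maps_to_other_embedding(self, model, rng):
        vol = _volume(rng)
        t_other = model.slice_encode_and_pool(vol, 3, "OTHER")
        t_junk = model.slice_encode_and_pool(vol, 3, "DIXON")
        a = model.transformer_contextualize([t_other])[0].embedding.data
        b = model.transformer_contextualize([t_junk])[0].embedding.data
        assert np.allclose(a, b)


class TestCrossSequencePool:
    def test_single_sequence_unit_passes_through(self, model, rng):
        tok = model.slice_encode_and_pool(_volume(rng), 17, "T1w")
        ctx = model.transformer_contextualize([tok])
        units = model.cross_sequence_pool(ctx)
        emb, w = units[17]
        assert np.allclose(w, [1.0])
        assert np.allclose(emb.data, ctx[0].embedding.data, atol=1e-12)

    def test_two_sequences_convex_combination(self, model, rng):
        toks = [model.slice_encode_and_pool(_volume(rng), 17, s)
                for s in ("T1w", "T2w")]
        ctx = model.transformer_contextualize(toks)
        emb, w = model.cross_sequence_pool(ctx)[17]
        assert w.sum() == pytest.approx(1.0) and (w >= 0).all()
        manual = w[0] * ctx[0].embedding.data + w[1] * ctx[1].embedding.data
        assert np.allclose(emb.data, manual, atol=1e-9)


class TestForwardStudy:
    @pytest.mark.parametrize("seqs", [["T1w"], ["T2w"], ["T1w", "T2w"]])
    def test_any_sequence_subset_supported(self, model, rng, seqs):
        volumes = [(lvl, s, _volume(rng)) for lvl in (16, 17, 18) for s in seqs]
        probs, attention = model.forward_study(volumes)
        for task in TASKS:
            assert set(probs[task.name]) == {16, 17, 18}
            for p in probs[task.name].values():
                assert p.data.sum() == pytest.approx(1.0)
        for _, _, w in attention["slice"]:
            assert np.asarray(w).sum() == pytest.approx(1.0)

    def test_empty_study_is_defined(self, model):
        probs, _ = model.forward_study([])
        assert all(not v for v in probs.values())

    def test_heads_are_independent(self, model, rng):
        volumes = [(17, "T2w", _volume(rng))]
        before = model.forward_study(volumes)[0]["pfirrmann"][17].data.copy()
        saved = model.heads[0].weight.data.copy()
        model.heads[0].weight.data += 1.0      # perturb the other task's head
        after = model.forward_study(volumes)[0]["pfirrmann"][17].data
        model.heads[0].weight.data[...] = saved
        assert np.allclose(before, after)


class TestGradingLoss:
    def _probs_from_logits(self, logits):
        return {i: logits[i].softmax(axis=-1) for i in range(logits.shape[0])}

    def test_all_unknown_no_flag_is_exactly_zero(self):
        logits = nn.Tensor(np.random.default_rng(0).normal(size=(4, 2)),
                           requires_grad=True)
        probs = {"t": self._probs_from_logits(logits)}
        loss = grading_loss(probs, {"t": {i: UNKNOWN for i in range(4)}},
                            {"t": None})
        assert loss.item() == 0.0

    def test_known_labels_reduce_to_masked_cross_entropy(self):
        rng = np.random.default_rng(1)
        logits = nn.Tensor(rng.normal(size=(3, 2)), requires_grad=True)
        probs = {"t": self._probs_from_logits(logits)}
        labels = {"t": {0: 1, 1: UNKNOWN, 2: 0}}
        loss = grading_loss(probs, labels, {"t": 1})   # flag must be ignored
        p = np.exp(logits.data - logits.data.max(axis=1, keepdims=True))
        p = p / p.sum(axis=1, keepdims=True)
        expected = -np.log(p[0, 1]) - np.log(p[2, 0])
        assert loss.item() == pytest.approx(expected, abs=1e-9)

    def test_mil_gradient_only_at_argmax_unit(self):
        rng = np.random.default_rng(2)
        logits = nn.Tensor(rng.normal(size=(5, 2)), requires_grad=True)
        probs = {"t": self._probs_from_logits(logits)}
        labels = {"t": {i: UNKNOWN for i in range(5)}}
        loss = grading_loss(probs, labels, {"t": 1})
        loss.backward()
        pos = probs["t"]
        argmax = int(np.argmax([pos[i].data[-1] for i in range(5)]))
        grads = np.abs(logits.grad).sum(axis=1)
        assert grads[argmax] > 1e-8
        others = np.delete(grads, argmax)
        assert np.all(others < 1e-12)
        # finite-difference check on the argmax unit
        eps = 1e-6
        base = loss.item()
        logits.data[argmax, 1] += eps
        probs2 = {"t": self._probs_from_logits(logits)}
        lp = grading_loss(probs2, labels, {"t": 1}).item()
        logits.data[argmax, 1] -= eps
        fd = (lp - base) / eps
        assert fd == pytest.approx(logits.grad[argmax, 1], abs=1e-4)

    def test_mil_negative_study_pushes_most_positive_down(self):
        logits = nn.Tensor(np.array([[0.0, 2.0], [0.0, -1.0]]),
                           requires_grad=True)
        probs = {"t": self._probs_from_logits(logits)}
        labels = {"t": {0: UNKNOWN, 1: UNKNOWN}}
        loss = grading_loss(probs, labels, {"t": 0})
        loss.backward()
        assert loss.item() > 0
        assert logits.grad[0, 1] > 0          # positive logit pushed down

    def test_out_of_range_label_rejected(self):
        logits = nn.Tensor(np.zeros((1, 2)))
        probs = {"t": {0: logits[0].softmax(axis=-1)}}
        with pytest.raises(ValueError):
            grading_loss(probs, {"t": {0: 5}}, {})


class TestSequenceDropout:
    def _study(self, rng):
        return [(i, s, _volume(rng, 8, 8, 1)) for i in range(2)
                for s in ("T1w", "T2w")]

    def test_zero_probabilities_are_identity(self, rng):
        vols = self._study(rng)
        assert sequence_dropout(vols, rng, 0.0, 0.0) == vols

    def test_drop_both_leaves_empty_but_defined(self, rng):
        vols = self._study(rng)
        out = sequence_dropout(vols, rng, 0.0, 1.0)
        assert out == []
        model = CastModel(TASKS, np.random.default_rng(0), CastConfig.tiny())
        probs, _ = model.forward_study(out)     # degenerate forward pass
        assert all(not v for v in probs.values())

    def test_empirical_rates_match_probabilities(self, rng):
        vols = self._study(rng)
        counts = {0: 0, 1: 0, 2: 0}
        n = 10_000
        for _ in range(n):
            out = sequence_dropout(vols, rng, 0.4, 0.1)
            seqs = {s for _, s, _ in out}
            counts[2 - len(seqs)] += 1
        assert counts[1] / n == pytest.approx(0.4, abs=0.02)
        assert counts[2] / n == pytest.approx(0.1, abs=0.02)


class TestMetrics:
    def test_perfect_predictions(self):
        assert balanced_accuracy([0, 1, 1, 0], [0, 1, 1, 0]) == 1.0

    def test_hand_computed_binary_case(self):
        # class 0 recall 1.0 (2/2), class 1 recall 0.5 (1/2)
        preds = [0, 0, 1, 0]
        labels = [0, 0, 1, 1]
        assert balanced_accuracy(preds, labels) == pytest.approx(0.75)

    def test_constant_predictor_scores_chance(self):
        assert balanced_accuracy([1] * 10, [0] * 5 + [1] * 5) == \
            pytest.approx(0.5)

    def test_unknown_labels_excluded(self):
        assert balanced_accuracy([0, 1, 0], [0, 1, UNKNOWN]) == 1.0

    def test_absent_class_warns(self):
        with pytest.warns(UserWarning):
            balanced_accuracy([0, 0], [0, 0])

    @pytest.mark.parametrize("grade,expected", [(1, 0), (2, 1), (3, 1), (4, 1)])
    def test_ccs_binarisation(self, grade, expected):
        assert binarize_ccs(grade) == expected

    def test_ccs_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            binarize_ccs(0)


class TestAugmentation:
    def test_sampled_parameters_respect_bounds(self, rng):
        for _ in range(200):
            p = sample_augmentation(rng)
            assert abs(p["rotation_deg"]) <= AUGMENT_BOUNDS["rotation_deg"]
            assert abs(p["translation_px"]) <= AUGMENT_BOUNDS["translation_px"]
            assert abs(p["scale_frac"]) <= AUGMENT_BOUNDS["scale_frac"]
            assert abs(p["intensity_frac"]) <= AUGMENT_BOUNDS["intensity_frac"]

    def test_augment_preserves_shape(self, rng):
        vol = _volume(rng, 28, 56, 3)
        out = augment_volume(vol, sample_augmentation(rng))
        assert out.shape == vol.shape


def test_labels_csv_with_compression_default_negative(tmp_path):
    csv = tmp_path / "labels.csv"
    csv.write_text(
        "study,level,task,label\n"
        "s1,L1,metastasis,1\n"
        "s1,L2,metastasis,UNKNOWN\n"
        "s1,L1,compression,1\n"
        "s1,L2,fracture,0\n")
    tasks = [GradingTaskSpec("metastasis", 2, unit="vertebra"),
             GradingTaskSpec("fracture", 2, unit="vertebra"),
             GradingTaskSpec("compression", 2, unit="vertebra")]
    labels, flags = read_labels_csv(csv, tasks)
    assert labels["s1"]["metastasis"]["L1"] == 1
    assert labels["s1"]["metastasis"]["L2"] == UNKNOWN
    # compression: unlabelled levels default to negative, not unknown
    assert labels["s1"]["compression"]["L2"] == 0
    assert labels["s1"]["compression"]["L1"] == 1
    assert flags == {}
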