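import math

import numpy as np
import pytest

from spinegrader import levels
from spinegrader.scan_io import SagittalScan
from spinegrader.synthetic import PhantomSpec, generate_phantom, instances_from_truth
from spinegrader.vfr import CORNER_KINDS, Landmark, QuadDetection, VertebraInstance


def test_ladder_has_23_levels_in_anatomical_order():
    assert len(levels.LADDER) == 23
    assert levels.LADDER[0] == "C3" and levels.LADDER[-1] == "S1"
    assert levels.LADDER.index("T12") + 1 == levels.LADDER.index("L1")


def _instance_with_rows(r0, r1, c0=10.0, c1=24.0, n_slices=1):
    quads = []
    for s in range(n_slices):
        corners = {
            "AS": Landmark("AS", np.array([r0, c0]), 1.0, np.zeros(2)),
            "PS": Landmark("PS", np.array([r0, c1]), 1.0, np.zeros(2)),
            "AI": Landmark("AI", np.array([r1, c0]), 1.0, np.zeros(2)),
            "PI": Landmark("PI", np.array([r1, c1]), 1.0, np.zeros(2)),
        }
        cen = Landmark("centroid", np.array([(r0 + r1) / 2, (c0 + c1) / 2]), 1.0)
        quads.append(QuadDetection(slice_index=s, corners=corners,
                                   centroid=cen, completed={}, confidence=1.0))
    return VertebraInstance(quads=quads)


class TestAppearanceVolume:
    def test_box_expanded_by_half_in_each_direction(self):
        # rows [100, 140) expand to [80, 160); verify via a row-ramp scan
        ramp = np.tile(np.arange(256, dtype=np.float32)[:, None], (1, 64))
        ramp = np.repeat(ramp[None], 3, axis=0)
        scan = SagittalScan(voxels=ramp, pixel_spacing_mm=(1, 1),
                            slice_spacing_mm=1)
        inst = _instance_with_rows(100.0, 140.0, n_slices=3)
        vol = levels.extract_appearance_volume(scan, inst,
                                               out_shape=(64, 64, 4))
        col = vol[:, 32, :].max(axis=1)   # central slices carry the ramp
        assert col[0] == pytest.approx(80.0, abs=1.0)
        assert col[-1] == pytest.approx(160.0, abs=2.0)

    def test_border_instance_zero_padded(self):
        scan = SagittalScan(voxels=np.ones((1, 64, 64), dtype=np.float32),
                            pixel_spacing_mm=(1, 1), slice_spacing_mm=1)
        inst = _instance_with_rows(0.0, 30.0, c0=0.0, c1=30.0)
        vol = levels.extract_appearance_volume(scan, inst, out_shape=(32, 32, 4))
        assert vol.shape == (32, 32, 4)
        assert vol.min() == 0.0           # padding visible

    def test_output_shape_contract(self):
        scan, truth = generate_phantom(PhantomSpec(n_vertebrae=4, seed=2))
        inst = instances_from_truth(truth)[1]
        vol = levels.extract_appearance_volume(scan, inst)
        assert vol.shape == (224, 224, 16)

    def test_empty_instance_rejected(self):
        scan = SagittalScan(voxels=np.ones((1, 64, 64), dtype=np.float32),
                            pixel_spacing_mm=(1, 1), slice_spacing_mm=1)
        with pytest.raises(ValueError):
            levels.extract_appearance_volume(scan, VertebraInstance(quads=[]))


class TestProbHeightMap:
    def test_band_rows_hold_the_softmax_vector(self):
        inst = _instance_with_rows(40.0, 60.0)
        logits = np.zeros((1, 23))
        logits[0, 5] = 4.0
        p = levels.build_prob_height_map([inst], logits, 100)
        expected = levels.temperature_softmax(logits[0], 0.1)
        assert np.allclose(p[40:60], expected[None, :])
        assert not p[:40].any() and not p[60:].any()

    def test_low_temperature_sharpens(self):
        logits = np.zeros(23)
        logits[0], logits[1] = 2.0, 1.0
        sharp = levels.temperature_softmax(logits, 0.1)
        soft = levels.temperature_softmax(logits, 1.0)
        assert sharp[0] >= 0.9999
        assert soft[0] < 0.9

    def test_disjoint_bands_are_independent(self):
        a = _instance_with_rows(10.0, 20.0)
        b = _instance_with_rows(50.0, 60.0)
        la = np.zeros(23); la[3] = 5.0
        lb = np.zeros(23); lb[9] = 5.0
        joint = levels.build_prob_height_map([a, b], np.stack([la, lb]), 80)
        alone = levels.build_prob_height_map([a], la[None], 80)
        assert np.allclose(joint[10:20], alone[10:20])

    def test_rows_in_bands_are_normalised(self):
        a = _instance_with_rows(10.0, 30.0)
        b = _instance_with_rows(25.0, 45.0)    # overlapping bands
        rng = np.random.default_rng(0)
        p = levels.build_prob_height_map([a, b], rng.normal(size=(2, 23)), 60)
        sums = p[10:45].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_band_beyond_scan_height_rejected(self):
        inst = _instance_with_rows(40.0, 60.0)
        with pytest.raises(ValueError):
            levels.build_prob_height_map([inst], np.zeros((1, 23)), 50)


class TestContextNet:
    def test_all_zero_map_is_defined(self):
        net = levels.ContextNet(np.random.default_rng(0))
        out = net.refine(np.zeros((48, 23)))
        assert out.shape == (48, 23)
        assert np.all(np.isfinite(out))
        assert not out.any()              # no bands -> nothing to refine

    def test_band_rows_renormalised(self):
        net = levels.ContextNet(np.random.default_rng(0))
        p = np.zeros((48, 23))
        p[10:20, 4] = 1.0
        out = net.refine(p)
        assert np.allclose(out[10:20].sum(axis=1), 1.0)
        assert not out[:10].any() and not out[20:].any()

    def test_odd_height_handled(self):
        net = levels.ContextNet(np.random.default_rng(0))
        out = net.refine(np.zeros((47, 23)))
        assert out.shape == (47, 23)


def _one_hot_probs(names):
    p = np.full((len(names), 23), 1e-9)
    for i, n in enumerate(names):
        p[i, levels.LEVEL_INDEX[n]] = 1.0
    return p / p.sum(axis=1, keepdims=True)


class TestBeamSearch:
    def test_one_hot_sequence_decodes_exactly_with_zero_score(self):
        probs = _one_hot_probs(["L3", "L4", "L5"])
        seq = levels.beam_search_decode(probs)
        assert seq.labels == ["L3", "L4", "L5"]
        assert seq.score == pytest.approx(0.0, abs=1e-6)
        assert not any(seq.skip_flags) and not seq.transitional

    def test_duplicate_argmax_resolved_against_oracle(self):
        probs = _one_hot_probs(["L4", "L4"])
        seq = levels.beam_search_decode(probs)
        assert len(set(seq.labels)) == 2          # no duplicate emitted
        assert "L4" in seq.labels                 # one keeps the argmax
        oracle = _viterbi(probs)
        assert seq.score == pytest.approx(oracle[1], abs=1e-9)

    def test_gap_sequence_pays_skip_penalty(self):
        probs = _one_hot_probs(["L2", "L5"])
        seq = levels.beam_search_decode(probs)
        oracle = _viterbi(probs)
        assert seq.score == pytest.approx(oracle[1], abs=1e-9)
        assert seq.labels == ["L2", "L5"]
        assert seq.skip_flags == [False, True]
        assert seq.score == pytest.approx(2 * math.log(0.2), abs=1e-6)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_oracle_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 9))
        probs = rng.dirichlet(np.full(23, 0.3), size=n)
        seq = levels.beam_search_decode(probs)
        labels, score = _viterbi(probs)
        assert seq.score == pytest.approx(score, abs=1e-9)
        assert seq.labels == labels

    @pytest.mark.parametrize("seed", range(10))
    def test_decoded_sequences_are_structurally_valid(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(2, 12))
        probs = rng.dirichlet(np.full(23, 0.2), size=n)
        seq = levels.beam_search_decode(probs)
        pos = [levels.LEVEL_INDEX[l] if l in levels.LEVEL_INDEX
               else levels.VIRTUAL_POS for l in seq.labels]
        assert all(b > a for a, b in zip(pos, pos[1:]))
        assert len(set(seq.labels)) == len(seq.labels)

    def test_too_many_instances_rejected(self):
        probs = np.full((25, 23), 1.0 / 23)
        with pytest.raises(ValueError):
            levels.beam_search_decode(probs)


def _viterbi(probs, lambda_skip=math.log(0.2), lambda_var=math.log(0.1)):
    """Independent exact decoder: dynamic programming over (slot, used_var).

    The scoring model matches beam_search_decode: strictly increasing ladder
    positions, (gap-1)*lambda_skip for skipped levels, lambda_var for the
    virtual lumbosacral slot (emitting L5's probability).
    """
    logp = np.log(np.maximum(probs, 1e-12))
    slots = [(float(i), levels.LADDER[i], i) for i in range(23)]
    slots.append((levels.VIRTUAL_POS, levels.VIRTUAL_LEVEL,
                  levels.LEVEL_INDEX["L5"]))
    slots.sort()
    n = probs.shape[0]
    best = {}
    for pos, label, col in slots:
        var = label == levels.VIRTUAL_LEVEL
        score = logp[0, col] + (lambda_var if var else 0.0)
        best[(pos, var)] = (score, [label])
    for i in range(1, n):
        nxt = {}
        for (pos, var), (score, labels) in best.items():
            for spos, label, col in slots:
                if spos <= pos:
                    continue
                is_var = label == levels.VIRTUAL_LEVEL
                if is_var and var:
                    continue
                gap = int(math.ceil(spos - pos))
                s = score + logp[i, col] + (gap - 1) * lambda_skip + \
                    (lambda_var if is_var else 0.0)
                key = (spos, var or is_var)
                if key not in nxt or s > nxt[key][0]:
                    nxt[key] = (s, labels + [label])
        best = nxt
    score, labels = max(best.values(), key=lambda t: t[0])
    return labels, score
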