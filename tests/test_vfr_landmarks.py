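import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from spinegrader import vfr
from spinegrader.synthetic import PhantomSpec, generate_phantom, truth_slice_quads


def make_landmark(kind, pos, pointing=None, score=1.0):
    return vfr.Landmark(kind=kind, position=np.asarray(pos, dtype=float),
                        score=score,
                        pointing=None if pointing is None
                        else np.asarray(pointing, dtype=float))


def exact_landmarks(corners, centroid):
    out = [make_landmark("centroid", centroid)]
    for ci, kind in enumerate(vfr.CORNER_KINDS):
        out.append(make_landmark(kind, corners[ci], centroid - corners[ci]))
    return out


class TestExtractLandmarks:
    def test_all_zero_heatmaps_give_empty_list(self):
        assert vfr.extract_landmarks(np.zeros((13, 32, 32))) == []

    def test_roundtrip_from_phantom_targets(self):
        scan, truth = generate_phantom(
            PhantomSpec(n_vertebrae=6, lowest_level="L5", noise_sd=0.0, seed=7))
        s = scan.n_slices // 2
        quads = truth_slice_quads(truth, s)
        target, _ = vfr.build_targets(quads, scan.shape[1:])
        found = vfr.extract_landmarks(target)
        by_kind = {k: [lm for lm in found if lm.kind == k]
                   for k in vfr.ALL_KINDS}
        for kind in vfr.ALL_KINDS:
            assert len(by_kind[kind]) == 6

    def test_close_peaks_suppressed_keeping_higher(self):
        tensor = np.zeros((13, 32, 32))
        tensor[4, 10, 10] = 0.9
        tensor[4, 10, 12] = 0.6      # 2 px away, min separation 4
        found = vfr.extract_landmarks(tensor, min_separation=4)
        cents = [lm for lm in found if lm.kind == "centroid"]
        assert len(cents) == 1
        assert cents[0].score == pytest.approx(0.9)

    def test_subpixel_refinement_recovers_offgrid_peak(self):
        quad = (np.array([[10.2, 10.7], [10.2, 22.7], [22.2, 10.7],
                          [22.2, 22.7]]), np.array([16.2, 16.7]))
        target, _ = vfr.build_targets([quad], (40, 40))
        found = vfr.extract_landmarks(target)
        cent = next(lm for lm in found if lm.kind == "centroid")
        assert np.linalg.norm(cent.position - quad[1]) < 0.05


class TestGrouping:
    def test_single_exact_quad(self):
        corners = np.array([[10.0, 10.0], [10.0, 20.0], [20.0, 10.0],
                            [20.0, 20.0]])
        centroid = corners.mean(axis=0)
        quads = vfr.group_landmarks(exact_landmarks(corners, centroid))
        assert len(quads) == 1
        assert not any(quads[0].completed.values())
        assert np.allclose(quads[0].corner_array(), corners)

    def test_far_pointing_corner_left_out_and_completed(self):
        corners = np.array([[10.0, 10.0], [10.0, 20.0], [20.0, 10.0],
                            [20.0, 20.0]])
        centroid = corners.mean(axis=0)
        lms = exact_landmarks(corners, centroid)
        lms[2] = make_landmark("PS", corners[1], pointing=np.array([300.0, 0.0]))
        quads = vfr.group_landmarks(lms, tolerance=3.0)
        assert len(quads) == 1
        assert quads[0].completed["PS"]
        # point reflection of AI through the centroid reproduces PS exactly
        assert np.allclose(quads[0].corners["PS"].position, corners[1])

    def test_two_adjacent_vertebrae_grouped_correctly(self):
        scan, truth = generate_phantom(
            PhantomSpec(n_vertebrae=2, lowest_level="L5", noise_sd=0.0, seed=3))
        s = scan.n_slices // 2
        lms = []
        for corners, centroid in truth_slice_quads(truth, s):
            lms.extend(exact_landmarks(corners, centroid))
        quads = vfr.group_landmarks(lms)
        assert len(quads) == 2
        truth_cents = sorted(c[1][0] for c in truth_slice_quads(truth, s))
        found_cents = sorted(q.centroid.position[0] for q in quads)
        assert np.allclose(truth_cents, found_cents, atol=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_greedy_matches_optimal_assignment(self, seed):
        """Greedy grouping equals the exhaustive (Hungarian) optimum on
        perturbed phantom pointing fields."""
        rng = np.random.default_rng(seed)
        scan, truth = generate_phantom(
            PhantomSpec(n_vertebrae=3 + seed % 4, lowest_level="S1",
                        noise_sd=0.0, seed=100 + seed))
        s = scan.n_slices // 2
        lms = []
        for corners, centroid in truth_slice_quads(truth, s):
            for ci, kind in enumerate(vfr.CORNER_KINDS):
                noise = rng.normal(0, 1.0, size=2)
                lms.append(make_landmark(kind, corners[ci],
                                         centroid - corners[ci] + noise))
            lms.append(make_landmark("centroid", centroid))
        tol = vfr.default_group_tolerance(lms)
        quads = vfr.group_landmarks(lms, tolerance=tol)
        greedy_err = _total_error(quads)
        optimal_err = _hungarian_error(lms, tol)
        assert greedy_err <= optimal_err * 1.05 + 1e-9

    def test_leftover_corner_quadruple_yields_inferred_centroid(self):
        corners = np.array([[10.0, 10.0], [10.0, 20.0], [20.0, 10.0],
                            [20.0, 20.0]])
        centroid = corners.mean(axis=0)
        lms = [lm for lm in exact_landmarks(corners, centroid)
               if lm.kind != "centroid"]
        quads = vfr.group_landmarks(lms, tolerance=3.0)
        assert len(quads) == 1
        assert quads[0].completed["centroid"]
        assert np.allclose(quads[0].centroid.position, centroid, atol=1e-9)


def _total_error(quads):
    total = 0.0
    for q in quads:
        for kind, lm in q.corners.items():
            if q.completed.get(kind):
                continue
            total += float(np.linalg.norm(lm.endpoint() - q.centroid.position))
    return total


def _hungarian_error(landmarks, tol):
    centroids = [lm for lm in landmarks if lm.kind == "centroid"]
    total = 0.0
    for kind in vfr.CORNER_KINDS:
        corners = [lm for lm in landmarks if lm.kind == kind]
        if not corners or not centroids:
            continue
        big = 1e6
        cost = np.full((len(corners), len(centroids)), big)
        for i, cor in enumerate(corners):
            for j, cen in enumerate(centroids):
                e = float(np.linalg.norm(cor.endpoint() - cen.position))
                if e <= tol:
                    cost[i, j] = e
        ri, ci = linear_sum_assignment(cost)
        total += float(cost[ri, ci][cost[ri, ci] < big].sum())
    return total


class TestRobustCompletion:
    def test_parallelogram_completion_is_exact(self):
        corners = {"AS": make_landmark("AS", (0.0, 0.0)),
                   "PS": make_landmark("PS", (0.0, 4.0)),
                   "AI": make_landmark("AI", (2.0, 0.0))}
        centroid = np.array([1.0, 2.0])
        pos = vfr.complete_missing_corner(corners, centroid, "PI")
        assert np.allclose(pos, [2.0, 4.0], atol=1e-9)

    def test_formula_is_point_reflection_for_any_quad(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            quad = rng.normal(size=(4, 2)) * 10
            centroid = quad.mean(axis=0)
            corners = {k: make_landmark(k, quad[i])
                       for i, k in enumerate(vfr.CORNER_KINDS) if k != "PI"}
            pos = vfr.complete_missing_corner(corners, centroid, "PI")
            assert np.allclose(pos, 2 * centroid - quad[0], atol=1e-12)

    def test_two_missing_corners_rejected(self):
        corners = {"AS": make_landmark("AS", (0.0, 0.0)),
                   "PS": make_landmark("PS", (0.0, 4.0))}
        with pytest.raises(ValueError):
            vfr.complete_missing_corner(corners, np.array([1.0, 2.0]), "PI")

    def test_sheared_phantom_completion_within_fifteen_percent_of_diagonal(self):
        scan, truth = generate_phantom(
            PhantomSpec(n_vertebrae=7, lowest_level="S1", noise_sd=0.0, seed=2))
        s = scan.n_slices // 2
        for corners, centroid in truth_slice_quads(truth, s):
            diag = np.linalg.norm(corners[0] - corners[3])
            for missing in range(4):
                kinds = [k for i, k in enumerate(vfr.CORNER_KINDS)
                         if i != missing]
                lms = {k: make_landmark(k, corners[vfr.CORNER_KINDS.index(k)])
                       for k in kinds}
                pos = vfr.complete_missing_corner(
                    lms, centroid, vfr.CORNER_KINDS[missing])
                err = np.linalg.norm(pos - corners[missing])
                assert err <= 0.15 * diag


class TestInferCentroid:
    def _corners(self, centroid, spread=0.0, rng=None):
        quad = np.array([[-5.0, -5.0], [-5.0, 5.0], [5.0, -5.0], [5.0, 5.0]])
        out = []
        for i, kind in enumerate(vfr.CORNER_KINDS):
            pos = centroid + quad[i]
            noise = rng.normal(0, spread, size=2) if rng is not None else 0.0
            out.append(make_landmark(kind, pos, centroid - pos + noise))
        return out

    def test_exact_fields_recover_centroid(self):
        centroid = np.array([12.0, 15.0])
        got = vfr.infer_centroid(self._corners(centroid), tolerance=2.0)
        assert got is not None
        assert np.allclose(got.position, centroid, atol=1e-9)

    def test_spread_endpoints_rejected(self):
        centroid = np.array([12.0, 15.0])
        corners = self._corners(centroid, spread=10.0,
                                rng=np.random.default_rng(0))
        assert vfr.infer_centroid(corners, tolerance=1.0) is None

    def test_three_corners_not_applicable(self):
        centroid = np.array([12.0, 15.0])
        assert vfr.infer_centroid(self._corners(centroid)[:3],
                                  tolerance=2.0) is None
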