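from itertools import combinations

import numpy as np
import pytest

from tripoint import (
    DegenerateGeometryError,
    LandmarkPair,
    Point3,
    TooFewLandmarksError,
    edge_discrepancy,
    point_error,
    rank_landmarks,
    system_error,
    triangle_error,
)

from .conftest import random_rigid, rigid_pairs


def pair(label, p, r):
    return LandmarkPair(
        label=label,
        p=Point3.from_array(p, space="P"),
        r=Point3.from_array(r, space="R"),
    )


class TestEdgeDiscrepancy:
    def test_equal_lengths_zero(self):
        i = pair("a", (0, 0, 0), (5, 5, 5))
        j = pair("b", (3, 0, 0), (5, 5, 8))
        assert edge_discrepancy(i, j) == 0.0

    def test_hand_value_two_vs_one(self):
        # |P edge| = 2, |R edge| = 1 -> 1 / 1.5
        i = pair("a", (0, 0, 0), (0, 0, 0))
        j = pair("b", (2, 0, 0), (1, 0, 0))
        assert edge_discrepancy(i, j) == pytest.approx(1 / 1.5, abs=1e-12)

    def test_symmetric_in_images(self, rng):
        for _ in range(20):
            pts = rng.uniform(-10, 10, (2, 2, 3))
            i = pair("a", pts[0, 0], pts[0, 1])
            j = pair("b", pts[1, 0], pts[1, 1])
            i_swap = pair("a", pts[0, 1], pts[0, 0])
            j_swap = pair("b", pts[1, 1], pts[1, 0])
            assert edge_discrepancy(i, j) == pytest.approx(
                edge_discrepancy(i_swap, j_swap), abs=1e-12
            )

    def test_range(self, rng):
        for _ in range(50):
            i = pair("a", rng.uniform(-9, 9, 3), rng.uniform(-9, 9, 3))
            j = pair("b", rng.uniform(-9, 9, 3), rng.uniform(-9, 9, 3))
            assert 0.0 <= edge_discrepancy(i, j) < 2.0

    def test_coincident_in_both_images_rejected(self):
        i = pair("a", (1, 1, 1), (2, 2, 2))
        j = pair("b", (1, 1, 1), (2, 2, 2))
        with pytest.raises(DegenerateGeometryError):
            edge_discrepancy(i, j)


def congruent_triple(rng, labels=("a", "b", "c")):
    pts = rng.uniform(-20, 20, (3, 3))
    rot, trans = random_rigid(rng)
    return rigid_pairs(pts, rot, trans, labels=list(labels))


class TestTriangleError:
    def test_congruent_triangles_zero(self, rng):
        a, b, c = congruent_triple(rng)
        assert triangle_error(a, b, c) == pytest.approx(0.0, abs=1e-12)

    def test_proportional_scaling(self):
        # R triangle scaled by k: every discrepancy is 2|k-1|/(k+1), t = 0
        k = 1.3
        p = np.array([[0, 0, 0], [4, 0, 0], [1, 3, 0]], dtype=float)
        a, b, c = (pair(l, p[i], k * p[i]) for i, l in enumerate("abc"))
        expected_edge = 2 * abs(k - 1) / (k + 1)
        assert edge_discrepancy(a, b) == pytest.approx(expected_edge, abs=1e-12)
        assert triangle_error(a, b, c) == pytest.approx(3 * expected_edge, abs=1e-12)

    def test_single_perturbed_edge_positive(self, rng):
        a, b, c = congruent_triple(rng)
        moved = pair("c", c.p.to_array(), c.r.to_array() + np.array([1.0, 0, 0]))
        assert triangle_error(a, b, moved) > 0.0

    def test_permutation_invariance(self, rng):
        pts_p = rng.uniform(-10, 10, (3, 3))
        pts_r = rng.uniform(-10, 10, (3, 3))
        a, b, c = (pair(l, pts_p[i], pts_r[i]) for i, l in enumerate("abc"))
        ref = triangle_error(a, b, c)
        for perm in ((a, c, b), (b, a, c), (b, c, a), (c, a, b), (c, b, a)):
            assert triangle_error(*perm) == pytest.approx(ref, abs=1e-12)

    def test_proportional_beats_single_edge(self):
        # same total length distortion, spread proportionally vs on one edge
        p = np.array([[0, 0, 0], [4, 0, 0], [2, 3, 0]], dtype=float)
        a, b, c = (pair(l, p[i], 1.1 * p[i]) for i, l in enumerate("abc"))
        proportional = triangle_error(a, b, c)
        skew_r = p.copy()
        skew_r[1] *= 1.35  # distorts AB (and BC) but not AC
        a2, b2, c2 = (pair(l, p[i], skew_r[i]) for i, l in enumerate("abc"))
        assert proportional < triangle_error(a2, b2, c2)


class TestPointError:
    def test_zero_for_congruent_pool(self, rng):
        pts = rng.uniform(-20, 20, (5, 3))
        rot, trans = random_rigid(rng)
        pool = rigid_pairs(pts, rot, trans)
        for p in pool:
            assert point_error(p, pool) == pytest.approx(0.0, abs=1e-10)

    def test_matches_explicit_triangle_sum(self, rng):
        pts_p = rng.uniform(-20, 20, (6, 3))
        pts_r = pts_p + rng.normal(0, 0.5, (6, 3))
        pool = [pair(f"L{i}", pts_p[i], pts_r[i]) for i in range(6)]
        target = pool[2]
        others = [p for p in pool if p.label != target.label]
        expected = sum(
            triangle_error(target, u, v) for u, v in combinations(others, 2)
        )
        assert point_error(target, pool) == pytest.approx(expected, rel=1e-12)

    def test_corrupted_pair_has_largest_error(self, rng):
        pts = rng.uniform(-30, 30, (4, 3))
        rot, trans = random_rigid(rng)
        pool = rigid_pairs(pts, rot, trans)
        bad = pair("L2", pool[1].p.to_array(), pool[1].r.to_array() + [2.0, 0, 0])
        pool[1] = bad
        errors = {p.label: point_error(p, pool) for p in pool}
        assert max(errors, key=errors.get) == "L2"

    def test_invariant_under_pool_order(self, rng):
        pts_p = rng.uniform(-20, 20, (5, 3))
        pts_r = pts_p + rng.normal(0, 0.3, (5, 3))
        pool = [pair(f"L{i}", pts_p[i], pts_r[i]) for i in range(5)]
        ref = point_error(pool[0], pool)
        shuffled = [pool[0], pool[3], pool[1], pool[4], pool[2]]
        assert point_error(pool[0], shuffled) == pytest.approx(ref, rel=1e-12)

    def test_pool_too_small(self):
        a = pair("a", (0, 0, 0), (0, 0, 0))
        b = pair("b", (1, 0, 0), (1, 0, 0))
        with pytest.raises(TooFewLandmarksError):
            point_error(a, [a, b])


class TestRankLandmarks:
    def test_exactly_three_pairs(self, rng):
        triple = congruent_triple(rng)
        ranking = rank_landmarks(triple)
        assert ranking.basic_triple == ("a", "b", "c")
        assert ranking.elimination_order == ()
        assert ranking.fourth_pair is None

    def test_too_few_pairs(self, rng):
        a, b, _ = congruent_triple(rng)
        with pytest.raises(TooFewLandmarksError):
            rank_landmarks([a, b])

    def test_duplicate_labels_rejected(self, rng):
        a, b, c = congruent_triple(rng)
        with pytest.raises(ValueError, match="duplicate"):
            rank_landmarks([a, b, c, pair("a", (9, 9, 9), (9, 9, 9))])

    def test_corrupted_pair_eliminated_first(self, rng):
        for _ in range(20):
            pts = rng.uniform(-30, 30, (6, 3))
            rot, trans = random_rigid(rng)
            pairs = rigid_pairs(pts, rot, trans)
            # small noise everywhere, large displacement on L4
            noisy = []
            for p in pairs:
                r = p.r.to_array() + rng.normal(0, 0.02, 3)
                if p.label == "L4":
                    r = r + np.array([0, 2.0, 0])
                noisy.append(pair(p.label, p.p.to_array(), r))
            ranking = rank_landmarks(noisy)
            assert ranking.elimination_order[0] == "L4"
            assert "L4" not in ranking.basic_triple

    def test_first_elimination_agrees_with_point_error_op(self, rng):
        # dual route: the matrix-based ranking vs the brute-force operation
        pts_p = rng.uniform(-30, 30, (7, 3))
        pts_r = pts_p + rng.normal(0, 0.3, (7, 3))
        pool = [pair(f"L{i}", pts_p[i], pts_r[i]) for i in range(7)]
        ranking = rank_landmarks(pool)
        brute = {p.label: point_error(p, pool) for p in pool}
        worst = max(brute, key=brute.get)
        assert ranking.elimination_order[0] == worst
        assert ranking.point_errors[worst] == pytest.approx(brute[worst], rel=1e-9)

    def test_all_congruent_tie_break_is_deterministic(self, rng):
        # identical coordinates in both images: discrepancies are exactly 0,
        # a float rigid transform would leave ~1e-16 residuals and break ties
        pts = rng.uniform(-30, 30, (5, 3))
        pairs = [pair(f"L{i + 1}", pts[i], pts[i]) for i in range(5)]
        ranking = rank_landmarks(pairs)
        # all errors tie at zero; later input labels are eliminated first
        assert ranking.elimination_order == ("L5", "L4")
        assert ranking.basic_triple == ("L1", "L2", "L3")
        err, _ = system_error(pairs, ranking)
        assert err < 1e-9

    def test_deterministic(self, rng):
        pts_p = rng.uniform(-30, 30, (8, 3))
        pts_r = pts_p + rng.normal(0, 0.2, (8, 3))
        pool = [pair(f"L{i}", pts_p[i], pts_r[i]) for i in range(8)]
        assert rank_landmarks(pool) == rank_landmarks(pool)

    def test_every_label_appears_once(self, rng):
        pts_p = rng.uniform(-30, 30, (9, 3))
        pts_r = pts_p + rng.normal(0, 0.2, (9, 3))
        pool = [pair(f"L{i}", pts_p[i], pts_r[i]) for i in range(9)]
        ranking = rank_landmarks(pool)
        seen = set(ranking.elimination_order) | set(ranking.basic_triple)
        assert seen == {p.label for p in pool}
        assert len(ranking.elimination_order) + 3 == len(pool)
        assert ranking.fourth_pair == ranking.elimination_order[-1]

    def test_collinear_basic_triple_rejected(self):
        # all pairs exactly congruent and collinear -> unusable selection
        pts = np.array([[i, 0.0, 0.0] for i in range(4)]) * 7.0
        pairs = [pair(f"L{i}", pts[i], pts[i]) for i in range(4)]
        with pytest.raises(DegenerateGeometryError):
            rank_landmarks(pairs)


class TestSystemError:
    def test_exact_rigid_copy(self, rng):
        pts = rng.uniform(-30, 30, (6, 3))
        rot, trans = random_rigid(rng)
        pairs = rigid_pairs(pts, rot, trans)
        ranking = rank_landmarks(pairs)
        err, residuals = system_error(pairs, ranking)
        assert err < 1e-9
        assert set(residuals) == set(ranking.elimination_order)
        assert all(v < 1e-9 for v in residuals.values())

    def test_displaced_fourth_pair_recovers_magnitude(self, rng):
        for _ in range(10):
            pts = rng.uniform(-30, 30, (4, 3))
            ab, ac = pts[1] - pts[0], pts[2] - pts[0]
            if np.linalg.norm(np.cross(ab, ac)) < 10.0:
                continue
            rot, trans = random_rigid(rng)
            pairs = rigid_pairs(pts, rot, trans)
            d = rng.uniform(-1, 1, 3)
            pairs[3] = pair("L4", pairs[3].p.to_array(), pairs[3].r.to_array() + d)
            ranking = rank_landmarks(pairs)
            assert ranking.fourth_pair == "L4"
            err, _ = system_error(pairs, ranking)
            assert err == pytest.approx(np.linalg.norm(d), abs=1e-9)

    def test_requires_four_pairs(self, rng):
        triple = congruent_triple(rng)
        ranking = rank_landmarks(triple)
        with pytest.raises(TooFewLandmarksError):
            system_error(triple, ranking)

    def test_invariant_under_rigid_motion_of_either_space(self, rng):
        pts_p = rng.uniform(-30, 30, (6, 3))
        pts_r = pts_p + rng.normal(0, 0.2, (6, 3))
        pool = [pair(f"L{i}", pts_p[i], pts_r[i]) for i in range(6)]
        ranking = rank_landmarks(pool)
        err_ref, _ = system_error(pool, ranking)

        rot, trans = random_rigid(rng)
        moved = [
            pair(p.label, p.p.to_array(), rot @ p.r.to_array() + trans) for p in pool
        ]
        ranking2 = rank_landmarks(moved)
        # intra-image distances unchanged up to float round-off
        assert ranking2.elimination_order == ranking.elimination_order
        assert ranking2.basic_triple == ranking.basic_triple
        for label, e in ranking.point_errors.items():
            assert ranking2.point_errors[label] == pytest.approx(e, abs=1e-9)
        err_moved, _ = system_error(moved, ranking2)
        assert err_moved == pytest.approx(err_ref, abs=1e-9)

    def test_mean_error_increases_with_noise(self, rng):
        means = []
        for sigma in (0.05, 0.1, 0.2):
            errs = []
            for _ in range(120):
                pts = rng.uniform(-30, 30, (6, 3))
                ab, ac = pts[1] - pts[0], pts[2] - pts[0]
                if np.linalg.norm(np.cross(ab, ac)) < 20.0:
                    continue
                rot, trans = random_rigid(rng)
                pairs = rigid_pairs(pts, rot, trans)
                noisy = [
                    pair(
                        p.label,
                        p.p.to_array() + rng.normal(0, sigma, 3),
                        p.r.to_array() + rng.normal(0, sigma, 3),
                    )
                    for p in pairs
                ]
                ranking = rank_landmarks(noisy)
                errs.append(system_error(noisy, ranking)[0])
            means.append(np.mean(errs))
        assert means[0] < means[1] < means[2]
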