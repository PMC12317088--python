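"""Correlation matrix, ratio test, geometric filtering, affine estimation, warping."""

import numpy as np
import pytest

from poolreg import matching
from poolreg.exceptions import (
    DegenerateGeometryError,
    InsufficientMatchesError,
    ValidationError,
)
from poolreg.matching import AffineTransform, MatchSet
from poolreg.pyramid import KeyPoint


def kp(u, v, desc):
    desc = np.asarray(desc, dtype=float)
    return KeyPoint(loc=(u, v), descriptor=desc, magnitude=float(np.linalg.norm(desc)))


def match_set(pairs, stage="ratio_filtered"):
    m, f, d = zip(*pairs)
    return MatchSet(np.array(m), np.array(f), np.array(d, dtype=float), stage=stage)


class TestCorrelationMatrix:
    def test_identical_single_descriptors(self):
        h = matching.correlation_matrix([kp(0, 0, [1, 2])], [kp(5, 5, [1, 2])])
        assert h.shape == (1, 1) and h[0, 0] == 0.0

    def test_three_four_five(self):
        h = matching.correlation_matrix([kp(0, 0, [0, 0])], [kp(0, 0, [3, 4])])
        assert h[0, 0] == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self, rng):
        mov = [kp(i, 0, rng.random(6)) for i in range(5)]
        fix = [kp(i, 1, rng.random(6)) for i in range(7)]
        h = matching.correlation_matrix(mov, fix)
        for i in range(5):
            for j in range(7):
                expected = np.sqrt(
                    sum((mov[i].descriptor[k] - fix[j].descriptor[k]) ** 2 for k in range(6))
                )
                assert h[i, j] == pytest.approx(expected, abs=1e-12)

    def test_mismatched_descriptor_lengths_rejected(self):
        with pytest.raises(ValidationError):
            matching.correlation_matrix([kp(0, 0, [1, 2])], [kp(0, 0, [1, 2, 3])])


class TestRatioTest:
    def test_clear_winner_accepted(self):
        out = matching.ratio_test_match(np.array([[1.0, 2.0]]), ratio=0.75)
        assert len(out) == 1 and out.stage == "ratio_filtered"

    def test_ambiguous_match_rejected(self):
        out = matching.ratio_test_match(np.array([[1.0, 1.2]]), ratio=0.75)
        assert len(out) == 0

    def test_exact_boundary_accepted(self):
        # acceptance uses <=, so best exactly 0.75 * second-best passes
        out = matching.ratio_test_match(np.array([[0.75, 1.0]]), ratio=0.75)
        assert len(out) == 1
        out = matching.ratio_test_match(np.array([[0.7501, 1.0]]), ratio=0.75)
        assert len(out) == 0

    def test_accepts_0p9_vs_1p2(self):
        out = matching.ratio_test_match(np.array([[0.9, 1.2]]), ratio=0.75)
        assert len(out) == 1
        assert out.fixed_idx[0] == 0 and out.distance[0] == pytest.approx(0.9)

    def test_duplicate_fixed_target_keeps_closest(self):
        h = np.array([[0.5, 2.0, 3.0], [0.2, 2.0, 3.0]])
        out = matching.ratio_test_match(h, ratio=0.75)
        assert len(out) == 1
        assert out.moving_idx[0] == 1 and out.distance[0] == pytest.approx(0.2)

    def test_shrinks_monotonically_with_ratio(self, rng):
        # the row-wise acceptance rule is monotone in the ratio (the
        # one-to-one dedup step can reshuffle claimants, so it is tested
        # on the plain rule)
        h = rng.random((40, 10))
        prev = None
        for ratio in (0.9, 0.75, 0.6, 0.4):
            out = matching.ratio_test_match(h, ratio, unique_fixed=False)
            accepted = set(out.moving_idx.tolist())
            if prev is not None:
                assert accepted <= prev
            prev = accepted

    def test_single_fixed_column_rejected(self):
        with pytest.raises(ValidationError):
            matching.ratio_test_match(np.array([[1.0]]))


def affine_pairs(n, transform, rng, span=200.0):
    """Keypoint lists + identity-paired MatchSet under a known affine."""
    src = rng.uniform(10, span, size=(n, 2))
    dst = transform.apply(src)
    mov = [kp(x, y, [i, 0]) for i, (x, y) in enumerate(src)]
    fix = [kp(x, y, [i, 0]) for i, (x, y) in enumerate(dst)]
    pairs = match_set([(i, i, 0.1) for i in range(n)])
    return mov, fix, pairs


class TestGeometryFilter:
    def test_consistent_pairs_all_retained(self, rng):
        t = AffineTransform.from_params(rotation_deg=8, scale=1.02, translation=(4, -2))
        mov, fix, pairs = affine_pairs(10, t, rng)
        out = matching.geometry_filter(pairs, mov, fix, seed=0)
        assert len(out) == 10 and out.stage == "geometry_filtered"

    def test_gross_outliers_removed_exactly(self, rng):
        # 8 consistent pairs plus 2 whose fixed partners swap top and bottom
        t = AffineTransform.from_params(translation=(5, 3))
        mov, fix, _ = affine_pairs(10, t, rng)
        fix[8], fix[9] = (
            kp(fix[8].loc[0], fix[8].loc[1] + 150, fix[8].descriptor),
            kp(fix[9].loc[0], fix[9].loc[1] - 150, fix[9].descriptor),
        )
        pairs = match_set([(i, i, 0.1) for i in range(10)])
        out = matching.geometry_filter(pairs, mov, fix, seed=0)
        assert sorted(out.moving_idx.tolist()) == list(range(8))

    def test_never_adds_pairs(self, rng):
        t = AffineTransform.from_params(rotation_deg=3)
        mov, fix, pairs = affine_pairs(12, t, rng)
        out = matching.geometry_filter(pairs, mov, fix, seed=1)
        assert set(out.moving_idx.tolist()) <= set(pairs.moving_idx.tolist())

    def test_too_few_pairs_raises(self, rng):
        t = AffineTransform.identity()
        mov, fix, _ = affine_pairs(3, t, rng)
        with pytest.raises(InsufficientMatchesError):
            matching.geometry_filter(match_set([(i, i, 0.1) for i in range(3)]), mov, fix)

    def test_collinear_pairs_degenerate(self):
        mov = [kp(i * 10, i * 10, [i, 0]) for i in range(4)]
        fix = [kp(i * 10, i * 10, [i, 0]) for i in range(4)]
        pairs = match_set([(i, i, 0.1) for i in range(4)])
        with pytest.raises(DegenerateGeometryError):
            matching.geometry_filter(pairs, mov, fix, seed=0)

    def test_seeded_and_reproducible(self, rng):
        t = AffineTransform.from_params(rotation_deg=5, translation=(2, 2))
        mov, fix, pairs = affine_pairs(20, t, rng)
        a = matching.geometry_filter(pairs, mov, fix, seed=3)
        b = matching.geometry_filter(pairs, mov, fix, seed=3)
        assert np.array_equal(a.moving_idx, b.moving_idx)


class TestEstimateAffine:
    def test_identity_for_identical_point_sets(self, rng):
        mov, fix, pairs = affine_pairs(3, AffineTransform.identity(), rng)
        t, d_proj = matching.estimate_affine(pairs, mov, fix)
        assert np.allclose(t.matrix, np.eye(3), atol=1e-10)
        assert d_proj == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_affine_exactly(self, rng):
        truth = AffineTransform.from_params(
            rotation_deg=10, scale=1.05, translation=(7, -3)
        )
        mov, fix, pairs = affine_pairs(12, truth, rng)
        t, d_proj = matching.estimate_affine(pairs, mov, fix)
        assert np.allclose(t.matrix, truth.matrix, atol=1e-8)
        assert d_proj < 1e-6

    def test_noisy_recovery_within_one_pixel_corners(self, rng):
        truth = AffineTransform.from_params(
            rotation_deg=10, scale=1.05, translation=(7, -3)
        )
        src = rng.uniform(0, 256, size=(50, 2))
        dst = truth.apply(src) + rng.normal(0, 0.5, size=(50, 2))
        mov = [kp(x, y, [i, 0]) for i, (x, y) in enumerate(src)]
        fix = [kp(x, y, [i, 0]) for i, (x, y) in enumerate(dst)]
        pairs = match_set([(i, i, 0.1) for i in range(50)])
        t, _ = matching.estimate_affine(pairs, mov, fix)
        corners = np.array([[0, 0], [255, 0], [0, 255], [255, 255]], dtype=float)
        err = np.linalg.norm(t.apply(corners) - truth.apply(corners), axis=1)
        assert err.max() < 1.0

    def test_collinear_configuration_rejected(self):
        mov = [kp(i, i, [i, 0]) for i in range(5)]
        fix = [kp(i, i, [i, 0]) for i in range(5)]
        pairs = match_set([(i, i, 0.1) for i in range(5)])
        with pytest.raises(DegenerateGeometryError):
            matching.estimate_affine(pairs, mov, fix)


class TestProjectionError:
    def test_zero_for_exact_map(self, rng):
        mov, fix, pairs = affine_pairs(5, AffineTransform.identity(), rng)
        assert matching.projection_error(
            AffineTransform.identity(), pairs, mov, fix
        ) == pytest.approx(0.0)

    def test_single_offset_pair_is_its_norm(self):
        mov = [kp(0, 0, [0, 0])]
        fix = [kp(3, 4, [0, 0])]
        pairs = match_set([(0, 0, 0.0)])
        assert matching.projection_error(
            AffineTransform.identity(), pairs, mov, fix
        ) == pytest.approx(5.0)

    def test_matches_scalar_loop_sum(self, rng):
        t = AffineTransform.from_params(rotation_deg=4, translation=(1, 2))
        mov = [kp(*rng.uniform(0, 100, 2), [i, 0]) for i in range(8)]
        fix = [kp(*rng.uniform(0, 100, 2), [i, 0]) for i in range(8)]
        pairs = match_set([(i, i, 0.1) for i in range(8)])
        expected = sum(
            np.sqrt(np.sum((np.array(fix[i].loc) - t.apply(np.array(mov[i].loc))[0]) ** 2))
            for i in range(8)
        )
        got = matching.projection_error(t, pairs, mov, fix)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_empty_match_set_rejected(self):
        empty = MatchSet(np.empty(0, int), np.empty(0, int), np.empty(0))
        with pytest.raises(ValidationError):
            matching.projection_error(AffineTransform.identity(), empty, [], [])


class TestAffineTransform:
    def test_last_row_enforced(self):
        with pytest.raises(ValidationError):
            AffineTransform(np.arange(9, dtype=float).reshape(3, 3))

    def test_compose_order_scale_rotate_translate(self):
        # explicit 3x3 composition oracle: T @ R @ S, no centre offset
        t = AffineTransform.from_params(
            rotation_deg=15, scale=1.1, translation=(10, -5)
        )
        th = np.deg2rad(15)
        r = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        s = np.diag([1.1, 1.1, 1.0])
        tr = np.eye(3)
        tr[:2, 2] = (10, -5)
        assert np.allclose(t.matrix, tr @ r @ s, atol=1e-12)

    def test_inverse_round_trip(self, rng):
        t = AffineTransform.from_params(rotation_deg=30, scale=0.9, translation=(4, 4))
        pts = rng.uniform(0, 100, size=(10, 2))
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)

    def test_json_round_trip(self):
        t = AffineTransform.from_params(rotation_deg=7, translation=(1, 2))
        again = AffineTransform.from_json(t.to_json(note="x"))
        assert np.allclose(t.matrix, again.matrix)


class TestWarpImage:
    def test_identity_nearest_is_exact_copy(self, rng):
        img = rng.random((32, 32))
        out = matching.warp_image(img, AffineTransform.identity(), order=0)
        assert np.array_equal(out, img)

    def test_identity_bilinear_is_near_exact(self, rng):
        img = rng.random((32, 32))
        out = matching.warp_image(img, AffineTransform.identity(), order=1)
        assert np.allclose(out, img, atol=1e-12)

    def test_integer_translation_shifts_content(self, rng):
        img = rng.random((20, 20))
        t = AffineTransform.from_params(translation=(5, 0))
        out = matching.warp_image(img, t, order=0)
        assert np.array_equal(out[:, 5:], img[:, :-5])
        assert np.all(out[:, :5] == 0.0)

    def test_round_trip_small_on_smooth_image(self, blob_image):
        t = AffineTransform.from_params(
            rotation_deg=10, translation=(3, -2), center=(31.5, 31.5)
        )
        warped = matching.warp_image(blob_image, t)
        back = matching.warp_image(warped, t.inverse())
        interior = (slice(10, -10), slice(10, -10))
        mad = np.abs(back[interior] - blob_image[interior]).mean()
        assert mad < 0.02 * np.ptp(blob_image)

    def test_singular_transform_rejected(self, rng):
        m = np.eye(3)
        m[0, 0] = 0.0
        m[0, 1] = 0.0
        with pytest.raises(ValidationError):
            matching.warp_image(rng.random((8, 8)), AffineTransform(m))
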