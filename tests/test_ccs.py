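import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest, rankdata

from crosssort import (
    EmbeddingParams,
    ccs,
    ccs_score_from_curve,
    ccs_significance,
    delay_embed,
    nerr2_curve,
    null_err2,
    pairwise_rank_distances,
    rank_error,
)
from crosssort.ccs import ErrorCurve


def _embed_points(points):
    """Wrap raw coordinates as a fake 1-D 'embedding' for rank tests."""
    from crosssort.embedding import DelayEmbedding

    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    return DelayEmbedding(points, np.arange(len(points)), EmbeddingParams(1, 1))


class TestPairwiseRankDistances:
    def test_identical_embeddings_have_identical_ranks(self, rng):
        pts = rng.standard_normal((12, 2))
        m = _embed_points(pts)
        rc = pairwise_rank_distances(m, m, exclusion_window=0)
        np.testing.assert_array_equal(rc.rank_x, rc.rank_y)

    def test_affine_rescaling_preserves_ranks(self):
        """Order-preserving coordinate maps leave distance ranks unchanged."""
        pts = np.array([0.0, 1.0, 3.0, 7.0])
        rc = pairwise_rank_distances(
            _embed_points(pts), _embed_points(5 * pts + 7), exclusion_window=0
        )
        np.testing.assert_array_equal(rc.rank_x, rc.rank_y)

    def test_reversed_distances_reverse_ranks(self):
        # three points on a line: pair distances (1, 2, 3) vs reversed geometry
        a = _embed_points([0.0, 1.0, 3.0])  # d(01)=1, d(12)=2, d(02)=3
        b = _embed_points([0.0, 3.0, 5.0])  # d(01)=3, d(12)=2, d(02)=5 -> ranks 2,1,3
        rc = pairwise_rank_distances(a, b, exclusion_window=0)
        assert rankdata(rc.rank_x).tolist() == [1.0, 3.0, 2.0]
        assert rankdata(rc.rank_y).tolist() == [2.0, 3.0, 1.0]

    def test_exclusion_window_drops_near_pairs(self):
        m = _embed_points(np.arange(10.0))
        rc = pairwise_rank_distances(m, m, exclusion_window=3)
        assert np.all(np.abs(rc.pair_index[1] - rc.pair_index[0]) > 3)

    def test_constant_embedding_is_degenerate(self):
        m = _embed_points(np.zeros(6))
        other = _embed_points(np.arange(6.0))
        with pytest.raises(ValueError, match="degenerate"):
            pairwise_rank_distances(m, other, exclusion_window=0)

    def test_too_few_pairs_error(self):
        m = _embed_points(np.arange(3.0))
        with pytest.raises(ValueError, match="fewer than 2"):
            pairwise_rank_distances(m, m, exclusion_window=5)


class TestRankError:
    def test_identical_ranks_zero_error(self, rng):
        pts = rng.standard_normal((10, 2))
        m = _embed_points(pts)
        rc = pairwise_rank_distances(m, m, 0)
        assert np.all(rank_error(rc, "x_to_y") == 0)
        assert np.all(rank_error(rc, "y_to_x") == 0)

    def test_hand_example_ordering(self):
        """rank_x=(1,2,3), rank_y=(2,1,3): ordered by R_Y the errors are (+1,-1,0)."""
        from crosssort.ccs import RankCorrespondence

        rc = RankCorrespondence(
            rank_x=np.array([1.0, 2.0, 3.0]),
            rank_y=np.array([2.0, 1.0, 3.0]),
            pair_index=np.zeros((2, 3), dtype=int),
        )
        np.testing.assert_array_equal(rank_error(rc, "x_to_y"), [1, -1, 0])
        np.testing.assert_array_equal(rank_error(rc, "y_to_x"), [-1, 1, 0])

    def test_anti_ordered_closed_form(self):
        """For fully reversed ranks ERR at conditioning rank r is (N+1-r)-r."""
        from crosssort.ccs import RankCorrespondence

        N = 7
        rc = RankCorrespondence(
            rank_x=np.arange(1.0, N + 1),
            rank_y=np.arange(N, 0.0, -1),
            pair_index=np.zeros((2, N), dtype=int),
        )
        err = rank_error(rc, "x_to_y")
        r = np.arange(1, N + 1)
        np.testing.assert_array_equal(err, (N + 1 - r) - r)


class TestNullErr2:
    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_marginal_matches_brute_force_enumeration(self, n):
        """E[(R_X - R_Y)^2] over all permutation pairs equals (n^2-1)/6."""
        from fractions import Fraction

        perms = list(itertools.permutations(range(1, n + 1)))
        total = sum(
            sum((a - b) ** 2 for a, b in zip(px, py))
            for px in perms
            for py in perms
        )
        mean = Fraction(total, len(perms) ** 2 * n)
        assert mean == Fraction(n**2 - 1, 6)
        assert null_err2(n) == pytest.approx(float(mean), abs=1e-12)

    def test_known_values(self):
        assert null_err2(3) == pytest.approx(4 / 3)
        assert null_err2(2) == pytest.approx(1 / 2)
        assert null_err2(5, "conditional", rank=3) == pytest.approx(2.0)

    @pytest.mark.parametrize("n,r", [(4, 1), (5, 2), (6, 6)])
    def test_conditional_matches_enumeration(self, n, r):
        expected = np.mean([(rx - r) ** 2 for rx in range(1, n + 1)])
        assert null_err2(n, "conditional", rank=r) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(ValueError):
            null_err2(1)
        with pytest.raises(ValueError, match="rank"):
            null_err2(5, "conditional")


class TestNerr2Curve:
    def test_perfect_correspondence(self):
        c = nerr2_curve(np.zeros(10), null=4.0)
        assert np.all(c.cum_nerr2 == 1.0)
        assert c.rank_grid[-1] == 1.0

    def test_null_level_errors_give_zero(self):
        null = 9.0
        c = nerr2_curve(np.full(5, 3.0), null)  # ERR^2 == null
        np.testing.assert_allclose(c.cum_nerr2, 0.0)

    def test_hand_computed_cumulative(self):
        null = 4.0
        c = nerr2_curve(np.array([0.0, 2.0, 0.0]), null)  # ERR^2 = 0, null, 0
        np.testing.assert_allclose(c.cum_nerr2, [1.0, 0.5, 2 / 3])

    def test_empty_error_vector_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            nerr2_curve(np.array([]), 1.0)

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=50)
    def test_curve_bounded_above_by_one(self, errs):
        c = nerr2_curve(np.array(errs), null=10.0)
        assert np.all(c.cum_nerr2 <= 1.0 + 1e-12)


class TestScoreFromCurve:
    def _curve(self, y):
        y = np.asarray(y, dtype=float)
        g = np.arange(1, len(y) + 1) / len(y)
        return ErrorCurve(g, y, 1.0)

    def test_constant_one(self):
        score, ok = ccs_score_from_curve(self._curve(np.ones(40)), 1.0)
        assert score == pytest.approx(1.0)
        assert ok

    def test_constant_zero(self):
        score, _ = ccs_score_from_curve(self._curve(np.zeros(40)), 1.0)
        assert score == pytest.approx(0.0)

    def test_recovers_synthetic_exponential(self):
        g = np.arange(1, 101) / 100
        y = 0.6 * np.exp(-3 * g) + 0.2
        score, ok = ccs_score_from_curve(ErrorCurve(g, y, 1.0), max_rank_frac=1.0)
        assert ok
        assert score == pytest.approx(0.8, abs=1e-6)

    def test_too_few_points_names_threshold(self):
        with pytest.raises(ValueError, match="max_rank_frac=0.01"):
            ccs_score_from_curve(self._curve(np.linspace(1, 0, 50)), max_rank_frac=0.01)

    def test_score_clipped_to_unit_interval(self):
        g = np.arange(1, 51) / 50
        y = 5.0 * np.exp(-0.5 * g)  # intercept would be 5
        score, _ = ccs_score_from_curve(ErrorCurve(g, y, 1.0), max_rank_frac=1.0)
        assert score == 1.0


class TestCcsEndToEnd:
    def test_identity_is_symmetric_and_maximal(self, lm_trace, p21):
        res = ccs(lm_trace, lm_trace, p21)
        assert res["x_to_y"].value == pytest.approx(res["y_to_x"].value)
        assert res["x_to_y"].value > 0.95

    def test_rank_invariance_under_monotone_distortion(self, lm_trace, p21):
        """A strictly increasing transform of one series' embedding scale
        (affine coordinates) leaves the CCS score unchanged."""
        base = ccs(lm_trace, lm_trace * 1.0, p21, standardize=False)
        warped = ccs(lm_trace, 5.0 * lm_trace + 7.0, p21, standardize=False)
        assert warped["x_to_y"].value == pytest.approx(base["x_to_y"].value)
        assert warped["y_to_x"].value == pytest.approx(base["y_to_x"].value)

    def test_score_bounded(self, rng, p21):
        a, b = rng.standard_normal((2, 150))
        for sc in ccs(a, b, p21).values():
            assert -1.0 <= sc.value <= 1.0

    def test_unequal_lengths_rejected(self, p21):
        with pytest.raises(ValueError, match="equal length"):
            ccs(np.arange(10.0), np.arange(12.0), p21)

    def test_oracle_equivalence_small_n(self):
        """Ranks, ERR and NERR^2 match an exhaustive brute-force recomputation
        from raw distances for a tiny point set."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((4, 2))
        Y = rng.standard_normal((4, 2))
        mx, my = _embed_points(X), _embed_points(Y)
        rc = pairwise_rank_distances(mx, my, 0)
        # brute force: all unordered pairs in fixed order
        pairs = list(itertools.combinations(range(4), 2))
        dX = np.array([np.linalg.norm(X[i] - X[j]) for i, j in pairs])
        dY = np.array([np.linalg.norm(Y[i] - Y[j]) for i, j in pairs])
        np.testing.assert_allclose(rc.rank_x, rankdata(dX))
        np.testing.assert_allclose(rc.rank_y, rankdata(dY))
        err = rank_error(rc, "x_to_y")
        order = np.argsort(rankdata(dY), kind="stable")
        np.testing.assert_allclose(err, (rankdata(dX) - rankdata(dY))[order])
        null = null_err2(len(pairs))
        curve = nerr2_curve(err, null)
        np.testing.assert_allclose(
            curve.cum_nerr2,
            np.cumsum((null - err**2) / null) / np.arange(1, len(err) + 1),
        )


class TestSignificance:
    def test_identity_beats_surrogates(self, lm_trace, p21):
        obs, p = ccs_significance(lm_trace, lm_trace, p21, n_surrogates=99, seed=0)
        assert obs > 0.95
        assert p == pytest.approx(1 / 100)

    def test_p_never_zero(self, lm_trace, p21):
        _, p = ccs_significance(lm_trace, lm_trace, p21, n_surrogates=19, seed=0)
        assert p >= 1 / 20

    def test_minimum_surrogates_enforced(self, lm_trace, p21):
        with pytest.raises(ValueError, match="19"):
            ccs_significance(lm_trace, lm_trace, p21, n_surrogates=5)

    def test_short_series_relative_to_exclusion_rejected(self, p21):
        x = np.sin(np.arange(30.0))
        with pytest.raises(ValueError, match="too short"):
            ccs_significance(x, x, p21, n_surrogates=19, exclusion_window=12)

    def test_null_p_values_roughly_uniform(self):
        """On independent noise the surrogate p-value is uniform on its grid."""
        rng = np.random.default_rng(7)
        p21 = EmbeddingParams(2, 1)
        pvals = []
        for _ in range(40):
            a, b = rng.standard_normal((2, 120))
            _, p = ccs_significance(a, b, p21, n_surrogates=19, seed=int(rng.integers(2**31)))
            pvals.append(p)
        assert kstest(pvals, "uniform").pvalue > 0.01
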