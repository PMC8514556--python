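import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom
from sklearn.metrics import adjusted_rand_score

from crosssort import cluster_states, sequence_statistics, windowed_ccs
from crosssort.netstate import (
    PAIR_ORDER,
    WindowedScores,
    canonical_cycle,
    n_canonical_sequences,
)
from crosssort.simulators import NetworkSpec, simulate_logistic_map


def _lm_channel(L, seed, r=3.8):
    spec = NetworkSpec(1, np.zeros((1, 1)), "lm", {"r": [r]})
    return simulate_logistic_map(spec, L, seed=seed).series.values


class TestWindowedCcs:
    def test_identical_channels_score_near_one_everywhere(self):
        x = _lm_channel(240, seed=0)
        vals = np.column_stack([x, x, x])
        ws = windowed_ccs(vals, epoch_len=120, window_len=60)
        assert ws.scores.shape == (2, 3, 6)
        assert np.all(ws.scores > 0.9)

    def test_independent_channels_score_near_zero(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((240, 3))
        ws = windowed_ccs(vals, epoch_len=120, window_len=60)
        assert abs(ws.scores.mean()) < 0.15

    def test_window_too_short_names_minimum(self):
        with pytest.raises(ValueError, match="minimum"):
            windowed_ccs(np.random.default_rng(0).standard_normal((100, 3)),
                         epoch_len=50, window_len=4)

    def test_scores_track_scripted_coupling_switch(self):
        """Windows generated under strong driving score higher than windows
        generated uncoupled, within the same epochs."""
        K = np.zeros((3, 3))
        K[0, 1] = 0.35
        on = NetworkSpec(3, K, "lm", {})
        off = NetworkSpec(3, np.zeros((3, 3)), "lm", {})
        segs = []
        for e in range(6):  # epoch = [off | on] halves of 60 samples
            segs.append(simulate_logistic_map(off, 60, seed=10 + e).series.values)
            segs.append(simulate_logistic_map(on, 60, seed=50 + e).series.values)
        vals = np.vstack(segs)
        ws = windowed_ccs(vals, epoch_len=120, window_len=60, step=60, n_windows=2)
        idx = PAIR_ORDER.index((0, 1))
        diff = ws.scores[:, 1, idx] - ws.scores[:, 0, idx]  # on minus off
        assert diff.mean() > 0.2
        assert (diff > 0).sum() >= 5


class TestClusterStates:
    def _blob_scores(self, rng, centers, n_per, noise=0.02):
        X = np.vstack([c + noise * rng.standard_normal((n_per, 6)) for c in centers])
        n_windows = 3
        n_epochs = len(X) // n_windows
        return WindowedScores(
            X[: n_epochs * n_windows].reshape(n_epochs, n_windows, 6), 10, 5
        )

    def test_two_separated_blobs_recovered_exactly(self, rng):
        centers = [np.full(6, 0.8), np.full(6, -0.5)]
        ws = self._blob_scores(rng, centers, 30)
        out = cluster_states(ws, k=2, seed=0)
        truth = np.repeat([0, 1], 30)
        assert adjusted_rand_score(truth, out["labels"]) == 1.0

    def test_same_seed_identical_centroids(self, rng):
        ws = self._blob_scores(rng, [np.zeros(6), np.ones(6)], 15)
        a = cluster_states(ws, k=2, seed=3)
        b = cluster_states(ws, k=2, seed=3)
        np.testing.assert_array_equal(a["centroids"], b["centroids"])

    def test_centroids_back_transformed_to_score_units(self, rng):
        """Whitening round-trip: centroids match per-cluster raw means."""
        ws = self._blob_scores(rng, [np.full(6, 0.7), np.full(6, -0.3)], 40)
        out = cluster_states(ws, k=2, seed=1)
        X = ws.flat
        for c in range(2):
            mask = out["labels"] == c
            np.testing.assert_allclose(
                out["centroids"][c], X[mask].mean(axis=0), atol=1e-8
            )

    def test_k_exceeding_windows_rejected(self, rng):
        ws = self._blob_scores(rng, [np.zeros(6)], 3)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_states(ws, k=50)


class TestCanonicalization:
    def test_all_rotations_map_to_one_class(self):
        assert (
            canonical_cycle([0, 1, 2])
            == canonical_cycle([1, 2, 0])
            == canonical_cycle([2, 0, 1])
        )

    @given(st.lists(st.integers(0, 4), min_size=1, max_size=6))
    @settings(deadline=None, max_examples=100)
    def test_idempotent_and_rotation_invariant(self, seq):
        canon = canonical_cycle(seq)
        assert canonical_cycle(canon) == canon
        for r in range(len(seq)):
            assert canonical_cycle(seq[r:] + seq[:r]) == canon

    @pytest.mark.parametrize("k,length,expected", [(5, 3, 45), (2, 3, 4), (3, 2, 6)])
    def test_necklace_counts(self, k, length, expected):
        # brute-force verification of the Burnside count
        import itertools

        classes = {canonical_cycle(s) for s in itertools.product(range(k), repeat=length)}
        assert len(classes) == expected
        assert n_canonical_sequences(k, length) == expected


class TestSequenceStatistics:
    def test_cyclic_equivalents_pool_to_full_frequency(self):
        seqs = np.array([[0, 1, 2], [1, 2, 0], [2, 0, 1]])
        df = sequence_statistics(seqs, n_states=3)
        assert len(df) == 1
        assert df.iloc[0]["pct"] == pytest.approx(100.0)

    def test_binomial_standard_error_of_percentage(self):
        # one pattern in 100 of 200 epochs: SE = sqrt(.5*.5/200)*100 ~ 3.54
        seqs = np.array([[0, 0, 0]] * 100 + [[i % 5, (i + 1) % 5, (i + 2) % 5]
                                             for i in range(100)])
        df = sequence_statistics(seqs, n_states=5)
        top = df[df["rank"] == 1].iloc[0]
        assert top["count"] == 100
        assert top["pct_se"] == pytest.approx(100 * np.sqrt(0.25 / 200), rel=1e-6)

    def test_binomial_mode_matches_closed_form_tail(self):
        seqs = np.array([[0, 1, 2]] * 7 + [[3, 3, 3]] * 3)
        df = sequence_statistics(seqs, n_states=5, null="binomial")
        top = df[df["rank"] == 1].iloc[0]
        expected = -np.log10(binom.sf(6, 10, 1 / 45))
        assert top["neg_log10_p"] == pytest.approx(expected)

    def test_order_statistic_null_less_extreme_than_binomial(self):
        """Accounting for the selection of the most frequent pattern can only
        make its observed count less surprising."""
        rng = np.random.default_rng(3)
        seqs = rng.integers(0, 5, size=(100, 3))
        a = sequence_statistics(seqs, n_states=5, null="order")
        b = sequence_statistics(seqs, n_states=5, null="binomial")
        top_a = a[a["rank"] == 1].iloc[0]["neg_log10_p"]
        top_b = b[b["rank"] == 1].iloc[0]["neg_log10_p"]
        assert top_a <= top_b + 1e-9

    def test_uniform_sequences_rarely_extreme(self):
        """Under a uniform null the top pattern's extremeness stays small."""
        rng = np.random.default_rng(9)
        n_classes = n_canonical_sequences(5, 3)
        hits = 0
        n_sim = 60
        for _ in range(n_sim):
            # draw canonical classes uniformly (the null the statistic assumes)
            import itertools

            classes = sorted({canonical_cycle(s)
                              for s in itertools.product(range(5), repeat=3)})
            seqs = np.array([classes[i] for i in rng.integers(0, n_classes, 200)])
            df = sequence_statistics(seqs, n_states=5)
            hits += df[df["rank"] == 1].iloc[0]["neg_log10_p"] < 2
        assert hits >= 0.95 * n_sim

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError):
            sequence_statistics(np.zeros((0, 3), dtype=int))

    def test_per_condition_tables(self):
        seqs = np.array([[0, 0, 0]] * 4 + [[1, 1, 1]] * 4)
        conds = np.array(["a"] * 4 + ["b"] * 4)
        df = sequence_statistics(seqs, conditions=conds, n_states=2)
        assert set(df["condition"]) == {"a", "b"}
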