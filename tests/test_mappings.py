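import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lexlearn as ll
from conftest import random_weighted_instance


def replication_oracle(X, Y, f):
    """Ground truth for frequency weighting: repeat row i f_i times, solve EL."""
    f = np.asarray(f, dtype=int)
    Xr = np.repeat(X, f, axis=0)
    Yr = np.repeat(Y, f, axis=0)
    return ll.solve_linear_mapping(Xr, Yr).matrix


class TestSolveLinearMapping:
    def test_identity_input_returns_targets(self):
        Y = np.arange(6.0).reshape(3, 2)
        F = ll.solve_linear_mapping(np.eye(3), Y)
        np.testing.assert_allclose(F.matrix, Y)

    def test_zero_targets_give_zero_map(self):
        X = np.random.default_rng(0).random((5, 3))
        F = ll.solve_linear_mapping(X, np.zeros((5, 2)))
        np.testing.assert_allclose(F.matrix, 0, atol=1e-12)

    def test_recovers_planted_map_from_full_rank_system(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((6, 4))
        F_star = rng.standard_normal((4, 2))
        F = ll.solve_linear_mapping(X, X @ F_star)
        # independent oracle: the Moore-Penrose pseudo-inverse
        np.testing.assert_allclose(F.matrix, np.linalg.pinv(X) @ (X @ F_star),
                                   atol=1e-8)
        np.testing.assert_allclose(F.matrix, F_star, atol=1e-8)

    def test_rank_deficient_system_falls_back_to_min_norm(self):
        # duplicate rows (homophones) make the Gram matrix singular
        X = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 1.0, 1.0]])
        Y = np.array([[1.0], [1.0], [0.0]])
        F = ll.solve_linear_mapping(X, Y)
        np.testing.assert_allclose(F.matrix, np.linalg.pinv(X) @ Y, atol=1e-8)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="mismatch"):
            ll.solve_linear_mapping(np.eye(3), np.zeros((4, 2)))
        with pytest.raises(ValueError, match="all-zero"):
            ll.solve_linear_mapping(np.zeros((3, 3)), np.zeros((3, 2)))
        with pytest.raises(ValueError, match="ridge"):
            ll.solve_linear_mapping(np.eye(2), np.eye(2), ridge=-1.0)


class TestFrequencyInformed:
    def test_uniform_weights_collapse_to_endstate(self, planted_system):
        _, C, S, _ = planted_system
        el = ll.solve_linear_mapping(C, S).matrix
        fil = ll.solve_frequency_informed(C, S, np.full(C.shape[0], 7.0)).matrix
        np.testing.assert_allclose(fil, el, atol=1e-10)

    def test_scale_invariance(self, noisy_zipf_system):
        lex, C, S = noisy_zipf_system
        f = lex.frequencies.astype(float)
        F1 = ll.solve_frequency_informed(C, S, f).matrix
        F2 = ll.solve_frequency_informed(C, S, 10.0 * f).matrix
        np.testing.assert_allclose(F1, F2, atol=1e-10)

    def test_five_word_toy_matches_row_replication(self):
        rng = np.random.default_rng(8)
        X = (rng.random((5, 6)) < 0.5).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1.0
        Y = rng.standard_normal((5, 3))
        f = np.array([1, 4, 2, 7, 3])
        fil = ll.solve_frequency_informed(X, Y, f).matrix
        np.testing.assert_allclose(fil, replication_oracle(X, Y, f), atol=1e-8)

    def test_random_instances_match_replication_oracle(self):
        rng = np.random.default_rng(123)
        worst = 0.0
        for _ in range(50):
            X, Y, f = random_weighted_instance(rng)
            fil = ll.solve_frequency_informed(X, Y, f.astype(float)).matrix
            worst = max(worst, np.abs(fil - replication_oracle(X, Y, f)).max())
        assert worst < 1e-8

    def test_zero_weight_rows_do_not_constrain_fit(self):
        rng = np.random.default_rng(5)
        X = np.vstack([np.eye(3), [1.0, 1.0, 1.0]])
        Y = rng.standard_normal((4, 2))
        f = np.array([1.0, 1.0, 1.0, 0.0])
        fil = ll.solve_frequency_informed(X, Y, f).matrix
        np.testing.assert_allclose(fil, Y[:3], atol=1e-8)

    def test_invalid_weights(self, planted_system):
        _, C, S, _ = planted_system
        with pytest.raises(ValueError, match="zero"):
            ll.solve_frequency_informed(C, S, np.zeros(C.shape[0]))
        with pytest.raises(ValueError, match="negative"):
            f = np.ones(C.shape[0]); f[0] = -1
            ll.solve_frequency_informed(C, S, f)


class TestFrequenciesToEvents:
    def test_raw_frequency_100_gives_100_events(self):
        ev = ll.frequencies_to_events(np.array([100]), transform="raw")
        assert len(ev) == 100
        assert (ev.indices == 0).all()

    @pytest.mark.parametrize(
        "f,transform,divisor,expected",
        [
            ([250, 1], "scaled", 100, [3, 1]),
            ([99, 100, 101], "scaled", 100, [1, 1, 2]),
            # round(ln(f+1)): ln(2)=0.69->1(floored), ln(8)=2.08->2, ln(150)=5.01->5
            ([1, 7, 149], "log_backoff", 100, [1, 2, 5]),
            ([0, 5], "raw", 100, [0, 5]),
        ],
    )
    def test_event_counts_per_transform(self, f, transform, divisor, expected):
        ev = ll.frequencies_to_events(np.array(f), transform=transform,
                                      divisor=divisor, order="as_given")
        counts = np.bincount(ev.indices, minlength=len(f))
        assert counts.tolist() == expected

    def test_attested_words_keep_at_least_one_event(self):
        # scaled and log transforms must not silence attested words
        f = np.array([1, 2, 1000])
        for transform in ("scaled", "log_backoff"):
            ev = ll.frequencies_to_events(f, transform=transform, divisor=100)
            assert set(np.unique(ev.indices)) == {0, 1, 2}

    def test_all_zero_frequencies_error(self):
        with pytest.raises(ValueError, match="events"):
            ll.frequencies_to_events(np.array([0, 0]), transform="raw")

    def test_divisor_below_one_rejected(self):
        with pytest.raises(ValueError, match="divisor"):
            ll.frequencies_to_events(np.array([5]), transform="scaled",
                                     divisor=0.5)

    def test_shuffle_is_seed_deterministic(self):
        f = np.arange(1, 20)
        a = ll.frequencies_to_events(f, seed=4).indices
        b = ll.frequencies_to_events(f, seed=4).indices
        c = ll.frequencies_to_events(f, seed=5).indices
        assert (a == b).all()
        assert not (a == c).all()


class TestTrainIncremental:
    def test_single_event_closed_form(self):
        # from zero initial state one update gives eta * c^T s
        C = np.array([[1.0, 0.0, 1.0]])
        S = np.array([[2.0, -1.0]])
        F = ll.train_incremental(C, S, [0], eta=0.5)
        np.testing.assert_allclose(F.matrix, 0.5 * np.outer(C[0], S[0]),
                                   atol=1e-15)

    def test_zero_error_event_leaves_map_unchanged(self):
        C = np.array([[1.0, 0.0], [0.0, 1.0]])
        F0 = np.array([[1.0, 2.0], [3.0, 4.0]])
        S = C @ F0
        F = ll.train_incremental(C, S, [0, 1, 0], eta=0.3, F0=F0)
        np.testing.assert_allclose(F.matrix, F0, atol=1e-15)

    def test_two_events_match_hand_unrolled_recurrence(self):
        # orthogonal unit cue vectors, eta = 0.5, unrolled by hand:
        # F1 = eta * c1^T s1 ; F2 = F1 + eta * c2^T (s2 - c2 F1)
        C = np.eye(2)
        S = np.array([[1.0, 2.0], [3.0, 4.0]])
        eta = 0.5
        F1 = eta * np.outer(C[0], S[0])
        F2 = F1 + eta * np.outer(C[1], S[1] - C[1] @ F1)
        got = ll.train_incremental(C, S, [0, 1], eta=eta)
        np.testing.assert_allclose(got.matrix, F2, atol=1e-12)

    def test_sparse_and_dense_inputs_agree(self, planted_system):
        _, C, S, _ = planted_system
        ev = ll.frequencies_to_events(np.ones(C.shape[0], dtype=int), seed=0)
        Fs = ll.train_incremental(C, S, ev, eta=0.01).matrix
        Fd = ll.train_incremental(C.toarray(), S, ev, eta=0.01).matrix
        np.testing.assert_allclose(Fs, Fd, atol=1e-12)

    def test_snapshots_recorded_every_n_events(self, planted_system):
        _, C, S, _ = planted_system
        ev = np.zeros(10, dtype=int)
        F = ll.train_incremental(C, S, ev, eta=0.01, snapshot_every=4)
        assert [t for t, _ in F.snapshots] == [4, 8]

    def test_out_of_range_event_named(self, planted_system):
        _, C, S, _ = planted_system
        with pytest.raises(IndexError, match="out of range"):
            ll.train_incremental(C, S, [0, C.shape[0]], eta=0.01)

    def test_divergence_raises_with_event_index(self):
        C = np.full((2, 3), 2.0)
        S = np.ones((2, 2))
        with pytest.raises(FloatingPointError, match="event"):
            ll.train_incremental(C, S, np.tile([0, 1], 200), eta=10.0)

    def test_determinism_given_seeded_events(self, noisy_zipf_system):
        lex, C, S = noisy_zipf_system
        ev = ll.frequencies_to_events(lex.frequencies, seed=2)
        F1 = ll.train_incremental(C, S, ev, eta=1e-3).matrix
        F2 = ll.train_incremental(C, S, ev, eta=1e-3).matrix
        assert (F1 == F2).all()


class TestWHLLimits:
    def test_whl_approaches_endstate_with_uniform_epochs(self, planted_system):
        """With f = 1 for all words and many shuffled low-eta epochs the
        incremental learner approaches the least-squares endstate."""
        _, C, S, _ = planted_system
        el = ll.solve_linear_mapping(C, S).matrix
        rng = np.random.default_rng(0)
        m = C.shape[0]
        F = None
        dist = []
        for _ in range(500):
            F = ll.train_incremental(C, S, rng.permutation(m), eta=0.02, F0=F)
            dist.append(np.linalg.norm(F.matrix - el))
        norm = np.linalg.norm(el)
        assert dist[-1] < dist[0]
        assert dist[-1] / norm < 1e-3

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_fil_equals_replication_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        X, Y, f = random_weighted_instance(rng)
        fil = ll.solve_frequency_informed(X, Y, f.astype(float)).matrix
        oracle = replication_oracle(X, Y, f)
        assert np.abs(fil - oracle).max() < 1e-8
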