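"""Distances, null models, thresholding and stable-period segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegnetdyn.datatypes import (
    ConnectivityMatrix,
    DistanceVector,
    MultichannelRecording,
    NullDistribution,
)
from eegnetdyn.stability import (
    alt_distance,
    build_null_distribution,
    detect_stable_periods,
    distance_vector,
    edit_distance,
    randomize_network,
    stability_threshold,
    temporal_shift_null,
)

from conftest import random_symmetric


def brute_l1(A, B):
    total = 0.0
    for i in range(A.shape[0]):
        for j in range(A.shape[1]):
            total += abs(A[i, j] - B[i, j])
    return total


class TestEditDistance:
    def test_identical_matrices(self, rng):
        A = random_symmetric(rng, 6)
        assert edit_distance(A, A) == 0.0

    def test_single_symmetric_pair_difference_counts_twice(self):
        A = np.zeros((2, 2))
        B = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert edit_distance(A, B) == 2.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_double_loop_oracle(self, seed):
        g = np.random.default_rng(seed)
        A, B = g.normal(0, 1, (32, 32)), g.normal(0, 1, (32, 32))
        assert edit_distance(A, B) == pytest.approx(brute_l1(A, B), rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            edit_distance(np.zeros((3, 3)), np.zeros((4, 4)))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_metric_axioms_on_random_triples(self, seed):
        g = np.random.default_rng(seed)
        A, B, C = g.normal(0, 1, (3, 5, 5))
        dAB = edit_distance(A, B)
        assert dAB >= 0
        assert dAB == pytest.approx(edit_distance(B, A))
        assert edit_distance(A, A) == 0
        assert dAB <= edit_distance(A, C) + edit_distance(C, B) + 1e-12


class TestAltDistance:
    def test_cosine_of_identical_matrices_is_zero(self, rng):
        A = random_symmetric(rng, 5)
        assert alt_distance(A, A, "cosine") == pytest.approx(0.0, abs=1e-12)

    def test_cosine_scale_invariance_and_l2_norm(self, rng):
        A = random_symmetric(rng, 5)
        assert alt_distance(A, 2 * A, "cosine") == pytest.approx(0.0, abs=1e-12)
        assert alt_distance(A, 2 * A, "l2") == pytest.approx(np.linalg.norm(A))

    def test_matches_closed_forms(self, rng):
        A, B = rng.normal(0, 1, (6, 6)), rng.normal(0, 1, (6, 6))
        assert alt_distance(A, B, "l2") == pytest.approx(
            np.sqrt(((A - B) ** 2).sum())
        )
        cos = 1 - (A * B).sum() / (np.linalg.norm(A) * np.linalg.norm(B))
        assert alt_distance(A, B, "cosine") == pytest.approx(cos)

    def test_cosine_with_zero_matrix_rejected(self, rng):
        with pytest.raises(ValueError, match="zero matrix"):
            alt_distance(np.zeros((3, 3)), random_symmetric(rng, 3), "cosine")


class TestRandomizeNetwork:
    def test_equal_weights_yield_permutation_of_input(self, rng):
        W = (np.ones((5, 5)) - np.eye(5)) * 0.7
        R = randomize_network(W, seed=4).weights
        assert np.array_equal(np.sort(R[np.triu_indices(5, 1)]),
                              np.sort(W[np.triu_indices(5, 1)]))
        assert np.array_equal(R, R.T)
        assert np.array_equal(R, W)  # complete graph with equal weights is fixed

    @pytest.mark.parametrize("signed", [False, True])
    def test_weight_multiset_and_degree_conserved(self, signed):
        iu = np.triu_indices(10, 1)
        for seed in range(25):
            g = np.random.default_rng(1000 + seed)
            W = random_symmetric(g, 10, density=0.5, signed=signed)
            R = randomize_network(W, seed=seed).weights
            assert np.allclose(np.sort(R[iu]), np.sort(W[iu]))
            assert np.array_equal((R != 0).sum(axis=1), (W != 0).sum(axis=1))
            assert np.all(np.diag(R) == 0)
            assert np.array_equal(R, R.T)

    def test_strength_tracking_on_heterogeneous_graphs(self):
        # observed over 100 seeded 10-node lognormal-weight graphs
        cors = []
        for s in range(100):
            g = np.random.default_rng(1000 + s)
            W = g.lognormal(0, 0.8, (10, 10))
            W = (W + W.T) / 2
            mask = np.triu(g.random((10, 10)) < 0.5, 1)
            W = W * (mask | mask.T) / W.max()
            if (W != 0).sum(axis=1).min() == 0:
                continue
            R = randomize_network(W, seed=s).weights
            cors.append(np.corrcoef(np.abs(W).sum(1), np.abs(R).sum(1))[0, 1])
        assert np.mean(cors) > 0.85
        assert min(cors) > 0.5


class TestTemporalShiftNull:
    def test_output_exactly_30s_every_seed(self, white_noise_recording):
        for seed in range(10):
            out = temporal_shift_null(white_noise_recording, seed=seed)
            assert out.n_samples == 15360

    def test_start_offsets_within_5s_range(self, white_noise_recording):
        # locate each channel's slice in the original; offsets must lie in
        # 0..2559 (start coordinate 1..2560, 1-based)
        out = temporal_shift_null(white_noise_recording, seed=7)
        X = white_noise_recording.samples
        offsets = []
        for ch in range(out.n_channels):
            probe = out.samples[ch, :32]
            hits = [
                s for s in range(0, 2560)
                if np.array_equal(X[ch, s : s + 32], probe)
            ]
            assert len(hits) == 1
            offsets.append(hits[0])
        assert len(set(offsets)) > 1  # channels shifted independently

    def test_zero_deletion_returns_leading_window(self, white_noise_recording):
        out = temporal_shift_null(white_noise_recording, seed=0, max_delete=0.0)
        assert np.array_equal(out.samples, white_noise_recording.samples[:, :15360])

    def test_too_short_recording_rejected(self, rng):
        rec = MultichannelRecording(rng.normal(0, 1, (2, 512 * 20)), fs=512.0)
        with pytest.raises(ValueError, match="too short"):
            temporal_shift_null(rec)


class TestNullDistribution:
    def test_degenerate_identical_equalweight_matrices(self):
        W = (np.ones((4, 4)) - np.eye(4)) * 0.5
        seq = [ConnectivityMatrix(W.copy(), epoch_index=k) for k in range(4)]
        null = build_null_distribution([seq], "matrix_randomization",
                                       n_replicates=3, seed=0)
        assert null.mean == 0.0
        assert null.sd == 0.0

    def test_pooled_sample_count(self, rng):
        seq_a = [ConnectivityMatrix(random_symmetric(rng, 5)) for _ in range(4)]
        seq_b = [ConnectivityMatrix(random_symmetric(rng, 5)) for _ in range(6)]
        null = build_null_distribution([seq_a, seq_b], "matrix_randomization",
                                       n_replicates=7, seed=1)
        assert len(null.samples) == 7 * (3 + 5)

    def test_mean_stable_under_replicate_doubling(self, rng):
        seq = [ConnectivityMatrix(random_symmetric(rng, 8)) for _ in range(6)]
        n1 = build_null_distribution([seq], "matrix_randomization",
                                     n_replicates=40, seed=5)
        n2 = build_null_distribution([seq], "matrix_randomization",
                                     n_replicates=80, seed=6)
        sem = n1.sd / np.sqrt(len(n1.samples))
        assert abs(n1.mean - n2.mean) < 4 * sem

    def test_temporal_shift_model_reruns_connectivity(self, rng):
        rec = MultichannelRecording(rng.normal(0, 10, (3, 512 * 36)), fs=512.0)
        null = build_null_distribution(
            [rec], "temporal_shift", n_replicates=2, seed=2,
            epoch_length=7.5, max_lag=10,
        )
        # 30 s / 7.5 s -> 4 epochs -> 3 consecutive distances per replicate
        assert len(null.samples) == 2 * 3
        assert np.all(null.samples >= 0)

    def test_fewer_than_two_matrices_rejected(self, rng):
        seq = [ConnectivityMatrix(random_symmetric(rng, 4))]
        with pytest.raises(ValueError, match="at least 2"):
            build_null_distribution([seq], "matrix_randomization", seed=0)


class TestStabilityThreshold:
    def test_two_sd_below_mean(self):
        samples = np.array([10 - np.sqrt(2), 10 + np.sqrt(2)])  # mean 10, sd 2
        null = NullDistribution(samples, model="matrix_randomization")
        assert stability_threshold(null) == pytest.approx(6.0)

    def test_zero_sd_threshold_equals_mean(self):
        null = NullDistribution(np.array([5.0, 5.0, 5.0]), model="temporal_shift")
        assert stability_threshold(null) == pytest.approx(5.0)

    def test_gaussian_null_flags_phi_minus_two_fraction(self):
        g = np.random.default_rng(123)
        samples = g.normal(20.0, 3.0, 100_000)
        null = NullDistribution(samples, model="matrix_randomization")
        frac = float(np.mean(samples < stability_threshold(null)))
        assert frac == pytest.approx(0.02275, abs=0.002)


class TestDetectStablePeriods:
    @staticmethod
    def _mats(n, rng):
        return [ConnectivityMatrix(random_symmetric(rng, 4), epoch_index=k)
                for k in range(n)]

    def test_two_isolated_stable_transitions(self, rng):
        # distances [5, 7, 4] against threshold 6: transitions 1->2 and 3->4
        # are stable, giving two periods of two epochs each
        mats = self._mats(4, rng)
        periods = detect_stable_periods(np.array([5.0, 7.0, 4.0]), 6.0, 1.875, mats)
        assert [(p.start_epoch, p.end_epoch) for p in periods] == [(0, 1), (2, 3)]
        assert all(p.duration == pytest.approx(2 * 1.875) for p in periods)
        expected = (mats[0].weights + mats[1].weights) / 2
        assert np.allclose(periods[0].averaged_network.weights, expected)

    def test_no_transition_below_threshold(self, rng):
        mats = self._mats(4, rng)
        assert detect_stable_periods(np.array([6.0, 7.0, 8.0]), 6.0, 1.0, mats) == []

    def test_all_stable_spans_whole_window(self, rng):
        mats = self._mats(16, rng)
        periods = detect_stable_periods(np.full(15, 1.0), 2.0, 1.875, mats)
        assert len(periods) == 1
        assert periods[0].duration == pytest.approx(30.0)
        assert periods[0].n_epochs == 16

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            detect_stable_periods(np.array([1.0]), 2.0, 1.0, self._mats(4, rng))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 16))
    def test_period_count_bound_and_minimum_duration(self, seed, n_epochs):
        g = np.random.default_rng(seed)
        mats = self._mats(n_epochs, g)
        d = g.uniform(0, 10, n_epochs - 1)
        periods = detect_stable_periods(d, 5.0, 1.0, mats)
        assert len(periods) <= n_epochs // 2 + (n_epochs % 2)
        for p in periods:
            assert p.duration >= 2 * 1.0  # a period spans at least 2 epochs


class TestDistanceVector:
    def test_consecutive_distances(self, rng):
        mats = [random_symmetric(rng, 4) for _ in range(5)]
        dv = distance_vector(mats, "l1")
        assert len(dv) == 4
        assert dv.values[2] == pytest.approx(edit_distance(mats[2], mats[3]))

    def test_unknown_metric_rejected(self, rng):
        with pytest.raises(ValueError):
            DistanceVector(np.array([1.0]), metric="chebyshev")
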