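"""Histogram mutual information: oracle equivalence, identities, cross-correlation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kpsignal import (VoltageRecording, entropy, joint_probability,
                      max_cross_correlation, mi_matrix, mutual_information)
from kpsignal.synthetic import (ChannelConfig, SyntheticConfig,
                                generate_recording)


def plugin_mi_oracle(p):
    """Exhaustive double-loop plug-in MI (bits) over a joint table."""
    p = np.asarray(p, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    total = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                total += p[i, j] * np.log2(p[i, j] / (px[i] * py[j]))
    return total


def mi_from_counts(counts):
    """Run the package estimator on data realizing an exact joint count table."""
    counts = np.asarray(counts, dtype=int)
    xs, ys = [], []
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            xs += [i] * counts[i, j]
            ys += [j] * counts[i, j]
    return mutual_information(np.array(xs, float), np.array(ys, float),
                              bins=counts.shape[0])


class TestJointProbability:
    def test_two_level_dependent(self):
        p, px, py = joint_probability([0, 1, 0, 1], [0, 1, 0, 1], bins=2)
        np.testing.assert_allclose(p, [[0.5, 0.0], [0.0, 0.5]])
        np.testing.assert_allclose(px, [0.5, 0.5])
        np.testing.assert_allclose(py, [0.5, 0.5])

    def test_normalization_exact(self):
        rng = np.random.default_rng(2)
        p, px, py = joint_probability(rng.normal(size=997), rng.normal(size=997),
                                      bins=7)
        assert abs(p.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(px, p.sum(axis=1))
        np.testing.assert_allclose(py, p.sum(axis=0))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            joint_probability([1, 2], [1, 2, 3], bins=2)


class TestMutualInformation:
    def test_perfectly_dependent_two_levels_one_bit(self):
        x = np.array([0.0, 1.0] * 200)
        assert np.isclose(mutual_information(x, x, bins=2), 1.0)

    def test_four_level_identity_two_bits(self):
        x = np.array([0.0, 1.0, 2.0, 3.0] * 100)
        assert np.isclose(mutual_information(x, x, bins=4), 2.0)
        assert np.isclose(entropy(x, bins=4), 2.0)

    def test_hand_evaluated_asymmetric_table(self):
        # p = [[0.4, 0.1], [0.1, 0.4]] -> 0.8 log2 1.6 + 0.2 log2 0.4
        expected = 0.8 * np.log2(1.6) + 0.2 * np.log2(0.4)
        got = mi_from_counts(np.array([[4000, 1000], [1000, 4000]]))
        assert np.isclose(got, expected, atol=1e-12)
        assert np.isclose(expected, 0.2781, atol=5e-5)

    def test_matches_double_loop_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            b = rng.integers(2, 7)
            counts = rng.multinomial(2000, rng.dirichlet(np.ones(b * b))).reshape(b, b)
            p = counts / counts.sum()
            assert abs(mi_from_counts(counts) - plugin_mi_oracle(p)) < 1e-12

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=500), rng.normal(size=500)
        a = mutual_information(x, y, bins=8)
        b = mutual_information(y, x, bins=8)
        assert np.isclose(a, b, atol=1e-12)
        assert a >= -1e-12

    def test_coarsening_never_increases_mi(self):
        # merging adjacent bins is a deterministic function of the binned
        # variable: data-processing inequality
        rng = np.random.default_rng(6)
        x = rng.normal(size=2000)
        y = x + rng.normal(size=2000)
        mis = [mutual_information(x, y, bins=b) for b in (16, 8, 4, 2)]
        # equal-width edges at b and b/2 are nested, so coarsening halves bins
        assert all(mis[i] >= mis[i + 1] - 1e-12 for i in range(len(mis) - 1))

    def test_rank_mode_monotone_invariance(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(1.0, 2.0, size=1500)
        y = x**2 + rng.uniform(0, 0.1, size=1500)
        base = mutual_information(x, y, bins=10, rank=True)
        warped = mutual_information(np.exp(x), y**3, bins=10, rank=True)
        assert np.isclose(base, warped, atol=1e-12)

    def test_independent_noise_near_plugin_bias(self):
        rng = np.random.default_rng(1)
        vals = [mutual_information(rng.normal(size=3600), rng.normal(size=3600),
                                   bins=10) for _ in range(20)]
        assert max(vals) < 0.05  # bias ~ (B-1)^2 / (2 N ln 2) ~ 0.016 bits

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 6))
    def test_self_mi_equals_entropy_and_log_bound(self, seed, bins):
        x = np.random.default_rng(seed).normal(size=200)
        h = entropy(x, bins=bins)
        assert np.isclose(mutual_information(x, x, bins=bins), h, atol=1e-12)
        assert h <= np.log2(bins) + 1e-12


class TestMIMatrix:
    def test_identical_channels_diag_equals_offdiag(self, two_identical_channels):
        m = mi_matrix(two_identical_channels, bins=10)
        assert np.isclose(m.values[0, 1], m.values[0, 0], atol=1e-12)
        assert np.isclose(m.values[0, 0], m.values[1, 1], atol=1e-12)

    def test_symmetric_with_entropy_diagonal(self):
        rng = np.random.default_rng(12)
        rec = VoltageRecording(fs=1.0, channels=[f"ch{i}" for i in range(4)],
                               values=rng.normal(size=(800, 4)))
        m = mi_matrix(rec, bins=10)
        np.testing.assert_array_equal(m.values, m.values.T)
        for i in range(4):
            assert np.isclose(m.values[i, i], entropy(rec.values[:, i], bins=10))

    def test_coupled_pair_dominates_independent(self):
        cfg = SyntheticConfig(
            channels=[ChannelConfig(noise_std=5.0) for _ in range(6)],
            duration=3600.0, coupling=[(3, 4, 0.95)], seed=21)
        rec, _ = generate_recording(cfg)
        m = mi_matrix(rec, bins=10)
        others = [m.values[i, j] for i, j in
                  itertools.combinations(range(6), 2) if (i, j) != (3, 4)]
        assert m.values[3, 4] >= 10.0 * np.median(others)


class TestMaxCrossCorrelation:
    def test_identity_zero_lag(self):
        x = np.random.default_rng(0).normal(size=300)
        r, lag = max_cross_correlation(x, x, max_lag=10)
        assert np.isclose(r, 1.0) and lag == 0

    def test_shifted_copy_found_at_shift(self):
        x = np.random.default_rng(1).normal(size=500)
        y = np.roll(x, 5)  # y[t] = x[t-5]: y trails x by 5 samples
        r, lag = max_cross_correlation(x[10:-10], y[10:-10], max_lag=8)
        assert r > 0.99 and lag == 5

    def test_independent_noise_small_max(self):
        rng = np.random.default_rng(2)
        r, _ = max_cross_correlation(rng.normal(size=1000),
                                     rng.normal(size=1000), max_lag=10)
        assert r < 0.15

    def test_zero_variance_overlap_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            max_cross_correlation(np.ones(50), np.arange(50.0), max_lag=2)
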