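"""Hebbian association learning and Hopfield energy identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kpsignal import (ActivityPattern, binarize_response, energy_landscape,
                      hebbian_delta, network_energy, train_association)


class TestHebbianDelta:
    def test_scalar_examples(self):
        assert hebbian_delta([1.0], [1.0], 0.1)[0, 0] == pytest.approx(0.1)
        assert hebbian_delta([0.0], [5.0], 0.3)[0, 0] == 0.0
        assert hebbian_delta([2.0], [3.0], 0.01)[0, 0] == pytest.approx(0.06)

    def test_linear_in_epsilon(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=6), rng.normal(size=7)
        np.testing.assert_array_equal(hebbian_delta(a, b, 0.35),
                                      0.35 * hebbian_delta(a, b, 1.0))

    def test_outer_product_shape(self):
        assert hebbian_delta(np.ones(6), np.ones(7), 0.1).shape == (6, 7)


class TestTrainAssociation:
    def test_single_pair_equals_delta(self):
        a, b = [1.0, 0.0, 1.0], [0.0, 1.0]
        wm = train_association([(a, b)], epsilon=0.2)
        np.testing.assert_array_equal(wm.w, hebbian_delta(a, b, 0.2))

    def test_repeated_presentation_additivity(self):
        pair = ([1.0, 1.0], [1.0, 0.0])
        once = train_association([pair], epsilon=0.1).w
        twice = train_association([pair, pair], epsilon=0.1).w
        np.testing.assert_allclose(twice, 2.0 * once)

    def test_orthogonal_pairs_give_identity(self):
        wm = train_association([([1.0, 0.0], [1.0, 0.0]),
                                ([0.0, 1.0], [0.0, 1.0])], epsilon=1.0)
        np.testing.assert_array_equal(wm.w, np.eye(2))

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        pairs = [(rng.normal(size=4), rng.normal(size=4)) for _ in range(5)]
        w1 = train_association(pairs, epsilon=0.1).w
        w2 = train_association(pairs[::-1], epsilon=0.1).w
        np.testing.assert_allclose(w1, w2, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            train_association([([1.0, 0.0], [1.0])], w0=np.zeros((3, 3)))


class TestBinarizeResponse:
    def test_vector_thresholding(self):
        p = binarize_response([0.5, -0.2, 1.1], thresholds=[0.0, 0.0, 0.0])
        np.testing.assert_array_equal(p.values, [1.0, 0.0, 1.0])
        assert p.is_binary and p.width == 3

    def test_all_below_gives_zero_pattern(self):
        p = binarize_response([-1.0, -2.0], thresholds=[0.0, 0.0])
        np.testing.assert_array_equal(p.values, [0.0, 0.0])

    def test_scalar_thermometer_code(self):
        p = binarize_response(0.6, thresholds=[0.1, 0.4, 0.7], width=3)
        np.testing.assert_array_equal(p.values, [1.0, 1.0, 0.0])

    def test_median_thresholds_against_loop_oracle(self):
        rng = np.random.default_rng(2)
        resp = rng.normal(size=(50, 6))
        med = np.median(resp, axis=0)
        for row in resp:
            got = binarize_response(row, thresholds=med).values
            expected = [1.0 if row[b] > med[b] else 0.0 for b in range(6)]
            np.testing.assert_array_equal(got, expected)

    def test_symmetric_coding(self):
        p = ActivityPattern([1.0, 0.0, 1.0])
        np.testing.assert_array_equal(p.to_symmetric().values, [1.0, -1.0, 1.0])


class TestNetworkEnergy:
    def test_zero_weights_zero_energy(self):
        assert network_energy(np.zeros((3, 3)), [1.0, -1.0, 0.5]) == 0.0

    def test_two_unit_symmetric_example(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert network_energy(w, [1.0, 1.0]) == pytest.approx(-1.0)

    def test_bilinear_scaling(self):
        rng = np.random.default_rng(3)
        w = rng.normal(size=(5, 5))
        a = rng.normal(size=5)
        assert network_energy(w, 2.0 * a) == pytest.approx(4.0 * network_energy(w, a))

    def test_symmetrization_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            w = rng.normal(size=(6, 6))
            a = rng.normal(size=6)
            ws = 0.5 * (w + w.T)
            assert network_energy(w, a) == pytest.approx(network_energy(ws, a))

    def test_single_flip_matches_brute_force(self):
        # flipping one +-1 unit changes E by the local-field amount
        rng = np.random.default_rng(5)
        w = rng.normal(size=(6, 6))
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        s = rng.choice([-1.0, 1.0], size=6)
        for i in range(6):
            flipped = s.copy()
            flipped[i] = -flipped[i]
            predicted = 2.0 * s[i] * (w[i] @ s)
            assert (network_energy(w, flipped) - network_energy(w, s)
                    == pytest.approx(predicted))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            network_energy(np.zeros((2, 3)), [1.0, 1.0])


class TestEnergyLandscape:
    def test_zero_weights_flat_surface(self):
        ls = energy_landscape(np.zeros((2, 2)), 0, 1, grid=11)
        np.testing.assert_array_equal(ls.energy, 0.0)

    def test_positive_coupling_minima_at_aligned_corners(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        ls = energy_landscape(w, 0, 1, grid=21)
        e = ls.energy
        corners = {(0, 0): e[0, 0], (0, -1): e[0, -1],
                   (-1, 0): e[-1, 0], (-1, -1): e[-1, -1]}
        # aligned corners (product +1) are the two equal minima: E = -1
        assert corners[(0, 0)] == pytest.approx(-1.0)
        assert corners[(-1, -1)] == pytest.approx(-1.0)
        assert corners[(0, -1)] == pytest.approx(1.0)
        assert e.min() == pytest.approx(-1.0)

    def test_determinism(self):
        rng = np.random.default_rng(6)
        w = rng.normal(size=(4, 4))
        a = energy_landscape(w, 1, 3, grid=15, fixed=[0.2, 0.0, -0.1, 0.0])
        b = energy_landscape(w, 1, 3, grid=15, fixed=[0.2, 0.0, -0.1, 0.0])
        np.testing.assert_array_equal(a.energy, b.energy)

    def test_same_unit_rejected(self):
        with pytest.raises(ValueError):
            energy_landscape(np.zeros((3, 3)), 1, 1)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_training_is_pure_summation(seed):
    rng = np.random.default_rng(seed)
    pairs = [(rng.normal(size=3), rng.normal(size=3)) for _ in range(4)]
    total = train_association(pairs, epsilon=0.1).w
    manual = sum(hebbian_delta(a, b, 0.1) for a, b in pairs)
    np.testing.assert_allclose(total, manual, atol=1e-12)
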