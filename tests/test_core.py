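"""Aitchison geometry, pivot ilr/clr maps and their exact identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import codaprop as cp
from conftest import random_composition

E = np.e


positive_vectors = st.integers(2, 8).flatmap(
    lambda D: st.lists(st.floats(1e-4, 1e4), min_size=D, max_size=D)
).map(np.asarray)


class TestClosure:
    @pytest.mark.parametrize("x, kappa, expected", [
        ((1, 1, 2), 1.0, (0.25, 0.25, 0.5)),
        ((2, 3, 5), 100.0, (20, 30, 50)),
    ])
    def test_proportional_rescaling(self, x, kappa, expected):
        np.testing.assert_allclose(cp.closure(np.asarray(x, float), kappa),
                                   expected)

    def test_idempotent(self, rng):
        x = random_composition(rng, 5)
        np.testing.assert_allclose(cp.closure(cp.closure(x)), cp.closure(x))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="positive"):
            cp.closure(np.array([1.0, 0.0, 2.0]))
        with pytest.raises(ValueError, match="kappa"):
            cp.closure(np.array([1.0, 2.0]), kappa=-1)


class TestPerturbationAndPowering:
    def test_neutral_element_and_inverse(self, rng):
        x = random_composition(rng, 4)
        neutral = np.ones(4)
        np.testing.assert_allclose(cp.perturb(x, neutral), cp.closure(x))
        np.testing.assert_allclose(cp.perturb(x, cp.power(-1.0, x)),
                                   cp.closure(neutral), atol=1e-15)

    def test_examples(self):
        np.testing.assert_allclose(
            cp.perturb(np.array([2.0, 1.0]), np.array([1.0, 2.0])), [0.5, 0.5])
        np.testing.assert_allclose(
            cp.power(2.0, np.array([2.0, 1.0])), [0.8, 0.2])

    def test_power_degenerate_exponents(self, rng):
        x = random_composition(rng, 3)
        np.testing.assert_allclose(cp.power(0.0, x), np.ones(3) / 3)
        np.testing.assert_allclose(cp.power(1.0, x), cp.closure(x))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            cp.perturb(np.ones(3), np.ones(4))


class TestInnerNormDistance:
    def test_inner_with_neutral_is_zero(self, rng):
        x = random_composition(rng, 5)
        assert cp.aitchison_inner(x, np.ones(5)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_expanded_values(self):
        # D=2: <(e,1),(e,1)> = (1/4)*[ln e * ln e]*2 terms = 0.5
        v = cp.aitchison_inner(np.array([E, 1.0]), np.array([E, 1.0]))
        assert v == pytest.approx(0.5, abs=1e-12)
        assert cp.aitchison_norm(np.array([E, 1.0])) == pytest.approx(
            np.sqrt(0.5), abs=1e-10)
        assert cp.aitchison_distance(np.array([E, 1.0]),
                                     np.array([1.0, E])) == pytest.approx(
            np.sqrt(2.0), abs=1e-10)

    def test_metric_and_bilinearity_axioms(self, rng):
        x, y = random_composition(rng, 6), random_composition(rng, 6)
        assert cp.aitchison_inner(x, y) == pytest.approx(
            cp.aitchison_inner(y, x), rel=1e-12)
        assert cp.aitchison_distance(x, x) == pytest.approx(0.0, abs=1e-12)
        assert cp.aitchison_distance(x, y) == pytest.approx(
            cp.aitchison_distance(y, x), rel=1e-12)
        a = -1.7
        assert cp.aitchison_norm(cp.power(a, x)) == pytest.approx(
            abs(a) * cp.aitchison_norm(x), rel=1e-10)


class TestGeometricMean:
    @pytest.mark.parametrize("x, expected", [
        ((1, 1, 1), 1.0), ((2, 8), 4.0), ((1, 2, 4), 2.0),
    ])
    def test_values(self, x, expected):
        assert cp.geometric_mean(np.asarray(x, float)) == pytest.approx(expected)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            cp.geometric_mean(np.array([1.0, -2.0]))


class TestIlrPivot:
    def test_neutral_maps_to_origin(self):
        np.testing.assert_allclose(cp.ilr_pivot(np.ones(3) / 3), [0.0, 0.0],
                                   atol=1e-15)

    def test_hand_values(self):
        np.testing.assert_allclose(cp.ilr_pivot(np.array([E, 1.0])),
                                   [np.sqrt(0.5)], atol=1e-12)
        np.testing.assert_allclose(cp.ilr_pivot(np.array([4.0, 2.0, 2.0])),
                                   [np.sqrt(2 / 3) * np.log(2), 0.0],
                                   atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(positive_vectors, st.floats(1e-3, 1e3))
    def test_scale_invariance(self, x, k):
        np.testing.assert_allclose(cp.ilr_pivot(k * x), cp.ilr_pivot(x),
                                   atol=1e-10)

    def test_round_trip_and_inverse_values(self, rng):
        x = random_composition(rng, 7)
        z = cp.ilr_pivot(x)
        np.testing.assert_allclose(cp.ilr_inverse(z), cp.closure(x),
                                   atol=1e-12)
        np.testing.assert_allclose(cp.ilr_pivot(cp.ilr_inverse(z)), z,
                                   atol=1e-12)
        np.testing.assert_allclose(cp.ilr_inverse(np.zeros(4)),
                                   np.ones(5) / 5, atol=1e-15)
        np.testing.assert_allclose(cp.ilr_inverse(np.array([np.sqrt(0.5)])),
                                   cp.closure(np.array([E, 1.0])), atol=1e-12)

    def test_dataframe_in_dataframe_out(self, toy_matrix):
        Z = cp.ilr_pivot(toy_matrix)
        assert isinstance(Z, pd.DataFrame)
        assert list(Z.columns) == ["z_1", "z_2"]
        np.testing.assert_allclose(Z.to_numpy(),
                                   cp.ilr_pivot(toy_matrix.to_numpy()))


class TestClr:
    def test_values_and_centering(self, rng):
        np.testing.assert_allclose(
            cp.clr_coefficients(np.array([4.0, 2.0, 2.0])),
            [0.46209812, -0.23104906, -0.23104906], atol=1e-8)
        c = cp.clr_coefficients(random_composition(rng, 9))
        assert c.sum() == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(cp.clr_coefficients(np.ones(4)),
                                   np.zeros(4), atol=1e-15)

    def test_clr_ilr_link(self, rng):
        # z_1 = sqrt(D/(D-1)) * clr_1 for every composition
        for D in (2, 5, 12):
            x = random_composition(rng, D)
            z1 = cp.ilr_pivot(x)[0]
            clr1 = cp.clr_coefficients(x)[0]
            assert z1 == pytest.approx(np.sqrt(D / (D - 1)) * clr1, rel=1e-10)


class TestPivotToFront:
    def test_reorders_and_preserves(self, toy_matrix):
        out = cp.pivot_to_front(toy_matrix, "c")
        assert list(out.columns) == ["c", "a", "b"]
        assert list(cp.pivot_to_front(toy_matrix, "a").columns) == ["a", "b", "c"]
        with pytest.raises(KeyError):
            cp.pivot_to_front(toy_matrix, "nope")

    def test_front_coordinate_carries_the_part(self, toy_matrix):
        # z_1 after pivoting "c" to the front is proportional to clr of c
        out = cp.pivot_to_front(toy_matrix, "c")
        Z = cp.ilr_pivot(out).to_numpy()
        D = out.shape[1]
        clr_c = cp.clr_coefficients(out).to_numpy()[:, 0]
        np.testing.assert_allclose(Z[:, 0], np.sqrt(D / (D - 1)) * clr_c,
                                   atol=1e-12)


class TestIsometryAndLinearity:
    def test_isometry_random_pairs(self, rng):
        for D in (2, 3, 5, 20):
            for _ in range(25):
                x, y = random_composition(rng, D), random_composition(rng, D)
                dz = np.linalg.norm(cp.ilr_pivot(x) - cp.ilr_pivot(y))
                assert abs(cp.aitchison_distance(x, y) - dz) < 1e-10
                ip = float(np.dot(cp.ilr_pivot(x), cp.ilr_pivot(y)))
                assert abs(cp.aitchison_inner(x, y) - ip) < 1e-10

    def test_linearity(self, rng):
        x, y = random_composition(rng, 8), random_composition(rng, 8)
        np.testing.assert_allclose(cp.ilr_pivot(cp.perturb(x, y)),
                                   cp.ilr_pivot(x) + cp.ilr_pivot(y),
                                   atol=1e-12)
        np.testing.assert_allclose(cp.ilr_pivot(cp.power(2.5, x)),
                                   2.5 * cp.ilr_pivot(x), atol=1e-12)


def test_validate_composition_matrix_errors():
    bad = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, -1.0]})
    with pytest.raises(ValueError, match="'b'"):
        cp.validate_composition_matrix(bad)
    arr = np.array([[1.0, 2.0], [3.0, 4.0]])
    df = cp.validate_composition_matrix(arr)
    assert list(df.columns) == ["part_1", "part_2"]
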