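"""Correlation-matrix builders against brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fastfc import (
    TetrachoricLookupTable,
    TriangularCorrelationMatrix,
    dichotomize_matrix,
    n11_pair,
    pack,
    pearson_matrix,
    pearson_pair,
    tetrachoric_from_n11,
    tetrachoric_matrix,
    triangular_index,
)


def naive_pearson_triangle(x):
    """Double-loop textbook oracle."""
    V = x.shape[0]
    out = np.empty(V * (V - 1) // 2)
    pos = 0
    for i in range(V):
        for j in range(i + 1, V):
            xi = x[i] - x[i].mean()
            xj = x[j] - x[j].mean()
            out[pos] = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
            pos += 1
    return out


def naive_tetrachoric_triangle(bits):
    """Per-pair -cos(2*pi*p11) from unpacked bits."""
    V, T = bits.shape
    out = np.empty(V * (V - 1) // 2)
    pos = 0
    for i in range(V):
        for j in range(i + 1, V):
            n11 = int(np.sum(bits[i] & bits[j]))
            out[pos] = -np.cos(2 * np.pi * n11 / T)
            pos += 1
    return out


class TestTriangularIndex:
    def test_known_positions(self):
        assert triangular_index(0, 1, 4) == 0
        assert triangular_index(2, 3, 4) == 5

    def test_symmetric_and_rejects_diagonal(self):
        assert triangular_index(3, 1, 10) == triangular_index(1, 3, 10)
        with pytest.raises(ValueError):
            triangular_index(2, 2, 10)

    @pytest.mark.parametrize("V", [2, 3, 7, 30])
    def test_bijection_by_enumeration(self, V):
        seen = [triangular_index(i, j, V) for i, j in itertools.combinations(range(V), 2)]
        assert sorted(seen) == list(range(V * (V - 1) // 2))


class TestPearson:
    def test_known_pairs(self):
        assert pearson_pair([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert pearson_pair([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
        assert pearson_pair([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        assert pearson_pair(3.2 * x - 7, y) == pytest.approx(pearson_pair(x, y))

    def test_constant_input_missing(self):
        with pytest.warns(UserWarning):
            assert np.isnan(pearson_pair([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_matrix_against_double_loop_oracle(self, rng):
        x = rng.standard_normal((50, 200))
        C = pearson_matrix(x, block=16)
        np.testing.assert_allclose(C.values, naive_pearson_triangle(x), rtol=0, atol=1e-6)

    @pytest.mark.parametrize("block", [1, 3, 17, 50, 256])
    def test_blocking_invariance(self, rng, block):
        x = rng.standard_normal((23, 40))
        ref = pearson_matrix(x, block=23).values
        np.testing.assert_allclose(pearson_matrix(x, block=block).values, ref, atol=1e-12)

    def test_duplicated_rows_give_unit_correlation(self, rng):
        x = rng.standard_normal((3, 30))
        x[1] = x[0]
        assert pearson_matrix(x).lookup(0, 1) == pytest.approx(1.0)

    def test_degenerate_row_masks_its_pairs(self, rng):
        x = rng.standard_normal((4, 30))
        x[2] = 5.0
        C = pearson_matrix(x)
        assert np.isnan(C.lookup(0, 2)) and np.isnan(C.lookup(2, 3))
        assert np.isfinite(C.lookup(0, 1))
        assert C.missing_count == 3

    def test_single_row_rejected(self, rng):
        with pytest.raises(ValueError):
            pearson_matrix(rng.standard_normal((1, 30)))


class TestTetrachoric:
    def test_closed_form_anchor_points(self):
        assert tetrachoric_from_n11(25, 100) == pytest.approx(0.0, abs=1e-12)  # T/4
        assert tetrachoric_from_n11(50, 100) == pytest.approx(1.0)  # T/2
        assert tetrachoric_from_n11(0, 100) == pytest.approx(-1.0)

    def test_monotone_on_lower_half(self):
        vals = [tetrachoric_from_n11(n, 100) for n in range(51)]
        assert np.all(np.diff(vals) > 0)

    def test_above_attainable_max_warns_but_computes(self):
        with pytest.warns(UserWarning):
            v = tetrachoric_from_n11(80, 100)
        assert v == pytest.approx(-np.cos(2 * np.pi * 0.8))

    @pytest.mark.parametrize("T, expected", [(100, np.arange(0, 51)), (119, np.arange(1, 61))])
    def test_lookup_table_attainable_sets(self, T, expected):
        lut = TetrachoricLookupTable.build(T)
        assert (lut.attainable_n11 == expected).all()
        np.testing.assert_allclose(lut.table, -np.cos(2 * np.pi * np.arange(T + 1) / T))

    @pytest.mark.parametrize("T", [99, 100, 119, 275])
    def test_n11_pair_matches_bit_dot_product(self, rng, T):
        bits, _ = dichotomize_matrix(rng.standard_normal((2, T)))
        pb = pack(bits, 64)
        assert n11_pair(pb.words[0], pb.words[1]) == int((bits[0] & bits[1]).sum())

    def test_n11_self_and_complement(self, rng):
        bits, _ = dichotomize_matrix(rng.standard_normal((1, 100)))
        comp = 1 - bits
        pb = pack(np.vstack([bits, comp]), 64)
        assert n11_pair(pb.words[0], pb.words[0]) == 50
        assert n11_pair(pb.words[0], pb.words[1]) == 0

    @pytest.mark.parametrize("T", [99, 100, 119, 275])
    @pytest.mark.parametrize("word_width", [8, 32, 64])
    def test_matrix_matches_unpacked_oracle_bit_exactly(self, rng, T, word_width):
        bits, deg = dichotomize_matrix(rng.standard_normal((20, T)))
        C = tetrachoric_matrix(pack(bits, word_width, deg))
        assert (C.values == naive_tetrachoric_triangle(bits)).all()

    def test_values_confined_to_attainable_set(self, rng):
        T = 100
        bits, deg = dichotomize_matrix(rng.standard_normal((30, T)))
        C = tetrachoric_matrix(pack(bits, 64, deg))
        lut = TetrachoricLookupTable.build(T)
        assert np.isin(C.values, lut.attainable_values).all()

    def test_duplicated_rows_give_unit_correlation(self, rng):
        x = rng.standard_normal((2, 100))
        x = np.vstack([x, x[0]])
        bits, deg = dichotomize_matrix(x)
        C = tetrachoric_matrix(pack(bits, 64, deg))
        assert C.lookup(0, 2) == pytest.approx(1.0)

    def test_degenerate_rows_masked(self):
        x = np.vstack([np.arange(10.0), np.ones(10), np.arange(10.0)[::-1]])
        with pytest.warns(UserWarning):
            bits, deg = dichotomize_matrix(x)
        C = tetrachoric_matrix(pack(bits, 64, deg))
        assert np.isnan(C.lookup(0, 1)) and np.isnan(C.lookup(1, 2))
        assert np.isfinite(C.lookup(0, 2))


class TestTriangleContainer:
    def test_dense_export_is_symmetric(self, rng):
        C = pearson_matrix(rng.standard_normal((6, 20)))
        dense = C.to_dense()
        assert (dense == dense.T).all()
        assert dense[2, 4] == C.lookup(4, 2)
        assert (np.diag(dense) == 1.0).all()

    def test_save_load_roundtrip(self, rng, tmp_path):
        C = pearson_matrix(rng.standard_normal((6, 20)))
        C.save(tmp_path / "tri")
        back = TriangularCorrelationMatrix.load(tmp_path / "tri")
        np.testing.assert_array_equal(back.values, C.values)
        assert (back.V, back.T, back.estimator) == (C.V, C.T, C.estimator)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    V=st.integers(2, 12),
    T=st.integers(4, 60),
    block=st.integers(1, 13),
    seed=st.integers(0, 2**16),
)
def test_builders_agree_with_oracles_property(V, T, block, seed):
    """Both builders reproduce their brute-force oracles on random shapes."""
    x = np.random.default_rng(seed).standard_normal((V, T))
    np.testing.assert_allclose(
        pearson_matrix(x, block=block).values, naive_pearson_triangle(x), atol=1e-9
    )
    bits, deg = dichotomize_matrix(x)
    assert (
        tetrachoric_matrix(pack(bits, 32, deg)).values == naive_tetrachoric_triangle(bits)
    ).all()
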