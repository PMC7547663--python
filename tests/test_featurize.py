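"""Moment features: encodings, raw/central/Hahn moments, PRIM/RPRIM, scaling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.preprocessing import MinMaxScaler, StandardScaler

from glapred import (
    AMINO_ACIDS,
    DEFAULT_ORDERS,
    FeaturizeConfig,
    HahnBasis,
    apply_scaler,
    central_moments,
    compute_prim,
    compute_rprim,
    encode_residues,
    feature_names,
    featurize,
    fit_scaler,
    get_hahn_basis,
    hahn_moments,
    hahn_polynomial,
    hahn_reconstruct,
    inverse_scale,
    raw_moments,
    reduce_matrix,
    sequence_to_matrix,
)

residue_text = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=41)


# --------------------------------------------------------------------------
# Independent oracles
# --------------------------------------------------------------------------

def brute_raw(beta, i, j):
    n = beta.shape[0]
    return sum(
        (b**i) * (q**j) * beta[b - 1, q - 1]
        for b in range(1, n + 1)
        for q in range(1, n + 1)
    )


def brute_central(beta, i, j):
    m00 = brute_raw(beta, 0, 0)
    xbar = brute_raw(beta, 1, 0) / m00
    ybar = brute_raw(beta, 0, 1) / m00
    n = beta.shape[0]
    return sum(
        ((b - xbar) ** i) * ((q - ybar) ** j) * beta[b - 1, q - 1]
        for b in range(1, n + 1)
        for q in range(1, n + 1)
    )


def pochhammer(a, k):
    p = 1.0
    for m in range(k):
        p *= a + m
    return p


def series_hahn(n, r, N, u=0.0, v=0.0):
    """Term-by-term evaluation of the Hahn series, kept independent of the
    implementation's incremental-ratio scheme."""
    from math import factorial

    pref = pochhammer(N + v - 1, n) * pochhammer(N - 1, n)
    total = sum(
        (-1) ** k
        * pochhammer(-n, k)
        * pochhammer(-r, k)
        * pochhammer(2 * N + u + v - n - 1, k)
        / (pochhammer(N + v - 1, k) * pochhammer(N - 1, k) * factorial(k))
        for k in range(n + 1)
    )
    return pref * total


# --------------------------------------------------------------------------
# Encoding and matrix mapping
# --------------------------------------------------------------------------

class TestEncoding:
    def test_alphabet_endpoints_and_pad(self, make_window):
        assert encode_residues(make_window("A")).tolist() == [1]
        assert encode_residues(make_window("Y")).tolist() == [20]
        assert encode_residues(make_window("X")).tolist() == [0]

    def test_index_lookup(self, make_window):
        assert encode_residues(make_window("ACE")).tolist() == [1, 2, 4]

    def test_row_major_fill_with_zero_tail(self, make_window):
        grid = sequence_to_matrix(make_window("A" * 41), n=7).values
        flat = grid.ravel()
        assert flat[:41].tolist() == [1.0] * 41
        assert flat[41:].tolist() == [0.0] * 8

    def test_all_pad_window_maps_to_zero_matrix(self, make_window):
        grid = sequence_to_matrix(make_window("X" * 41), n=7).values
        assert not grid.any()

    def test_too_small_matrix_rejected(self, make_window):
        with pytest.raises(ValueError):
            sequence_to_matrix(make_window("A" * 41), n=6)


# --------------------------------------------------------------------------
# Raw and central moments
# --------------------------------------------------------------------------

class TestRawCentralMoments:
    def test_two_by_two_hand_case(self):
        beta = np.array([[1.0, 2.0], [3.0, 4.0]])
        values = dict(zip(DEFAULT_ORDERS, raw_moments(beta).values))
        assert values[(0, 0)] == 10
        assert values[(1, 0)] == 17
        assert values[(0, 1)] == 16
        assert values[(1, 1)] == 27

    def test_all_ones_mass(self):
        beta = np.ones((5, 5))
        assert raw_moments(beta).values[0] == 25

    def test_zero_matrix_annihilates(self):
        beta = np.zeros((7, 7))
        assert not raw_moments(beta).values.any()
        assert not central_moments(beta).values.any()

    def test_order_beyond_three_rejected(self):
        with pytest.raises(ValueError):
            raw_moments(np.ones((3, 3)), orders=[(2, 2)])
        with pytest.raises(ValueError):
            central_moments(np.ones((3, 3)), orders=[(4, 0)])

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(200):
            beta = rng.integers(0, 21, size=(7, 7)).astype(float)
            raw = raw_moments(beta).values
            cen = central_moments(beta).values
            for k, (i, j) in enumerate(DEFAULT_ORDERS):
                assert raw[k] == pytest.approx(brute_raw(beta, i, j), abs=1e-9)
                if beta.sum() > 0:
                    assert cen[k] == pytest.approx(brute_central(beta, i, j), abs=1e-9)

    def test_first_order_central_moments_vanish(self, rng):
        for _ in range(50):
            beta = rng.random((7, 7)) + 0.01
            values = dict(zip(DEFAULT_ORDERS, central_moments(beta).values))
            assert values[(1, 0)] == pytest.approx(0.0, abs=1e-9)
            assert values[(0, 1)] == pytest.approx(0.0, abs=1e-9)

    def test_central_moments_translation_invariance(self, rng):
        # shifting the mass by whole rows/columns leaves order >= 2 unchanged
        beta = np.zeros((9, 9))
        beta[1:5, 2:6] = rng.random((4, 4)) + 0.1
        shifted = np.roll(np.roll(beta, 3, axis=0), 2, axis=1)
        orders = [(1, 1), (2, 1), (1, 2), (3, 0), (0, 3)]
        np.testing.assert_allclose(
            central_moments(beta, orders).values,
            central_moments(shifted, orders).values,
            atol=1e-9,
        )

    def test_zero_mass_centroid_falls_back_to_center(self, caplog):
        with caplog.at_level("INFO"):
            values = central_moments(np.zeros((3, 3))).values
        assert not values.any()


# --------------------------------------------------------------------------
# Hahn polynomials, basis, moments
# --------------------------------------------------------------------------

class TestHahn:
    def test_order_zero_is_one_everywhere(self):
        assert all(hahn_polynomial(0, r, 7) == 1.0 for r in range(7))

    def test_pochhammer_base_case(self):
        assert pochhammer(-3.7, 0) == 1.0

    def test_order_one_against_series_oracle(self):
        # closed form at N=7, u=v=0: h_1(r) = 36 - 12 r
        for r in range(7):
            value = hahn_polynomial(1, r, 7)
            assert value == pytest.approx(36.0 - 12.0 * r, abs=1e-9)
            assert value == pytest.approx(series_hahn(1, r, 7), abs=1e-9)

    @pytest.mark.parametrize("n", range(7))
    def test_matches_series_oracle_all_orders(self, n):
        for r in range(7):
            assert hahn_polynomial(n, r, 7, u=0.5, v=1.5) == pytest.approx(
                series_hahn(n, r, 7, u=0.5, v=1.5), rel=1e-10, abs=1e-10
            )

    def test_out_of_range_arguments_rejected(self):
        with pytest.raises(ValueError):
            hahn_polynomial(7, 0, 7)
        with pytest.raises(ValueError):
            hahn_polynomial(0, 7, 7)

    @pytest.mark.parametrize("N,u,v", [(7, 0.0, 0.0), (7, 1.0, 2.0), (20, 0.0, 0.0)])
    def test_basis_rows_orthonormal(self, N, u, v):
        table = HahnBasis.build(N, u, v).table
        np.testing.assert_allclose(table @ table.T, np.eye(N), atol=1e-8)

    def test_full_order_transform_reconstructs(self, rng):
        basis = get_hahn_basis(7)
        for _ in range(20):
            beta = rng.random((7, 7)) * 20
            full = basis.table @ beta @ basis.table.T
            np.testing.assert_allclose(hahn_reconstruct(full, basis), beta, atol=1e-6)

    def test_moments_match_brute_force_double_sum(self, rng):
        basis = get_hahn_basis(3)
        beta = rng.random((3, 3))
        values = hahn_moments(beta, basis, orders=[(0, 0), (1, 1), (2, 1)]).values
        for k, (i, j) in enumerate([(0, 0), (1, 1), (2, 1)]):
            expected = sum(
                beta[q, b] * basis.table[i, q] * basis.table[j, b]
                for q in range(3)
                for b in range(3)
            )
            assert values[k] == pytest.approx(expected, abs=1e-12)

    def test_zero_matrix_gives_zero_moments(self):
        basis = get_hahn_basis(7)
        assert not hahn_moments(np.zeros((7, 7)), basis).values.any()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hahn_moments(np.zeros((5, 5)), get_hahn_basis(7))


# --------------------------------------------------------------------------
# PRIM / RPRIM
# --------------------------------------------------------------------------

class TestIncidenceMatrices:
    def test_shapes_are_400_coefficients(self, make_window):
        w = make_window("ACDEFGHIKL" * 4 + "M")
        assert compute_prim(w).values.size == 400
        assert compute_rprim(w).values.size == 400

    def test_single_residue_type_populates_one_row(self, make_window):
        prim = compute_prim(make_window("A" * 41)).values
        a = AMINO_ACIDS.index("A")
        assert prim[a, a] == sum(p - 1 for p in range(2, 42))
        mask = np.ones(20, dtype=bool)
        mask[a] = False
        assert not prim[mask, :].any()
        assert not prim[:, mask].any()

    def test_toy_peptide_hand_enumeration(self, make_window):
        prim = compute_prim(make_window("ACA")).values
        a, c = AMINO_ACIDS.index("A"), AMINO_ACIDS.index("C")
        assert prim[a, c] == 1  # C at 2 relative to first A at 1
        assert prim[a, a] == 2  # second A at 3 relative to first A at 1
        assert prim[c, a] == 1  # A at 3 relative to first C at 2
        assert prim[c, c] == 0

    def test_palindrome_rprim_equals_prim(self, make_window):
        w = make_window("ACA")
        np.testing.assert_array_equal(compute_prim(w).values, compute_rprim(w).values)

    @given(residue_text)
    def test_rprim_is_prim_of_reversed_window(self, seq):
        from glapred import PeptideWindow

        w = PeptideWindow(seq, 0, "H", 1)
        w_rev = PeptideWindow(seq[::-1], 0, "H", 1)
        np.testing.assert_array_equal(
            compute_rprim(w).values, compute_prim(w_rev).values
        )

    def test_pad_only_window_gives_zero_matrix(self, make_window):
        assert not compute_prim(make_window("X" * 41)).values.any()

    def test_pads_keep_window_positions(self, make_window):
        # "XAX C": A at window position 2, C at 4 -> offset 2 despite the pad
        prim = compute_prim(make_window("XAXC")).values
        a, c = AMINO_ACIDS.index("A"), AMINO_ACIDS.index("C")
        assert prim[a, c] == 2


# --------------------------------------------------------------------------
# Reduction, assembly, scaling
# --------------------------------------------------------------------------

class TestReduceAndFeaturize:
    def test_reduction_yields_24_values(self, rng):
        assert reduce_matrix(rng.random((7, 7))).shape == (24,)
        assert reduce_matrix(rng.random((20, 20))).shape == (24,)

    def test_zero_matrix_reduces_to_zeros(self):
        assert not reduce_matrix(np.zeros((7, 7))).any()

    def test_reduction_is_deterministic(self, rng):
        beta = rng.random((20, 20))
        np.testing.assert_array_equal(reduce_matrix(beta), reduce_matrix(beta))

    def test_non_square_rejected(self, rng):
        with pytest.raises(ValueError):
            reduce_matrix(rng.random((7, 6)))

    def test_feature_vector_length_and_layout(self, small_dataset):
        _, _, windows = small_dataset
        fv = featurize(windows[0])
        assert len(fv.values) == 72
        assert fv.layout == (("win", 24), ("prim", 24), ("rprim", 24))
        assert len(feature_names()) == 72

    def test_identical_windows_identical_vectors(self, small_dataset):
        _, _, windows = small_dataset
        np.testing.assert_array_equal(
            featurize(windows[3]).values, featurize(windows[3]).values
        )

    def test_reverse_window_swaps_prim_and_rprim_segments(self, make_window):
        w = make_window("ACDEFGHIKLMNPQRSTVWYEAYWVTSRQPNMLKIHGFEDC")
        w_rev = make_window(w.residues[::-1])
        fv, fv_rev = featurize(w), featurize(w_rev)
        np.testing.assert_allclose(fv.values[24:48], fv_rev.values[48:72], atol=1e-9)
        np.testing.assert_allclose(fv.values[48:72], fv_rev.values[24:48], atol=1e-9)


class TestScaling:
    def test_minmax_endpoints(self):
        X = np.array([[2.0], [4.0], [6.0]])
        params = fit_scaler(X, mode="minmax")
        np.testing.assert_allclose(
            apply_scaler(params, X).ravel(), [0.0, 0.5, 1.0]
        )

    def test_standard_mode_centres_and_scales(self, rng):
        X = rng.random((40, 5)) * 10
        scaled = apply_scaler(fit_scaler(X, mode="standard"), X)
        np.testing.assert_allclose(scaled.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(scaled.std(axis=0), 1.0, atol=1e-12)

    def test_constant_feature_maps_to_zero(self):
        X = np.array([[3.0, 1.0], [3.0, 2.0], [3.0, 3.0]])
        for mode in ("standard", "minmax"):
            scaled = apply_scaler(fit_scaler(X, mode=mode), X)
            assert not scaled[:, 0].any()

    def test_agrees_with_sklearn_scalers(self, rng):
        X = rng.random((30, 8)) * 5
        np.testing.assert_allclose(
            apply_scaler(fit_scaler(X, "standard"), X),
            StandardScaler().fit_transform(X),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            apply_scaler(fit_scaler(X, "minmax"), X),
            MinMaxScaler().fit_transform(X),
            atol=1e-12,
        )

    def test_round_trip_inverse(self, rng):
        X = rng.random((25, 6))
        for mode in ("standard", "minmax"):
            params = fit_scaler(X, mode=mode)
            np.testing.assert_allclose(
                inverse_scale(params, apply_scaler(params, X)), X, atol=1e-12
            )

    def test_json_round_trip(self, tmp_path, rng):
        from glapred import ScalerParams

        X = rng.random((10, 4))
        params = fit_scaler(X, mode="minmax")
        params.to_json(tmp_path / "s.json")
        back = ScalerParams.from_json(tmp_path / "s.json")
        np.testing.assert_array_equal(
            apply_scaler(params, X), apply_scaler(back, X)
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_scaler(np.empty((0, 3)))

    def test_config_controls_orders_and_layout(self, small_dataset):
        _, _, windows = small_dataset
        config = FeaturizeConfig(orders=((0, 0), (1, 1)))
        fv = featurize(windows[0], config)
        assert len(fv.values) == 18  # 3 segments x 3 families x 2 orders
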