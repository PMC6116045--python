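import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_local_dpp
from dbpstack.features_evolutionary import (
    DwtConfig,
    NormalizedPssm,
    SegmentSpec,
    dwt_column_features,
    dwt_decompose,
    local_dpp,
    normalize_pssm,
    pssm_dwt,
    segment_bounds,
)
from dbpstack.io_formats import PssmProfile


def random_normalized(rng, length):
    return normalize_pssm(
        PssmProfile("r", rng.normal(size=(length, 20)))
    )


class TestNormalizePssm:
    def test_two_point_column_is_plus_minus_one(self):
        scores = np.zeros((2, 20))
        scores[:, 3] = [1.0, 3.0]
        out = normalize_pssm(PssmProfile("r", scores)).values
        np.testing.assert_allclose(out[:, 3], [-1.0, 1.0])

    def test_constant_column_maps_to_zero(self):
        scores = np.full((3, 20), 5.0)
        out = normalize_pssm(PssmProfile("r", scores)).values
        assert np.all(out == 0.0)

    def test_nonconstant_columns_are_z_scored(self):
        rng = np.random.default_rng(0)
        out = random_normalized(rng, 37).values
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-9)

    def test_single_row_profile_rejected(self):
        with pytest.raises(ValueError):
            normalize_pssm(PssmProfile("r", np.zeros((1, 20))))


class TestSegmentBounds:
    @pytest.mark.parametrize(
        "length,n,expected",
        [
            (7, 2, [(0, 3), (3, 7)]),
            (6, 3, [(0, 2), (2, 4), (4, 6)]),
            (5, 1, [(0, 5)]),
        ],
    )
    def test_floor_partition(self, length, n, expected):
        assert segment_bounds(length, n) == expected

    def test_oversplit_rejected(self):
        with pytest.raises(ValueError):
            segment_bounds(3, 4)

    @given(st.integers(1, 200), st.integers(1, 10))
    @settings(max_examples=60, derandomize=True)
    def test_ranges_tile_without_overlap(self, length, n):
        if length // n == 0:
            return
        bounds = segment_bounds(length, n)
        assert bounds[0][0] == 0 and bounds[-1][1] == length
        for (_, prev_end), (start, _) in zip(bounds, bounds[1:]):
            assert prev_end == start


class TestLocalDpp:
    @pytest.mark.parametrize("n,lam", [(2, 2), (3, 1)])
    def test_dimension_is_20_times_1_plus_lambda_times_n(self, n, lam):
        rng = np.random.default_rng(1)
        block = local_dpp(random_normalized(rng, 60), SegmentSpec(n, lam))
        assert len(block) == 20 * (1 + lam) * n == 120

    def test_zero_matrix_yields_zero_vector(self):
        npssm = NormalizedPssm(np.zeros((40, 20)), "r")
        assert np.all(local_dpp(npssm, SegmentSpec(2, 2)).values == 0.0)

    def test_toy_matrix_against_literal_formulas(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(4, 20))
        npssm = NormalizedPssm(values, "r")
        block = local_dpp(npssm, SegmentSpec(1, 1))
        np.testing.assert_allclose(block.values[:20], values.mean(axis=0))
        expected_lag = ((values[:-1] - values[1:]) ** 2).mean(axis=0)
        np.testing.assert_allclose(block.values[20:], expected_lag)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            length = int(rng.integers(20, 90))
            n = int(rng.integers(1, 4))
            lam = int(rng.integers(1, 4))
            npssm = random_normalized(rng, length)
            got = local_dpp(npssm, SegmentSpec(n, lam)).values
            np.testing.assert_allclose(
                got, brute_local_dpp(npssm.values, n, lam), atol=1e-10
            )

    def test_segment_major_compositionality(self):
        rng = np.random.default_rng(4)
        npssm = random_normalized(rng, 60)
        whole = local_dpp(npssm, SegmentSpec(3, 2)).values
        parts = []
        for start, end in segment_bounds(60, 3):
            seg = NormalizedPssm(npssm.values[start:end], "seg")
            parts.append(local_dpp(seg, SegmentSpec(1, 2)).values)
        np.testing.assert_allclose(whole, np.concatenate(parts))

    def test_lambda_must_be_below_shortest_segment(self):
        npssm = NormalizedPssm(np.zeros((10, 20)), "r")
        with pytest.raises(ValueError, match="lambda"):
            local_dpp(npssm, SegmentSpec(5, 2))


class TestDwt:
    def test_haar_constant_signal(self):
        bands = dwt_decompose([1.0, 1.0, 1.0, 1.0], DwtConfig())
        approx, detail = bands[0]
        np.testing.assert_allclose(approx, [np.sqrt(2), np.sqrt(2)])
        np.testing.assert_allclose(detail, [0.0, 0.0])

    def test_zero_signal_all_bands_zero(self):
        for approx, detail in dwt_decompose(np.zeros(64), DwtConfig()):
            assert np.all(approx == 0.0) and np.all(detail == 0.0)

    def test_haar_energy_conservation(self):
        rng = np.random.default_rng(5)
        signal = rng.normal(size=64)
        current = signal
        for approx, detail in dwt_decompose(signal, DwtConfig()):
            energy_in = np.sum(current**2)
            energy_out = np.sum(approx**2) + np.sum(detail**2)
            assert abs(energy_in - energy_out) < 1e-8
            current = approx


class TestPssmDwt:
    def test_dimension_is_52_per_column_1040_total(self):
        rng = np.random.default_rng(6)
        npssm = random_normalized(rng, 100)
        block = pssm_dwt(npssm)
        assert len(block) == 1040
        values, labels = dwt_column_features(npssm.values[:, 0])
        assert len(values) == len(labels) == 52

    def test_zero_matrix_yields_zero_vector(self):
        block = pssm_dwt(NormalizedPssm(np.zeros((64, 20)), "r"))
        assert np.all(block.values == 0.0)

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        npssm = random_normalized(rng, 80)
        perm = rng.permutation(20)
        permuted = NormalizedPssm(
            npssm.values[:, perm],
            "r",
            tuple(npssm.column_order[j] for j in perm),
        )
        base = pssm_dwt(npssm).values.reshape(20, 52)
        got = pssm_dwt(permuted).values.reshape(20, 52)
        np.testing.assert_allclose(got, base[perm])

    @pytest.mark.parametrize("length", [16, 23, 50, 200, 2000])
    def test_output_finite_across_lengths(self, length):
        rng = np.random.default_rng(length)
        block = pssm_dwt(random_normalized(rng, length))
        assert len(block) == 1040
        assert np.all(np.isfinite(block.values))

    def test_short_signal_levels_padded_with_zeros(self):
        # an 8-residue signal supports only 3 Haar levels; level 4 is zero
        values, labels = dwt_column_features(np.arange(8.0))
        level4 = values[39:52]
        assert np.all(level4 == 0.0)
        assert labels[39].startswith("lvl4.")
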