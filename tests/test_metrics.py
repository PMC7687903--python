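import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers import brute_acf, brute_mi_bits, brute_pe, brute_pe_grid_search
from thinpred import (
    CountSeries,
    PEConfig,
    RealSeries,
    autocorrelation,
    best_lag,
    mutual_information,
    pe_grid_search,
    permutation_entropy,
)


class TestAutocorrelation:
    def test_perfectly_linear(self):
        assert autocorrelation([1, 2, 3, 4, 5], 1) == pytest.approx(1.0)

    def test_perfect_alternation(self):
        assert autocorrelation([1, 2, 1, 2, 1, 2], 1) == pytest.approx(-1.0)

    def test_constant_series_raises(self):
        with pytest.raises(ZeroDivisionError, match="constant"):
            autocorrelation([5, 5, 5, 5], 1)

    def test_matches_brute_force(self, rng):
        v = rng.poisson(6, size=300)
        for lag in (1, 3, 7):
            assert autocorrelation(v, lag) == pytest.approx(brute_acf(v, lag), abs=1e-12)

    def test_time_reversal_symmetry_at_lag_one(self, rng):
        v = rng.poisson(6, size=200)
        assert autocorrelation(v, 1) == pytest.approx(autocorrelation(v[::-1], 1))

    def test_bounded(self, rng):
        v = rng.integers(0, 30, size=500)
        assert -1.0 <= autocorrelation(v, 2) <= 1.0


class TestBestLag:
    def test_periodic_signal_recovers_period(self):
        t = np.arange(400)
        v = np.sin(2 * np.pi * t / 7)
        assert best_lag(v, 10) == 7

    def test_monotone_series_ties_break_to_smallest_lag(self):
        assert best_lag(np.arange(1, 51), 5) == 1

    def test_matches_brute_force_on_noise(self, rng):
        v = rng.poisson(10, size=1000).astype(float)
        lags = range(1, 11)
        brute = max(lags, key=lambda k: (abs(brute_acf(v, k)), -k))
        assert best_lag(v, 10) == brute


class TestPermutationEntropy:
    @pytest.mark.parametrize("d,tau", [(2, 1), (3, 1), (4, 2), (5, 3)])
    def test_strictly_increasing_series_has_zero_entropy(self, d, tau):
        v = np.arange(50)
        cfg = PEConfig(order=d, delay=tau, weighted=False)
        assert permutation_entropy(v, cfg) == 0.0

    def test_alternating_series_brute_forced(self):
        # 3 "up" + 2 "down" motifs: H = -(0.6 log2 0.6 + 0.4 log2 0.4)
        v = [1, 2, 1, 2, 1, 2]
        cfg = PEConfig(order=2, delay=1, weighted=False)
        expected = brute_pe(v, 2, 1, weighted=False)
        assert expected == pytest.approx(0.970951, abs=1e-6)
        assert permutation_entropy(v, cfg) == pytest.approx(expected, abs=1e-12)

    def test_weighted_worked_example(self):
        # motifs (1,3),(3,2),(2,4) with variances 1, 0.25, 1: P(up)=8/9
        v = [1, 3, 2, 4]
        cfg = PEConfig(order=2, delay=1, weighted=True)
        expected = brute_pe(v, 2, 1, weighted=True)
        assert expected == pytest.approx(0.5032, abs=1e-3)
        assert permutation_entropy(v, cfg) == pytest.approx(expected, abs=1e-12)

    @given(
        values=st.lists(st.integers(min_value=0, max_value=9), min_size=10, max_size=60),
        d=st.integers(min_value=2, max_value=4),
        tau=st.integers(min_value=1, max_value=3),
        weighted=st.booleans(),
    )
    def test_matches_brute_force_enumeration(self, values, d, tau, weighted):
        """Dual route: vectorized implementation vs plain-Python motif count."""
        cfg = PEConfig(order=d, delay=tau, weighted=weighted)
        if len(values) < cfg.min_length():
            return
        try:
            got = permutation_entropy(values, cfg)
        except ZeroDivisionError:
            # only weighted mode can degenerate, and the oracle must agree
            assert weighted
            with pytest.raises(AssertionError, match="degenerate"):
                brute_pe(values, d, tau, weighted=True)
            return
        assert got == pytest.approx(brute_pe(values, d, tau, weighted), abs=1e-10)

    def test_normalized_range(self, rng):
        v = rng.integers(0, 100, size=500)
        h = permutation_entropy(v, PEConfig(order=3, delay=1, weighted=False))
        assert 0.0 <= h <= 1.0

    def test_unweighted_invariant_under_monotone_transform(self, rng):
        v = rng.integers(0, 50, size=300).astype(float)
        cfg = PEConfig(order=3, delay=2, weighted=False)
        assert permutation_entropy(np.exp(v / 10), cfg) == pytest.approx(
            permutation_entropy(v, cfg), abs=1e-12
        )

    def test_weighted_invariant_under_positive_affine_transform(self, rng):
        # weights scale by slope^2 so weight shares are unchanged
        v = rng.integers(0, 50, size=300).astype(float)
        cfg = PEConfig(order=3, delay=1, weighted=True)
        assert permutation_entropy(3.0 * v + 7.0, cfg) == pytest.approx(
            permutation_entropy(v, cfg), abs=1e-10
        )

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="no motif"):
            permutation_entropy([1, 2], PEConfig(order=3, delay=2))

    def test_all_constant_motifs_raise_in_weighted_mode(self):
        with pytest.raises(ZeroDivisionError, match="degenerate"):
            permutation_entropy([4, 4, 4, 4, 4], PEConfig(order=2, delay=1, weighted=True))

    def test_series_types_accepted(self):
        cfg = PEConfig(order=2, delay=1, weighted=False)
        a = permutation_entropy(CountSeries([1, 3, 2, 4]), cfg)
        b = permutation_entropy(RealSeries([1.0, 3.0, 2.0, 4.0]), cfg)
        assert a == b


class TestPEGridSearch:
    def test_monotone_series_tie_breaks_to_2_1(self):
        assert pe_grid_search(np.arange(100)) == (2, 1)

    def test_matches_exhaustive_rescan(self, rng):
        v = rng.integers(0, 40, size=400)
        assert pe_grid_search(v) == brute_pe_grid_search(list(v))

    def test_short_series_skips_infeasible_points(self, rng, caplog):
        v = rng.integers(0, 10, size=8)
        with caplog.at_level("WARNING"):
            d, tau = pe_grid_search(v)
        assert (d - 1) * tau + 1 <= 8
        assert any("skipping infeasible" in r.message for r in caplog.records)

    def test_entirely_infeasible_grid_raises(self):
        with pytest.raises(ValueError, match="no feasible"):
            pe_grid_search([1])


class TestMutualInformation:
    def test_self_information_of_fair_binary_symbol(self):
        v = [0, 1] * 10
        assert mutual_information(v, v, bins="none") == pytest.approx(1.0)

    def test_jointly_uniform_pairs_are_independent(self):
        assert mutual_information([0, 0, 1, 1], [0, 1, 0, 1], bins="none") == pytest.approx(0.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            mutual_information([1, 2, 3], [1, 2])

    def test_independent_series_near_zero(self, rng):
        x = rng.integers(0, 10, size=20_000)
        y = rng.integers(0, 10, size=20_000)
        assert mutual_information(x, y, bins="none") < 0.05

    def test_matches_brute_force(self, rng):
        x = rng.integers(0, 5, size=500)
        y = (x + rng.integers(0, 3, size=500)) % 5
        got = mutual_information(x, y, bins="none")
        assert got == pytest.approx(brute_mi_bits(list(x), list(y)), abs=1e-10)

    def test_self_information_equals_plug_in_entropy(self, rng):
        x = list(rng.integers(0, 7, size=400))
        assert mutual_information(x, x, bins="none") == pytest.approx(
            brute_mi_bits(x, x), abs=1e-10
        )

    @given(shift=st.integers(min_value=-3, max_value=3))
    def test_invariant_under_symbol_relabeling(self, shift):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 6, size=300)
        y = rng.integers(0, 6, size=300)
        a = mutual_information(x, y, bins="none")
        b = mutual_information(x + shift + 3, y, bins="none")
        assert a == pytest.approx(b, abs=1e-12)

    def test_quantile_binning_for_real_signals(self, rng):
        x = CountSeries(rng.poisson(20, size=2000))
        s = RealSeries(x.values + rng.normal(0, 1, size=2000))
        dependent = mutual_information(x, s)  # auto: none for x, sqrt-T bins for s
        shuffled = RealSeries(rng.permutation(s.values))
        assert dependent > mutual_information(x, shuffled)
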