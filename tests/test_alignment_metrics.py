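import math

import numpy as np
import pytest

from dyadalign import (
    dauc_lag1,
    dauc_normalized,
    dauc_raw,
    lagged_correlations,
    simulate_dyad,
    summarize_dyads,
)
from dyadalign.alignment_metrics import (
    lag1_pairing,
    shifted_overlap,
    summarize_series,
)
from dyadalign.synthetic_fixtures import DyadSimSpec
from conftest import make_series

# ----------------------------------------------------------------- oracles


def trapezoid_oracle(a, b):
    """Brute-force trapezoidal area under |a - b| with unit spacing."""
    d = [abs(x - y) for x, y in zip(a, b)]
    return sum((d[t] + d[t + 1]) / 2.0 for t in range(len(d) - 1))


def pearson_oracle(x, y):
    """Textbook product-moment coefficient."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def rank_oracle(x):
    """Average ranks for ties, 1-based."""
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    return pearson_oracle(rank_oracle(x), rank_oracle(y))


def shift_oracle(a, b, k):
    """Explicitly re-paired vectors for offset k of the first speaker."""
    n = len(a)
    if k >= 0:
        return a[k:], b[:n - k]
    return a[:n + k], b[-k:]


# ------------------------------------------------------------------- dAUC


class TestDaucRaw:
    def test_identical_series_zero(self):
        assert dauc_raw([1, 2, 3], [1, 2, 3]) == 0.0

    def test_constant_difference_closed_form(self):
        T, d = 12, 2.5
        a = np.zeros(T)
        b = np.full(T, d)
        assert dauc_raw(a, b) == pytest.approx(d * (T - 1))

    def test_matches_oracle_on_random_pair(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert dauc_raw(a, b) == pytest.approx(trapezoid_oracle(a, b),
                                               abs=1e-10)

    def test_swapping_speakers_invariant(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=15), rng.normal(size=15)
        assert dauc_raw(a, b) == pytest.approx(dauc_raw(b, a), abs=1e-12)

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="insufficient turns"):
            dauc_raw([1.0], [2.0])

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="filled"):
            dauc_raw([1.0, np.nan], [2.0, 3.0])

    def test_nonnegative(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            a, b = rng.normal(size=8), rng.normal(size=8)
            assert dauc_raw(a, b) >= 0.0

    def test_constant_shift_increases_area(self):
        rng = np.random.default_rng(14)
        a = rng.normal(size=30)
        b = a.copy()
        assert dauc_raw(a, b + 3.0) == pytest.approx(3.0 * 29)


class TestDaucNormalized:
    def test_printed_equation(self):
        assert dauc_normalized(100.0, 25) == pytest.approx(200.0)

    def test_fixed_point_at_50(self):
        assert dauc_normalized(100.0, 50) == pytest.approx(100.0)

    def test_nonpositive_turn_count_errors(self):
        with pytest.raises(ValueError):
            dauc_normalized(1.0, 0)

    def test_length_invariance_up_to_end_effect(self):
        # same constant per-turn difference, lengths T and 2T
        d, T = 1.5, 20
        raw_short = dauc_raw(np.zeros(T), np.full(T, d))
        raw_long = dauc_raw(np.zeros(2 * T), np.full(2 * T, d))
        norm_short = dauc_normalized(raw_short, T)
        norm_long = dauc_normalized(raw_long, 2 * T)
        # exact oracle values: d*(T-1)*50/T vs d*(2T-1)*50/(2T)
        assert norm_short == pytest.approx(d * (T - 1) * 50 / T)
        assert norm_long == pytest.approx(d * (2 * T - 1) * 50 / (2 * T))
        assert abs(norm_short - norm_long) <= d * 50 / T


class TestDaucLag1:
    def test_perfect_one_slot_echo_zero(self):
        # first speaker echoes partner: a[t+1] == b[t]
        rng = np.random.default_rng(15)
        b = rng.normal(size=20)
        a = np.concatenate([[rng.normal()], b[:-1]])
        s = make_series(a, b)
        raw, _ = dauc_lag1(s)
        assert raw == pytest.approx(0.0, abs=1e-12)
        assert dauc_raw(a, b) > 0.0

    def test_constant_series_zero_both_pairings(self):
        s = make_series(np.full(10, 2.0), np.full(10, 2.0))
        raw, norm = dauc_lag1(s)
        assert raw == 0.0 and norm == 0.0
        assert dauc_raw(s.values_a, s.values_b) == 0.0

    def test_matches_repaired_oracle(self):
        rng = np.random.default_rng(16)
        a, b = rng.normal(size=25), rng.normal(size=25)
        s = make_series(a, b)
        raw, norm = dauc_lag1(s)
        assert raw == pytest.approx(trapezoid_oracle(a[1:], b[:-1]),
                                    abs=1e-10)
        assert norm == pytest.approx(raw * 50 / s.turn_count_observed)

    def test_pairing_helper_trims_ends(self):
        a2, b2 = lag1_pairing([1, 2, 3], [4, 5, 6])
        assert a2.tolist() == [2, 3]
        assert b2.tolist() == [4, 5]


# ----------------------------------------------------------- correlations


class TestLaggedCorrelations:
    def test_identical_vectors_offset_zero(self):
        rng = np.random.default_rng(17)
        a = rng.normal(size=20)
        s = make_series(a, a.copy())
        for method in ("pearson", "spearman"):
            corr = lagged_correlations(s, offsets=[0], method=method)
            assert corr[0] == pytest.approx(1.0)

    def test_echo_identifies_follower(self):
        # partner delayed by one slot: b[t] = a[t-1]; only the offset that
        # leads the first speaker by one aligns them perfectly.
        a = np.array([3, 1, 4, 1, 5, 9, 2, 6, 5, 3, 5, 8], dtype=float)
        b = np.concatenate([[0.0], a[:-1]])
        s = make_series(a, b)
        corr = lagged_correlations(s, offsets=range(-3, 4),
                                   method="pearson")
        perfect = [k for k, v in corr.items()
                   if v == pytest.approx(1.0, abs=1e-12)]
        assert perfect == [-1]

    @pytest.mark.parametrize("method,oracle", [
        ("pearson", pearson_oracle), ("spearman", spearman_oracle)])
    def test_matches_oracle_all_offsets(self, method, oracle):
        rng = np.random.default_rng(18)
        a, b = rng.normal(size=30), rng.normal(size=30)
        s = make_series(a, b)
        corr = lagged_correlations(s, offsets=range(-3, 4), method=method)
        for k in range(-3, 4):
            xs, ys = shift_oracle(list(a), list(b), k)
            assert corr[k] == pytest.approx(oracle(xs, ys), abs=1e-10), k

    def test_coefficients_in_unit_interval(self):
        rng = np.random.default_rng(19)
        s = make_series(rng.normal(size=40), rng.normal(size=40))
        corr = lagged_correlations(s, offsets=range(-5, 6))
        assert all(-1.0 <= v <= 1.0 for v in corr.values())

    def test_symmetry_under_speaker_swap(self):
        rng = np.random.default_rng(20)
        a, b = rng.normal(size=25), rng.normal(size=25)
        fwd = lagged_correlations(make_series(a, b), offsets=range(-3, 4),
                                  method="pearson")
        rev = lagged_correlations(make_series(b, a), offsets=range(-3, 4),
                                  method="pearson")
        for k in range(-3, 4):
            assert fwd[k] == pytest.approx(rev[-k], abs=1e-12)

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(21)
        a, b = rng.normal(size=30), rng.normal(size=30)
        base = lagged_correlations(make_series(a, b), offsets=[0])
        moved = lagged_correlations(make_series(a + 7.5, b), offsets=[0])
        assert base[0] == pytest.approx(moved[0], abs=1e-12)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(22)
        a, b = rng.normal(size=30), rng.normal(size=30)
        base = lagged_correlations(make_series(a, b), offsets=[-1, 0, 1],
                                   method="spearman")
        warped = lagged_correlations(
            make_series(np.exp(a), b ** 3), offsets=[-1, 0, 1],
            method="spearman")
        for k in (-1, 0, 1):
            assert base[k] == pytest.approx(warped[k], abs=1e-12)

    def test_zero_variance_gives_na_with_warning(self):
        s = make_series(np.full(10, 1.0), np.arange(10, dtype=float))
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = lagged_correlations(s, offsets=[0], method="pearson")
        assert np.isnan(corr[0])

    def test_short_overlap_gives_na_with_warning(self):
        s = make_series(np.arange(4, dtype=float),
                        np.array([2.0, 1.0, 4.0, 3.0]))
        with pytest.warns(UserWarning, match="too short"):
            corr = lagged_correlations(s, offsets=[3])
        assert np.isnan(corr[3])

    def test_unknown_method_errors(self):
        s = make_series([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="unknown method"):
            lagged_correlations(s, method="kendall")

    def test_unfilled_series_rejected(self):
        s = make_series([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="filled"):
            lagged_correlations(s)


class TestParameterRecovery:
    def test_follower_direction_recovered(self):
        hits = 0
        for rep in range(100):
            spec = DyadSimSpec(n_slots=200, rho=0.3, beta=0.8, delay=1,
                               noise_sd=0.5, seed=1000 + rep)
            s = simulate_dyad(spec)
            corr = lagged_correlations(s, offsets=range(-3, 4),
                                       method="pearson")
            peak = max(corr, key=lambda k: corr[k])
            hits += peak == -1  # partner follows the first speaker
        assert hits > 90

    def test_uncoupled_dyads_centered_at_zero(self):
        vals = []
        for rep in range(100):
            spec = DyadSimSpec(n_slots=200, rho=0.3, beta=0.0, delay=1,
                               noise_sd=0.5, seed=2000 + rep)
            s = simulate_dyad(spec)
            vals.append(lagged_correlations(s, offsets=[0],
                                            method="pearson")[0])
        assert abs(np.mean(vals)) < 0.05


# --------------------------------------------------------------- summary


class TestSummarize:
    def test_row_contents(self):
        rng = np.random.default_rng(23)
        s = make_series(rng.normal(size=30), rng.normal(size=30))
        row = summarize_series(s, offsets=range(-2, 3))
        assert row["dauc_normalized"] == pytest.approx(
            row["dauc_raw"] * 50 / row["turn_count_observed"])
        assert row["first_speaker"] == "A"
        assert {"corr_lag-2", "corr_lag0", "corr_lag2"} <= set(row)

    def test_average_dauc_flag(self):
        rng = np.random.default_rng(24)
        s = make_series(rng.normal(size=20), rng.normal(size=20))
        row = summarize_series(s, average_dauc=True)
        assert row["dauc_norm_mean"] == pytest.approx(
            (row["dauc_normalized"] + row["dauc_norm_lag1"]) / 2)

    def test_fills_unfilled_series(self):
        s = make_series([1.0, np.nan, 3.0, 4.0], [2.0, 2.0, np.nan, 4.0])
        frame = summarize_dyads([s], offsets=[0])
        assert not frame["dauc_raw"].isna().any()

    def test_shift_helper_conventions(self):
        a = np.arange(5, dtype=float)
        b = np.arange(10, 15, dtype=float)
        x, y = shifted_overlap(a, b, 2)
        assert x.tolist() == [2, 3, 4] and y.tolist() == [10, 11, 12]
        x, y = shifted_overlap(a, b, -2)
        assert x.tolist() == [0, 1, 2] and y.tolist() == [12, 13, 14]
        x, y = shifted_overlap(a, b, 7)
        assert len(x) == 0
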