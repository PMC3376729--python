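"""Dinucleotide closest-distance and frequency profiles vs naive oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dinucmap as dm
from dinucmap.dinuc import eligible_positions, frequency_histogram
from dinucmap.genomes import revcomp


# ---------------------------------------------------------------------------
# independent position-by-position oracles


def naive_closest(seq: str, midpoints, dinuc: str, window: int):
    """Brute-force closest-dinucleotide histogram (string scan per midpoint)."""
    occ = [i for i in range(len(seq) - 1) if seq[i:i + 2] == dinuc]
    hist = np.zeros(2 * window + 1)
    n_used = 0
    for m in midpoints:
        if not (window <= m <= len(seq) - 2 - window):
            continue
        n_used += 1
        dists = [p - m for p in occ if abs(p - m) <= window]
        if not dists:
            continue
        best = min(abs(d) for d in dists)
        nearest = [d for d in dists if abs(d) == best]
        for d in set(nearest):
            hist[window + d] += 1.0 / len(set(nearest))
    return hist, n_used


def naive_frequency(seq: str, midpoints, dinuc: str, window: int):
    counts = np.zeros(2 * window + 1)
    n_used = 0
    for m in midpoints:
        if not (window <= m <= len(seq) - 2 - window):
            continue
        n_used += 1
        for j, o in enumerate(range(-window, window + 1)):
            if seq[m + o:m + o + 2] == dinuc:
                counts[j] += 1
    bg = sum(seq[i:i + 2] == dinuc for i in range(len(seq) - 1)) / (len(seq) - 1)
    frac = counts / n_used if n_used else counts
    return frac, bg, n_used


class TestClosestDistance:
    def test_nearer_side_wins(self):
        seq = "AAAA" + "ACGTACGT" + "AAAA"  # CG at 5 and 9; midpoint 8
        hist, n = dm.closest_distance_histogram({"c": seq}, {"c": np.array([8])},
                                                "CG", window=4)
        assert n == 1
        expected = np.zeros(9)
        expected[4 + 1] = 1.0  # distance +1 beats -3
        assert np.array_equal(hist, expected)

    def test_exact_tie_splits_half_half(self):
        seq = "CGAACG"  # CG at 0 and 4; midpoint 2 is equidistant
        hist, n = dm.closest_distance_histogram({"c": seq}, {"c": np.array([2])},
                                                "CG", window=2)
        assert n == 1
        assert hist[2 - 2] == 0.5 and hist[2 + 2] == 0.5 and hist.sum() == 1.0

    def test_absent_dinucleotide_contributes_nothing(self):
        hist, n = dm.closest_distance_histogram({"c": "A" * 30}, {"c": np.array([10])},
                                                "CG", window=5)
        assert n == 1 and hist.sum() == 0

    def test_invalid_dinucleotide_rejected(self):
        with pytest.raises(ValueError):
            dm.closest_distance_histogram({"c": "ACGT" * 10}, {"c": np.array([5])},
                                          "CX", window=3)

    def test_edge_positions_excluded(self):
        seq = "ACGT" * 10
        hist, n = dm.closest_distance_histogram({"c": seq}, {"c": np.array([1, 20, 38])},
                                                "CG", window=5)
        assert n == 1  # only position 20 is >= 5 from both edges

    def test_per_midpoint_weight_conservation(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        mids = rng.integers(0, 400, size=60)
        for dinuc in ("AA", "CG", "TA"):
            hist, n = dm.closest_distance_histogram({"c": seq}, {"c": mids}, dinuc, 20)
            oracle, n_o = naive_closest(seq, mids, dinuc, 20)
            assert n == n_o
            assert hist.sum() == oracle.sum()  # 1 or 0 per midpoint, ties sum to 1

    def test_periodic_genome_background_matches_oracle(self):
        seq = "CG" * 30
        hist, n = dm.background_closest_distance({"c": seq}, "CG", window=5)
        oracle, n_o = naive_closest(seq, range(len(seq)), "CG", 5)
        assert n == n_o and np.array_equal(hist, oracle)
        # mass only at distances 0 and +/-2 (even phase) or +/-1 (odd phase)
        nonzero = np.flatnonzero(hist) - 5
        assert set(nonzero.tolist()) <= {-2, -1, 0, 1, 2}

    def test_background_total_counts_positions_with_occurrence(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300, p=[0.4, 0.1, 0.1, 0.4]))
        W = 10
        hist, n = dm.background_closest_distance({"c": seq}, "CG", window=W)
        oracle, _ = naive_closest(seq, range(len(seq)), "CG", W)
        assert np.array_equal(hist, oracle)
        n_with = sum(1 for m in eligible_positions(len(seq), W)
                     if any(seq[p:p + 2] == "CG" and abs(p - m) <= W
                            for p in range(len(seq) - 1)))
        assert hist.sum() == n_with


class TestFrequencyStatistic:
    def test_periodic_alternating_genome(self):
        seq = "AT" * 40
        mids = np.arange(10, 70, 2)  # even positions start "AT"
        frac, bg, n = frequency_histogram({"c": seq}, {"c": mids}, "AT", window=4)
        assert n == len(mids)
        assert np.array_equal(frac[::2], np.ones(5)) and np.array_equal(frac[1::2], np.zeros(4))
        assert bg == pytest.approx(40 / 79, abs=1e-12)  # 40 "AT" starts in 79 positions

    def test_single_midpoint_binary_values(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=50))
        frac, _, n = frequency_histogram({"c": seq}, {"c": np.array([25])}, "GG", window=2)
        assert n == 1 and len(frac) == 5 and set(frac.tolist()) <= {0.0, 1.0}

    def test_ambiguity_codes_never_match(self):
        seq = "ANNN" * 20
        frac, bg, n = frequency_histogram({"c": seq}, {"c": np.array([40])}, "AA", window=3)
        assert bg == 0.0 and frac.sum() == 0.0


class TestOracleEquivalence:
    """Both statistics match a naive position scan exactly on small genomes."""

    @given(st.integers(0, 10_000))
    @settings(max_examples=12, deadline=None, derandomize=True)
    def test_closest_matches_naive_scan(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(60, 1000))
        seq = "".join(rng.choice(list("ACGT"), size=L))
        mids = np.unique(rng.integers(0, L, size=30))
        W = int(rng.integers(5, 40))
        for dinuc in dm.DINUCLEOTIDES:
            hist, n = dm.closest_distance_histogram({"c": seq}, {"c": mids}, dinuc, W)
            oracle, n_o = naive_closest(seq, mids, dinuc, W)
            assert n == n_o
            np.testing.assert_array_equal(hist, oracle)

    @given(st.integers(0, 10_000))
    @settings(max_examples=8, deadline=None, derandomize=True)
    def test_frequency_matches_naive_scan(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(60, 800))
        seq = "".join(rng.choice(list("ACGT"), size=L))
        mids = np.unique(rng.integers(0, L, size=25))
        W = int(rng.integers(3, 25))
        for dinuc in ("AA", "AC", "CG", "GC", "TT"):
            frac, bg, n = frequency_histogram({"c": seq}, {"c": mids}, dinuc, W)
            o_frac, o_bg, o_n = naive_frequency(seq, mids, dinuc, W)
            assert n == o_n and bg == pytest.approx(o_bg, abs=1e-12)
            np.testing.assert_allclose(frac, o_frac, atol=1e-12)


class TestNormalization:
    def test_observed_equals_background_gives_100(self):
        obs = np.array([3.0, 0.0, 5.0])
        norm, masked = dm.normalize_to_baseline(obs, obs, 10, 10)
        assert np.array_equal(norm[~masked], [100.0, 100.0])
        assert masked.tolist() == [False, True, False]

    def test_double_rate_gives_200(self):
        norm, _ = dm.normalize_to_baseline(np.array([4.0]), np.array([2.0]), 10, 10)
        assert norm[0] == pytest.approx(200.0)

    def test_zero_sample_sizes_rejected(self):
        with pytest.raises(ValueError):
            dm.normalize_to_baseline(np.ones(3), np.ones(3), 0, 5)


class TestRunAllDinucs:
    def test_exactly_sixteen_profiles(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        mids = {"c": np.sort(rng.integers(100, 2900, size=50))}
        profs = dm.run_all_dinucs({"c": seq}, mids, statistic="closest", window=50)
        assert sorted(profs) == sorted(dm.DINUCLEOTIDES) and len(profs) == 16

    def test_revcomp_symmetric_input_mirrors_profiles(self, rng):
        half = "".join(rng.choice(list("ACGT"), size=600))
        seq = half + revcomp(half)
        L = len(seq)
        base = rng.integers(50, 500, size=20)
        mids = np.unique(np.concatenate([base, L - 2 - base]))
        W = 25
        for dinuc in ("AA", "CG", "CT", "GA"):
            a, _ = dm.closest_distance_histogram({"c": seq}, {"c": mids}, dinuc, W)
            b, _ = dm.closest_distance_histogram({"c": seq}, {"c": mids}, revcomp(dinuc), W)
            np.testing.assert_array_equal(a, b[::-1])

    def test_frequency_baseline_near_100_on_random_genome(self, rng):
        # scalar genome-wide background: identity holds up to O(W/L) edge effects
        seq = "".join(rng.choice(list("ACGT"), size=20_000))
        mids = {"c": eligible_positions(len(seq), 50)}
        profs = dm.run_all_dinucs({"c": seq}, mids, statistic="frequency", window=50)
        for p in profs.values():
            vals = p.normalized[~p.masked]
            assert np.all(np.abs(vals - 100.0) < 15.0)
            assert abs(vals.mean() - 100.0) < 2.0

    def test_planted_linker_bias_recovered_at_di_midpoints(self, default_sim):
        piles = dm.count_piles(default_sim.di)
        mids = dm.midpoints_dict(piles, min_pile=5)
        profs = dm.run_all_dinucs(default_sim.genome, mids, statistic="closest", window=500)

        def near_zero(p):
            sel = (np.abs(p.offsets) <= 3) & ~p.masked
            return float(np.nanmean(p.normalized[sel]))

        for d in ("CC", "CG", "GC", "GG"):
            assert near_zero(profs[d]) > 100.0
        for d in ("AT", "TA"):
            assert near_zero(profs[d]) < 100.0
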