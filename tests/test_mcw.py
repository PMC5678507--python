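import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from regenhet.mcw import (
    BinAssignment,
    PairedMeasure,
    compute_gebi,
    comparison_seeds,
    draw_expression_restricted,
    draw_subset_indices,
    draw_timepoint_restricted,
    draw_unrestricted,
    gebi_rows,
    make_expression_bins,
    permutation_test,
    run_series,
)
from regenhet.simulate import preset, simulate
from regenhet.io import summarize

from conftest import make_summary


def brute_force_signed_rank(t0, tx):
    """Independent reimplementation: sort |d| with insertion into a list,
    assign integer ranks (distinct |d| assumed), sum signed ranks."""
    d = [b - a for a, b in zip(t0, tx)]
    order = sorted(range(len(d)), key=lambda i: abs(d[i]))
    w = 0.0
    for rank, i in enumerate(order, start=1):
        w += (0 if d[i] == 0 else (1 if d[i] > 0 else -1)) * rank
    return w


def pairs_of(t0, tx, day=1.0, kind="cv"):
    ids = np.array([f"p{i}" for i in range(len(t0))])
    return PairedMeasure(ids, np.asarray(t0, float), np.asarray(tx, float), kind, day)


class TestComputeGebi:
    def test_hand_worked_example_with_tie_and_zero(self):
        # d = [-0.2, +0.1, -0.2, 0]; midranks (3.5, 2, 3.5, 1) -> W = -5
        w, w_max, g = compute_gebi(
            value_t0=[0.50, 0.40, 0.30, 0.20], value_tx=[0.30, 0.50, 0.10, 0.20]
        )
        assert (w, w_max, g) == (-5.0, 10.0, -0.5)

    def test_all_increase_gives_plus_one(self, rng):
        t0 = rng.uniform(0.1, 1.0, 20)
        w, w_max, g = compute_gebi(value_t0=t0, value_tx=t0 + rng.uniform(0.01, 1, 20))
        assert g == 1.0 and w == w_max

    def test_identical_columns_give_zero(self):
        t0 = np.array([0.3, 0.7, 0.2])
        w, _, g = compute_gebi(value_t0=t0, value_tx=t0.copy())
        assert (w, g) == (0.0, 0.0)

    @given(
        st.lists(
            st.tuples(st.floats(0.01, 10), st.floats(0.01, 10)),
            min_size=1, max_size=30,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_antisymmetry(self, pairs):
        t0 = np.array([a for a, _ in pairs])
        tx = np.array([b for _, b in pairs])
        w, w_max, g = compute_gebi(value_t0=t0, value_tx=tx)
        w_swap, _, g_swap = compute_gebi(value_t0=tx, value_tx=t0)
        assert -1.0 <= g <= 1.0
        assert w_swap == -w and g_swap == -g
        d = tx - t0
        if g in (1.0, -1.0):
            assert np.all(d != 0) and len(set(np.sign(d))) == 1

    def test_probeset_order_invariance(self, rng):
        t0 = rng.uniform(0.1, 1.0, 15)
        tx = rng.uniform(0.1, 1.0, 15)
        perm = rng.permutation(15)
        assert compute_gebi(value_t0=t0, value_tx=tx)[0] == pytest.approx(
            compute_gebi(value_t0=t0[perm], value_tx=tx[perm])[0]
        )

    @given(st.integers(0, 2 ** 32 - 1), st.integers(2, 7))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_on_distinct_deltas(self, seed, n):
        r = np.random.Generator(np.random.PCG64(seed))
        t0 = r.uniform(0.1, 1.0, n)
        tx = t0 + r.choice([-1, 1], n) * r.uniform(0.01, 0.5, n) * np.arange(1, n + 1)
        w, _, _ = compute_gebi(value_t0=t0, value_tx=tx)
        assert w == brute_force_signed_rank(t0, tx)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            compute_gebi(value_t0=[0.1, np.nan], value_tx=[0.2, 0.3])


class TestEmpiricalPValues:
    def test_direct_count_rule(self):
        # observed -0.5 vs sims [-0.6, -0.2, 0.1, 0.3]
        from regenhet.mcw import _empirical_pvalues
        p_up, p_lo, _, _ = _empirical_pvalues(-0.5, np.array([-0.6, -0.2, 0.1, 0.3]))
        assert (p_lo, p_up) == (0.25, 0.75)

    def test_overlap_inequality(self, rng):
        from regenhet.mcw import _empirical_pvalues
        sims = rng.normal(size=500)
        obs = float(sims[17])  # value present in the sample counts in both tails
        p_up, p_lo, _, _ = _empirical_pvalues(obs, sims)
        assert p_up + p_lo >= 1.0


class TestPermutationDesigns:
    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError, match="unknown design"):
            permutation_test(pairs_of([0.1], [0.2]), "bogus", 10, 0)

    def test_determinism_same_seed(self, rng):
        p = pairs_of(rng.uniform(0.1, 1, 50), rng.uniform(0.1, 1, 50))
        a = permutation_test(p, "unrestricted", 200, 11)
        b = permutation_test(p, "unrestricted", 200, 11)
        assert np.array_equal(a.simulated_gebis, b.simulated_gebis)
        assert (a.p_lower, a.p_upper) == (b.p_lower, b.p_upper)

    def test_monte_carlo_matches_exhaustive_enumeration(self, rng):
        """At n=3, MC tail probabilities agree with full enumeration of all
        720 rearrangements of the 6 pooled values, within 3 standard errors."""
        t0 = np.array([0.31, 0.55, 0.20])
        tx = np.array([0.44, 0.25, 0.61])
        obs = compute_gebi(value_t0=t0, value_tx=tx)[2]
        pooled = np.concatenate([t0, tx])
        exact = []
        for perm in itertools.permutations(range(6)):
            v = pooled[list(perm)]
            exact.append(compute_gebi(value_t0=v[:3], value_tx=v[3:])[2])
        exact = np.array(exact)
        p_lo_exact = np.mean(exact <= obs)
        p_up_exact = np.mean(exact >= obs)
        n_perm = 4000
        res = permutation_test(pairs_of(t0, tx), "unrestricted", n_perm, 99)
        for p_mc, p_ex in [(res.p_lower, p_lo_exact), (res.p_upper, p_up_exact)]:
            se = np.sqrt(p_ex * (1 - p_ex) / n_perm)
            assert abs(p_mc - p_ex) <= 3 * se

    def test_timepoint_restricted_preserves_column_multisets(self, rng):
        t0 = rng.uniform(0.1, 1, 40)
        tx = rng.uniform(0.1, 1, 40)
        a, b = draw_timepoint_restricted(t0, tx, 25, rng)
        for i in range(25):
            assert np.array_equal(np.sort(a[i]), np.sort(t0))
            assert np.array_equal(np.sort(b[i]), np.sort(tx))

    def test_unrestricted_preserves_pooled_multiset(self, rng):
        t0 = rng.uniform(0.1, 1, 40)
        tx = rng.uniform(0.1, 1, 40)
        a, b = draw_unrestricted(t0, tx, 25, rng)
        pooled = np.sort(np.concatenate([t0, tx]))
        for i in range(25):
            assert np.array_equal(np.sort(np.concatenate([a[i], b[i]])), pooled)

    def test_expression_restricted_never_crosses_bins(self, rng):
        n = 30
        t0 = rng.uniform(0.1, 1, n)
        tx = rng.uniform(0.1, 1, n)
        codes = np.concatenate([rng.integers(0, 5, n), rng.integers(0, 5, n)])
        bins = BinAssignment(codes_t0=codes[:n], codes_tx=codes[n:],
                             decimals=2, tx_day=1.0)
        a, b = draw_expression_restricted(t0, tx, 20, rng, bins)
        pooled = np.concatenate([t0, tx])
        for i in range(20):
            new_pooled = np.concatenate([a[i], b[i]])
            for c in np.unique(codes):
                assert np.array_equal(
                    np.sort(new_pooled[codes == c]), np.sort(pooled[codes == c])
                )

    def test_functionally_restricted_subset_size_conserved(self, rng):
        idx = draw_subset_indices(100, 17, 30, rng)
        assert idx.shape == (30, 17)
        for row in idx:
            assert len(set(row.tolist())) == 17

    def test_functionally_restricted_validates_subset(self, rng):
        uni = pairs_of(rng.uniform(0.1, 1, 20), rng.uniform(0.1, 1, 20))
        with pytest.raises(ValueError, match="empty"):
            permutation_test(uni, "functionally_restricted", 10, 0,
                             subset=[], universe=uni)
        with pytest.raises(ValueError, match="not in universe"):
            permutation_test(uni, "functionally_restricted", 10, 0,
                             subset=["nope"], universe=uni)

    def test_null_pairs_uniformish_pvalues(self, rng):
        """Exchangeable null: a single unrestricted test should not produce
        an extreme p-value much more often than its nominal rate (spot check
        at one seeded draw; the full calibration lives in the acceptance
        suite)."""
        t0 = rng.gamma(9.0, 1.0, 500)
        tx = rng.gamma(9.0, 1.0, 500)
        res = permutation_test(pairs_of(t0, tx), "unrestricted", 500, 5)
        assert res.p_lower > 0.001 and res.p_upper > 0.001


class TestExpressionBins:
    def test_rounding_arithmetic(self):
        s = make_summary(
            ["a", "b", "c"], [0.0, 1.0],
            means=[[2.314, 2.309, 5.001]] * 2,
            cvs=[[0.1, 0.2, 0.3]] * 2,
        )
        bins = make_expression_bins(s, 1.0, decimals=2)
        # keys 2.31, 2.31, 5.00 in both columns -> 2 bins of sizes 4 and 2
        assert bins.n_bins == 2
        assert bins.size_histogram().to_dict() == {2: 1, 4: 1}

    def test_three_decimals_refines_two(self, rng):
        means = [list(rng.uniform(1, 2, 50))] * 2
        s = make_summary([f"p{i}" for i in range(50)], [0.0, 1.0],
                         means=means, cvs=[[0.1] * 50] * 2)
        b2 = make_expression_bins(s, 1.0, decimals=2)
        b3 = make_expression_bins(s, 1.0, decimals=3)
        assert b3.n_bins >= b2.n_bins

    def test_identical_means_single_bin_equals_unrestricted(self, rng):
        n = 40
        cvs = [list(rng.uniform(0.1, 0.5, n)), list(rng.uniform(0.1, 0.5, n))]
        s = make_summary([f"p{i}" for i in range(n)], [0.0, 1.0],
                         means=[[3.0] * n] * 2, cvs=cvs)
        bins = make_expression_bins(s, 1.0, decimals=2)
        assert bins.n_bins == 1
        pairs = PairedMeasure.from_summary(s, "cv", 1.0)
        a = permutation_test(pairs, "expression_restricted_2dp", 300, 7, bins=bins)
        b = permutation_test(pairs, "unrestricted", 300, 7)
        # one all-spanning bin is the unrestricted pool: same null distribution
        assert abs(np.mean(a.simulated_gebis) - np.mean(b.simulated_gebis)) < 0.02

    def test_decimal_guard(self, toy_summary):
        with pytest.raises(ValueError, match="decimals"):
            make_expression_bins(toy_summary, 1.0, decimals=5)
        make_expression_bins(toy_summary, 1.0, decimals=5, allow_any_decimals=True)


class TestRunSeries:
    def test_missing_baseline_rejected(self):
        s = make_summary(["a", "b"], [1.0, 2.0],
                         means=[[1, 2]] * 2, cvs=[[0.1, 0.2]] * 2)
        with pytest.raises(ValueError, match="day-0"):
            run_series(s, "cv", "unrestricted", 10, 0)

    def test_series_deterministic_and_day_ordered(self):
        matrix, _ = simulate(preset("null", seed=3, n_probesets=150))
        s = summarize(matrix)
        a = run_series(s, "cv", "timepoint_restricted", 50, 21)
        b = run_series(s, "cv", "timepoint_restricted", 50, 21)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())
        assert np.all(np.diff(a.tx_days) > 0)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.simulated_gebis, rb.simulated_gebis)

    def test_comparison_seeds_stable(self):
        assert comparison_seeds(123, 5) == comparison_seeds(123, 5)
        assert comparison_seeds(123, 5) != comparison_seeds(124, 5)

    def test_null_series_mean_gebi_near_zero(self):
        matrix, _ = simulate(preset("null", seed=9))
        s = summarize(matrix)
        series = run_series(s, "cv", "unrestricted", 20, 4)
        assert abs(series.observed.mean()) < 0.02

    def test_tsv_export_surface(self, tmp_path):
        matrix, _ = simulate(preset("null", seed=5, n_probesets=100))
        s = summarize(matrix)
        series = run_series(s, "mean", "unrestricted", 30, 8)
        series.write_tsv(tmp_path / "series.tsv")
        df = pd.read_csv(tmp_path / "series.tsv", sep="\t")
        assert {"tx_day", "observed_gebi", "p_upper", "p_lower",
                "sim_min", "sim_p5", "sim_p95", "sim_max"} <= set(df.columns)
        assert (df["sim_min"] <= df["sim_p5"]).all()
        assert (df["sim_p95"] <= df["sim_max"]).all()
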