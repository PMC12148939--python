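"""Drift-null statistics: F, Ne estimation, p-values, selection coefficients."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from evorepeat.drift import (adjust_generations, detect_candidates,
                             drift_null_pvalue, estimate_Ne,
                             estimate_selection_coefficient,
                             inbreeding_coefficient, ne_from_F,
                             sampling_aware_pvalues, sampling_F)
from evorepeat.synth import sample_poolseq, simulate_wf_trajectory

import pandas as pd


class TestAdjustGenerations:
    @pytest.mark.parametrize("nominal,regime,expected", [
        (57, "cold", 60), (59, "cold", 62),  # printed cold range 60-62
        (67, "hot", 64), (69, "hot", 66),    # printed hot range 64-66
        (3, "hot", 0),                       # proxy compared with itself
    ])
    def test_proxy_adjustment(self, nominal, regime, expected):
        assert adjust_generations(nominal, regime) == expected

    def test_negative_adjusted_time_raises(self):
        with pytest.raises(ValueError):
            adjust_generations(2, "hot")


class TestInbreedingCoefficient:
    def test_limits_and_closed_form(self):
        assert inbreeding_coefficient(100, 0) == 0.0
        assert inbreeding_coefficient(1e12, 100) < 1e-9
        assert np.isclose(inbreeding_coefficient(100, 10), 0.04889, atol=5e-5)

    @given(ne=st.floats(2, 1e4), t1=st.integers(0, 120), dt=st.integers(1, 50))
    def test_monotone_in_time(self, ne, t1, dt):
        lo = inbreeding_coefficient(ne, t1)
        hi = inbreeding_coefficient(ne, t1 + dt)
        if lo < 1.0 - 1e-12:  # strict until F saturates numerically
            assert hi > lo
        else:
            assert hi >= lo

    def test_undefined_below_half(self):
        with pytest.raises(ValueError):
            inbreeding_coefficient(0.5, 10)

    def test_round_trip_with_ne_from_F(self):
        for ne, t in ((50, 10), (215.4, 60), (1000, 5)):
            assert np.isclose(ne_from_F(inbreeding_coefficient(ne, t), t), ne)


class TestEstimateNe:
    def test_no_change_flags_no_drift(self, rng):
        p = rng.uniform(0.1, 0.9, 500)
        est = estimate_Ne(p, p, 50, 50, 60, t=10)
        assert est.no_drift and est.ne == np.inf

    def test_parameter_recovery_from_simulated_poolseq(self, rng):
        true_ne, t = 100, 10
        p0 = rng.uniform(0.05, 0.95, 10_000)
        pt = simulate_wf_trajectory(p0, true_ne, 0.0, t, rng)
        a, _ = sample_poolseq(p0, 60, 100, rng)
        b, _ = sample_poolseq(pt, 60, 100, rng)
        est = estimate_Ne(a, b, 100, 100, 60, t)
        assert abs(est.ne / true_ne - 1) < 0.15

    def test_halving_ne_roughly_doubles_corrected_F(self, rng):
        t = 10
        Fs = {}
        for ne in (100, 50):
            p0 = rng.uniform(0.2, 0.8, 20_000)
            pt = simulate_wf_trajectory(p0, ne, 0.0, t, rng)
            Fs[ne] = estimate_Ne(p0, pt, 10**6, 10**6, 10**6, t,
                                 correct_sampling=False).F_corrected
        assert np.isclose(Fs[50] / Fs[100], 2.0, rtol=0.15)

    def test_recovery_across_true_ne_values(self, rng):
        # relative bias < 15% across the experiment-relevant Ne range
        for true_ne in (50, 215.4, 500):
            p0 = rng.uniform(0.05, 0.95, 10_000)
            pt = simulate_wf_trajectory(p0, true_ne, 0.0, 60, rng)
            a, _ = sample_poolseq(p0, 60, 50, rng)
            b, _ = sample_poolseq(pt, 60, 50, rng)
            est = estimate_Ne(a, b, 50, 50, 60, 60)
            assert abs(est.ne / true_ne - 1) < 0.15, true_ne

    def test_requires_informative_loci(self):
        with pytest.raises(ValueError):
            estimate_Ne(np.zeros(500), np.zeros(500), 50, 50, 60, 10)


class TestDriftNullPvalue:
    def test_symmetry_under_allele_relabeling(self):
        p1, _ = drift_null_pvalue(0.3, 0.5, Ne=100, t=20)
        p2, _ = drift_null_pvalue(0.7, 0.5, Ne=100, t=20)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_null_median_gives_p_near_one(self):
        from scipy import stats
        F = inbreeding_coefficient(100, 20)
        a, b = 0.4 * (1 - F) / F + 0.001, 0.6 * (1 - F) / F + 0.001
        median = stats.beta.ppf(0.5, a, b)
        p, _ = drift_null_pvalue(0.4, median, 100, 20)
        assert p > 0.999

    def test_monotone_decreasing_in_change_magnitude(self):
        deltas = np.linspace(0.01, 0.45, 20)
        ps = np.array([drift_null_pvalue(0.5, 0.5 + d, 100, 20)[0]
                       for d in deltas])
        assert np.all(np.diff(ps) < 0)

    def test_direction_sign(self):
        _, up = drift_null_pvalue(0.3, 0.6, 100, 20)
        _, down = drift_null_pvalue(0.6, 0.3, 100, 20)
        assert up == 1 and down == -1

    def test_tails_approximate_wf_simulation(self, rng):
        # The beta approximation tracks brute-force WF tail probabilities
        # to within ~30% relative error at moderate drift (its tails are
        # thinner than the discrete chain's near absorption).
        Ne, t, p0, n = 50, 20, 0.5, 400_000
        pt = simulate_wf_trajectory(np.full(n, p0), Ne, 0.0, t, rng)
        for dp in (0.2, 0.3, 0.4):
            emp = np.mean(np.abs(pt - p0) >= dp)
            approx, _ = drift_null_pvalue(p0, p0 + dp, Ne, t)
            assert np.isclose(approx, emp, rtol=0.30), dp

    def test_degenerate_null_raises(self):
        with pytest.raises(ValueError):
            drift_null_pvalue(0.5, 0.6, Ne=100, t=0)


class TestSamplingAwareNull:
    def test_null_pvalues_are_uniform(self, rng):
        # drift + two-stage sampling simulated under the null: randomized
        # p-values should be uniform (KS) and per-tail rates nominal
        Ne, t, pool, depth, n = 100, 20, 60, 40, 40_000
        p0 = rng.uniform(0.1, 0.9, n)
        pt = simulate_wf_trajectory(p0, Ne, 0.0, t, rng)
        f0, _ = sample_poolseq(p0, pool, depth, rng)
        ft, _ = sample_poolseq(pt, pool, depth, rng)
        r0 = np.rint(f0 * depth).astype(int)
        rt = np.rint(ft * depth).astype(int)
        keep = (r0 > 0) & (r0 < depth)
        p, d = sampling_aware_pvalues(r0[keep], depth, rt[keep], depth,
                                      Ne, t, pool, seed=3)
        from scipy import stats
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 1e-3
        for q in (0.05, 0.01):
            for sign in (-1, 1):
                rate = np.mean((p / 2 < q) & (d == sign))
                se = np.sqrt(q * (1 - q) / keep.sum())
                assert abs(rate - q) < 4 * se, (q, sign)

    def test_boundary_counts_receive_proper_null_mass(self):
        # an observed count of 0 out of few reads is unremarkable under
        # drift from a low starting frequency
        p, _ = sampling_aware_pvalues([5], 50, [0], 50, Ne=100, t=30,
                                      pool_size=60, smoothing="none")
        assert p[0] > 0.05

    def test_beta_drift_model_is_available(self):
        p1, _ = sampling_aware_pvalues([20], 50, [45], 50, 100, 30, 60,
                                       smoothing="midp")
        p2, _ = sampling_aware_pvalues([20], 50, [45], 50, 100, 30, 60,
                                       smoothing="midp", drift_model="beta")
        assert p1[0] != p2[0]  # different nulls, same order of magnitude
        assert np.isclose(np.log(p1[0]), np.log(p2[0]), atol=2.0)

    def test_read_counts_validated(self):
        with pytest.raises(ValueError):
            sampling_aware_pvalues([60], 50, [10], 50, 100, 30, 60)


class TestDetectCandidates:
    def test_all_ones_yield_empty_set(self):
        pv = pd.DataFrame({"a": [1.0, 1.0], "b": [1.0, 1.0]})
        dr = pd.DataFrame({"a": [1, -1], "b": [1, 1]})
        flags = detect_candidates(pv, dr, 1e-4)
        assert not flags.any().any()

    def test_single_hit_attributed_to_its_line(self):
        pv = pd.DataFrame({"a": [1e-6, 1.0], "b": [1.0, 1.0]})
        dr = pd.DataFrame({"a": [1, 1], "b": [1, 1]})
        flags = detect_candidates(pv, dr, 1e-4)
        assert flags.loc[0, "a"] and not flags.loc[0, "b"]
        assert flags.any(axis=1).tolist() == [True, False]

    def test_tail_modes_differ_by_factor_two(self):
        pv = pd.DataFrame({"a": [1.5e-4]})
        dr = pd.DataFrame({"a": [1]})
        assert detect_candidates(pv, dr, 1e-4, mode="per_tail").loc[0, "a"]
        assert not detect_candidates(pv, dr, 1e-4, mode="two_sided").loc[0, "a"]

    def test_threshold_validated(self):
        pv = pd.DataFrame({"a": [0.5]})
        dr = pd.DataFrame({"a": [1]})
        with pytest.raises(ValueError):
            detect_candidates(pv, dr, 0.6)


class TestSelectionCoefficient:
    def test_no_change_gives_zero(self):
        est = estimate_selection_coefficient(0.4, 0.4, t=10)
        assert est.s[0] == 0.0 and not est.clamped[0]

    def test_worked_logit_slope(self):
        est = estimate_selection_coefficient(0.5, 0.62, t=10)
        assert np.isclose(est.s[0], 0.04895, atol=5e-5)

    def test_recovers_s_from_deterministic_trajectory(self):
        pt = simulate_wf_trajectory(0.3, Ne=1_000_000, s=0.05, t=30, seed=1)
        est = estimate_selection_coefficient(0.3, pt, t=30)
        assert abs(est.s[0] - np.log(1.05)) < 0.005

    def test_boundary_frequencies_clamp_and_flag(self):
        est = estimate_selection_coefficient(0.5, 1.0, t=10, pool_size=60)
        assert est.clamped[0] and np.isfinite(est.s[0])


class TestSamplingF:
    def test_two_stage_coefficient_value(self):
        # 1/120 + (1 - 1/120)/50
        assert np.isclose(sampling_F(60, 50), 1 / 120 + (119 / 120) / 50)

    def test_decreases_with_depth(self):
        assert sampling_F(60, 100) < sampling_F(60, 50)
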