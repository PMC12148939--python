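"""Change-vector geometry: scaling, angles, divergence, rates, null tests."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import ortho_group

from evorepeat.geometry import (ChangeVector, ancestor_scale, change_vector,
                                divergence, evolutionary_rate,
                                mean_scale_traits, pairwise_angle,
                                permutation_regime_test, random_angle_null)


def vec(values, anc_se=None, evo_se=None, t=50, shared=None, **meta):
    values = np.asarray(values, float)
    return ChangeVector(
        values=values,
        anc_errors=np.zeros_like(values) if anc_se is None else np.asarray(anc_se, float),
        evo_errors=np.zeros_like(values) if evo_se is None else np.asarray(evo_se, float),
        t=t, shared_ancestor_id=shared, **meta)


class TestMeanScaling:
    def _panel(self):
        rows = []
        for line, regime, m in (("anc1", "ancestor", 1.0), ("anc2", "ancestor", 3.0),
                                ("evo", "hot", 3.0)):
            for temp in (23.0, 35.0):
                rows.append({"line_id": line, "regime": regime, "trait": "lrs",
                             "assay_temp": temp, "mean": m, "se": 0.2})
        return pd.DataFrame(rows)

    def test_divides_means_and_errors_by_ancestral_grand_mean(self):
        scaled = mean_scale_traits(self._panel())  # grand mean = 2.0
        evo = scaled[scaled["line_id"] == "evo"].iloc[0]
        assert evo["mean"] == pytest.approx(1.5)
        assert evo["se"] == pytest.approx(0.1)

    def test_second_pass_is_identity_once_grand_mean_is_one(self):
        once = mean_scale_traits(self._panel())
        twice = mean_scale_traits(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_assay_temperatures_scale_independently(self):
        panel = self._panel()
        hot = panel["assay_temp"] == 35.0
        panel.loc[hot & (panel["regime"] == "ancestor"), "mean"] *= 10
        scaled = mean_scale_traits(panel)
        cold_rows = scaled[(scaled["line_id"] == "evo")
                           & (scaled["assay_temp"] == 23.0)]
        assert cold_rows["mean"].iloc[0] == pytest.approx(1.5)

    def test_zero_grand_mean_raises(self):
        panel = self._panel()
        panel.loc[panel["regime"] == "ancestor", "mean"] = [1.0, 1.0, -1.0, -1.0]
        with pytest.raises(ValueError):
            mean_scale_traits(panel)


class TestChangeVector:
    def test_difference_and_error_carriage(self):
        cv = change_vector([1, 2], [0.1, 0.2], [1.5, 1.5], [0.3, 0.4], t=10,
                           shared_ancestor_id="anc")
        assert np.allclose(cv.values, [0.5, -0.5])
        assert np.allclose(cv.anc_errors, [0.1, 0.2])
        assert np.allclose(cv.evo_errors, [0.3, 0.4])
        assert cv.shared_ancestor_id == "anc"

    def test_identical_endpoints_give_zero_vector(self):
        cv = change_vector([1, 2, 3], [0] * 3, [1, 2, 3], [0] * 3, t=5)
        assert np.all(cv.values == 0)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            change_vector([1, 2], [0, 0], [1, 2, 3], [0, 0, 0], t=5)


class TestRates:
    def test_three_four_five(self):
        r = evolutionary_rate(vec([0.3, 0.4]), dataset_max=None)
        assert r.raw_rate == pytest.approx(0.01)

    def test_scaling_by_dataset_max(self):
        r = evolutionary_rate(vec([0.3, 0.4]), dataset_max=0.01)
        assert r.scaled_rate == pytest.approx(1.0)

    def test_zero_vector_rate(self):
        assert evolutionary_rate(vec([0.0, 0.0])).raw_rate == 0.0


class TestPairwiseAngle:
    def test_canonical_angles(self):
        a, b = vec([1, 0]), vec([0, 1])
        assert pairwise_angle(a, a).theta == pytest.approx(0.0)
        assert pairwise_angle(a, b).theta == pytest.approx(90.0)
        assert pairwise_angle(a, vec([-1, 0])).theta == pytest.approx(180.0)

    def test_worked_shared_ancestor_correction(self):
        # a.b = 2.0, shared error 0.5, |a||b| = 2 -> cos 0.75, 41.41 deg
        a = vec([1, 1], anc_se=[0.5, 0.5], shared="anc")
        b = vec([1, 1], anc_se=[0.5, 0.5], shared="anc")
        res = pairwise_angle(a, b, correction="numerator")
        assert res.corrected
        assert res.theta == pytest.approx(np.degrees(np.arccos(0.75)), abs=1e-9)
        assert res.theta == pytest.approx(41.41, abs=0.01)

    def test_error_exceeding_signal_is_undefined(self):
        a = vec([0.1, 0.1], anc_se=[0.5, 0.5], shared="anc")
        b = vec([0.1, 0.1], anc_se=[0.5, 0.5], shared="anc")
        res = pairwise_angle(a, b)
        assert not res.defined and res.undefined_reason == "error exceeds signal"

    def test_independent_ancestors_skip_correction(self):
        a = vec([1, 1], anc_se=[0.5, 0.5], shared="anc1")
        b = vec([1, 1], anc_se=[0.5, 0.5], shared="anc2")
        res = pairwise_angle(a, b)
        assert not res.corrected and res.theta == pytest.approx(0.0)

    def test_matches_brute_force_cosine(self, rng):
        for _ in range(100):
            x, y = rng.normal(size=(2, 5))
            manual = sum(x[i] * y[i] for i in range(5))
            manual /= np.sqrt(sum(v * v for v in x)) * np.sqrt(sum(v * v for v in y))
            theta = np.degrees(np.arccos(np.clip(manual, -1, 1)))
            assert pairwise_angle(vec(x), vec(y)).theta == pytest.approx(theta)

    @given(st.integers(0, 2**32 - 1))
    def test_symmetry_and_range(self, seed):
        r = np.random.default_rng(seed)
        a, b = vec(r.normal(size=4)), vec(r.normal(size=4))
        ab, ba = pairwise_angle(a, b), pairwise_angle(b, a)
        assert ab.theta == pytest.approx(ba.theta)
        assert 0 <= ab.theta <= 180

    def test_correction_removes_shared_error_bias(self, rng):
        # true 45-degree pair measured against a noisy shared ancestor:
        # full correction restores truth, no correction biases the angle low
        dim, sigma, reps = 7, np.sqrt(0.1 / 7), 400
        a0 = np.zeros(dim); a0[0] = 1.0
        b0 = np.zeros(dim); b0[:2] = np.sqrt(0.5)
        se = np.full(dim, sigma)
        unc, full = [], []
        for _ in range(reps):
            e = rng.normal(0, sigma, dim)
            a = vec(a0 + e, anc_se=se, shared="anc")
            b = vec(b0 + e, anc_se=se, shared="anc")
            unc.append(pairwise_angle(a, b, correction="none").theta)
            res = pairwise_angle(a, b, correction="full")
            if res.defined:
                full.append(res.theta)
        assert abs(np.mean(full) - 45.0) < 2.0
        assert np.mean(unc) < 44.0

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            pairwise_angle(vec([0, 0]), vec([1, 0]))


class TestDivergence:
    def test_no_evolution_means_no_divergence(self):
        res = divergence([0, 0], [1, 0], np.array([0.0, 0.0]), np.array([1.0, 0.0]))
        assert res.div == pytest.approx(0.0)

    def test_scaled_divergence_arithmetic(self):
        res = divergence([0, 0], [1, 0], np.array([0.0, 0.0]),
                         np.array([1.5, 0.0]), scale=2.0)
        assert res.div == pytest.approx(0.5)
        assert res.div_scaled == pytest.approx(0.25)

    def test_error_floor_sets_flag(self):
        # squared distance 0.04 but error term 0.09 -> E_d floored at 0
        res = divergence([0.0], [0.0], np.array([0.2]), np.array([0.0]),
                         evolved_a_se=np.array([0.3]),
                         evolved_b_se=np.array([0.0]),
                         shared_ancestor=True)
        assert res.E_d == 0.0 and res.floored

    def test_invariant_under_rotation_of_trait_space(self, rng):
        anc_a, anc_b = rng.normal(size=(2, 5))
        evo_a, evo_b = rng.normal(size=(2, 5))
        base = divergence(anc_a, anc_b, evo_a, evo_b)
        for seed in range(5):
            R = ortho_group.rvs(5, random_state=seed)
            rot = divergence(R @ anc_a, R @ anc_b, R @ evo_a, R @ evo_b)
            assert rot.div == pytest.approx(base.div, abs=1e-9)

    def test_ancestor_scale_picks_most_differentiated_pair(self):
        anc = [np.array([0.0, 0.0]), np.array([1.0, 0.0]), np.array([4.0, 0.0])]
        assert ancestor_scale(anc) == pytest.approx(4.0)


class TestRandomAngleNull:
    def test_isotropic_mean_is_ninety_degrees(self):
        null = random_angle_null(dim=7, n_pairs=1, iterations=100_000, seed=1)
        assert abs(null.mean() - 90.0) < 0.2

    def test_lower_dimensions_are_more_variable(self):
        sd2 = random_angle_null(2, 1, 20_000, seed=2).std()
        sd7 = random_angle_null(7, 1, 20_000, seed=2).std()
        assert sd2 > sd7

    def test_observed_at_median_gives_p_near_one(self):
        null = random_angle_null(7, 3, 2000, seed=3)
        res = random_angle_null(7, 3, 2000, seed=3,
                                observed_mean=float(np.median(null)))
        assert res.pvalue > 0.9


class TestPermutationRegimeTest:
    def _vectors(self, rng, effect=0.0):
        out = []
        for bg in ("A", "B", "C"):
            for regime in ("cold", "hot"):
                for rep in range(2):
                    base = rng.normal(size=7)
                    if regime == "hot" and effect:
                        base = np.array([1.0] * 7) + rng.normal(0, effect, 7)
                    out.append(vec(base, background=bg, regime=regime,
                                   label=f"{bg}_{regime}_{rep}"))
        return out

    def test_identical_vectors_give_p_one(self):
        v = [vec([1.0, 2.0], background=b, regime=r)
             for b in ("A", "B") for r in ("cold", "hot") for _ in range(2)]
        res = permutation_regime_test(v, "angle", iterations=200, seed=1)
        assert res.observed == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_detects_collinear_hot_lines(self, rng):
        # with label exchange stratified within 3 backgrounds of 4 lines,
        # only ~2 of 216 distinct relabelings reproduce |observed|, so the
        # smallest attainable p is about 1/108 plus Monte-Carlo noise
        vectors = self._vectors(rng, effect=0.05)
        res = permutation_regime_test(vectors, "angle", iterations=1000, seed=2)
        assert res.observed < 0  # hot angles far smaller
        assert res.pvalue <= 0.015

    def test_rate_statistic_runs(self, rng):
        res = permutation_regime_test(self._vectors(rng), "rate",
                                      iterations=200, seed=3)
        assert 0 < res.pvalue <= 1

    def test_null_calibration_on_label_noise(self):
        # under exchangeable regimes the test rejects at ~nominal rate
        rejections = 0
        reps = 120
        for i in range(reps):
            r = np.random.default_rng(1000 + i)
            vectors = self._vectors(r)
            res = permutation_regime_test(vectors, "angle", iterations=199,
                                          seed=i)
            rejections += res.pvalue <= 0.05
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se + 0.01

    def test_requires_two_lines_per_regime(self):
        v = [vec([1, 0], background="A", regime="cold"),
             vec([0, 1], background="A", regime="hot")]
        with pytest.raises(ValueError):
            permutation_regime_test(v, "angle", iterations=100)
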