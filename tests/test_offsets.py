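"""Reference selection, genomic/phenotypic/fitness offsets, correlations."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from evorepeat.offsets import (build_offset_table, fitness_offset,
                               genomic_offset, laboratory_fitness,
                               offset_correlation, phenotypic_offset,
                               random_snp_offsets, reference_candidate_set,
                               select_reference)
from evorepeat.synth import sample_poolseq, simulate_wf_trajectory
from evorepeat.drift import sampling_aware_pvalues


class TestLaboratoryFitness:
    def test_ratio(self):
        assert laboratory_fitness(80, 28) == pytest.approx(2.857, abs=1e-3)
        assert laboratory_fitness(0, 28) == 0.0

    def test_homogeneous_of_degree_zero(self):
        assert laboratory_fitness(80, 28) == laboratory_fitness(160, 56)

    def test_nonpositive_dev_time_raises(self):
        with pytest.raises(ValueError):
            laboratory_fitness(80, 0)


class TestSelectReference:
    def test_picks_highest_fitness_line(self):
        ref, tie = select_reference(pd.Series({"line7": 2.88, "line8": 3.65}))
        assert ref == "line8" and not tie

    def test_single_line_is_its_own_reference(self):
        assert select_reference(pd.Series({"only": 1.0}))[0] == "only"

    def test_exact_tie_breaks_lexicographically_with_flag(self):
        ref, tie = select_reference(pd.Series({"b": 2.0, "a": 2.0}))
        assert ref == "a" and tie

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            select_reference(pd.Series(dtype=float))


class TestReferenceCandidateSet:
    def test_exact_quantile_without_ties(self, rng):
        pv = pd.Series(rng.permutation(np.linspace(1e-9, 1, 100_000)))
        loci, _, tie = reference_candidate_set(pv, 0.001)
        assert len(loci) == 100 and not tie
        assert pv.loc[loci].max() <= np.sort(pv.to_numpy())[99]

    def test_all_equal_pvalues_return_everything_tied(self):
        pv = pd.Series(np.full(50, 0.5))
        loci, _, tie = reference_candidate_set(pv, 0.1)
        assert len(loci) == 50 and tie

    def test_planted_selected_loci_enrich_the_top_quantile(self, rng):
        # Strong selection among neutral drift.  Under the calibrated
        # discrete null a completed sweep's p-value saturates at the
        # null's own absorption probability (percent-level for sweeps
        # from high starting frequency), so total capture is bounded;
        # what holds is massive enrichment of planted loci in the
        # smallest-p quantile, growing as the quantile widens to
        # accommodate the absorption atoms.
        n, n_planted, ne, t, depth, pool = 200_000, 100, 200, 60, 50, 60
        p0 = rng.uniform(0.2, 0.8, n)
        s = np.zeros(n)
        planted = rng.choice(n, n_planted, replace=False)
        s[planted] = 0.15
        pt = p0.copy()
        for _ in range(t):
            pt = pt * (1 + s) / (1 + pt * s)
            pt = rng.binomial(2 * ne, pt) / (2 * ne)
        f0, _ = sample_poolseq(p0, pool, depth, rng)
        ft, _ = sample_poolseq(pt, pool, depth, rng)
        r0 = np.rint(f0 * depth).astype(int)
        rt = np.rint(ft * depth).astype(int)
        keep = (r0 > 0) & (r0 < depth)
        pv = np.ones(n)
        pv[keep], _ = sampling_aware_pvalues(r0[keep], depth, rt[keep], depth,
                                             ne, t, pool, seed=4)
        capture = {}
        for frac in (0.001, 0.01):
            loci, _, _ = reference_candidate_set(pd.Series(pv), frac)
            capture[frac] = np.isin(planted, loci.to_numpy()).mean()
        assert capture[0.001] / 0.001 >= 100  # >=100-fold enrichment
        assert capture[0.01] > capture[0.001]
        assert capture[0.01] >= 0.5

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            reference_candidate_set(pd.Series(dtype=float), 0.001)


class TestGenomicOffset:
    def test_worked_arithmetic(self):
        ref = pd.Series([0.8, 0.2])
        test = pd.Series([0.6, 0.2])
        w = pd.Series([0.1, 0.05])
        assert genomic_offset(ref, test, w) == pytest.approx(0.02)

    def test_self_offset_is_zero_and_weights_scale_linearly(self):
        ref = pd.Series([0.5, 0.1, 0.9])
        w = pd.Series([0.2, 0.3, 0.1])
        assert genomic_offset(ref, ref, w) == 0.0
        test = pd.Series([0.4, 0.3, 0.5])
        assert genomic_offset(ref, test, 2 * w) == \
            pytest.approx(2 * genomic_offset(ref, test, w))

    @given(st.integers(0, 2**32 - 1))
    def test_weighted_l1_metric_properties(self, seed):
        r = np.random.default_rng(seed)
        a, b, c = (pd.Series(r.uniform(0, 1, 6)) for _ in range(3))
        w = pd.Series(r.uniform(0, 0.3, 6))
        assert genomic_offset(a, b, w) == pytest.approx(genomic_offset(b, a, w))
        assert genomic_offset(a, c, w) <= \
            genomic_offset(a, b, w) + genomic_offset(b, c, w) + 1e-12

    def test_mismatched_snp_sets_raise(self):
        a = pd.Series([0.5], index=[1])
        b = pd.Series([0.5], index=[2])
        with pytest.raises(ValueError):
            genomic_offset(a, b, pd.Series([1.0], index=[1]))


class TestPhenotypicOffset:
    def test_euclidean(self):
        a = np.zeros(7)
        b = np.zeros(7)
        b[0], b[1] = 0.3, 0.4
        assert phenotypic_offset(a, b) == pytest.approx(0.5)
        assert phenotypic_offset(a, a) == 0.0

    def test_permutation_invariance(self, rng):
        a, b = rng.normal(size=(2, 7))
        perm = rng.permutation(7)
        assert phenotypic_offset(a[perm], b[perm]) == \
            pytest.approx(phenotypic_offset(a, b))


class TestFitnessOffset:
    def test_relative_fitness(self):
        assert fitness_offset(3.65, 3.65) == 1.0
        assert fitness_offset(2.88, 3.65) == pytest.approx(0.789, abs=1e-3)
        assert fitness_offset(2.88 * 3, 3.65 * 3) == \
            pytest.approx(fitness_offset(2.88, 3.65))

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            fitness_offset(1.0, 0.0)


class TestRandomSnpOffsets:
    def freqs(self, rng):
        return pd.DataFrame(rng.uniform(0, 1, size=(50, 3)),
                            columns=["ref", "t1", "t2"])

    def test_full_set_is_deterministic_across_iterations(self, rng):
        f = self.freqs(rng)
        out = random_snp_offsets(f, 50, "ref", ["t1", "t2"], iterations=5,
                                 seed=1)
        assert (out.nunique() == 1).all()

    def test_same_seed_reproduces_draws(self, rng):
        f = self.freqs(rng)
        a = random_snp_offsets(f, 10, "ref", ["t1"], iterations=10, seed=2)
        b = random_snp_offsets(f, 10, "ref", ["t1"], iterations=10, seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_oversized_subset_raises(self, rng):
        with pytest.raises(ValueError):
            random_snp_offsets(self.freqs(rng), 51, "ref", ["t1"])


class TestOffsetCorrelation:
    def table(self, rng, n=8):
        g = rng.uniform(0, 1, n)
        return pd.DataFrame({
            "genomic": np.concatenate([g, g]),
            "phenotypic": np.concatenate([2 * g, rng.uniform(0, 1, n)]),
            "fitness": np.concatenate([1 - g, rng.uniform(0.5, 1.5, n)]),
            "group": ["within"] * n + ["between"] * n,
        })

    def test_collinear_points_give_unit_correlation(self, rng):
        tab = self.table(rng)
        cors, tests = offset_correlation(tab)
        within = next(c for c in cors if c.group == "within")
        assert within.r_pheno == pytest.approx(1.0)
        assert within.r_fit == pytest.approx(-1.0)
        assert set(tests) == {"phenotypic", "fitness"}
        assert tests["phenotypic"].df_num == 1

    def test_constant_genomic_offset_is_flagged_degenerate(self, rng):
        tab = self.table(rng)
        tab.loc[tab["group"] == "within", "genomic"] = 0.5
        cors, _ = offset_correlation(tab)
        within = next(c for c in cors if c.group == "within")
        assert within.degenerate and within.r_pheno is None

    def test_too_few_points_raise(self, rng):
        tab = self.table(rng).iloc[:2]
        with pytest.raises(ValueError):
            offset_correlation(tab)


class TestBuildOffsetTable:
    def test_self_offsets_and_groups(self, rng):
        loci = pd.RangeIndex(5)
        freqs = pd.DataFrame(rng.uniform(0, 1, (5, 3)),
                             columns=["A_hot_1", "A_hot_2", "B_hot_1"],
                             index=loci)
        weights = pd.Series(rng.uniform(0, 0.2, 5), index=loci)
        traits = {ln: rng.normal(size=7) for ln in freqs.columns}
        fitness = pd.Series({"A_hot_1": 3.0, "A_hot_2": 2.0, "B_hot_1": 2.5})
        table = build_offset_table(
            {"A": "A_hot_1"}, freqs, {"A_hot_1": (loci, weights)}, traits,
            fitness, {"A_hot_1": "A", "A_hot_2": "A", "B_hot_1": "B"})
        assert len(table) == 2  # reference excluded from its own tests
        within = table[table["test"] == "A_hot_2"].iloc[0]
        assert within["group"] == "within"
        assert table[table["test"] == "B_hot_1"]["group"].iloc[0] == "between"
        assert within["fitness"] == pytest.approx(2.0 / 3.0)
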