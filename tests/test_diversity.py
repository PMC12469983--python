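"""Diversity indices against closed forms and independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from tcrdyn import diversity as dv
from tcrdyn.clonotypes import ClonotypeTable


def table(sizes, patient="P1", condition="pre_GFD", mode="strict"):
    return ClonotypeTable(patient, condition, mode,
                          pd.Series(sizes, index=[f"c{i}" for i in range(len(sizes))]))


def oracle_indices(counts):
    """Direct-summation reference, independent of the implementation."""
    counts = [c for c in counts if c > 0]
    n = sum(counts)
    p = [c / n for c in counts]
    s = len(counts)
    h = -sum(x * math.log(x) for x in p)
    d = sum(x * x for x in p)
    f = {k: sum(1 for c in counts if c == k) for k in range(1, 11)}
    chao1 = s + f[1] * (f[1] - 1) / (2 * (f[2] + 1))
    rare = [c for c in counts if c <= 10]
    s_rare, n_rare = len(rare), sum(rare)
    s_abund = s - s_rare
    c_ace = 1 - f[1] / n_rare if n_rare else 0.0
    if c_ace <= 0 or n_rare <= 1:
        ace = chao1
    else:
        g2 = max(s_rare * sum(k * (k - 1) * f[k] for k in range(1, 11))
                 / (c_ace * n_rare * (n_rare - 1)) - 1, 0.0)
        ace = s_abund + s_rare / c_ace + f[1] / c_ace * g2
    return {"shannon": h, "inv_simpson": 1 / d, "gini_simpson": 1 - d,
            "norm_entropy": h / math.log(s) if s > 1 else 0.0,
            "chao1": chao1, "ace": ace}


class TestClosedForms:
    def test_uniform_multi_cell_clones(self):
        res = dv.diversity_profile(table([2, 2, 2, 2]))
        assert res.shannon == pytest.approx(math.log(4))
        assert res.inv_simpson == pytest.approx(4.0)
        assert res.gini_simpson == pytest.approx(0.75)
        assert res.norm_entropy == pytest.approx(1.0)
        assert res.chao1 == pytest.approx(4.0)  # f1 = f2 = 0

    def test_single_clone_degenerate(self):
        res = dv.diversity_profile(table([10]))
        assert (res.shannon, res.inv_simpson, res.gini_simpson,
                res.norm_entropy) == (0.0, 1.0, 0.0, 0.0)

    def test_hand_computed_mixed_repertoire(self):
        res = dv.diversity_profile(table([1, 1, 2, 3]))
        assert res.S_obs == 4 and res.f_k[1] == 2 and res.f_k[2] == 1
        assert res.chao1 == pytest.approx(4.5)
        assert res.shannon == pytest.approx(1.27703, abs=1e-5)

    def test_chao1_equals_richness_without_singletons(self):
        for sizes in ([2, 3, 4], [5, 5], [2, 2, 2, 2, 7]):
            assert dv.diversity_profile(table(sizes)).chao1 == len(sizes)

    def test_uniform_singletons_ace_coverage_zero_falls_back(self):
        res = dv.diversity_profile(table([1, 1, 1]))
        assert res.C_ACE == 0.0
        assert res.ace == res.chao1

    def test_merging_identical_tables_preserves_entropy(self):
        a = dv.diversity_profile(table([4, 2, 1]))
        b = dv.diversity_profile(table([8, 4, 2]))
        assert b.shannon == pytest.approx(a.shannon)
        assert b.inv_simpson == pytest.approx(a.inv_simpson)


class TestOracleEquivalence:
    def test_1000_random_count_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            s = rng.integers(1, 60)
            counts = rng.integers(1, 40, size=s).tolist()
            got = dv.diversity_profile(table(counts)).point_estimates()
            want = oracle_indices(counts)
            for name, val in want.items():
                assert got[name] == pytest.approx(val, abs=1e-9), name

    def test_skbio_cross_check(self):
        """Shannon (base e), Chao1 bias-corrected and ACE vs scikit-bio."""
        from skbio.diversity import alpha
        rng = np.random.default_rng(7)
        for _ in range(50):
            counts = rng.integers(1, 30, size=rng.integers(3, 40))
            got = dv.diversity_profile(table(counts.tolist()))
            assert got.shannon == pytest.approx(float(alpha.shannon(counts, base=math.e)))
            assert got.chao1 == pytest.approx(float(alpha.chao1(counts, bias_corrected=True)))
            assert got.inv_simpson == pytest.approx(float(alpha.enspie(counts)))
            if (counts == 1).sum() < (counts <= 10).sum():  # C_ACE > 0
                assert got.ace == pytest.approx(float(alpha.ace(counts)), rel=1e-9)


class TestBootstrap:
    def test_single_clone_sample_zero_sd(self):
        tables = {("P1", "pre_GFD"): table([40])}
        res = dv.bootstrap_diversity(tables, B=20, depth=10, seed=0)[("P1", "pre_GFD")]
        assert all(sd == 0.0 for sd in res.boot_sd.values())

    def test_seeded_reproducibility(self):
        tables = {("P1", "pre_GFD"): table([5, 3, 2, 1, 1])}
        a = dv.bootstrap_diversity(tables, B=30, seed=3)[("P1", "pre_GFD")]
        b = dv.bootstrap_diversity(tables, B=30, seed=3)[("P1", "pre_GFD")]
        assert a.boot_mean == b.boot_mean

    def test_downsampling_bias_is_negative(self):
        """Subsampling a uniform 100-clone repertoire must lose entropy."""
        tables = {("P1", "pre_GFD"): table([1] * 100)}
        res = dv.bootstrap_diversity(tables, B=500, depth=50, seed=1)[("P1", "pre_GFD")]
        assert res.boot_mean["shannon"] < math.log(100)

    def test_depth_exceeding_smallest_sample_rejected(self):
        tables = {("P1", "pre_GFD"): table([3, 2])}
        with pytest.raises(ValueError):
            dv.bootstrap_diversity(tables, B=10, depth=10)

    def test_small_B_rejected(self):
        with pytest.raises(ValueError):
            dv.bootstrap_diversity({("P1", "pre_GFD"): table([3])}, B=1)


class TestPairedTest:
    def test_hand_computed_t_and_p(self):
        res = dv.paired_condition_test([0.5, 0.6, 0.7, 0.8, 0.9],
                                       [0.7, 0.9, 0.8, 1.0, 1.1])
        assert res.mean_diff == pytest.approx(0.2)
        assert res.t == pytest.approx(6.3246, abs=2e-4)
        assert res.p == pytest.approx(0.0032, abs=2e-4)

    def test_zero_variance_flagged(self):
        res = dv.paired_condition_test([1, 2, 3], [2, 3, 4])
        assert res.zero_variance and math.isnan(res.p)

    def test_matches_scipy_ttest_rel(self):
        rng = np.random.default_rng(0)
        from scipy import stats
        for _ in range(20):
            pre = rng.normal(size=6)
            post = pre + rng.normal(0.3, 0.5, size=6)
            res = dv.paired_condition_test(pre, post)
            ref = stats.ttest_rel(post, pre)
            assert res.t == pytest.approx(ref.statistic)
            assert res.p == pytest.approx(ref.pvalue)


class TestMorisita:
    def test_identical_and_disjoint(self):
        a = table([3, 2, 1])
        assert dv.morisita_overlap(a, a) == pytest.approx(1.0)
        b = ClonotypeTable("P2", "pre_GFD", "strict",
                           pd.Series([3, 2, 1], index=["x", "y", "z"]))
        assert dv.morisita_overlap(a, b) == 0.0

    def test_hand_computed_value(self):
        a = ClonotypeTable("P1", "pre_GFD", "strict", pd.Series({"a": 1, "b": 1}))
        b = ClonotypeTable("P1", "post_GFD", "strict", pd.Series({"a": 1, "b": 3}))
        assert dv.morisita_overlap(a, b) == pytest.approx(8 / 9)

    def test_mode_mismatch_hard_error(self):
        a = table([1, 2], mode="gene")
        b = table([1, 2], mode="strict")
        with pytest.raises(ValueError, match="mode"):
            dv.morisita_overlap(a, b)

    def test_matrix_symmetric_unit_diagonal(self, small_cohort_cells):
        from tcrdyn.clonotypes import call_clonotypes
        tables = call_clonotypes(small_cohort_cells, "strict")
        om = dv.overlap_matrix(tables)
        v = om.values.to_numpy()
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)
        assert ((v >= 0) & (v <= 1)).all()
        k = len(om.samples)
        assert len(om.to_long()) == k * (k - 1) // 2
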