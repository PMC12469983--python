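"""Gene usage, pairing arrays, CMH tests, Fisher/OR and p adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tcrdyn import pairing as pr
from tests.test_clonotypes import cells_frame


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    probs = {x: stats.hypergeom.pmf(x, n, r1, c1) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


class TestGeneUsage:
    def test_proportions(self):
        cells = cells_frame([
            ("P1", "pre_GFD", "TRAV1", "TRAJ4", "TRBV28", "TRBJ1-1", "A", "G"),
            ("P1", "pre_GFD", "TRAV1", "TRAJ4", "TRBV28", "TRBJ1-1", "A", "G"),
            ("P1", "pre_GFD", "TRAV1", "TRAJ4", "TRBV28", "TRBJ1-1", "A", "G"),
            ("P1", "pre_GFD", "TRAV1", "TRAJ4", "TRBV14", "TRBJ1-1", "A", "G"),
        ])
        gu = pr.gene_usage(cells, "TRBV")
        assert gu.loc["TRBV28", "P1_pre_GFD"] == pytest.approx(0.75)
        assert gu.loc["TRBV14", "P1_pre_GFD"] == pytest.approx(0.25)

    def test_equal_size_aggregation_is_mean(self):
        cells = cells_frame([
            ("P1", "pre_GFD", "TRAV1", "TRAJ4", "TRBV28", "TRBJ1-1", "A", "G"),
            ("P1", "pre_GFD", "TRAV1", "TRAJ4", "TRBV14", "TRBJ1-1", "A", "G"),
            ("P2", "pre_GFD", "TRAV1", "TRAJ4", "TRBV28", "TRBJ1-1", "A", "G"),
            ("P2", "pre_GFD", "TRAV1", "TRAJ4", "TRBV28", "TRBJ1-1", "A", "G"),
        ])
        gu = pr.gene_usage(cells, "TRBV")
        mean = (gu["P1_pre_GFD"] + gu["P2_pre_GFD"]) / 2
        assert np.allclose(gu["all_pre_GFD"], mean)

    def test_unseen_pool_gene_dense_zero_row(self):
        cells = cells_frame([
            ("P1", "pre_GFD", "TRAV1", "TRAJ4", "TRBV28", "TRBJ1-1", "A", "G")])
        gu = pr.gene_usage(cells, "TRBV", pool=["TRBV28", "TRBV9"])
        assert gu.loc["TRBV9", "P1_pre_GFD"] == 0.0


class TestPairingArray:
    def test_counts_land_in_their_cell(self):
        cells = cells_frame([
            ("P1", "pre_GFD", "TRAV10", "TRAJ4", "TRBV28", "TRBJ1-1", "A", "G"),
            ("P1", "pre_GFD", "TRAV10", "TRAJ4", "TRBV28", "TRBJ1-1", "C", "T"),
        ])
        arr = pr.pairing_array(cells)
        i = arr.row_genes.index("TRAV10")
        j = arr.col_genes.index("TRBV28")
        k = arr.strata.index("pre_GFD")
        assert arr.counts[i, j, k] == 2 and arr.counts.sum() == 2

    def test_clonotype_unit_collapses_clones(self):
        rows = [("P1", "pre_GFD", "TRAV10", "TRAJ4", "TRBV28", "TRBJ1-1", "AAA", "GGG")] * 5
        arr = pr.pairing_array(cells_frame(rows), unit="clonotypes")
        assert arr.counts.sum() == 1

    def test_stratum_totals_conserve_units(self, small_cohort_cells):
        arr = pr.pairing_array(small_cohort_cells)
        for k, _ in enumerate(arr.strata):
            assert arr.counts[:, :, k].sum() == arr.stratum_totals()[k]
        assert arr.counts.sum() == len(small_cohort_cells)


class TestCmh2x2xK:
    def test_single_stratum_closed_form(self):
        res = pr.cmh_2x2xk(np.array([[[10, 5], [3, 12]]]))
        closed = 29 * 105 ** 2 / (15 * 15 * 13 * 17)
        assert res.statistic == pytest.approx(closed, abs=1e-9)
        assert res.statistic == pytest.approx(6.4298, abs=1e-4)
        assert res.df == 1

    def test_null_table_zero_statistic(self):
        res = pr.cmh_2x2xk(np.array([[[5, 5], [5, 5]]] * 2))
        assert res.statistic == pytest.approx(0.0)

    def test_invariant_under_double_swap(self):
        t = np.array([[[10, 5], [3, 12]], [[2, 8], [9, 1]]])
        swapped = t[:, ::-1, ::-1]
        a = pr.cmh_2x2xk(t)
        b = pr.cmh_2x2xk(swapped)
        assert a.statistic == pytest.approx(b.statistic)

    def test_matches_statsmodels_stratified_table(self):
        from statsmodels.stats.contingency_tables import StratifiedTable
        rng = np.random.default_rng(1)
        for _ in range(20):
            t = rng.integers(1, 30, size=(3, 2, 2))
            ours = pr.cmh_2x2xk(t)
            ref = StratifiedTable(np.moveaxis(t, 0, -1).astype(float))
            got = ref.test_null_odds(correction=False)
            assert ours.statistic == pytest.approx(got.statistic, rel=1e-9)
            assert ours.p == pytest.approx(got.pvalue, rel=1e-6)

    def test_all_degenerate_errors(self):
        with pytest.raises(ValueError):
            pr.cmh_2x2xk(np.array([[[3, 0], [5, 0]]]))


class TestCmhGeneral:
    def test_reduces_to_2x2xk(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            t = rng.integers(1, 25, size=(2, 2, 4))
            q1 = pr.cmh_general(t).statistic
            q2 = pr.cmh_2x2xk(np.moveaxis(t, -1, 0)).statistic
            assert q1 == pytest.approx(q2, abs=1e-9)

    def test_frozen_reference_fixture(self):
        """3x3x2 array checked against an independent reference run of
        the stratified general-association test:
        array(c(12,5,9,7,13,4,3,8,16, 10,2,6,5,9,11,8,4,7), dim=c(3,3,2))
        -> statistic 16.5106139124, df 4, p 2.4052297635e-03."""
        a1 = np.array([12, 5, 9, 7, 13, 4, 3, 8, 16]).reshape(3, 3, order="F")
        a2 = np.array([10, 2, 6, 5, 9, 11, 8, 4, 7]).reshape(3, 3, order="F")
        res = pr.cmh_general(np.stack([a1, a2], axis=-1))
        assert res.statistic == pytest.approx(16.5106139124, abs=1e-6)
        assert res.df == 4
        assert res.p == pytest.approx(2.4052297635e-3, rel=1e-6)

    def test_outer_product_strata_near_zero(self):
        r = np.array([0.5, 0.3, 0.2])
        c = np.array([0.6, 0.4])
        t = np.stack([600 * np.outer(r, c), 400 * np.outer(r, c)], axis=-1)
        res = pr.cmh_general(t)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.integers(1, 20, size=(4, 3, 2)).astype(float)
        base = pr.cmh_general(t).statistic
        perm_r = rng.permutation(4)
        perm_c = rng.permutation(3)
        assert pr.cmh_general(t[perm_r][:, perm_c][:, :, ::-1]).statistic == \
            pytest.approx(base, abs=1e-9)


class TestPerPairFisher:
    @staticmethod
    def _array(counts_pre, counts_post, genes_a=("TRAV1",), genes_b=("TRBV2",)):
        counts = np.stack([np.atleast_2d(counts_post), np.atleast_2d(counts_pre)],
                          axis=-1)  # strata sorted: post before pre
        return pr.PairingArray("TRAV", "TRBV", list(genes_a), list(genes_b),
                               ["post_GFD", "pre_GFD"], counts, "cells")

    def test_symmetric_margins_hand_case(self):
        # a=2 of 5 pre, c=3 of 5 post
        arr = self._array([[2]], [[3]])
        arr.counts = np.zeros((2, 1, 2), dtype=int)
        arr.row_genes = ["TRAV1", "TRAVX"]
        arr.counts[0, 0, 1] = 2  # pre pair
        arr.counts[1, 0, 1] = 3  # pre other
        arr.counts[0, 0, 0] = 3  # post pair
        arr.counts[1, 0, 0] = 2  # post other
        res = pr.per_pair_fisher(arr).set_index("gene_a").loc["TRAV1"]
        assert res.p == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(4 / 9)
        assert res.p == pytest.approx(fisher_oracle(2, 3, 3, 2))

    def test_absent_pair_neutral(self):
        arr = self._array([[0], [7]], [[0], [9]],
                          genes_a=("TRAV1", "TRAVX"), genes_b=("TRBV2",))
        row = pr.per_pair_fisher(arr).set_index("gene_a").loc["TRAV1"]
        assert row.odds_ratio == pytest.approx(1.0)
        assert row.p == 1.0 and row.direction == "none"

    def test_zero_pre_count_is_enriched_post(self):
        arr = self._array([[0], [10]], [[6], [4]],
                          genes_a=("TRAV1", "TRAVX"), genes_b=("TRBV2",))
        row = pr.per_pair_fisher(arr).set_index("gene_a").loc["TRAV1"]
        assert row.direction == "enriched_post" and row.odds_ratio < 1

    def test_p_matches_enumeration_oracle_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 15, size=4)
            if (a + b == 0) or (c + d == 0):
                continue
            got = float(stats.fisher_exact([[a, b], [c, d]])[1])
            assert got == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-7)

    def test_zero_total_stratum_errors(self):
        arr = self._array([[0]], [[0]])
        with pytest.raises(ValueError):
            pr.per_pair_fisher(arr)


class TestAdjustPvalues:
    def test_bh_step_up_hand_case(self):
        out = pr.adjust_pvalues(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged_and_bonferroni(self):
        assert pr.adjust_pvalues(np.array([0.2]))[0] == pytest.approx(0.2)
        out = pr.adjust_pvalues(np.array([0.01] * 10), method="bonferroni")
        assert np.allclose(out, 0.1)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(6)
        p = rng.uniform(1e-6, 1, size=200)
        ours = pr.adjust_pvalues(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref)
        assert (ours >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pr.adjust_pvalues(np.array([0.0, 0.5]))
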