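"""EHH decay, AUC, permutation contrast and the categorical tests."""

import itertools

import numpy as np
import pytest

from pleiosweep.ehh_sweep import (
    co_inheritance_test,
    count_chi_square,
    ehh_auc,
    ehh_decay,
    permutation_auc_contrast,
    wilcoxon_allele_ehh,
)

from conftest import make_geno, make_panel


def brute_force_ehh(haps, core, allele):
    """Exhaustive pair-enumeration oracle for EHH at every position."""
    carriers = [i for i in range(haps.shape[0]) if haps[i, core] == allele]
    c = len(carriers)
    m = haps.shape[1]
    out = np.zeros(m)
    total = c * (c - 1) // 2
    for x in range(m):
        lo, hi = min(core, x), max(core, x)
        ident = sum(
            1 for a, b in itertools.combinations(carriers, 2)
            if np.array_equal(haps[a, lo:hi + 1], haps[b, lo:hi + 1])
        )
        out[x] = ident / total
    return out


class TestEhhDecay:
    def test_identical_carriers_give_unit_ehh(self):
        haps = np.vstack([np.tile([1, 0, 1, 1, 0], (4, 1)),
                          np.array([[1, 0, 0, 1, 1], [0, 1, 0, 1, 0]])])
        panel = make_panel(haps)
        prof = ehh_decay(panel, 2, 0)  # carriers of 0 at core: rows 4, 5 differ
        prof1 = ehh_decay(panel, 2, 1)  # the four identical rows
        np.testing.assert_allclose(prof1.ehh, 1.0)

    def test_core_position_is_one(self, rng):
        haps = rng.integers(0, 2, size=(12, 9))
        haps[:, 4] = [1, 1, 1, 1, 0, 0, 1, 1, 0, 0, 1, 1]
        panel = make_panel(haps)
        prof = ehh_decay(panel, 4, 1)
        core_pos = panel.variants["pos"].iloc[4]
        assert prof.ehh[list(prof.positions).index(core_pos)] == 1.0

    def test_two_two_split_at_first_flank(self):
        haps = np.array([
            [1, 0], [1, 0], [1, 1], [1, 1],  # carriers split 2/2 at flank SNP
            [0, 0], [0, 1],
        ])
        panel = make_panel(haps)
        prof = ehh_decay(panel, 0, 1)
        assert prof.ehh[1] == pytest.approx(1 / 3)  # (1 + 1) / C(4,2)

    def test_insufficient_carriers_errors(self):
        haps = np.array([[1, 0], [0, 0], [0, 1], [0, 0]])
        with pytest.raises(ValueError, match="insufficient carriers"):
            ehh_decay(make_panel(haps), 0, 1)

    def test_monotone_non_increasing_and_bounded(self, rng):
        haps = rng.integers(0, 2, size=(30, 25))
        haps[:, 12] = rng.integers(0, 2, 30) | 1  # ensure carriers
        panel = make_panel(haps)
        prof = ehh_decay(panel, 12, 1)
        core_i = list(prof.positions).index(prof.core_pos)
        right = prof.ehh[core_i:]
        left = prof.ehh[:core_i + 1][::-1]
        assert np.all(np.diff(right) <= 1e-12)
        assert np.all(np.diff(left) <= 1e-12)
        assert np.all((prof.ehh >= 0) & (prof.ehh <= 1))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            n_hap = int(rng.integers(4, 21))
            m = int(rng.integers(3, 16))
            if n_hap % 2:
                n_hap += 1
            haps = rng.integers(0, 2, size=(n_hap, m))
            core = int(rng.integers(m))
            for allele in (0, 1):
                if (haps[:, core] == allele).sum() < 2:
                    continue
                panel = make_panel(haps)
                prof = ehh_decay(panel, core, allele)
                np.testing.assert_allclose(
                    prof.ehh, brute_force_ehh(haps, core, allele), atol=1e-12
                )


class TestAuc:
    def test_unit_ehh_rectangle(self):
        haps = np.tile([1, 1, 1], (4, 1))
        panel = make_panel(haps, pos=[1, 500_000, 1_000_001])
        prof = ehh_decay(panel, 0, 1)
        res = ehh_auc(prof)
        assert res.auc == pytest.approx(1_000_000)

    def test_trapezoid_arithmetic(self):
        # EHH points (0 bp, 1.0) and (100 bp, 0.5): area = 100 * 0.75 = 75
        assert np.trapezoid([1.0, 0.5], [0, 100]) == pytest.approx(75.0)

    def test_both_flanks_match_independent_integration(self, rng):
        haps = rng.integers(0, 2, size=(16, 11))
        haps[:, 5] = 1
        pos = np.sort(rng.choice(np.arange(1, 10_000), 11, replace=False))
        panel = make_panel(haps, pos=pos)
        prof = ehh_decay(panel, 5, 1)
        res = ehh_auc(prof)
        i = list(prof.positions).index(prof.core_pos)
        expected = np.trapezoid(prof.ehh[:i + 1], prof.positions[:i + 1]) + \
            np.trapezoid(prof.ehh[i:], prof.positions[i:])
        assert res.auc == pytest.approx(expected, rel=1e-12)

    def test_single_point_flank_contributes_zero(self):
        haps = np.tile([1, 1], (4, 1))
        panel = make_panel(haps, pos=[10, 500])
        prof = ehh_decay(panel, 0, 1)  # left flank is the core alone
        assert ehh_auc(prof).auc == pytest.approx(490)


class TestPermutation:
    def test_same_locus_gives_zero_diff_and_p_near_one(self, rng):
        haps = rng.integers(0, 2, size=(20, 15))
        haps[:, 7] = rng.integers(0, 2, 20) | 1
        panel = make_panel(haps)
        obs, p = permutation_auc_contrast(panel, 7, 1, 7, 1, n_perm=200, seed=1)
        assert obs == 0.0
        assert p > 0.99

    def test_reproducible_under_seed_and_bounded(self, rng):
        haps = rng.integers(0, 2, size=(24, 20))
        haps[:, 5] |= 1
        haps[:, 15] |= 1
        panel = make_panel(haps)
        r1 = permutation_auc_contrast(panel, 5, 1, 15, 1, n_perm=300, seed=9)
        r2 = permutation_auc_contrast(panel, 5, 1, 15, 1, n_perm=300, seed=9)
        assert r1 == r2
        assert 1 / 301 <= r1[1] <= 1.0

    def test_small_n_perm_warns(self, rng):
        haps = rng.integers(0, 2, size=(12, 8))
        haps[:6, 2] = 1
        haps[6:, 2] = 0  # both alleles carried at the core
        panel = make_panel(haps)
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_auc_contrast(panel, 2, 1, 2, 0, n_perm=50, seed=0)


class TestWilcoxon:
    def _pair(self, e1, e2):
        from pleiosweep.ehh_sweep import EhhProfile

        pos = np.arange(len(e1)) * 100
        a = EhhProfile("v", 0, 1, pos, np.asarray(e1, float), 5)
        b = EhhProfile("v", 0, 0, pos, np.asarray(e2, float), 5)
        return a, b

    def test_identical_profiles_p_one(self):
        a, b = self._pair([1, 0.5, 0.2], [1, 0.5, 0.2])
        stat, p = wilcoxon_allele_ehh([(a, b)])
        assert (stat, p) == (0.0, 1.0)

    def test_uniform_shift_highly_significant(self, rng):
        base = rng.uniform(0.2, 0.8, 50)
        a, b = self._pair(base + 0.1, base)
        _, p = wilcoxon_allele_ehh([(a, b)])
        assert p < 0.001

    def test_allele_swap_negates_statistic(self, rng):
        e1 = rng.uniform(0, 1, 30)
        e2 = rng.uniform(0, 1, 30)
        a, b = self._pair(e1, e2)
        s1, p1 = wilcoxon_allele_ehh([(a, b)])
        s2, p2 = wilcoxon_allele_ehh([(b, a)])
        assert s2 == -s1
        assert p2 == p1


class TestCountChiSquare:
    @pytest.mark.parametrize("k,n,chi2,p", [
        (4, 8, 0.0, 1.0),
        (8, 9, 49 / 9, 0.0196),
        (9, 9, 9.0, 0.0027),
    ])
    def test_formula_values(self, k, n, chi2, p):
        c, pv = count_chi_square(k, n)
        assert c == pytest.approx(chi2, abs=1e-9)
        assert pv == pytest.approx(p, abs=5e-4)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            count_chi_square(0, 0)
        with pytest.raises(ValueError):
            count_chi_square(5, 4)


class TestCoInheritance:
    def _geno_from_table(self, table):
        da, db = [], []
        for ga in range(3):
            for gb in range(3):
                da += [ga] * int(table[ga][gb])
                db += [gb] * int(table[ga][gb])
        return make_geno(np.column_stack([da, db]).astype(float))

    def test_exact_independence_gives_zero(self):
        table = [[1, 2, 1], [2, 4, 2], [1, 2, 1]]  # outer product of margins
        geno = self._geno_from_table(table)
        chi2, df, p = co_inheritance_test(geno, 0, 1)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_full_table_df_is_four(self):
        table = [[5, 1, 1], [1, 5, 1], [1, 1, 5]]
        _, df, _ = co_inheritance_test(self._geno_from_table(table), 0, 1)
        assert df == 4

    def test_matches_cell_by_cell_oracle(self):
        table = np.array([[10, 2, 1], [2, 12, 2], [1, 2, 9]], float)
        chi2, df, p = co_inheritance_test(self._geno_from_table(table), 0, 1)
        n = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / n
        oracle = ((table - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(oracle, rel=1e-12)

    def test_zero_margin_collapses_with_warning(self):
        table = [[5, 3, 0], [3, 6, 0], [2, 2, 0]]  # no hom-alt at locus B
        geno = self._geno_from_table(table)
        with pytest.warns(UserWarning, match="collapsed"):
            chi2, df, p = co_inheritance_test(geno, 0, 1)
        assert df == 2
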