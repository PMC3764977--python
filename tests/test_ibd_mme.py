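"""Unit and property tests for the method-of-moments IBD machinery.

The conditional IBS estimators are checked against an exhaustive draw
enumeration oracle (every ordered 3- or 4-allele draw from the reference
pool), against the algebraically equivalent plug-in-times-correction form,
and against their infinite-population limits.
"""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_table
from ibdcheck.genotype_data import MISSING, AlleleCounts
from ibdcheck.ibd_mme import (
    cond_ibs_table,
    cond_ibs_unbiased,
    estimate_all_pairs,
    estimate_pair_ibd,
    ibs_state,
    pair_ibs_summary,
)


def ibs_of_allele_pairs(pair1, pair2):
    g1 = sum(pair1)
    g2 = sum(pair2)
    return 2 - abs(g1 - g2) if {g1, g2} != {0, 2} else 0


def enumeration_oracle(X, Y):
    """Conditional IBS probabilities by enumerating every ordered draw of
    distinct alleles from a pool of X ones (allele A) and Y zeros.

    Z=0: four draws, two per individual.  Z=1: three draws, the first shared.
    Returns a 3x3 [i, z] matrix with the structural Z=2 column filled.
    """
    pool = [1] * X + [0] * Y
    out = np.zeros((3, 3))
    n4 = 0
    for draw in permutations(range(len(pool)), 4):
        a, b, c, d = (pool[i] for i in draw)
        i = ibs_of_allele_pairs((a, b), (c, d))
        out[i, 0] += 1
        n4 += 1
    out[:, 0] /= n4
    n3 = 0
    for draw in permutations(range(len(pool)), 3):
        s, b, c = (pool[i] for i in draw)
        i = ibs_of_allele_pairs((s, b), (s, c))
        out[i, 1] += 1
        n3 += 1
    out[:, 1] /= n3
    out[2, 2] = 1.0
    return out


class TestIbsState:
    @pytest.mark.parametrize(
        "g1, g2, expected",
        [
            (2, 0, 0),  # opposite homozygotes share nothing
            (0, 2, 0),
            (1, 1, 2),
            (2, 2, 2),
            (2, 1, 1),
            (0, 1, 1),
            (2, MISSING, None),
            (MISSING, MISSING, None),
        ],
    )
    def test_cases(self, g1, g2, expected):
        assert ibs_state(g1, g2) == expected

    @given(st.integers(0, 2), st.integers(0, 2))
    @settings(derandomize=True)
    def test_symmetric(self, g1, g2):
        assert ibs_state(g1, g2) == ibs_state(g2, g1)


class TestCondIbsUnbiased:
    def test_matches_enumeration_oracle_all_pools(self):
        for T in range(4, 11):
            for X in range(T + 1):
                got = cond_ibs_unbiased(AlleleCounts(X, T - X, T))
                want = enumeration_oracle(X, T - X)
                np.testing.assert_allclose(got, want, atol=1e-12)

    def test_balanced_four_allele_pool(self):
        # {A,A,a,a}: P(I=0|Z=0) = 2*2*1*2*1/(4*3*2*1) = 1/3
        got = cond_ibs_unbiased(AlleleCounts(2, 2, 4))
        assert got[0, 0] == pytest.approx(1 / 3)

    def test_monomorphic_pool(self):
        got = cond_ibs_unbiased(AlleleCounts(6, 0, 6))
        assert got[0, 0] == 0
        assert got[2, 0] == 1
        assert got[2, 1] == 1

    def test_plug_in_limit(self):
        # X, Y -> inf at fixed p: entries converge to the plug-in values
        p, q = 0.3, 0.7
        T = 10**7
        X = int(round(p * T))
        got = cond_ibs_unbiased(AlleleCounts(X, T - X, T))
        assert got[0, 0] == pytest.approx(2 * p**2 * q**2, rel=1e-4)
        assert got[1, 0] == pytest.approx(4 * p**3 * q + 4 * p * q**3, rel=1e-4)
        assert got[1, 1] == pytest.approx(2 * p**2 * q + 2 * p * q**2, rel=1e-4)

    def test_equivalent_to_correction_factor_form(self):
        # count form == plug-in x correction factors wherever the latter is
        # defined (X, Y >= 1), e.g. for P(I=0|Z=0):
        # 2 p^2 q^2 (X-1)/X (Y-1)/Y T/(T-1) T/(T-2) T/(T-3)
        for T in range(4, 201, 7):
            for X in range(1, T):
                Y = T - X
                p, q = X / T, Y / T
                corr = (
                    2 * p**2 * q**2
                    * (X - 1) / X * (Y - 1) / Y
                    * T / (T - 1) * T / (T - 2) * T / (T - 3)
                )
                got = cond_ibs_unbiased(AlleleCounts(X, Y, T))[0, 0]
                assert got == pytest.approx(corr, rel=1e-12, abs=1e-15)

    @given(st.integers(4, 500), st.data())
    @settings(derandomize=True, max_examples=200)
    def test_rows_sum_to_one(self, T, data):
        X = data.draw(st.integers(0, T))
        got = cond_ibs_unbiased(AlleleCounts(X, T - X, T))
        for z in range(3):
            assert got[:, z].sum() == pytest.approx(1.0, abs=1e-12)

    def test_t_below_four_rejected(self):
        with pytest.raises(ValueError, match="T=2"):
            cond_ibs_unbiased(AlleleCounts(1, 1, 2))


class TestExactUnbiasedness:
    """Weighted enumeration over X ~ Binomial(T, p): the count-form
    estimators are exactly unbiased for the infinite-population conditional
    probabilities; the plug-in forms are not."""

    @pytest.mark.parametrize("T", [4, 8, 12])
    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5])
    def test_count_form_unbiased_plug_in_biased(self, T, p):
        from scipy.stats import binom

        q = 1 - p
        targets = {
            (0, 0): 2 * p**2 * q**2,
            (1, 0): 4 * p**3 * q + 4 * p * q**3,
            (2, 0): p**4 + q**4 + 4 * p**2 * q**2,
            (1, 1): 2 * p**2 * q + 2 * p * q**2,
            (2, 1): p**3 + q**3 + p * q,
        }
        weights = binom.pmf(np.arange(T + 1), T, p)
        e_count = np.zeros((3, 3))
        e_plug = np.zeros((3, 3))
        for X in range(T + 1):
            e_count += weights[X] * cond_ibs_unbiased(AlleleCounts(X, T - X, T))
            ph, qh = X / T, 1 - X / T
            e_plug[0, 0] += weights[X] * 2 * ph**2 * qh**2
        for (i, z), val in targets.items():
            assert e_count[i, z] == pytest.approx(val, abs=1e-12)
        assert abs(e_plug[0, 0] - targets[(0, 0)]) > 1e-4  # bias reproduced


class TestPairSummaryAndSolve:
    def test_identical_vectors(self):
        t = make_table(np.tile([2, 1, 0, 1, 1, 0, 2, 1, 0, 1], (4, 1)))
        tables = cond_ibs_table(t)
        s = pair_ibs_summary(t.genotypes[0], t.genotypes[1], tables)
        assert s.L == 10
        assert s.n_ibs.tolist() == [0, 0, 10]
        est = estimate_pair_ibd(s)
        assert (est.k0, est.k1, est.k2) == (0.0, 0.0, 1.0)

    def test_conditional_sums_equal_L(self, rng):
        g = rng.integers(0, 3, size=(8, 40)).astype(np.int8)
        t = make_table(g)
        tables = cond_ibs_table(t)
        s = pair_ibs_summary(g[0], g[1], tables)
        for z in range(3):
            assert s.n_cond[:, z].sum() == pytest.approx(s.L, abs=1e-9)

    def test_two_snp_hand_worked_toy(self):
        # both SNPs have counts X=3, Y=3, T=6; pair genotypes (2,0), (1,1)
        # hand arithmetic: P(0|0)=0.2 P(1|0)=0.4 P(2|0)=0.4 P(1|1)=0.6 P(2|1)=0.4
        t = make_table([[2, 1], [0, 1], [1, 1]])
        tables = cond_ibs_table(t)
        s = pair_ibs_summary(t.genotypes[0], t.genotypes[1], tables)
        assert s.n_ibs.tolist() == [1, 0, 1]
        np.testing.assert_allclose(s.n_cond[:, 0], [0.4, 0.8, 0.8], atol=1e-12)
        np.testing.assert_allclose(s.n_cond[:, 1], [0.0, 1.2, 0.8], atol=1e-12)
        est = estimate_pair_ibd(s)
        # k0 = 1/0.4 = 2.5; k1 = (0 - 2.5*0.8)/1.2 = -5/3; k2 = 1 - k0 - k1
        assert est.k0 == pytest.approx(2.5)
        assert est.k1 == pytest.approx(-5 / 3)
        assert est.k2 == pytest.approx(1 - 2.5 + 5 / 3)

    def test_missing_snps_excluded(self):
        g = np.array([[2, 1, MISSING], [0, MISSING, 1], [1, 1, 1], [1, 0, 1]])
        t = make_table(g)
        tables = cond_ibs_table(t)
        s = pair_ibs_summary(g[0], g[1], tables)
        assert s.L == 1  # only snp1 observed in both

    def test_inestimable_pair(self):
        g = np.array([[MISSING, MISSING], [0, 1], [1, 1], [2, 0]])
        t = make_table(g)
        tables = cond_ibs_table(t)
        est = estimate_pair_ibd(pair_ibs_summary(g[0], g[1], tables), "a", "b")
        assert est.status == "no_usable_snps"
        assert np.isnan(est.k0)

    @given(st.data())
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_k_sums_to_one(self, data):
        n_snps = data.draw(st.integers(2, 30))
        seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, size=(6, n_snps)).astype(np.int8)
        t = make_table(g)
        tables = cond_ibs_table(t)
        est = estimate_pair_ibd(pair_ibs_summary(g[0], g[1], tables))
        if est.status == "ok":
            assert est.k0 + est.k1 + est.k2 == pytest.approx(1.0, abs=1e-10)


class TestAllPairs:
    def test_pair_count_and_order(self, rng):
        g = rng.integers(0, 3, size=(5, 30)).astype(np.int8)
        t = make_table(g)
        df = estimate_all_pairs(t)
        assert len(df) == 10
        pairs = list(zip(df["subject1"], df["subject2"]))
        assert pairs == sorted(pairs)

    def test_duplicate_subject_detected(self, rng):
        g = rng.integers(0, 3, size=(3, 60)).astype(np.int8)
        g[2] = g[0]
        t = make_table(g)
        df = estimate_all_pairs(t)
        dup = df[(df["subject1"] == "sub1") & (df["subject2"] == "sub3")].iloc[0]
        assert (dup.k0, dup.k1, dup.k2) == (0.0, 0.0, 1.0)
        others = df[~((df["subject1"] == "sub1") & (df["subject2"] == "sub3"))]
        assert not ((others.k0 == 0) & (others.k1 == 0)).any()

    def test_matches_single_pair_path(self, rng):
        # the vectorised all-pairs path agrees with the per-pair path
        g = rng.integers(-1, 3, size=(6, 50)).astype(np.int8)
        g[:, :2] = 1
        t = make_table(g)
        tables = cond_ibs_table(t)
        df = estimate_all_pairs(t, tables).set_index(["subject1", "subject2"])
        for i in range(6):
            for j in range(i + 1, 6):
                est = estimate_pair_ibd(pair_ibs_summary(g[i], g[j], tables))
                row = df.loc[(f"sub{i + 1}", f"sub{j + 1}")]
                if est.status == "ok":
                    assert row.k0 == pytest.approx(est.k0, abs=1e-10)
                    assert row.k1 == pytest.approx(est.k1, abs=1e-10)
                    assert row.L == est.L

    def test_invariant_to_subject_order(self, rng):
        g = rng.integers(0, 3, size=(5, 40)).astype(np.int8)
        t = make_table(g)
        df1 = estimate_all_pairs(t)
        perm = rng.permutation(5)
        t2 = t.subset(subject_idx=perm)
        df2 = estimate_all_pairs(t2)
        m1 = df1.set_index(["subject1", "subject2"])[["k0", "k1", "k2"]]
        m2 = df2.set_index(["subject1", "subject2"])[["k0", "k1", "k2"]]
        assert np.allclose(m1.sort_index(), m2.sort_index(), atol=1e-12)
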