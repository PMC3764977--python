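import numpy as np
import pytest

from conftest import make_table
from ibdcheck.fixture import independent_snp_panel, sample_population
from ibdcheck.genedrop import (
    DEFAULT_RELATIONSHIPS,
    PedMember,
    Pedigree,
    SimulatedPair,
    _meiosis,
    apply_missingness,
    builtin_pedigree,
    drop_founder_labels,
    drop_genes,
    ibd_share_counts,
    read_pedigree,
    simulate_reference_pairs,
    validate_pedigree,
)
from ibdcheck.genotype_data import MISSING, SnpInfo
from ibdcheck.ibd_mme import cond_ibs_table


def first_cousin_marriage_pedigree():
    """Mother-daughter pair where the daughter's parents are first cousins
    (8 members; inbred, but a valid pedigree)."""
    P = PedMember
    return Pedigree(
        [
            P(1, 3, 2, 2),  # daughter (inbred)
            P(2, 4, 5, 2),  # mother, cousin of 3
            P(3, 6, 7, 1),  # father, cousin of 2
            P(4, 0, 0, 1),
            P(5, 8, 9, 2),  # sib of 6
            P(6, 8, 9, 1),
            P(7, 0, 0, 2),
            P(8, 0, 0, 1),
            P(9, 0, 0, 2),
        ],
        name="user",
    )


class TestPedigrees:
    def test_builtin_structures(self):
        po = builtin_pedigree("parent.offspring")
        assert len(po.members) == 3 and len(po.founders) == 2
        hs = builtin_pedigree("half.sibs")
        a, b = hs.members[0], hs.members[1]
        shared = {a.father_id, a.mother_id} & {b.father_id, b.mother_id}
        assert len(shared) == 1
        fc = builtin_pedigree("cousins")
        assert len(fc.members) == 8
        assert validate_pedigree(fc) == []

    def test_unknown_name(self):
        with pytest.raises(ValueError, match="unknown relationship"):
            builtin_pedigree("second.cousins")

    def test_inbred_pedigree_valid(self):
        ped = first_cousin_marriage_pedigree()
        assert validate_pedigree(ped) == []

    def test_female_father_rejected(self):
        P = PedMember
        members = [P(1, 2, 3, 1), P(2, 0, 0, 2), P(3, 0, 0, 2)]
        with pytest.raises(ValueError, match="father 2 has sex 2"):
            Pedigree(members)

    def test_descent_cycle_rejected(self):
        P = PedMember
        members = [P(1, 2, 3, 1), P(2, 1, 3, 1), P(3, 0, 0, 2)]
        with pytest.raises(ValueError, match="cycle"):
            Pedigree(members)

    def test_read_pedigree_file(self, tmp_path):
        p = tmp_path / "ped.txt"
        p.write_text("# target pair first\n1 2 3 2\n2 0 0 1\n3 0 0 2\n")
        ped = read_pedigree(p)
        assert [m.member_id for m in ped.members] == [1, 2, 3]
        assert ped.members[0].sex == 2


@pytest.fixture(scope="module")
def panel():
    rng = np.random.default_rng(77)
    snps, models = independent_snp_panel(200, rng, n_chromosomes=4, spacing_cm=10)
    data = sample_population(models, snps, 120, rng)
    return snps, models, data


class TestDropGenes:
    def test_mz_identical(self, panel, rng):
        snps, models, _ = panel
        pair = drop_genes(builtin_pedigree("dup.mz"), models, snps, rng)
        assert np.array_equal(pair.g1, pair.g2)

    def test_parent_offspring_share_allele_everywhere(self, panel, rng):
        snps, models, _ = panel
        for _ in range(5):
            pair = drop_genes(builtin_pedigree("parent.offspring"), models, snps, rng)
            opposite = ((pair.g1 == 2) & (pair.g2 == 0)) | ((pair.g1 == 0) & (pair.g2 == 2))
            assert not opposite.any()

    def test_offspring_alleles_come_from_parents(self, panel, rng):
        snps, _, _ = panel
        ped = builtin_pedigree("full.sibs")
        labels = drop_founder_labels(ped, snps, rng)
        for child in (1, 2):
            for row in labels[child]:
                # every transmitted label exists among the founders' labels
                assert set(np.unique(row)) <= {6, 7, 8, 9}
            # paternal haplotype labels come from the father (member 3)
            assert set(np.unique(labels[child][0])) <= {6, 7}
            assert set(np.unique(labels[child][1])) <= {8, 9}

    def test_crossover_rate_haldane(self, rng):
        # 100 cM map: mean crossovers per meiosis = 1 Morgan
        pos = np.linspace(0.0, 100.0, 201)
        hap = np.vstack([np.zeros(201, dtype=np.int8), np.ones(201, dtype=np.int8)])
        switches = []
        for _ in range(2000):
            out = _meiosis(hap, pos, rng)
            switches.append((np.diff(out) != 0).sum())
        assert np.mean(switches) == pytest.approx(1.0, abs=0.07)

    def test_missing_genetic_positions_rejected(self, panel, rng):
        _, models, _ = panel
        bad = [SnpInfo("x", 1, 100)]
        with pytest.raises(ValueError, match="genetic position"):
            drop_genes(builtin_pedigree("unrelated"), models, bad, rng)


class TestRealizedIbd:
    def test_full_sib_proportions(self, rng):
        snps, _ = independent_snp_panel(300, rng, n_chromosomes=10, spacing_cm=10)
        ped = builtin_pedigree("full.sibs")
        props = np.zeros(3)
        n_rep = 500
        for _ in range(n_rep):
            labels = drop_founder_labels(ped, snps, rng)
            z = ibd_share_counts(labels[1], labels[2])
            props += np.bincount(z, minlength=3) / len(z)
        props /= n_rep
        np.testing.assert_allclose(props, [0.25, 0.5, 0.25], atol=0.03)

    def test_inbred_offspring_can_autozygote(self, rng):
        # offspring of first cousins: the two haplotypes can carry the same
        # founder label (inbreeding coefficient 1/16)
        snps, _ = independent_snp_panel(100, rng, n_chromosomes=4, spacing_cm=20)
        ped = first_cousin_marriage_pedigree()
        auto = 0
        for _ in range(200):
            labels = drop_founder_labels(ped, snps, rng)
            auto += (labels[1][0] == labels[1][1]).mean()
        assert 0.01 < auto / 200 < 0.15  # around 1/16


class TestMissingness:
    def test_complete_study_unchanged(self, panel, rng):
        snps, models, data = panel
        pair = drop_genes(builtin_pedigree("unrelated"), models, snps, rng)
        out = apply_missingness(pair, data, rng)
        assert np.array_equal(out.g1, pair.g1)
        assert np.array_equal(out.g2, pair.g2)

    def test_single_subject_mask_forced(self, rng):
        g = np.ones((1, 20), dtype=np.int8)
        g[0, :10] = MISSING
        study = make_table(g)
        pair = SimulatedPair(
            g1=np.ones(20, dtype=np.int8), g2=np.ones(20, dtype=np.int8),
            relationship="unrelated",
        )
        out = apply_missingness(pair, study, rng)
        assert (out.g1[:10] == MISSING).all() and (out.g1[10:] == 1).all()
        assert (out.g2[:10] == MISSING).all()

    def test_marginal_rate_matches_study(self, rng):
        g = np.ones((30, 50), dtype=np.int8)
        g[rng.random(g.shape) < 0.08] = MISSING
        study = make_table(g)
        study_rate = (g == MISSING).mean()
        sim_missing = []
        for _ in range(500):
            pair = SimulatedPair(
                g1=np.ones(50, dtype=np.int8), g2=np.ones(50, dtype=np.int8),
                relationship="unrelated",
            )
            out = apply_missingness(pair, study, rng)
            sim_missing.append((out.g1 == MISSING).mean())
            sim_missing.append((out.g2 == MISSING).mean())
        assert np.mean(sim_missing) == pytest.approx(study_rate, abs=0.02)


class TestSimulateReferencePairs:
    def test_default_relationship_set(self):
        assert DEFAULT_RELATIONSHIPS == (
            "unrelated", "dup.mz", "parent.offspring", "full.sibs", "half.sibs",
        )
        assert "cousins" not in DEFAULT_RELATIONSHIPS

    def test_mz_estimates_are_dup_point(self, panel, rng):
        snps, models, data = panel
        tables = cond_ibs_table(data)
        df = simulate_reference_pairs("dup.mz", 20, models, data, tables, rng)
        ok = df[df.status == "ok"]
        assert np.allclose(ok[["k0", "k1"]], 0.0)
        assert np.allclose(ok["k2"], 1.0)

    def test_unrelated_recovery(self, rng):
        # widely spaced SNPs so loci are effectively independent
        snps, models = independent_snp_panel(500, rng, n_chromosomes=20, spacing_cm=50)
        data = sample_population(models, snps, 150, rng)
        tables = cond_ibs_table(data)
        df = simulate_reference_pairs("unrelated", 200, models, data, tables, rng)
        ok = df[df.status == "ok"]
        assert ok["k0"].mean() == pytest.approx(1.0, abs=0.03)
        assert ok["k1"].mean() == pytest.approx(0.0, abs=0.03)

    def test_deterministic_under_seed(self, panel):
        snps, models, data = panel
        tables = cond_ibs_table(data)
        df1 = simulate_reference_pairs(
            "full.sibs", 10, models, data, tables, np.random.default_rng(3)
        )
        df2 = simulate_reference_pairs(
            "full.sibs", 10, models, data, tables, np.random.default_rng(3)
        )
        assert df1.equals(df2)
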