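"""Synthetic study generator with planted related pairs.

Emulates the genotype data of a candidate-gene case-control study: a modest
number of SNPs clustered into gene-like groups spread over several
autosomes, with LD between SNPs of the same gene and (near-)independence
between genes.  The truth haplotype model is a Markov chain per chromosome:
each gene draws an allele frequency, and within a gene adjacent SNPs copy
the previous allele with probability ``ld_strength`` (0 = independent SNPs,
1 = a single haplotype block).

Unrelated subjects receive two independent haplotypes per chromosome;
planted related pairs are produced by gene drop from the same truth model,
so the planted signal is genuine IBD sharing, not a genotype artifact.
Missingness is independent per call at ``missing_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genedrop import builtin_pedigree, drop_genes
from .genotype_data import MISSING, GenotypeTable, SnpInfo, SubjectInfo, infer_genetic_map
from .ld_model import HaplotypeModel, sample_haplotypes

GENE_SIZE = 6  # SNPs per gene-like cluster
SNP_SPACING_BP = 2_000  # within-gene spacing
GENE_SPACING_BP = 3_000_000  # between-gene spacing


def truth_models(
    n_snps: int,
    n_chromosomes: int,
    ld_strength: float,
    rng: np.random.Generator,
    freq_low: float = 0.1,
    freq_high: float = 0.9,
) -> tuple[list[SnpInfo], dict[int, HaplotypeModel]]:
    """Build SNP metadata and the per-chromosome truth haplotype models."""
    if not 0.0 <= ld_strength < 1.0:
        raise ValueError("ld_strength must be in [0, 1)")
    if not 1 <= n_chromosomes <= 22:
        raise ValueError("n_chromosomes must be in 1..22")
    # genes round-robin over chromosomes, GENE_SIZE SNPs each
    snps: list[SnpInfo] = []
    gene_of: list[int] = []
    per_chrom_count = [0] * n_chromosomes
    n_genes = (n_snps + GENE_SIZE - 1) // GENE_SIZE
    snp_no = 0
    for g in range(n_genes):
        chrom = g % n_chromosomes + 1
        gene_idx_on_chrom = g // n_chromosomes
        base = 1_000_000 + gene_idx_on_chrom * GENE_SPACING_BP
        for j in range(GENE_SIZE):
            if snp_no >= n_snps:
                break
            snps.append(
                SnpInfo(
                    snp_id=f"snp{snp_no + 1}",
                    chromosome=chrom,
                    physical_pos=base + j * SNP_SPACING_BP,
                )
            )
            gene_of.append(g)
            per_chrom_count[chrom - 1] += 1
            snp_no += 1
    order = sorted(range(len(snps)), key=lambda i: (snps[i].chromosome, snps[i].physical_pos))
    snps = [snps[i] for i in order]
    gene_of = [gene_of[i] for i in order]
    snps = infer_genetic_map(snps)

    freqs_by_gene = {g: rng.uniform(freq_low, freq_high) for g in sorted(set(gene_of))}
    models: dict[int, HaplotypeModel] = {}
    for chrom in range(1, n_chromosomes + 1):
        idx = [i for i, s in enumerate(snps) if s.chromosome == chrom]
        if not idx:
            continue
        ids = [snps[i].snp_id for i in idx]
        p = np.array([freqs_by_gene[gene_of[i]] for i in idx])
        transitions = np.empty((len(idx) - 1, 2, 2))
        for m in range(1, len(idx)):
            same_gene = gene_of[idx[m]] == gene_of[idx[m - 1]]
            r = ld_strength if same_gene else 0.0
            pm = p[m]
            transitions[m - 1] = [
                [1 - (1 - r) * pm - 0.0, (1 - r) * pm],
                [(1 - r) * (1 - pm), r + (1 - r) * pm],
            ]
            transitions[m - 1, 0, 0] = 1 - transitions[m - 1, 0, 1]
        models[chrom] = HaplotypeModel(chrom, ids, float(p[0]), transitions, "truth")
    return snps, models


def independent_snp_panel(
    n_snps: int,
    rng: np.random.Generator,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    n_chromosomes: int = 20,
    spacing_cm: float = 50.0,
) -> tuple[list[SnpInfo], dict[int, HaplotypeModel]]:
    """Panel of effectively independent SNPs with MAF ~ U(maf_low, maf_high).

    SNPs are spread over ``n_chromosomes`` autosomes at wide genetic spacing
    and the haplotype models carry no LD, so simulated genotypes are
    independent across SNPs — the idealized setting in which the moment
    estimators' behaviour is known in closed form.
    """
    snps: list[SnpInfo] = []
    models: dict[int, HaplotypeModel] = {}
    per_chrom = (n_snps + n_chromosomes - 1) // n_chromosomes
    snp_no = 0
    for c in range(1, n_chromosomes + 1):
        ids = []
        freqs = []
        for j in range(per_chrom):
            if snp_no >= n_snps:
                break
            sid = f"snp{snp_no + 1}"
            ids.append(sid)
            snps.append(
                SnpInfo(sid, c, int((j * spacing_cm + 1) * 1e6), genetic_pos=j * spacing_cm + 1.0)
            )
            freqs.append(rng.uniform(maf_low, maf_high))
            snp_no += 1
        if not ids:
            break
        p = np.array(freqs)
        transitions = np.empty((len(ids) - 1, 2, 2))
        for m in range(1, len(ids)):
            transitions[m - 1] = [[1 - p[m], p[m]], [1 - p[m], p[m]]]
        models[c] = HaplotypeModel(c, ids, float(p[0]), transitions, "independence")
    return snps, models


def sample_population(
    models: dict[int, HaplotypeModel],
    snps: list[SnpInfo],
    n_subjects: int,
    rng: np.random.Generator,
    id_prefix: str = "ref",
) -> GenotypeTable:
    """Sample unrelated diploid subjects (two haplotypes each) from the
    models; all subjects are flagged as reference-pool members."""
    chroms = np.array([s.chromosome for s in snps])
    G = np.empty((n_subjects, len(snps)), dtype=np.int8)
    for c, model in models.items():
        idx = np.flatnonzero(chroms == c)
        haps = sample_haplotypes(model, 2 * n_subjects, rng)
        G[:, idx] = haps[0::2] + haps[1::2]
    subjects = [SubjectInfo(f"{id_prefix}{i + 1}") for i in range(n_subjects)]
    return GenotypeTable(G, snps, subjects)


@dataclass
class Fixture:
    data: GenotypeTable
    truth: pd.DataFrame  # columns subject1, subject2, relationship
    models: dict[int, HaplotypeModel] = field(repr=False, default_factory=dict)


def generate_fixture(
    n_subjects: int = 208,
    n_snps: int = 1250,
    n_chromosomes: int = 22,
    planted: dict[str, int] | None = None,
    ld_strength: float = 0.6,
    missing_rate: float = 0.01,
    seed: int | np.random.Generator = 0,
    reference_fraction: float = 0.52,
) -> Fixture:
    """Generate a synthetic study with known planted relationships.

    Planted pairs occupy the tail of the subject list (outside the reference
    pool when it is large enough), mirroring related cases slipping into a
    nominally unrelated sample.  ``reference_fraction`` of subjects, from the
    head of the list, form the reference pool.  Fully deterministic for a
    fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    planted = dict(planted or {})
    n_planted_subjects = 2 * sum(planted.values())
    if n_planted_subjects > n_subjects:
        raise ValueError(
            f"{sum(planted.values())} planted pairs need {n_planted_subjects} subjects, "
            f"only {n_subjects} requested"
        )
    snps, models = truth_models(n_snps, n_chromosomes, ld_strength, rng)
    n_unrelated = n_subjects - n_planted_subjects

    G = np.empty((n_subjects, len(snps)), dtype=np.int8)
    chrom_idx = {
        c: np.flatnonzero(np.array([s.chromosome for s in snps]) == c)
        for c in sorted(models)
    }
    for c, model in models.items():
        haps = sample_haplotypes(model, 2 * n_unrelated, rng)
        G[:n_unrelated, chrom_idx[c]] = haps[0::2] + haps[1::2]

    truth_rows = []
    row = n_unrelated
    for rel in sorted(planted):
        ped = builtin_pedigree(rel)
        for _ in range(planted[rel]):
            pair = drop_genes(ped, models, snps, rng)
            G[row] = pair.g1
            G[row + 1] = pair.g2
            truth_rows.append(
                {
                    "subject1": f"sub{row + 1}",
                    "subject2": f"sub{row + 2}",
                    "relationship": rel,
                }
            )
            row += 2

    if missing_rate > 0:
        G[rng.random(G.shape) < missing_rate] = MISSING

    n_ref = int(round(reference_fraction * n_subjects))
    subjects = [
        SubjectInfo(subject_id=f"sub{i + 1}", is_reference=i < n_ref)
        for i in range(n_subjects)
    ]
    data = GenotypeTable(G, snps, subjects)
    truth = pd.DataFrame(truth_rows, columns=["subject1", "subject2", "relationship"])
    return Fixture(data=data, truth=truth, models=models)
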