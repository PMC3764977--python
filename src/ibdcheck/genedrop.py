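"""Gene-drop simulation of genotype pairs with known relationship.

Founders of a minimal pedigree receive haplotypes sampled from a fitted
haplotype model; alleles are then "dropped" through the pedigree by
Mendelian segregation.  Each meiosis transmits a recombinant of the parent's
two haplotypes, with crossover points drawn as a Poisson process on the
genetic map (Haldane model: no chiasma interference) and the starting
haplotype chosen with probability 1/2.  Chromosomes segregate independently.
Finally, simulated genotypes are masked with the missingness pattern of a
randomly sampled study subject so the simulated pairs face the same data
loss as the study pairs they calibrate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_data import MISSING, GenotypeTable, SnpInfo
from .ibd_mme import CondIBSTable, estimate_simulated_pairs
from .ld_model import HaplotypeModel, sample_haplotypes

BUILTIN_RELATIONSHIPS = (
    "unrelated",
    "dup.mz",
    "parent.offspring",
    "full.sibs",
    "half.sibs",
    "cousins",
)

#: simulated by default; first cousins are rarely distinguishable from
#: unrelated pairs with candidate-gene marker sets, so they are opt-in
DEFAULT_RELATIONSHIPS = (
    "unrelated",
    "dup.mz",
    "parent.offspring",
    "full.sibs",
    "half.sibs",
)


@dataclass
class PedMember:
    member_id: int
    father_id: int
    mother_id: int
    sex: int  # 1 = male, 2 = female

    @property
    def is_founder(self) -> bool:
        return self.father_id == 0 and self.mother_id == 0


@dataclass
class Pedigree:
    """Relationship template; the first two members are the target pair.

    ``mz`` marks the monozygotic-twin/duplicate special case, where the
    second member is a genomic copy of the first rather than a separate
    meiotic product.
    """

    members: list[PedMember]
    name: str = "user"
    mz: bool = False

    def __post_init__(self) -> None:
        errors = validate_pedigree(self)
        if errors:
            raise ValueError("invalid pedigree: " + "; ".join(errors))

    @property
    def founders(self) -> list[PedMember]:
        return [m for m in self.members if m.is_founder]


def validate_pedigree(ped: Pedigree) -> list[str]:
    """Check pedigree invariants; returns one message per violation.

    Inbred pedigrees (e.g. an offspring of a first-cousin marriage) are
    valid; only cycles of descent are rejected.
    """
    errors: list[str] = []
    members = ped.members
    if len(members) < 2:
        errors.append("pedigree needs at least two members (the target pair)")
    ids = [m.member_id for m in members]
    if len(set(ids)) != len(ids):
        errors.append("duplicate member ids")
        return errors
    by_id = {m.member_id: m for m in members}
    for m in members:
        if m.sex not in (1, 2):
            errors.append(f"member {m.member_id}: sex must be 1 (male) or 2 (female)")
        if (m.father_id == 0) != (m.mother_id == 0):
            errors.append(
                f"member {m.member_id}: founders need both parent ids zero"
            )
            continue
        if m.is_founder:
            continue
        for pid, want_sex, role in (
            (m.father_id, 1, "father"),
            (m.mother_id, 2, "mother"),
        ):
            parent = by_id.get(pid)
            if parent is None:
                errors.append(f"member {m.member_id}: {role} {pid} not in pedigree")
            elif parent.sex != want_sex:
                errors.append(
                    f"member {m.member_id}: {role} {pid} has sex {parent.sex}"
                )
    # cycle check by DFS over parent links
    state: dict[int, int] = {}

    def visit(mid: int) -> bool:
        if state.get(mid) == 1:
            return False
        if state.get(mid) == 2:
            return True
        state[mid] = 1
        m = by_id.get(mid)
        ok = True
        if m is not None and not m.is_founder:
            for pid in (m.father_id, m.mother_id):
                if pid in by_id:
                    ok = ok and visit(pid)
        state[mid] = 2
        return ok

    for m in members:
        if not visit(m.member_id):
            errors.append(f"descent cycle involving member {m.member_id}")
            break
    return errors


def builtin_pedigree(name: str) -> Pedigree:
    """Minimal pedigree for a built-in relationship, target pair first."""
    P = PedMember
    if name == "unrelated":
        members = [P(1, 0, 0, 1), P(2, 0, 0, 2)]
    elif name == "dup.mz":
        members = [P(1, 0, 0, 1), P(2, 0, 0, 1)]
        return Pedigree(members, name=name, mz=True)
    elif name == "parent.offspring":
        members = [P(1, 2, 3, 2), P(2, 0, 0, 1), P(3, 0, 0, 2)]
    elif name == "full.sibs":
        members = [P(1, 3, 4, 1), P(2, 3, 4, 2), P(3, 0, 0, 1), P(4, 0, 0, 2)]
    elif name == "half.sibs":
        members = [
            P(1, 3, 4, 1),
            P(2, 3, 5, 2),
            P(3, 0, 0, 1),
            P(4, 0, 0, 2),
            P(5, 0, 0, 2),
        ]
    elif name == "cousins":
        # sibs 3 and 5 (children of 7 x 8) marry founders 4 and 6
        members = [
            P(1, 3, 4, 1),
            P(2, 5, 6, 2),
            P(3, 7, 8, 1),
            P(4, 0, 0, 2),
            P(5, 7, 8, 1),
            P(6, 0, 0, 2),
            P(7, 0, 0, 1),
            P(8, 0, 0, 2),
        ]
    else:
        raise ValueError(f"unknown relationship {name!r}; "
                         f"built-ins are {BUILTIN_RELATIONSHIPS}")
    return Pedigree(members, name=name)


def read_pedigree(path) -> Pedigree:
    """Read a whitespace-delimited pedigree file: id, father, mother, sex.

    Founders have father = mother = 0; the first two rows are the target
    pair whose relationship is being simulated.
    """
    members = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            members.append(PedMember(*(int(v) for v in parts)))
    return Pedigree(members, name="user")


# -- meiosis and dropping ------------------------------------------------------


def _meiosis(
    hap_pair: np.ndarray, genetic_pos: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Transmit one recombinant haplotype (Haldane crossover process).

    Crossover count is Poisson with mean = map length in Morgans; crossover
    locations are uniform on the genetic map; the starting haplotype is
    chosen with probability 1/2.
    """
    lo, hi = genetic_pos[0], genetic_pos[-1]
    length_morgans = (hi - lo) / 100.0
    n_cross = rng.poisson(length_morgans)
    start = rng.integers(2)
    if n_cross == 0:
        return hap_pair[start]
    cuts = np.sort(rng.uniform(lo, hi, size=n_cross))
    source = (start + np.searchsorted(cuts, genetic_pos, side="right")) % 2
    return hap_pair[source, np.arange(len(genetic_pos))]


def _drop_chromosome(
    ped: Pedigree,
    founder_haps: dict[int, np.ndarray],
    genetic_pos: np.ndarray,
    rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    """Drop one chromosome through the pedigree.

    ``founder_haps[id]`` is a (2, M) array; the result maps every member to
    its (2, M) haplotype pair (paternal row 0, maternal row 1).  Works for
    arbitrary integer-valued founder arrays, so allele haplotypes and
    founder-origin labels drop through the same code path.
    """
    haps: dict[int, np.ndarray] = {}

    def resolve(mid: int) -> np.ndarray:
        if mid in haps:
            return haps[mid]
        m = next(mm for mm in ped.members if mm.member_id == mid)
        if m.is_founder:
            haps[mid] = founder_haps[mid]
        else:
            pat = _meiosis(resolve(m.father_id), genetic_pos, rng)
            mat = _meiosis(resolve(m.mother_id), genetic_pos, rng)
            haps[mid] = np.stack([pat, mat])
        return haps[mid]

    for m in ped.members:
        resolve(m.member_id)
    return haps


@dataclass
class SimulatedPair:
    """Genotype vectors of the target pair, aligned to the study SNP list."""

    g1: np.ndarray
    g2: np.ndarray
    relationship: str
    replicate: int = 0


def _chrom_blocks(snps: Sequence[SnpInfo]) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """(chromosome, snp index array, genetic positions) per chromosome."""
    chroms = np.array([s.chromosome for s in snps])
    blocks = []
    for c in sorted(set(chroms.tolist())):
        idx = np.flatnonzero(chroms == c)
        gp = np.array([snps[i].genetic_pos for i in idx], dtype=float)
        if np.any(np.isnan(gp)):
            raise ValueError(f"chromosome {c}: genetic positions missing")
        blocks.append((c, idx, gp))
    return blocks


def drop_genes(
    ped: Pedigree,
    models: dict[int, HaplotypeModel],
    snps: Sequence[SnpInfo],
    rng: np.random.Generator,
) -> SimulatedPair:
    """Simulate the target pair's genotypes (before missingness).

    Founder haplotypes come from the per-chromosome models; every chromosome
    present in ``snps`` must have a model and genetic positions.  For the
    MZ/duplicate pedigree the second member is a copy of the first genome.
    """
    for s in snps:
        if s.genetic_pos is None:
            raise ValueError(f"SNP {s.snp_id}: genetic position required for gene drop")
    n_snps = len(snps)
    g1 = np.empty(n_snps, dtype=np.int8)
    g2 = np.empty(n_snps, dtype=np.int8)
    t1, t2 = ped.members[0].member_id, ped.members[1].member_id
    for c, idx, gp in _chrom_blocks(snps):
        if c not in models:
            raise ValueError(f"no haplotype model for chromosome {c}")
        model = models[c]
        founders = ped.founders
        haps = sample_haplotypes(model, 2 * len(founders), rng)
        founder_haps = {
            f.member_id: haps[2 * i : 2 * i + 2] for i, f in enumerate(founders)
        }
        dropped = _drop_chromosome(ped, founder_haps, gp, rng)
        g1[idx] = dropped[t1].sum(axis=0)
        g2[idx] = dropped[t1].sum(axis=0) if ped.mz else dropped[t2].sum(axis=0)
    return SimulatedPair(g1=g1, g2=g2, relationship=ped.name)


def drop_founder_labels(
    ped: Pedigree,
    snps: Sequence[SnpInfo],
    rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    """Drop unique founder-allele labels instead of alleles.

    Founder ``f`` carries labels (2f, 2f+1); the result maps each member to
    its (2, M) label arrays.  Realized IBD sharing of the target pair is the
    per-SNP count of matching labels, which tests use to check Mendelian
    transmission and genome-wide IBD proportions.
    """
    n_snps = len(snps)
    out = {m.member_id: np.empty((2, n_snps), dtype=np.int64) for m in ped.members}
    for c, idx, gp in _chrom_blocks(snps):
        founder_haps = {
            f.member_id: np.tile(
                np.array([[2 * f.member_id], [2 * f.member_id + 1]]), (1, len(idx))
            )
            for f in ped.founders
        }
        dropped = _drop_chromosome(ped, founder_haps, gp, rng)
        for mid, arr in dropped.items():
            out[mid][:, idx] = arr
    if ped.mz:
        out[ped.members[1].member_id] = out[ped.members[0].member_id].copy()
    return out


def ibd_share_counts(labels1: np.ndarray, labels2: np.ndarray) -> np.ndarray:
    """Per-SNP count of alleles shared IBD given founder-label haplotypes."""
    a, b = labels1
    c, d = labels2
    # maximum matching between {a,b} and {c,d}
    direct = (a == c).astype(int) + (b == d).astype(int)
    crossed = (a == d).astype(int) + (b == c).astype(int)
    return np.maximum(direct, crossed)


# -- missingness and reference-pair simulation ---------------------------------


def apply_missingness(
    pair: SimulatedPair, study: GenotypeTable, rng: np.random.Generator
) -> SimulatedPair:
    """Mask each simulated member with a random study subject's missingness.

    The two members draw their pattern subjects independently.
    """
    if study.n_subjects == 0:
        raise ValueError("study table has no subjects")
    masks = study.missing_mask()
    g1 = pair.g1.copy()
    g2 = pair.g2.copy()
    g1[masks[rng.integers(study.n_subjects)]] = MISSING
    g2[masks[rng.integers(study.n_subjects)]] = MISSING
    return SimulatedPair(g1, g2, pair.relationship, pair.replicate)


def simulate_reference_pairs(
    relationship: str | Pedigree,
    n_pairs: int,
    models: dict[int, HaplotypeModel],
    data: GenotypeTable,
    tables: CondIBSTable,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate ``n_pairs`` pairs of a relationship and estimate their IBD
    coefficients with the same conditional IBS tables as the study pairs.

    Returns the estimate frame of :func:`~ibdcheck.ibd_mme.estimate_simulated_pairs`;
    inestimable replicates keep their row with a non-"ok" status.
    """
    ped = relationship if isinstance(relationship, Pedigree) else builtin_pedigree(relationship)
    n_snps = data.n_snps
    G1 = np.empty((n_pairs, n_snps), dtype=np.int8)
    G2 = np.empty((n_pairs, n_snps), dtype=np.int8)
    for j in range(n_pairs):
        pair = drop_genes(ped, models, data.snps, rng)
        pair = apply_missingness(pair, data, rng)
        G1[j] = pair.g1
        G2[j] = pair.g2
    return estimate_simulated_pairs(G1, G2, tables, relationship=ped.name)
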