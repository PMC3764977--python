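"""Genotype data model and I/O.

The central container is :class:`GenotypeTable`: an additive genotype matrix
(subjects x SNPs, each cell counting copies of ``allele_a``, with -1 for
missing) together with per-SNP metadata (:class:`SnpInfo`) and per-subject
metadata (:class:`SubjectInfo`).  Subjects flagged ``is_reference`` form the
pool treated as a population random sample; allele frequencies, conditional
IBS probabilities and haplotype-frequency (LD) models are estimated from that
pool only.

Supported formats are PLINK text (.ped/.map) and VCF.  Only biallelic
autosomal SNPs (chromosomes 1-22) are handled; within a chromosome SNPs are
kept sorted by ascending physical position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MISSING = -1

AUTOSOMES = frozenset(range(1, 23))


@dataclass
class SnpInfo:
    """Metadata for one biallelic autosomal SNP.

    ``genetic_pos`` is in centiMorgans and may be absent on input; see
    :func:`infer_genetic_map`.  ``physical_pos`` is 1-based base pairs.
    """

    snp_id: str
    chromosome: int
    physical_pos: int
    allele_a: str = "A"
    allele_b: str = "B"
    genetic_pos: Optional[float] = None

    def __post_init__(self) -> None:
        if self.chromosome not in AUTOSOMES:
            raise ValueError(
                f"SNP {self.snp_id}: chromosome {self.chromosome} is not an autosome 1-22"
            )
        if self.physical_pos <= 0:
            raise ValueError(f"SNP {self.snp_id}: physical_pos must be positive")


@dataclass
class SubjectInfo:
    """One study subject; ``is_reference`` marks membership in the pool used
    for allele-frequency, conditional-IBS and LD estimation (e.g. controls)."""

    subject_id: str
    is_reference: bool = True


@dataclass
class AlleleCounts:
    """Reference-pool allele counts at one SNP: X copies of allele A, Y of
    allele a, T = X + Y = twice the number of observed reference genotypes."""

    X: int
    Y: int
    T: int

    def __post_init__(self) -> None:
        if self.X + self.Y != self.T:
            raise ValueError("allele counts must satisfy X + Y = T")

    @property
    def p_hat(self) -> float:
        return self.X / self.T

    @property
    def q_hat(self) -> float:
        return self.Y / self.T


@dataclass
class GenotypeTable:
    """Subjects x SNPs additive genotype matrix with metadata.

    ``genotypes[s, m]`` counts copies of ``snps[m].allele_a`` carried by
    subject ``s`` (0, 1 or 2) or is ``MISSING`` (-1).
    """

    genotypes: np.ndarray
    snps: list[SnpInfo]
    subjects: list[SubjectInfo]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotype matrix must be 2-dimensional")
        n_sub, n_snp = self.genotypes.shape
        if n_sub != len(self.subjects) or n_snp != len(self.snps):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match metadata "
                f"({len(self.subjects)} subjects, {len(self.snps)} SNPs)"
            )
        valid = np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"invalid genotype value {self.genotypes[tuple(bad)]} at "
                f"subject {bad[0]}, SNP {bad[1]}"
            )
        self._check_sorted()

    def _check_sorted(self) -> None:
        for prev, cur in zip(self.snps, self.snps[1:]):
            if cur.chromosome == prev.chromosome and cur.physical_pos < prev.physical_pos:
                raise ValueError(
                    f"SNPs out of order on chromosome {cur.chromosome}: "
                    f"{prev.snp_id} @ {prev.physical_pos} precedes {cur.snp_id} @ {cur.physical_pos}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def reference_mask(self) -> np.ndarray:
        return np.array([s.is_reference for s in self.subjects], dtype=bool)

    @property
    def chromosomes(self) -> list[int]:
        """Distinct chromosomes present, ascending."""
        return sorted({s.chromosome for s in self.snps})

    def snp_indices(self, chromosome: int) -> np.ndarray:
        return np.flatnonzero(
            np.array([s.chromosome for s in self.snps]) == chromosome
        )

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def subset(
        self,
        subject_idx: Optional[Sequence[int]] = None,
        snp_idx: Optional[Sequence[int]] = None,
    ) -> "GenotypeTable":
        g = self.genotypes
        subjects = self.subjects
        snps = self.snps
        if subject_idx is not None:
            subject_idx = np.asarray(subject_idx)
            g = g[subject_idx, :]
            subjects = [subjects[i] for i in subject_idx]
        if snp_idx is not None:
            snp_idx = np.asarray(snp_idx)
            g = g[:, snp_idx]
            snps = [snps[i] for i in snp_idx]
        return GenotypeTable(g.copy(), list(snps), list(subjects))


# -- allele counting -----------------------------------------------------------


def allele_counts(data: GenotypeTable, snp_index: int) -> AlleleCounts:
    """Reference-pool allele counts X, Y, T at one SNP.

    Raises ``ValueError`` when no reference genotype is observed (T = 0).
    """
    g = data.genotypes[data.reference_mask, snp_index]
    obs = g != MISSING
    T = 2 * int(obs.sum())
    if T == 0:
        raise ValueError(
            f"SNP {data.snps[snp_index].snp_id}: no observed reference genotypes"
        )
    X = int(g[obs].sum())
    return AlleleCounts(X=X, Y=T - X, T=T)


def allele_counts_all(data: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised reference-pool counts for every SNP: arrays (X, T).

    SNPs with no observed reference genotypes get T = 0 (callers must mask)."""
    g = data.genotypes[data.reference_mask, :]
    obs = g != MISSING
    T = 2 * obs.sum(axis=0)
    X = np.where(obs, g, 0).sum(axis=0)
    return X.astype(np.int64), T.astype(np.int64)


# -- genetic map ---------------------------------------------------------------


def infer_genetic_map(snps: Sequence[SnpInfo], rate: float = 1.0) -> list[SnpInfo]:
    """Fill missing genetic positions from physical positions.

    SNPs without a ``genetic_pos`` get ``physical_pos * rate / 1e6`` cM
    (default 1 cM/Mb, the conventional genome-wide average); SNPs that already
    carry a genetic position are returned unchanged.
    """
    if rate < 0:
        raise ValueError("cM/Mb rate must be non-negative")
    out = []
    for s in snps:
        if s.genetic_pos is None:
            out.append(replace(s, genetic_pos=s.physical_pos * rate / 1e6))
        else:
            out.append(replace(s))
    return out


# -- PLINK text I/O ------------------------------------------------------------


def read_plink(ped_path, map_path) -> GenotypeTable:
    """Read PLINK text .ped/.map into a :class:`GenotypeTable`.

    The .map file has columns chromosome, SNP id, genetic position (cM,
    0 = unknown), physical position (bp).  The .ped file has six leading
    columns (family, individual, father, mother, sex, phenotype) followed by
    two allele columns per SNP; allele "0" is missing.  ``allele_a`` is the
    first non-missing allele observed for each SNP.  SNPs are sorted by
    (chromosome, bp) on load.
    """
    snps: list[SnpInfo] = []
    seen_ids: set[str] = set()
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, snp_id, cm, bp = parts
            if snp_id in seen_ids:
                raise ValueError(f"{map_path}:{lineno}: duplicate SNP id {snp_id!r}")
            seen_ids.add(snp_id)
            cm_val = float(cm)
            snps.append(
                SnpInfo(
                    snp_id=snp_id,
                    chromosome=int(chrom),
                    physical_pos=int(bp),
                    genetic_pos=cm_val if cm_val != 0.0 else None,
                )
            )
    n_snps = len(snps)

    subjects: list[SubjectInfo] = []
    rows: list[np.ndarray] = []
    # per-SNP observed allele labels, in order of first appearance
    alleles: list[list[str]] = [[] for _ in range(n_snps)]
    raw: list[tuple[int, list[str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} columns "
                    f"for {n_snps} SNPs, got {len(parts)}"
                )
            subjects.append(SubjectInfo(subject_id=parts[1]))
            calls = parts[6:]
            raw.append((lineno, calls))
            for m in range(n_snps):
                for a in calls[2 * m : 2 * m + 2]:
                    if a != "0" and a not in alleles[m]:
                        alleles[m].append(a)
                        if len(alleles[m]) > 2:
                            raise ValueError(
                                f"{ped_path}:{lineno}: SNP {snps[m].snp_id} has more "
                                f"than two alleles: {alleles[m]}"
                            )

    for m, s in enumerate(snps):
        obs = alleles[m]
        s.allele_a = obs[0] if len(obs) > 0 else "A"
        s.allele_b = obs[1] if len(obs) > 1 else "B"

    for lineno, calls in raw:
        row = np.empty(n_snps, dtype=np.int8)
        for m in range(n_snps):
            a1, a2 = calls[2 * m], calls[2 * m + 1]
            if a1 == "0" or a2 == "0":
                row[m] = MISSING
            else:
                row[m] = (a1 == snps[m].allele_a) + (a2 == snps[m].allele_a)
        rows.append(row)

    g = np.vstack(rows) if rows else np.empty((0, n_snps), dtype=np.int8)
    order = sorted(range(n_snps), key=lambda i: (snps[i].chromosome, snps[i].physical_pos))
    if order != list(range(n_snps)):
        g = g[:, order]
        snps = [snps[i] for i in order]
    return GenotypeTable(g, snps, subjects)


def write_plink(data: GenotypeTable, ped_path, map_path) -> None:
    """Write PLINK text files in the canonical form :func:`read_plink` accepts.

    Genetic positions are written to full precision (%.17g); unknown cM is 0.
    ``read_plink(write_plink(t))`` reproduces ``t`` and the byte content is a
    fixed point of read-then-write.
    """
    with open(map_path, "w") as fh:
        for s in data.snps:
            cm = 0.0 if s.genetic_pos is None else s.genetic_pos
            fh.write(f"{s.chromosome} {s.snp_id} {cm:.17g} {s.physical_pos}\n")
    with open(ped_path, "w") as fh:
        for i, sub in enumerate(data.subjects):
            fields = [sub.subject_id, sub.subject_id, "0", "0", "0", "-9"]
            for m, s in enumerate(data.snps):
                g = data.genotypes[i, m]
                if g == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [s.allele_a] * int(g) + [s.allele_b] * int(2 - g)
            fh.write(" ".join(fields) + "\n")


# -- VCF -----------------------------------------------------------------------


def read_vcf(path) -> GenotypeTable:
    """Read biallelic SNP records from a VCF into a :class:`GenotypeTable`.

    ``allele_a`` is REF, so a 0/0 call codes as genotype 2.  Phase is ignored;
    half-missing and fully missing calls both code as missing.  Multi-allelic
    or non-SNP records are skipped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = [SubjectInfo(subject_id=s) for s in vcf.samples]
    snps: list[SnpInfo] = []
    cols: list[np.ndarray] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        chrom = var.CHROM.removeprefix("chr")
        try:
            chrom_i = int(chrom)
        except ValueError:
            skipped += 1
            continue
        if chrom_i not in AUTOSOMES:
            skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        col = np.select(
            [gt == 0, gt == 1, gt == 3], [2, 1, 0], default=MISSING
        ).astype(np.int8)
        snps.append(
            SnpInfo(
                snp_id=var.ID or f"{chrom_i}:{var.POS}",
                chromosome=chrom_i,
                physical_pos=var.POS,
                allele_a=var.REF,
                allele_b=var.ALT[0],
            )
        )
        cols.append(col)
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-autosomal records", skipped)
    g = np.column_stack(cols) if cols else np.empty((len(subjects), 0), dtype=np.int8)
    order = sorted(range(len(snps)), key=lambda i: (snps[i].chromosome, snps[i].physical_pos))
    if order != list(range(len(snps))):
        g = g[:, order]
        snps = [snps[i] for i in order]
    return GenotypeTable(g, snps, subjects)


# -- subject metadata ----------------------------------------------------------


def read_subjects_tsv(path, reference_col: str = "is_reference") -> list[SubjectInfo]:
    """Read a subject table (TSV with header) carrying at least ``subject_id``
    and a boolean/0-1 reference-pool column."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in df.columns or reference_col not in df.columns:
        raise ValueError(
            f"{path}: need columns 'subject_id' and {reference_col!r}, got {list(df.columns)}"
        )
    truthy = {"1", "true", "yes"}
    return [
        SubjectInfo(
            subject_id=row["subject_id"],
            is_reference=str(row[reference_col]).strip().lower() in truthy,
        )
        for _, row in df.iterrows()
    ]


def attach_subjects(data: GenotypeTable, subjects: list[SubjectInfo]) -> GenotypeTable:
    """Replace subject metadata by id, preserving genotype row order."""
    by_id = {s.subject_id: s for s in subjects}
    missing = [s.subject_id for s in data.subjects if s.subject_id not in by_id]
    if missing:
        raise ValueError(f"subject table lacks entries for: {missing[:5]}")
    new = [by_id[s.subject_id] for s in data.subjects]
    return GenotypeTable(data.genotypes.copy(), [replace(s) for s in data.snps], new)
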