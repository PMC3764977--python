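"""Bias-corrected method-of-moments estimation of pairwise IBD coefficients.

For a pair of diploid individuals, let Z be the number of alleles shared
identical by descent at a locus (0, 1 or 2 genome-wide proportions
k0 = P(Z=0), k1 = P(Z=1), k2 = P(Z=2)) and I the observed identity-by-state
count.  The marginal IBS probability at SNP m decomposes as

    P_m(I = i) = sum_z P_m(I = i | Z = z) P(Z = z),

where the conditional probabilities depend only on the SNP's allele
frequencies and so apply to every pair.  Summing over SNPs and solving the
three moment identities sequentially yields the estimators

    k0 = N(I=0) / N(I=0|Z=0)
    k1 = [N(I=1) - k0 N(I=1|Z=0)] / N(I=1|Z=1)
    k2 = [N(I=2) - k0 N(I=2|Z=0) - k1 N(I=2|Z=1)] / N(I=2|Z=2),

with N(I=i) the observed count of SNPs at IBS state i and N(I=i|Z=z) the sum
of per-SNP conditional probabilities over the same SNPs.  The estimates sum
to 1 by construction and are deliberately not clamped to [0, 1].

The conditional probabilities are estimated without bias by treating the T
reference-pool alleles as draws without replacement: e.g. with X copies of
allele A and Y of allele a,

    P(I=0|Z=0) = 2 X(X-1) Y(Y-1) / [T(T-1)(T-2)(T-3)],

the fraction of ordered four-allele draws that form opposite homozygotes.
The naive plug-in forms (e.g. 2 p^2 q^2 with p = X/T) are biased at finite T;
the count forms used here are exactly unbiased under binomial sampling of X.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .genotype_data import MISSING, AlleleCounts, GenotypeTable, allele_counts_all

#: genotype pairs sharing 0 alleles IBS: opposite homozygotes
_IBS_LOOKUP = np.array(
    [
        [2, 1, 0],
        [1, 2, 1],
        [0, 1, 2],
    ],
    dtype=np.int8,
)


def ibs_state(g1: int, g2: int) -> Optional[int]:
    """IBS count for one genotype pair, or None if either is missing.

    Opposite homozygotes (2, 0) share no alleles; identical genotypes share
    two; every other combination shares one.
    """
    if g1 == MISSING or g2 == MISSING:
        return None
    return int(_IBS_LOOKUP[g1, g2])


@dataclass
class CondIBSTable:
    """Per-SNP conditional IBS probabilities P(I = i | Z = z).

    ``probs`` has shape (3, 3, n_snps) indexed [i, z, m].  Structural zeros
    (sharing z alleles IBD forces at least z IBS) and P(I=2|Z=2)=1 are filled.
    ``usable`` marks SNPs with T >= 4 reference alleles; only those enter any
    pair's sums, keeping numerator and denominator SNP sets identical.
    """

    probs: np.ndarray
    usable: np.ndarray
    X: np.ndarray
    T: np.ndarray

    @property
    def n_snps(self) -> int:
        return self.probs.shape[2]


def _cond_probs_from_counts(X: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Count-form unbiased conditional IBS probabilities, shape (3, 3, L).

    Entries for SNPs with T < 4 are meaningless (guarded by the caller's
    ``usable`` mask); the denominators are made safe here.
    """
    X = np.asarray(X, dtype=np.float64)
    T = np.asarray(T, dtype=np.float64)
    Y = T - X
    d4 = T * (T - 1) * (T - 2) * (T - 3)
    d3 = T * (T - 1) * (T - 2)
    d4 = np.where(d4 > 0, d4, np.inf)
    d3 = np.where(d3 > 0, d3, np.inf)

    p = np.zeros((3, 3) + X.shape)
    # Z = 0: two independent allele pairs, four draws without replacement
    p[0, 0] = 2 * X * (X - 1) * Y * (Y - 1) / d4
    p[1, 0] = (4 * X * (X - 1) * (X - 2) * Y + 4 * X * Y * (Y - 1) * (Y - 2)) / d4
    p[2, 0] = (
        X * (X - 1) * (X - 2) * (X - 3)
        + Y * (Y - 1) * (Y - 2) * (Y - 3)
        + 4 * X * (X - 1) * Y * (Y - 1)
    ) / d4
    # Z = 1: one shared allele plus one free allele each, three draws
    p[1, 1] = (2 * X * (X - 1) * Y + 2 * X * Y * (Y - 1)) / d3
    p[2, 1] = (
        X * (X - 1) * (X - 2)
        + Y * (Y - 1) * (Y - 2)
        + X * Y * (Y - 1)
        + Y * X * (X - 1)
    ) / d3
    # Z = 2: genotypes identical with certainty
    p[2, 2] = 1.0
    return p


def cond_ibs_unbiased(counts: AlleleCounts) -> np.ndarray:
    """3x3 matrix [i, z] of unbiased conditional IBS probabilities at one SNP.

    Requires T >= 4 (four distinct allele draws must be possible).
    """
    if counts.T < 4:
        raise ValueError(f"T={counts.T} < 4: conditional IBS estimators undefined")
    return _cond_probs_from_counts(
        np.array([counts.X]), np.array([counts.T])
    )[:, :, 0]


def cond_ibs_table(data: GenotypeTable) -> CondIBSTable:
    """Conditional IBS probabilities for every SNP, from the reference pool.

    Computed once and reused for every study or simulated pair.
    """
    X, T = allele_counts_all(data)
    usable = T >= 4
    probs = _cond_probs_from_counts(X, T)
    return CondIBSTable(probs=probs, usable=usable, X=X, T=T)


@dataclass
class PairIBSSummary:
    """Observed and expected IBS counts for one pair over its L usable SNPs."""

    n_ibs: np.ndarray  # shape (3,): observed SNP counts at IBS 0, 1, 2
    n_cond: np.ndarray  # shape (3, 3): [i, z] sums of conditional probabilities
    L: int


@dataclass
class IBDEstimate:
    """Estimated IBD coefficients for one pair.  k0+k1+k2 = 1 when estimable;
    individual values may fall outside [0, 1] (not clamped)."""

    subject1: str
    subject2: str
    k0: float
    k1: float
    k2: float
    L: int
    status: str = "ok"


def pair_ibs_summary(
    g1: np.ndarray, g2: np.ndarray, tables: CondIBSTable
) -> PairIBSSummary:
    """IBS summary for one pair of genotype vectors aligned to the SNP list.

    Only SNPs usable in ``tables`` (T >= 4) and non-missing in both subjects
    contribute.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    use = (g1 != MISSING) & (g2 != MISSING) & tables.usable
    L = int(use.sum())
    ibs = _IBS_LOOKUP[g1[use], g2[use]]
    n_ibs = np.bincount(ibs, minlength=3).astype(np.float64)
    n_cond = tables.probs[:, :, use].sum(axis=2)
    return PairIBSSummary(n_ibs=n_ibs, n_cond=n_cond, L=L)


def estimate_pair_ibd(
    summary: PairIBSSummary, subject1: str = "", subject2: str = ""
) -> IBDEstimate:
    """Solve the moment identities sequentially for one pair."""
    if summary.L == 0:
        return IBDEstimate(subject1, subject2, np.nan, np.nan, np.nan, 0, "no_usable_snps")
    n = summary.n_ibs
    c = summary.n_cond
    if c[0, 0] <= 0:
        return IBDEstimate(
            subject1, subject2, np.nan, np.nan, np.nan, summary.L, "zero_N00"
        )
    if c[1, 1] <= 0:
        return IBDEstimate(
            subject1, subject2, np.nan, np.nan, np.nan, summary.L, "zero_N11"
        )
    k0 = n[0] / c[0, 0]
    k1 = (n[1] - k0 * c[1, 0]) / c[1, 1]
    k2 = (n[2] - k0 * c[2, 0] - k1 * c[2, 1]) / c[2, 2]
    return IBDEstimate(subject1, subject2, float(k0), float(k1), float(k2), summary.L)


def _pairwise_components(G: np.ndarray, tables: CondIBSTable):
    """All-pairs IBS counts and conditional sums via indicator matrix products.

    Returns (N0, N1, N2, C, L) where N* are (n, n) observed IBS-count
    matrices, C is a dict (i, z) -> (n, n) conditional-sum matrices and L the
    (n, n) usable-SNP counts.
    """
    use_cols = tables.usable
    Gs = G[:, use_cols].astype(np.float64)
    H = [(Gs == k).astype(np.float64) for k in (0, 1, 2)]
    M = (Gs != MISSING).astype(np.float64)
    N2 = sum(Hk @ Hk.T for Hk in H)
    N0 = H[0] @ H[2].T + H[2] @ H[0].T
    L = M @ M.T
    N1 = L - N0 - N2
    C = {}
    for i, z in ((0, 0), (1, 0), (2, 0), (1, 1), (2, 1)):
        w = tables.probs[i, z, use_cols]
        C[(i, z)] = (M * w) @ M.T
    C[(2, 2)] = L
    return N0, N1, N2, C, L


def estimate_all_pairs(
    data: GenotypeTable, tables: Optional[CondIBSTable] = None
) -> pd.DataFrame:
    """IBD coefficients for every unordered pair of subjects.

    Conditional tables default to the reference pool of ``data``; all
    subjects, reference or not, are paired.  Returns one row per pair with
    columns subject1, subject2, k0, k1, k2, L, status, ordered
    lexicographically by subject labels (so the result is invariant to input
    order up to row identity).
    """
    if tables is None:
        tables = cond_ibs_table(data)
    G = data.genotypes
    n = data.n_subjects
    N0, N1, N2, C, L = _pairwise_components(G, tables)

    iu, ju = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        k0 = N0[iu, ju] / C[(0, 0)][iu, ju]
        k1 = (N1[iu, ju] - k0 * C[(1, 0)][iu, ju]) / C[(1, 1)][iu, ju]
        k2 = (N2[iu, ju] - k0 * C[(2, 0)][iu, ju] - k1 * C[(2, 1)][iu, ju]) / C[(2, 2)][iu, ju]
    Lp = L[iu, ju].astype(int)
    status = np.where(
        Lp == 0,
        "no_usable_snps",
        np.where(
            C[(0, 0)][iu, ju] <= 0,
            "zero_N00",
            np.where(C[(1, 1)][iu, ju] <= 0, "zero_N11", "ok"),
        ),
    )
    bad = status != "ok"
    k0[bad] = np.nan
    k1[bad] = np.nan
    k2[bad] = np.nan

    ids = np.array(data.subject_ids)
    s1, s2 = ids[iu], ids[ju]
    swap = s1 > s2
    s1, s2 = np.where(swap, s2, s1), np.where(swap, s1, s2)
    df = pd.DataFrame(
        {
            "subject1": s1,
            "subject2": s2,
            "k0": k0,
            "k1": k1,
            "k2": k2,
            "L": Lp,
            "status": status,
        }
    )
    return df.sort_values(["subject1", "subject2"], kind="mergesort").reset_index(drop=True)


def estimate_simulated_pairs(
    G1: np.ndarray, G2: np.ndarray, tables: CondIBSTable, relationship: str = ""
) -> pd.DataFrame:
    """IBD coefficients for row-aligned simulated genotype pairs.

    ``G1`` and ``G2`` are (n_pairs, n_snps) matrices; pair j is row j of each.
    Uses the same conditional tables as the study pairs.
    """
    use = tables.usable
    g1 = G1[:, use]
    g2 = G2[:, use]
    both = (g1 != MISSING) & (g2 != MISSING)
    ibs = _IBS_LOOKUP[np.clip(g1, 0, 2), np.clip(g2, 0, 2)]
    N0 = ((ibs == 0) & both).sum(axis=1).astype(np.float64)
    N1 = ((ibs == 1) & both).sum(axis=1).astype(np.float64)
    N2 = ((ibs == 2) & both).sum(axis=1).astype(np.float64)
    B = both.astype(np.float64)
    C = {
        (i, z): B @ tables.probs[i, z, use]
        for i, z in ((0, 0), (1, 0), (2, 0), (1, 1), (2, 1))
    }
    L = both.sum(axis=1)
    C[(2, 2)] = L.astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        k0 = N0 / C[(0, 0)]
        k1 = (N1 - k0 * C[(1, 0)]) / C[(1, 1)]
        k2 = (N2 - k0 * C[(2, 0)] - k1 * C[(2, 1)]) / C[(2, 2)]
    status = np.where(
        L == 0,
        "no_usable_snps",
        np.where(C[(0, 0)] <= 0, "zero_N00", np.where(C[(1, 1)] <= 0, "zero_N11", "ok")),
    )
    bad = status != "ok"
    k0[bad] = np.nan
    k1[bad] = np.nan
    k2[bad] = np.nan
    return pd.DataFrame(
        {
            "relationship": relationship,
            "replicate": np.arange(len(L)),
            "k0": k0,
            "k1": k1,
            "k2": k2,
            "L": L.astype(int),
            "status": status,
        }
    )
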