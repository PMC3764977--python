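"""Quality-control filtering of subjects and SNPs before IBD estimation.

Subjects are filtered first (on genotype call rate over all SNPs), then SNPs
(on call rate over the remaining subjects, and on minor-allele frequency and
Hardy-Weinberg equilibrium computed in the reference pool).  The order is
fixed so a run is reproducible from its thresholds alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_data import MISSING, GenotypeTable


@dataclass
class FilterThresholds:
    """QC thresholds, all proportions/probabilities in [0, 1].

    Defaults are conventional GWAS values: retain SNPs and subjects with
    >= 90% call rate, SNPs with reference-pool MAF >= 1% and HWE exact-test
    p >= 1e-3.
    """

    snp_call_rate: float = 0.9
    subject_call_rate: float = 0.9
    maf_min: float = 0.01
    hwe_p_min: float = 0.001

    def __post_init__(self) -> None:
        for name in ("snp_call_rate", "subject_call_rate", "maf_min", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test.

    Conditional on the observed allele counts, the number of heterozygotes
    under HWE follows the distribution of Levene/Haldane; the p-value sums the
    probabilities of all heterozygote counts whose probability does not exceed
    that of the observed count.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype required")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_A, n_a)
    # attainable heterozygote counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    # P(n_Aa = h | n_A, n) = n! / (homr! h! homc!) * n_A! n_a! / (2n)! * 2^h
    logp = (
        gammaln(n + 1)
        - gammaln(homr + 1)
        - gammaln(hets + 1)
        - gammaln(homc + 1)
        + gammaln(n_A + 1)
        + gammaln(n_a + 1)
        - gammaln(2 * n + 1)
        + hets * np.log(2.0)
    )
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _empty_report() -> pd.DataFrame:
    return pd.DataFrame(columns=["item", "rule", "value", "threshold"])


def filter_subjects(
    data: GenotypeTable, th: FilterThresholds
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Drop subjects whose genotype call rate is below ``subject_call_rate``."""
    call = (data.genotypes != MISSING).mean(axis=1)
    keep = call >= th.subject_call_rate
    rows = [
        {
            "item": data.subjects[i].subject_id,
            "rule": "subject_call_rate",
            "value": call[i],
            "threshold": th.subject_call_rate,
        }
        for i in np.flatnonzero(~keep)
    ]
    if not keep.any():
        raise ValueError("subject filtering removed every subject")
    out = data.subset(subject_idx=np.flatnonzero(keep)) if rows else data
    return out, (pd.DataFrame(rows) if rows else _empty_report())


def filter_snps(
    data: GenotypeTable, th: FilterThresholds
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Drop SNPs failing call rate (all subjects), MAF or HWE (reference pool).

    A SNP failing several rules is reported once, under the first failing rule
    in the order call rate, MAF, HWE.
    """
    g = data.genotypes
    ref = data.reference_mask
    rows = []
    keep = np.ones(data.n_snps, dtype=bool)
    call = (g != MISSING).mean(axis=0)
    for m in range(data.n_snps):
        snp_id = data.snps[m].snp_id
        if call[m] < th.snp_call_rate:
            keep[m] = False
            rows.append(
                {"item": snp_id, "rule": "snp_call_rate", "value": call[m],
                 "threshold": th.snp_call_rate}
            )
            continue
        gr = g[ref, m]
        gr = gr[gr != MISSING]
        if gr.size == 0:
            keep[m] = False
            rows.append(
                {"item": snp_id, "rule": "maf", "value": np.nan, "threshold": th.maf_min}
            )
            continue
        p = gr.sum() / (2 * gr.size)
        maf = min(p, 1 - p)
        if maf < th.maf_min:
            keep[m] = False
            rows.append(
                {"item": snp_id, "rule": "maf", "value": maf, "threshold": th.maf_min}
            )
            continue
        n_AA = int((gr == 2).sum())
        n_Aa = int((gr == 1).sum())
        n_aa = int((gr == 0).sum())
        p_hwe = hwe_exact_test(n_AA, n_Aa, n_aa)
        if p_hwe < th.hwe_p_min:
            keep[m] = False
            rows.append(
                {"item": snp_id, "rule": "hwe", "value": p_hwe, "threshold": th.hwe_p_min}
            )
    if not keep.any():
        raise ValueError("SNP filtering removed every SNP")
    out = data.subset(snp_idx=np.flatnonzero(keep)) if rows else data
    return out, (pd.DataFrame(rows) if rows else _empty_report())


def apply_qc(
    data: GenotypeTable, th: FilterThresholds | None = None, enabled: bool = True
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Run the full QC pass (subjects first, then SNPs); ``enabled=False``
    bypasses filtering entirely, e.g. for data already filtered upstream."""
    if not enabled:
        return data, _empty_report()
    th = th or FilterThresholds()
    data, rep_sub = filter_subjects(data, th)
    data, rep_snp = filter_snps(data, th)
    parts = [df for df in (rep_sub, rep_snp) if len(df)]
    report = pd.concat(parts, ignore_index=True) if parts else _empty_report()
    return data, report
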