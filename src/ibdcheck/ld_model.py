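"""Per-chromosome haplotype-frequency models capturing linkage disequilibrium.

Founder haplotypes for gene-drop simulation must reflect the LD of the study
markers: simulating SNPs independently understates the variance of the IBD
estimators and yields reference clusters that are too tight.  Here LD is
captured by a first-order inhomogeneous Markov chain over alleles along each
chromosome: an initial allele frequency at the first SNP and, for each
adjacent SNP pair, a 2x2 transition matrix P(allele at m | allele at m-1).

Each transition matrix is fitted by the classic two-locus
expectation-maximization over the unobserved phase of adjacent-SNP genotype
pairs (only double heterozygotes are phase-ambiguous), using reference-pool
subjects.  An independence variant (transitions equal to marginal allele
frequencies) is available for comparison; its clusters demonstrably
understate variability on LD data.

Haplotype alleles are coded 0/1 with 1 = ``allele_a`` (the allele counted by
the genotype coding), so a genotype is the sum of its two haplotype entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genotype_data import MISSING, GenotypeTable

logger = logging.getLogger(__name__)

EM_TOL = 1e-6
EM_MAX_ITER = 500


@dataclass
class HaplotypeModel:
    """Markov haplotype-frequency model for one chromosome.

    ``p0`` is the frequency of allele 1 (= allele A) at the first SNP;
    ``transitions[m-1, a, b]`` is P(allele b at SNP m | allele a at SNP m-1)
    for m = 1..M-1.  ``model_kind`` records whether transitions were fitted
    by EM ("markov_ld") or set to marginals ("independence").
    """

    chromosome: int
    snp_ids: list[str]
    p0: float
    transitions: np.ndarray  # shape (M-1, 2, 2)
    model_kind: str = "markov_ld"

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=np.float64).reshape(
            (len(self.snp_ids) - 1, 2, 2)
        )
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"initial frequency {self.p0} outside [0, 1]")
        if self.transitions.size and not np.allclose(
            self.transitions.sum(axis=2), 1.0, atol=1e-9
        ):
            raise ValueError("transition rows must sum to 1")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def marginal_freqs(self) -> np.ndarray:
        """Implied chain marginals of allele 1 at each SNP."""
        p = np.empty(self.n_snps)
        p[0] = self.p0
        for m in range(1, self.n_snps):
            t = self.transitions[m - 1]
            p[m] = (1 - p[m - 1]) * t[0, 1] + p[m - 1] * t[1, 1]
        return p


# -- fitting -------------------------------------------------------------------


def _marginal_freq(g: np.ndarray) -> float:
    obs = g != MISSING
    if not obs.any():
        raise ValueError("no observed genotypes at SNP")
    return float(g[obs].sum() / (2 * obs.sum()))


def _two_locus_em(
    g_left: np.ndarray,
    g_right: np.ndarray,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    trace_loglik: bool = False,
):
    """EM for the four haplotype frequencies of an adjacent SNP pair.

    ``h`` is indexed [left allele, right allele] with allele 1 = allele A.
    Under random mating an individual's two haplotypes are independent, so
    the genotype pair determines the haplotype multiset except for double
    heterozygotes (phase AB/ab vs Ab/aB).  Initialization is the linkage-
    equilibrium product of marginals, which makes fitting deterministic.
    """
    both = (g_left != MISSING) & (g_right != MISSING)
    gl = g_left[both].astype(np.intp)
    gr = g_right[both].astype(np.intp)
    n = gl.size
    if n == 0:
        raise ValueError("no individuals observed at both SNPs of an adjacent pair")
    counts = np.zeros((3, 3))
    np.add.at(counts, (gl, gr), 1.0)

    pl = (2 * counts[2].sum() + counts[1].sum()) / (2 * n)
    pr = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n)
    h = np.array(
        [[(1 - pl) * (1 - pr), (1 - pl) * pr], [pl * (1 - pr), pl * pr]]
    )

    # haplotype contribution of each unambiguous genotype combo:
    # genotype g contributes its alleles as (g choose haplotypes) pairs
    def loglik(h):
        ll = 0.0
        for a in range(3):
            for b in range(3):
                if counts[a, b] == 0:
                    continue
                prob = _geno_pair_prob(h, a, b)
                ll += counts[a, b] * np.log(max(prob, 1e-300))
        return ll

    trace = [loglik(h)] if trace_loglik else None
    for _ in range(max_iter):
        e = np.zeros((2, 2))
        for a in range(3):
            for b in range(3):
                c = counts[a, b]
                if c == 0:
                    continue
                if a == 1 and b == 1:
                    # double het: split between cis (00/11) and trans (01/10)
                    cis = h[0, 0] * h[1, 1]
                    trans = h[0, 1] * h[1, 0]
                    tot = cis + trans
                    w = 0.5 if tot == 0 else cis / tot
                    e[0, 0] += c * w
                    e[1, 1] += c * w
                    e[0, 1] += c * (1 - w)
                    e[1, 0] += c * (1 - w)
                else:
                    # alleles at each locus split deterministically
                    left = [1, 1] if a == 2 else ([0, 0] if a == 0 else [0, 1])
                    right = [1, 1] if b == 2 else ([0, 0] if b == 0 else [0, 1])
                    if a == 1:
                        # het left, hom right: one haplotype of each left allele
                        e[0, right[0]] += c
                        e[1, right[0]] += c
                    elif b == 1:
                        e[left[0], 0] += c
                        e[left[0], 1] += c
                    else:
                        e[left[0], right[0]] += 2 * c
        h_new = e / (2 * n)
        delta = np.abs(h_new - h).max()
        h = h_new
        if trace_loglik:
            trace.append(loglik(h))
        if delta < tol:
            break
    return (h, trace) if trace_loglik else h


def _geno_pair_prob(h: np.ndarray, a: int, b: int) -> float:
    """P(two-locus genotype (a, b)) under haplotype frequencies h and
    random mating (sum over compatible ordered haplotype pairs)."""
    prob = 0.0
    for l1 in range(2):
        for r1 in range(2):
            for l2 in range(2):
                for r2 in range(2):
                    if l1 + l2 == a and r1 + r2 == b:
                        prob += h[l1, r1] * h[l2, r2]
    return prob


def _transition_from_h(h: np.ndarray, fallback_pr: float) -> np.ndarray:
    """Row-normalised P(right allele | left allele); rows with zero marginal
    fall back to the right-SNP marginal (they are never visited anyway)."""
    t = np.empty((2, 2))
    for a in range(2):
        row_sum = h[a, 0] + h[a, 1]
        if row_sum > 0:
            t[a] = h[a] / row_sum
        else:
            t[a] = [1 - fallback_pr, fallback_pr]
    return t


def fit_markov_model(data: GenotypeTable, chromosome: int) -> HaplotypeModel:
    """Fit the Markov LD model for one chromosome from reference-pool data."""
    idx = data.snp_indices(chromosome)
    if idx.size == 0:
        raise ValueError(f"no SNPs on chromosome {chromosome}")
    g = data.genotypes[data.reference_mask, :][:, idx]
    snp_ids = [data.snps[i].snp_id for i in idx]
    p0 = _marginal_freq(g[:, 0])
    transitions = np.empty((len(idx) - 1, 2, 2))
    for m in range(1, len(idx)):
        h = _two_locus_em(g[:, m - 1], g[:, m])
        pr = _marginal_freq(g[:, m])
        transitions[m - 1] = _transition_from_h(h, pr)
    return HaplotypeModel(chromosome, snp_ids, p0, transitions, "markov_ld")


def fit_independence_model(data: GenotypeTable, chromosome: int) -> HaplotypeModel:
    """Model with no LD: every transition row equals the marginal frequency."""
    idx = data.snp_indices(chromosome)
    if idx.size == 0:
        raise ValueError(f"no SNPs on chromosome {chromosome}")
    g = data.genotypes[data.reference_mask, :][:, idx]
    snp_ids = [data.snps[i].snp_id for i in idx]
    freqs = [_marginal_freq(g[:, m]) for m in range(len(idx))]
    transitions = np.empty((len(idx) - 1, 2, 2))
    for m in range(1, len(idx)):
        transitions[m - 1] = [[1 - freqs[m], freqs[m]], [1 - freqs[m], freqs[m]]]
    return HaplotypeModel(chromosome, snp_ids, freqs[0], transitions, "independence")


def fit_models(
    data: GenotypeTable, fit_ld: bool = True
) -> dict[int, HaplotypeModel]:
    """Fit one model per chromosome present in the data."""
    fit = fit_markov_model if fit_ld else fit_independence_model
    return {c: fit(data, c) for c in data.chromosomes}


# -- sampling ------------------------------------------------------------------


def sample_haplotypes(
    model: HaplotypeModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n haplotypes (n, M) of 0/1 alleles from the chain."""
    M = model.n_snps
    out = np.empty((n, M), dtype=np.int8)
    out[:, 0] = rng.random(n) < model.p0
    for m in range(1, M):
        t = model.transitions[m - 1]
        p_one = np.where(out[:, m - 1] == 1, t[1, 1], t[0, 1])
        out[:, m] = rng.random(n) < p_one
    return out


def sample_haplotype(model: HaplotypeModel, rng: np.random.Generator) -> np.ndarray:
    """Draw a single haplotype; reproducible under a fixed generator state."""
    return sample_haplotypes(model, 1, rng)[0]


# -- serialization -------------------------------------------------------------


def _model_filename(chromosome: int) -> str:
    return f"ld_model_chr{chromosome}.txt"


def save_models(models: dict[int, HaplotypeModel], directory) -> list[str]:
    """Write one plain-text file per chromosome; returns the file paths.

    Format: a header line ``chromosome <c> n_snps <M> model_kind <kind>``,
    then one tab-separated line per SNP: snp_id, implied marginal frequency,
    and the four transition entries from the previous SNP in previous-allele-
    major order t[0,0] t[0,1] t[1,0] t[1,1] (the first SNP repeats its
    marginal).  Floats carry 17 significant digits so reloading is bit-exact.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for c in sorted(models):
        m = models[c]
        path = directory / _model_filename(c)
        marg = m.marginal_freqs()
        with open(path, "w") as fh:
            fh.write(f"chromosome\t{c}\tn_snps\t{m.n_snps}\tmodel_kind\t{m.model_kind}\n")
            for j, sid in enumerate(m.snp_ids):
                if j == 0:
                    row = [1 - m.p0, m.p0, 1 - m.p0, m.p0]
                else:
                    row = m.transitions[j - 1].ravel()
                vals = "\t".join(f"{v:.17g}" for v in row)
                fh.write(f"{sid}\t{marg[j]:.17g}\t{vals}\n")
        paths.append(str(path))
    return paths


def load_models(paths) -> dict[int, HaplotypeModel]:
    """Reload models written by :func:`save_models`."""
    models: dict[int, HaplotypeModel] = {}
    for path in paths:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            try:
                chrom = int(header[1])
                n_snps = int(header[3])
                kind = header[5]
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:1: malformed header: {exc}") from exc
            snp_ids = []
            p0 = None
            transitions = np.empty((n_snps - 1, 2, 2))
            for lineno, line in enumerate(fh, 2):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 6:
                    raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
                j = lineno - 2
                snp_ids.append(parts[0])
                try:
                    vals = [float(v) for v in parts[1:]]
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad float: {exc}") from exc
                if j == 0:
                    p0 = vals[4]  # t[1,1] column of the repeated-marginal row
                else:
                    transitions[j - 1] = np.array(vals[1:]).reshape(2, 2)
            if len(snp_ids) != n_snps:
                raise ValueError(
                    f"{path}: header says {n_snps} SNPs, found {len(snp_ids)}"
                )
        models[chrom] = HaplotypeModel(chrom, snp_ids, p0, transitions, kind)
    return models
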