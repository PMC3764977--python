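# Methods

`ibdcheck` diagnoses cryptic relatedness — undocumented close relationships —
in a nominally unrelated, homogeneous sample of SNP-genotyped subjects. It is
aimed at candidate-gene association studies, where markers cluster inside a
modest number of genes and are therefore in linkage disequilibrium (LD), so
thinning to an independent marker subset is not an option and the sampling
variability of relatedness estimators cannot be ignored.

## IBD coefficient estimation

For a pair of diploid individuals, let `Z` denote the number of alleles shared
identical by descent (IBD) at a locus and `I` the observed identity-by-state
(IBS) count. The genome-wide proportions `k0 = P(Z=0)`, `k1 = P(Z=1)`,
`k2 = P(Z=2)` summarize the pair's relatedness. At SNP m the marginal IBS
probability decomposes as

    P_m(I = i) = Σ_z P_m(I = i | Z = z) · P(Z = z),

where the conditional probabilities depend only on the SNP's allele
frequencies, hence apply to every pair. Summing over the L SNPs typed in both
members and substituting the observed IBS counts `N(I=i)` for
`Σ_m P_m(I=i)` gives three moment equations solved sequentially:

    k0 = N(I=0) / N(I=0|Z=0)
    k1 = [N(I=1) − k0·N(I=1|Z=0)] / N(I=1|Z=1)
    k2 = [N(I=2) − k0·N(I=2|Z=0) − k1·N(I=2|Z=1)] / N(I=2|Z=2)

with `N(I=i|Z=z)` the sums of per-SNP conditional probabilities over the same
L SNPs. The estimates sum to one by construction. They are *not* clamped to
[0, 1]: out-of-range values are informative scatter and truncating them would
distort the reference clusters.

**Bias-corrected conditional probabilities.** The naive plug-in estimators
(e.g. `2p̂²q̂²` for `P(I=0|Z=0)` with `p̂ = X/T`) are biased at finite
reference-pool size. We instead treat the `T` observed reference-pool alleles
(X copies of A, Y of a) as draws *without replacement* and count draw
configurations, e.g.

    P̂(I=0|Z=0) = 2·X(X−1)·Y(Y−1) / [T(T−1)(T−2)(T−3)],

the fraction of ordered four-allele draws forming opposite homozygotes; the
`Z=1` entries use three-allele draws with the first allele shared. These count
forms are algebraically equal to "plug-in × correction factor" expressions
but avoid 0/0 when X or Y is 0, and they are *exactly* unbiased under binomial
sampling of X (a factorial-moment identity; the test suite verifies this by
weighted enumeration over all outcomes of X, with no sampling). SNPs with
`T < 4` are excluded from both the observed and the conditional sums, keeping
numerator and denominator SNP sets identical.

The conditional tables are computed once from the reference pool — the
subjects flagged `is_reference`, typically the controls of a case-control
study, regarded as a population random sample — and reused for every study
and simulated pair. All subjects, reference or not, are paired.

## Reference clusters by gene drop

Rather than deriving the joint distribution of (k̂0, k̂1) under LD, the
package *simulates* it: for each candidate relationship a minimal pedigree
(target pair first) receives founder haplotypes drawn from a fitted haplotype
model, alleles are dropped through the pedigree by Mendelian segregation, and
the simulated pair is estimated with the same conditional tables as the study
pairs. Built-in relationships: unrelated, monozygotic twin/duplicate,
parent-offspring, full siblings, half siblings and first cousins; the default
simulated set excludes cousins, which candidate-gene panels rarely separate
from unrelated pairs. Arbitrary user pedigrees, including inbred ones, are
accepted.

Meioses place crossovers as a Poisson process on the genetic map (Haldane
model, no chiasma interference), the standard minimal recombination model;
chromosomes segregate independently. Genetic positions missing from the input
are inferred at a constant 1 cM/Mb (overridable), a deliberate simplification
of genome-build lookup tables; users with non-human diploid data supply their
own map. The duplicate relationship copies one simulated genome and then
applies missingness independently to each copy; likewise every simulated
individual is masked with the missingness pattern of one uniformly drawn
study subject (one pattern per individual, not per pair), so simulated pairs
face the same data loss as study pairs.

## The LD model

Founder haplotypes must reflect the LD of the study markers: simulating SNPs
independently understates estimator variance and produces reference clusters
that are too tight, which manifests as spurious flags. LD is modeled by a
first-order inhomogeneous Markov chain over alleles along each chromosome: an
initial allele frequency plus a 2×2 transition matrix per adjacent SNP pair.
Each transition matrix is fitted by the classic two-locus EM over the
unobserved phase of adjacent-SNP genotypes (only double heterozygotes are
ambiguous), initialized at linkage equilibrium so fitting is deterministic;
convergence at max parameter change < 1e-6 or 500 iterations. A Markov chain
captures only adjacent-pair LD — it is the simplest samplable model meeting
the founder-sampling contract, not a full graphical haplotype model — and the
`model_kind` field records which model produced any given file. An
independence variant (transitions equal to marginals) exists chiefly to
demonstrate what ignoring LD does.

Fitted models are stored as one plain-text TSV per chromosome (floats at 17
significant digits, so reloading is bit-exact) and can be reused across runs,
skipping the fitting stage.

## Prediction ellipses and flagging

Each simulated relationship cluster is summarized by its sample mean and
covariance in the (k0, k1) plane; the coverage-level prediction ellipse is
the set of points whose squared Mahalanobis distance does not exceed the
chi-square(2 df) quantile at that level (boundary inclusive). A ridge of
1e-10 on the covariance diagonal handles degenerate clusters (e.g. duplicates
with complete data). The default coverage is 0.95; the *unrelated* ellipse
alone is Bonferroni-adjusted to `1 − (1 − coverage)/n_pairs`, since nearly
all study pairs are unrelated. A study pair is auto-flagged for a
relationship when it lies inside that relationship's ellipse and outside the
unrelated ellipse. A coordinate/pair query facility reports ellipse
memberships for any point, the scriptable replacement for interactive point
picking. The bivariate-normal approximation is slightly light-tailed relative
to the actual estimator distribution, so empirical coverage a little below
the nominal level is expected and a few genuinely unrelated pairs will sit
just outside their ellipse.

## Quality control

Subjects are filtered first (call rate ≥ 0.9 over all SNPs), then SNPs (call
rate ≥ 0.9, reference-pool MAF ≥ 0.01, reference-pool Hardy–Weinberg exact
test p ≥ 1e-3). These are conventional GWAS values chosen as explicit,
overridable defaults; HWE and MAF use the reference pool to avoid
case-enrichment artifacts. The HWE test is the exact conditional
(Levene–Haldane) test, summing probabilities of heterozygote counts no more
likely than the observed one. QC can be bypassed entirely for pre-filtered
data.

## Synthetic studies

The fixture generator emulates a candidate-gene case-control panel: SNPs in
6-SNP gene-like clusters spread round-robin over up to 22 autosomes (2 kb
within genes, 3 Mb between), one allele frequency per gene drawn
U(0.1, 0.9), and within-gene LD from a copy-probability Markov chain
(`ld_strength` = probability an allele copies its left neighbour; 0.6 by
default, "moderate"). Unrelated subjects get two independent haplotypes;
planted related pairs are produced by gene drop from the same truth model, so
planted signal is genuine IBD sharing. Missingness is independent per call
(1% default). Defaults mirror the scale of a published candidate-gene panel:
208 subjects (108 reference), 1250 SNPs in ~209 genes. What the generator
does **not** emulate: real MAF spectra, long-range or between-gene LD,
population structure/admixture, genotyping error, and informative (platform-
or DNA-quality-driven) missingness — so green tests support correctness of
the machinery under the stated model, not robustness to those real-data
features.

A separate panel helper produces *effectively independent* SNPs (50 cM
spacing across 20 autosomes, MAF U(0.05, 0.5)); in that idealized setting
the estimators' means are known in closed form and the suite checks recovery
of (k0, k1) for all six relationships to ±0.03.

## Numerical and design choices

- Conditional tables are computed in exact integer-count form; row sums equal
  1 to ≈1e-16 and `k0+k1+k2 = 1` is an algebraic identity of the solver.
- All-pairs estimation is vectorized as indicator-matrix products
  (`O(n²·L)` in matrix ops), so thousands of subjects are feasible.
- One `numpy` Generator is threaded through founder sampling, meiosis and
  missingness; every run is reproducible from its seed, and equal seeds plus
  reused LD files reproduce simulated estimates exactly.
- Pairs with zero usable SNPs or zero denominators are reported with a status
  rather than dropped silently.
- Problem sizes in the test suite (e.g. 120–208 subjects, 600–1250 SNPs,
  200 simulated pairs per relationship, 5-seed comparisons) were chosen as
  the smallest studies at which the statistical contrasts of interest are
  unambiguous.

## Known limitations

- The Markov LD model ignores LD beyond adjacent pairs; clusters under very
  block-like LD will be slightly narrower than under a full haplotype model.
- Half siblings, avuncular and grandparent-grandchild pairs share the same
  expected (k0, k1) = (0.5, 0.5) and are indistinguishable here; with
  candidate-gene panels the half-sib and unrelated ellipses overlap
  substantially, so half-sib flags warrant manual review.
- A ~5% tail of genuinely related pairs falls outside their own 95% ellipse
  by construction; detection claims should be read per-study, not per-pair.
- Autosomes 1–22 only; no sex chromosomes, dosages, or binary PLINK input.
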