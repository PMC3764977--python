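# ibdcheck

Diagnose **cryptic relatedness** — undocumented close relationships — among
nominally unrelated subjects of a SNP association study, with full support
for markers in linkage disequilibrium (LD).

Standard association tests assume independent subjects; an unnoticed
parent-offspring or sibling pair inflates test statistics. `ibdcheck`
estimates, for every pair of subjects, the proportions of the genome at
which they share 0, 1 or 2 alleles identical by descent,

    (k0, k1, k2) = (P(Z=0), P(Z=1), P(Z=2)),

by a bias-corrected method of moments: observed identity-by-state (IBS)
counts are equated to their expectations, decomposed over IBD states, using
conditional IBS probabilities estimated *without bias* from reference-pool
allele counts (draws without replacement from the pool of T observed
alleles, e.g. `P̂(I=0|Z=0) = 2X(X−1)Y(Y−1)/[T(T−1)(T−2)(T−3)]`).

Because the sampling distribution of (k̂0, k̂1) is intractable when markers
are in LD — the situation in candidate-gene studies, where SNPs cluster
inside genes — reference distributions are obtained by **simulation**: a
Markov haplotype model capturing LD is fitted to the reference pool, founder
haplotypes are drawn from it, and pairs of known relationship (duplicates/MZ
twins, parent-offspring, full sibs, half sibs, first cousins, or any custom
pedigree) are generated by gene drop with Haldane recombination. Each
relationship cluster is summarized by a bivariate-normal **prediction
ellipse**; study pairs inside a relationship's 95% ellipse and outside the
(Bonferroni-adjusted) unrelated ellipse are flagged automatically.

Expected cluster centres: unrelated (1, 0), parent-offspring (0, 1), full
sibs (0.25, 0.5), half sibs (0.5, 0.5), first cousins (0.75, 0.25),
duplicates (0, 0).

## Worked example

Generate a synthetic 80-subject candidate-gene study (600 SNPs in gene-like
LD clusters on 12 autosomes) with one planted parent-offspring and one
planted full-sib pair, then run the full check:

```sh
ibdcheck simulate-fixture --n-subjects 80 --n-snps 600 --n-chromosomes 12 \
    --parent-offspring 1 --full-sibs 1 --seed 3 --out fixture
ibdcheck run --ped fixture/study.ped --map fixture/study.map \
    --subjects fixture/subjects.tsv --simulate --seed 3 --out results
```

which prints

```
3160 study pairs estimated
2 pairs auto-flagged
```

and `results/flagged_pairs.tsv` contains exactly the two planted pairs:

```
subject1  subject2  relationship      mode       k0                  k1
sub77     sub78     full.sibs         automatic  0.5799803139433914  0.11532736916048897
sub79     sub80     parent.offspring  automatic  0.0                 1.0843879144610393
```

The parent-offspring pair sits at (k0, k1) ≈ (0, 1.08): k0 is exactly 0
(parent and child always share an allele, so no opposite homozygotes occur)
and k1 scatters around 1 — estimates are deliberately not clamped to [0, 1].
The full-sib pair is an atypical realization of its cluster but still falls
inside the full-sib ellipse and outside the unrelated one. `results/` also
holds per-pair estimates, simulated cluster estimates, ellipse parameters,
one overview plot and one windowed plot per relationship, and the fitted LD
model files (`results/ld_models/`, one text file per chromosome, reusable
via `--ld-files` to skip the fitting stage).

Membership of any pair can be queried explicitly (the scriptable
replacement for clicking points on an interactive plot):

```
$ ibdcheck query-pair --run-dir results --pair sub77,sub78
subject1 subject2     relationship  mode      k0       k1  inside
   sub77    sub78        unrelated query 0.57998 0.115327   False
   ...
   sub77    sub78        full.sibs query 0.57998 0.115327    True
```

The same pipeline is available as a library: `ibdcheck.run_ibdcheck(config)`
or `ibdcheck.check_table(genotype_table, config)`; see `docs/methods.md` for
the model details and design choices.

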