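# ldabf

Detection of balancing selection from phased haplotypes.

Balanced polymorphisms — heterozygote advantage at loci like the HLA genes —
keep alleles segregating for so long that the surrounding sequence becomes
unusually dense in variants held in strong linkage disequilibrium (LD). This
package scores that footprint with **LD-ABF**, a windowed penalized-Bayesian
LD statistic, for population geneticists scanning phased diploid VCFs, and
ships everything needed around it: the comparator statistics Tajima's *D*
and *D*<sub>ng</sub>, family-based variant QC, greedy peak calling with
exclusion neighborhoods, and a forward-time Wright–Fisher simulator with
overdominance for power benchmarking.

## The statistic

For a test SNP *x* and each neighboring variant *y* within a centered window
of width *W* (default 1 kb), fit the logistic model
P(y=1 | x) = logit⁻¹(β₀ + β₁x) at its posterior mode under independent
logF(*m*, *m*) priors, i.e. maximize the penalized log-likelihood

&nbsp;&nbsp;&nbsp;&nbsp;ℓ(β) + Σ_c [ (m/2)β_c − m·log(1 + e^{β_c}) ]

(the mode is computed by data augmentation: m pseudo-trials with m/2
successes per penalized coefficient, then Newton iteration; m = 1, the
default, is Jeffreys' prior in the one-parameter model and keeps every fit
finite under perfect LD). The evidence for each neighbor is a log
approximate Bayes factor — the penalized objective of the slope model minus
that of the intercept-only model, each at its mode — and the site's score is

&nbsp;&nbsp;&nbsp;&nbsp;LD-ABF = (1/W) Σ_j log BF_j

over segregating neighbors within ±W/2 bp. Monomorphic positions contribute
log 1 = 0, so the score rises with both polymorphism density and LD
strength. See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Score a small phased VCF and inspect one SNP pair:

```sh
$ ldabf scan --vcf toy.vcf --stat ld_abf,d_ng --min-maf 0 --out scores.tsv
wrote 6 rows (3 sites) to scores.tsv

$ cat scores.tsv
chrom   pos     stat    value                   n_neighbors
1       1000    ld_abf  0.0006859706119338451   2
1       1000    d_ng    1.1111111111111112      2
1       1200    ld_abf  0.0006859706119338451   2
1       1200    d_ng    1.1111111111111112      2
1       1400    ld_abf  -0.001013309951271248   2
1       1400    d_ng    0.2222222222222222      2
```

The sites at 1000 and 1200 carry identical haplotype columns (perfect LD)
and score highest; the site at 1400 is only weakly linked to either. The
`pair` command exposes the underlying fits — here the perfectly linked pair:

```sh
$ ldabf pair --vcf toy.vcf --pos-x 1000 --pos-y 1200
M1: beta0 = -1.168861, beta1 = 2.908062, objective = -3.659405 (5 iterations)
M0: beta0 = 0.000000, objective = -4.852030
log-ABF = 1.192626
```

A positive log-ABF (1.19) says the slope model is favored even after the
prior's complexity cost: the neighbor is predictable from the test SNP.
A weakly linked pair at the same site gives log-ABF = −0.51 — evidence
*against* the slope model, near the independent-pair baseline of
−log 2 ≈ −0.69. Dividing the windowed sum by W = 1000 yields the per-site
scores in the table.

Peak calling and annotation on a genome-wide score table work the same way:

```sh
ldabf peaks --scores scores.tsv --stat ld_abf --exclusion 1000000 \
    --top 100 --annot genes.bed --out peaks.tsv
```

Simulated data for experimentation comes from the built-in simulator, which
writes phased VCFs the scan consumes unchanged:

```sh
ldabf simulate --mode balancing --h 100 --s 0.01 --rescale 50 --seed 7 \
    --out sim.vcf
```

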