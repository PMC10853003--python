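# Methods

## The statistic

Balancing selection (heterozygote advantage, frequency dependence) keeps an
allele segregating far longer than drift would, so neutral variation
accumulates on the two allelic backgrounds: the neighborhood of the balanced
site becomes unusually dense in polymorphism and unusually rich in
linkage disequilibrium (LD). LD-ABF scores exactly that footprint from
phased haplotypes.

For a test SNP with phased genotypes x ∈ {0,1} and a neighboring variant
y ∈ {0,1}, we model P(y=1 | x) = logit⁻¹(β₀ + β₁x) and place an independent
logF(m, m) prior on each coefficient. The log posterior (up to a constant)
is the penalized log-likelihood

    ℓ(β) + Σ_c [ (m/2) β_c − m log(1 + e^{β_c}) ],

whose mode is found by data augmentation: each penalized coefficient adds a
pseudo-observation of m trials with m/2 successes at a design row that is 1
for that coefficient and 0 elsewhere, after which a damped Newton iteration
on the augmented binomial likelihood converges in a handful of steps. The
augmented log-likelihood at the mode *equals* the penalized objective, which
is what the implementation reports. m = 0 recovers maximum likelihood; the
default m = 1 corresponds to Jeffreys' prior in the one-parameter model and
keeps every fit finite under complete separation (perfect LD) and sparsity
— the two situations that break an unpenalized logistic fit and that are
routine in real haplotype data.

The per-neighbor evidence is a log approximate Bayes factor: the penalized
objective of the slope model at its mode (both priors included) minus that
of the intercept-only model at its mode (intercept prior included). The
slope model carries one extra prior factor and no normalizing constant is
attached, so an exactly independent, perfectly symmetric pair contributes
−log 2 at m = 1. This "literal" form is the default; the logF normalizing
constant log B(m/2, m/2) can be added per neighbor by callers who want a
zero-centered independent case, since it is the same constant for every
neighbor it only shifts scores uniformly.

The windowed score at a test SNP is

    LD-ABF = (1/W) Σ_j log BF_j

over all segregating neighbors j within W/2 bases on either side (closed at
the boundary; W = 1000 by default). Positions with no segregating variant
contribute log 1 = 0, so the normalization is always by the full window
width: the statistic deliberately rewards polymorphism density as well as
LD strength. The test SNP is excluded from its own window by default
(self-regression is degenerate perfect LD and would add a MAF-dependent
constant); `include_self` exists for sensitivity analysis. Scores scale
with sample size — like any evidence-based statistic — so scores are only
comparable within a population of fixed size.

## Comparators

* **Tajima's D** over the same centered window: (π − S/a₁)/√(e₁S + e₂S(S−1))
  with the standard constants; π is the unbiased mean pairwise difference
  Σ 2c(n−c)/(n(n−1)). Windows with S = 0 are undefined (NaN), never zero.
* **D_ng**: Σ_j r²(x, y_j) over segregating neighbors. The squared Pearson
  correlation of binary columns is the default contribution (sign-free,
  bounded by the neighbor count); signed r and |r| are exposed as options
  because the literature leaves the choice open.

## Input handling and QC

VCF input must be phased and diploid; biallelic SNPs only, with
multiallelic records, indels and monomorphic-in-sample columns dropped and
unphased genotypes a hard error. Missing genotypes default to reference
(`missing_as_ref=True`, matching the merging convention of the array/exome
pipelines this targets); strict dropping is available. Internal coordinates
are 1-based (VCF); masks are 0-based half-open (BED) and applied to pos−1.
Allele coding is as-read; LD-ABF and D_ng are invariant to flipping a
neighbor's coding (tested exhaustively on small configurations).

The trio filters remove artifacts of paralogy and mismapping before a scan:

* **het-family**: flag when more than 95% of complete families are entirely
  heterozygous (strict inequality; a family with any missing genotype is
  excluded from the denominator).
* **transmission binomial**: among complete trios with both parents het, a
  homozygous child of a given class is expected 25% of the time; an exact
  binomial test at threshold 0.005 flags departures. The test is two-sided
  by default with hom-alt as the success class (the class sensitive to
  false het calls); hom-ref and "either homozygote" (p = 0.5) are options
  since the convention is not fixed by the procedure itself.
* **Mendel errors**: rate of impossible proband genotypes > 0.01.
* **allele flip**: alternate-allele frequency > 0.95 (ref/alt flipped
  sites; the mirror of a 5% MAF floor).

All filters are pure set-valued functions, so any application order gives
the same result. Scans additionally restrict to MAF > 0.05 (strict).

## Peaks

Greedy peak calling: accept the highest remaining score whose distance to
every accepted peak on the same chromosome exceeds half the exclusion
width; ties break by (chrom, pos) ascending. "1 Mb neighborhood" is read as
total excluded width (±500 kb); a flag switches to the full width on each
side. Defaults mirror the scan conventions: 1 Mb coarse and 100 kb fine
neighborhoods, top 100 peaks, and a 99.9% linear-interpolation quantile as
the genome-wide threshold. Chromosome ends get no special treatment. Peak
annotation is plain half-open interval containment against a BED4 file, and
cross-platform replication is summarized as the fraction of peak-window
polymorphisms found in a second call set (callers typically require ≥ 50%).

## Simulator

`simeval` is a discrete-generation Wright–Fisher diploid simulator: parents
are sampled proportionally to fitness (determined solely by the focal-site
genotype: 1, 1 + hs, 1 + s), gametes recombine with Poisson(r·L) uniform
crossovers and mutate with Poisson(μ·L) new infinite-sites variants
(collisions resampled). In balancing mode the focal mutation enters at the
sequence center after the burn-in, with restart-from-burn-in conditioning
on retention (cap 1,000 restarts; failed attempts are cheap because loss is
detected immediately). Nominal parameters follow the benchmark convention:
L = 10 kb, μ = r = 2.5×10⁻⁸, s = 10⁻², h ∈ {−0.5, 100, 1.5} mapping to
equilibrium frequencies {0.25, 0.5, 0.75} via p̂ = h/(2h−1), burn-in 100,000
generations, selection phases of 250,000 / 100,000 / 10,000 generations
(older / younger / recent), and 10,000 sampled haplotypes. The population
size is not pinned by that convention; the package default is N = 10,000
diploids.

Two choices depart from a literal reading of the nominal grid and are the
package's own:

* **The eq-0.25 arm uses s = −10⁻² with h = −0.5.** Under fitnesses
  (1, 1+hs, 1+s), h = −0.5 with positive s makes the heterozygote the least
  fit genotype: the 0.25 equilibrium is unstable and a single-copy
  introduction essentially never establishes. Flipping the sign of s gives
  the stable mirror (het fittest, same equilibrium 0.25), which is the
  balancing-selection scenario the equilibrium-frequency grid describes.
  The simulator itself accepts either sign.
* **Desk-scale rescaling.** Full-scale runs (N·generations ≈ 10⁹ site
  updates per replicate, thousands of replicates) are cluster work. The
  shipped grid applies λ = 50 rescaling — N/λ, s·λ, μ·λ, r·λ,
  generations/λ, sample/λ — preserving θ = 4Nμ, ρ = 4Nr and 2Ns: one
  replicate is then 200 diploids over 4,000 generations with a 200-haplotype
  sample, and 200 replicates per arm complete in minutes. At this scale the
  benchmark supports directional and significance statements (AUC ≫ 0.5,
  LD-ABF ≥ Tajima's D at skewed equilibria, hitchhiking diversity excess
  near the focal site), not the two-decimal AUC/F1 values of a full-scale
  run; absolute power is lower than at full scale because the sample is 50×
  smaller, and rescaled selection is strong (sλ up to 0.5), which
  compresses sojourn-time variation relative to the nominal process.

What the generator does not emulate: demographic structure or size change,
the ancestral-species split needed by cross-species statistics, gene
conversion, mutation-rate heterogeneity, and sequencing/phasing error — so
passing benchmarks say nothing about robustness to platform artifacts
(that robustness is exactly what the trio QC filters are for on real data).

Each replicate draws its own random stream from (seed, CRC32(arm name),
replicate index), so any grid subset replays identically and replicates are
independently reproducible.

## Power evaluation

Each replicate is scored at the segregating sampled site nearest the focal
position (the focal variant itself may be absent from a neutral sample).
The decision threshold is the (1 − FPR) empirical quantile (linear
interpolation) of the neutral arm at FPR = 5%; precision, recall and F1
follow from the counts at that threshold, and AUC is the Mann–Whitney U
against the neutral arm over the product of set sizes with ties counted
half. AUC standard errors use the Hanley–McNeil formula. In windows without
segregating sites LD-ABF and D_ng are exactly 0 while Tajima's D is
undefined and ranked below every defined value.

## Numerical choices

* Newton convergence at max |gradient| < 10⁻⁸, at most 100 iterations,
  step-halving line search; everything is deterministic given input.
* log(1 + eˣ) is computed as logaddexp; no probability clamping is applied
  anywhere that reaches reported coefficients.
* Per-pair log-ABFs depend on the data only through the 2×2 haplotype
  table, so results are memoized on table counts; a genome scan is
  O(window × sites) fits as the windowed construction intends.
* Quantiles (peak thresholds, FPR cutoffs) use linear interpolation on
  sorted values.
* Tajima's D at S = 0 and replication fractions over empty windows return
  NaN rather than a sentinel value.

## Known limitations

* Only diploid, fully phased input; no phasing, imputation or multiallelic
  decomposition.
* No asymptotic p-values for LD-ABF; inference is by empirical thresholds
  and peak ranks.
* Cross-species comparators (HKA, BetaScan, B2) are out of scope; Tajima's
  D and D_ng are the in-package baselines.
* Region queries on VCFs require bgzip + tabix indexing (plain files are
  always read whole).
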