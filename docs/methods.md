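# Methods

## Problem setting

Plasma cfDNA in pregnancy is a two-genome mixture: a fraction *C* (the
fetal fraction) of fragments derive from the placenta and carry the fetal
genotype; the remainder carry the maternal genotype. Given (a) maternal
and paternal germline calls phased into haplotype blocks (phase-set
annotated VCFs), (b) a per-locus plasma allele-count table, and
optionally (c) a truth VCF for evaluation, the package infers the fetal
genotype at every biallelic SNV/InDel. Loci are classified by parental
zygosity only — AAAB, ABAA, ABAB, AAAA — with homozygous-alt parents
relabelled so the shared homozygous allele plays the "A" role; the
taxonomy is symbolic, not allele-literal. Opposite-homozygous parents
fall in the both-homozygous class; the Bayesian prior still forces an
obligate-heterozygous fetus there, so the coarse label loses nothing.

## Fetal-fraction estimator

FF = 2p/(p+q)×100 over maternal-homozygous sites where the father carries
the allele the mother lacks; *p* sums reads of that paternal-only allele,
*q* reads of the maternal allele. Two operational site sets:

* **obligate sites** (father homozygous for the other allele): the fetus
  is het with certainty and the formula is unbiased as written;
* **father-het sites**: the fetus inherits the paternal-only allele only
  half the time, so the numerator's *p* is doubled while the denominator
  keeps the raw read total — in expectation 4p/(p+q) = C.

The obligate set is used alone when it holds ≥ 500 sites (default,
configurable); otherwise the corrected father-het set is used. Residual
bias from the read-error channel is +2·err·(1−C) in proportion terms
(≈ +0.2 percentage points at err = 10⁻³), well inside the estimator's
practical tolerance. Zero-depth sites are skipped; with no informative
site at all the estimator raises and asks for an explicit `--ff`.

## Bayesian engine

The enumeration holds n = 10 maternal×fetal combinations. With fetal
pairs ordered (F₁ maternal transmission, F₂ paternal transmission) the
Mendelian-consistent set has 8 entries — maternal AA: {AA, AB}; AB:
{AA, AB, BA, BB}; BB: {BA, BB} — plus the two maternal-error pairs
(AA, BB) and (BB, AA), which receive prior mass only through the
genotyping-error rate ε. The prior is

P(A_i) = P(M | called maternal gt; ε) · P(F₁ | M; transmission flip ε)
· P(F₂ | called paternal gt; genotype-level ε), renormalised over the
enumerated support. With ε = 0 this reduces to exact Mendelian
transmission from the called genotypes.

Per-combination allele probabilities follow the mixture
P_j = B_jF/2·C + B_jM/2·(1−C), then pass through a symmetric read-error
channel P′_j = P_j(1−err) + (1−P_j)·err/k (k = number of alternative
alleles, 1 in biallelic ref/alt bookkeeping); smoothing can be disabled.

Two likelihood modes are provided:

* **multinomial** (default): the count log-likelihood Σ_j A_j log P′_j —
  the proper scoring rule; all accuracy results in this package use it.
* **literal**: the linear weighted mean Σ_j P′_j A_j / Σ_j A_j. It is
  retained because the mixture model is sometimes presented in this
  linear form, but being a linear functional of the empirical allele
  frequency its argmax always sits at the combination most concentrated
  on the plasma-majority allele (e.g. at an AAAB locus with 10% alt
  reads at C = 0.2 it prefers fetus AA over the correct AB). It is a
  reference implementation, not a caller.

The posterior is prior × likelihood, normalised over the 10 entries
(Σ = 1 within 10⁻⁹, property-tested). The call is the fetal genotype of
the argmax *combination*; its confidence sums the posterior over
combinations sharing that unordered genotype. Exact posterior ties prefer
the combination consistent with the called parental genotypes, then the
genotype with fewer alt alleles — a deterministic, deliberately
label-dependent tie-break, which is why the ref/alt-swap symmetry
property is asserted away from exact ties. Zero-depth loci are returned
unclassified. Defaults ε = err = 10⁻³ (typical short-read platform error).

## Haplotype engine (relative haplotype dosage)

At a phased maternal-het locus with paternal contribution *f* (the
father's allele at ABAA loci; the inferred transmitted allele at ABAB
loci), the plasma fraction of the allele matching *f* is q₁ = 0.5 + C/2
when the fetus inherited the maternal haplotype carrying it and
q₀ = 0.5 otherwise. Each locus contributes a binomial log-likelihood-
ratio term for "fetus carries Hap I" vs "Hap II", sign-flipped when *f*
sits on Hap II. The SPRT accumulates terms along each block in position
order; at |llr| ≥ log L all loci of the current segment take the decided
label and the accumulator resets, so crossovers inside a block (N50
~18.7 Mb greatly exceeds typical inter-crossover distances) flip later
segments instead of corrupting the block. Segments that never reach a
boundary stay unclassified. A single symmetric threshold L = 1200
(≈ 7.09 nats) is used rather than separate type-I/II error rates; at
~100× and C = 0.13 a decision needs roughly eight informative loci, and
the per-decision error rate is of order 1/L. Note that balanced counts
(x = n/2) are mild evidence *for* q₀ — the LR there is (4q₁(1−q₁))^{n/2},
not 1 — which is the correct behaviour of an asymmetric binomial SPRT.

Unclassified loci are imputed from the nearest labelled locus in the same
block within 200 kb (algorithm 1) or 500 kb (algorithm 2); when the
nearest upstream and downstream anchors inside the window disagree the
locus is left unclassified rather than guessed. Imputation never crosses
block boundaries. Window arithmetic is on 1-based positions, inclusive.

## Combined dispatch

SNVs: AAAA/AAAB → Bayesian; ABAA → SPRT, then closest-variant 1, then
Bayesian; ABAB → paternal allele from the nearest Bayesian AAAB anchor
(confidence ≥ 0.95 by default; anchor errors propagate along blocks, so
low-confidence anchors are excluded) within 200 kb in the paternal block,
maternal side through the SPRT flow, residual gaps → Bayesian. InDels are
excluded from the SPRT accumulator (their counts are noisier; the
simulator models this with a 2× error multiplier): paternal side via
algorithm 2, maternal side via the containing SPRT segment or algorithm
2, and loci the haplotype path cannot resolve stay unclassified — the
Bayesian rescue is reserved for SNVs. When both paths resolve a locus
and disagree, the haplotype call wins (it is the more accurate engine at
maternally heterozygous loci) and the conflict is logged. Loci with
missing maternal phase fall back to the Bayesian path with a warning.
Every locus receives exactly one provenance among
{bayes, sprt, closest1, closest2, unclassified}.

## Simulator

`simulate.simulate_family` draws, per chromosome: locus positions
(Poisson, default 10⁻³ SNV/bp and 10⁻⁴ InDel/bp); a per-locus population
alt frequency uniform on [0.05, 0.95]; four parental haplotype alleles as
Bernoulli draws (all-reference loci dropped); phase blocks as exponential
fragments rescaled until the realised length-weighted N50 is within 10%
of target (defaults 18.72 Mb maternal / 13.57 Mb paternal — a single
calibration statistic, hence the exponential choice), each block reported
in a random orientation; fetal transmission with Poisson crossovers
(default 0.012/Mb, ≈ 1.2 cM/Mb); and plasma counts with Poisson depth
(default 100×), Binomial(ff) fetal reads and a symmetric per-read error
channel (10⁻³; ×2 for InDels). One seeded generator drives everything, so
a seed fixes all outputs byte-for-byte.

Default sizes (one 50 Mb chromosome, ~45k loci) are the package's study
scale: large enough that category accuracies are stable to a few tenths
of a percentage point, small enough to iterate on.

What the simulator does **not** emulate: GC/mappability bias, duplicated
or soft-clipped fragments, phasing switch errors inside a block,
population linkage disequilibrium, multiallelic sites, and maternal
mosaicism. Consequently the haplotype engine's simulated accuracy
(≈ 99–100% classified, ≈ 99.8% correct at ABAA loci, C = 0.13, 100×) sits
at the optimistic edge of what real trios show; passing tests demonstrate
the inference machinery is correct under the stated generative model, not
that real-world error modes are handled. The *orderings* — haplotype ≥
combined ≥ Bayesian on accuracy, combined ≥ haplotype on coverage, and
accuracy rising with fetal fraction and depth — are the transferable
results, and those are what the acceptance checks assert.

## Numerical and interface choices

* Coordinates are 1-based as in VCF; genotypes are allele-index pairs
  over (ref, alt); unphased genotypes stored sorted, phased ones ordered
  (Hap I, Hap II) with the block id from the PS tag.
* Parental-VCF hygiene filters default to QUAL ≥ 30 and DP ≥ 10 (upper
  bound optional, e.g. 3× mean depth), configurable; multiallelic and
  symbolic-allele records are dropped with counted reasons.
* Sites present in only one parent's VCF are treated as homozygous
  reference for the absent parent.
* X-linked loci are scored like autosomal ones only if the caller maps a
  hemizygous father to a homozygous genotype for his single allele
  upstream; no X-specific mixture model is provided.
* Likelihoods are computed in log space with the max subtracted before
  exponentiation; per-(C, err) probability matrices and per-genotype
  priors are cached.
* `table1_accuracy` rounds half-up to one decimal (`decimal.Decimal`),
  matching how percentage tables are conventionally printed.

## Known limitations

De-novo mutations are not called (AAAA loci are scored but a fetal
non-parental allele is outside the enumeration's support except through
the error terms). Fragment-size and fragment-end features, which would
sharpen fetal/maternal read discrimination, are not modelled. CNVs,
aneuploidy and multiallelic sites are out of scope. The targeted
(diagnostic) report is a genotype report; it performs no clinical
variant interpretation.
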