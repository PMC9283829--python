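# fetoscope

Non-invasive reconstruction of a fetal genome from maternal-plasma
cell-free DNA (cfDNA) allele counts and phased parental genotypes.

During pregnancy, plasma cfDNA is a mixture of maternal and placental
(fetal) fragments; the fetal fraction *C* is typically 4–27%. Given
parental genotypes phased into long haplotype blocks and a per-locus
plasma allele-count table, `fetoscope` infers the fetal genotype at every
biallelic SNV and InDel, combining three inference paths and reporting the
provenance of every call. It is aimed at method developers and analysts
working on non-invasive prenatal diagnosis (NIPD) of monogenic disease who
need a transparent, testable implementation with a built-in simulator
providing ground truth.

## The model

Loci are grouped by parental zygosity: **AAAB** (mother homozygous, father
heterozygous), **ABAA** (het/hom), **ABAB** (het/het), **AAAA** (both
homozygous).

**Fetal fraction.** At maternal-homozygous sites where the father carries
the other allele, reads bearing the paternal-only allele must be fetal:

    FF = 2p / (p + q) × 100

with *p* the fetal-specific and *q* the maternal-allele read counts.

**Bayesian engine** (all categories; primary caller at AAAB). For each of
n = 10 maternal×fetal genotype combinations *A_i* = (M₁M₂, F₁F₂), the
plasma probability of allele *j* is the two-genome mixture

    P_j = B_jF/2 · C + B_jM/2 · (1 − C)

where *B_jF*, *B_jM* count allele *j* in the fetal and maternal genotype.
The posterior is P(A_i | B) ∝ P(B | A_i) · P(A_i), with a Mendelian prior
from the called parental genotypes (genotyping-error mass ε) and a
count likelihood Σ_j A_j log P_j. The call is the fetal genotype of the
maximum-posterior combination.

**Haplotype engine** (primary at ABAA/ABAB — relative haplotype dosage).
At a phased maternal-het locus the allele matching the paternal
contribution has expected plasma fraction q₁ = 0.5 + C/2 if the fetus
inherited the maternal haplotype carrying it, else q₀ = 0.5. A sequential
probability ratio test accumulates the binomial log-likelihood ratio along
each block until it crosses ±log L (default L = 1200), labels the segment
Hap I / Hap II, and resets (so recombination breakpoints flip later
segments). Undecided loci inherit the nearest classified locus's label
within 200 kb in the same block (closest-variant algorithm 1; 500 kb,
algorithm 2, for InDels), vetoed when flanking anchors disagree. ABAB
paternal alleles are anchored on nearby high-confidence Bayesian AAAB
calls; residual SNV gaps fall back to the Bayesian call.

## Worked example

```bash
fetoscope simulate --seed 5 --length 5000000 --out sim
fetoscope ff --mat sim/maternal.vcf --pat sim/paternal.vcf --counts sim/plasma_counts.tsv
```

```
region  ff_percent  n_sites
genome  13.27       1205
```

The simulated family was generated at a true fetal fraction of 13%; the
estimate from 1,205 informative sites is 13.27%.

```bash
fetoscope genotype --mat sim/maternal.vcf --pat sim/paternal.vcf \
    --counts sim/plasma_counts.tsv --out fetus.vcf
fetoscope evaluate --calls fetus.vcf --truth sim/fetus_truth.vcf \
    --mat sim/maternal.vcf --pat sim/paternal.vcf
```

```
estimated fetal fraction: 13.27% (1205 sites)
combined: 4598/4598 loci called -> fetus.vcf
category  vclass  n_true  n_total  accuracy
AAAA      InDel   123     123      100.0
AAAA      SNV     1260    1260     100.0
AAAB      InDel   115     115      100.0
AAAB      SNV     1084    1090     99.4
ABAA      InDel   116     116      100.0
ABAA      SNV     1095    1095     100.0
ABAB      InDel   74      74       100.0
ABAB      SNV     724     725      99.9
```

Every locus received a call; accuracy is scored per category against the
simulated truth VCF. `fetus.vcf` tags each record with `METHOD=` (bayes,
sprt, closest1, closest2 or unclassified) and `CONF=`. Passing
`--engine bayes` shows why the combination matters: the Bayesian-only path
drops to ~75% at ABAA and ~62% at ABAB loci at this fetal fraction.

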