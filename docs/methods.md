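# Methods

## Model

An individual transmits, at each heterozygous locus, one of its two alleles
with probability ½. Code the transmitted allele at locus *j* as the
indicator *t_j* = +½ if the gamete carries the reference allele and −½
otherwise. Each *t_j* has variance ¼ (binomial, one draw, p = q = ½), and
two heterozygous loci *j*, *k* on the same chromosome have

    Cov(t_j, t_k) = al_jk · (¼ − r_jk/2)

where *r_jk* is the recombination rate between them and *al_jk* is +1 when
the reference alleles are in coupling and −1 in repulsion. The matrix of
these (co)variances over the heterozygous loci is **P**. Given
allele-substitution effects α, the gametic variance of a trait is the
quadratic form α′**P**α and the between-trait gametic covariance the
bilinear form α_x′**P**α_y. Homozygous loci contribute nothing to the
variance but enter HOM = Σα² (homozygous loci), the denominator term of
CRV = σ/√(0.5·HOM + σ²). GEBV is the dot product of −1/0/+1 genotype codes
with α; the mean gamete value on the centered ±½ scale is exactly GEBV/2,
which ties the gametic layer to the breeding-value layer and is asserted in
the tests.

Distance input comes in two dialects. With cumulative centimorgan
positions, the off-diagonal is al·(−cM/200 + 0.25) with pairwise distance
|pos_k − pos_j|, and loci more than 50 cM apart are treated as independent
(the linear formula itself reaches zero at exactly 50 cM, so the cutoff is
continuous and "greater than 50" vs "at least 50" is observationally
irrelevant). With recombination-rate input, the off-diagonal is
al·(−rate/2 + 0.25), zero at rate ≥ 0.5. The cM pathway is implemented
exactly as the linear formula, without a mapping-function conversion; for
two loci the two pathways agree under the linear convention rate = cM/100.

Adjacent-interval rates are composed into pairwise rates with the
no-interference (Markov) rule r⊕s = r(1−s) + (1−r)s, equivalently
1−2r_jk = Π(1−2r_i) over the spanned intervals, computed with prefix sums
of log(1−2r) and an absorbing-zero count (an interval at rate 0.5 makes
every pair across it independent). A full pairwise-rate matrix, when
supplied, is used verbatim. Note the two dialects are *not* identical on
three or more loci: the linear-cM convention is additive in distance while
rate composition is not; this is an inherent property of the two input
conventions, not a numerical issue.

In rate mode with consistently composed rates, **P** is the covariance
matrix of a realizable meiosis and therefore positive semi-definite, so
σ² ≥ 0 and the Cauchy–Schwarz bound σ_XY² ≤ σ²_X·σ²_Y holds; both are
property-tested. The cM pathway with the hard 50 cM cutoff does not
guarantee PSD; a negative total variance (rare, pathological maps) is
clamped to zero for σ-derived statistics with a logged warning.

## Selection layer

RPTA = GEBV/2 + σ_gamete·i_f with default intensity i_f = 1.5. The progeny
count needed to observe the expected gametic variability with confidence z
(default 1.96, 95%) at maximum relative EBV change d (default 0.1) is
z²·CRV²/d², reported both raw and as its ceiling (a progeny count is
integral). z and d are configurable; negative GEBV is not truncated.

## Per-individual reports

Computation is chromosome by chromosome; all chromosomes are treated as
autosomes and totals are simple sums. CRV, RPTA and progeny numbers are
computed from genome-wide totals; per-chromosome CRV columns are emitted as
a labelled extension (`crv_ext_chrom_*`). The degenerate CRV case 0/0
(fully homozygous individual with all-zero effects) is defined as 0 and
logged. All K(K−1)/2 unordered trait pairs are reported, ordered by the
upper triangle in effect-file column order. For up to 8192 heterozygous
loci the dense **P** is materialized; beyond that the quadratic form is
accumulated in row blocks with identical results (the 50 cM cutoff makes
the cM-mode sum effectively banded).

## Oracles and the synthetic generator

Two independent routes validate the analytic quadratic form:

* **Exact enumeration** — all 2^N source-haplotype paths of the Markov
  crossover model (equiprobable starting haplotype; each interval
  independently recombinant with its adjacent rate) are enumerated,
  collapsed to a distribution over distinct gametes, and the exact mean and
  (co)variance of gamete breeding values computed. Capped at 20 markers;
  fuzz tests use ≤ 12.
* **Monte-Carlo meiosis** — a vectorized sampler from the same model for
  larger instances; used for the progeny-variance identity (progeny value
  variance = σ²_sire + σ²_dam, checked within 3 standard errors using the
  fourth-moment standard error of a sample variance).

The generator draws haplotypes allele-wise at uniform allele frequencies in
a configurable MAF range (default 0.1–0.5), i.e. linkage equilibrium and
Hardy–Weinberg proportions; maps are sorted-uniform cM positions or uniform
adjacent rates; effects are Normal(0, sd) per trait. All randomness flows
from a single seed through one named generator. This emulates the input
*shapes* of real phased panels, not their LD structure, allele-frequency
spectra or effect-size architecture — passing tests demonstrate the
correctness of the transmission algebra and the file plumbing, not
predictive performance on real populations, which depends entirely on the
externally estimated marker effects.

## Numerical and design choices

* Reference-allele convention: haplotype allele 1 is the reference allele;
  α is the substitution effect of that allele; in VCF input, REF maps to
  allele 1. One fixed convention removes the sign ambiguity of al_jk.
* Marker alignment is by marker id only, never by position; VCF bp is never
  used as genetic distance (map positions always come from the map file).
* Lenient mode drops problem loci (unphased/multi-allelic VCF records,
  effect-less map markers) for all individuals with logged counts and
  re-composes rate intervals across the gap; strict mode fails instead.
* Outputs are TSV with 6-significant-digit floats for diff stability,
  written incrementally per individual so memory scales with markers per
  chromosome rather than individuals; parallel runs (`--jobs`) merge
  per-individual results in input order and are byte-identical to serial.
* Chromosome-additivity of totals is tested at 1e−9 relative tolerance;
  oracle-vs-quadratic-form equivalence at 1e−10 relative.
* Test problem sizes: 500 enumeration-checked individuals (≤ 12 het loci),
  50 parent pairs × 100 000 Monte-Carlo progeny, and one end-to-end run of
  8 traits × 4340 markers × 100 individuals on one chromosome.

## Limitations

* No crossover interference (Haldane-style independence between intervals);
  no sex-specific maps or sex-chromosome inheritance.
* Effects are taken as known constants; estimating them (and GEBV
  reliability) is out of scope, as are dominance and epistatic gametic
  effects.
* Multi-allelic loci and missing genotypes are not representable in the
  core types; readers fail or drop such loci.
* The cM pathway's linear covariance rule is kept exactly as stated even
  where it disagrees with rate composition beyond two loci (see above).
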