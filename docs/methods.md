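# Methods

This note records the statistical model implemented by `plasmacall`, the
parameter choices and their rationale, the scope of the synthetic data
generator, and the numerical decisions that make runs reproducible.

## Problem setting

Maternal plasma contains cell-free DNA (cfDNA) from two sources: the mother and
the fetus (via the placenta). At a biallelic locus where the parental genotypes
are known, the fetal genotype can be inferred from the alleles carried by
plasma fragments, because a fraction *f* of those fragments — the *fetal
fraction*, typically 5–25% in the first trimester — is fetal-derived. Two
physical facts make this tractable:

1. **Mendelian constraint.** The fetus inherits one allele from each parent,
   so the parental genotypes induce a prior over the three fetal genotypes and
   rule some out entirely.
2. **Fragment-length difference.** Fetal cfDNA fragments are shorter than
   maternal ones (length distributions peaking near 140 bp vs the
   mononucleosomal 166 bp), so a fragment's length carries information about
   its probability of being fetal.

Sites are classified by the parental genotypes:

| mother \ father | hom-ref | het | hom-alt |
|---|---|---|---|
| **hom-ref** | uninformative | paternal-only het | fetal-informative |
| **het** | maternal-only het | double het | maternal-only het |
| **hom-alt** | fetal-informative | paternal-only het | uninformative |

Fetal-informative sites (parents opposite homozygotes) are used to estimate the
fetal fraction; the three heterozygous categories are the calling/evaluation
categories. At single-parent-het sites the call reduces to het vs homozygous
(baseline accuracy 0.5); at double-het sites all three genotypes are possible
(baseline 1/3). Paternal-only sites are easiest (the maternal background is
homozygous, so any opposite-allele signal is decisive), maternal-only sites
harder, and double-het sites hardest — orderings the acceptance tests check.

## Fetal-fraction estimation

At fetal-informative sites every fragment carrying the paternal-specific allele
must be fetal. With *b* such fragments against *a* shared-allele fragments,

  f = 2b / (a + b),

the factor 2 because the fetus is heterozygous there, so only half of its
fragments show the paternal allele. Binning the same counts by template length
gives a per-length fraction f_L = 2·b_L/(a_L + b_L). Length bins with fewer
than `min_count` (default 50) informative fragments fall back to the pooled
total; fragments that are not properly paired or are longer than 500 bp always
fall back to the total. All fractions are clamped to [1e-6, 1]: the floor keeps
zero-count estimates strictly positive (a hard 0 would make maternal-het sites
unidentifiable), and estimating zero fetal content from finite data is never
justified.

The estimator is slightly biased upward under allele-observation error ε
(errors at informative sites convert shared alleles into apparent paternal
ones, inflating f by ≈ 2ε); with the default ε = 0.002 generator this bias is
≈ 0.008 and is accepted rather than corrected, as it is within the tolerance of
every downstream use.

## Bayesian genotype model

For a site with parental genotypes (G_M, G_F) and per-fragment observations
r_1..r_n, the fetal genotype posterior is

  P(G | r) ∝ P(G | G_M, G_F) · Π_j [ P(r_j | fetal, G)·f_j + P(r_j | maternal, G_M)·(1 − f_j) ]

where f_j is the fetal fraction assigned to fragment j: the per-length value
f_L for properly paired fragments with length ≤ 500 bp, the total f otherwise
(`LENGTH_DEPENDENT` mode), or the total f for every fragment (`FIXED` mode).

- **Prior**: each parent transmits its alt allele with probability g/2 (g = 0,
  1, 2 alt alleles), independently. De novo events are not modeled: genotypes
  with zero prior keep posterior zero regardless of data.
- **Emission**: a fragment from genotype g shows the alt allele with
  probability ε, ½, or 1 − ε for g = 0, 1, 2; ε (default 10⁻³) absorbs
  sequencing and alignment error at the allele level. ε = 0 recovers the
  idealized emissions, under which e.g. P(r = A | G = aa, G_M = Aa, f) =
  0·f + 0.5·(1 − f) — an exactness the tests assert to machine precision.
- **Numerics**: per-genotype log-likelihoods are accumulated in natural-log
  space and normalized with a max-shift; with zero observations the posterior
  equals the prior exactly. The call is the posterior argmax; exact ties are
  flagged and resolved toward the earlier genotype.

## Evidence extraction

The caller's only read-level input is the *evidence store*: one row per
physical fragment per site with (allele, |template length|, properly-paired
flag, base quality, mapping quality). Extraction from alignments skips
duplicate/secondary/supplementary/QC-fail reads and applies MAPQ ≥ 20,
baseQ ≥ 13 defaults. Each read pair contributes at most one observation per
site; mates that disagree about the allele discard the fragment. SNP support is
the base at the position; indel support requires the read's aligned local
haplotype over the reference span of the variant — with anchor bases aligned at
both boundaries — to match REF or ALT exactly, else the read is discarded.
(The source method delegated indel handling to an external caller; the ref-span
exact-match rule is this package's deterministic equivalent.)

## Synthetic generator

The generator exists to make the statistical claims testable at desk scale; it
is a study design, not a fit to data, and its defaults were fixed before the
acceptance conditions were frozen.

- Parental genotypes per category as in the table above; fetal genotype drawn
  from the Mendelian prior; per-site depth Poisson(`depth_mean`, default 100).
- Each fragment is fetal with probability `true_ff` (default 0.15) and draws
  its length from a discretized left-skewed skew-normal: mode 140 bp, scale 33
  (fetal) vs mode 166 bp, scale 30 (maternal), shape −4, support 50–500 bp.
  Only the modes are constrained by the literature; scales/shape were chosen
  once to give realistic overlap.
- Allele observations flip with error 0.002; a 5% subpopulation of *noisy*
  sites has error 0.02 with depressed base (≈N(26,4)) and mapping (≈N(45,8))
  qualities, emulating context-dependent error.
- A 5% subpopulation of *reference-biased* sites loses ALT-derived reads to REF
  at rate 0.08, and the surviving ALT reads carry depressed mapping quality —
  the classic alignment/capture-bias signature. This channel is asymmetric by
  design: symmetric flips at mother-het sites barely move the allelic balance,
  so without it the recalibrator would have no structured errors to learn.
- 2% of fragments are improperly paired (template length recorded as 0).

**Fetal-fraction reduction** rewrites a store to a lower target *d*. Where the
mother is homozygous the fetal-specific allele is identifiable: a proportion
1 − d/f of the fetal-allele reads is discarded (randomized rounding), the same
number of shared-allele reads — sampled ∝ their length's frequency under the
fetal length law — get maternal-law lengths, and the same number of new
shared-allele reads is generated, preserving depth. Where the mother is
heterozygous the fetal reads are unidentifiable; the excess fetal mass
(1 − d/f)·f of reads is sampled by fetal-length frequency and made fully
maternal-like: maternal-law length *and* an allele redrawn uniformly from the
het mother's two alleles (a distributional no-op for truly maternal reads, a
correction for fetal ones, so allelic imbalance scales down with f). A literal
variant that converts the proportion d/f instead is available as
`maternal_het_mode="literal"`. **Depth downsampling** keeps each observation
independently with probability target-median / measured-median.

## Recalibration

A per-category random forest (300 trees, `max_features="sqrt"`,
`class_weight="balanced"`, `min_samples_leaf=2`, seeded) learns P(call correct)
from 38 features the caller does not model jointly: depth and allelic balance,
per-allele length/quality summaries with presence flags (absent sides
zero-imputed), pairing, the caller's posteriors, log-likelihoods, called
genotype, prior/posterior entropies, and the fetal fraction. Training pools
follow the source scheme: the paternal-only SNP model pools SNPs from all three
categories (its own errors are too rare), indel models pool SNPs and indels of
the same category, other SNP models train within category. 75% train / 25%
stratified holdout; the holdout AUC is recorded in the model provenance.
Filtering keeps calls with score ≥ τ (default 0.7). Plain bagged trees
(`max_features=None`) were evaluated and were clearly worse on held-out
families, so the random forest default stands.

## Reproducibility

Every stochastic entry point takes an explicit seed and uses
`numpy.random.default_rng`; derived seeds are drawn as integers < 2³¹. Store
writes pin the gzip mtime and filename so identical stores are byte-identical;
profiles serialize floats via `repr` for exact round trips; VCF output is
timestamp-free. CLI commands write a provenance sidecar (tool version, resolved
parameters, input hashes) next to each output.

## Known limitations

- One fetus, diploid autosomes, biallelic sites only; no de novo mutations.
- The generator draws qualities independently of the allele-error process
  except through the noisy/biased site channels; real error is more structured.
- The fetal-fraction estimator's ≈2ε upward bias is documented, not corrected.
- Indel simulation shares the SNP error model; real indel error is
  length-dependent.
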