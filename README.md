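# plasmacall

Bayesian noninvasive fetal genotyping from cell-free DNA (cfDNA) in maternal
plasma.

Given both parents' genotypes (single-sample VCFs) and the mother's plasma
cfDNA alignments, `plasmacall` calls the fetal genotype at every biallelic
parental site. A fraction *f* of plasma fragments is fetal-derived, and fetal
fragments are shorter (length mode ≈140 bp vs the maternal ≈166 bp), so each
fragment's allele is modeled as a mixture of a fetal and a maternal source
weighted by a per-fragment-length fetal fraction:

    P(G | reads) ∝ P(G | G_M, G_F) · Π_j [ P(r_j | fetal, G)·f_j + P(r_j | maternal, G_M)·(1 − f_j) ]

with a Mendelian trio prior P(G | G_M, G_F) and per-read fractions f_j looked
up from a fragment-length profile estimated at *fetal-informative* sites
(parents homozygous for different alleles, where every paternal-allele fragment
is provably fetal: f = 2b/(a+b)). A random-forest recalibration stage scores
each call's probability of being correct from features the caller does not
model, enabling quality filtering. A synthetic-trio simulator with controllable
fetal fraction, depth, and error structure makes the whole pipeline testable
without access to clinical data. See `docs/methods.md` for the full model.

## Worked example

Simulate a family (11,000 sites at fetal fraction 0.15, mean depth 100),
estimate the fetal fraction, call fetal genotypes and score them against the
simulated truth:

    $ plasmacall simulate trio --seed 7 --out-prefix fam
    simulated 11000 sites, 1100423 fragments -> fam.*

    $ plasmacall estimate-ff --store fam.store.tsv.gz \
        --mother fam.mother.vcf --father fam.father.vcf --out fam.profile.tsv
    total fetal fraction: 0.1585

    $ plasmacall genotype --store fam.store.tsv.gz \
        --mother fam.mother.vcf --father fam.father.vcf \
        --profile fam.profile.tsv --out fam.calls.vcf
    wrote 11000 fetal calls to fam.calls.vcf

    $ plasmacall evaluate --calls fam.calls.vcf --truth fam.truth.vcf \
        --mother fam.mother.vcf --father fam.father.vcf
    category                     n   accuracy      auc
    MATERNAL_ONLY_HET         2000     0.8575   0.9398
    PATERNAL_ONLY_HET         2000     0.9750   0.9868
    DOUBLE_HET                2000     0.8045   0.8876
    TOTAL                     6000

The output VCF carries the called genotype, the three genotype posteriors (GP),
log-likelihoods (LL), depth, site category and fetal-fraction mode:

    #CHROM  POS    ID  REF  ALT  QUAL  FILTER  INFO  FORMAT                FETUS
    chr1    10600  .   T    A    .     .       .     GT:GP:LL:DP:CAT:FFM   0/1:0.030564,0.959971,0.009465:-78.307,-75.553,-79.4792:109:DOUBLE_HET:LENGTH_DEPENDENT

On real data, start from an indexed BAM/CRAM instead:

    plasmacall preprocess --cfdna plasma.bam --mother mother.vcf \
        --father father.vcf --out evidence.tsv.gz

then run `estimate-ff` and `genotype` on the evidence store, or use
`plasmacall run` to execute the whole chain. Recalibration trains on a family
with known fetal truth and transfers to new families:

    plasmacall recal extract --calls fam.calls.vcf --store fam.store.tsv.gz \
        --mother fam.mother.vcf --father fam.father.vcf \
        --profile fam.profile.tsv --out fam.features.tsv
    plasmacall recal train --features fam.features.tsv --truth fam.truth.vcf \
        --category MATERNAL_ONLY_HET --seed 3 --out maternal.joblib
    plasmacall recal apply --model maternal.joblib \
        --features other_family.features.tsv --out scores.tsv
    plasmacall recal filter --calls other_family.calls.vcf \
        --scores scores.tsv --tau 0.7 --out kept.tsv

`plasmacall simulate reduce-ff`, `simulate downsample` and `simulate grid`
subsample an existing store to lower fetal fractions / depths and map accuracy
over a (fetal fraction × depth) grid.

## Reproducing results

Every stochastic command takes an explicit `--seed`; identical seeds give
byte-identical outputs (stores, profiles and VCFs are written
timestamp-free). Each CLI output gets a `.provenance.json` sidecar with the
tool version, resolved parameters and input hashes.

To run the test suite (unit, property-based and acceptance tests):

    pytest -q

To regenerate the headline study quantities — fetal-fraction recovery,
per-category calling accuracy in both fetal-fraction modes, the subsampling
closed loop, and raw vs recalibrated AUC on an independent family — run:

    python scripts/acceptance.py --seed 1 --out acceptance.json

which writes each quantity as `{"value": ..., "n": ...}` (n = number of units
it was computed over). The run takes about half a minute.

## Layout

- `src/plasmacall/` — library: `sites`, `store`, `bamio`, `vcfio`,
  `fetal_fraction`, `bayes`, `evaluate`, `simulate`, `recalibrate`, `cli`
- `tests/` — pytest suite; `tests/test_acceptance.py` holds the release criteria
- `scripts/acceptance.py` — headline-quantity report
- `docs/methods.md` — model, parameter rationale, generator scope and limits
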