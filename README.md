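# rohprio

Homozygosity mapping as evidence for variant pathogenicity in recessive
Mendelian disease.

## The problem

In consanguineous families, a recessive disease-causing variant is almost
always homozygous because both copies descend from a recent common ancestor.
The same descent process leaves a signature around the variant: a
multi-megabase run of homozygosity (ROH). Short ROH (typically < 1 Mb) come
instead from ancient haplotype sharing in the population, and variants
inside them have been exposed to purifying selection for many generations —
they are much less likely to cause severe disease. The *largest* ROH in a
patient's genome are therefore the natural place to look for the causative
variant, and a candidate variant's position relative to those regions is
usable evidence when classifying it.

`rohprio` is for clinical and research geneticists triaging candidate
homozygous variants from sequencing data. It provides:

* an ROH caller — a two-state hidden Markov model over VCF genotypes that
  tolerates isolated erroneous heterozygous calls and can drop sites out of
  Hardy–Weinberg equilibrium (both mitigate the false hets that otherwise
  shatter large regions);
* region scoring — for each ROH in a sample, its **rank** (1 = largest),
  **relative size** (size / size of the sample's largest region), and
  **HR score**, the percentage of the sample's ROH bases lying in regions
  strictly smaller than the one under consideration;
* a variant-level verdict — a homozygous candidate earns ACMG-style
  *supporting* evidence when it lies in one of the ten largest regions or
  in a region with HR score ≥ 42. Variants within 3 Mb of a telomere are
  flagged with a caution (chromosome ends truncate the covering segment, so
  telomere proximity must not be used to exclude a variant), as are samples
  with > 8% of the genome in ROH; cautions annotate, they never veto;
* consanguinity classification from the data alone — a sample is
  consanguineous when regions > 3 Mb cover > 1.5% of the genome, the
  expected autozygosity of second-cousin offspring (F = 1/64);
* cohort evaluation — capture curves and base-weighted ROC/AUC measuring
  how far variant capture runs ahead of the ROH base share, exclusion
  filters, Fisher's exact test, and proportion-test power;
* a synthetic-cohort simulator with known ground truth: recent autozygous
  tracts (two-state Markov process along the genetic map, exit rate *m* per
  Morgan for an *m*-meiosis inbreeding loop, stationary autozygous fraction
  F), sub-megabase ancestral tracts, Hardy–Weinberg genotypes with
  controlled het-error inside tracts, and one planted causative variant per
  sample.

## Worked example

Simulate a small cohort, call ROH for one sample, and annotate its planted
causative variant:

```sh
rohprio simulate --n 3 --meioses 6 --seed 7 --out sim/
rohprio call --vcf sim/sample000.vcf --sample sample000 \
    --chrom-sizes sim/genome.sizes --out sample000.roh.bed
# -> sample000: 30 regions, 150.7 Mb
rohprio score --roh sample000.roh.bed --chrom-sizes sim/genome.sizes \
    --out sample000.scores.tsv
# -> sample000: homozygosity 5.24%, consanguineous=True
```

The caller reports the multi-megabase recent tracts plus the few largest
ancestral tracts; most sub-megabase ancestral ROH fall below the default
1 Mb / 25-site floor. The planted variant for sample000 sits at
chr3:38,953,225 (columns 3–4 of `sim/cohort.tsv`):

```sh
printf 'chr3\t38953225\n' > cand.tsv
rohprio annotate --roh sample000.roh.bed --variants cand.tsv \
    --sample sample000 --chrom-sizes sim/genome.sizes --out annotated.tsv
cat annotated.tsv
# chrom  pos       in_roh  rank  hr_score  supporting_evidence  caution_telomere  caution_high_homozygosity
# chr3   38953225  1       1     68.94     1                    0                 0
```

Reading: the variant lies inside the sample's largest ROH; 68.9% of the
sample's ROH bases are in smaller regions. Rank 1 ≤ 10 (and HR 68.9 ≥ 42),
so the variant earns supporting evidence, with no telomere or
high-homozygosity caution.

Cohort-level evaluation runs off a manifest
(`sample_id TAB roh_bed TAB chrom TAB pos`), such as the one the simulator
writes:

```sh
rohprio evaluate --cohort-manifest sim/cohort.tsv \
    --chrom-sizes sim/genome.sizes --out eval/
# -> 3 samples evaluated (0 excluded); AUC[rank]=0.851; AUC[size]=0.811;
#    AUC[relative_size]=0.851; AUC[hr_score]=0.844; AUC[combined]=0.811
```

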