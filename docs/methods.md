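# Methods

## Scientific setting

Offspring of consanguineous unions carry long stretches of autozygosity:
both haplotypes identical by descent through a recent inbreeding loop. A
recessive causative variant must be homozygous and, because it arrived
through that loop, it tends to lie inside one of the *largest* runs of
homozygosity (ROH) in the genome. Shorter ROH descend from distant common
ancestors; variants inside them have faced purifying selection in the
homozygous state for many generations and are depleted of severe
disease alleles. The package turns this size signal into region scores and
a variant-level evidence flag, and measures its predictive power on
labelled cohorts.

## Coordinate conventions

ROH intervals are 0-based half-open (BED); variant positions are 1-based
(VCF). A variant at position p lies in region [s, e) iff s < p ≤ e — the
join rule is defined once and used everywhere. Sex and mitochondrial
chromosomes are excluded by default from calling and from genome-size
denominators (hemizygosity mimics autozygosity); the exclusion list is an
argument of `read_chrom_sizes`.

## ROH calling

A two-state HMM (A = autozygous, N = non-autozygous) is decoded by Viterbi
independently per chromosome.

Emissions at a site with alternate-allele frequency f (clipped to
[1e-6, 1−1e-6]):

| genotype | state N (Hardy–Weinberg) | state A |
|----------|--------------------------|---------|
| hom ref  | (1−f)²                   | (1−f)(1−e) |
| het      | 2f(1−f)                  | e |
| hom alt  | f²                       | f(1−e) |
| missing  | 1                        | 1 |

e is the het-error rate inside autozygous tracts (default 0.01): an
isolated miscalled het costs log(e) − log(2f(1−f)) ≈ 3.5 nats in state A,
less than the cost of leaving and re-entering the state, so single errors
do not split a multi-megabase region; a run of true hets does. Setting
e → 0 removes this tolerance and demonstrably fragments planted tracts
(asserted in the tests).

Transitions over a physical gap of d bp: A→N with probability
1 − exp(−d/L), L = `expected_segment_mb` × 10⁶ (default 4 Mb, of the order
of tract lengths after several meioses); N→A at the rate scaled by
`prior_autozygosity`/(1 − `prior_autozygosity`) (default prior 0.02), which
fixes the stationary autozygous fraction at the prior. Initial state
probabilities are the stationary ones.

Decoded A-runs are trimmed to their outermost observed homozygous sites
(no inter-site interpolation, so results are reproducible from the site
stream alone), merged across gaps ≤ 100 kb (`merge_adjacent`, countering
residual splits), then filtered: size ≥ 1 Mb, ≥ 25 supporting sites, het
fraction ≤ 0.05. All defaults are exposed on `RohCallerParams`.

Allele frequencies come from the VCF INFO/AF field, else from cohort
genotype counts in multi-sample VCFs, else a constant 0.25 with a warning —
a mid-range value that degrades gracefully rather than failing. Sites out
of Hardy–Weinberg equilibrium (1-df chi-square, p < 1e-6) can be dropped
cohort-wide before calling; the filter demands ≥ 20 genotyped samples, as
the test is meaningless on fewer, and monomorphic sites are never dropped
(no test is possible).

## Region scores and the evidence rule

Within a sample, regions are ordered by size descending, ties broken by
genomic position (chromosome order, then start) for reproducibility:

* rank — position in that order (1 = largest);
* relative size — size / size of the largest region (in (0, 1]);
* HR score — 100 × (sum of sizes of *strictly* smaller regions) / (total
  ROH bases). The largest region of a sample scores highest, the smallest
  exactly 0; tied sizes share a score. The HR score is computed
  within-sample: its denominator is the sample's own ROH content, which is
  what makes 42 a portable threshold across samples with very different
  total homozygosity.

A homozygous candidate variant earns the supporting-evidence flag when it
lies inside an ROH that is in the top ten by rank **or** has HR score ≥ 42.
The two published criteria are each usable alone, so the default combines
them with OR; `ScoringThresholds.evidence_rule` also offers `and`,
`top_k`, `hr_score`. Two cautions annotate but never veto: variant within
3 Mb of a chromosome end (truncation makes the covering region smaller and
lower-ranked than the descent process alone would — see below), and sample
homozygosity > 8% (rank discriminates less when ROH are everywhere).

Consanguinity is classified from the data: regions > 3 Mb covering > 1.5%
of the genome (the expectation for second-cousin offspring, F = 1/64).
Both inequalities are strict, as printed. The 8% threshold and the 3 Mb
telomere distance are likewise strict and config-exposed.

## Cohort evaluation

The capture curve reports, for each rank cutoff k, the fraction of
causative variants inside a region of rank ≤ k against the fraction of
pooled ROH bases those regions hold. Prioritization is useful exactly when
capture runs ahead of base share.

ROC construction is base-weighted: sweeping a threshold over a region
metric, y = fraction of causative variants in qualifying regions (variants
outside any ROH never qualify), x = fraction of pooled ROH bases admitted.
The base weighting is chosen because the null — variants placed uniformly
over ROH bases — then calibrates to the diagonal and AUC 0.5, making AUC
directly interpretable as enrichment beyond base content. (The alternative,
counting each region once, calibrates to 0.5 only under uniform-over-regions
placement, which is not the relevant null for a variant-hunting workflow.)
AUC is the trapezoid area over the threshold-sweep points with endpoints
(0,0) and (1,1); an independent per-segment fine-grid integration oracle
agrees to 1e-9 in the tests.

The combined metric is the unweighted mean of the three pooled percentile
ranks (rank inverted so larger = better) — parameter-free, no fitting, no
leakage. In simulation the three metrics order regions identically within a
sample (all are monotone in size), so the combination tracks the mean of
the single-metric AUCs rather than dominating the best one; gains from
combining require the cross-metric heterogeneity of real data.

Exclusion filters drop samples with > 8% homozygosity and variants within
3 Mb of a telomere, returning counts per reason; retained samples' scores
are passed through untouched.

Fisher's exact test (scipy's hypergeometric implementation, cross-checked
in the tests against full table enumeration) covers the telomere 2×2:
with 179 variants of which 143 are in the top ten, and 8 telomeric
variants of which 1 is in the top ten, the one-sided depletion p is
5.5 × 10⁻⁵.

`min_samples_for_proportion` returns the smallest n at which a two-sided
test of a proportion attains a requested power: the default mode builds the
exact-binomial rejection region from the null pmf and sums the alternative
pmf over it; a normal-approximation mode implements the standard
one-sample formula. For p₀ = 0.5 vs p₁ = 0.79 at α = 0.05 and 80% power
these give n = 23 and n = 21 respectively. Published figures for this kind
of design depend on an effect size assumption the operation deliberately
leaves to the caller.

## Synthetic cohorts

The generator's defaults are the study conditions; they emulate the
structure the analysis relies on, not any particular population.

* Recent autozygosity: a two-state Markov process along a constant genetic
  map (1 cM/Mb — the analysis is in physical Mb throughout, and a real map
  would add assembly dependence without changing any tested behaviour).
  For an m-meiosis inbreeding loop (default m = 8, second cousins;
  m = 6, first cousins), tracts end at rate m per Morgan (mean tract
  100/m cM) and begin at rate mF/(1−F), making the stationary autozygous
  fraction exactly F = 1/2^(m−2). This is the standard exponential
  approximation of the IBD process around an inbreeding loop; exact
  pedigree crossover simulation is out of scope.
* Ancestral ROH: Poisson starts (default 5 per 100 Mb) with exponential
  lengths (mean 0.5 Mb — sub-megabase by construction). No quantitative
  population value is claimed for these defaults; they are plausibility
  choices exposed in the config. Ancestral tracts are genuinely autozygous
  in the emission model, so the caller can separate the two classes only by
  size — size is the discriminating signal, exactly the premise under test.
* Genotypes: sites at 100/Mb (Poisson), f ~ Uniform(0.05, 0.5) written to
  INFO/AF; homozygous by allele frequency inside tracts, miscalled het with
  probability 0.005; Hardy–Weinberg outside. Expected het fraction outside
  tracts is E[2f(1−f)] = 0.365.
* Causative variant: one per sample; uniform over recent-segment bases
  (the disease model), uniform over all ROH bases (the evaluation null), or
  uniform over the genome. Samples with no recent segment fall back to
  uniform-genome with a warning — under F = 1/64 a few samples genuinely
  have none.
* Determinism: sample i uses seed + i; genotype emission uses an offset
  seed stream so it cannot perturb segment truth. Same seed, same bytes.

What the generator does **not** emulate: population structure and founder
effects, LD between sites, a non-uniform recombination map, genotyping
batch artefacts, and clustering of false hets in hard-to-sequence regions
(errors here are independent per site). Passing tests therefore show the
method behaves correctly under its own model assumptions — enrichment
detected when present, null calibrated at AUC 0.5, regions recovered from
genotypes — not that the published cohort-level effect sizes transfer to
any particular population.

## Calibration and the two telomere effects

Tract-length calibration uses the right-censored exponential MLE (total
tract length / number of tracts ending before a chromosome end): tracts
running into an end are censored observations, and the naive mean over
interior tracts is biased ~10% low because it conditions each tract on
fitting its chromosome.

Chromosome ends produce a size-restriction effect with two distinct
readings. Segment-anchored: the mean observed size of end-touching tracts
is close to the unconditional mean (memorylessness of the exponential) and
can exceed the interior mean. Base-anchored: a base within 3 Mb of a
telomere can only be covered by a tract with no room to extend past the
end, so its covering tract is much smaller on average (≈ 18 vs ≈ 30 Mb at
m = 6). The base-anchored contrast is the one a causative variant samples,
and the reason telomere-proximal variants rank poorly — hence the caution
flag rather than an exclusion. `inspection_paradox_summary` reports both.

## Problem sizes

Simulation-based checks use cohorts of 200–600 samples at segment level
(the GRCh38 autosomes) and 6–9 samples at genotype level on a reduced
4 × 75 Mb genome, sizes at which every reported quantity is stable across
seeds to well within its asserted band; the full test suite and the
acceptance script each run in under a minute on one core.

## Known limitations

* The caller's boundaries stop at the outermost homozygous site, so called
  regions are slightly conservative at low site density.
* HR-score portability across cohorts with systematically different ROH
  content is assumed, not tested, matching its within-sample definition.
* Multi-allelic VCF records are skipped (biallelic SNVs carry the signal);
  no phasing, no inter-individual IBD, no depth-based CNV/LOH detection.
* The simulator's exchangeable samples cannot exhibit the real-data
  heterogeneity that makes combining metrics outperform the best single
  metric.
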