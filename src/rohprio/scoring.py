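"""Region-level homozygosity metrics and variant-level evidence verdicts.

A sample's regions of homozygosity are ranked by size (rank 1 = largest).
Three per-region metrics quantify how prominent a region is within its
sample:

* rank — position in the size ordering;
* relative size — region size divided by the size of the sample's largest
  region (1 for the largest region itself);
* HR score — the percentage of the sample's ROH bases lying in regions
  strictly smaller than the one under consideration (100 x sum of smaller
  region sizes / total ROH bases); the largest region of a sample scores
  highest, the smallest scores 0.

A homozygous candidate variant earns supporting evidence (the weakest ACMG
evidence tier) when it falls inside a region that is among the sample's ten
largest or has an HR score of at least 42.  Variants within 3 Mb of a
telomere get a caution flag — chromosome ends truncate segments (inspection
paradox), so proximity to a telomere should not be used to exclude a
variant — and samples with more than 8% of the genome in ROH get a second
caution; cautions annotate, they never veto.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    CandidateVariant,
    ChromosomeMap,
    RohRegion,
    SampleRohProfile,
)


@dataclass
class ScoringThresholds:
    """Decision thresholds; defaults are the published operating points.

    consang_min_fraction / consang_region_min_mb
        A sample is consanguineous when regions larger than
        ``consang_region_min_mb`` cover more than ``consang_min_fraction`` of
        the genome (the expected autozygosity of second-cousin offspring).
    top_k
        Evidence rule: variant in one of the ``top_k`` largest regions.
    hr_score_min
        Evidence rule: variant in a region with HR score at least this.
    telomere_mb
        Caution distance from a chromosome end.
    high_homozygosity_fraction
        Caution / exclusion threshold on the sample's ROH genome fraction.
    large_region_mb, relative_size_factor
        Summary-statistic cutoffs (regions > 5 Mb; regions no more than five
        times smaller than the sample's largest).
    evidence_rule
        How the two evidence criteria combine: "or" (default), "and",
        "top_k", or "hr_score".
    """

    consang_min_fraction: float = 0.015
    consang_region_min_mb: float = 3.0
    top_k: int = 10
    hr_score_min: float = 42.0
    telomere_mb: float = 3.0
    high_homozygosity_fraction: float = 0.08
    large_region_mb: float = 5.0
    relative_size_factor: float = 5.0
    evidence_rule: str = "or"

    def __post_init__(self):
        if not 0 < self.consang_min_fraction < 1:
            raise ValueError("consang_min_fraction must be in (0,1)")
        for name in (
            "consang_region_min_mb", "top_k", "hr_score_min", "telomere_mb",
            "high_homozygosity_fraction", "large_region_mb",
            "relative_size_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.evidence_rule not in ("or", "and", "top_k", "hr_score"):
            raise ValueError(f"unknown evidence_rule {self.evidence_rule!r}")


@dataclass(frozen=True)
class RegionScore:
    """Metrics for one region within its sample."""

    region: RohRegion
    rank: int
    size_bp: int
    relative_size: float
    hr_score: float
    in_top_k: bool
    telomere_flagged: bool


@dataclass(frozen=True)
class AnnotatedVariant:
    """A candidate variant joined to its containing region's scores."""

    variant: CandidateVariant
    region_score: Optional[RegionScore]
    in_roh: bool
    supporting_evidence: bool
    caution_telomere: bool
    caution_high_homozygosity: bool


def classify_consanguinity(
    profile: SampleRohProfile,
    chrom_map: ChromosomeMap,
    thresholds: Optional[ScoringThresholds] = None,
) -> SampleRohProfile:
    """Set genome_fraction and the consanguineous / high-homozygosity flags.

    ``genome_fraction`` uses all regions; the consanguinity test counts only
    regions strictly larger than ``consang_region_min_mb`` (3 Mb), because
    only multi-megabase segments indicate recent parental relatedness.
    Both comparisons are strict, as published.
    """
    t = thresholds or ScoringThresholds()
    if len(chrom_map) == 0:
        raise ValueError("empty chromosome map")
    genome = chrom_map.genome_size
    qualifying = sum(
        r.size_bp for r in profile.regions
        if r.size_bp > t.consang_region_min_mb * 1e6
    )
    profile.genome_fraction = profile.total_roh_bp / genome
    profile.consanguineous = qualifying / genome > t.consang_min_fraction
    profile.high_homozygosity = (
        profile.genome_fraction > t.high_homozygosity_fraction
    )
    return profile


def score_regions(
    profile: SampleRohProfile,
    chrom_map: ChromosomeMap,
    thresholds: Optional[ScoringThresholds] = None,
) -> list[RegionScore]:
    """Compute rank, relative size, HR score and flags for every region.

    Regions are ordered by size descending; ties are broken by genomic
    position (chromosome map order, then start) for reproducibility.  The HR
    score counts strictly smaller regions only, so tied sizes share an HR
    score.  Returned list is in rank order.  Empty profile -> empty list.
    """
    t = thresholds or ScoringThresholds()
    if not profile.regions:
        return []
    ordered = sorted(
        profile.regions,
        key=lambda r: (-r.size_bp, chrom_map.order(r.chrom), r.start),
    )
    total = sum(r.size_bp for r in ordered)
    largest = ordered[0].size_bp
    telo_bp = t.telomere_mb * 1e6

    # sum of strictly smaller region sizes, for every region at once
    sizes_desc = np.array([r.size_bp for r in ordered], dtype=np.int64)
    asc = np.sort(sizes_desc)
    csum = np.concatenate(([0], np.cumsum(asc)))
    smaller_sums = csum[np.searchsorted(asc, sizes_desc, side="left")]

    scores: list[RegionScore] = []
    for i, r in enumerate(ordered):
        smaller = int(smaller_sums[i])
        scores.append(
            RegionScore(
                region=r,
                rank=i + 1,
                size_bp=r.size_bp,
                relative_size=r.size_bp / largest,
                hr_score=100.0 * smaller / total,
                in_top_k=i + 1 <= t.top_k,
                telomere_flagged=(
                    chrom_map.region_telomere_distance(r.chrom, r.start, r.end)
                    < telo_bp
                ),
            )
        )
    return scores


def locate_region(
    scores: Sequence[RegionScore], chrom: str, pos: int
) -> Optional[RegionScore]:
    """Find the scored region containing a 1-based position (s < pos <= e)."""
    for sc in scores:
        if sc.region.chrom == chrom and sc.region.contains(pos):
            return sc
    return None


def annotate_variant(
    variant: CandidateVariant,
    profile: SampleRohProfile,
    scores: Sequence[RegionScore],
    chrom_map: ChromosomeMap,
    thresholds: Optional[ScoringThresholds] = None,
) -> AnnotatedVariant:
    """Attach region scores and the supporting-evidence verdict to a variant.

    Requires a homozygous variant on a mapped chromosome.  The verdict is
    ``in_roh and (in_top_k or hr_score >= hr_score_min)`` under the default
    rule; cautions are informational only.
    """
    t = thresholds or ScoringThresholds()
    if variant.zygosity != "homozygous":
        raise ValueError(
            f"only homozygous variants are scored, got {variant.zygosity!r}"
        )
    if variant.chrom not in chrom_map:
        raise KeyError(f"chromosome {variant.chrom!r} not in map")

    sc = locate_region(scores, variant.chrom, variant.pos)
    in_roh = sc is not None
    if in_roh:
        by_top = sc.in_top_k
        by_hr = sc.hr_score >= t.hr_score_min
        if t.evidence_rule == "or":
            evidence = by_top or by_hr
        elif t.evidence_rule == "and":
            evidence = by_top and by_hr
        elif t.evidence_rule == "top_k":
            evidence = by_top
        else:
            evidence = by_hr
    else:
        evidence = False

    caution_telomere = (
        chrom_map.telomere_distance(variant.chrom, variant.pos)
        < t.telomere_mb * 1e6
    )
    caution_high = bool(profile.high_homozygosity)

    return AnnotatedVariant(
        variant=variant,
        region_score=sc,
        in_roh=in_roh,
        supporting_evidence=evidence,
        caution_telomere=caution_telomere,
        caution_high_homozygosity=caution_high,
    )
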