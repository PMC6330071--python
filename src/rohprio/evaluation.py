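"""Cohort-level evaluation of homozygosity-based variant prioritization.

Given a labelled cohort — one causative homozygous variant per sample, each
sample with called ROH and region scores — this module measures how well
region prominence predicts where the causative variant lies:

* capture curve: for each rank cutoff k, the fraction of causative variants
  inside a region of rank <= k, against the fraction of pooled ROH bases
  those regions account for.  Prioritization helps exactly when variant
  capture runs ahead of the base fraction.
* base-weighted ROC / AUC per metric: sweeping a threshold over a region
  metric (rank, size, relative size, HR score, or their combination), the
  true-positive rate is the fraction of causative variants in qualifying
  regions and the false-positive rate is the fraction of pooled ROH bases
  admitted.  Under null placement (variants uniform over ROH bases) the
  curve is the diagonal and the AUC is 0.5.
* exclusion filters: samples with more than 8% of the genome in ROH and
  variants within 3 Mb of a telomere, the two conditions under which
  region rank loses power.
* Fisher's exact test on 2x2 tables (e.g. telomeric variants vs top-10
  membership) and the minimum sample size for a one-sample proportion test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CandidateVariant, ChromosomeMap, SampleRohProfile
from .scoring import (
    RegionScore,
    ScoringThresholds,
    classify_consanguinity,
    locate_region,
    score_regions,
)

logger = logging.getLogger("rohprio")

METRICS = ("rank", "size", "relative_size", "hr_score", "combined")


@dataclass
class CohortSample:
    """One labelled sample: profile, scores, and its causative variant."""

    sample_id: str
    profile: SampleRohProfile
    scores: list[RegionScore]
    variant: CandidateVariant
    containing: Optional[RegionScore]  # scored region holding the variant


@dataclass
class LabelledCohort:
    samples: list[CohortSample]

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class CohortEvaluation:
    """Evaluation outputs for one labelled cohort."""

    capture_table: pd.DataFrame
    auc_by_metric: dict[str, float]
    n_samples_used: int
    n_excluded: int
    exclusion_reasons: dict[str, int] = field(default_factory=dict)
    summary: Optional[pd.DataFrame] = None


def build_cohort(
    profiles: Sequence[SampleRohProfile],
    variants: Sequence[CandidateVariant],
    chrom_map: ChromosomeMap,
    thresholds: Optional[ScoringThresholds] = None,
) -> LabelledCohort:
    """Assemble a labelled cohort: classify, score, and locate each variant.

    ``variants`` must hold exactly one homozygous variant per profile,
    matched by ``sample_id``.
    """
    t = thresholds or ScoringThresholds()
    by_sample = {v.sample_id: v for v in variants}
    if len(by_sample) != len(variants):
        raise ValueError("exactly one causative variant per sample is required")
    samples: list[CohortSample] = []
    for profile in profiles:
        if profile.sample_id not in by_sample:
            raise ValueError(f"no variant for sample {profile.sample_id!r}")
        v = by_sample[profile.sample_id]
        classify_consanguinity(profile, chrom_map, t)
        scores = score_regions(profile, chrom_map, t)
        containing = locate_region(scores, v.chrom, v.pos)
        samples.append(CohortSample(profile.sample_id, profile, scores, v, containing))
    return LabelledCohort(samples)


# ---------------------------------------------------------------------------
# capture curve
# ---------------------------------------------------------------------------

def capture_curve(cohort: LabelledCohort, max_k: int = 25) -> pd.DataFrame:
    """Cumulative variant capture and ROH base share by region rank.

    Row k gives ``variant_capture`` = fraction of causative variants whose
    containing region has rank <= k, and ``base_fraction`` = fraction of all
    pooled ROH bases lying in regions of rank <= k.  Variants outside any
    ROH never contribute to capture.
    """
    if not cohort.samples:
        raise ValueError("empty cohort")
    n = len(cohort.samples)
    total_bases = sum(
        sc.size_bp for s in cohort.samples for sc in s.scores
    )
    rows = []
    for k in range(1, max_k + 1):
        captured = sum(
            1 for s in cohort.samples
            if s.containing is not None and s.containing.rank <= k
        )
        bases = sum(
            sc.size_bp for s in cohort.samples for sc in s.scores if sc.rank <= k
        )
        rows.append(
            {
                "k": k,
                "variant_capture": captured / n,
                "base_fraction": bases / total_bases if total_bases else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# base-weighted ROC / AUC
# ---------------------------------------------------------------------------

def _pooled_table(cohort: LabelledCohort) -> pd.DataFrame:
    """One row per region across the cohort with metrics and the variant flag."""
    rows = []
    for s in cohort.samples:
        for sc in s.scores:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "rank": sc.rank,
                    "size": sc.size_bp,
                    "relative_size": sc.relative_size,
                    "hr_score": sc.hr_score,
                    "size_bp": sc.size_bp,
                    "has_variant": sc is s.containing,
                }
            )
    return pd.DataFrame(rows)


def combined_score(cohort: LabelledCohort) -> pd.DataFrame:
    """Parameter-free combination of rank, size and relative size.

    Each metric is converted to its percentile rank pooled across every
    region of the cohort (rank inverted so that larger = better) and the
    three percentiles are averaged.  No fitting, hence no leakage.
    """
    table = _pooled_table(cohort)
    n = len(table)
    if n == 0:
        return table.assign(combined=[])
    pct = {}
    for metric, sign in (("rank", -1.0), ("size", 1.0), ("relative_size", 1.0)):
        pct[metric] = stats.rankdata(sign * table[metric].to_numpy()) / n
    table["combined"] = (pct["rank"] + pct["size"] + pct["relative_size"]) / 3.0
    return table


def roc_points(cohort: LabelledCohort, metric: str) -> np.ndarray:
    """ROC points (x = pooled ROH base fraction admitted, y = variant
    fraction captured) from a threshold sweep over one region metric.

    Rank is swept ascending (rank <= t qualifies); all other metrics
    descending (value >= t qualifies).  Returns an (m, 2) array starting at
    (0, 0) and ending at (1, 1).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    table = combined_score(cohort) if metric == "combined" else _pooled_table(cohort)
    if len(table) == 0:
        raise ValueError("cohort has no regions")
    n_variants = len(cohort.samples)
    total_bases = float(table["size_bp"].sum())

    values = table[metric].to_numpy(dtype=float)
    goodness = -values if metric == "rank" else values
    order = np.argsort(-goodness, kind="stable")
    g = goodness[order]
    bases = table["size_bp"].to_numpy(dtype=float)[order]
    hits = table["has_variant"].to_numpy(dtype=float)[order]

    cum_bases = np.cumsum(bases)
    cum_hits = np.cumsum(hits)
    # one ROC point per distinct threshold value: last index of each tie group
    boundary = np.nonzero(np.diff(g))[0]
    idx = np.concatenate([boundary, [len(g) - 1]])

    x = cum_bases[idx] / total_bases
    y = cum_hits[idx] / n_variants
    pts = np.column_stack((x, y))
    pts = np.vstack(([0.0, 0.0], pts))
    if not np.allclose(pts[-1], [1.0, 1.0]):
        pts = np.vstack((pts, [1.0, 1.0]))
    return pts


def auc_metric(cohort: LabelledCohort, metric: str) -> float:
    """Area under the base-weighted ROC for one metric (trapezoid rule)."""
    pts = roc_points(cohort, metric)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def all_aucs(cohort: LabelledCohort) -> dict[str, float]:
    return {m: auc_metric(cohort, m) for m in METRICS}


# ---------------------------------------------------------------------------
# exclusion filters
# ---------------------------------------------------------------------------

def apply_exclusions(
    cohort: LabelledCohort,
    chrom_map: ChromosomeMap,
    thresholds: Optional[ScoringThresholds] = None,
) -> tuple[LabelledCohort, dict[str, int]]:
    """Drop high-homozygosity samples and telomeric variants.

    A sample is removed when its ROH genome fraction exceeds the
    high-homozygosity threshold (reason ``high_homozygosity``) or when its
    causative variant lies within the telomere distance of a chromosome end
    (reason ``telomere``).  Retained samples are passed through untouched.
    Returns the filtered cohort and counts removed per reason.
    """
    t = thresholds or ScoringThresholds()
    kept: list[CohortSample] = []
    reasons: dict[str, int] = {"high_homozygosity": 0, "telomere": 0}
    for s in cohort.samples:
        gf = s.profile.genome_fraction
        if gf is None:
            classify_consanguinity(s.profile, chrom_map, t)
            gf = s.profile.genome_fraction
        if gf > t.high_homozygosity_fraction:
            reasons["high_homozygosity"] += 1
            continue
        if (
            chrom_map.telomere_distance(s.variant.chrom, s.variant.pos)
            < t.telomere_mb * 1e6
        ):
            reasons["telomere"] += 1
            continue
        kept.append(s)
    if not kept:
        logger.warning("all samples excluded by filters")
    reasons = {k: v for k, v in reasons.items() if v}
    return LabelledCohort(kept), reasons


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def fisher_exact_2x2(
    table: Sequence[Sequence[int]], sidedness: str = "two-sided"
) -> float:
    """Fisher's exact p-value for a 2x2 contingency table.

    ``sidedness``: "less" / "greater" (one-sided hypergeometric tail on the
    [0][0] cell) or "two-sided" (sum over tables at most as probable as the
    observed one).
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("cells must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    if sidedness not in ("less", "greater", "two-sided"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return float(stats.fisher_exact(arr, alternative=sidedness).pvalue)


def min_samples_for_proportion(
    p0: float,
    p1: float,
    alpha: float = 0.05,
    power: float = 0.8,
    method: str = "exact",
    max_n: int = 5000,
) -> int:
    """Smallest n at which a two-sided test of proportion p0 attains the
    requested power against alternative p1.

    ``method="exact"`` uses the exact binomial test (rejection region built
    from the null pmf, power summed under p1); ``method="normal"`` uses the
    standard two-sided one-sample normal approximation.  Exact-test power is
    not monotone in n; the first n reaching the target is returned.
    """
    if not (0 < p0 < 1 and 0 < p1 < 1) or p0 == p1:
        raise ValueError("need 0 < p0 != p1 < 1")
    if not 0 < power < 1:
        raise ValueError("power must be in (0,1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")

    if method == "normal":
        z_a = stats.norm.ppf(1 - alpha / 2)
        z_b = stats.norm.ppf(power)
        num = z_a * math.sqrt(p0 * (1 - p0)) + z_b * math.sqrt(p1 * (1 - p1))
        return math.ceil((num / abs(p1 - p0)) ** 2)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")

    for n in range(1, max_n + 1):
        k = np.arange(n + 1)
        pmf0 = stats.binom.pmf(k, n, p0)
        # two-sided exact p-value per outcome: mass of outcomes no more likely
        pvals = np.array(
            [pmf0[pmf0 <= pmf0[i] * (1 + 1e-12)].sum() for i in range(n + 1)]
        )
        reject = pvals <= alpha
        if not reject.any():
            continue
        achieved = stats.binom.pmf(k[reject], n, p1).sum()
        if achieved >= power:
            return n
    raise RuntimeError(f"power {power} not reached by n = {max_n}")


def cohort_summary(
    cohort: LabelledCohort,
    thresholds: Optional[ScoringThresholds] = None,
) -> pd.DataFrame:
    """Descriptive statistics: homozygosity levels, region sizes, and the
    fraction of variants in large / relatively large regions.

    Standard deviations are sample SDs (ddof=1; 0 for a single value).
    """
    t = thresholds or ScoringThresholds()
    if not cohort.samples:
        raise ValueError("empty cohort")
    gf = np.array(
        [s.profile.genome_fraction for s in cohort.samples], dtype=float
    )
    sizes = np.array(
        [sc.size_bp for s in cohort.samples for sc in s.scores], dtype=float
    )
    large = t.large_region_mb * 1e6

    def _sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    n_var = len(cohort.samples)
    var_in_large = sum(
        1 for s in cohort.samples
        if s.containing is not None and s.containing.size_bp > large
    )
    var_in_relative = sum(
        1 for s in cohort.samples
        if s.containing is not None
        and s.containing.relative_size >= 1.0 / t.relative_size_factor
    )
    rows = [
        ("mean_genome_fraction_pct", 100 * float(gf.mean())),
        ("sd_genome_fraction_pct", 100 * _sd(gf)),
        ("mean_region_size_mb", float(sizes.mean()) / 1e6 if len(sizes) else 0.0),
        ("sd_region_size_mb", _sd(sizes) / 1e6),
        ("fraction_regions_large", float((sizes > large).mean()) if len(sizes) else 0.0),
        ("fraction_variants_in_large_region", var_in_large / n_var),
        ("fraction_variants_within_relative_factor", var_in_relative / n_var),
    ]
    return pd.DataFrame(rows, columns=["statistic", "value"])


def evaluate_cohort(
    cohort: LabelledCohort,
    chrom_map: ChromosomeMap,
    thresholds: Optional[ScoringThresholds] = None,
    exclude: bool = False,
    max_k: int = 25,
) -> CohortEvaluation:
    """Full evaluation: optional exclusions, capture curve, AUCs, summary."""
    t = thresholds or ScoringThresholds()
    n_input = len(cohort.samples)
    reasons: dict[str, int] = {}
    if exclude:
        cohort, reasons = apply_exclusions(cohort, chrom_map, t)
    return CohortEvaluation(
        capture_table=capture_curve(cohort, max_k=max_k),
        auc_by_metric=all_aucs(cohort),
        n_samples_used=len(cohort.samples),
        n_excluded=n_input - len(cohort.samples),
        exclusion_reasons=reasons,
        summary=cohort_summary(cohort, t),
    )
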