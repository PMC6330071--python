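"""Run-of-homozygosity detection from a genotype stream.

The caller is a two-state hidden Markov model over the sites of one sample,
decoded by Viterbi independently per chromosome:

* state N (non-autozygous): genotypes follow Hardy-Weinberg proportions
  ``{(1-f)^2, 2f(1-f), f^2}`` at a site with alternate-allele frequency ``f``;
* state A (autozygous): the two haplotypes are identical by descent, so a
  genotype is homozygous for an allele drawn by frequency, miscalled
  heterozygous with a small error probability ``e``:
  ``{(1-f)(1-e), e, f(1-e)}``.

Missing genotypes emit probability 1 in both states.  Transitions depend on
the physical gap ``d`` between adjacent sites: leaving an autozygous segment
has per-bp rate ``1 / (expected_segment_mb * 1e6)``; the entry rate is scaled
so that the stationary autozygous fraction equals ``prior_autozygosity``.

Two mitigations for sequencing artefacts are built in: sites violating
Hardy-Weinberg equilibrium in the cohort can be dropped before calling
(`hwe_site_filter`), and isolated erroneous heterozygous calls inside a
genuine segment are absorbed by the emission error rate ``e`` rather than
splitting the segment.  Decoded segments are trimmed to their outermost
observed homozygous sites (no inter-site interpolation), optionally merged
across small gaps, then filtered by size, site count and het fraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .io_formats import (
    FALLBACK_ALT_FREQ,
    ChromosomeMap,
    GenotypeSite,
    RohRegion,
    SampleRohProfile,
)

logger = logging.getLogger("rohprio")

#: minimum cohort size for the Hardy-Weinberg site filter to be meaningful
HWE_MIN_SAMPLES = 20


@dataclass
class RohCallerParams:
    """Tunable parameters of the ROH caller.

    expected_segment_mb
        Mean length of an autozygous segment under the model; sets the
        segment-exit rate. Default 4 Mb.
    prior_autozygosity
        Stationary fraction of the genome autozygous. Default 0.02.
    het_error_rate
        Probability that a site inside an autozygous segment is (mis)called
        heterozygous. Default 0.01.
    min_region_mb, min_sites
        Post-decoding filters on region size and supporting site count.
    hwe_alpha
        Significance level of the per-site Hardy-Weinberg chi-square filter.
    max_het_fraction
        Maximum tolerated fraction of heterozygous sites in a reported region.
    """

    expected_segment_mb: float = 4.0
    prior_autozygosity: float = 0.02
    het_error_rate: float = 0.01
    min_region_mb: float = 1.0
    min_sites: int = 25
    hwe_alpha: float = 1e-6
    max_het_fraction: float = 0.05

    def __post_init__(self):
        for name in ("prior_autozygosity", "het_error_rate", "max_het_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.expected_segment_mb < self.min_region_mb:
            raise ValueError("expected_segment_mb must be >= min_region_mb")
        if self.expected_segment_mb <= 0 or self.min_region_mb <= 0:
            raise ValueError("segment lengths must be positive")
        if self.min_sites < 1:
            raise ValueError("min_sites must be >= 1")


def hwe_site_filter(
    counts: Sequence[tuple[int, int, int]] | tuple[int, int, int],
    alpha: float = 1e-6,
) -> np.ndarray | bool:
    """Keep/drop decision per site from cohort genotype counts.

    ``counts`` is one or many ``(n_hom_ref, n_het, n_hom_alt)`` triples.  A
    site is dropped iff the one-degree-of-freedom chi-square goodness-of-fit
    test against Hardy-Weinberg expectations gives ``p < alpha``.  Monomorphic
    sites are kept (no test is possible).  Returns a boolean (scalar input)
    or boolean array: True = keep.
    """
    arr = np.asarray(counts, dtype=float)
    scalar = arr.ndim == 1
    if scalar:
        arr = arr[None, :]
    if arr.shape[1] != 3 or (arr < 0).any():
        raise ValueError("counts must be non-negative (n_hom_ref, n_het, n_hom_alt)")
    n = arr.sum(axis=1)
    if (n == 0).any():
        raise ValueError("site with zero genotyped samples")

    p = (2 * arr[:, 0] + arr[:, 1]) / (2 * n)  # ref allele frequency
    q = 1.0 - p
    expected = np.column_stack((n * p**2, n * 2 * p * q, n * q**2))

    keep = np.ones(len(arr), dtype=bool)
    poly = (p > 0) & (p < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(
            expected > 0, (arr - expected) ** 2 / expected, 0.0
        ).sum(axis=1)
    pval = stats.chi2.sf(chi2, df=1)
    keep[poly] = pval[poly] >= alpha
    return bool(keep[0]) if scalar else keep


def cohort_genotype_counts(sites_by_sample: dict[str, list[GenotypeSite]]):
    """Tally (n_hom_ref, n_het, n_hom_alt) per (chrom, pos) across samples."""
    counts: dict[tuple[str, int], list[int]] = {}
    idx = {"hom_ref": 0, "het": 1, "hom_alt": 2}
    for sites in sites_by_sample.values():
        for s in sites:
            if s.gt_class == "missing":
                continue
            counts.setdefault((s.chrom, s.pos), [0, 0, 0])[idx[s.gt_class]] += 1
    return counts


def _viterbi_chrom(
    pos: np.ndarray,
    gt_code: np.ndarray,
    freq: np.ndarray,
    params: RohCallerParams,
) -> np.ndarray:
    """Viterbi decode one chromosome; returns boolean array, True = autozygous.

    gt_code: 0=hom_ref, 1=het, 2=hom_alt, 3=missing.
    """
    n = len(pos)
    e = params.het_error_rate
    f = np.clip(freq, 1e-6, 1 - 1e-6)

    # log-emission matrix, shape (n, 2): column 0 = A, column 1 = N
    log_em = np.zeros((n, 2))
    hom_ref = gt_code == 0
    het = gt_code == 1
    hom_alt = gt_code == 2
    log_em[hom_ref, 0] = np.log((1 - f[hom_ref]) * (1 - e))
    log_em[hom_ref, 1] = np.log((1 - f[hom_ref]) ** 2)
    log_em[het, 0] = math.log(e)
    log_em[het, 1] = np.log(2 * f[het] * (1 - f[het]))
    log_em[hom_alt, 0] = np.log(f[hom_alt] * (1 - e))
    log_em[hom_alt, 1] = np.log(f[hom_alt] ** 2)
    # missing: log(1) = 0 in both states

    prior = params.prior_autozygosity
    rate_an = 1.0 / (params.expected_segment_mb * 1e6)  # per bp, A -> N
    rate_na = rate_an * prior / (1.0 - prior)  # stationary fraction = prior

    gaps = np.diff(pos).astype(float)
    p_an = -np.expm1(-gaps * rate_an)
    p_na = -np.expm1(-gaps * rate_na)
    # transition log-probs per gap: [[A->A, A->N], [N->A, N->N]]
    log_t = np.empty((n - 1, 2, 2)) if n > 1 else np.empty((0, 2, 2))
    if n > 1:
        log_t[:, 0, 0] = np.log1p(-p_an)
        log_t[:, 0, 1] = np.log(p_an)
        log_t[:, 1, 0] = np.log(p_na)
        log_t[:, 1, 1] = np.log1p(-p_na)

    delta = np.empty((n, 2))
    psi = np.zeros((n, 2), dtype=np.int8)
    delta[0, 0] = math.log(prior) + log_em[0, 0]
    delta[0, 1] = math.log(1 - prior) + log_em[0, 1]
    for i in range(1, n):
        cand = delta[i - 1][:, None] + log_t[i - 1]  # (from, to)
        psi[i] = np.argmax(cand, axis=0)
        delta[i] = cand[psi[i], (0, 1)] + log_em[i]

    states = np.empty(n, dtype=np.int8)
    states[-1] = int(np.argmax(delta[-1]))
    for i in range(n - 2, -1, -1):
        states[i] = psi[i + 1][states[i + 1]]
    return states == 0  # True = autozygous


def _segment_from_run(
    chrom: str,
    pos: np.ndarray,
    gt_code: np.ndarray,
    i0: int,
    i1: int,
) -> Optional[RohRegion]:
    """Trim a decoded A-run [i0, i1] (inclusive site indices) to its outermost
    homozygous sites and build a region; None if no homozygous site."""
    idx = np.arange(i0, i1 + 1)
    hom = (gt_code[idx] == 0) | (gt_code[idx] == 2)
    if not hom.any():
        return None
    first = idx[hom][0]
    last = idx[hom][-1]
    span = np.arange(first, last + 1)
    observed = gt_code[span] != 3
    n_sites = int(observed.sum())
    n_het = int((gt_code[span] == 1).sum())
    # 1-based site positions p_first..p_last -> 0-based half-open interval
    # [p_first - 1, p_last) containing both endpoints under the join rule.
    return RohRegion(chrom, int(pos[first]) - 1, int(pos[last]), n_sites, n_het)


def merge_adjacent(
    regions: Sequence[RohRegion], max_gap_bp: int = 100_000
) -> list[RohRegion]:
    """Merge same-chromosome regions separated by at most ``max_gap_bp``.

    Input must be sorted and non-overlapping per chromosome; site and het
    counts are summed.  Idempotent.
    """
    out: list[RohRegion] = []
    for r in regions:
        if out and r.chrom == out[-1].chrom:
            prev = out[-1]
            if r.start < prev.start:
                raise ValueError("merge_adjacent requires sorted regions")
            if r.start - prev.end <= max_gap_bp:
                out[-1] = RohRegion(
                    prev.chrom,
                    prev.start,
                    max(prev.end, r.end),
                    prev.n_sites + r.n_sites,
                    prev.n_het + r.n_het,
                )
                continue
        out.append(r)
    return out


def call_roh(
    sites: Iterable[GenotypeSite],
    params: Optional[RohCallerParams] = None,
    chrom_map: Optional[ChromosomeMap] = None,
    sample_id: str = "sample",
    merge_gap_bp: int = 100_000,
) -> SampleRohProfile:
    """Call runs of homozygosity for one sample.

    ``sites`` must be sorted by (chromosome, position); chromosomes absent
    from ``chrom_map`` (e.g. sex chromosomes) are skipped.  Decoding is
    deterministic.  Returns a :class:`SampleRohProfile` whose regions are
    sorted, non-overlapping, and satisfy the size / site-count / het-fraction
    filters in ``params``.
    """
    params = params or RohCallerParams()

    gt_idx = {"hom_ref": 0, "het": 1, "hom_alt": 2, "missing": 3}
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    order: list[str] = []
    last: Optional[tuple[str, int]] = None
    n_missing_af = 0
    skipped_chroms: set[str] = set()

    for s in sites:
        if chrom_map is not None and s.chrom not in chrom_map:
            skipped_chroms.add(s.chrom)
            continue
        if last is not None:
            if s.chrom == last[0] and s.pos < last[1]:
                raise ValueError(
                    f"unsorted input: {s.chrom}:{s.pos} after {last[0]}:{last[1]}"
                )
            if s.chrom != last[0] and s.chrom in by_chrom:
                raise ValueError(f"unsorted input: chromosome {s.chrom} reappears")
        last = (s.chrom, s.pos)
        f = s.alt_freq
        if f is None:
            f = FALLBACK_ALT_FREQ
            n_missing_af += 1
        if s.chrom not in by_chrom:
            by_chrom[s.chrom] = []
            order.append(s.chrom)
        by_chrom[s.chrom].append((s.pos, gt_idx[s.gt_class], f))

    if skipped_chroms:
        logger.info("skipped chromosomes outside map: %s", sorted(skipped_chroms))
    if n_missing_af:
        logger.warning(
            "%d sites lacked an allele frequency; using fallback alt_freq=%.2f",
            n_missing_af, FALLBACK_ALT_FREQ,
        )
    if not by_chrom:
        logger.warning("no usable sites for sample %s; empty profile", sample_id)
        return SampleRohProfile(sample_id=sample_id)

    min_bp = params.min_region_mb * 1e6
    regions: list[RohRegion] = []
    for chrom in order:
        rows = by_chrom[chrom]
        pos = np.array([r[0] for r in rows], dtype=np.int64)
        gt = np.array([r[1] for r in rows], dtype=np.int8)
        freq = np.array([r[2] for r in rows], dtype=float)

        auto = _viterbi_chrom(pos, gt, freq, params)

        chrom_regions: list[RohRegion] = []
        i = 0
        n = len(auto)
        while i < n:
            if auto[i]:
                j = i
                while j + 1 < n and auto[j + 1]:
                    j += 1
                seg = _segment_from_run(chrom, pos, gt, i, j)
                if seg is not None:
                    chrom_regions.append(seg)
                i = j + 1
            else:
                i += 1

        if merge_gap_bp > 0:
            chrom_regions = merge_adjacent(chrom_regions, merge_gap_bp)

        for r in chrom_regions:
            if r.size_bp < min_bp or r.n_sites < params.min_sites:
                continue
            if r.n_sites > 0 and r.n_het / r.n_sites > params.max_het_fraction:
                continue
            if chrom_map is not None and r.end > chrom_map.length(chrom):
                r = RohRegion(
                    r.chrom, r.start, chrom_map.length(chrom), r.n_sites, r.n_het
                )
            regions.append(r)

    if chrom_map is not None:
        regions.sort(key=lambda r: (chrom_map.order(r.chrom), r.start))
    return SampleRohProfile(sample_id=sample_id, regions=regions)


def apply_hwe_filter(
    sites_by_sample: dict[str, list[GenotypeSite]],
    alpha: float = 1e-6,
) -> dict[str, list[GenotypeSite]]:
    """Drop HWE-violating sites from every sample's stream using cohort counts.

    Skipped with a warning when fewer than ``HWE_MIN_SAMPLES`` samples are
    available: the test is meaningless on a handful of genotypes.
    """
    if len(sites_by_sample) < HWE_MIN_SAMPLES:
        logger.warning(
            "HWE filter skipped: %d samples < %d required",
            len(sites_by_sample), HWE_MIN_SAMPLES,
        )
        return sites_by_sample
    counts = cohort_genotype_counts(sites_by_sample)
    keys = list(counts)
    keep_arr = hwe_site_filter([tuple(counts[k]) for k in keys], alpha)
    keep = {k for k, ok in zip(keys, keep_arr) if ok}
    dropped = len(keys) - len(keep)
    if dropped:
        logger.info("HWE filter dropped %d/%d sites", dropped, len(keys))
    return {
        sid: [s for s in sites if (s.chrom, s.pos) in keep or s.gt_class == "missing"]
        for sid, sites in sites_by_sample.items()
    }
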