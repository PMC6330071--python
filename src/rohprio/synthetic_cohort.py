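"""Synthetic consanguineous cohorts with known autozygosity ground truth.

Real cohorts of consanguineous patients with a known causative homozygous
variant are rarely shareable, so this module generates them.  Each sample
carries two classes of autozygous segment:

* recent segments — identity by descent around an inbreeding loop of ``m``
  meioses (m = 6: first-cousin parents, F = 1/16; m = 8: second cousins,
  F = 1/64).  Along the genetic map, autozygosity is a two-state Markov
  process: an autozygous tract ends at rate ``m`` per Morgan (mean interior
  tract length 100/m cM), and begins at rate ``m * F / (1 - F)``, which makes
  the stationary autozygous fraction exactly F.  Tracts are truncated at
  chromosome ends, so end-touching tracts are systematically shorter than
  interior ones (the inspection paradox).
* ancestral segments — short homozygous stretches from old haplotype
  sharing in the population: Poisson-distributed starts with exponential
  lengths (default mean 0.5 Mb, i.e. sub-megabase).

Genotypes are emitted at uniformly placed sites: inside any autozygous
segment one allele is drawn by frequency and the genotype is homozygous
(miscalled heterozygous with a small error probability); outside, genotypes
follow Hardy-Weinberg proportions.  Ancestral segments are genuinely
autozygous in the emission model, so a caller can separate the classes only
by size — size is the discriminating signal, not an artefact of emission.

One "causative" homozygous variant is planted per sample: uniformly over the
recent segments (the disease-enriched alternative), uniformly over all
autozygous bases (the evaluation null), or uniformly over the genome.
Everything is deterministic given the cohort seed; sample i uses seed + i.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    CandidateVariant,
    ChromosomeMap,
    RohRegion,
    SampleRohProfile,
    write_chrom_sizes,
    write_roh_bed,
)

logger = logging.getLogger("rohprio")

PLACEMENT_MODES = ("recent_segments", "uniform_roh_bases", "uniform_genome")

#: GRCh38 autosome lengths (bp) — a realistic default coordinate space.
GRCH38_AUTOSOMES: tuple[tuple[str, int], ...] = (
    ("chr1", 248956422), ("chr2", 242193529), ("chr3", 198295559),
    ("chr4", 190214555), ("chr5", 181538259), ("chr6", 170805979),
    ("chr7", 159345973), ("chr8", 145138636), ("chr9", 138394717),
    ("chr10", 133797422), ("chr11", 135086622), ("chr12", 133275309),
    ("chr13", 114364328), ("chr14", 107043718), ("chr15", 101991189),
    ("chr16", 90338345), ("chr17", 83257441), ("chr18", 80373285),
    ("chr19", 58617616), ("chr20", 64444167), ("chr21", 46709983),
    ("chr22", 50818468),
)


def default_autosome_map() -> ChromosomeMap:
    """GRCh38 autosomes — the default simulation coordinate space."""
    return ChromosomeMap(GRCH38_AUTOSOMES)


def small_test_map(n_chrom: int = 4, chrom_mb: float = 75.0) -> ChromosomeMap:
    """A reduced genome for fast genotype-level simulations."""
    return ChromosomeMap(
        (f"chr{i + 1}", int(chrom_mb * 1e6)) for i in range(n_chrom)
    )


@dataclass
class SimulationConfig:
    """Cohort simulation parameters.

    meioses
        Meioses in the inbreeding loop; 8 (second cousins) by default.
    inbreeding_f
        Expected autozygous genome fraction; ``1 / 2**(meioses - 2)`` when
        left unset (1/64 for m=8, 1/16 for m=6).
    cm_per_mb
        Constant genetic-map scaling (1 cM/Mb).
    ancestral_rate_per_100mb / ancestral_mean_mb
        Density and mean length of ancestral (sub-megabase) segments.
    site_density_per_mb
        Mean genotyped-site density for VCF emission.
    af_low / af_high
        Alternate-allele frequencies are Uniform(af_low, af_high) per site.
    het_error_in_roh
        Probability an in-segment site is miscalled heterozygous.
    placement_mode
        Where the causative variant goes (see module docstring).
    """

    chrom_map: ChromosomeMap = field(default_factory=default_autosome_map)
    n_samples: int = 100
    meioses: int = 8
    inbreeding_f: Optional[float] = None
    cm_per_mb: float = 1.0
    ancestral_rate_per_100mb: float = 5.0
    ancestral_mean_mb: float = 0.5
    site_density_per_mb: float = 100.0
    af_low: float = 0.05
    af_high: float = 0.5
    het_error_in_roh: float = 0.005
    placement_mode: str = "recent_segments"
    seed: int = 0

    def __post_init__(self):
        if self.meioses < 2:
            raise ValueError("meioses must be >= 2")
        if self.inbreeding_f is None:
            self.inbreeding_f = 1.0 / 2 ** (self.meioses - 2)
        if not 0.0 <= self.inbreeding_f < 1.0:
            raise ValueError("inbreeding_f must be in [0,1)")
        if self.placement_mode not in PLACEMENT_MODES:
            raise ValueError(
                f"placement_mode must be one of {PLACEMENT_MODES}"
            )
        for name in ("cm_per_mb", "site_density_per_mb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.ancestral_rate_per_100mb < 0 or self.ancestral_mean_mb <= 0:
            raise ValueError("ancestral segment parameters must be positive")
        if not 0.0 <= self.het_error_in_roh < 1.0:
            raise ValueError("het_error_in_roh must be in [0,1)")


@dataclass
class TruthRecord:
    """Ground truth for one simulated sample."""

    sample_id: str
    recent_segments: list[tuple[str, int, int]]
    ancestral_segments: list[tuple[str, int, int]]
    causative_variant: tuple[str, int]
    containing_segment_class: str  # recent | ancestral | none

    def all_segments(self) -> list[tuple[str, int, int]]:
        return merge_intervals(self.recent_segments + self.ancestral_segments)


def sample_rng(config: SimulationConfig, index: int) -> np.random.Generator:
    """Per-sample generator; sample i is seeded with ``seed + i`` (mod 2^31)."""
    return np.random.default_rng((config.seed + index) % 2**31)


def merge_intervals(
    intervals: Sequence[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    """Union of half-open intervals, sorted by (chrom, start)."""
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(intervals):
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            out.append((chrom, start, end))
    return out


# ---------------------------------------------------------------------------
# segment processes
# ---------------------------------------------------------------------------

def simulate_recent_segments(
    config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Autozygous tracts from the two-state Markov process along the map.

    Exit rate m per Morgan, entry rate m*F/(1-F) per Morgan, initial state
    autozygous with probability F; maximal tracts returned in bp.
    """
    f = config.inbreeding_f
    if f == 0.0:
        return []
    m = float(config.meioses)
    morgans_per_bp = config.cm_per_mb / 100.0 / 1e6
    rate_exit = m * morgans_per_bp  # per bp
    rate_enter = m * f / (1.0 - f) * morgans_per_bp

    segments: list[tuple[str, int, int]] = []
    for chrom, length in config.chrom_map.entries:
        pos = 0.0
        auto = rng.random() < f
        while pos < length:
            rate = rate_exit if auto else rate_enter
            sojourn = rng.exponential(1.0 / rate)
            nxt = min(pos + sojourn, float(length))
            if auto and int(nxt) > int(pos):
                segments.append((chrom, int(pos), int(nxt)))
            pos = nxt
            auto = not auto
    return segments


def simulate_ancestral_segments(
    config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Short ancestral tracts: Poisson starts, exponential lengths, clipped."""
    rate = config.ancestral_rate_per_100mb
    if rate == 0.0:
        return []
    mean_bp = config.ancestral_mean_mb * 1e6
    segments: list[tuple[str, int, int]] = []
    for chrom, length in config.chrom_map.entries:
        count = rng.poisson(rate * length / 1e8)
        if count == 0:
            continue
        starts = np.sort(rng.uniform(0, length, size=count))
        lens = rng.exponential(mean_bp, size=count)
        for s, l in zip(starts, lens):
            start = int(s)
            end = min(int(s + l) + 1, length)
            if end > start:
                segments.append((chrom, start, end))
    return merge_intervals(segments)


def is_truncated(
    segment: tuple[str, int, int], chrom_map: ChromosomeMap
) -> bool:
    """True when a segment touches either end of its chromosome."""
    chrom, start, end = segment
    return start == 0 or end == chrom_map.length(chrom)


def recent_segment_length_mle(
    records: Sequence[TruthRecord], chrom_map: ChromosomeMap
) -> float:
    """Mean recent-tract length in bp, by right-censored exponential MLE.

    Tracts running into a chromosome end are censored observations of the
    underlying exponential tract length: the unbiased estimator is total
    observed tract length divided by the number of tracts that terminate
    before an end.  A naive mean over interior tracts is biased downward
    because it conditions each tract on fitting its chromosome.
    """
    total = 0
    n_complete = 0
    for rec in records:
        for chrom, s, e in rec.recent_segments:
            total += e - s
            if e < chrom_map.length(chrom):
                n_complete += 1
    if n_complete == 0:
        raise ValueError("no uncensored recent segments observed")
    return total / n_complete


def inspection_paradox_summary(
    records: Sequence[TruthRecord],
    chrom_map: ChromosomeMap,
    telomere_mb: float = 3.0,
) -> dict[str, float]:
    """Quantify how chromosome ends restrict recent-segment size.

    Two views of the same size-biased-sampling effect:

    * segment-anchored: mean observed size of recent segments touching a
      chromosome end (``mean_truncated_mb``) vs segments wholly interior
      (``mean_interior_mb``).  With exponentially distributed tract lengths
      the clipped piece at an end is again exponential with the same mean
      (memorylessness), while interior segments are conditioned to fit their
      chromosome, so this contrast is weak and can even invert.
    * base-anchored: mean size of the segment covering a base within
      ``telomere_mb`` of a chromosome end (``mean_covering_telomeric_mb``)
      vs covering an interior base (``mean_covering_interior_mb``).  A base
      near a telomere can only be covered by a segment that has no room to
      extend past the end, so its covering segment is systematically
      smaller.  This is the view a causative variant samples, and the reason
      telomere-proximal variants land in smaller, lower-ranked regions.
    """
    t_bp = telomere_mb * 1e6
    trunc_sizes: list[int] = []
    interior_sizes: list[int] = []
    w_near = 0.0
    w_far = 0.0
    sz_near = 0.0
    sz_far = 0.0
    for rec in records:
        for seg in rec.recent_segments:
            chrom, s, e = seg
            size = e - s
            if is_truncated(seg, chrom_map):
                trunc_sizes.append(size)
            else:
                interior_sizes.append(size)
            length = chrom_map.length(chrom)
            near = (
                max(0.0, min(e, t_bp) - min(s, t_bp))
                + max(0.0, max(e, length - t_bp) - max(s, length - t_bp))
            )
            far = size - near
            w_near += near
            w_far += far
            sz_near += size * near
            sz_far += size * far
    return {
        "n_truncated": float(len(trunc_sizes)),
        "n_interior": float(len(interior_sizes)),
        "mean_truncated_mb": float(np.mean(trunc_sizes)) / 1e6
        if trunc_sizes else float("nan"),
        "mean_interior_mb": float(np.mean(interior_sizes)) / 1e6
        if interior_sizes else float("nan"),
        "mean_covering_telomeric_mb": sz_near / w_near / 1e6
        if w_near else float("nan"),
        "mean_covering_interior_mb": sz_far / w_far / 1e6
        if w_far else float("nan"),
    }


# ---------------------------------------------------------------------------
# genotype emission
# ---------------------------------------------------------------------------

def emit_genotypes(
    segments: Sequence[tuple[str, int, int]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[str, int, float, str]]:
    """Draw genotyped sites: (chrom, pos, alt_freq, gt_string).

    ``segments`` is the merged union of all autozygous intervals.  Sites are
    uniform at ``site_density_per_mb``; inside a segment the genotype is
    homozygous for an allele drawn by frequency (miscalled "0/1" with
    probability ``het_error_in_roh``); outside, Hardy-Weinberg.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in segments:
        by_chrom.setdefault(chrom, []).append((start, end))

    out: list[tuple[str, int, float, str]] = []
    for chrom, length in config.chrom_map.entries:
        n = rng.poisson(config.site_density_per_mb * length / 1e6)
        if n == 0:
            continue
        pos = np.unique(rng.integers(1, length + 1, size=n))
        f = rng.uniform(config.af_low, config.af_high, size=len(pos))

        segs = by_chrom.get(chrom, [])
        inside = np.zeros(len(pos), dtype=bool)
        if segs:
            starts = np.array([s for s, _ in segs])
            ends = np.array([e for _, e in segs])
            # 1-based pos p is inside [s, e) iff s < p <= e
            i = np.searchsorted(starts, pos, side="left") - 1
            valid = i >= 0
            inside[valid] = pos[valid] <= ends[i[valid]]

        u = rng.random(len(pos))
        err = rng.random(len(pos)) < config.het_error_in_roh
        for j in range(len(pos)):
            if inside[j]:
                if err[j]:
                    gt = "0/1"
                else:
                    gt = "1/1" if u[j] < f[j] else "0/0"
            else:
                if u[j] < (1 - f[j]) ** 2:
                    gt = "0/0"
                elif u[j] < (1 - f[j]) ** 2 + 2 * f[j] * (1 - f[j]):
                    gt = "0/1"
                else:
                    gt = "1/1"
            out.append((chrom, int(pos[j]), float(f[j]), gt))
    return out


def write_sample_vcf(
    records: Sequence[tuple[str, int, float, str]],
    sample_id: str,
    chrom_map: ChromosomeMap,
    path: str | Path,
) -> None:
    """Write emitted genotypes as a minimal valid single-sample VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in chrom_map.entries:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            '##INFO=<ID=AF,Number=A,Type=Float,'
            'Description="Alternate allele frequency">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample_id}\n"
        )
        for chrom, pos, af, gt in records:
            fh.write(
                f"{chrom}\t{pos}\t.\tA\tC\t.\tPASS\tAF={af:.4f}\tGT\t{gt}\n"
            )


# ---------------------------------------------------------------------------
# causative-variant placement
# ---------------------------------------------------------------------------

def plant_causative_variant(
    recent: Sequence[tuple[str, int, int]],
    ancestral: Sequence[tuple[str, int, int]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[str, int]:
    """Choose the causative variant's (chrom, 1-based pos).

    ``recent_segments``: length-weighted uniform over recent segments;
    ``uniform_roh_bases``: uniform over all autozygous bases;
    ``uniform_genome``: uniform anywhere.  Falls back to uniform_genome with
    a warning when the requested target set is empty.
    """
    mode = config.placement_mode
    if mode == "recent_segments":
        targets = list(recent)
    elif mode == "uniform_roh_bases":
        targets = merge_intervals(list(recent) + list(ancestral))
    else:
        targets = []

    if mode != "uniform_genome" and not targets:
        logger.warning(
            "no eligible segments for placement_mode=%s; "
            "falling back to uniform_genome", mode,
        )
        mode = "uniform_genome"

    if mode == "uniform_genome":
        lengths = np.array([l for _, l in config.chrom_map.entries], dtype=float)
        i = rng.choice(len(lengths), p=lengths / lengths.sum())
        chrom, length = config.chrom_map.entries[i]
        return chrom, int(rng.integers(1, length + 1))

    sizes = np.array([e - s for _, s, e in targets], dtype=float)
    i = rng.choice(len(targets), p=sizes / sizes.sum())
    chrom, start, end = targets[i]
    # uniform over the bases of [start, end): 1-based positions start+1..end
    return chrom, int(rng.integers(start + 1, end + 1))


def _interval_class(
    pos: tuple[str, int],
    recent: Sequence[tuple[str, int, int]],
    ancestral: Sequence[tuple[str, int, int]],
) -> str:
    chrom, p = pos
    for c, s, e in recent:
        if c == chrom and s < p <= e:
            return "recent"
    for c, s, e in ancestral:
        if c == chrom and s < p <= e:
            return "ancestral"
    return "none"


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def simulate_truth_record(config: SimulationConfig, index: int) -> TruthRecord:
    """Segments and causative variant for sample ``index`` (no genotypes)."""
    rng = sample_rng(config, index)
    recent = simulate_recent_segments(config, rng)
    ancestral = simulate_ancestral_segments(config, rng)
    # keep classes disjoint: ancestral bases already autozygous via a recent
    # segment are absorbed into it
    recent_merged = merge_intervals(recent)
    ancestral = _subtract(ancestral, recent_merged)
    variant = plant_causative_variant(recent_merged, ancestral, config, rng)
    return TruthRecord(
        sample_id=f"sample{index:03d}",
        recent_segments=recent_merged,
        ancestral_segments=ancestral,
        causative_variant=variant,
        containing_segment_class=_interval_class(variant, recent_merged, ancestral),
    )


def _subtract(
    intervals: Sequence[tuple[str, int, int]],
    remove: Sequence[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    """Set-difference of half-open interval lists (both sorted outputs)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in remove:
        by_chrom.setdefault(chrom, []).append((s, e))
    out: list[tuple[str, int, int]] = []
    for chrom, s, e in intervals:
        pieces = [(s, e)]
        for rs, re_ in by_chrom.get(chrom, []):
            nxt: list[tuple[int, int]] = []
            for ps, pe in pieces:
                if re_ <= ps or rs >= pe:
                    nxt.append((ps, pe))
                    continue
                if ps < rs:
                    nxt.append((ps, rs))
                if re_ < pe:
                    nxt.append((re_, pe))
            pieces = nxt
        out.extend((chrom, ps, pe) for ps, pe in pieces if pe > ps)
    return sorted(out)


def truth_profile(
    record: TruthRecord, chrom_map: ChromosomeMap
) -> SampleRohProfile:
    """A ROH profile taken directly from truth segments (oracle profiles)."""
    regions = [
        RohRegion(chrom, start, end)
        for chrom, start, end in record.all_segments()
    ]
    regions.sort(key=lambda r: (chrom_map.order(r.chrom), r.start))
    return SampleRohProfile(sample_id=record.sample_id, regions=regions)


def simulate_truth_cohort(
    config: SimulationConfig,
) -> tuple[list[SampleRohProfile], list[CandidateVariant], list[TruthRecord]]:
    """Segment-level cohort: truth profiles + planted variants, no genotypes.

    Fast path for evaluation studies where the ROH are taken as known.
    """
    profiles, variants, records = [], [], []
    for i in range(config.n_samples):
        rec = simulate_truth_record(config, i)
        records.append(rec)
        profiles.append(truth_profile(rec, config.chrom_map))
        chrom, pos = rec.causative_variant
        variants.append(CandidateVariant(chrom, pos, rec.sample_id, "homozygous"))
    return profiles, variants, records


def simulate_cohort(
    config: SimulationConfig,
    out_dir: str | Path,
    force: bool = False,
) -> list[TruthRecord]:
    """Full cohort simulation with files on disk.

    Writes, per sample, ``<id>.vcf`` (genotypes) and ``<id>.truth.bed``
    (autozygous segments); plus ``genome.sizes``, an evaluate-ready manifest
    ``cohort.tsv`` (sample_id, truth bed path, variant chrom, variant pos)
    and ``truth.json``.  Deterministic given ``config.seed``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty")
    out.mkdir(parents=True, exist_ok=True)

    write_chrom_sizes(config.chrom_map, out / "genome.sizes")
    records: list[TruthRecord] = []
    manifest_rows: list[str] = []
    for i in range(config.n_samples):
        rec = simulate_truth_record(config, i)
        records.append(rec)
        # emission uses an offset seed stream so genotype draws cannot
        # perturb segment/placement truth
        emission_rng = np.random.default_rng(
            (config.seed + i + 1_000_003) % 2**31
        )
        sites = emit_genotypes(rec.all_segments(), config, emission_rng)
        vcf_path = out / f"{rec.sample_id}.vcf"
        write_sample_vcf(sites, rec.sample_id, config.chrom_map, vcf_path)

        bed_path = out / f"{rec.sample_id}.truth.bed"
        write_roh_bed(truth_profile(rec, config.chrom_map), bed_path)
        chrom, pos = rec.causative_variant
        manifest_rows.append(f"{rec.sample_id}\t{bed_path.name}\t{chrom}\t{pos}")

    (out / "cohort.tsv").write_text("\n".join(manifest_rows) + "\n")
    (out / "truth.json").write_text(
        json.dumps(
            [
                {
                    "sample_id": r.sample_id,
                    "recent_segments": r.recent_segments,
                    "ancestral_segments": r.ancestral_segments,
                    "causative_variant": list(r.causative_variant),
                    "containing_segment_class": r.containing_segment_class,
                }
                for r in records
            ],
            indent=1,
        )
    )
    return records
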