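"""Shared domain types, coordinate conventions, and file formats.

Coordinate conventions used throughout the package:

* ROH intervals are 0-based half-open ``[start, end)`` (BED convention).
* Variant positions are 1-based (VCF convention).
* A variant at position ``p`` lies in region ``[s, e)`` iff ``s < p <= e``.

Formats handled here: two-column ``chrom.sizes`` text, VCF 4.x genotype
streams (via cyvcf2), and BED3+ ROH interval files with ``sample_id``,
``n_sites`` and ``n_het`` as extra columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

logger = logging.getLogger("rohprio")

GT_CLASSES = ("hom_ref", "het", "hom_alt", "missing")

#: chromosome names excluded by default from calling and from genome-size
#: denominators: hemizygosity on sex chromosomes mimics autozygosity.
DEFAULT_EXCLUDED_CHROMS = frozenset(
    {"chrX", "chrY", "chrM", "chrMT", "X", "Y", "M", "MT"}
)

#: fallback alternate-allele frequency when a site carries no AF annotation
#: and cohort counts are unavailable; a mid-range constant degrades gracefully.
FALLBACK_ALT_FREQ = 0.25


class ChromosomeMap:
    """Ordered chromosome names and lengths defining the coordinate space.

    The total genome size is the denominator for genome-fraction statistics,
    and chromosome ends define telomere positions.
    """

    def __init__(self, entries: Iterable[tuple[str, int]]):
        self.entries: list[tuple[str, int]] = []
        seen: set[str] = set()
        for name, length in entries:
            if name in seen:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            seen.add(name)
            self.entries.append((str(name), length))
        self._lengths = dict(self.entries)
        self._order = {name: i for i, (name, _) in enumerate(self.entries)}

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.entries]

    @property
    def genome_size(self) -> int:
        total = sum(length for _, length in self.entries)
        if total <= 0:
            raise ValueError("genome size must be positive")
        return total

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __len__(self) -> int:
        return len(self.entries)

    def length(self, name: str) -> int:
        try:
            return self._lengths[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} not in map") from None

    def order(self, name: str) -> int:
        """Rank of a chromosome in file order (for deterministic tie-breaks)."""
        try:
            return self._order[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} not in map") from None

    def telomere_distance(self, chrom: str, pos: int) -> int:
        """Distance in bp from a 1-based position to the nearer chromosome end."""
        length = self.length(chrom)
        return min(pos - 1, length - pos)

    def region_telomere_distance(self, chrom: str, start: int, end: int) -> int:
        """Distance in bp from a 0-based half-open interval to the nearer end."""
        length = self.length(chrom)
        return min(start, length - end)

    def subset(self, exclude: Iterable[str]) -> "ChromosomeMap":
        excl = set(exclude)
        return ChromosomeMap((n, l) for n, l in self.entries if n not in excl)


@dataclass(frozen=True)
class GenotypeSite:
    """One biallelic genotyped site for one sample."""

    chrom: str
    pos: int  # 1-based
    gt_class: str  # one of GT_CLASSES
    alt_freq: Optional[float] = None

    def __post_init__(self):
        if self.gt_class not in GT_CLASSES:
            raise ValueError(f"invalid gt_class {self.gt_class!r}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class CandidateVariant:
    """A candidate (putatively causative) variant for one sample."""

    chrom: str
    pos: int  # 1-based
    sample_id: str
    zygosity: str = "homozygous"  # homozygous | other


@dataclass(frozen=True)
class RohRegion:
    """One called run of homozygosity, 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    n_sites: int = 0
    n_het: int = 0

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"region end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise ValueError("region start must be >= 0")

    @property
    def size_bp(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """Join rule: 1-based variant position p is inside [start, end) iff
        start < p <= end."""
        return self.start < pos <= self.end


@dataclass
class SampleRohProfile:
    """All ROH called for one sample, plus sample-level classifications.

    ``genome_fraction`` and the two flags are filled in by
    :func:`rohprio.scoring.classify_consanguinity`.
    """

    sample_id: str
    regions: list[RohRegion] = field(default_factory=list)
    genome_fraction: Optional[float] = None
    consanguineous: Optional[bool] = None
    high_homozygosity: Optional[bool] = None

    @property
    def total_roh_bp(self) -> int:
        return sum(r.size_bp for r in self.regions)


# ---------------------------------------------------------------------------
# chrom.sizes
# ---------------------------------------------------------------------------

def read_chrom_sizes(
    path: str | Path,
    exclude: Iterable[str] = DEFAULT_EXCLUDED_CHROMS,
) -> ChromosomeMap:
    """Read a two-column whitespace-delimited chromosome-sizes file.

    File order is preserved. Chromosomes named in ``exclude`` (sex and
    mitochondrial contigs by default) are dropped; pass ``exclude=()`` to
    keep everything.
    """
    entries: list[tuple[str, int]] = []
    excl = set(exclude)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed line {lineno}: {raw!r}")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError:
                raise ValueError(
                    f"{path}: malformed length on line {lineno}: {parts[1]!r}"
                ) from None
            if name in excl:
                continue
            entries.append((name, length))
    if not entries:
        raise ValueError(f"{path}: no chromosomes parsed")
    return ChromosomeMap(entries)


def write_chrom_sizes(chrom_map: ChromosomeMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in chrom_map.entries:
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# VCF genotype streams
# ---------------------------------------------------------------------------

def read_genotype_sites(
    vcf_path: str | Path,
    sample_id: str,
    af_field: Optional[str] = "AF",
) -> Iterator[GenotypeSite]:
    """Stream one sample's biallelic genotype sites from a VCF.

    ``gt_class`` is derived from GT (0/0 -> hom_ref, 0/1 or 1/0 -> het,
    1/1 -> hom_alt, ./. -> missing).  ``alt_freq`` comes from the named INFO
    field when present, else from cohort genotype counts when the VCF is
    multi-sample, else is absent.  Multi-allelic records are skipped with a
    logged warning; an unsorted VCF or an unknown sample raises.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if sample_id not in samples:
        raise ValueError(f"sample {sample_id!r} not in VCF header ({vcf_path})")
    sidx = samples.index(sample_id)
    multi = len(samples) >= 2

    warned_multiallelic = False
    seen_chroms: set[str] = set()
    cur_chrom: Optional[str] = None
    last_pos = 0

    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    gt_map = {0: "hom_ref", 1: "het", 2: "missing", 3: "hom_alt"}

    for rec in vcf:
        if len(rec.ALT) != 1:
            if not warned_multiallelic:
                logger.warning(
                    "skipping multi-allelic record(s) (first at %s:%d)",
                    rec.CHROM, rec.POS,
                )
                warned_multiallelic = True
            continue
        if rec.CHROM != cur_chrom:
            if rec.CHROM in seen_chroms:
                raise ValueError(
                    f"unsorted VCF: chromosome {rec.CHROM} appears twice"
                )
            seen_chroms.add(rec.CHROM)
            cur_chrom = rec.CHROM
            last_pos = 0
        if rec.POS < last_pos:
            raise ValueError(
                f"unsorted VCF: {rec.CHROM}:{rec.POS} after {rec.CHROM}:{last_pos}"
            )
        last_pos = rec.POS

        gt_class = gt_map[int(rec.gt_types[sidx])]

        alt_freq: Optional[float] = None
        if af_field is not None:
            raw = rec.INFO.get(af_field)
            if raw is not None:
                alt_freq = float(raw[0] if isinstance(raw, tuple) else raw)
        if alt_freq is None and multi:
            gts = rec.gt_types
            n_ref = int((gts == 0).sum())
            n_het = int((gts == 1).sum())
            n_alt = int((gts == 3).sum())
            called = n_ref + n_het + n_alt
            if called > 0:
                alt_freq = (n_het + 2 * n_alt) / (2 * called)

        yield GenotypeSite(rec.CHROM, rec.POS, gt_class, alt_freq)


# ---------------------------------------------------------------------------
# ROH BED
# ---------------------------------------------------------------------------

def write_roh_bed(profile: SampleRohProfile, path: str | Path) -> None:
    """Write a profile's regions as BED3+ with sample_id, n_sites, n_het."""
    with open(path, "w") as fh:
        for r in profile.regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{profile.sample_id}"
                f"\t{r.n_sites}\t{r.n_het}\n"
            )


def read_roh_bed(path: str | Path, sample_id: Optional[str] = None) -> SampleRohProfile:
    """Read ROH intervals from BED3+; round-trips :func:`write_roh_bed`.

    Raises on ``end <= start`` or overlapping intervals on a chromosome.
    If ``sample_id`` is not given it is taken from column 4 (or the file stem).
    """
    regions: list[RohRegion] = []
    inferred: Optional[str] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(
                    f"{path}: line {lineno}: end {end} <= start {start}"
                )
            n_sites = int(parts[4]) if len(parts) > 4 else 0
            n_het = int(parts[5]) if len(parts) > 5 else 0
            if len(parts) > 3 and inferred is None:
                inferred = parts[3]
            regions.append(RohRegion(chrom, start, end, n_sites, n_het))

    by_chrom: dict[str, list[RohRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        rs_sorted = sorted(rs, key=lambda r: r.start)
        for a, b in zip(rs_sorted, rs_sorted[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{path}: overlapping intervals on {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    sid = sample_id or inferred or Path(path).stem
    return SampleRohProfile(sample_id=sid, regions=regions)


def sort_regions(
    regions: Sequence[RohRegion], chrom_map: Optional[ChromosomeMap] = None
) -> list[RohRegion]:
    """Sort regions genomically (chromosome map order, then start)."""
    if chrom_map is not None:
        return sorted(regions, key=lambda r: (chrom_map.order(r.chrom), r.start))
    return sorted(regions, key=lambda r: (r.chrom, r.start))
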