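import numpy as np
import pytest

from rohprio.io_formats import ChromosomeMap, GenotypeSite


@pytest.fixture
def chrom_map():
    """Small two-chromosome genome (150 Mb)."""
    return ChromosomeMap([("chr1", 100_000_000), ("chr2", 50_000_000)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def hwe_sites(
    rng,
    chrom: str,
    lo: int,
    hi: int,
    n: int,
    hom_tracts=(),
    het_error: float = 0.0,
):
    """Genotype sites on [lo, hi]: Hardy-Weinberg outside ``hom_tracts``
    (1-based inclusive position ranges), homozygous inside, with optional
    erroneous het calls inside tracts."""
    pos = np.sort(rng.integers(lo, hi + 1, size=n))
    pos = np.unique(pos)
    sites = []
    for p in pos:
        f = float(rng.uniform(0.1, 0.5))
        in_tract = any(a < p <= b for a, b in hom_tracts)
        if in_tract:
            if het_error > 0 and rng.random() < het_error:
                gt = "het"
            else:
                gt = "hom_alt" if rng.random() < f else "hom_ref"
        else:
            u = rng.random()
            p_rr = (1 - f) ** 2
            p_het = 2 * f * (1 - f)
            gt = "hom_ref" if u < p_rr else ("het" if u < p_rr + p_het else "hom_alt")
        sites.append(GenotypeSite(chrom, int(p), gt, f))
    return sites
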