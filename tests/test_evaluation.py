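"""Cohort evaluation: capture curves, base-weighted ROC, filters, statistics."""

import math

import numpy as np
import pytest

from rohprio.evaluation import (
    apply_exclusions,
    auc_metric,
    build_cohort,
    capture_curve,
    cohort_summary,
    combined_score,
    fisher_exact_2x2,
    min_samples_for_proportion,
    roc_points,
)
from rohprio.io_formats import CandidateVariant, ChromosomeMap, RohRegion, SampleRohProfile
from rohprio.synthetic_cohort import SimulationConfig, simulate_truth_cohort

MB = 1_000_000


def make_cohort(layout, chrom_map):
    """layout: list of (sample_id, [sizes_mb], variant_region_index or None).

    Regions are laid left to right; the variant lands mid-region (or far
    outside any region when the index is None).
    """
    profiles, variants = [], []
    for sid, sizes, vidx in layout:
        regions, cursor = [], 0
        for s in sizes:
            regions.append(RohRegion("chr1", cursor, cursor + int(s * MB)))
            cursor += int((s + 1) * MB)
        profiles.append(SampleRohProfile(sid, regions))
        if vidx is None:
            pos = chrom_map.length("chr1") - 1000
        else:
            r = regions[vidx]
            pos = (r.start + r.end) // 2
        variants.append(CandidateVariant("chr1", pos, sid, "homozygous"))
    return build_cohort(profiles, variants, chrom_map)


@pytest.fixture
def wide_map():
    return ChromosomeMap([("chr1", 4000 * MB)])


class TestCaptureCurve:
    def test_all_variants_in_rank1(self, wide_map):
        cohort = make_cohort(
            [("a", [10, 5], 0), ("b", [8, 2], 0)], wide_map
        )
        tab = capture_curve(cohort, max_k=3)
        assert tab.variant_capture.iloc[0] == 1.0

    def test_tie_break_forces_rank2(self, wide_map):
        # two equal 10 Mb regions; the variant sits in the positionally
        # later one, which the tie-break demotes to rank 2
        cohort = make_cohort(
            [("a", [10, 10], 1), ("b", [10, 10], 1)], wide_map
        )
        tab = capture_curve(cohort, max_k=2)
        assert tab.variant_capture.iloc[0] == 0.0
        assert tab.variant_capture.iloc[1] == 1.0
        assert tab.base_fraction.iloc[0] == pytest.approx(0.5)

    def test_null_placement_tracks_base_fraction(self):
        """Uniform-over-ROH placement: variant capture matches base share."""
        cfg = SimulationConfig(
            n_samples=200, placement_mode="uniform_roh_bases", seed=42
        )
        profiles, variants, _ = simulate_truth_cohort(cfg)
        cohort = build_cohort(profiles, variants, cfg.chrom_map)
        tab = capture_curve(cohort, max_k=25)
        # Monte-Carlo/binomial bound: per-k capture is a binomial proportion
        # around x(k); 3 sigma at worst x = 0.5, n = 200 is ~0.106, the
        # envelope below is the one a correct implementation stays within
        assert (tab.variant_capture - tab.base_fraction).abs().max() <= 0.08

    def test_fractions_nondecreasing(self, wide_map):
        cohort = make_cohort(
            [("a", [10, 5, 2], 1), ("b", [9, 3], None), ("c", [4], 0)],
            wide_map,
        )
        tab = capture_curve(cohort, max_k=6)
        assert (tab.variant_capture.diff().dropna() >= 0).all()
        assert (tab.base_fraction.diff().dropna() >= 0).all()
        assert tab.variant_capture.iloc[-1] <= 1.0


def auc_grid_oracle(pts, per_segment=256):
    """Independent AUC: fine-grid integration of each ROC polyline segment.

    Each straight segment between consecutive ROC points is sampled densely
    and integrated; vertical jumps (zero-width segments) carry no area.
    """
    total = 0.0
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        if x1 == x0:
            continue
        t = np.linspace(0.0, 1.0, per_segment)
        total += float(
            np.trapezoid(y0 + t * (y1 - y0), x0 + t * (x1 - x0))
        )
    return total


class TestAuc:
    def test_closed_form_two_point_curve(self, wide_map):
        # every variant in its sample's largest region; per-sample base
        # shares [0.6, 0.4] -> rank ROC points (0,0),(0.6,1),(1,1), AUC 0.7
        cohort = make_cohort(
            [("a", [6, 4], 0), ("b", [6, 4], 0)], wide_map
        )
        assert auc_metric(cohort, "rank") == pytest.approx(0.7)

    def test_all_variants_outside_roh(self, wide_map):
        cohort = make_cohort(
            [("a", [6, 4], None), ("b", [5], None)], wide_map
        )
        assert auc_metric(cohort, "rank") == pytest.approx(0.0)

    def test_matches_fine_grid_oracle_on_random_cohorts(self, rng, wide_map):
        for trial in range(100):
            n_samples = int(rng.integers(1, 6))
            layout = []
            for i in range(n_samples):
                sizes = list(rng.uniform(1, 30, size=int(rng.integers(1, 7))))
                vidx = (
                    None if rng.random() < 0.2
                    else int(rng.integers(0, len(sizes)))
                )
                layout.append((f"s{i}", sizes, vidx))
            cohort = make_cohort(layout, wide_map)
            for metric in ("rank", "size", "relative_size", "hr_score",
                           "combined"):
                pts = roc_points(cohort, metric)
                assert auc_metric(cohort, metric) == pytest.approx(
                    auc_grid_oracle(pts), abs=1e-9
                )

    def test_null_simulation_calibrates_to_half(self):
        cfg = SimulationConfig(
            n_samples=300, placement_mode="uniform_roh_bases", seed=9
        )
        profiles, variants, _ = simulate_truth_cohort(cfg)
        cohort = build_cohort(profiles, variants, cfg.chrom_map)
        for metric in ("rank", "size", "relative_size", "hr_score"):
            assert 0.45 <= auc_metric(cohort, metric) <= 0.55

    def test_unknown_metric_rejected(self, wide_map):
        cohort = make_cohort([("a", [5], 0)], wide_map)
        with pytest.raises(ValueError):
            auc_metric(cohort, "charisma")


class TestCombinedScore:
    def test_best_region_gets_maximum(self, wide_map):
        cohort = make_cohort([("a", [20, 10, 5], 0)], wide_map)
        table = combined_score(cohort)
        best = table.sort_values("rank").iloc[0]
        assert best.combined == table.combined.max()

    def test_median_region_near_half(self, wide_map):
        cohort = make_cohort([("a", list(range(1, 22)), 0)], wide_map)
        table = combined_score(cohort)
        mid = table[table["rank"] == 11]
        assert mid.combined.iloc[0] == pytest.approx(0.5, abs=0.05)

    def test_combined_tracks_singles_on_enriched_cohort(self):
        """The percentile-mean combination stays close to its inputs.

        Within a simulated sample the three metrics order regions
        identically (all are monotone in region size), so the combination
        can only reweight across samples: it tracks the mean of the single
        metrics rather than dominating the best one, while remaining far
        above the null 0.5.
        """
        cfg = SimulationConfig(
            n_samples=150, placement_mode="recent_segments", seed=21
        )
        profiles, variants, _ = simulate_truth_cohort(cfg)
        cohort = build_cohort(profiles, variants, cfg.chrom_map)
        singles = [
            auc_metric(cohort, m) for m in ("rank", "size", "relative_size")
        ]
        combined = auc_metric(cohort, "combined")
        assert combined >= np.mean(singles) - 0.02
        assert combined > 0.7


class TestExclusions:
    def test_high_homozygosity_sample_removed(self):
        cm = ChromosomeMap([("chr1", 1000 * MB)])
        cohort = make_cohort(
            [("hot", [50, 40], 0), ("cool", [10, 5], 0)], cm
        )
        filtered, reasons = apply_exclusions(cohort, cm)
        assert [s.sample_id for s in filtered.samples] == ["cool"]
        assert reasons == {"high_homozygosity": 1}

    def test_telomeric_variant_removed(self):
        cm = ChromosomeMap([("chr1", 1000 * MB)])
        profiles = [SampleRohProfile("t", [RohRegion("chr1", 0, 10 * MB)])]
        variants = [CandidateVariant("chr1", int(2.9 * MB), "t", "homozygous")]
        cohort = build_cohort(profiles, variants, cm)
        filtered, reasons = apply_exclusions(cohort, cm)
        assert not filtered.samples and reasons == {"telomere": 1}

    def test_clean_cohort_untouched(self, wide_map):
        cohort = make_cohort(
            [("a", [10, 5], 0), ("b", [8], 0)], wide_map
        )
        filtered, reasons = apply_exclusions(cohort, wide_map)
        assert filtered.samples == cohort.samples  # same objects, same scores
        assert reasons == {}


def fisher_enumeration_oracle(table, sidedness):
    """Exhaustive 2x2 enumeration at fixed margins (independent oracle)."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d

    def log_comb(n_, k_):
        return (
            math.lgamma(n_ + 1) - math.lgamma(k_ + 1) - math.lgamma(n_ - k_ + 1)
        )

    def prob(a_):
        b_, c_ = r1 - a_, c1 - a_
        d_ = n - r1 - c_
        if min(b_, c_, d_) < 0:
            return 0.0
        return math.exp(
            log_comb(r1, a_) + log_comb(n - r1, c_) - log_comb(n, c1)
        )

    p_obs = prob(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    if sidedness == "less":
        return sum(prob(k) for k in range(lo, a + 1))
    if sidedness == "greater":
        return sum(prob(k) for k in range(a, hi + 1))
    return sum(
        prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9)
    )


class TestFisher:
    def test_telomere_depletion_table(self):
        # combined-cohort reconstruction: 179 variants, 143 in top-10,
        # 8 telomeric of which 1 in top-10
        table = [[1, 7], [142, 29]]
        p = fisher_exact_2x2(table, "less")
        assert p == pytest.approx(fisher_enumeration_oracle(table, "less"),
                                  rel=1e-9)
        assert p == pytest.approx(5.5e-5, abs=5e-6)

    def test_no_association(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]], "two-sided") == pytest.approx(1.0)

    def test_extreme_table_two_sided_matches_enumeration(self):
        table = [[0, 10], [10, 0]]
        assert fisher_exact_2x2(table, "two-sided") == pytest.approx(
            fisher_enumeration_oracle(table, "two-sided"), rel=1e-9
        )

    def test_random_tables_match_enumeration(self, rng):
        for _ in range(30):
            t = rng.integers(1, 30, size=(2, 2)).tolist()
            for side in ("less", "greater", "two-sided"):
                assert fisher_exact_2x2(t, side) == pytest.approx(
                    fisher_enumeration_oracle(t, side), rel=1e-8
                )

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 5], [5, 5]])

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [5, 5]])


class TestPower:
    def test_large_effect_needs_few_samples(self):
        assert min_samples_for_proportion(0.5, 0.99) <= 10

    def test_sample_size_grows_as_effect_shrinks(self):
        ns = [
            min_samples_for_proportion(0.5, p1, method="normal")
            for p1 in (0.95, 0.85, 0.75, 0.65)
        ]
        assert ns == sorted(ns)

    def test_normal_approximation_worked_example(self):
        # ((1.95996*0.5 + 0.84162*sqrt(0.79*0.21)) / 0.29)^2 = 20.8 -> 21
        assert min_samples_for_proportion(
            0.5, 0.79, alpha=0.05, power=0.8, method="normal"
        ) == 21

    def test_exact_power_verified_by_direct_binomial(self):
        from scipy import stats

        n = min_samples_for_proportion(0.5, 0.8, alpha=0.05, power=0.8)
        k = np.arange(n + 1)
        pmf0 = stats.binom.pmf(k, n, 0.5)
        pvals = np.array(
            [pmf0[pmf0 <= pmf0[i] * (1 + 1e-12)].sum() for i in range(n + 1)]
        )
        achieved = stats.binom.pmf(k[pvals <= 0.05], n, 0.8).sum()
        assert achieved >= 0.8

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            min_samples_for_proportion(0.5, 0.5)
        with pytest.raises(ValueError):
            min_samples_for_proportion(0.5, 0.8, power=1.0)


class TestCohortSummary:
    def test_mean_and_sample_sd_convention(self):
        cm = ChromosomeMap([("chr1", 1000 * MB)])
        cohort = make_cohort([("a", [40], 0), ("b", [60], 0)], cm)
        summ = cohort_summary(cohort).set_index("statistic").value
        assert summ.mean_genome_fraction_pct == pytest.approx(5.0)
        assert summ.sd_genome_fraction_pct == pytest.approx(math.sqrt(2))

    def test_single_region_sd_zero(self, wide_map):
        cohort = make_cohort([("a", [10], 0)], wide_map)
        summ = cohort_summary(cohort).set_index("statistic").value
        assert summ.mean_region_size_mb == pytest.approx(10.0)
        assert summ.sd_region_size_mb == 0.0

    def test_fraction_of_large_regions(self, wide_map):
        cohort = make_cohort([("a", [6, 4], 0)], wide_map)
        summ = cohort_summary(cohort).set_index("statistic").value
        assert summ.fraction_regions_large == pytest.approx(0.5)
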