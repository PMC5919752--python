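"""Peak context classification, expression percentiles and the confidence
screen's flag/tier logic."""
import numpy as np
import pandas as pd
import pytest

from peakscreen import (ScreenConfig, classify_peak_context,
                        confidence_screen, expression_percentile)
from peakscreen.errors import UndefinedStatisticError
from peakscreen.intervals import GeneModel, GenomeInterval
from peakscreen.peaks import ConsolidatedRegion, PeakShapeMetrics
from peakscreen.screen import (GENE_BODY, INTERGENIC, PROMOTER, PeakContext,
                               TIER_AMBIGUOUS, TIER_HIGH, TIER_REJECTED)

GENES = [
    GeneModel("gPlus", GenomeInterval("c", 5000, 7000, "+")),
    GeneModel("gMinus", GenomeInterval("c", 10000, 12000, "-")),
]


class TestClassifyContext:
    def test_region_inside_gene_body(self):
        ctx = classify_peak_context(GenomeInterval("c", 5500, 5900), GENES)
        assert ctx.context_label == GENE_BODY
        assert ctx.overlapped_gene == "gPlus"
        assert ctx.gene_body_overlap_fraction == 1.0

    def test_region_upstream_of_tss_is_promoter(self):
        ctx = classify_peak_context(GenomeInterval("c", 4700, 4900), GENES,
                                    promoter_window=500)
        assert ctx.context_label == PROMOTER
        assert ctx.overlapped_gene == "gPlus"

    def test_minus_strand_promoter_is_downstream_in_coordinates(self):
        ctx = classify_peak_context(GenomeInterval("c", 12100, 12300), GENES,
                                    promoter_window=500)
        assert ctx.context_label == PROMOTER
        assert ctx.overlapped_gene == "gMinus"

    def test_gene_free_region_is_intergenic(self):
        ctx = classify_peak_context(GenomeInterval("c", 20000, 20400), GENES)
        assert ctx.context_label == INTERGENIC
        assert ctx.overlapped_gene is None

    def test_fraction_threshold_separates_body_from_promoter(self):
        # 40% inside the gene: below the 0.5 body cutoff, overlapping promoter
        region = GenomeInterval("c", 4880, 5080)
        ctx = classify_peak_context(region, GENES)
        assert ctx.context_label == PROMOTER
        assert ctx.gene_body_overlap_fraction == pytest.approx(0.4)


class TestExpressionPercentile:
    def test_unique_maximum_is_100(self):
        vals = [1.0, 5.0, 3.0, 9.0]
        assert expression_percentile(9.0, vals) == 100.0

    def test_mean_rank_of_median(self):
        # brute force: value 2 has rank 2 among {1,2,3} -> 100 * 2/3
        assert expression_percentile(2, [1, 2, 3]) == pytest.approx(200 / 3)

    def test_all_ties_mean_rank(self):
        n = 8
        assert expression_percentile(4.0, [4.0] * n) == pytest.approx(50 + 50 / n)

    def test_matches_brute_force_mean_rank(self):
        rng = np.random.default_rng(23)
        vals = rng.choice([0.0, 1.5, 2.5, 7.0], size=40)
        for v in np.unique(vals):
            less = np.sum(vals < v)
            equal = np.sum(vals == v)
            mean_rank = np.mean(np.arange(less + 1, less + equal + 1))
            assert expression_percentile(v, vals) == pytest.approx(
                100 * mean_rank / len(vals))

    def test_empty_reference_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            expression_percentile(1.0, [])


def good_metrics(height=50.0, fc=2.0):
    return PeakShapeMetrics(10, height, fc, 20, 500.0, 0.8)


def make_region(rid, start, end, metrics=None, callers=("A", "B"),
                support=None):
    return ConsolidatedRegion(
        rid, GenomeInterval("c", start, end), frozenset(callers),
        support if support is not None else {"c1": 3},
        metrics if metrics is not None else {"c1": good_metrics()})


@pytest.fixture
def fpkm_table():
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(20)] + ["gPlus", "gMinus", "gHot"]
    df = pd.DataFrame({"c1": rng.uniform(1, 50, len(genes))}, index=genes)
    df.loc["gHot", "c1"] = 1e4  # clear top expresser
    return df


def run_screen(regions, contexts, fpkm, negative=(), config=ScreenConfig()):
    ctx_map = {r.region_id: PeakContext(r.region_id, *contexts[r.region_id])
               for r in regions}
    return confidence_screen(regions, ctx_map, fpkm, all_callers={"A", "B"},
                             negative_regions=list(negative), config=config)


class TestConfidenceScreen:
    def test_clean_promoter_peak_is_high(self, fpkm_table):
        r = make_region("1", 4500, 4900)
        report = run_screen([r], {"1": (PROMOTER, "gPlus", 0.0)}, fpkm_table)
        assert report.tier("1") == TIER_HIGH

    def test_highly_expressed_gene_body_rejected_as_hyperchip(self, fpkm_table):
        r = make_region("1", 5000, 7000)
        report = run_screen([r], {"1": (GENE_BODY, "gHot", 1.0)}, fpkm_table)
        rec = report.records[0]
        assert rec.hyperchip_flag and rec.tier == TIER_REJECTED

    def test_negative_overlap_rejected(self, fpkm_table):
        r = make_region("1", 4500, 4900)
        report = run_screen([r], {"1": (PROMOTER, "gPlus", 0.0)}, fpkm_table,
                            negative=[GenomeInterval("c", 4800, 4950)])
        assert report.tier("1") == TIER_REJECTED

    def test_missing_caller_support_is_ambiguous(self, fpkm_table):
        r = make_region("1", 4500, 4900, callers=("A",))
        report = run_screen([r], {"1": (PROMOTER, "gPlus", 0.0)}, fpkm_table)
        assert report.tier("1") == TIER_AMBIGUOUS

    def test_no_metrics_rejected_with_reason(self, fpkm_table):
        r = make_region("1", 4500, 4900, metrics={}, support={})
        report = run_screen([r], {"1": (PROMOTER, "gPlus", 0.0)}, fpkm_table)
        rec = report.records[0]
        assert rec.tier == TIER_REJECTED and rec.reason == "no signal"

    def test_weak_signal_is_ambiguous(self, fpkm_table):
        r = make_region("1", 4500, 4900,
                        metrics={"c1": good_metrics(height=1.0, fc=0.05)})
        report = run_screen([r], {"1": (PROMOTER, "gPlus", 0.0)}, fpkm_table)
        assert report.tier("1") == TIER_AMBIGUOUS

    def test_hyperchip_monotone_in_expression(self, fpkm_table):
        """Raising the overlapped gene's expression can only turn the flag
        on, never off."""
        r = make_region("1", 5000, 7000)
        flags = []
        for expr in [1.0, 10.0, 100.0, 1e3, 1e5]:
            table = fpkm_table.copy()
            table.loc["gPlus", "c1"] = expr
            report = run_screen([r], {"1": (GENE_BODY, "gPlus", 1.0)}, table)
            flags.append(report.records[0].hyperchip_flag)
        assert flags == sorted(flags)

    def test_tiers_partition_regions(self, fpkm_table):
        regions = [
            make_region("1", 4500, 4900),
            make_region("2", 5000, 7000),
            make_region("3", 8000, 8400, callers=("A",)),
        ]
        contexts = {"1": (PROMOTER, "gPlus", 0.0),
                    "2": (GENE_BODY, "gHot", 1.0),
                    "3": (INTERGENIC, None, 0.0)}
        report = run_screen(regions, contexts, fpkm_table)
        tiers = [rec.tier for rec in report.records]
        assert sorted(tiers) == [TIER_AMBIGUOUS, TIER_HIGH, TIER_REJECTED]
        for rec in report.records:
            assert (rec.tier == TIER_HIGH) <= (not rec.hyperchip_flag
                                               and not rec.negative_flag)

    def test_order_invariance(self, fpkm_table):
        regions = [
            make_region("1", 4500, 4900),
            make_region("2", 5000, 7000),
            make_region("3", 8000, 8400, callers=("A",)),
        ]
        contexts = {"1": (PROMOTER, "gPlus", 0.0),
                    "2": (GENE_BODY, "gHot", 1.0),
                    "3": (INTERGENIC, None, 0.0)}
        fwd = run_screen(regions, contexts, fpkm_table)
        rev = run_screen(regions[::-1], contexts, fpkm_table)
        assert {r.region_id: r.tier for r in fwd.records} == \
               {r.region_id: r.tier for r in rev.records}
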