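"""Coverage summaries: parsing contracts, hand-computed examples, bin
placement, and brute-force / pooled-identity properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelval import coverage
from panelval.errors import ConfigurationError, DataError, ParseError
from panelval.model import COVERAGE_THRESHOLDS, TargetRegion


def _region(chrom="chr1", start=0, end=100, rid="r0", gene="G"):
    return TargetRegion(rid, gene, chrom, start, end, exons=((start, end),))


def _depth_map(values, chrom="chr1", start=0):
    return {(chrom, start + i + 1): v for i, v in enumerate(values)}


def _write_depth(tmp_path, rows, header="chrom\tpos\ttotal_depth\ts1"):
    p = tmp_path / "depth.tsv"
    p.write_text(header + "\n" + "\n".join(rows) + "\n")
    return p


class TestReadDepthTable:
    def test_well_formed_rows_parse(self, tmp_path):
        p = _write_depth(tmp_path, ["chr1\t1\t10\t10", "chr1\t2\t20\t20",
                                    "chr2\t1\t5\t5"])
        depths = coverage.read_depth_table(p)
        assert len(depths) == 3 and depths[("chr1", 2)] == 20

    def test_duplicate_locus_is_data_error(self, tmp_path):
        p = _write_depth(tmp_path, ["chr1\t1\t10\t10", "chr1\t1\t20\t20"])
        with pytest.raises(DataError, match="duplicate locus chr1:1"):
            coverage.read_depth_table(p)

    def test_non_integer_depth_names_line(self, tmp_path):
        p = _write_depth(tmp_path, ["chr1\t1\t10\t10", "chr1\t2\t12.5\t12.5"])
        with pytest.raises(ParseError, match=":3"):
            coverage.read_depth_table(p)

    def test_mean_over_sample_columns(self, tmp_path):
        p = _write_depth(tmp_path, ["chr1\t1\t30\t10\t20"],
                         header="chrom\tpos\ttotal_depth\ts1\ts2")
        assert coverage.read_depth_table(p)[("chr1", 1)] == 15
        assert coverage.read_depth_table(p, statistic="total")[("chr1", 1)] == 30


class TestSummarizeRegion:
    def test_constant_depth(self):
        s = coverage.summarize_region(_region(), _depth_map([250] * 100))
        assert s.mean == 250 and s.q1 == s.median == s.q3 == 250
        assert s.pct_at_least[250] == 100 and s.pct_at_least[500] == 0

    def test_hand_computed_five_bases(self):
        s = coverage.summarize_region(
            _region(end=5), _depth_map([0, 10, 20, 50, 100]))
        assert s.mean == 36
        assert s.pct_at_least[1] == 80
        assert s.pct_at_least[10] == 80
        assert s.pct_at_least[20] == 60
        assert s.pct_at_least[50] == 40
        assert s.pct_at_least[100] == 20

    def test_missing_bases_count_as_zero(self):
        s = coverage.summarize_region(_region(end=10), _depth_map([100] * 5))
        assert s.mean == 50 and s.pct_at_least[1] == 50

    def test_zero_length_region_rejected(self):
        with pytest.raises(ConfigurationError):
            TargetRegion("r", "G", "chr1", 5, 5)

    def test_threshold_fractions_monotone(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.integers(0, 2000, size=40)
            s = coverage.summarize_region(_region(end=40), _depth_map(vals))
            pcts = [s.pct_at_least[t] for t in COVERAGE_THRESHOLDS]
            assert pcts == sorted(pcts, reverse=True)
            assert s.q1 <= s.median <= s.q3


class TestBinRegions:
    def test_boundary_placement_above_top(self):
        s = coverage.summarize_region(_region(end=10), _depth_map([1502] * 10))
        bins = coverage.bin_regions([s])
        assert len(bins) == 1 and bins[0].label == ">1500"
        assert bins[0].n_regions == 1

    def test_low_depth_regions_share_lowest_bin(self):
        ss = [coverage.summarize_region(_region(end=10, rid=f"r{i}"),
                                        _depth_map([d] * 10))
              for i, d in enumerate([68, 82])]
        bins = coverage.bin_regions(ss)
        assert bins[0].label == "<100" and bins[0].n_regions == 2

    @pytest.mark.parametrize("mean, label", [
        (0, "<100"), (99.9, "<100"), (100, "100–199"), (1499, "1400–1499"),
        (1500, ">1500")])
    def test_bin_label_edges(self, mean, label):
        assert coverage.bin_label(mean) == label

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigurationError):
            coverage.bin_regions([])

    def test_synthetic_regions_counts_conserved(self, small_dataset):
        depth_map = {key: small_dataset.depth_columns["AA001"][i]
                     for i, key in enumerate(small_dataset.depth_index)}
        summaries = [coverage.summarize_region(t, depth_map)
                     for t in small_dataset.targets]
        bins = coverage.bin_regions(summaries)
        assert sum(b.n_regions for b in bins) == len(small_dataset.targets)


class TestPanelSummary:
    def test_single_region_identity(self):
        dm = _depth_map([5, 10, 700, 0, 3])
        r = _region(end=5)
        single = coverage.summarize_region(r, dm)
        pooled = coverage.panel_summary([r], dm)
        assert pooled.mean == single.mean
        assert pooled.pct_at_least == single.pct_at_least
        assert (pooled.q1, pooled.median, pooled.q3) == (
            single.q1, single.median, single.q3)

    def test_two_equal_regions_pooled(self):
        dm = {**_depth_map([100] * 10, chrom="chr1"),
              **_depth_map([300] * 10, chrom="chr2")}
        regions = [_region(chrom="chr1", end=10, rid="a"),
                   _region(chrom="chr2", end=10, rid="b")]
        pooled = coverage.panel_summary(regions, dm)
        assert pooled.mean == 200 and pooled.pct_at_least[250] == 50

    def test_all_zero_panel(self):
        r = _region(end=10)
        pooled = coverage.panel_summary([r], {})
        assert all(v == 0 for v in pooled.pct_at_least.values())

    def test_pooled_mean_equals_length_weighted_mean(self):
        rng = np.random.default_rng(1)
        regions, dm = [], {}
        for i, ln in enumerate([7, 13, 31]):
            chrom = f"chr{i}"
            vals = rng.integers(0, 1200, size=ln)
            regions.append(_region(chrom=chrom, end=ln, rid=f"r{i}"))
            dm.update(_depth_map(vals, chrom=chrom))
        pooled = coverage.panel_summary(regions, dm)
        summaries = [coverage.summarize_region(r, dm) for r in regions]
        weighted = (sum(s.mean * s.length for s in summaries)
                    / sum(s.length for s in summaries))
        assert pooled.mean == pytest.approx(weighted, abs=1e-12)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=3000),
                min_size=1, max_size=50))
def test_summary_matches_brute_force_recount(values):
    """On random small regions the summary equals an explicit per-base
    recount."""
    s = coverage.summarize_region(
        _region(end=len(values)), _depth_map(values))
    assert s.mean == pytest.approx(sum(values) / len(values))
    for t in COVERAGE_THRESHOLDS:
        expected = 100 * sum(1 for v in values if v >= t) / len(values)
        assert s.pct_at_least[t] == pytest.approx(expected)
    assert s.median == pytest.approx(float(np.median(values)))
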