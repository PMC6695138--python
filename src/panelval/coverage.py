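"""Depth-of-coverage summaries for targeted panel regions.

Per-region summaries report the arithmetic mean depth, quartiles
(linear interpolation between order statistics, the "type 7"
convention), and the percent of bases covered at or above each
threshold in :data:`~panelval.model.COVERAGE_THRESHOLDS`. Regions are
then grouped into 100X-wide mean-depth bins (closed-left, open top bin
at 1500X) mirroring the standard panel-QC table layout. Bases absent
from the depth table count as depth 0, so uncovered target bases
depress both the mean and the >=1X fraction.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import ConfigurationError, DataError, ParseError
from .model import (COVERAGE_THRESHOLDS, DepthBinProfile,
                    RegionCoverageSummary, TargetRegion)

BIN_WIDTH = 100
BIN_TOP = 1500


def read_depth_table(path, statistic: str = "mean") -> dict:
    """Parse a per-base depth TSV into a map (chrom, pos) -> depth.

    Expected columns: chrom, pos (1-based), total_depth, then one
    integer depth column per sample. ``statistic`` selects the map
    value: ``"mean"`` (total over sample columns / n samples, or
    total_depth when no per-sample columns exist) or ``"total"``.
    """
    if statistic not in ("mean", "total"):
        raise ConfigurationError(f"unknown depth statistic {statistic!r}")
    depths: dict = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["chrom", "pos", "total_depth"]:
            raise ParseError(f"{path}: unexpected header {header[:3]}")
        n_samples = len(header) - 3
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(f"{path}:{lineno}: expected "
                                 f"{len(header)} fields, got {len(fields)}")
            try:
                pos = int(fields[1])
                values = [int(v) for v in fields[2:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            key = (fields[0], pos)
            if key in depths:
                raise DataError(f"{path}:{lineno}: duplicate locus "
                                f"{fields[0]}:{pos}")
            if statistic == "total" or n_samples == 0:
                depths[key] = values[0]
            else:
                depths[key] = sum(values[1:]) / n_samples
    return depths


def region_depths(region: TargetRegion, depths: dict) -> np.ndarray:
    """Per-base depth vector over [start, end); missing bases are 0."""
    return np.array(
        [depths.get((region.chrom, p), 0) for p in
         range(region.start + 1, region.end + 1)],
        dtype=float,
    )


def _summarize(region_id: str, gene: str, vec: np.ndarray) -> RegionCoverageSummary:
    if vec.size == 0:
        raise ConfigurationError(f"region {region_id} has zero length")
    q1, med, q3 = np.percentile(vec, [25, 50, 75])
    pct = {t: 100.0 * float(np.count_nonzero(vec >= t)) / vec.size
           for t in COVERAGE_THRESHOLDS}
    return RegionCoverageSummary(
        region_id=region_id, gene=gene, length=int(vec.size),
        mean=float(vec.mean()), q1=float(q1), median=float(med),
        q3=float(q3), pct_at_least=pct,
    )


def summarize_region(region: TargetRegion, depths: dict) -> RegionCoverageSummary:
    """Coverage summary of one target region against a depth map."""
    return _summarize(region.region_id, region.gene, region_depths(region, depths))


def panel_summary(regions, depths, label: str = "panel") -> RegionCoverageSummary:
    """Base-pair-weighted summary over a set of regions.

    Pools the per-base depth multiset of every region, so the mean is
    the length-weighted mean of region means and quartiles are those of
    the pooled distribution (not quartiles of means).
    """
    regions = list(regions)
    if not regions:
        raise ConfigurationError("panel_summary requires at least one region")
    pooled = np.concatenate([region_depths(r, depths) for r in regions])
    return _summarize(label, label, pooled)


def bin_label(mean_depth: float) -> str:
    if mean_depth < BIN_WIDTH:
        return f"<{BIN_WIDTH}"
    if mean_depth >= BIN_TOP:
        return f">{BIN_TOP}"
    lo = int(mean_depth // BIN_WIDTH) * BIN_WIDTH
    return f"{lo}–{lo + BIN_WIDTH - 1}"


def bin_regions(summaries) -> list[DepthBinProfile]:
    """Group region summaries into 100X mean-depth bins.

    Bins are [0,100), [100,200), ..., [1400,1500), [1500, inf),
    closed-left. Per-bin threshold percentages are unweighted means over
    member regions; empty bins are omitted from the output.
    """
    summaries = list(summaries)
    if not summaries:
        raise ConfigurationError("bin_regions requires a non-empty list")
    edges = [(lo, lo + BIN_WIDTH) for lo in range(0, BIN_TOP, BIN_WIDTH)]
    edges.append((BIN_TOP, math.inf))
    profiles = []
    for lo, hi in edges:
        members = [s for s in summaries if lo <= s.mean < hi]
        if not members:
            continue
        mean_pct = {
            t: float(np.mean([m.pct_at_least[t] for m in members]))
            for t in COVERAGE_THRESHOLDS
        }
        profiles.append(
            DepthBinProfile(
                label=bin_label(lo if lo < BIN_TOP else BIN_TOP),
                low=float(lo), high=float(hi),
                n_regions=len(members), mean_pct_at_least=mean_pct,
            )
        )
    return profiles
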