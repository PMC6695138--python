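"""Core domain types for targeted-panel analytical validation.

Coordinate conventions: target regions are 0-based half-open (BED);
variant positions are 1-based (VCF). Allele-frequency values are
proportions in [0, 0.5]; ``None`` means the variant is absent from the
population reference table and is treated as rare by the MAF filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .errors import ConfigurationError

#: functional classes retained by the positional filter regardless of
#: distance to an intron-exon boundary
CODING_CLASSES = frozenset({"nonsynonymous", "synonymous", "frameshift"})

#: depth thresholds (X) used in coverage summaries
COVERAGE_THRESHOLDS = (1, 10, 20, 50, 100, 250, 500, 1000, 10000)


@dataclass(frozen=True)
class TargetRegion:
    """A captured interval with gene identity and exon structure.

    ``exons`` holds the exonic sub-intervals in absolute 0-based
    half-open coordinates; intronic flank bases are the remainder of
    [start, end). A fully exonic region has a single exon spanning it.
    """

    region_id: str
    gene: str
    chrom: str
    start: int
    end: int
    accession: str = "."
    exons: tuple[tuple[int, int], ...] = ()
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ConfigurationError(
                f"region {self.region_id}: start {self.start} >= end {self.end}"
            )
        for es, ee in self.exons:
            if not (self.start <= es < ee <= self.end):
                raise ConfigurationError(
                    f"region {self.region_id}: exon [{es},{ee}) outside region"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos1: int) -> bool:
        """Whether a 1-based position falls inside the region."""
        return self.start < pos1 <= self.end

    def boundary_distance(self, pos1: int) -> int:
        """Distance (bp) from a 1-based position to the nearest
        intron-exon boundary; 0 for exonic positions.

        Matches HGVS intron-offset counting: the first intronic base
        after an exon (c.X+1) and the base just before one (c.X-1) are
        both at distance 1.
        """
        p = pos1 - 1  # 0-based
        if not self.exons:
            return 0
        best = None
        for es, ee in self.exons:
            if es <= p < ee:
                return 0
            d = es - p if p < es else p - ee + 1
            best = d if best is None else min(best, d)
        return best


@dataclass
class VariantCall:
    """One per-sample, bi-allelic variant call with its annotations."""

    sample: str
    gene: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype: str  # "het" | "hom"
    dp: int
    ad_alt: int
    gq: int = 99
    group: str = "."  # ancestry label
    func_class: str = "other"
    boundary_distance: Optional[int] = None  # bp, intronic calls
    dna_change: str = "."
    aa_change: str = "."
    prediction: str = "."
    clinvar: str = "."
    mafs: dict = field(default_factory=dict)  # group -> proportion | None
    # pipeline-stage annotations
    confidence: Optional[str] = None  # "high" | "low"
    excluded_low_ab: Optional[bool] = None
    label: Optional[str] = None  # "TP" | "FP" | "unresolved"

    def __post_init__(self) -> None:
        if not (0 <= self.ad_alt <= self.dp):
            raise ConfigurationError(
                f"{self.chrom}:{self.pos} {self.sample}: AD_alt {self.ad_alt} "
                f"outside [0, DP={self.dp}]"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def allele_balance(self) -> float:
        """Alt allelic depth over total depth; undefined at DP=0."""
        if self.dp == 0:
            raise ZeroDivisionError("allele balance undefined at DP=0")
        return self.ad_alt / self.dp

    @property
    def is_pathogenic(self) -> bool:
        """Clinical-significance label indicates pathogenicity.

        Labels are opaque pass-through strings; only 'pathogenic' and
        'risk factor' (case-insensitive) count for true-negative logic.
        """
        lab = self.clinvar.strip().lower()
        return lab in {"pathogenic", "risk factor"}

    def annotated(self, **kw) -> "VariantCall":
        return replace(self, **kw)


@dataclass(frozen=True)
class TruthRecord:
    """Orthogonal-assay outcome for one sample.

    Sanger records are variant-scoped (outcome ``confirmed`` /
    ``not_confirmed``); clinical records are gene-scoped (outcome
    ``negative_full_screen`` / ``positive`` / ``negative_targeted``,
    the last meaning a targeted familial-variant test that can never
    establish a true negative).
    """

    sample: str
    scope: str  # "variant" | "gene"
    gene: str = "."
    outcome: str = "."
    key: Optional[tuple[str, int, str, str]] = None

    def __post_init__(self) -> None:
        if self.scope == "gene" and self.outcome == "positive" and self.key is None:
            raise ConfigurationError(
                f"clinical positive for {self.sample}/{self.gene} lacks a variant key"
            )


@dataclass(frozen=True)
class TriageThresholds:
    """Depth / allele-balance cutoffs for call-confidence triage.

    high confidence requires DP >= ``high_conf_depth`` AND
    AB >= ``high_conf_ab`` (both inclusive); the exclusion filter drops
    calls with AB <= ``exclusion_ab``.
    """

    high_conf_depth: int = 100
    high_conf_ab: float = 0.40
    exclusion_ab: float = 0.20

    def __post_init__(self) -> None:
        if self.high_conf_depth < 1:
            raise ConfigurationError("high_conf_depth must be >= 1")
        if not 0 < self.exclusion_ab < self.high_conf_ab < 1:
            raise ConfigurationError(
                "thresholds must satisfy 0 < exclusion_ab < high_conf_ab < 1"
            )


@dataclass(frozen=True)
class RegionCoverageSummary:
    """Per-region (or pooled) depth-of-coverage summary."""

    region_id: str
    gene: str
    length: int
    mean: float
    q1: float
    median: float
    q3: float
    pct_at_least: dict  # threshold (X) -> percent of bases


@dataclass(frozen=True)
class DepthBinProfile:
    """One row of a depth-bin profile: regions grouped by mean depth."""

    label: str
    low: float
    high: float  # inf for the open top bin
    n_regions: int
    mean_pct_at_least: dict  # threshold -> unweighted mean percent


@dataclass(frozen=True)
class ConcordanceSummary:
    """Per-gene confusion counts and derived metrics (NaN = undefined)."""

    gene: str
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    fdr: float
    tp_dp_mean: float
    tp_ab_mean: float
    fp_dp_mean: float
    fp_ab_mean: float
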