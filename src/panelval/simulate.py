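"""Seeded synthetic panel-screening datasets.

Generates everything the downstream analysis consumes — target regions,
per-base depth tables, variant calls, a population MAF table, and
orthogonal truth tables — with the statistical structure a HaloPlex-style
capture produces:

* region mean depth is log-normal (long right tail across regions),
  with multiplicative AR(1) per-base noise on the log scale and
  independent per-base dropout, so deeply covered regions can still
  contain uncovered bases;
* true heterozygote alt allelic depth is Binomial(DP, 0.5); homozygote
  alt depth equals DP;
* artifact calls appear at low depth with a skewed allele-balance
  distribution (Beta(2,4) truncated to (0.05, 0.70)), optionally
  clustered in one designated "pseudogene-homologous" region;
* Sanger truth equals ground truth: planted variants confirm,
  artifacts fail confirmation.

All randomness derives from the master seed through named substreams
(one per file type, sub-keyed by region/sample index), so identical
configs produce byte-identical outputs and adding samples does not
perturb earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .model import TargetRegion, TruthRecord, VariantCall

_BASES = ("A", "C", "G", "T")
# substream ids: one logical stream per output file type
_S_DEPTH, _S_VARIANT, _S_ARTIFACT, _S_TRUTH, _S_SAMPLE = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class GeneSpec:
    """Layout of one gene's captured regions.

    Each region is an exon of ``region_length - 2*intron_flank`` bp
    with ``intron_flank`` intronic bases on either side.
    """

    name: str
    n_regions: int = 5
    region_length: int = 140
    intron_flank: int = 10
    chrom: str = ""

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ConfigurationError(f"gene {self.name}: n_regions must be >= 1")
        if self.region_length <= 2 * self.intron_flank:
            raise ConfigurationError(
                f"gene {self.name}: region_length must exceed twice the flank")


@dataclass(frozen=True)
class DepthModel:
    """Log-normal region means plus AR(1) per-base log-noise and dropout.

    ``log_mean``/``log_sd`` parameterize log region mean depth;
    ``noise_scale`` is the stationary sd of the per-base AR(1) process
    (coefficient ``ar_coeff``); ``dropout`` is the per-base probability
    of zero coverage; ``sample_sd`` scales a per-sample log-normal
    capture-efficiency factor.
    """

    log_mean: float = math.log(675.0)
    log_sd: float = 0.6
    noise_scale: float = 0.25
    ar_coeff: float = 0.9
    dropout: float = 0.01
    sample_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.log_sd < 0 or self.noise_scale < 0 or self.sample_sd < 0:
            raise ConfigurationError("depth_model: scales must be non-negative")
        if not 0 <= self.dropout <= 1:
            raise ConfigurationError("depth_model.dropout must be in [0,1]")
        if not 0 <= self.ar_coeff < 1:
            raise ConfigurationError("depth_model.ar_coeff must be in [0,1)")


@dataclass(frozen=True)
class VariantSpec:
    """A planted variant with per-group population MAFs."""

    gene: str
    region_index: int = 0
    offset: int = 30  # bp from region start
    ref: str = "A"
    alt: str = "G"
    mafs: dict = field(default_factory=dict)  # group -> MAF | None
    zygosity: str = "hwe"  # "hwe" | "all_het" | "all_hom"
    func_class: str = "nonsynonymous"
    clinvar: str = "VUS"

    def __post_init__(self) -> None:
        if self.zygosity not in ("hwe", "all_het", "all_hom"):
            raise ConfigurationError(
                f"variant_model: unknown zygosity {self.zygosity!r}")
        for g, m in self.mafs.items():
            if m is not None and not 0 <= m <= 0.5:
                raise ConfigurationError(
                    f"variant_model: MAF {m} for group {g} outside [0, 0.5]")


@dataclass(frozen=True)
class ArtifactModel:
    """Low-depth skewed-balance false calls, optionally clustered."""

    rate: float = 0.02  # expected artifact calls per region (cohort-wide)
    depth_range: tuple = (12, 63)
    ab_alpha: float = 2.0
    ab_beta: float = 4.0
    ab_bounds: tuple = (0.05, 0.70)
    pseudogene_region: str | None = None
    pseudogene_rate: float = 8.0  # expected extra artifacts in that region

    def __post_init__(self) -> None:
        if self.rate < 0 or self.pseudogene_rate < 0:
            raise ConfigurationError("artifact_model: rates must be >= 0")
        if not 1 <= self.depth_range[0] <= self.depth_range[1]:
            raise ConfigurationError("artifact_model.depth_range invalid")
        if not 0 <= self.ab_bounds[0] < self.ab_bounds[1] <= 1:
            raise ConfigurationError("artifact_model.ab_bounds invalid")


@dataclass(frozen=True)
class TruthModel:
    """Fraction of samples with prior full-gene clinical screening."""

    screened_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0 <= self.screened_fraction <= 1:
            raise ConfigurationError(
                "truth_model.screened_fraction must be in [0,1]")


@dataclass(frozen=True)
class SimulationConfig:
    genes: tuple
    n_samples_per_group: dict = field(
        default_factory=lambda: {"AA": 23, "EA": 20})
    depth_model: DepthModel = DepthModel()
    variant_model: tuple = ()
    artifact_model: ArtifactModel = ArtifactModel()
    truth_model: TruthModel = TruthModel()
    min_call_depth: int = 8  # caller emission threshold (reads)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ConfigurationError("genes: at least one gene is required")
        for g, n in self.n_samples_per_group.items():
            if n < 0:
                raise ConfigurationError(
                    f"n_samples_per_group[{g}] must be non-negative")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth behind one emitted call."""

    sample: str
    key: tuple  # (chrom, pos, ref, alt)
    true_genotype: str  # "het" | "hom" | "absent"
    is_artifact: bool


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def simulate_depth_profile(region: TargetRegion, depth_model: DepthModel,
                           rng: np.random.Generator,
                           region_mean: float | None = None) -> np.ndarray:
    """Per-base integer depth for one region (one sample).

    Draws the region mean from the log-normal law unless supplied, adds
    AR(1) multiplicative noise per base, then applies dropout.
    """
    length = region.length
    if region_mean is None:
        region_mean = float(
            np.exp(rng.normal(depth_model.log_mean, depth_model.log_sd)))
    x = np.empty(length)
    innov_sd = depth_model.noise_scale * math.sqrt(1 - depth_model.ar_coeff**2)
    x[0] = rng.normal(0.0, depth_model.noise_scale) if depth_model.noise_scale else 0.0
    for i in range(1, length):
        x[i] = depth_model.ar_coeff * x[i - 1] + (
            rng.normal(0.0, innov_sd) if innov_sd else 0.0)
    depth = np.rint(region_mean * np.exp(x)).astype(int)
    if depth_model.dropout > 0:
        depth[rng.random(length) < depth_model.dropout] = 0
    return np.maximum(depth, 0)


def build_targets(config: SimulationConfig) -> list[TargetRegion]:
    """Deterministic region layout: one synthetic chromosome per gene,
    regions separated by 1 kb of uncaptured sequence."""
    targets = []
    for gi, gene in enumerate(config.genes):
        chrom = gene.chrom or f"chr{gi + 1}"
        for j in range(gene.n_regions):
            start = 10_000 + j * (gene.region_length + 1_000)
            end = start + gene.region_length
            exons = ((start + gene.intron_flank, end - gene.intron_flank),)
            targets.append(TargetRegion(
                region_id=f"{gene.name}_r{j}", gene=gene.name, chrom=chrom,
                start=start, end=end, exons=exons))
    return targets


def _sample_names(config: SimulationConfig) -> dict:
    samples = {}
    for group in sorted(config.n_samples_per_group):
        for i in range(config.n_samples_per_group[group]):
            samples[f"{group}{i + 1:03d}"] = group
    return samples


@dataclass
class PanelDataset:
    """A complete simulated screening: inputs plus the planted ledger."""

    config: SimulationConfig
    targets: list
    samples: dict  # sample -> group
    depth_columns: dict  # sample -> np.ndarray over all target bases
    depth_index: list  # (chrom, pos) in row order
    calls: list
    maf_table: dict
    sanger_truth: list
    clinical_truth: list
    planted: list  # PlantedTruth, one per emitted call
    missed: list  # planted genotypes that did not emit a call

    def write(self, outdir) -> dict:
        """Emit every interchange file; returns name -> path."""
        from . import vcfio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "targets": outdir / "targets.bed",
            "depth": outdir / "depth.tsv",
            "calls": outdir / "calls.vcf",
            "maf": outdir / "maf.tsv",
            "clinical": outdir / "truth_clinical.tsv",
            "sanger": outdir / "truth_sanger.tsv",
            "planted": outdir / "planted.tsv",
            "samples": outdir / "samples.tsv",
        }
        vcfio.write_bed(self.targets, paths["targets"])
        vcfio.write_depth_table(self.depth_index, self.depth_columns,
                                paths["depth"])
        vcfio.write_vcf(self.calls, paths["calls"],
                        samples=sorted(self.samples),
                        contigs=sorted({t.chrom for t in self.targets}))
        vcfio.write_maf_table(self.maf_table, paths["maf"])
        vcfio.write_truth(self.clinical_truth, paths["clinical"])
        vcfio.write_truth(self.sanger_truth, paths["sanger"])
        with open(paths["planted"], "w", encoding="utf-8") as fh:
            fh.write("sample\tchrom\tpos\tref\talt\ttrue_genotype\tis_artifact\n")
            for p in self.planted:
                fh.write(f"{p.sample}\t{p.key[0]}\t{p.key[1]}\t{p.key[2]}\t"
                         f"{p.key[3]}\t{p.true_genotype}\t"
                         f"{int(p.is_artifact)}\n")
        with open(paths["samples"], "w", encoding="utf-8") as fh:
            fh.write("sample\tgroup\n")
            for s in sorted(self.samples):
                fh.write(f"{s}\t{self.samples[s]}\n")
        return paths


def _genotype_for(spec: VariantSpec, group: str,
                  rng: np.random.Generator) -> str:
    if spec.zygosity == "all_het":
        return "het"
    if spec.zygosity == "all_hom":
        return "hom"
    p = spec.mafs.get(group) or 0.0
    u = rng.random()
    if u < p * p:
        return "hom"
    if u < p * p + 2 * p * (1 - p):
        return "het"
    return "absent"


def simulate_panel(config: SimulationConfig) -> PanelDataset:
    """Generate a complete dataset bundle from a validated config."""
    targets = build_targets(config)
    samples = _sample_names(config)
    sample_list = sorted(samples)
    seed = config.seed

    # per-sample capture-efficiency factors
    factors = {
        s: float(np.exp(_rng(seed, _S_SAMPLE, i).normal(
            0.0, config.depth_model.sample_sd)))
        for i, s in enumerate(sample_list)
    }

    # depth: region mean shared across samples, per-sample noisy profile
    depth_index: list = []
    depth_columns = {s: [] for s in sample_list}
    region_depth: dict = {}  # (region_id, sample) -> per-base vector
    for ri, region in enumerate(targets):
        region_rng = _rng(seed, _S_DEPTH, ri)
        region_mean = float(np.exp(region_rng.normal(
            config.depth_model.log_mean, config.depth_model.log_sd)))
        depth_index.extend(
            (region.chrom, p) for p in range(region.start + 1, region.end + 1))
        for si, s in enumerate(sample_list):
            vec = simulate_depth_profile(
                region, config.depth_model, _rng(seed, _S_DEPTH, ri, si),
                region_mean=region_mean * factors[s])
            depth_columns[s].append(vec)
            region_depth[(region.region_id, s)] = vec
    depth_columns = {s: np.concatenate(v) if v else np.array([], dtype=int)
                     for s, v in depth_columns.items()}

    gene_regions: dict = {}
    for t in targets:
        gene_regions.setdefault(t.gene, []).append(t)

    calls: list = []
    planted: list = []
    missed: list = []
    maf_table: dict = {}
    pathogenic_truth: dict = {}  # (sample, gene) -> key

    # planted variants
    for vi, spec in enumerate(config.variant_model):
        if spec.gene not in gene_regions:
            raise ConfigurationError(
                f"variant_model[{vi}]: unknown gene {spec.gene!r}")
        regions = gene_regions[spec.gene]
        if not 0 <= spec.region_index < len(regions):
            raise ConfigurationError(
                f"variant_model[{vi}]: region_index out of range")
        region = regions[spec.region_index]
        pos = region.start + 1 + spec.offset  # 1-based
        if not region.contains(pos):
            raise ConfigurationError(
                f"variant_model[{vi}]: offset outside region")
        key = (region.chrom, pos, spec.ref, spec.alt)
        maf_table[key] = dict(spec.mafs)
        bdist = region.boundary_distance(pos)
        for si, s in enumerate(sample_list):
            grng = _rng(seed, _S_VARIANT, vi, si)
            gt = _genotype_for(spec, samples[s], grng)
            if gt == "absent":
                continue
            dp = int(region_depth[(region.region_id, s)][spec.offset])
            if gt == "hom":
                ad_alt = dp
            else:
                ad_alt = int(grng.binomial(dp, 0.5)) if dp else 0
            if dp < config.min_call_depth or ad_alt < 1:
                missed.append(PlantedTruth(s, key, gt, False))
                if spec.clinvar.lower() == "pathogenic":
                    pathogenic_truth[(s, spec.gene)] = key
                continue
            calls.append(VariantCall(
                sample=s, gene=spec.gene, chrom=region.chrom, pos=pos,
                ref=spec.ref, alt=spec.alt, genotype=gt, dp=dp,
                ad_alt=ad_alt, gq=99, group=samples[s],
                func_class=spec.func_class,
                boundary_distance=bdist if spec.func_class == "intronic" else None,
                clinvar=spec.clinvar, mafs=dict(spec.mafs)))
            planted.append(PlantedTruth(s, key, gt, False))
            if spec.clinvar.lower() == "pathogenic":
                pathogenic_truth[(s, spec.gene)] = key

    # artifacts
    am = config.artifact_model
    if sample_list:
        for ri, region in enumerate(targets):
            arng = _rng(seed, _S_ARTIFACT, ri)
            lam = am.rate
            if am.pseudogene_region == region.region_id:
                lam += am.pseudogene_rate
            n_art = int(arng.poisson(lam)) if lam > 0 else 0
            for _ in range(n_art):
                s = sample_list[int(arng.integers(len(sample_list)))]
                pos = int(arng.integers(region.start + 1, region.end + 1))
                ref, alt = arng.choice(_BASES, size=2, replace=False)
                dp = int(arng.integers(am.depth_range[0],
                                       am.depth_range[1] + 1))
                ab = float(arng.beta(am.ab_alpha, am.ab_beta))
                while not am.ab_bounds[0] < ab < am.ab_bounds[1]:
                    ab = float(arng.beta(am.ab_alpha, am.ab_beta))
                ad_alt = min(dp, max(1, round(ab * dp)))
                calls.append(VariantCall(
                    sample=s, gene=region.gene, chrom=region.chrom, pos=pos,
                    ref=str(ref), alt=str(alt), genotype="het", dp=dp,
                    ad_alt=ad_alt, gq=int(arng.integers(40, 100)),
                    group=samples[s], func_class="nonsynonymous",
                    clinvar=".", mafs={}))
                planted.append(PlantedTruth(
                    s, (region.chrom, pos, str(ref), str(alt)),
                    "absent", True))

    pairs = sorted(zip(calls, planted),
                   key=lambda cp: (cp[0].chrom, cp[0].pos, cp[0].ref,
                                   cp[0].alt, cp[0].sample))
    calls = [c for c, _ in pairs]
    planted = [p for _, p in pairs]

    # truth tables
    sanger = [
        TruthRecord(sample=p.sample, scope="variant", gene=c.gene,
                    outcome="not_confirmed" if p.is_artifact else "confirmed",
                    key=p.key)
        for c, p in zip(calls, planted)
    ]
    trng = _rng(seed, _S_TRUTH)
    clinical: list = []
    for group in sorted(config.n_samples_per_group):
        members = [s for s in sample_list if samples[s] == group]
        n_screen = int(round(config.truth_model.screened_fraction * len(members)))
        screened = sorted(
            trng.choice(members, size=n_screen, replace=False)) if n_screen else []
        for s in screened:
            for gene in sorted(gene_regions):
                key = pathogenic_truth.get((s, gene))
                if key is not None:
                    clinical.append(TruthRecord(
                        sample=s, scope="gene", gene=gene,
                        outcome="positive", key=key))
                else:
                    clinical.append(TruthRecord(
                        sample=s, scope="gene", gene=gene,
                        outcome="negative_full_screen"))

    return PanelDataset(
        config=config, targets=targets, samples=samples,
        depth_columns=depth_columns, depth_index=depth_index, calls=calls,
        maf_table=maf_table, sanger_truth=sanger, clinical_truth=clinical,
        planted=planted, missed=missed)


def study_scale_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study-scale configuration: a 43-sample cohort
    (23 AA / 20 EA), ten genes with 225 regions in total, panel mean
    depth ~810X, sparse artifacts with one pseudogene-homologous
    cluster region."""
    region_counts = {
        "ATM": (65, 239), "BRCA1": (24, 323), "BRCA2": (28, 431),
        "CDH1": (16, 329), "CHEK2": (23, 200), "NBN": (22, 304),
        "PALB2": (13, 332), "PTEN": (10, 1025), "STK11": (10, 348),
        "TP53": (14, 301),
    }
    genes = tuple(GeneSpec(name=g, n_regions=n, region_length=ln)
                  for g, (n, ln) in region_counts.items())
    variants = tuple(
        VariantSpec(gene=g, region_index=i % region_counts[g][0],
                    offset=20 + 7 * i,
                    mafs={"AA": 0.008 + 0.001 * i, "EA": 0.004 + 0.001 * i})
        for g in region_counts for i in range(3)
    )
    kw = dict(
        genes=genes,
        variant_model=variants,
        artifact_model=ArtifactModel(rate=0.02,
                                     pseudogene_region="PTEN_r7",
                                     pseudogene_rate=8.0),
        seed=seed,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)
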