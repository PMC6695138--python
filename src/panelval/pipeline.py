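"""End-to-end orchestration: filter -> triage -> concordance ->
association -> reports.

``PipelineConfig`` collects input paths and tunables; every field has a
CLI override, with precedence CLI > config file > defaults. The config
file is a flat ``key = value`` text document (# comments allowed).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, fields, replace
from pathlib import Path

from . import association, concordance, coverage, filtering, triage, vcfio
from .errors import ConfigurationError
from .model import TriageThresholds

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    calls: str = ""
    outdir: str = "panelval_out"
    targets: str | None = None
    depth: str | None = None
    maf: str | None = None
    sanger: str | None = None
    clinical: str | None = None
    samples: str | None = None  # sample -> ancestry TSV
    genes: tuple | None = None
    maf_cutoff: float = filtering.MAF_CUTOFF
    intron_window: int = filtering.INTRON_WINDOW
    min_depth: int = 100
    min_ab: float = 0.40
    exclude_ab: float = 0.20
    seed: int = 0

    @property
    def thresholds(self) -> TriageThresholds:
        return TriageThresholds(high_conf_depth=self.min_depth,
                                high_conf_ab=self.min_ab,
                                exclusion_ab=self.exclude_ab)

    def validate(self) -> None:
        if not self.calls:
            raise ConfigurationError("calls: an input call file is required")
        for name in ("calls", "targets", "depth", "maf", "sanger",
                     "clinical", "samples"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise ConfigurationError(f"{name}: path {p} does not exist")
        self.thresholds  # noqa: B018 - raises on invalid combination


_FLOAT_KEYS = {"maf_cutoff", "min_ab", "exclude_ab"}
_INT_KEYS = {"intron_window", "min_depth", "seed"}


def read_config(path) -> PipelineConfig:
    """Parse a flat ``key = value`` config file."""
    valid = {f.name for f in fields(PipelineConfig)}
    kw: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected key = value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in valid:
                raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
            if key == "genes":
                kw[key] = tuple(g.strip() for g in value.split(",") if g.strip())
            elif key in _FLOAT_KEYS:
                kw[key] = float(value)
            elif key in _INT_KEYS:
                kw[key] = int(value)
            else:
                kw[key] = value
    return PipelineConfig(**kw)


def with_overrides(config: PipelineConfig, **overrides) -> PipelineConfig:
    return replace(config, **{k: v for k, v in overrides.items() if v is not None})


def _read_samples(path) -> dict:
    groups = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            f = dict(zip(header, line.rstrip("\n").split("\t")))
            groups[f["sample"]] = f.get("group", f.get("ancestry", "."))
    return groups


def _load_calls(config: PipelineConfig):
    path = Path(config.calls)
    groups = _read_samples(config.samples) if config.samples else None
    if path.suffix == ".vcf":
        return vcfio.read_vcf(path, sample_groups=groups)
    calls = vcfio.read_calls_tsv(path)
    if groups:
        calls = [c.annotated(group=groups.get(c.sample, c.group)) for c in calls]
    return calls


def _json_ready(obj):
    if isinstance(obj, dict):
        return {k: _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, float):
        return None if math.isnan(obj) else round(obj, 6)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full downstream pipeline; returns computed results.

    Writes deterministic reports into ``config.outdir``. Any stage
    error propagates with the stage name prefixed and partial outputs
    removed.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list = []
    stage = "setup"

    def emit(name, writer, *args):
        p = outdir / name
        writer(*args, p)
        written.append(p)
        return p

    try:
        stage = "load"
        calls = _load_calls(config)
        log.info("load: %d calls in", len(calls))

        stage = "filter"
        maf_table = vcfio.read_maf_table(config.maf) if config.maf else None
        targets = vcfio.read_bed(config.targets) if config.targets else None
        kept, audit = filtering.filter_cascade(
            calls, maf_table=maf_table, gene_set=config.genes,
            targets=targets, cutoff=config.maf_cutoff,
            window=config.intron_window)
        emit("audit.tsv", vcfio.write_audit_tsv, audit)
        emit("filtered_calls.tsv", vcfio.write_calls_tsv, kept)
        log.info("filter: %d calls in, %d kept", len(calls), len(kept))

        stage = "triage"
        triaged = triage.annotate_triage(kept, config.thresholds)
        emit("triaged_calls.tsv", vcfio.write_calls_tsv, triaged)
        log.info("triage: %d high confidence",
                 sum(1 for c in triaged if c.confidence == "high"))

        results: dict = {"n_calls_in": len(calls), "n_filtered": len(kept)}

        stage = "concordance"
        labeled = triaged
        if config.sanger:
            sanger = vcfio.read_truth(config.sanger)
            clinical = (vcfio.read_truth(config.clinical)
                        if config.clinical else ())
            labeled = concordance.label_calls(triaged, sanger)
            metrics = {
                mode: concordance.concordance_metrics(
                    labeled, clinical, mode=mode, thresholds=config.thresholds)
                for mode in ("all", "ab_filtered")
            }
            summaries = concordance.class_summaries(labeled, config.thresholds)
            emit("labeled_calls.tsv", vcfio.write_calls_tsv, labeled)
            emit("metrics.tsv", vcfio.write_metrics_tsv, metrics)
            p = outdir / "class_summaries.json"
            p.write_text(json.dumps(_json_ready(summaries), indent=2,
                                    sort_keys=True) + "\n", encoding="utf-8")
            written.append(p)
            results.update(metrics=metrics, class_summaries=summaries,
                           labeled=labeled)
            log.info("concordance: TP=%d FP=%d",
                     sum(1 for c in labeled if c.label == "TP"),
                     sum(1 for c in labeled if c.label == "FP"))

        stage = "association"
        if config.sanger and config.samples:
            groups = _read_samples(config.samples)
            sizes: dict = {}
            for g in groups.values():
                sizes[g] = sizes.get(g, 0) + 1
            if len(sizes) == 2:
                pair = tuple(sorted(sizes))
                rows = []
                for min_tp, name in ((1, "ge1_tp"), (2, "ge2_tp")):
                    t = association.tp_carrier_table(
                        labeled, sizes, groups=pair, min_tp=min_tp)
                    rows.append((name, t, association.fisher_exact(t)))
                emit("association.tsv", vcfio.write_association_tsv, rows)
                results["association"] = rows
                log.info("association: %d comparisons", len(rows))

        stage = "coverage"
        if config.depth and config.targets:
            depths = coverage.read_depth_table(config.depth)
            summaries = [coverage.summarize_region(t, depths) for t in targets]
            pooled = coverage.panel_summary(targets, depths)
            emit("coverage_regions.tsv", vcfio.write_coverage_tsv,
                 summaries + [pooled])
            emit("coverage_bins.tsv", vcfio.write_bins_tsv,
                 coverage.bin_regions(summaries))
            results["coverage"] = {"summaries": summaries, "pooled": pooled}
            log.info("coverage: %d regions", len(summaries))

        return results
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise type(exc)(f"[stage {stage}] {exc}") from exc
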