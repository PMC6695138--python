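"""Readers and writers for the pipeline's interchange formats.

Formats: VCF v4.2 (1-based; FORMAT GT:GQ:DP:AD, per-call annotations in
INFO), BED6 targets (0-based half-open; name=gene, score=region index),
per-base depth TSV (1-based; chrom, pos, total_depth, one column per
sample), MAF TSV, truth TSVs, and the per-call TSV used between
pipeline stages. VCF parsing is done with :mod:`pysam`; writers emit
deterministic, byte-stable text.

ANNOVAR-style alleles ('-' for a deleted allele) cannot be represented
in VCF directly; the VCF writer anchors them on a synthetic 'N' base at
pos-1, and the reader reverses exactly that encoding.
"""

from __future__ import annotations

import math
from pathlib import Path

import pysam

from .errors import DataError, ParseError
from .model import COVERAGE_THRESHOLDS, TargetRegion, TruthRecord, VariantCall

_VCF_INFO_HEADERS = [
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=FUNC,Number=1,Type=String,Description="Functional class">',
    '##INFO=<ID=BD,Number=1,Type=Integer,Description='
    '"Distance to nearest intron-exon boundary (bp)">',
    '##INFO=<ID=CLNSIG,Number=1,Type=String,Description='
    '"Clinical significance label (pass-through)">',
]
_VCF_FORMAT_HEADERS = [
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
    '"Allelic depths (ref, alt)">',
]


def _vcf_alleles(call: VariantCall) -> tuple[int, str, str]:
    """(pos, ref, alt) in VCF representation, anchoring '-' alleles."""
    if "-" in (call.ref, call.alt):
        ref = "" if call.ref == "-" else call.ref
        alt = "" if call.alt == "-" else call.alt
        return call.pos - 1, "N" + ref, "N" + alt
    return call.pos, call.ref, call.alt


def _from_vcf_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    if ref.startswith("N") and alt.startswith("N") and (len(ref) == 1 or len(alt) == 1):
        return pos + 1, ref[1:] or "-", alt[1:] or "-"
    return pos, ref, alt


def write_vcf(calls, path, samples=None, contigs=None) -> None:
    """Write calls as a multi-sample VCF v4.2, sites sorted, samples
    without a call encoded ./. ."""
    calls = list(calls)
    if samples is None:
        samples = sorted({c.sample for c in calls})
    if contigs is None:
        contigs = sorted({c.chrom for c in calls})
    sites: dict = {}
    for c in calls:
        sites.setdefault(c.key, {})
        if c.sample in sites[c.key]:
            raise DataError(f"duplicate call for {c.sample} at {c.key}")
        sites[c.key][c.sample] = c
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={ctg}>" for ctg in contigs]
    lines += _VCF_INFO_HEADERS + _VCF_FORMAT_HEADERS
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    for key in sorted(sites, key=lambda k: (k[0], k[1], k[2], k[3])):
        carriers = sites[key]
        any_call = next(iter(carriers.values()))
        pos, ref, alt = _vcf_alleles(any_call)
        info = [f"GENE={any_call.gene}", f"FUNC={any_call.func_class}"]
        if any_call.boundary_distance is not None:
            info.append(f"BD={any_call.boundary_distance}")
        if any_call.clinvar not in (".", ""):
            info.append(f"CLNSIG={any_call.clinvar.replace(' ', '_')}")
        cols = [any_call.chrom, str(pos), ".", ref, alt, ".", "PASS",
                ";".join(info), "GT:GQ:DP:AD"]
        for s in samples:
            c = carriers.get(s)
            if c is None:
                cols.append("./.")
            else:
                gt = "1/1" if c.genotype == "hom" else "0/1"
                cols.append(f"{gt}:{c.gq}:{c.dp}:{c.dp - c.ad_alt},{c.ad_alt}")
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_vcf(path, sample_groups=None) -> list[VariantCall]:
    """Read a VCF into per-sample, per-alt-allele calls.

    Records with missing genotype are skipped; missing DP or AD on a
    called genotype is a record-level error naming CHROM:POS.
    ``sample_groups`` maps sample id -> ancestry label.
    """
    sample_groups = sample_groups or {}
    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = dict(rec.info)
            for sample, sdata in rec.samples.items():
                alleles = sdata.get("GT")
                if alleles is None or all(a is None for a in alleles):
                    continue
                alt_idx = sorted({a for a in alleles if a})
                if not alt_idx:
                    continue  # hom-ref entry carries no alt call
                dp = sdata.get("DP")
                ad = sdata.get("AD")
                if dp is None or ad is None or any(v is None for v in ad):
                    raise DataError(
                        f"{rec.chrom}:{rec.pos}: sample {sample} lacks DP/AD")
                for ai in alt_idx:
                    alt = rec.alts[ai - 1]
                    pos, ref, alt_ = _from_vcf_alleles(rec.pos, rec.ref, alt)
                    genotype = "hom" if all(a == ai for a in alleles) else "het"
                    bd = info.get("BD")
                    calls.append(VariantCall(
                        sample=sample,
                        gene=info.get("GENE", "."),
                        chrom=rec.chrom, pos=pos, ref=ref, alt=alt_,
                        genotype=genotype, dp=int(dp), ad_alt=int(ad[ai]),
                        gq=int(sdata.get("GQ") or 0),
                        group=sample_groups.get(sample, "."),
                        func_class=info.get("FUNC", "other"),
                        boundary_distance=int(bd) if bd is not None else None,
                        clinvar=str(info.get("CLNSIG", ".")).replace("_", " "),
                    ))
    return calls


def write_bed(targets, path) -> None:
    """BED6: chrom, start, end, name=gene, score=region index, strand."""
    lines = []
    for i, t in enumerate(targets):
        lines.append(f"{t.chrom}\t{t.start}\t{t.end}\t{t.gene}\t{i}\t{t.strand}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_bed(path) -> list[TargetRegion]:
    """Read BED6 targets.

    Exon substructure is not representable in BED6; regions are read
    as fully exonic, so boundary distances must come from call
    annotations.
    """
    targets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            targets.append(TargetRegion(
                region_id=f"{fields[3]}_{lineno}", gene=fields[3],
                chrom=fields[0], start=start, end=end,
                exons=((start, end),),
                strand=fields[5] if len(fields) > 5 else "+"))
    return targets


def write_depth_table(depth_index, depth_columns, path) -> None:
    samples = sorted(depth_columns)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tpos\ttotal_depth" +
                 "".join(f"\t{s}" for s in samples) + "\n")
        for i, (chrom, pos) in enumerate(depth_index):
            per = [int(depth_columns[s][i]) for s in samples]
            fh.write(f"{chrom}\t{pos}\t{sum(per)}" +
                     "".join(f"\t{d}" for d in per) + "\n")


def write_maf_table(maf_table, path) -> None:
    groups = sorted({g for m in maf_table.values() for g in m})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tpos\tref\talt" +
                 "".join(f"\tmaf_{g}" for g in groups) + "\n")
        for key in sorted(maf_table):
            mafs = maf_table[key]
            row = [key[0], str(key[1]), key[2], key[3]]
            row += ["." if mafs.get(g) is None else f"{mafs[g]:g}"
                    for g in groups]
            fh.write("\t".join(row) + "\n")


def read_maf_table(path) -> dict:
    """MAF TSV -> {(chrom,pos,ref,alt): {group: maf|None}}; conflicting
    duplicate rows are a data error."""
    table: dict = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["chrom", "pos", "ref", "alt"]:
            raise ParseError(f"{path}: unexpected MAF header")
        groups = [h[4:] for h in header[4:] if h.startswith("maf_")]
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(f"{path}:{lineno}: wrong field count")
            key = (fields[0], int(fields[1]), fields[2], fields[3])
            mafs = {g: (None if v == "." else float(v))
                    for g, v in zip(groups, fields[4:])}
            if key in table and table[key] != mafs:
                raise DataError(f"{path}:{lineno}: conflicting MAF rows "
                                f"for {key}")
            table[key] = mafs
    return table


def write_truth(records, path) -> None:
    records = list(records)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\tscope\tgene\toutcome\tchrom\tpos\tref\talt\n")
        for r in records:
            key = r.key or (".", ".", ".", ".")
            fh.write(f"{r.sample}\t{r.scope}\t{r.gene}\t{r.outcome}\t"
                     f"{key[0]}\t{key[1]}\t{key[2]}\t{key[3]}\n")


def read_truth(path) -> list[TruthRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "sample":
            raise ParseError(f"{path}: unexpected truth header")
        for lineno, line in enumerate(fh, start=2):
            f = dict(zip(header, line.rstrip("\n").split("\t")))
            key = None
            if f.get("chrom", ".") != ".":
                key = (f["chrom"], int(f["pos"]), f["ref"], f["alt"])
            records.append(TruthRecord(
                sample=f["sample"], scope=f.get("scope", "gene"),
                gene=f.get("gene", "."), outcome=f["outcome"], key=key))
    return records


_CALL_COLUMNS = [
    "sample", "group", "gene", "chrom", "pos", "ref", "alt", "func_class",
    "boundary_distance", "dna_change", "clinvar", "genotype", "gq", "dp",
    "ad_alt", "allele_balance", "confidence", "excluded_low_ab", "label",
]


def _fmt(v) -> str:
    if v is None:
        return "."
    if isinstance(v, bool):
        return str(int(v))
    if isinstance(v, float):
        return "." if math.isnan(v) else f"{v:.2f}"
    return str(v)


def write_calls_tsv(calls, path) -> None:
    """Per-call TSV with allele balance and pipeline-stage annotations;
    allele balance is reported to 2 decimals."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for c in calls:
            ab = c.allele_balance if c.dp > 0 else None
            row = [c.sample, c.group, c.gene, c.chrom, c.pos, c.ref, c.alt,
                   c.func_class, c.boundary_distance, c.dna_change, c.clinvar,
                   c.genotype, c.gq, c.dp, c.ad_alt, ab, c.confidence,
                   c.excluded_low_ab, c.label]
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_calls_tsv(path) -> list[VariantCall]:
    calls = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for lineno, line in enumerate(fh, start=2):
            f = dict(zip(header, line.rstrip("\n").split("\t")))
            try:
                bd = f.get("boundary_distance", ".")
                calls.append(VariantCall(
                    sample=f["sample"], group=f.get("group", "."),
                    gene=f["gene"], chrom=f["chrom"], pos=int(f["pos"]),
                    ref=f["ref"], alt=f["alt"],
                    func_class=f.get("func_class", "other"),
                    boundary_distance=None if bd == "." else int(bd),
                    dna_change=f.get("dna_change", "."),
                    clinvar=f.get("clinvar", "."),
                    genotype=f["genotype"], gq=int(f.get("gq", 0)),
                    dp=int(f["dp"]), ad_alt=int(f["ad_alt"]),
                    confidence=None if f.get("confidence", ".") == "."
                    else f["confidence"],
                    excluded_low_ab=None if f.get("excluded_low_ab", ".") == "."
                    else bool(int(f["excluded_low_ab"])),
                    label=None if f.get("label", ".") == "." else f["label"],
                ))
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return calls


def write_metrics_tsv(results: dict, path) -> None:
    """Per-gene metrics table (one row per gene plus a pooled row).

    ``results`` maps mode -> output of
    :func:`panelval.concordance.concordance_metrics`; FDR columns carry
    one value per mode. Proportions are printed to 2 decimals, NA for
    undefined.
    """
    all_res = results["all"]
    filt_res = results.get("ab_filtered")

    def fmt_prop(v):
        return "NA" if v is None or math.isnan(v) else f"{v:.2f}"

    lines = ["gene\tTP\tFP\tTN\tFN\tsensitivity\tspecificity\t"
             "FDR_all\tFDR_filtered"]

    def row(gene, s_all, s_filt):
        return "\t".join([
            gene, str(s_all.tp), str(s_all.fp), str(s_all.tn), str(s_all.fn),
            fmt_prop(s_all.sensitivity), fmt_prop(s_all.specificity),
            fmt_prop(s_all.fdr),
            fmt_prop(s_filt.fdr if s_filt else math.nan),
        ])

    for gene in sorted(all_res["per_gene"]):
        lines.append(row(gene, all_res["per_gene"][gene],
                         filt_res["per_gene"].get(gene) if filt_res else None))
    if all_res["pooled"] is not None:
        lines.append(row("pooled:" + all_res["pooled"].gene, all_res["pooled"],
                         filt_res["pooled"] if filt_res else None))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_coverage_tsv(summaries, path) -> None:
    """Region-summary table: mean depth to whole X, percents to 1 dp."""
    cols = ["region", "gene", "length", "mean_depth", "q1", "median", "q3"]
    cols += [f"pct_ge_{t}x" for t in COVERAGE_THRESHOLDS]
    lines = ["\t".join(cols)]
    for s in summaries:
        row = [s.region_id, s.gene, str(s.length), f"{s.mean:.0f}",
               f"{s.q1:.0f}", f"{s.median:.0f}", f"{s.q3:.0f}"]
        row += [f"{s.pct_at_least[t]:.1f}" for t in COVERAGE_THRESHOLDS]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_bins_tsv(profiles, path) -> None:
    cols = ["depth_bin", "n_regions"]
    cols += [f"mean_pct_ge_{t}x" for t in COVERAGE_THRESHOLDS]
    lines = ["\t".join(cols)]
    for p in profiles:
        row = [p.label, str(p.n_regions)]
        row += [f"{p.mean_pct_at_least[t]:.1f}" for t in COVERAGE_THRESHOLDS]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_association_tsv(rows, path) -> None:
    """``rows``: iterable of (name, TwoByTwo, ExactTestResult)."""
    lines = ["comparison\ta\tb\tc\td\tp_two_sided\tor_cmle\tci95_low\tci95_high"]
    for name, t, r in rows:
        hi = "inf" if math.isinf(r.ci95_high) else f"{r.ci95_high:.2f}"
        lines.append(f"{name}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t"
                     f"{r.p_two_sided:.3g}\t{r.or_cmle:.2f}\t"
                     f"{r.ci95_low:.2f}\t{hi}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_audit_tsv(audit_rows, path) -> None:
    lines = ["sample\tchrom\tpos\tref\talt\tstage\tkept\treason"]
    for r in audit_rows:
        lines.append(f"{r['sample']}\t{r['chrom']}\t{r['pos']}\t{r['ref']}\t"
                     f"{r['alt']}\t{r['stage']}\t{int(r['kept'])}\t{r['reason']}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
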