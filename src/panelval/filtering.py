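"""Variant-filtering cascade: gene subset, population rarity, position.

The cascade keeps a call iff all of the following hold:

* its gene is in the assessed gene set;
* its minor allele frequency is <= the cutoff (default 2%) in *every*
  ancestry group — a variant absent from the population table counts
  as rare;
* it is coding (nonsynonymous / synonymous / frameshift) or intronic
  within ``window`` bp (default 10) of an intron-exon boundary.

The predicates are conjunctive, hence order-independent and
idempotent; filters never mutate calls except for MAF annotation.
"""

from __future__ import annotations

import logging
import re

from .model import CODING_CLASSES, VariantCall

log = logging.getLogger(__name__)

MAF_CUTOFF = 0.02
INTRON_WINDOW = 10

_INTRON_OFFSET_RE = re.compile(r"c\.[0-9*]+([+-])(\d+)")


def hgvs_intron_offset(dna_change: str):
    """Intron-offset distance encoded in a c. DNA-change string.

    ``c.186-7C>T`` -> 7, ``c.3993+5G>T`` -> 5; returns None for purely
    exonic descriptions (no +N/-N offset).
    """
    m = _INTRON_OFFSET_RE.match(dna_change)
    return int(m.group(2)) if m else None


def annotate_maf(calls, maf_table: dict) -> list[VariantCall]:
    """Attach per-group population MAFs from a variant-keyed table.

    Variants absent from the table get None ("absent") in every group
    present in the table; an empty table leaves annotations empty.
    """
    groups = sorted({g for mafs in maf_table.values() for g in mafs})
    out = []
    for c in calls:
        mafs = maf_table.get(c.key)
        if mafs is None:
            mafs = {g: None for g in groups}
        out.append(c.annotated(mafs=dict(mafs)))
    return out


def is_rare(call: VariantCall, cutoff: float = MAF_CUTOFF) -> bool:
    return all(maf is None or maf <= cutoff for maf in call.mafs.values())


def filter_rare(calls, cutoff: float = MAF_CUTOFF) -> list[VariantCall]:
    """Keep calls rare (MAF <= cutoff, inclusive) in every group."""
    return [c for c in calls if is_rare(c, cutoff)]


def _positional_keep(call: VariantCall, targets, window: int):
    """(keep, reason) for the coding / near-splice predicate."""
    if call.func_class in CODING_CLASSES:
        return True, "coding"
    dist = call.boundary_distance
    if dist is None and targets is not None:
        region = next(
            (r for r in targets
             if r.chrom == call.chrom and r.contains(call.pos)),
            None,
        )
        if region is None:
            return False, "outside_targets"
        dist = region.boundary_distance(call.pos)
    if call.func_class == "intronic" and dist is not None and dist <= window:
        return True, f"intronic_within_{window}bp"
    return False, "non_coding_far_from_boundary"


def filter_positional(calls, targets=None, window: int = INTRON_WINDOW) -> list[VariantCall]:
    """Keep coding calls and near-boundary intronic calls.

    Boundary distance comes from the call annotation when present,
    otherwise from the exon model of the enclosing target region; calls
    outside every target are dropped with a warning.
    """
    kept = []
    for c in calls:
        keep, reason = _positional_keep(c, targets, window)
        if keep:
            kept.append(c)
        elif reason == "outside_targets":
            log.warning("call %s:%d (%s) outside all target regions; dropped",
                        c.chrom, c.pos, c.sample)
    return kept


def restrict_genes(calls, gene_set) -> list[VariantCall]:
    """Keep calls whose gene is in ``gene_set``; order preserved."""
    gene_set = frozenset(gene_set)
    return [c for c in calls if c.gene in gene_set]


def filter_cascade(calls, maf_table=None, gene_set=None, targets=None,
                   cutoff: float = MAF_CUTOFF, window: int = INTRON_WINDOW):
    """Run the full cascade; returns (surviving calls, audit rows).

    Audit rows are dicts (sample, chrom, pos, ref, alt, stage, kept,
    reason), one per call, recording the first stage that dropped it.
    """
    if maf_table is not None:
        calls = annotate_maf(calls, maf_table)
    audit = []
    kept = []
    for c in calls:
        stage, keep, reason = "pass", True, "kept"
        if gene_set is not None and c.gene not in frozenset(gene_set):
            stage, keep, reason = "restrict_genes", False, "gene_not_assessed"
        elif not is_rare(c, cutoff):
            stage, keep, reason = "filter_rare", False, f"maf_above_{cutoff}"
        else:
            ok, why = _positional_keep(c, targets, window)
            if not ok:
                stage, keep, reason = "filter_positional", False, why
        audit.append({"sample": c.sample, "chrom": c.chrom, "pos": c.pos,
                      "ref": c.ref, "alt": c.alt, "stage": stage,
                      "kept": keep, "reason": reason})
        if keep:
            kept.append(c)
    return kept, audit
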