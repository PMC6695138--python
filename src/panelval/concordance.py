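"""Concordance of panel calls against orthogonal truth.

Confusion classes follow the screening-validation convention:

* **TP** — a panel call confirmed by Sanger sequencing (or matching a
  clinically known, laboratory-confirmed variant);
* **FP** — a panel call that failed Sanger confirmation;
* **FN** — a clinically known, confirmed variant the panel missed;
* **TN** — a (sample, gene) pair with a prior negative *full-gene*
  clinical screen and no pathogenic panel call in that gene. A
  targeted familial-variant test never establishes a TN, and samples
  without clinical screening are never TNs.

Derived metrics: sensitivity TP/(TP+FN), specificity TN/(TN+FP), and
FDR FP/(TP+FP), the last in two modes — over all calls, and after
excluding calls with allele balance <= 0.20. Undefined ratios are NaN,
never 0. Specificity pools TN units per (sample, gene) pair across the
requested gene set.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .errors import DataError
from .model import ConcordanceSummary, TriageThresholds, VariantCall
from .triage import DEFAULT_THRESHOLDS, exclude_low_ab

log = logging.getLogger(__name__)


def keys_equivalent(a: tuple, b: tuple) -> bool:
    """Variant-key equality tolerant of indel naming conventions.

    Deletions inside short tandem repeats have several legitimate
    left/right-aligned names; two keys with identical chrom/ref/alt
    whose positions differ by at most the indel length are treated as
    the same variant. SNV keys must match exactly.
    """
    if a == b:
        return True
    (ca, pa, ra, aa), (cb, pb, rb, ab) = a, b
    if ca != cb or ra != rb or aa != ab:
        return False
    is_indel = len(ra) != len(aa) or "-" in (ra, aa)
    return is_indel and abs(pa - pb) <= max(len(ra), len(aa))


def _match_call(calls, sample: str, key: tuple):
    for c in calls:
        if c.sample == sample and keys_equivalent(c.key, key):
            return c
    return None


def label_calls(calls, sanger_truth) -> list[VariantCall]:
    """Label each call TP/FP from variant-level Sanger outcomes.

    Calls without a Sanger record are labeled ``unresolved`` and
    excluded from metrics (the count is logged). Contradictory
    duplicate records for one sample x variant raise DataError.
    """
    outcomes: dict = {}
    for rec in sanger_truth:
        if rec.scope != "variant":
            continue
        k = (rec.sample, rec.key)
        if k in outcomes and outcomes[k] != rec.outcome:
            raise DataError(
                f"contradictory Sanger records for {rec.sample} {rec.key}")
        outcomes[k] = rec.outcome
    labeled = []
    n_unresolved = 0
    for c in calls:
        outcome = outcomes.get((c.sample, c.key))
        if outcome is None:  # tolerant indel rematch
            for (s, k), v in outcomes.items():
                if s == c.sample and keys_equivalent(k, c.key):
                    outcome = v
                    break
        if outcome is None:
            labeled.append(c.annotated(label="unresolved"))
            n_unresolved += 1
        else:
            labeled.append(c.annotated(
                label="TP" if outcome == "confirmed" else "FP"))
    if n_unresolved:
        log.info("%d calls had no Sanger record; labeled unresolved",
                 n_unresolved)
    return labeled


def derive_fn(clinical_truth, calls) -> dict:
    """Per-gene FN counts: clinically confirmed variants with no
    matching panel call in the same sample."""
    fn: dict = {}
    for rec in clinical_truth:
        if rec.scope != "gene":
            continue
        fn.setdefault(rec.gene, 0)
        if rec.outcome == "positive":
            if _match_call(calls, rec.sample, rec.key) is None:
                fn[rec.gene] += 1
    return fn


def derive_tn(clinical_truth, calls) -> dict:
    """Per-gene TN counts over (sample, gene) negative-full-screen
    pairs without a pathogenic panel call in that gene."""
    tn: dict = {}
    for rec in clinical_truth:
        if rec.scope != "gene":
            continue
        tn.setdefault(rec.gene, 0)
        if rec.outcome != "negative_full_screen":
            continue
        pathogenic = any(
            c.sample == rec.sample and c.gene == rec.gene and c.is_pathogenic
            for c in calls
        )
        if not pathogenic:
            tn[rec.gene] += 1
    return tn


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def _mean(values) -> float:
    return float(np.mean(values)) if values else math.nan


def _gene_summary(gene: str, calls, fn: int, tn: int) -> ConcordanceSummary:
    tp_calls = [c for c in calls if c.label == "TP"]
    fp_calls = [c for c in calls if c.label == "FP"]
    tp, fp = len(tp_calls), len(fp_calls)
    return ConcordanceSummary(
        gene=gene, tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_ratio(tp, tp + fn) if fn >= 0 else math.nan,
        specificity=_ratio(tn, tn + fp) if tn >= 0 else math.nan,
        fdr=_ratio(fp, tp + fp),
        tp_dp_mean=_mean([c.dp for c in tp_calls]),
        tp_ab_mean=_mean([c.allele_balance for c in tp_calls]),
        fp_dp_mean=_mean([c.dp for c in fp_calls]),
        fp_ab_mean=_mean([c.allele_balance for c in fp_calls]),
    )


def concordance_metrics(labeled_calls, clinical_truth=(), mode: str = "all",
                        thresholds: TriageThresholds = DEFAULT_THRESHOLDS,
                        genes=None) -> dict:
    """Per-gene and pooled confusion counts and metrics.

    ``mode`` is ``"all"`` or ``"ab_filtered"`` (recompute after the
    AB <= 0.20 exclusion). Sensitivity and specificity are reported
    per gene — and pooled — only for genes covered by clinical truth;
    FDR is reported for every gene with calls. The pooled row uses
    per-(sample, gene) TN units summed over the clinical gene set.
    """
    if mode not in ("all", "ab_filtered"):
        raise DataError(f"unknown concordance mode {mode!r}")
    calls = [c for c in labeled_calls if c.label in ("TP", "FP")]
    if mode == "ab_filtered":
        calls = exclude_low_ab(calls, thresholds)
    clinical = [r for r in clinical_truth if r.scope == "gene"]
    fn_by_gene = derive_fn(clinical, calls)
    tn_by_gene = derive_tn(clinical, calls)
    clinical_genes = sorted(fn_by_gene)

    if genes is None:
        genes = sorted({c.gene for c in calls} | set(clinical_genes))
    per_gene = {}
    for gene in genes:
        gcalls = [c for c in calls if c.gene == gene]
        if gene in fn_by_gene:
            s = _gene_summary(gene, gcalls, fn_by_gene[gene], tn_by_gene[gene])
        else:  # no clinical coverage: sens/spec undefined
            s = _gene_summary(gene, gcalls, 0, 0)
            s = ConcordanceSummary(
                **{**s.__dict__, "sensitivity": math.nan,
                   "specificity": math.nan, "tn": 0, "fn": 0})
        per_gene[gene] = s

    pooled = None
    if clinical_genes:
        pcalls = [c for c in calls if c.gene in clinical_genes]
        pooled = _gene_summary(
            "/".join(clinical_genes), pcalls,
            sum(fn_by_gene.values()), sum(tn_by_gene.values()))
    return {"per_gene": per_gene, "pooled": pooled, "mode": mode}


def _stats(calls) -> dict:
    dps = [c.dp for c in calls]
    abs_ = [c.allele_balance for c in calls if c.dp > 0]
    n_tp = sum(1 for c in calls if c.label == "TP")
    return {
        "n": len(calls), "n_tp": n_tp,
        "dp_mean": _mean(dps),
        "dp_min": min(dps) if dps else math.nan,
        "dp_max": max(dps) if dps else math.nan,
        "ab_mean": _mean(abs_),
        "ab_min": min(abs_) if abs_ else math.nan,
        "ab_max": max(abs_) if abs_ else math.nan,
    }


def class_summaries(labeled_calls,
                    thresholds: TriageThresholds = DEFAULT_THRESHOLDS) -> dict:
    """Mean/range of DP and AB per confusion class plus the depth /
    confidence subsets used to justify triage criteria.

    Keys: ``tp``, ``fp``, ``below_depth`` (all calls with DP under the
    high-confidence depth), ``below_depth_tp``, ``at_or_above_depth``,
    ``at_or_above_depth_het`` (heterozygous high-depth calls), and
    ``high_confidence`` (calls passing both triage thresholds).
    """
    calls = [c for c in labeled_calls if c.label in ("TP", "FP")]
    d = thresholds.high_conf_depth
    below = [c for c in calls if c.dp < d]
    above = [c for c in calls if c.dp >= d]
    high = [c for c in above
            if c.dp > 0 and c.allele_balance >= thresholds.high_conf_ab]
    return {
        "tp": _stats([c for c in calls if c.label == "TP"]),
        "fp": _stats([c for c in calls if c.label == "FP"]),
        "below_depth": _stats(below),
        "below_depth_tp": _stats([c for c in below if c.label == "TP"]),
        "at_or_above_depth": _stats(above),
        "at_or_above_depth_het": _stats(
            [c for c in above if c.genotype == "het"]),
        "high_confidence": _stats(high),
    }
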