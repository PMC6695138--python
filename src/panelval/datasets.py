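"""Packaged reference dataset: a published analytical-validation benchmark.

The benchmark is the complete per-call validation table of an initial
43-sample hereditary breast/ovarian/prostate panel screening (23 African
American [AA] and 20 European American [EA] participants; 10 clinically
actionable genes assessed). Each of the 74 filtered calls carries its
genotype, genotype quality, total depth, allele balance, the published
high-confidence flag, and the Sanger-validation outcome (61 confirmed
true positives, 13 false positives).

Clinical-screening truth: six participants had prior negative full-gene
BRCA1/2 screens, one (1CB-a) a positive BRCA2 report and one (1CAD-a) a
positive targeted familial BRCA1 test; a further relative (1CAD-f)
tested negative for the familial variant only, which cannot establish a
true negative. The published record gives the *count* of negative full
screens but not which samples they were; the assignment of those six
records to named samples in ``reference_clinical_reconstructed.tsv`` is
a synthetic reconstruction consistent with every published count (any
six samples without a positive report reproduce them).

The table prints allele balance, not allelic depth; alt allelic depths
are back-computed as round(AB x DP), which reproduces the printed AB at
two decimals for every row.
"""

from __future__ import annotations

import csv
from importlib import resources

from .errors import DataError
from .model import TruthRecord, VariantCall

#: ancestry composition of the screened cohort
COHORT_SIZES = {"AA": 23, "EA": 20}

#: the ten genes assessed for analytical validity
ASSESSED_GENES = (
    "ATM", "BRCA1", "BRCA2", "CDH1", "CHEK2",
    "NBN", "PALB2", "PTEN", "STK11", "TP53",
)

_FUNC_MAP = {
    "NS": "nonsynonymous",
    "S": "synonymous",
    "FSD": "frameshift",
    "Intronic": "intronic",
}


def _opt_float(s: str):
    return None if s == "." else float(s)


def _read_packaged(name: str):
    ref = resources.files("panelval.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        yield from csv.DictReader(fh, delimiter="\t")


def load_reference_calls() -> list[VariantCall]:
    """The 74 filtered per-sample calls of the benchmark screening."""
    from .filtering import hgvs_intron_offset

    calls = []
    for row in _read_packaged("reference_calls.tsv"):
        dp = int(row["dp"])
        ab = float(row["ab"])
        ad_alt = round(ab * dp)
        calls.append(
            VariantCall(
                sample=row["sample"],
                gene=row["gene"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                genotype="hom" if row["gt"] == "Homo" else "het",
                dp=dp,
                ad_alt=ad_alt,
                gq=int(row["gq"]),
                group=row["ancestry"],
                func_class=_FUNC_MAP.get(row["func"], "other"),
                boundary_distance=hgvs_intron_offset(row["dna_change"]),
                dna_change=row["dna_change"],
                aa_change=row["aa_change"],
                prediction=row["prediction"],
                clinvar=row["clinvar"],
                mafs={"EA": _opt_float(row["maf_ea"]),
                      "AA": _opt_float(row["maf_aa"])},
            )
        )
    if len(calls) != 74:
        raise DataError(f"reference call table has {len(calls)} rows, expected 74")
    return calls


def load_reference_flags() -> list[tuple[str, str]]:
    """Published (high-confidence flag, validation outcome) per call,
    in file order; used to cross-check the triage classifier."""
    return [(r["high_conf"], r["validation"]) for r in
            _read_packaged("reference_calls.tsv")]


def reference_sanger_truth() -> list[TruthRecord]:
    """Variant-level Sanger outcomes, one per benchmark call."""
    recs = []
    for row in _read_packaged("reference_calls.tsv"):
        recs.append(
            TruthRecord(
                sample=row["sample"],
                scope="variant",
                gene=row["gene"],
                outcome="confirmed" if row["validation"] == "TP" else "not_confirmed",
                key=(row["chrom"], int(row["pos"]), row["ref"], row["alt"]),
            )
        )
    return recs


def reference_clinical_truth() -> list[TruthRecord]:
    """Gene-level clinical-screening outcomes (partly reconstructed; see
    module docstring)."""
    recs = []
    for row in _read_packaged("reference_clinical_reconstructed.tsv"):
        key = None
        if row["chrom"] != ".":
            key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        recs.append(
            TruthRecord(
                sample=row["sample"],
                scope="gene",
                gene=row["gene"],
                outcome=row["outcome"],
                key=key,
            )
        )
    return recs


def reference_maf_table() -> dict:
    """Population MAF table keyed by variant, as the MAF filter consumes."""
    table: dict = {}
    for row in _read_packaged("reference_calls.tsv"):
        key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        mafs = {"EA": _opt_float(row["maf_ea"]), "AA": _opt_float(row["maf_aa"])}
        if key in table and table[key] != mafs:
            raise DataError(f"conflicting MAF rows for {key}")
        table[key] = mafs
    return table
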