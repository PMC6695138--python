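"""Call-confidence triage by sequencing depth and allele balance.

A call is *high confidence* iff DP >= 100 and AB >= 0.40 (both
inclusive, configurable via :class:`~panelval.model.TriageThresholds`).
High-confidence calls are the ones a screening laboratory would accept
without orthogonal confirmation; everything else is routed to Sanger
validation. A separate exclusion filter removes calls with AB <= 0.20,
a band in which no call has ever validated in the benchmark screening.

Allele balance is alt allelic depth / total depth: ~0.5 for true
heterozygotes, 1.0 for homozygous-alternate calls, and typically
skewed for alignment artifacts.
"""

from __future__ import annotations

from .errors import DataError
from .model import TriageThresholds, VariantCall

DEFAULT_THRESHOLDS = TriageThresholds()


def allele_balance(ad_alt: int, dp: int) -> float:
    """Fraction of reads supporting the alternate allele."""
    if dp < 1:
        raise DataError("allele balance undefined at DP=0")
    if not 0 <= ad_alt <= dp:
        raise DataError(f"AD_alt {ad_alt} outside [0, DP={dp}]")
    return ad_alt / dp


def classify_confidence(call: VariantCall,
                        thresholds: TriageThresholds = DEFAULT_THRESHOLDS) -> str:
    """"high" iff DP and AB both meet their thresholds, else "low".

    A call with DP=0 has no allele balance and is never high
    confidence.
    """
    if call.dp == 0:
        return "low"
    ab = allele_balance(call.ad_alt, call.dp)
    high = call.dp >= thresholds.high_conf_depth and ab >= thresholds.high_conf_ab
    return "high" if high else "low"


def exclude_low_ab(calls, thresholds: TriageThresholds = DEFAULT_THRESHOLDS):
    """Drop calls with AB <= exclusion threshold (boundary excluded)."""
    return [c for c in calls
            if c.dp > 0 and allele_balance(c.ad_alt, c.dp) > thresholds.exclusion_ab]


def annotate_triage(calls, thresholds: TriageThresholds = DEFAULT_THRESHOLDS):
    """Return calls with confidence and exclusion flags attached."""
    out = []
    for c in calls:
        excluded = c.dp == 0 or allele_balance(c.ad_alt, c.dp) <= thresholds.exclusion_ab
        out.append(c.annotated(confidence=classify_confidence(c, thresholds),
                               excluded_low_ab=excluded))
    return out
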