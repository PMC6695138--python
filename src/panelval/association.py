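"""Exact inference for 2x2 tables and carrier-frequency computation.

For a table [[a, b], [c, d]] with fixed margins, the two-sided Fisher
p-value sums hypergeometric probabilities not exceeding that of the
observed table (minimum-likelihood rule, with the customary 1 + 1e-7
relative tolerance on the comparison). The reported odds ratio is the
*conditional maximum-likelihood* estimate — the noncentrality psi
maximizing the Fisher noncentral hypergeometric likelihood of the
observed first cell — with a 95% CI from inverting the two one-sided
exact tests (P(X >= a; psi_lo) = 0.025, P(X <= a; psi_hi) = 0.025).
This is the convention of R's ``fisher.test``; note the CMLE differs
from the sample cross-product ratio ad/bc. When the observed cell sits
at an attainable extreme of its support the estimate/bound degenerates
to 0 or infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .errors import ConfigurationError


@dataclass(frozen=True)
class TwoByTwo:
    """Counts [[a, b], [c, d]]: rows are groups, columns with/without
    the trait."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ConfigurationError("2x2 counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ConfigurationError("2x2 table is all zero")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def transpose(self) -> "TwoByTwo":
        return TwoByTwo(self.a, self.c, self.b, self.d)


@dataclass(frozen=True)
class ExactTestResult:
    p_two_sided: float
    or_cmle: float
    ci95_low: float
    ci95_high: float


def fisher_exact(table: TwoByTwo, confidence: float = 0.95) -> ExactTestResult:
    """Two-sided Fisher exact test with conditional-MLE odds ratio."""
    arr = table.array
    p = float(stats.fisher_exact(arr, alternative="two-sided").pvalue)
    res = _scipy_odds_ratio(arr, kind="conditional")
    ci = res.confidence_interval(confidence_level=confidence)
    return ExactTestResult(
        p_two_sided=p,
        or_cmle=float(res.statistic),
        ci95_low=float(ci.low),
        ci95_high=float(ci.high),
    )


def _log_nchg_likelihood(table: TwoByTwo, log_psi: np.ndarray) -> np.ndarray:
    """Log-likelihood of the observed first cell over a log-psi grid."""
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, col1 = a + b, a + c
    n = a + b + c + d
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    support = np.arange(lo, hi + 1)

    def logcomb(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    # log C(row1, k) + log C(n - row1, col1 - k)
    logw = logcomb(row1, support) + logcomb(n - row1, col1 - support)
    out = np.empty_like(log_psi, dtype=float)
    for i, lp in enumerate(np.atleast_1d(log_psi)):
        terms = logw + support * lp
        denom = np.logaddexp.reduce(terms)
        obs = logw[support == a][0] + a * lp
        out[i] = obs - denom
    return out


def cmle_oracle(table: TwoByTwo) -> float:
    """Grid-search conditional-MLE odds ratio (verification oracle).

    Maximizes the noncentral hypergeometric log-likelihood over
    log-psi in [-15, 15], refined twice around the best point. Used in
    tests as an implementation-independent check of
    :func:`fisher_exact`'s estimate; returns 0 / inf at the support
    boundary.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, col1 = a + b, a + c
    n = a + b + c + d
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    if a == lo and a == hi:
        return 1.0  # degenerate support
    if a == lo:
        return 0.0
    if a == hi:
        return math.inf
    grid = np.linspace(-15.0, 15.0, 601)
    for _ in range(3):
        ll = _log_nchg_likelihood(table, grid)
        best = grid[int(np.argmax(ll))]
        step = grid[1] - grid[0]
        grid = np.linspace(best - step, best + step, 201)
    return float(np.exp(best))


def carrier_maf(carriers: int, samples: int, zygosity: str = "all-het",
                hom_carriers: int = 0) -> float:
    """Cohort minor-allele frequency implied by carrier counts.

    ``all-het`` assumes every carrier is heterozygous: carriers / 2N.
    ``counted-alleles`` counts alleles explicitly:
    (het carriers + 2 x hom carriers) / 2N.
    """
    if samples <= 0:
        raise ConfigurationError("samples must be positive")
    if not 0 <= carriers <= samples:
        raise ConfigurationError("carriers must be within [0, samples]")
    if zygosity == "all-het":
        return carriers / (2 * samples)
    if zygosity == "counted-alleles":
        return (carriers + hom_carriers) / (2 * samples)
    raise ConfigurationError(f"unknown zygosity scheme {zygosity!r}")


def tp_carrier_table(labeled_calls, group_sizes: dict, groups=("AA", "EA"),
                     min_tp: int = 1) -> TwoByTwo:
    """2x2 table of individuals with >= ``min_tp`` validated calls by
    ancestry group, against the cohort composition.

    Row 1 = first group (with / without), row 2 = second group.
    """
    g1, g2 = groups
    counts = {g1: {}, g2: {}}
    for c in labeled_calls:
        if c.label == "TP" and c.group in counts:
            counts[c.group][c.sample] = counts[c.group].get(c.sample, 0) + 1
    with1 = sum(1 for v in counts[g1].values() if v >= min_tp)
    with2 = sum(1 for v in counts[g2].values() if v >= min_tp)
    return TwoByTwo(with1, group_sizes[g1] - with1,
                    with2, group_sizes[g2] - with2)
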