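"""Exact-test comparison of observed frequencies against null expectations.

Observed FISH association frequencies are compared with the random
expectation of the spatial null model by a two-sided Fisher's exact test
on a 2x2 table (observed associated/not vs. expected associated/not at
the same sample size), annotated with the conventional significance
tiers *P < 0.05, **P < 0.01, ***P < 0.001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import scipy.stats

from .errors import NucAssocError
from .scoring import FrequencySummary

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "fisher_exact_two_sided",
    "compare_to_null",
    "significance_stars",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: row 1 = observed associated / not, row 2 = expected."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c, self.d)
        if any(v < 0 for v in vals):
            raise NucAssocError("contingency counts must be non-negative")
        if all(v == 0 for v in vals):
            raise NucAssocError("contingency table must contain at least one count")

    def as_list(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


@dataclass(frozen=True)
class TestResult:
    table: ContingencyTable2x2
    p_value: float
    stars: str


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    The two-sided p sums the hypergeometric probabilities of all tables
    with the same margins whose point probability does not exceed that of
    the observed table (with a small relative tie tolerance).
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    p = scipy.stats.fisher_exact(table.as_list(), alternative="two-sided").pvalue
    return min(float(p), 1.0)


def significance_stars(p: float) -> str:
    """Significance tier for a p-value: ***, **, * or '' (strict cuts)."""
    if not (0.0 <= p <= 1.0) or math.isnan(p):
        raise NucAssocError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def compare_to_null(
    observed: FrequencySummary,
    null_percent: float,
    method: str = "fisher",
) -> TestResult:
    """Test an observed frequency against a null expectation (percent).

    ``method="fisher"`` (default) builds the 2x2 table
    ``[[k, n-k], [k0, n-k0]]`` with ``k0 = round(null_percent * n / 100)``
    — the expected counts at the observed sample size — and applies the
    two-sided Fisher's exact test, mirroring a comparison of two equally
    sized samples.  ``method="binomial"`` instead runs an exact two-sided
    binomial test of k out of n against the fixed null proportion.
    """
    if not (0.0 <= null_percent <= 100.0):
        raise NucAssocError(f"null_percent {null_percent} outside [0, 100]")
    if observed.n < 1:
        raise NucAssocError("observed summary has no scored units")
    k, n = observed.k, observed.n
    k0 = _round_half_up(null_percent * n / 100.0)
    table = ContingencyTable2x2(k, n - k, k0, n - k0)
    if method == "fisher":
        p = fisher_exact_two_sided(table)
    elif method == "binomial":
        p = float(scipy.stats.binomtest(k, n, null_percent / 100.0).pvalue)
    else:
        raise NucAssocError(f"unknown method {method!r}")
    return TestResult(table=table, p_value=p, stars=significance_stars(p))
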