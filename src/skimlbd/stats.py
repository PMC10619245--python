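"""Pairwise association statistics on 2x2 abstract-count tables.

For a term pair (x, y) over an N-document corpus the contingency table is

    a = abstracts containing both x and y
    b = abstracts containing x only
    c = abstracts containing y only
    d = abstracts containing neither

The canonical measure is the one-sided Fisher's Exact Test in the
enrichment direction: p = P(X >= a) for X ~ Hypergeometric(N, n_x, n_y),
including the observed table.  The tail is summed in log space so that
p-values far below double precision's normal range remain meaningful; a
p-value that underflows entirely maps deterministically to 0.0 and is
displayed as "0" (the display floor is 2.2e-308).  A chi-square measure is
provided as a non-canonical alternative; it is unreliable when expected
counts are small.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, NamedTuple, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2 as _chi2_dist

from skimlbd.index import CorpusIndex
from skimlbd.terms import TermSpec

#: p-values below this are displayed as "0" (smallest normal double).
P_DISPLAY_FLOOR = 2.2e-308

RESULTS_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 abstract counts for a term pair."""

    n_both: int
    n_x_only: int
    n_y_only: int
    n_neither: int

    def __post_init__(self) -> None:
        for name in ("n_both", "n_x_only", "n_y_only", "n_neither"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_x(self) -> int:
        return self.n_both + self.n_x_only

    @property
    def n_y(self) -> int:
        return self.n_both + self.n_y_only

    @property
    def n_total(self) -> int:
        return self.n_both + self.n_x_only + self.n_y_only + self.n_neither

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.n_both, self.n_y_only, self.n_x_only, self.n_neither)


@dataclass(frozen=True)
class PairResult:
    """Association result for one (x, y) term pair.

    ``ratio`` is n_both / n_y — the fraction of y's abstracts that also
    mention x (0 when y is absent from the corpus).  ``absent`` flags pairs
    where either term matched no eligible abstract; their p-value is 1.
    """

    x_label: str
    y_label: str
    table: ContingencyTable
    p_value: float
    pmid_evidence: frozenset[int]
    absent: bool = False

    @property
    def ratio(self) -> float:
        if self.table.n_y == 0:
            return 0.0
        return self.table.n_both / self.table.n_y

    def sort_key(self) -> tuple:
        # ascending p, then stronger overlap first, then labels: a total,
        # deterministic order for reproducible result files
        return (self.p_value, -self.table.n_both, self.x_label, self.y_label)


# ---------------------------------------------------------------------------
# Table construction from the index
# ---------------------------------------------------------------------------


def contingency(
    index: CorpusIndex,
    term_x: TermSpec | str,
    term_y: TermSpec | str,
    cutoff_year: int | None = None,
) -> ContingencyTable:
    """Count abstracts containing both terms, each alone, and neither.

    All matching, and the total N, are restricted to documents eligible
    under ``cutoff_year``.
    """
    hits_x = index.match_term(term_x, cutoff_year=cutoff_year)
    hits_y = index.match_term(term_y, cutoff_year=cutoff_year)
    n_total = index.n_eligible(cutoff_year)
    a = len(hits_x & hits_y)
    b = len(hits_x) - a
    c = len(hits_y) - a
    return ContingencyTable(a, b, c, n_total - a - b - c)


def pair_result(
    index: CorpusIndex,
    term_x: TermSpec | str,
    term_y: TermSpec | str,
    cutoff_year: int | None = None,
    measure: str = "fet",
) -> PairResult:
    """Build the full association result (table, p-value, evidence PMIDs)."""
    term_x = TermSpec.coerce(term_x)
    term_y = TermSpec.coerce(term_y)
    hits_x = index.match_term(term_x, cutoff_year=cutoff_year)
    hits_y = index.match_term(term_y, cutoff_year=cutoff_year)
    both = hits_x & hits_y
    n_total = index.n_eligible(cutoff_year)
    table = ContingencyTable(
        len(both), len(hits_x) - len(both), len(hits_y) - len(both),
        n_total - len(hits_x | hits_y),
    )
    absent = table.n_x == 0 or table.n_y == 0
    if absent:
        p = 1.0
    elif measure == "fet":
        p = fisher_one_sided(table)
    elif measure == "chi2":
        p = chi_square(table).p_value
    else:
        raise ValueError(f"unknown association measure {measure!r}")
    return PairResult(
        x_label=term_x.label,
        y_label=term_y.label,
        table=table,
        p_value=p,
        pmid_evidence=frozenset(both),
        absent=absent,
    )


# ---------------------------------------------------------------------------
# Exact test
# ---------------------------------------------------------------------------


def _log_hypergeom_pmf(ks: np.ndarray, n_total: int, n_x: int, n_y: int) -> np.ndarray:
    return (
        gammaln(n_x + 1)
        - gammaln(ks + 1)
        - gammaln(n_x - ks + 1)
        + gammaln(n_total - n_x + 1)
        - gammaln(n_y - ks + 1)
        - gammaln(n_total - n_x - n_y + ks + 1)
        - (gammaln(n_total + 1) - gammaln(n_y + 1) - gammaln(n_total - n_y + 1))
    )


def log_fisher_one_sided(table: ContingencyTable) -> float:
    """Natural log of the enrichment tail P(X >= a), without underflow."""
    a = table.n_both
    n_total, n_x, n_y = table.n_total, table.n_x, table.n_y
    k_min = max(0, n_x + n_y - n_total)
    k_max = min(n_x, n_y)
    if a <= k_min:
        return 0.0  # the whole support: p = 1
    ks = np.arange(a, k_max + 1)
    if ks.size == 0:
        # a beyond the support is impossible for a valid table
        raise ValueError("observed count exceeds the hypergeometric support")
    if ks.size <= 64:
        # scalar path: cheaper than numpy for tiny tails, and math.lgamma is
        # accurate to a few ulp
        log_den = (
            math.lgamma(n_total + 1) - math.lgamma(n_y + 1) - math.lgamma(n_total - n_y + 1)
        )
        logs = [
            math.lgamma(n_x + 1)
            - math.lgamma(k + 1)
            - math.lgamma(n_x - k + 1)
            + math.lgamma(n_total - n_x + 1)
            - math.lgamma(n_y - k + 1)
            - math.lgamma(n_total - n_x - n_y + k + 1)
            - log_den
            for k in range(a, k_max + 1)
        ]
        peak = max(logs)
        total = sum(math.exp(val - peak) for val in logs)
        log_p = peak + math.log(total)
    else:
        log_p = float(logsumexp(_log_hypergeom_pmf(ks, n_total, n_x, n_y)))
    return min(log_p, 0.0)


def fisher_one_sided(table: ContingencyTable) -> float:
    """One-sided (enrichment) Fisher's Exact Test p-value.

    P(X >= a) for X ~ Hypergeometric(N, n_x, n_y), observed table included.
    Underflow below the subnormal range maps to 0.0; the display convention
    (:func:`format_p`) renders anything below 2.2e-308 as "0".
    """
    if table.n_both == 0:
        return 1.0
    return math.exp(log_fisher_one_sided(table))


class ChiSquareResult(NamedTuple):
    statistic: float
    p_value: float
    degenerate: bool


def chi_square(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square on the 2x2 table, 1 df, no continuity correction.

    Unreliable when expected counts are small; provided only as an
    alternative measure.  Any zero margin makes the statistic undefined:
    the result is flagged degenerate with p = 1.
    """
    n = table.n_total
    row1, row2 = table.n_x, table.n_total - table.n_x
    col1, col2 = table.n_y, table.n_total - table.n_y
    if 0 in (row1, row2, col1, col2):
        return ChiSquareResult(statistic=0.0, p_value=1.0, degenerate=True)
    observed = np.array(
        [[table.n_both, table.n_x_only], [table.n_y_only, table.n_neither]], dtype=float
    )
    expected = np.outer([row1, row2], [col1, col2]) / n
    statistic = float(((observed - expected) ** 2 / expected).sum())
    return ChiSquareResult(
        statistic=statistic, p_value=float(_chi2_dist.sf(statistic, df=1)), degenerate=False
    )


def format_p(p: float) -> str:
    """Display form of a p-value: "0" below the 2.2e-308 floor, otherwise
    one-significant-figure scientific notation ("2e-33"), with values at
    percent scale or above rendered as plain decimals ("0.2", "1")."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p!r} outside [0, 1]")
    if p < P_DISPLAY_FLOOR:
        return "0"
    mantissa, exponent = f"{p:.0e}".split("e")
    exp = int(exponent)
    # rounding can carry the mantissa to 10 (e.g. 9.7e-3 -> 10e-3)
    if mantissa == "10":
        mantissa, exp = "1", exp + 1
    if exp >= -2:
        value = float(mantissa) * 10.0**exp
        return f"{value:.10g}"
    return f"{mantissa}e{exp}"


# ---------------------------------------------------------------------------
# Single-stage KinderMiner query: every A term against every B term
# ---------------------------------------------------------------------------


def km_query(
    a_terms: Sequence[TermSpec | str],
    b_terms: Sequence[TermSpec | str],
    index: CorpusIndex,
    cutoff_year: int | None = None,
    measure: str = "fet",
) -> list[PairResult]:
    """All (a, b) association results, ascending by p with deterministic ties."""
    if not a_terms or not b_terms:
        raise ValueError("km_query requires non-empty A and B term lists")
    results = [
        pair_result(index, a, b, cutoff_year=cutoff_year, measure=measure)
        for a in a_terms
        for b in b_terms
    ]
    results.sort(key=PairResult.sort_key)
    return results


RESULTS_COLUMNS = [
    "x_label", "y_label", "n_x", "n_y", "n_both", "N",
    "p_value", "p_display", "ratio", "evidence_pmids",
]


def write_results_tsv(
    results: Sequence[PairResult],
    dest: str | Path | IO[str],
    max_evidence: int = 20,
) -> None:
    """Write pairwise results as TSV with a versioned header comment line."""
    close = False
    if isinstance(dest, (str, Path)):
        handle: IO[str] = open(dest, "w", encoding="utf-8", newline="")
        close = True
    else:
        handle = dest
    try:
        handle.write(f"# skimlbd pair-results v{RESULTS_SCHEMA_VERSION}\n")
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(RESULTS_COLUMNS)
        for res in results:
            evidence = ",".join(str(p) for p in sorted(res.pmid_evidence)[:max_evidence])
            writer.writerow(
                [
                    res.x_label,
                    res.y_label,
                    res.table.n_x,
                    res.table.n_y,
                    res.table.n_both,
                    res.table.n_total,
                    repr(res.p_value),
                    format_p(res.p_value),
                    f"{res.ratio:.6g}",
                    evidence,
                ]
            )
    finally:
        if close:
            handle.close()
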