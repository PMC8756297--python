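"""The KinderMiner statistic: contingency tables, one-sided Fisher's
exact test, threshold filtering and ratio ranking.

For each target term the corpus is partitioned by presence/absence of
the term and of the key phrase into a 2x2 table with cells
``a = |term & key|``, ``b = |term & ~key|``, ``c = |~term & key|``,
``d = |~term & ~key|`` summing to the eligible corpus size ``N``.  The
one-sided Fisher p-value is the upper-tail hypergeometric probability

    p = sum_{x=a}^{min(T,K)} C(K, x) C(N-K, T-x) / C(N, T)

with ``T = a+b`` (term margin) and ``K = a+c`` (key-phrase margin); a
small p indicates enrichment of the term among key-phrase documents.
Terms passing a significance threshold are ranked by the association
proportion ``a / T``.  The tail sum is evaluated in log space with
cached log-factorials so it stays finite for corpora of tens of
millions of documents.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO

import numpy as np
from scipy.special import logsumexp

from .text_index import CorpusIndex, UnmatchablePhraseError, tokenize

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 1e-5


@dataclass(frozen=True)
class ContingencyTable:
    """Document-level 2x2 co-occurrence table for one (term, key) pair."""

    n_both: int   # a
    n_term: int   # T = a + b
    n_key: int    # K = a + c
    n_total: int  # N

    def __post_init__(self) -> None:
        a, t, k, n = self.n_both, self.n_term, self.n_key, self.n_total
        for name, value in (
            ("n_both", a), ("n_term", t), ("n_key", k), ("n_total", n)
        ):
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
        if a > t:
            raise ValueError(f"inconsistent table: n_both ({a}) > n_term ({t})")
        if a > k:
            raise ValueError(f"inconsistent table: n_both ({a}) > n_key ({k})")
        if t > n:
            raise ValueError(f"inconsistent table: n_term ({t}) > n_total ({n})")
        if k > n:
            raise ValueError(f"inconsistent table: n_key ({k}) > n_total ({n})")
        if n - t - k + a < 0:
            raise ValueError(
                f"inconsistent table: implied d cell negative "
                f"(n_both ({a}) < n_term + n_key - n_total ({t + k - n}))"
            )

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """The (a, b, c, d) cells."""
        a, t, k, n = self.n_both, self.n_term, self.n_key, self.n_total
        return a, t - a, k - a, n - t - k + a


def make_contingency(
    n_both: int, n_term: int, n_key: int, n_total: int
) -> ContingencyTable:
    """Build and validate a contingency table from the three document
    counts and the corpus size."""
    return ContingencyTable(n_both, n_term, n_key, n_total)


class _LogFactorialCache:
    """Incrementally grown table of log(k!)."""

    def __init__(self) -> None:
        self._table = np.zeros(2)

    def __call__(self, upto: int) -> np.ndarray:
        if upto >= len(self._table):
            start = len(self._table)
            grown = np.empty(upto + 1)
            grown[:start] = self._table
            grown[start:] = np.log(np.arange(start, upto + 1))
            self._table = np.cumsum(grown) if start == 0 else grown
            if start > 0:
                self._table[start:] = self._table[start - 1] + np.cumsum(
                    grown[start:]
                )
        return self._table


_log_factorial = _LogFactorialCache()


def fisher_one_sided(
    table: ContingencyTable, alternative: str = "enrichment"
) -> float:
    """One-sided Fisher's exact test p-value for a 2x2 table.

    ``alternative="enrichment"`` (default) returns the upper-tail
    probability P(X >= a) under the hypergeometric null with the
    table's margins fixed — the direction KinderMiner filters on.
    ``"depletion"`` returns the lower tail P(X <= a).  Deterministic,
    computed in log space; the result is clipped to (0, 1].
    """
    a, t, k, n = table.n_both, table.n_term, table.n_key, table.n_total
    if alternative not in ("enrichment", "depletion"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if t > k:
        t, k = k, t  # hypergeometric is symmetric in the margins
    lo, hi = max(0, t + k - n), min(t, k)
    # a tail covering the whole support is exactly 1
    if alternative == "enrichment" and a <= lo:
        return 1.0
    if alternative == "depletion" and a >= hi:
        return 1.0
    lf = _log_factorial(n)

    if alternative == "enrichment":
        xs = np.arange(a, hi + 1)
    else:
        xs = np.arange(lo, a + 1)
    # log C(K,x) + log C(N-K, T-x) - log C(N, T)
    log_terms = (
        lf[k] - lf[xs] - lf[k - xs]
        + lf[n - k] - lf[t - xs] - lf[n - k - (t - xs)]
        - (lf[n] - lf[t] - lf[n - t])
    )
    p = float(np.exp(logsumexp(log_terms)))
    return min(p, 1.0)


def hypergeom_log_pmf(table: ContingencyTable) -> float:
    """Log point probability of the observed a cell (same machinery as
    the tail sum; exposed for normalization checks)."""
    a, t, k, n = table.n_both, table.n_term, table.n_key, table.n_total
    lf = _log_factorial(n)
    return float(
        lf[k] - lf[a] - lf[k - a]
        + lf[n - k] - lf[t - a] - lf[n - k - t + a]
        - (lf[n] - lf[t] - lf[n - t])
    )


@dataclass(frozen=True)
class KMResult:
    """One row of the results list for a single target term."""

    term: str
    n_term: int
    n_key: int
    n_both: int
    n_total: int
    p_value: float
    ratio: float
    passes: bool
    rank: Optional[int] = None
    note: str = ""


@dataclass
class QuerySpec:
    """A full KinderMiner query.

    ``threshold`` defaults to 1e-5; the filter is strict (p < threshold).
    ``target_terms`` are deduplicated case-insensitively, first
    occurrence preserved.
    """

    key_phrase: str
    target_terms: Sequence[str]
    censor_year: Optional[int] = None
    threshold: float = DEFAULT_THRESHOLD
    alternative: str = "enrichment"

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        seen: set[str] = set()
        deduped = []
        for term in self.target_terms:
            key = term.strip().casefold()
            if key and key not in seen:
                seen.add(key)
                deduped.append(term.strip())
        if not deduped:
            raise ValueError("target term list is empty after deduplication")
        self.target_terms = deduped


def km_rank(
    term_counts: Iterable[tuple[str, int, int]],
    n_key: int,
    n_total: int,
    threshold: float = DEFAULT_THRESHOLD,
    alternative: str = "enrichment",
) -> list[KMResult]:
    """Score, filter and rank terms from their document counts.

    ``term_counts`` holds ``(term, n_term, n_both)`` triples.  Every
    input term yields a result row (the full downloadable list); terms
    with ``p < threshold`` and a non-empty term margin pass and are
    ranked 1..m by ratio descending, ties broken by p ascending then
    term (case-folded) lexicographically, so output is deterministic.
    Terms never seen in the corpus are retained with p = 1, ratio 0 and
    a note, not silently dropped.
    """
    results: list[KMResult] = []
    for term, n_term, n_both in term_counts:
        try:
            table = make_contingency(n_both, n_term, n_key, n_total)
        except ValueError as exc:
            raise ValueError(f"term {term!r}: {exc}") from exc
        if n_term == 0:
            p, ratio, note = 1.0, 0.0, "term not found in corpus"
        else:
            p = fisher_one_sided(table, alternative=alternative)
            ratio = n_both / n_term
            note = ""
        results.append(
            KMResult(
                term=term, n_term=n_term, n_key=n_key, n_both=n_both,
                n_total=n_total, p_value=p, ratio=ratio,
                passes=(p < threshold and n_term > 0), note=note,
            )
        )
    passing = [r for r in results if r.passes]
    passing.sort(key=lambda r: (-r.ratio, r.p_value, r.term.casefold()))
    rank_of = {r.term: i + 1 for i, r in enumerate(passing)}
    ranked = [
        KMResult(
            term=r.term, n_term=r.n_term, n_key=r.n_key, n_both=r.n_both,
            n_total=r.n_total, p_value=r.p_value, ratio=r.ratio,
            passes=r.passes, rank=rank_of.get(r.term), note=r.note,
        )
        for r in results
    ]
    # full list in rank order first, then non-passing by the same key
    ranked.sort(
        key=lambda r: (
            0 if r.rank is not None else 1,
            r.rank if r.rank is not None else 0,
            -r.ratio, r.p_value, r.term.casefold(),
        )
    )
    return ranked


def run_query(index: CorpusIndex, spec: QuerySpec) -> list[KMResult]:
    """Execute a query against an index: count margins, test, rank.

    The result depends only on index content and the query, not on
    record insertion order.  A key phrase that tokenizes to nothing is
    an error; target terms that tokenize to nothing are reported with
    zero counts and a warning.
    """
    key_tokens = tokenize(spec.key_phrase)
    if not key_tokens:
        raise UnmatchablePhraseError(
            f"unmatchable key phrase {spec.key_phrase!r}"
        )
    n_total = index.corpus_size(spec.censor_year)
    n_key = index.count_phrase(key_tokens, spec.censor_year)
    term_counts = []
    for term in spec.target_terms:
        term_tokens = tokenize(term)
        if not term_tokens:
            logger.warning("target term %r tokenizes to nothing", term)
            term_counts.append((term, 0, 0))
            continue
        n_term = index.count_phrase(term_tokens, spec.censor_year)
        n_both = (
            index.count_cooccurrence(term_tokens, key_tokens, spec.censor_year)
            if n_term
            else 0
        )
        term_counts.append((term, n_term, n_both))
    return km_rank(
        term_counts, n_key, n_total,
        threshold=spec.threshold, alternative=spec.alternative,
    )


def format_p_value(p: float) -> str:
    """6 significant digits; scientific notation below 1e-4."""
    if p != 0 and p < 1e-4:
        return f"{p:.5e}"
    return f"{p:.6g}"


TSV_COLUMNS = (
    "term", "n_term", "n_key", "n_both", "n_total",
    "p_value", "ratio", "rank", "passes",
)


def write_results_tsv(
    results: Iterable[KMResult], handle: TextIO, only_passing: bool = False
) -> int:
    """Write results as TSV with the canonical column set; returns the
    number of rows written."""
    handle.write("\t".join(TSV_COLUMNS) + "\n")
    n = 0
    for r in results:
        if only_passing and not r.passes:
            continue
        handle.write(
            "\t".join(
                [
                    r.term,
                    str(r.n_term), str(r.n_key), str(r.n_both), str(r.n_total),
                    format_p_value(r.p_value),
                    f"{r.ratio:.6g}",
                    "" if r.rank is None else str(r.rank),
                    "true" if r.passes else "false",
                ]
            )
            + "\n"
        )
        n += 1
    return n
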