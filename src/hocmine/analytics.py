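"""Query-hallmark association statistics over a classified collection.

Given sentence-level hallmark predictions, a plain-text query is matched as
a case-insensitive contiguous token phrase, and per-hallmark association is
quantified from sentence co-occurrence counts:

* CPROB — the conditional probability P(h | q) = P(h, q) / P(q),
* PMI   — log P(h, q) / (P(h) P(q))  (natural log, nats),
* NPMI  — PMI / (-log P(h, q)), bounded in [-1, 1].

Two queries are compared per hallmark with a 2x2 test on their matched
sentence sets: Fisher's exact test when any expected cell count falls below
five, otherwise Pearson's chi-squared (1 df, no continuity correction), with
Bonferroni correction over the number of hallmarks tested.

Probabilities are estimated over the whole supplied collection; undefined
quantities (e.g. PMI with zero joint count) are returned as ``None``, never
silently zeroed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from scipy import stats

from .corpus_io import SentenceRecord
from .taxonomy import Taxonomy

__all__ = [
    "CooccurrenceCounts",
    "AssociationResult",
    "ComparisonResult",
    "match_query",
    "count_cooccurrence",
    "cprob",
    "pmi_npmi",
    "choose_test",
    "fisher_exact",
    "chi2_test",
    "association_profile",
    "compare_queries",
]

SentenceId = Tuple[str, int]


@dataclass(frozen=True)
class CooccurrenceCounts:
    """Sentence counts: total N, query matches n_q, hallmark-positive n_h,
    and joint n_hq."""

    N: int
    n_q: int
    n_h: int
    n_hq: int

    def __post_init__(self):
        if not (0 <= self.n_hq <= min(self.n_q, self.n_h) and max(self.n_q, self.n_h) <= self.N):
            raise ValueError(f"inconsistent co-occurrence counts {self}")


@dataclass
class NodeAssociation:
    counts: CooccurrenceCounts
    cprob: Optional[float]
    pmi: Optional[float]
    npmi: Optional[float]


@dataclass
class AssociationResult:
    query: str
    per_node: Dict[str, NodeAssociation]


@dataclass
class NodeComparison:
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    test_used: str
    p_raw: float
    p_corrected: float
    degenerate: bool = False


@dataclass
class ComparisonResult:
    query_a: str
    query_b: str
    per_node: Dict[str, NodeComparison]
    n_tests: int
    overlap: int  # sentences matched by both queries (counted in both rows)


# ----------------------------------------------------------------- matching


def match_query(sentences: Sequence[SentenceRecord], query: str) -> Set[SentenceId]:
    """Case-insensitive contiguous token-phrase match over sentence tokens."""
    words = query.lower().split()
    if not words:
        raise ValueError("empty query")
    m = len(words)
    matched: Set[SentenceId] = set()
    for s in sentences:
        toks = [t.lower() for t in s.tokens]
        for i in range(len(toks) - m + 1):
            if toks[i : i + m] == words:
                matched.add(s.sentence_id)
                break
    return matched


def _bears(s: SentenceRecord, code: str) -> bool:
    return code in s.predicted_labels


def count_cooccurrence(
    sentences: Sequence[SentenceRecord],
    matched: Set[SentenceId],
    code: str,
) -> CooccurrenceCounts:
    if not sentences:
        raise ValueError("empty collection")
    n_q = n_h = n_hq = 0
    for s in sentences:
        q = s.sentence_id in matched
        h = _bears(s, code)
        n_q += q
        n_h += h
        n_hq += q and h
    return CooccurrenceCounts(N=len(sentences), n_q=n_q, n_h=n_h, n_hq=n_hq)


# --------------------------------------------------------------- statistics


def cprob(c: CooccurrenceCounts) -> Optional[float]:
    """P(h | q) = n_hq / n_q; None when the query matches nothing."""
    if c.n_q == 0:
        return None
    return c.n_hq / c.n_q


def pmi_npmi(c: CooccurrenceCounts) -> Tuple[Optional[float], Optional[float]]:
    """Natural-log PMI and NPMI from the count estimates.

    PMI is undefined (None) when any of n_hq, n_h, n_q is zero; NPMI is
    additionally undefined when P(h, q) = 1, where -log P(h, q) vanishes.
    """
    if c.n_hq == 0 or c.n_h == 0 or c.n_q == 0:
        return None, None
    p_hq = c.n_hq / c.N
    p_h = c.n_h / c.N
    p_q = c.n_q / c.N
    pmi = math.log(p_hq / (p_h * p_q))
    if p_hq == 1.0:
        return pmi, None
    return pmi, pmi / (-math.log(p_hq))


def association_profile(
    sentences: Sequence[SentenceRecord],
    query: str,
    taxonomy: Taxonomy,
    codes: Optional[Sequence[str]] = None,
) -> AssociationResult:
    codes = list(codes) if codes is not None else taxonomy.codes
    matched = match_query(sentences, query)
    per_node: Dict[str, NodeAssociation] = {}
    for code in codes:
        counts = count_cooccurrence(sentences, matched, code)
        pmi, npmi = pmi_npmi(counts)
        per_node[code] = NodeAssociation(
            counts=counts, cprob=cprob(counts), pmi=pmi, npmi=npmi
        )
    return AssociationResult(query=query, per_node=per_node)


# ------------------------------------------------------------ 2x2 testing


Table = Tuple[Tuple[int, int], Tuple[int, int]]


def _margins(table: Table) -> Tuple[int, int, int, int, int]:
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if n == 0:
        raise ValueError("empty table")
    return r1, r2, c1, c2, n


def choose_test(table: Table) -> str:
    """Route to ``"fisher"`` when any expected cell count (row total x column
    total / N) is below five, else ``"chi2"``.  A zero marginal makes the
    table degenerate: Fisher with p = 1."""
    r1, r2, c1, c2, n = _margins(table)
    if 0 in (r1, r2, c1, c2):
        return "fisher"
    expected = [r * c / n for r in (r1, r2) for c in (c1, c2)]
    return "fisher" if any(e < 5 for e in expected) else "chi2"


def fisher_exact(table: Table) -> float:
    """Two-sided Fisher exact p by the point-probability method.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table.
    Computed in exact integer arithmetic (binomial coefficients), so ties
    are resolved exactly; the float division happens once at the end.
    """
    (a, _), (c, _) = table
    r1, r2, c1, c2, n = _margins(table)
    if 0 in (r1, r2, c1, c2):
        return 1.0
    observed = math.comb(r1, a) * math.comb(r2, c)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    numerator = 0
    for k in range(lo, hi + 1):
        term = math.comb(r1, k) * math.comb(r2, c1 - k)
        if term <= observed:
            numerator += term
    return numerator / math.comb(n, c1)


def chi2_test(table: Table) -> float:
    """Pearson chi-squared p-value, 1 df, no continuity correction."""
    _margins(table)
    result = stats.chi2_contingency(table, correction=False)
    return float(result.pvalue)


def compare_queries(
    sentences: Sequence[SentenceRecord],
    query_a: str,
    query_b: str,
    taxonomy: Taxonomy,
    codes: Optional[Sequence[str]] = None,
) -> ComparisonResult:
    """Per-hallmark 2x2 comparison of two queries' matched sentence sets.

    Rows are the two queries' matches (a sentence matching both is counted
    in both rows and reported in ``overlap``); columns split each row by
    hallmark presence.  The expected-frequency rule selects Fisher or
    chi-squared per node; Bonferroni correction uses m = number of nodes
    tested.
    """
    codes = list(codes) if codes is not None else taxonomy.codes
    matched_a = match_query(sentences, query_a)
    matched_b = match_query(sentences, query_b)
    if not matched_a:
        raise ValueError(f"query {query_a!r} matches no sentences")
    if not matched_b:
        raise ValueError(f"query {query_b!r} matches no sentences")
    by_id = {s.sentence_id: s for s in sentences}
    m = len(codes)
    per_node: Dict[str, NodeComparison] = {}
    for code in codes:
        a_with = sum(1 for sid in matched_a if _bears(by_id[sid], code))
        b_with = sum(1 for sid in matched_b if _bears(by_id[sid], code))
        table = (
            (a_with, len(matched_a) - a_with),
            (b_with, len(matched_b) - b_with),
        )
        test = choose_test(table)
        degenerate = 0 in _margins(table)[:4]
        p_raw = fisher_exact(table) if test == "fisher" else chi2_test(table)
        per_node[code] = NodeComparison(
            table=table,
            test_used=test,
            p_raw=p_raw,
            p_corrected=min(1.0, m * p_raw),
            degenerate=degenerate,
        )
    return ComparisonResult(
        query_a=query_a,
        query_b=query_b,
        per_node=per_node,
        n_tests=m,
        overlap=len(matched_a & matched_b),
    )
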