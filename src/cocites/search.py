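"""The two citation-based searches and their screening thresholds.

The method starts from one or more known relevant *query articles* and runs
two searches over a citation graph:

* **Co-citation search** — collect the unique publications that cite any
  query article, walk their reference lists, and count for every other
  article the number of reference lists it appears in.  Each reference list
  contributes at most one count per article (reference lists are sets of
  unique identifiers).  An article frequently co-cited with the query set is
  likely on the same topic.

* **Citation search** — count, for every other article, the number of
  distinct query articles it cites or is cited by.  This catches recent
  articles that have not yet accumulated co-citations.

Candidates are ranked by frequency (competition ranking: ties share the
smallest applicable rank) and screened down by one of three threshold kinds:
a minimum count, a minimum count combined with a minimum fraction of the
citing publications (strict inequality), or the top *k* ranks including
every candidate tied with the k-th.

The two-stage workflow (:func:`run_cocites`) chains them: candidates passing
the co-citation threshold and judged relevant are added to the query set,
and the citation search runs on the expanded set.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional

from .corpus import CitationGraph
from .errors import UsageError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedCandidate:
    """An article with its search frequency and competition rank."""

    article_id: str
    frequency: int
    rank: int


@dataclass(frozen=True)
class ThresholdSpec:
    """One screening rule.

    kind:
        ``min_count`` — keep frequency >= ``min_count``;
        ``min_count_and_fraction`` — keep frequency >= ``min_count`` AND
        frequency strictly greater than ``min_fraction`` times the number
        of citing publications;
        ``top_k_ties`` — keep the first ``k`` candidates plus every later
        candidate tied in frequency with the k-th.
    """

    kind: str
    min_count: int | None = None
    min_fraction: float | None = None
    k: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "min_count":
            ok = self.min_count is not None and self.min_fraction is None and self.k is None
        elif self.kind == "min_count_and_fraction":
            ok = (
                self.min_count is not None
                and self.min_fraction is not None
                and 0 < self.min_fraction < 1
                and self.k is None
            )
        elif self.kind == "top_k_ties":
            ok = self.k is not None and self.k >= 1 and self.min_count is None and self.min_fraction is None
        else:
            raise UsageError(f"unknown threshold kind {self.kind!r}")
        if not ok:
            raise UsageError(f"threshold fields inconsistent with kind {self.kind!r}")

    # The four named rules used throughout the validation analyses.

    @classmethod
    def all_cocited(cls) -> "ThresholdSpec":
        """Co-cited at least once: no exclusions."""
        return cls("min_count", min_count=1)

    @classmethod
    def gt1(cls) -> "ThresholdSpec":
        """Co-cited (or citing/cited) more than once."""
        return cls("min_count", min_count=2)

    @classmethod
    def pct1(cls) -> "ThresholdSpec":
        """Co-cited more than once AND in more than 1% of citing articles."""
        return cls("min_count_and_fraction", min_count=2, min_fraction=0.01)

    @classmethod
    def top100(cls) -> "ThresholdSpec":
        """The 100 top-ranked, keeping every article tied with the 100th."""
        return cls("top_k_ties", k=100)

    _NAMES = {
        "all": "all_cocited",
        "gt1": "gt1",
        "pct1": "pct1",
        "top100": "top100",
    }

    @classmethod
    def from_name(cls, name: str) -> "ThresholdSpec":
        try:
            return getattr(cls, cls._NAMES[name])()
        except KeyError:
            raise UsageError(
                f"unknown threshold name {name!r}; expected one of "
                f"{sorted(cls._NAMES)}"
            ) from None


@dataclass(frozen=True)
class SearchOutcome:
    """Everything produced by one two-stage search.

    ``cocite_ranked`` / ``citation_ranked`` are the full ranked lists after
    any start-year filtering but before thresholding; ``cocite_results`` /
    ``citation_results`` are the thresholded lists a user would screen.
    ``screened_total_sum`` adds the two thresholded list lengths without
    removing duplicates (the convention used when result formats cannot be
    merged); ``screened_total_dedup`` counts unique ids across both lists.
    """

    query_ids: frozenset[str]
    cocite_ranked: tuple[RankedCandidate, ...]
    cocite_results: tuple[RankedCandidate, ...]
    n_citing: int
    expanded_query: frozenset[str]
    citation_ranked: tuple[RankedCandidate, ...]
    citation_results: tuple[RankedCandidate, ...]
    screened_total_sum: int = field(default=0)
    screened_total_dedup: int = field(default=0)


def cocitation_counts(
    graph: CitationGraph, query_ids: Iterable[str]
) -> tuple[dict[str, int], int]:
    """Co-citation frequency of every article with the query set.

    Returns ``(freq, n_citing)`` where ``n_citing`` is the number of unique
    publications citing any query article and ``freq[a]`` is the number of
    those publications whose reference list contains ``a``.  Query articles
    are excluded from the map.  Every count lies in ``1..n_citing``.
    """
    query = set(query_ids)
    if not query:
        raise UsageError("query set must be non-empty")
    citers = graph.citers_of(query)
    freq: Counter[str] = Counter()
    for citer in citers:
        for ref in graph.references_of(citer):
            if ref not in query:
                freq[ref] += 1
    return dict(freq), len(citers)


def citation_counts(graph: CitationGraph, query_ids: Iterable[str]) -> dict[str, int]:
    """Number of distinct query articles each article cites or is cited by.

    An article related to the same query article in both directions counts
    once; the count is bounded by the query-set size.  Query articles are
    excluded from the map.
    """
    query = set(query_ids)
    if not query:
        raise UsageError("query set must be non-empty")
    freq: Counter[str] = Counter()
    for q in query:
        related = graph.citers_of(q) | graph.references_of(q)
        for a in related:
            if a not in query:
                freq[a] += 1
    return dict(freq)


def rank_candidates(
    freq: Mapping[str, int], graph: Optional[CitationGraph] = None
) -> list[RankedCandidate]:
    """Order a frequency map into a deterministic ranked list.

    Sort key: frequency descending, then publication year descending
    (unknown year last; requires ``graph``), then id ascending.  Ranks are
    competition-style: equal frequencies share the smallest applicable rank
    and the next distinct frequency skips ahead.
    """
    if any(c < 1 for c in freq.values()):
        raise UsageError("all frequencies must be >= 1")

    def year_key(article_id: str) -> int:
        if graph is None:
            return -(10**9)
        y = graph.pub_year(article_id)
        return -(10**9) if y is None else y

    ordered = sorted(
        freq.items(), key=lambda kv: (-kv[1], -year_key(kv[0]), kv[0])
    )
    out: list[RankedCandidate] = []
    for pos, (article_id, count) in enumerate(ordered, start=1):
        rank = out[-1].rank if out and out[-1].frequency == count else pos
        out.append(RankedCandidate(article_id, count, rank))
    return out


def apply_threshold(
    ranked: list[RankedCandidate] | tuple[RankedCandidate, ...],
    spec: ThresholdSpec,
    n_citing: int | None = None,
) -> list[RankedCandidate]:
    """Screen a ranked list down to the candidates passing ``spec``.

    For ``min_count_and_fraction``, ``n_citing`` (the unique-citer count of
    the search that produced the list) is required; ``n_citing == 0`` yields
    an empty result rather than an error.  The fraction test is a strict
    inequality: with 400 citers and a 1% rule, frequency 4 fails (4 > 4.0 is
    false) while frequency 5 passes.
    """
    ranked = list(ranked)
    if spec.kind == "min_count":
        return [c for c in ranked if c.frequency >= spec.min_count]
    if spec.kind == "min_count_and_fraction":
        if n_citing is None:
            raise UsageError("n_citing is required for the fraction threshold")
        if n_citing == 0:
            return []
        cut = spec.min_fraction * n_citing
        return [
            c for c in ranked if c.frequency >= spec.min_count and c.frequency > cut
        ]
    if spec.kind == "top_k_ties":
        if len(ranked) <= spec.k:
            return ranked
        boundary = ranked[spec.k - 1].frequency
        return [
            c for i, c in enumerate(ranked) if i < spec.k or c.frequency == boundary
        ]
    raise UsageError(f"unknown threshold kind {spec.kind!r}")


def expand_query_top_ranked(
    ranked: list[RankedCandidate] | tuple[RankedCandidate, ...], k: int = 25
) -> set[str]:
    """Ids of the first ``k`` ranked candidates, tie-inclusive.

    Used as a fallback citation-search query set when too few relevant
    articles pass the co-citation threshold to seed an effective citation
    search: the top-ranked co-citation results stand in without any
    relevance screening.  ``k`` larger than the list returns the whole list.
    """
    kept = apply_threshold(list(ranked), ThresholdSpec("top_k_ties", k=k))
    return {c.article_id for c in kept}


def _filter_start_year(
    ranked: list[RankedCandidate], graph: CitationGraph, start_year: int | None
) -> list[RankedCandidate]:
    """Drop candidates published before ``start_year``.

    Applied only when the original review restricted its search period to
    1980 or later, for a fair comparison of screening burden; candidates
    with unknown year are kept.
    """
    if start_year is None or start_year < 1980:
        return ranked
    out = []
    for c in ranked:
        y = graph.pub_year(c.article_id)
        if y is None or y >= start_year:
            out.append(c)
    return out


def run_cocites(
    graph: CitationGraph,
    initial_query: Iterable[str],
    relevance: Callable[[str], bool],
    cocite_spec: ThresholdSpec | None = None,
    cite_spec: ThresholdSpec | None = None,
    start_year: int | None = None,
    max_citers: int | None = None,
) -> SearchOutcome:
    """Two-stage search: co-citation, query expansion, citation.

    Stage 1 ranks co-citation candidates and screens them with
    ``cocite_spec`` (default: the >1-and->1% rule).  Candidates passing the
    threshold for which ``relevance`` returns True join the query set.
    Stage 2 ranks citation candidates for the expanded set and screens them
    with ``cite_spec`` (default: frequency >= 2).

    ``max_citers`` optionally caps the co-citation stage to the N most
    recent citing publications (unknown years last, ties by id) — a
    screening-burden control for very highly cited query sets; off by
    default.
    """
    query = frozenset(initial_query)
    if not query:
        raise UsageError("initial query set must be non-empty")
    cocite_spec = cocite_spec or ThresholdSpec.pct1()
    cite_spec = cite_spec or ThresholdSpec.gt1()

    if max_citers is None:
        freq, n_citing = cocitation_counts(graph, query)
    else:
        freq, n_citing = _capped_cocitation_counts(graph, query, max_citers)

    cocite_ranked = _filter_start_year(rank_candidates(freq, graph), graph, start_year)
    cocite_results = apply_threshold(cocite_ranked, cocite_spec, n_citing)

    relevant = {c.article_id for c in cocite_results if relevance(c.article_id)}
    expanded = query | relevant
    logger.debug(
        "co-citation stage: %d citers, %d candidates, %d passed threshold, "
        "%d relevant added to query set",
        n_citing, len(cocite_ranked), len(cocite_results), len(relevant),
    )

    cite_freq = citation_counts(graph, expanded)
    citation_ranked = _filter_start_year(
        rank_candidates(cite_freq, graph), graph, start_year
    )
    citation_results = apply_threshold(citation_ranked, cite_spec)

    dedup = {c.article_id for c in cocite_results} | {
        c.article_id for c in citation_results
    }
    return SearchOutcome(
        query_ids=query,
        cocite_ranked=tuple(cocite_ranked),
        cocite_results=tuple(cocite_results),
        n_citing=n_citing,
        expanded_query=frozenset(expanded),
        citation_ranked=tuple(citation_ranked),
        citation_results=tuple(citation_results),
        screened_total_sum=len(cocite_results) + len(citation_results),
        screened_total_dedup=len(dedup),
    )


def _capped_cocitation_counts(
    graph: CitationGraph, query: frozenset[str], max_citers: int
) -> tuple[dict[str, int], int]:
    """Co-citation counts using only the most recent ``max_citers`` citers."""
    citers = graph.citers_of(query)
    recent = sorted(
        citers,
        key=lambda a: (-(graph.pub_year(a) if graph.pub_year(a) is not None else -(10**9)), a),
    )[:max_citers]
    freq: Counter[str] = Counter()
    for citer in recent:
        for ref in graph.references_of(citer):
            if ref not in query:
                freq[ref] += 1
    return dict(freq), len(recent)
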