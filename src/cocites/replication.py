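"""Validation harness: replicate a review's literature search and score it.

A *review record* is the gold standard: the set of articles a published
systematic review actually included, plus its search period.  Replication
asks: starting only from the gold set's most highly cited members as query
articles, what fraction of the gold set do the co-citation and citation
searches recover, and how many titles must be screened to get there?

Conventions, matching the validation design:

* Query articles are selected by citation count *at the review's search
  end year* — the two most-cited, with a cap: if every selected article
  exceeds ``cap`` citations (default 1000), the lowest-ranked is replaced
  by the most-cited gold article under the cap.
* Retrieval percentages include the query articles in both numerator and
  denominator (they are excluded from their own co-citation results but a
  user of the method already has them in hand).
* Relevance during query expansion is membership in the gold set.
* The combined screening burden sums the thresholded co-citation list (at
  the >1-and->1% rule) and the thresholded citation list without removing
  duplicates; a deduplicated count is reported alongside.
* When the review restricted its search period to 1980 or later, earlier
  publications are dropped from both result lists before thresholding.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .corpus import CitationGraph
from .errors import ParseError, SelectionError, UsageError
from .search import (
    RankedCandidate,
    SearchOutcome,
    ThresholdSpec,
    apply_threshold,
    run_cocites,
)
from .similarity import SimilarityResult, simpson_similarity

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

REVIEW_HEADER = (
    "review_id",
    "included_ids",
    "search_end_year",
    "search_start_year",
    "n_screened_original",
)

#: The four co-citation screening rules evaluated per review, loosest last.
COCITE_THRESHOLD_NAMES = ("all", "gt1", "pct1", "top100")

#: Minimum gold-set size for a review to enter the harness.
DEFAULT_MIN_GOLD = 5


@dataclass(frozen=True)
class ReviewRecord:
    """One review's gold set and search period."""

    review_id: str
    included_ids: frozenset[str]
    search_end_year: int
    search_start_year: int | None = None
    n_screened_original: int | None = None

    def __post_init__(self) -> None:
        if (
            self.search_start_year is not None
            and self.search_start_year > self.search_end_year
        ):
            raise UsageError(
                f"review {self.review_id!r}: search_start_year "
                f"{self.search_start_year} exceeds search_end_year "
                f"{self.search_end_year}"
            )


@dataclass(frozen=True)
class ThresholdMetrics:
    """Screening burden and retrieval at one threshold."""

    n_screened: int
    n_retrieved: int
    pct_retrieved: float


@dataclass(frozen=True)
class ReviewFactors:
    """Review-level characteristics used for stratified summaries."""

    n_citing: int
    similarity: SimilarityResult | None
    pct_in_pubmed: float


@dataclass(frozen=True)
class ReplicationMetrics:
    """All replication results for one review."""

    review_id: str
    n_included: int
    query_ids: tuple[str, ...]
    cocite: Mapping[str, ThresholdMetrics]  # keyed by COCITE_THRESHOLD_NAMES
    citation: ThresholdMetrics
    combined_sum_screened: int
    combined_dedup_screened: int
    pct_retrieved_combined: float
    factors: ReviewFactors
    outcome: SearchOutcome = field(repr=False)


# -- review table I/O ------------------------------------------------------


def load_reviews(
    path: PathLike, min_gold: int = DEFAULT_MIN_GOLD
) -> list[ReviewRecord]:
    """Read the tab-separated review table; reject gold sets under ``min_gold``."""
    reviews: list[ReviewRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != REVIEW_HEADER:
            raise ParseError(
                f"{path}, line 1: expected header "
                f"{chr(9).join(REVIEW_HEADER)!r}, got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(REVIEW_HEADER):
                raise ParseError(
                    f"{path}, line {lineno}: expected {len(REVIEW_HEADER)} "
                    f"fields, got {len(row)}"
                )
            review_id, ids_s, end_s, start_s, screened_s = row
            included = frozenset(i for i in ids_s.split(";") if i)
            if len(included) < min_gold:
                raise ParseError(
                    f"{path}, line {lineno}: review {review_id!r} includes "
                    f"{len(included)} articles, fewer than the minimum {min_gold}"
                )
            try:
                end_year = int(end_s)
                start_year = int(start_s) if start_s else None
                screened = int(screened_s) if screened_s else None
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from None
            reviews.append(
                ReviewRecord(review_id, included, end_year, start_year, screened)
            )
    return reviews


def save_reviews(reviews: Iterable[ReviewRecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REVIEW_HEADER)
        for r in reviews:
            writer.writerow(
                [
                    r.review_id,
                    ";".join(sorted(r.included_ids)),
                    r.search_end_year,
                    "" if r.search_start_year is None else r.search_start_year,
                    "" if r.n_screened_original is None else r.n_screened_original,
                ]
            )


# -- query-article selection ----------------------------------------------


def select_query_articles(
    graph: CitationGraph,
    review: ReviewRecord,
    k: int = 2,
    cap: int = 1000,
    replace: str = "one",
) -> list[str]:
    """The ``k`` gold articles most cited at the review's search end year.

    Ties on count break by id ascending.  If every selected article exceeds
    ``cap`` citations, the cap rule substitutes the most-cited gold article
    with fewer than ``cap`` citations: with ``replace="one"`` (default) only
    the lowest-ranked selection is swapped out, keeping the single
    highest-cited query; with ``replace="both"`` the whole selection is
    redrawn from the under-cap candidates (falling back to over-cap ones if
    too few exist).
    """
    if replace not in ("one", "both"):
        raise UsageError(f"replace must be 'one' or 'both', got {replace!r}")
    counts = {
        a: graph.citation_count_at_year(a, review.search_end_year).count
        for a in review.included_ids
    }
    citable = sorted(
        (a for a in counts if counts[a] >= 1), key=lambda a: (-counts[a], a)
    )
    if len(citable) < k:
        raise SelectionError(
            f"review {review.review_id!r}: only {len(citable)} gold articles "
            f"have any citation at year {review.search_end_year}; need {k} "
            f"(candidates: {citable})"
        )
    selected = citable[:k]
    if all(counts[a] > cap for a in selected):
        under_cap = [a for a in citable if counts[a] < cap]
        if replace == "one":
            if under_cap:
                selected = selected[:-1] + [under_cap[0]]
        else:
            redrawn = under_cap[:k]
            redrawn += [a for a in selected if a not in redrawn][: k - len(redrawn)]
            selected = sorted(redrawn, key=lambda a: (-counts[a], a))
    return selected


def select_low_cited_queries(
    graph: CitationGraph,
    review: ReviewRecord,
    min_citations: int = 10,
    k: int = 2,
) -> list[str]:
    """The ``k`` gold articles with the fewest (but at least ``min_citations``)
    total citations — used to test whether a search seeded from obscure
    articles still surfaces the field's highly cited ones.  Ties by id.
    """
    counts = {a: graph.in_degree(a) for a in review.included_ids}
    qualifying = sorted(
        (a for a in counts if counts[a] >= min_citations),
        key=lambda a: (counts[a], a),
    )
    if len(qualifying) < k:
        raise SelectionError(
            f"review {review.review_id!r}: only {len(qualifying)} gold articles "
            f"have >= {min_citations} citations; need {k}"
        )
    return qualifying[:k]


# -- replication -----------------------------------------------------------


def _retrieval(
    result_ids: set[str], gold: frozenset[str], query_ids: Sequence[str]
) -> tuple[int, float]:
    """Retrieved count and percentage, crediting the query articles."""
    retrieved = (result_ids & gold) | set(query_ids)
    n = len(retrieved)
    return n, 100.0 * n / len(gold)


def replicate_review(
    graph: CitationGraph,
    review: ReviewRecord,
    query_ids: Sequence[str],
    cocite_expansion_spec: ThresholdSpec | None = None,
    cite_spec: ThresholdSpec | None = None,
    max_citers: int | None = None,
) -> ReplicationMetrics:
    """Run the two-stage search against one review's gold set and score it.

    Relevance (for query expansion) is membership in the gold set.  The
    co-citation stage is scored at all four named thresholds; the citation
    stage at ``cite_spec`` (default frequency >= 2); the combined figures
    pair the >1-and->1% co-citation list with the citation list.
    """
    gold = review.included_ids
    if not set(query_ids) <= gold:
        raise UsageError(
            f"query ids {sorted(set(query_ids) - gold)} are outside the "
            f"gold set of review {review.review_id!r}"
        )
    expansion_spec = cocite_expansion_spec or ThresholdSpec.pct1()
    outcome = run_cocites(
        graph,
        query_ids,
        relevance=lambda a: a in gold,
        cocite_spec=expansion_spec,
        cite_spec=cite_spec,
        start_year=review.search_start_year,
        max_citers=max_citers,
    )

    cocite_metrics: dict[str, ThresholdMetrics] = {}
    for name in COCITE_THRESHOLD_NAMES:
        kept = apply_threshold(
            list(outcome.cocite_ranked), ThresholdSpec.from_name(name), outcome.n_citing
        )
        ids = {c.article_id for c in kept}
        n_ret, pct = _retrieval(ids, gold, query_ids)
        cocite_metrics[name] = ThresholdMetrics(len(kept), n_ret, pct)

    cite_ids = {c.article_id for c in outcome.citation_results}
    n_ret, pct = _retrieval(cite_ids, gold, query_ids)
    citation_metrics = ThresholdMetrics(len(outcome.citation_results), n_ret, pct)

    combined_ids = {c.article_id for c in outcome.cocite_results} | cite_ids
    n_comb, pct_comb = _retrieval(combined_ids, gold, query_ids)

    pmid_share = 100.0 * sum(
        1 for a in gold if graph.article(a).pmid is not None
    ) / len(gold)
    if len(query_ids) == 2:
        sim = simpson_similarity(
            graph, query_ids[0], query_ids[1], numerator_year=review.search_end_year
        )
    else:
        sim = None

    return ReplicationMetrics(
        review_id=review.review_id,
        n_included=len(gold),
        query_ids=tuple(query_ids),
        cocite=cocite_metrics,
        citation=citation_metrics,
        combined_sum_screened=outcome.screened_total_sum,
        combined_dedup_screened=outcome.screened_total_dedup,
        pct_retrieved_combined=pct_comb,
        factors=ReviewFactors(outcome.n_citing, sim, pmid_share),
        outcome=outcome,
    )


def replicate_reviews(
    graph: CitationGraph,
    reviews: Iterable[ReviewRecord],
    **kwargs,
) -> tuple[list[ReplicationMetrics], list[tuple[str, str]]]:
    """Batch replication; reviews that cannot be replicated are skipped.

    Returns (metrics, skipped) where skipped pairs each skipped review id
    with the reason.  A review is skipped when its gold set references
    articles absent from the graph or has fewer than two citable articles.
    """
    metrics: list[ReplicationMetrics] = []
    skipped: list[tuple[str, str]] = []
    for review in reviews:
        missing = sorted(a for a in review.included_ids if a not in graph)
        if missing:
            reason = f"gold articles missing from graph: {missing}"
            logger.warning("skipping review %s: %s", review.review_id, reason)
            skipped.append((review.review_id, reason))
            continue
        try:
            queries = select_query_articles(graph, review)
        except SelectionError as exc:
            logger.warning("skipping review %s: %s", review.review_id, exc)
            skipped.append((review.review_id, str(exc)))
            continue
        metrics.append(replicate_review(graph, review, queries, **kwargs))
    return metrics, skipped


# -- stratified summaries --------------------------------------------------

_FACTOR_GETTERS = {
    "n_citing": lambda m: float(m.factors.n_citing),
    "similarity": lambda m: (
        m.factors.similarity.score
        if m.factors.similarity is not None and m.factors.similarity.defined
        else None
    ),
    "pct_in_pubmed": lambda m: m.factors.pct_in_pubmed,
}


def _quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="midpoint")
    return float(med), float(q1), float(q3)


def stratify_metrics(
    metrics: Sequence[ReplicationMetrics],
    factor: str,
    bin_edges: Sequence[float],
) -> pd.DataFrame:
    """Median combined retrieval by strata of a review-level factor.

    ``bin_edges`` [e0, e1, ..., en] define bins [e0,e1), [e1,e2), ...,
    [e(n-1), en) plus an open top bin [en, inf).  Quartiles use midpoint
    interpolation.  Reviews whose
    factor is undefined (e.g. similarity with zero denominator, or a
    single-article query set) are excluded.  Empty bins appear with n=0.
    """
    if factor not in _FACTOR_GETTERS:
        raise UsageError(
            f"unknown factor {factor!r}; expected one of {sorted(_FACTOR_GETTERS)}"
        )
    edges = list(bin_edges)
    if len(edges) < 2 or any(a >= b for a, b in zip(edges, edges[1:])):
        raise UsageError("bin_edges must be strictly increasing with >= 2 entries")
    getter = _FACTOR_GETTERS[factor]
    labels = [f"[{edges[i]}, {edges[i + 1]})" for i in range(len(edges) - 1)]
    labels.append(f">= {edges[-1]}")
    binned: dict[str, list[float]] = {lab: [] for lab in labels}
    for m in metrics:
        x = getter(m)
        if x is None:
            continue
        if x < edges[0]:
            raise UsageError(
                f"factor value {x} below the first bin edge {edges[0]}; "
                "bins must cover the observed range"
            )
        idx = int(np.searchsorted(edges[1:], x, side="right"))
        binned[labels[idx]].append(m.pct_retrieved_combined)
    rows = []
    for lab in labels:
        vals = binned[lab]
        if vals:
            med, q1, q3 = _quartiles(vals)
        else:
            med = q1 = q3 = float("nan")
        rows.append(
            {"bin": lab, "n_reviews": len(vals), "median_pct": med,
             "q1_pct": q1, "q3_pct": q3}
        )
    return pd.DataFrame(rows, columns=["bin", "n_reviews", "median_pct",
                                       "q1_pct", "q3_pct"])


# -- article-level factors -------------------------------------------------

NOT_INDEXED = "not indexed"


def _times_cited_bin(n: int | None) -> str:
    if n is None:
        return NOT_INDEXED
    if n == 0:
        return "0"
    if n <= 5:
        return "1-5"
    if n <= 9:
        return "6-9"
    if n <= 19:
        return "10-19"
    if n <= 49:
        return "20-49"
    return ">=50"


def _n_references_bin(graph: CitationGraph, article_id: str) -> str:
    if not graph.article(article_id).indexed:
        return NOT_INDEXED
    n = graph.out_degree(article_id)
    if n < 5:
        return "<5"
    if n <= 9:
        return "5-9"
    return ">=10"


def _years_since_pub_bin(pub_year: int | None, end_year: int) -> str | None:
    if pub_year is None:
        return None
    d = end_year - pub_year
    if d <= 0:
        return "0-1"
    if d == 1:
        return "1-2"
    if d <= 4:
        return "2-5"
    if d <= 9:
        return "5-10"
    return ">10"


def article_level_factors(
    graph: CitationGraph,
    review: ReviewRecord,
    outcome: SearchOutcome,
) -> pd.DataFrame:
    """Per-article retrieval table for one review, query articles excluded.

    One row per non-query gold article with its retrieval status in the
    co-citation stage and in the combined stages, and its citation
    characteristics binned: times cited (not-indexed items have no Times
    Cited count), reference-list length, indexing status, and years since
    publication relative to the search end year (None when year unknown).
    """
    cocite_ids = {c.article_id for c in outcome.cocite_results}
    combined_ids = cocite_ids | {c.article_id for c in outcome.citation_results}
    rows = []
    for a in sorted(review.included_ids - set(outcome.query_ids)):
        rec = graph.article(a)
        times_cited = graph.in_degree(a) if rec.indexed else None
        rows.append(
            {
                "review_id": review.review_id,
                "article_id": a,
                "retrieved_cocite": a in cocite_ids,
                "retrieved_combined": a in combined_ids,
                "times_cited_bin": _times_cited_bin(times_cited),
                "indexed": rec.indexed,
                "n_references_bin": _n_references_bin(graph, a),
                "years_since_pub_bin": _years_since_pub_bin(
                    rec.pub_year, review.search_end_year
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "review_id", "article_id", "retrieved_cocite", "retrieved_combined",
            "times_cited_bin", "indexed", "n_references_bin",
            "years_since_pub_bin",
        ],
    )


# -- target ranks ----------------------------------------------------------


def rank_of_targets(
    ranked: Sequence[RankedCandidate], target_ids: Iterable[str]
) -> pd.DataFrame:
    """Where do specific target articles land in a ranked result list?

    Reports each target's competition rank (NA if absent) and whether it
    falls in the tie-inclusive top 10 and top 100.
    """
    by_id = {c.article_id: c for c in ranked}
    top10 = {c.article_id for c in apply_threshold(list(ranked), ThresholdSpec("top_k_ties", k=10))}
    top100 = {c.article_id for c in apply_threshold(list(ranked), ThresholdSpec("top_k_ties", k=100))}
    rows = []
    for t in sorted(set(target_ids)):
        cand = by_id.get(t)
        rows.append(
            {
                "target_id": t,
                "rank": cand.rank if cand is not None else pd.NA,
                "in_top10": t in top10,
                "in_top100": t in top100,
            }
        )
    return pd.DataFrame(rows, columns=["target_id", "rank", "in_top10", "in_top100"])


# -- long-format metrics export -------------------------------------------


def metrics_to_long(metrics: Sequence[ReplicationMetrics]) -> pd.DataFrame:
    """One row per (review, threshold, measure) for TSV export."""
    rows = []
    for m in metrics:
        for name in COCITE_THRESHOLD_NAMES:
            tm = m.cocite[name]
            rows.append((m.review_id, f"cocite_{name}", "n_screened", tm.n_screened))
            rows.append((m.review_id, f"cocite_{name}", "pct_retrieved", tm.pct_retrieved))
        rows.append((m.review_id, "citation", "n_screened", m.citation.n_screened))
        rows.append((m.review_id, "citation", "pct_retrieved", m.citation.pct_retrieved))
        rows.append((m.review_id, "combined", "n_screened_sum", m.combined_sum_screened))
        rows.append((m.review_id, "combined", "n_screened_dedup", m.combined_dedup_screened))
        rows.append((m.review_id, "combined", "pct_retrieved", m.pct_retrieved_combined))
        rows.append((m.review_id, "factors", "n_citing", m.factors.n_citing))
        sim = m.factors.similarity
        if sim is not None and sim.defined:
            rows.append((m.review_id, "factors", "similarity", sim.score))
        rows.append((m.review_id, "factors", "pct_in_pubmed", m.factors.pct_in_pubmed))
    return pd.DataFrame(rows, columns=["review_id", "threshold", "measure", "value"])
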