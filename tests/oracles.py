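"""Brute-force reference implementations used only to check the package.

Everything here works directly on a flat edge list (set of (citer, cited)
pairs) with exhaustive scans, independently of the adjacency structures the
package builds.
"""

from __future__ import annotations

from typing import Iterable, Mapping


def oracle_citers(edges: set[tuple[str, str]], ids: set[str]) -> set[str]:
    return {c for c, d in edges if d in ids}


def oracle_references(edges: set[tuple[str, str]], article_id: str) -> set[str]:
    return {d for c, d in edges if c == article_id}


def oracle_dated_count(
    edges: set[tuple[str, str]],
    years: Mapping[str, int | None],
    article_id: str,
    year: int,
) -> tuple[int, int]:
    count = unknown = 0
    for c, d in edges:
        if d != article_id:
            continue
        y = years.get(c)
        if y is None:
            unknown += 1
        elif y <= year:
            count += 1
    return count, unknown


def oracle_cocitation(
    edges: set[tuple[str, str]], query: set[str]
) -> tuple[dict[str, int], int]:
    """Triple loop: for each citer of the query set, for each article in its
    reference list, increment — skipping query articles."""
    citers = oracle_citers(edges, query)
    counts: dict[str, int] = {}
    for citer in citers:
        for c, d in edges:
            if c == citer and d not in query:
                counts[d] = counts.get(d, 0) + 1
    return counts, len(citers)


def oracle_citation_counts(
    edges: set[tuple[str, str]], query: set[str]
) -> dict[str, int]:
    """Distinct-query-article count via exhaustive edge enumeration."""
    counts: dict[str, int] = {}
    for q in query:
        related = {c for c, d in edges if d == q} | {d for c, d in edges if c == q}
        for a in related:
            if a not in query:
                counts[a] = counts.get(a, 0) + 1
    return counts


def oracle_simpson(
    edges: set[tuple[str, str]], a: str, b: str
) -> tuple[float | None, int, int]:
    ca = {c for c, d in edges if d == a}
    cb = {c for c, d in edges if d == b}
    denom = min(len(ca), len(cb))
    common = len(ca & cb)
    return (common / denom if denom else None), common, denom


def oracle_quartiles(values: Iterable[float]) -> tuple[float, float, float]:
    """Median and midpoint-interpolated quartiles, computed from scratch."""

    def pct(sorted_vals: list[float], q: float) -> float:
        h = (len(sorted_vals) - 1) * q
        lo, hi = int(h // 1), -(-h // 1)
        return (sorted_vals[int(lo)] + sorted_vals[int(hi)]) / 2.0

    s = sorted(values)
    return pct(s, 0.5), pct(s, 0.25), pct(s, 0.75)
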