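"""Citation-graph data model and plain-text I/O.

A corpus is a directed graph whose nodes are articles and whose edges point
from a citing article to a cited one (citer -> cited).  Two structural facts
about real citation databases are modelled explicitly:

* *Indexed vs non-indexed items.*  A non-indexed item enters the database
  only because something cites it; its own reference list is inaccessible.
  The invariant ``indexed is False  =>  no outgoing edges`` is enforced.

* *Date-restricted citation counting.*  Citation counts "as of" a search
  year count only citers whose publication year is known and ``<= year``;
  citers with unknown year are excluded and the number of exclusions is
  reported alongside the count.

File formats are tab-separated UTF-8 text:

* edge list — header ``citer_id<TAB>cited_id``, one edge per line;
* metadata — header ``id<TAB>pub_year<TAB>pmid<TAB>indexed<TAB>title``,
  ``indexed`` in {0,1}, empty fields allowed for ``pub_year``, ``pmid``
  and ``title``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Union

from .errors import IntegrityError, ParseError, UnknownArticleError

logger = logging.getLogger(__name__)

#: Sentinel range for plausible publication years.
MIN_YEAR, MAX_YEAR = 1800, 2100

PathLike = Union[str, Path]

EDGE_HEADER = ("citer_id", "cited_id")
METADATA_HEADER = ("id", "pub_year", "pmid", "indexed", "title")


@dataclass(frozen=True)
class ArticleRecord:
    """Metadata for one article.

    ``pub_year is None`` means the publication year is unknown; such
    articles are excluded from date-restricted counts and year strata.
    """

    id: str
    pub_year: int | None = None
    pmid: str | None = None
    indexed: bool = True
    title: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise IntegrityError("article id must be a non-empty string")
        if self.pub_year is not None and not (MIN_YEAR <= self.pub_year <= MAX_YEAR):
            raise IntegrityError(
                f"article {self.id!r}: pub_year {self.pub_year} outside "
                f"[{MIN_YEAR}, {MAX_YEAR}]"
            )


class DatedCitationCount(NamedTuple):
    """Citation count restricted to a search year, plus excluded citers."""

    count: int
    n_unknown_year: int


class CitationGraph:
    """Articles plus directed citation edges (citer -> cited).

    Invariants enforced at construction:

    * no self-edges;
    * every edge endpoint has an :class:`ArticleRecord`;
    * a non-indexed article has no outgoing edges.

    Duplicate edges collapse silently here (edges are a set); the loader is
    responsible for warning about duplicates in files.
    """

    def __init__(
        self,
        articles: Iterable[ArticleRecord],
        edges: Iterable[tuple[str, str]] = (),
    ):
        self._articles: dict[str, ArticleRecord] = {}
        for rec in articles:
            if rec.id in self._articles:
                raise IntegrityError(f"duplicate article id {rec.id!r}")
            self._articles[rec.id] = rec
        self._out: dict[str, set[str]] = {a: set() for a in self._articles}
        self._in: dict[str, set[str]] = {a: set() for a in self._articles}
        for citer, cited in edges:
            self.add_edge(citer, cited)

    # -- construction ---------------------------------------------------

    def add_edge(self, citer: str, cited: str) -> None:
        if citer == cited:
            raise IntegrityError(f"self-edge on article {citer!r}")
        for endpoint in (citer, cited):
            if endpoint not in self._articles:
                raise UnknownArticleError(endpoint)
        if not self._articles[citer].indexed:
            raise IntegrityError(
                f"non-indexed article {citer!r} cannot have outgoing edges"
            )
        self._out[citer].add(cited)
        self._in[cited].add(citer)

    # -- lookups ---------------------------------------------------------

    def __contains__(self, article_id: str) -> bool:
        return article_id in self._articles

    def __len__(self) -> int:
        return len(self._articles)

    def article(self, article_id: str) -> ArticleRecord:
        try:
            return self._articles[article_id]
        except KeyError:
            raise UnknownArticleError(article_id) from None

    @property
    def article_ids(self) -> Iterator[str]:
        return iter(self._articles)

    def articles(self) -> Iterator[ArticleRecord]:
        return iter(self._articles.values())

    def edges(self) -> Iterator[tuple[str, str]]:
        for citer in self._out:
            for cited in self._out[citer]:
                yield (citer, cited)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self._out.values())

    def pub_year(self, article_id: str) -> int | None:
        return self.article(article_id).pub_year

    # -- the citation relation -------------------------------------------

    def citers_of(self, ids: Iterable[str] | str) -> set[str]:
        """Union of all articles with an edge into any member of ``ids``.

        Members of ``ids`` appear in the result only if they genuinely cite
        another member.
        """
        if isinstance(ids, str):
            ids = [ids]
        out: set[str] = set()
        for article_id in ids:
            if article_id not in self._articles:
                raise UnknownArticleError(article_id)
            out |= self._in[article_id]
        return out

    def references_of(self, article_id: str) -> set[str]:
        """Targets of outgoing edges; empty for a non-indexed article."""
        if article_id not in self._articles:
            raise UnknownArticleError(article_id)
        return set(self._out[article_id])

    def in_degree(self, article_id: str) -> int:
        """Total number of citers, regardless of date."""
        if article_id not in self._articles:
            raise UnknownArticleError(article_id)
        return len(self._in[article_id])

    def out_degree(self, article_id: str) -> int:
        if article_id not in self._articles:
            raise UnknownArticleError(article_id)
        return len(self._out[article_id])

    def citation_count_at_year(self, article_id: str, year: int) -> DatedCitationCount:
        """Citers with known ``pub_year <= year``; unknown years excluded.

        The boundary year is inclusive: metadata carries calendar years
        only, so "published before the search date" is realised as
        ``pub_year <= year``.
        """
        if article_id not in self._articles:
            raise UnknownArticleError(article_id)
        count = unknown = 0
        for citer in self._in[article_id]:
            y = self._articles[citer].pub_year
            if y is None:
                unknown += 1
            elif y <= year:
                count += 1
        return DatedCitationCount(count, unknown)

    # -- interop ---------------------------------------------------------

    def to_networkx(self):
        """Export as a ``networkx.DiGraph`` with record fields as node attrs."""
        import networkx as nx

        g = nx.DiGraph()
        for rec in self.articles():
            g.add_node(rec.id, pub_year=rec.pub_year, pmid=rec.pmid,
                       indexed=rec.indexed, title=rec.title)
        g.add_edges_from(self.edges())
        return g

    # -- persistence ------------------------------------------------------

    def save(self, edges_path: PathLike, metadata_path: PathLike) -> None:
        save_graph(self, edges_path, metadata_path)


# -- module-level operations ----------------------------------------------


def citers_of(graph: CitationGraph, ids: Iterable[str]) -> set[str]:
    return graph.citers_of(ids)


def references_of(graph: CitationGraph, article_id: str) -> set[str]:
    return graph.references_of(article_id)


def citation_count_at_year(
    graph: CitationGraph, article_id: str, year: int
) -> DatedCitationCount:
    return graph.citation_count_at_year(article_id, year)


# -- I/O -------------------------------------------------------------------


def _parse_year(field: str, path: PathLike, lineno: int) -> int | None:
    if field == "":
        return None
    try:
        year = int(field)
    except ValueError:
        raise ParseError(f"{path}, line {lineno}: pub_year {field!r} is not an integer")
    if not (MIN_YEAR <= year <= MAX_YEAR):
        raise ParseError(
            f"{path}, line {lineno}: pub_year {year} outside [{MIN_YEAR}, {MAX_YEAR}]"
        )
    return year


def _read_metadata(metadata_source: PathLike) -> dict[str, ArticleRecord]:
    records: dict[str, ArticleRecord] = {}
    with open(metadata_source, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != METADATA_HEADER:
            raise ParseError(
                f"{metadata_source}, line 1: expected header "
                f"{chr(9).join(METADATA_HEADER)!r}, got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(METADATA_HEADER):
                raise ParseError(
                    f"{metadata_source}, line {lineno}: expected "
                    f"{len(METADATA_HEADER)} fields, got {len(row)}"
                )
            article_id, year_s, pmid, indexed_s, title = row
            if indexed_s not in ("0", "1"):
                raise ParseError(
                    f"{metadata_source}, line {lineno}: indexed must be 0 or 1, "
                    f"got {indexed_s!r}"
                )
            if article_id in records:
                raise ParseError(
                    f"{metadata_source}, line {lineno}: duplicate id {article_id!r}"
                )
            records[article_id] = ArticleRecord(
                id=article_id,
                pub_year=_parse_year(year_s, metadata_source, lineno),
                pmid=pmid or None,
                indexed=indexed_s == "1",
                title=title or None,
            )
    return records


def _read_edges(edges_source: PathLike) -> list[tuple[str, str]]:
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = n_self = 0
    with open(edges_source, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is not None and tuple(header) == ("cited_id", "citer_id"):
            raise ParseError(
                f"{edges_source}, line 1: header declares cited_id before "
                "citer_id; edge lists must be oriented citer -> cited"
            )
        if header is None or tuple(header) != EDGE_HEADER:
            raise ParseError(
                f"{edges_source}, line 1: expected header "
                f"{chr(9).join(EDGE_HEADER)!r}, got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2 or not row[0] or not row[1]:
                raise ParseError(
                    f"{edges_source}, line {lineno}: expected two non-empty "
                    f"tab-separated ids, got {row!r}"
                )
            citer, cited = row
            if citer == cited:
                n_self += 1
                logger.warning(
                    "%s, line %d: self-edge %s -> %s dropped",
                    edges_source, lineno, citer, cited,
                )
                continue
            if (citer, cited) in seen:
                n_dup += 1
                logger.warning(
                    "%s, line %d: duplicate edge %s -> %s collapsed",
                    edges_source, lineno, citer, cited,
                )
                continue
            seen.add((citer, cited))
            edges.append((citer, cited))
    if n_dup or n_self:
        logger.info(
            "%s: dropped %d duplicate and %d self edges", edges_source, n_dup, n_self
        )
    return edges


def load_graph(
    edges_source: PathLike,
    metadata_source: PathLike,
    auto_stub: bool = True,
) -> CitationGraph:
    """Build a :class:`CitationGraph` from an edge list and a metadata table.

    With ``auto_stub`` (the default), edge endpoints missing from the
    metadata become non-indexed records with unknown publication year —
    this mirrors how non-indexed items enter a citation database only as
    cited references.  With ``auto_stub=False`` a missing endpoint is a
    referential-integrity error.

    Duplicate edges collapse with a logged warning; self-edges are dropped
    with a logged warning.  A non-indexed article appearing as a citer is
    an integrity error naming the id.
    """
    records = _read_metadata(metadata_source)
    edges = _read_edges(edges_source)

    missing = {e for pair in edges for e in pair if e not in records}
    if missing and not auto_stub:
        raise IntegrityError(
            "edge endpoints missing from metadata (auto_stub disabled): "
            + ", ".join(sorted(missing))
        )
    for article_id in sorted(missing):
        records[article_id] = ArticleRecord(id=article_id, indexed=False)
        logger.warning("auto-stubbed %r as a non-indexed article", article_id)

    # Stubbed articles are non-indexed by construction; if one of them (or a
    # declared non-indexed article) appears as a citer, the constructor raises.
    return CitationGraph(records.values(), edges)


def save_graph(
    graph: CitationGraph, edges_path: PathLike, metadata_path: PathLike
) -> None:
    """Write the graph back to the two standard TSV files (sorted, stable)."""
    with open(metadata_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(METADATA_HEADER)
        for article_id in sorted(graph.article_ids):
            rec = graph.article(article_id)
            writer.writerow(
                [
                    rec.id,
                    "" if rec.pub_year is None else rec.pub_year,
                    rec.pmid or "",
                    "1" if rec.indexed else "0",
                    rec.title or "",
                ]
            )
    with open(edges_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(EDGE_HEADER)
        for citer, cited in sorted(graph.edges()):
            writer.writerow([citer, cited])
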