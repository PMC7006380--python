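"""Seeded generator of topic-clustered citation networks with gold sets.

The generator emulates the statistical structure a co-citation search
exploits, without fitting any real bibliographic database:

* articles belong to topics (plus a topic-free background pool) and draw
  most of their references from their own topic (``within_topic_affinity``),
  so same-topic articles accumulate co-citations;
* reference targets are additionally weighted by how often they are already
  cited (``preferential_attachment_weight``), producing the heavy-tailed
  citation-count distribution real corpora show;
* every citation points strictly backward in time (publication years are
  yearly; within-year citation is disallowed), so the graph is acyclic and
  recent articles are under-cited, as in reality;
* a share of articles is non-indexed: their reference lists are removed and
  they survive only as cited references;
* one gold-standard "review" per topic collects the topic members published
  inside a window, with the window end as the search end year.

Identical seeds yield bit-identical corpora.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .corpus import ArticleRecord, CitationGraph, save_graph
from .errors import UsageError
from .replication import DEFAULT_MIN_GOLD, ReviewRecord, save_reviews

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclass(frozen=True)
class CorpusConfig:
    """Generator parameters; defaults give a mid-sized, well-clustered corpus.

    ``within_topic_affinity`` is the probability mass a reference targets
    the citer's own topic; ``preferential_attachment_weight`` scales the
    propensity to cite already-cited articles (0 disables the rich-get-
    richer effect); ``gold_noise`` is the fraction of off-topic articles
    mixed into each gold set (0 = clean gold sets).
    """

    n_topics: int = 5
    articles_per_topic: int = 60
    background_articles: int = 100
    year_range: tuple[int, int] = (1980, 2015)
    mean_reflist_length: float = 15.0
    within_topic_affinity: float = 0.8
    preferential_attachment_weight: float = 1.0
    frac_non_indexed: float = 0.1
    frac_with_pmid: float = 0.9
    review_window: tuple[int, int] = (1990, 2010)
    gold_noise: float = 0.0
    min_gold: int = DEFAULT_MIN_GOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 1 or self.articles_per_topic < 5:
            raise UsageError("need n_topics >= 1 and articles_per_topic >= 5")
        if self.year_range[0] >= self.year_range[1]:
            raise UsageError("year_range start must precede end")
        if self.review_window[0] > self.review_window[1]:
            raise UsageError("review_window start must not exceed end")
        if self.mean_reflist_length <= 0:
            raise UsageError("mean_reflist_length must be positive")
        for name in ("within_topic_affinity", "frac_non_indexed",
                     "frac_with_pmid", "gold_noise"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise UsageError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 < self.within_topic_affinity):
            raise UsageError("within_topic_affinity must be positive")
        if self.preferential_attachment_weight < 0:
            raise UsageError("preferential_attachment_weight must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "CorpusConfig":
        d = dict(d)
        for key in ("year_range", "review_window"):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise UsageError(f"unknown corpus-config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: PathLike) -> "CorpusConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise UsageError(f"{path}: corpus config must be a mapping")
        return cls.from_dict(data)


def _weighted_sample(
    rng: np.random.Generator, pool: np.ndarray, weights: np.ndarray, size: int
) -> np.ndarray:
    if size <= 0 or pool.size == 0:
        return np.empty(0, dtype=pool.dtype)
    size = min(size, pool.size)
    p = weights / weights.sum()
    return rng.choice(pool, size=size, replace=False, p=p)


def generate_corpus(config: CorpusConfig) -> tuple[CitationGraph, list[ReviewRecord]]:
    """Generate a citation graph and one gold-set review per topic.

    Reference lists are Poisson-length around ``mean_reflist_length``,
    truncated to the number of strictly earlier articles; the earliest
    cohort therefore has empty reference lists (logged once).  Topics whose
    window holds fewer than ``min_gold`` members produce no review.
    """
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.year_range

    ids: list[str] = []
    topics: list[int | None] = []
    for t in range(config.n_topics):
        for i in range(config.articles_per_topic):
            ids.append(f"T{t:02d}-{i:03d}")
            topics.append(t)
    for i in range(config.background_articles):
        ids.append(f"BG-{i:03d}")
        topics.append(None)
    n = len(ids)
    years = rng.integers(y0, y1 + 1, size=n)

    # Process articles year by year so citation targets are strictly earlier
    # and preferential attachment sees up-to-date in-degrees.
    order = np.lexsort((np.array(ids), years))
    topic_arr = np.array([-1 if t is None else t for t in topics])
    indeg = np.zeros(n, dtype=float)
    edges: list[tuple[str, str]] = []
    earliest_logged = False

    pos = 0
    earlier: np.ndarray = np.empty(0, dtype=int)
    while pos < len(order):
        year = years[order[pos]]
        cohort = [order[pos]]
        pos += 1
        while pos < len(order) and years[order[pos]] == year:
            cohort.append(order[pos])
            pos += 1
        if earlier.size == 0 and not earliest_logged:
            logger.info(
                "earliest cohort (year %d, %d articles) has no citable "
                "predecessors; reference lists empty", year, len(cohort),
            )
            earliest_logged = True
        for idx in cohort:
            if earlier.size == 0:
                continue
            length = int(rng.poisson(config.mean_reflist_length))
            length = min(length, earlier.size)
            if length == 0:
                continue
            w = config.preferential_attachment_weight * indeg[earlier] + 1.0
            t = topic_arr[idx]
            if t >= 0:
                same = earlier[topic_arr[earlier] == t]
                other = earlier[topic_arr[earlier] != t]
                n_within = int(rng.binomial(length, config.within_topic_affinity))
                n_within = min(n_within, same.size)
                n_cross = min(length - n_within, other.size)
                chosen = np.concatenate(
                    [
                        _weighted_sample(
                            rng, same,
                            config.preferential_attachment_weight * indeg[same] + 1.0,
                            n_within,
                        ),
                        _weighted_sample(
                            rng, other,
                            config.preferential_attachment_weight * indeg[other] + 1.0,
                            n_cross,
                        ),
                    ]
                )
            else:
                chosen = _weighted_sample(rng, earlier, w, length)
            for j in chosen:
                edges.append((ids[idx], ids[int(j)]))
                indeg[int(j)] += 1.0
        earlier = np.concatenate([earlier, np.array(cohort, dtype=int)])

    non_indexed: set[int] = set()
    n_non_indexed = int(round(config.frac_non_indexed * n))
    if n_non_indexed:
        non_indexed = set(
            int(i) for i in rng.choice(n, size=n_non_indexed, replace=False)
        )
    has_pmid = rng.random(n) < config.frac_with_pmid

    records = []
    for i, article_id in enumerate(ids):
        t = topics[i]
        records.append(
            ArticleRecord(
                id=article_id,
                pub_year=int(years[i]),
                pmid=f"PM{i:06d}" if has_pmid[i] else None,
                indexed=i not in non_indexed,
                title=(
                    f"Background study {article_id}"
                    if t is None
                    else f"Topic {t} study {article_id}"
                ),
            )
        )
    id_to_idx = {a: i for i, a in enumerate(ids)}
    kept_edges = [(c, d) for c, d in edges if id_to_idx[c] not in non_indexed]
    graph = CitationGraph(records, kept_edges)

    reviews: list[ReviewRecord] = []
    w0, w1 = config.review_window
    topic_members = {
        t: [ids[i] for i in range(n) if topics[i] == t and w0 <= years[i] <= w1]
        for t in range(config.n_topics)
    }
    off_topic_pool = {
        t: sorted(
            ids[i] for i in range(n) if topics[i] != t and w0 <= years[i] <= w1
        )
        for t in range(config.n_topics)
    }
    for t in range(config.n_topics):
        gold = list(topic_members[t])
        if config.gold_noise > 0 and gold:
            n_noise = int(round(config.gold_noise * len(gold)))
            pool = off_topic_pool[t]
            if n_noise and pool:
                noise = rng.choice(len(pool), size=min(n_noise, len(pool)),
                                   replace=False)
                gold.extend(pool[int(j)] for j in noise)
        if len(gold) < config.min_gold:
            logger.warning(
                "topic %d: only %d articles in review window %s; no review "
                "generated", t, len(gold), config.review_window,
            )
            continue
        reviews.append(
            ReviewRecord(
                review_id=f"R-T{t:02d}",
                included_ids=frozenset(gold),
                search_end_year=w1,
            )
        )
    return graph, reviews


def write_corpus(
    graph: CitationGraph,
    reviews: list[ReviewRecord],
    out_dir: PathLike,
) -> dict[str, Path]:
    """Write edges.tsv, metadata.tsv and reviews.tsv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out / "edges.tsv",
        "metadata": out / "metadata.tsv",
        "reviews": out / "reviews.tsv",
    }
    save_graph(graph, paths["edges"], paths["metadata"])
    save_reviews(reviews, paths["reviews"])
    return paths
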