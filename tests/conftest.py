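from __future__ import annotations

import numpy as np
import pytest

from cocites import ArticleRecord, CitationGraph


def make_random_graph(
    seed: int,
    n: int = 50,
    p: float = 0.06,
    frac_unknown_year: float = 0.1,
    frac_non_indexed: float = 0.1,
) -> CitationGraph:
    """Seeded random directed graph with realistic metadata quirks."""
    rng = np.random.default_rng(seed)
    ids = [f"A{i:03d}" for i in range(n)]
    years = rng.integers(1985, 2021, size=n)
    unknown = rng.random(n) < frac_unknown_year
    non_indexed = rng.random(n) < frac_non_indexed
    records = [
        ArticleRecord(
            id=ids[i],
            pub_year=None if unknown[i] else int(years[i]),
            pmid=f"PM{i}" if rng.random() < 0.8 else None,
            indexed=not non_indexed[i],
        )
        for i in range(n)
    ]
    edges = []
    mask = rng.random((n, n)) < p
    for i in range(n):
        if non_indexed[i]:
            continue
        for j in range(n):
            if i != j and mask[i, j]:
                edges.append((ids[i], ids[j]))
    return CitationGraph(records, edges)


@pytest.fixture
def random_graph_factory():
    return make_random_graph


@pytest.fixture
def fig_graph() -> CitationGraph:
    """Two query articles cited by three publications in total.

    q1 and q2 are each cited by some of c1..c3; the three citers' reference
    lists contain x (in all three), y (in two) and z (in one), so co-cited
    articles appear 1 to 3 times.
    """
    ids = ["q1", "q2", "c1", "c2", "c3", "x", "y", "z"]
    records = [ArticleRecord(id=i, pub_year=2000 + k) for k, i in enumerate(ids)]
    edges = [
        ("c1", "q1"), ("c2", "q1"), ("c2", "q2"), ("c3", "q2"),
        ("c1", "x"), ("c2", "x"), ("c3", "x"),
        ("c1", "y"), ("c3", "y"),
        ("c2", "z"),
    ]
    return CitationGraph(records, edges)
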