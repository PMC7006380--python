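"""Simpson co-citation similarity between two query articles.

The Simpson (overlap) index measures how strongly two articles share their
citing literature: the number of publications citing both, divided by the
citation count of the less-cited article.  Two articles cited 10 and 20
times with 3 common citers score 3/10 = 0.3 — they are co-cited in 30% of
the citations of the less-cited one.

The numerator may be restricted to citers published up to a search year
(matching how a review's search date caps what was visible at the time)
while the denominator always uses total in-degrees, mirroring a
bibliographic download taken later.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus import CitationGraph
from .errors import UsageError


@dataclass(frozen=True)
class SimilarityResult:
    """Simpson index with its two counts.

    ``score is None`` marks the undefined case (both articles uncited, so
    the denominator is zero) — distinct from a genuine 0.0, so strata built
    on similarity can exclude it.
    """

    score: float | None
    n_cocitations: int
    n_citations_lesser: int

    @property
    def defined(self) -> bool:
        return self.score is not None


def simpson_similarity(
    graph: CitationGraph,
    a: str,
    b: str,
    numerator_year: int | None = None,
) -> SimilarityResult:
    """Simpson index between articles ``a`` and ``b``.

    numerator = number of common citers (restricted to citers with known
    ``pub_year <= numerator_year`` when given); denominator = the smaller
    total in-degree of the two articles.
    """
    if a == b:
        raise UsageError("Simpson similarity requires two distinct articles")
    citers_a = graph.citers_of(a)
    citers_b = graph.citers_of(b)
    common = citers_a & citers_b
    if numerator_year is not None:
        common = {
            c
            for c in common
            if graph.pub_year(c) is not None and graph.pub_year(c) <= numerator_year
        }
    denom = min(len(citers_a), len(citers_b))
    score = None if denom == 0 else len(common) / denom
    return SimilarityResult(score=score, n_cocitations=len(common),
                            n_citations_lesser=denom)
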