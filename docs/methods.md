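# Methods

This note documents the model and procedure the package implements, the
parameters that matter, the synthetic data it is validated on, and the
numerical and design choices that were genuinely open.

## Citation graph model

The corpus is a directed graph: nodes are articles, an edge `(citer,
cited)` means the citer's reference list contains the cited article.
Edges are a set (a reference list contributes each unique identifier
once); self-citation edges are rejected. Two database realities are
modelled explicitly:

* **Indexed vs non-indexed items.** Bibliographic databases contain items
  whose own reference lists are inaccessible — dissertations, reports,
  articles from uncovered journals — which enter the database only as
  cited references. These are `indexed = False` and have, invariantly, no
  outgoing edges; they can still be retrieved through co-citation (they
  appear in other articles' reference lists) but never contribute a
  reference list of their own. The graph loader auto-stubs edge endpoints
  missing from the metadata table as non-indexed with unknown year, since
  that is exactly how such items surface in practice (this can be
  disabled, in which case a missing endpoint is an error).
* **Date-restricted counting.** Citation counts "as of" a search year use
  `pub_year <= year`. Metadata tables carry calendar years, not full
  dates, so a strict "published before the search date" cannot be
  expressed at day resolution; the inclusive year boundary is the
  package's convention and is applied uniformly (query selection, Simpson
  numerators). Citers with unknown year are excluded from dated counts
  and the number of exclusions is reported alongside the count.

## The two searches

**Co-citation search.** With query set Q, collect the unique citers
C = citers(Q) and count, for each non-query article, the number of
members of C whose reference list contains it. Counts are bounded by
|C|; query articles are excluded from their own result list (a user
already has them; retrieval metrics still credit them, see below).

**Citation search.** For each non-query article, count the *distinct*
query articles it cites or is cited by. An article linked to the same
query article in both directions counts once; counts are bounded by the
query-set size.

**Ranking.** Frequency descending; ties broken by publication year
descending (recent first, unknown year last) and then id ascending — the
within-frequency order is otherwise arbitrary, and this total order makes
every output deterministic. Ranks are competition-style (tied frequencies
share the smallest applicable rank; the next distinct frequency skips
ahead), so tie-inclusive "top k" rules are well defined.

**Screening thresholds.** Four named rules, loosest to tightest along the
count axis:

| name     | rule                                                        |
|----------|-------------------------------------------------------------|
| `all`    | frequency ≥ 1 (no exclusions)                                |
| `gt1`    | frequency ≥ 2                                                |
| `pct1`   | frequency ≥ 2 AND frequency > 0.01 × n_citing (strict)       |
| `top100` | first 100 ranks plus every candidate tied with the 100th     |

The `pct1` fraction uses a strict inequality (with 400 citers, frequency
4 fails because 4 > 4.0 is false) and its denominator is the unique-citer
count of the *union* of query articles. `all ⊇ gt1 ⊇ pct1` always;
`top100` is not ordered against the others in general.

**Two-stage workflow.** Stage 1 thresholds the co-citation list (default
`pct1`) and adds the relevant survivors to the query set; stage 2 runs
the citation search on the expanded set (default threshold `gt1`). When
a review restricted its search period to some start year ≥ 1980,
candidates published earlier are dropped from both ranked lists before
thresholding, for a fair screening-burden comparison; the 1980 floor
means open-ended or very early start dates impose no filter. The
screening total is reported both as the plain sum of the two thresholded
list lengths (the convention when two result formats cannot be
deduplicated) and as the unique-id count across both lists.

Two variants are provided for difficult cases: `expand_query_top_ranked`
uses the tie-inclusive 25 top-ranked co-citation results as the citation
query set without any relevance screening (useful when too few relevant
articles pass the threshold to seed an effective citation search), and
`run_cocites(..., max_citers=N)` restricts the co-citation stage to the N
most recent citers — a screening-burden control for very highly cited
query sets; both are off by default.

## Simpson similarity

S(a,b) = |citers(a) ∩ citers(b)| / min(|citers(a)|, |citers(b)|). The
numerator may be restricted to citers with known publication year up to a
cutoff while the denominator always uses total in-degrees (numerator as
of the search date, denominator as of the bibliographic download). When
both articles are uncited the score is reported as undefined (`None`),
not 0, so similarity strata can exclude such pairs; this situation does
not arise for sensibly chosen (i.e. cited) query articles.

## Replication harness

For a review with gold set G and search end year Y:

* **Query selection**: the two gold articles with the highest citation
  counts at Y (ties by id). If *all* selected articles exceed the cap
  (default 1000 citations), the lowest-ranked selection is replaced by
  the most-cited gold article under the cap. Replacing only one keeps the
  single best-known article in the query while still tempering the citer
  explosion; replacing the whole selection is available via
  `replace="both"`. A low-cited variant selects the two gold articles
  with the *fewest* citations that still have at least ten, for testing
  whether obscure seeds surface the field's key articles
  (`rank_of_targets` then reports their tie-inclusive top-10/top-100
  membership).
* **Scoring**: relevance during expansion is membership in G. Retrieval
  percentage at a threshold = |(results ∩ G) ∪ Q| / |G| × 100 — query
  articles are credited even though the co-citation list excludes them,
  which slightly flatters the co-citation stage but reflects that a user
  starts with them in hand. Combined figures pair the `pct1` co-citation
  list with the `gt1` citation list.
* **Strata**: review-level factors are the unique-citer count of the
  query pair, the Simpson similarity of the query pair (numerator tied to
  Y), and the share of gold articles with a PMID (a proxy for
  findability in PubMed; used only for stratification, never filtering).
  Bin edges `[e0..en]` define `[e0,e1), ..., [e(n-1),en), [en,∞)`.
  Medians and quartiles use midpoint interpolation — a convention choice;
  no authoritative convention exists for these summaries.
* **Article-level factors**: per non-query gold article, retrieval status
  in the co-citation and combined stages plus bins for times cited
  (not-indexed / 0 / 1–5 / 6–9 / 10–19 / 20–49 / ≥50), reference-list
  length (not-indexed / <5 / 5–9 / ≥10) and years since publication
  relative to Y (0–1 / 1–2 / 2–5 / 5–10 / >10; with yearly resolution,
  Y−pub_year of 0 falls in "0–1", 1 in "1–2", 2–4 in "2–5", 5–9 in
  "5–10").

Batch replication skips, with a logged reason, reviews whose gold sets
reference unknown articles or contain fewer than two citable articles.

## Synthetic corpus generator

The generator produces the structure the method's assumptions require,
not a fit to any real database:

| parameter                        | default     | meaning |
|----------------------------------|-------------|---------|
| `n_topics` × `articles_per_topic`| 5 × 60      | topical clusters (units: articles) |
| `background_articles`            | 100         | topic-free articles diluting the clusters |
| `year_range`                     | (1980, 2015)| uniform publication years |
| `mean_reflist_length`            | 15          | Poisson mean of reference-list length |
| `within_topic_affinity`          | 0.8         | probability a reference targets the citer's own topic |
| `preferential_attachment_weight` | 1.0         | weight ∝ (w·indeg + 1) on citation targets |
| `frac_non_indexed`               | 0.1         | share of articles stripped of out-edges |
| `frac_with_pmid`                 | 0.9         | share of articles carrying a PMID |
| `review_window`                  | (1990, 2010)| gold-set eligibility window; window end = search end year |
| `gold_noise`                     | 0.0         | fraction of off-topic members mixed into gold sets |

Articles are processed in publication-year order; each reference list is
drawn (without replacement) from strictly earlier articles, splitting a
Binomial(affinity) share to the citer's own topic, with
preferential-attachment weights inside each pool. Citation within a year
is disallowed to avoid order ambiguity, so the graph is acyclic by
construction and the earliest cohort has empty reference lists. The
defaults give query pairs with a few dozen unique citers; the property
suite additionally uses a sparse regime (40 articles/topic, mean list
length 6) and a dense regime (300 articles/topic, mean list length 80,
years 1980–2020 with a 1990–2005 review window) so that the under-20 and
over-100 citer strata are both populated when checking that retrieval
rises with citer count. Identical seeds give bit-identical corpora; all
randomness flows from the single `seed` through one generator.

What the generator does *not* emulate: citation lag distributions, topic
drift and merging, journal-level effects, reference-list correlations
beyond topic membership, or erroneous gold-set inclusions (available only
via the off-by-default `gold_noise`). Passing tests therefore demonstrate
the method's behaviour under clean topical clustering — the regime its
assumptions describe — not its performance on any real review corpus.

## Numerical and degenerate-case choices

* Zero citers: co-citation search returns an empty map with n_citing = 0;
  the `pct1` threshold on n_citing = 0 returns empty rather than erroring.
* The loader collapses duplicate edge rows and drops self-edges, each with
  a warning naming the file line; malformed rows fail with the line
  number.
* Unknown publication years: excluded from dated counts (with an
  exclusion count), sorted last within frequency ties, never filtered by
  the start-year rule, and excluded from year-based strata.
* All tables are written with sorted, stable ordering so identical inputs
  produce byte-identical files.

## Known limitations

* Year-level date resolution; searches performed mid-year are not
  distinguishable.
* The harness replicates retrieval of *included* articles only; it cannot
  measure whether the method would have surfaced relevant articles the
  original reviewers missed.
* The `pct1` denominator convention (citers of the query-set union) is
  one of two defensible readings; the per-query alternative is not
  implemented.
* No proximity-weighted co-citation, multi-relation ranking, or
  visualization; no live database access or reference-manager formats.
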