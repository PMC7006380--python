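"""Review replication harness: query selection, metrics, strata."""

from __future__ import annotations

import pytest

from cocites import (
    ArticleRecord,
    CitationGraph,
    CorpusConfig,
    ReviewRecord,
    SelectionError,
    ThresholdSpec,
    UsageError,
    apply_threshold,
    article_level_factors,
    generate_corpus,
    rank_candidates,
    rank_of_targets,
    replicate_review,
    replicate_reviews,
    select_low_cited_queries,
    select_query_articles,
    stratify_metrics,
)
from cocites.replication import COCITE_THRESHOLD_NAMES

from oracles import oracle_quartiles


def graph_with_counts(counts: dict[str, int], year: int = 2000) -> CitationGraph:
    """Gold articles with prescribed citation counts at ``year``."""
    records = [ArticleRecord(id=a, pub_year=1990) for a in counts]
    edges = []
    for a, n in counts.items():
        for i in range(n):
            cid = f"citer_{a}_{i}"
            records.append(ArticleRecord(id=cid, pub_year=year))
            edges.append((cid, a))
    return CitationGraph(records, edges)


def review_for(counts, end_year=2005, **kw) -> ReviewRecord:
    return ReviewRecord("R1", frozenset(counts), end_year, **kw)


class TestSelectQueryArticles:
    def test_top_two_by_dated_count(self):
        counts = {"a": 300, "b": 120, "c": 5, "d": 2, "e": 1}
        g = graph_with_counts(counts)
        assert select_query_articles(g, review_for(counts)) == ["a", "b"]

    def test_cap_replaces_lower_ranked_only(self):
        counts = {"a": 1200, "b": 1100, "c": 300, "d": 1, "e": 1}
        g = graph_with_counts(counts)
        assert select_query_articles(g, review_for(counts), cap=1000) == ["a", "c"]

    def test_cap_inert_when_any_selected_under_cap(self):
        counts = {"a": 1200, "b": 900, "c": 300, "d": 1, "e": 1}
        g = graph_with_counts(counts)
        assert select_query_articles(g, review_for(counts), cap=1000) == ["a", "b"]

    def test_cap_replace_both(self):
        counts = {"a": 1200, "b": 1100, "c": 300, "d": 250, "e": 1}
        g = graph_with_counts(counts)
        assert select_query_articles(
            g, review_for(counts), cap=1000, replace="both"
        ) == ["c", "d"]

    def test_counts_respect_search_date(self):
        # b's citers are published after the search end year
        records = [ArticleRecord(id=a, pub_year=1990) for a in "abcde"]
        edges = []
        for i in range(5):
            records.append(ArticleRecord(id=f"ca{i}", pub_year=2000))
            edges.append((f"ca{i}", "a"))
            records.append(ArticleRecord(id=f"cb{i}", pub_year=2010))
            edges.append((f"cb{i}", "b"))
            records.append(ArticleRecord(id=f"cc{i}", pub_year=2000))
            if i < 3:
                edges.append((f"cc{i}", "c"))
        g = CitationGraph(records, edges)
        review = ReviewRecord("R1", frozenset("abcde"), 2005)
        assert select_query_articles(g, review) == ["a", "c"]

    def test_too_few_citable_is_selection_error(self):
        counts = {"a": 3, "b": 0, "c": 0, "d": 0, "e": 0}
        g = graph_with_counts(counts)
        with pytest.raises(SelectionError, match="R1"):
            select_query_articles(g, review_for(counts))


class TestSelectLowCitedQueries:
    def test_two_smallest_at_least_ten(self):
        counts = {"a": 160, "b": 40, "c": 12, "d": 11, "e": 8}
        g = graph_with_counts(counts)
        assert select_low_cited_queries(g, review_for(counts)) == ["d", "c"]

    def test_all_below_minimum_is_error(self):
        counts = {"a": 9, "b": 8, "c": 7, "d": 6, "e": 5}
        g = graph_with_counts(counts)
        with pytest.raises(SelectionError):
            select_low_cited_queries(g, review_for(counts))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_sort_and_filter_oracle(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        counts = {f"g{i}": int(rng.integers(0, 60)) for i in range(9)}
        g = graph_with_counts(counts)
        review = review_for(counts)
        qualifying = sorted(
            (a for a, n in counts.items() if n >= 10), key=lambda a: (counts[a], a)
        )
        if len(qualifying) < 2:
            with pytest.raises(SelectionError):
                select_low_cited_queries(g, review)
        else:
            assert select_low_cited_queries(g, review) == qualifying[:2]


def eight_article_review() -> tuple[CitationGraph, ReviewRecord]:
    """Gold set of 8 incl. 2 queries; the stages retrieve exactly 4 more.

    Five citers cite both queries and co-cite g3/g4 in every reference
    list (so g3, g4 pass the >1%-rule and join the query set); g5 cites the
    two expanded-query members g3 and g4, g6 cites q1 and g3 (citation
    counts 2, passing the >1 rule); g7 cites only q1 (count 1, screened
    out); g8 is disconnected and unretrievable.
    """
    gold = ["q1", "q2", "g3", "g4", "g5", "g6", "g7", "g8"]
    records = [ArticleRecord(id=a, pub_year=1995, pmid=f"PM-{a}") for a in gold]
    records += [ArticleRecord(id=f"c{i}", pub_year=2000 + i) for i in range(5)]
    edges = []
    for i in range(5):
        edges += [(f"c{i}", "q1"), (f"c{i}", "q2"), (f"c{i}", "g3"), (f"c{i}", "g4")]
    edges += [("g5", "g3"), ("g5", "g4"), ("g6", "q1"), ("g6", "g3"), ("g7", "q1")]
    graph = CitationGraph(records, edges)
    review = ReviewRecord("R75", frozenset(gold), search_end_year=2010)
    return graph, review


class TestReplicateReview:
    def test_hand_built_review_retrieves_six_of_eight(self):
        graph, review = eight_article_review()
        m = replicate_review(graph, review, ["q1", "q2"])
        assert m.pct_retrieved_combined == pytest.approx(75.0)
        # stage-wise: co-citation finds g3, g4 (+2 queries) = 4/8
        assert m.cocite["pct1"].pct_retrieved == pytest.approx(50.0)
        # citation stage alone: g5, g6 found, queries credited; g3, g4 are
        # query-set members there and credited only in the combined figure
        assert m.citation.n_retrieved == 4
        assert m.combined_sum_screened == len(m.outcome.cocite_results) + len(
            m.outcome.citation_results
        )
        assert m.combined_dedup_screened <= m.combined_sum_screened
        assert m.factors.pct_in_pubmed == pytest.approx(100.0)

    def test_full_retrieval_when_citation_stage_finds_the_rest(self):
        gold = ["q1", "q2", "g3", "g4"]
        records = [ArticleRecord(id=a, pub_year=1995) for a in gold]
        records += [ArticleRecord(id=f"c{i}", pub_year=2000) for i in range(3)]
        edges = []
        for i in range(3):
            edges += [(f"c{i}", "q1"), (f"c{i}", "q2")]
        edges += [("g3", "q1"), ("g3", "q2"), ("g4", "q1"), ("g4", "q2")]
        graph = CitationGraph(records, edges)
        review = ReviewRecord("R100", frozenset(gold), 2010)
        m = replicate_review(graph, review, ["q1", "q2"], )
        assert m.pct_retrieved_combined == pytest.approx(100.0)

    def test_query_outside_gold_rejected(self):
        graph, review = eight_article_review()
        with pytest.raises(UsageError):
            replicate_review(graph, review, ["q1", "c0"])

    def test_threshold_chain_monotone_and_combined_dominates(self):
        cfg = CorpusConfig(n_topics=3, articles_per_topic=40, seed=5)
        graph, reviews = generate_corpus(cfg)
        metrics, _ = replicate_reviews(graph, reviews)
        assert metrics
        for m in metrics:
            assert (
                m.cocite["all"].pct_retrieved
                >= m.cocite["gt1"].pct_retrieved
                >= m.cocite["pct1"].pct_retrieved
            )
            assert m.pct_retrieved_combined >= m.cocite["pct1"].pct_retrieved

    def test_metrics_equal_straight_line_recomputation(self):
        cfg = CorpusConfig(n_topics=3, articles_per_topic=40, seed=9)
        graph, reviews = generate_corpus(cfg)
        review = reviews[0]
        queries = select_query_articles(graph, review)
        m = replicate_review(graph, review, queries)
        gold = review.included_ids
        for name in COCITE_THRESHOLD_NAMES:
            kept = apply_threshold(
                list(m.outcome.cocite_ranked),
                ThresholdSpec.from_name(name),
                m.outcome.n_citing,
            )
            ids = {c.article_id for c in kept}
            expect = len((ids & gold) | set(queries))
            assert m.cocite[name].n_screened == len(kept)
            assert m.cocite[name].n_retrieved == expect
            assert m.cocite[name].pct_retrieved == pytest.approx(
                100.0 * expect / len(gold)
            )
        combined = (
            {c.article_id for c in m.outcome.cocite_results}
            | {c.article_id for c in m.outcome.citation_results}
        )
        expect_comb = len((combined & gold) | set(queries))
        assert m.pct_retrieved_combined == pytest.approx(
            100.0 * expect_comb / len(gold)
        )

    def test_removing_start_year_filter_never_decreases_counts(self):
        graph, review = eight_article_review()
        restricted = ReviewRecord(
            "R75", review.included_ids, review.search_end_year,
            search_start_year=1996,
        )
        m_full = replicate_review(graph, review, ["q1", "q2"])
        m_restr = replicate_review(graph, restricted, ["q1", "q2"])
        for name in COCITE_THRESHOLD_NAMES:
            assert m_full.cocite[name].n_screened >= m_restr.cocite[name].n_screened
            assert m_full.cocite[name].n_retrieved >= m_restr.cocite[name].n_retrieved


class TestStratify:
    def _metrics(self, pairs):
        graph, review = eight_article_review()
        base = replicate_review(graph, review, ["q1", "q2"])
        from dataclasses import replace

        out = []
        for i, (n_citing, pct) in enumerate(pairs):
            factors = replace(base.factors, n_citing=n_citing)
            out.append(
                replace(base, review_id=f"R{i}", factors=factors,
                        pct_retrieved_combined=pct)
            )
        return out

    def test_single_review_degenerate_iqr(self):
        table = stratify_metrics(self._metrics([(10, 75.0)]), "n_citing", [0, 20])
        row = table[table.n_reviews > 0].iloc[0]
        assert (row.median_pct, row.q1_pct, row.q3_pct) == (75.0, 75.0, 75.0)

    def test_median_of_three(self):
        table = stratify_metrics(
            self._metrics([(5, 30.0), (6, 50.0), (7, 70.0)]), "n_citing", [0, 20]
        )
        assert table.iloc[0].median_pct == 50.0

    def test_empty_bins_reported_with_zero(self):
        table = stratify_metrics(self._metrics([(150, 80.0)]), "n_citing", [0, 20, 100])
        assert list(table.n_reviews) == [0, 0, 1]

    def test_unordered_edges_rejected(self):
        with pytest.raises(UsageError):
            stratify_metrics(self._metrics([(10, 50.0)]), "n_citing", [20, 0])

    @pytest.mark.parametrize("seed", range(3))
    def test_quartiles_match_independent_oracle(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        pcts = [float(x) for x in rng.uniform(0, 100, size=11)]
        table = stratify_metrics(
            self._metrics([(10, p) for p in pcts]), "n_citing", [0, 20]
        )
        med, q1, q3 = oracle_quartiles(pcts)
        row = table.iloc[0]
        assert row.median_pct == pytest.approx(med)
        assert row.q1_pct == pytest.approx(q1)
        assert row.q3_pct == pytest.approx(q3)


class TestArticleLevelFactors:
    def test_bins_and_query_exclusion(self):
        graph, review = eight_article_review()
        m = replicate_review(graph, review, ["q1", "q2"])
        table = article_level_factors(graph, review, m.outcome)
        assert set(table.article_id) == {"g3", "g4", "g5", "g6", "g7", "g8"}
        row = table.set_index("article_id")
        assert bool(row.loc["g3", "retrieved_cocite"])
        assert not bool(row.loc["g5", "retrieved_cocite"])
        assert bool(row.loc["g5", "retrieved_combined"])
        assert row.loc["g3", "times_cited_bin"] == "6-9"  # 5 citers + g5, g6
        assert row.loc["g8", "times_cited_bin"] == "0"
        assert row.loc["g8", "n_references_bin"] == "<5"
        # published 1995, search end 2010 -> >10 years since publication
        assert row.loc["g3", "years_since_pub_bin"] == ">10"

    def test_non_indexed_article_bins(self):
        gold = ["q1", "q2", "g3", "g4", "nx"]
        records = [ArticleRecord(id=a, pub_year=2000) for a in gold[:4]]
        records.append(ArticleRecord(id="nx", pub_year=2010, indexed=False))
        records += [ArticleRecord(id=f"c{i}", pub_year=2005) for i in range(2)]
        edges = [(f"c{i}", q) for i in range(2) for q in ("q1", "q2", "nx")]
        graph = CitationGraph(records, edges)
        review = ReviewRecord("R", frozenset(gold), 2010)
        m = replicate_review(graph, review, ["q1", "q2"])
        table = article_level_factors(graph, review, m.outcome).set_index("article_id")
        assert table.loc["nx", "times_cited_bin"] == "not indexed"
        assert table.loc["nx", "n_references_bin"] == "not indexed"
        assert table.loc["nx", "years_since_pub_bin"] == "0-1"

    def test_binning_matches_brute_force(self):
        cfg = CorpusConfig(n_topics=2, articles_per_topic=30, seed=3)
        graph, reviews = generate_corpus(cfg)
        review = reviews[0]
        queries = select_query_articles(graph, review)
        m = replicate_review(graph, review, queries)
        table = article_level_factors(graph, review, m.outcome).set_index("article_id")
        for a in review.included_ids - set(queries):
            rec = graph.article(a)
            if not rec.indexed:
                assert table.loc[a, "times_cited_bin"] == "not indexed"
            else:
                n = graph.in_degree(a)
                expected = next(
                    lab
                    for lab, lo, hi in [
                        ("0", 0, 0), ("1-5", 1, 5), ("6-9", 6, 9),
                        ("10-19", 10, 19), ("20-49", 20, 49),
                        (">=50", 50, 10**9),
                    ]
                    if lo <= n <= hi
                )
                assert table.loc[a, "times_cited_bin"] == expected


class TestRankOfTargets:
    def test_found_and_absent_targets(self):
        ranked = rank_candidates({"a": 9, "b": 7, "c": 7, "d": 1})
        table = rank_of_targets(ranked, {"a", "zz"}).set_index("target_id")
        assert table.loc["a", "rank"] == 1
        assert bool(table.loc["a", "in_top10"]) and bool(table.loc["a", "in_top100"])
        assert table.loc["zz", "rank"] is not None  # pd.NA
        assert not bool(table.loc["zz", "in_top10"])

    def test_tie_inclusive_top_k_membership(self):
        freq = {f"x{i:03d}": 2 for i in range(15)}
        freq["top"] = 5
        ranked = rank_candidates(freq)
        table = rank_of_targets(ranked, set(freq)).set_index("target_id")
        # all 15 tied candidates share the boundary frequency -> all in top 10
        assert table.in_top10.all()

    def test_matches_linear_scan(self):
        import numpy as np

        rng = np.random.default_rng(0)
        freq = {f"a{i}": int(rng.integers(1, 20)) for i in range(120)}
        ranked = rank_candidates(freq)
        targets = sorted(freq)[::17] + ["absent"]
        table = rank_of_targets(ranked, targets).set_index("target_id")
        for t in targets:
            matches = [c for c in ranked if c.article_id == t]
            if matches:
                assert table.loc[t, "rank"] == matches[0].rank
            else:
                assert not bool(table.loc[t, "in_top100"])


def test_batch_replication_skips_with_reasons():
    cfg = CorpusConfig(n_topics=2, articles_per_topic=30, seed=2)
    graph, reviews = generate_corpus(cfg)
    phantom = ReviewRecord("R-missing", frozenset({"no1", "no2", "no3", "no4", "no5"}), 2010)
    metrics, skipped = replicate_reviews(graph, reviews + [phantom])
    assert len(metrics) == len(reviews)
    assert skipped and skipped[0][0] == "R-missing"
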