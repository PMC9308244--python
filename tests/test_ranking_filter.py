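"""Merging, size filtering and the subset-coverage redundancy filter."""

from __future__ import annotations

import itertools
import logging

import pytest

from enrichsum import (
    FilterConfig,
    RankedTermList,
    filter_enrichment_results,
    filter_redundant,
    is_covered,
    merge_rankings,
    remove_undersized,
)

from conftest import build_collection, naive_filter_reference, random_collection_and_list


class TestMergeRankings:
    def test_best_rank_is_minimum_over_sources(self):
        l1 = RankedTermList("L1", ("X", "Y", "Z"))
        l2 = RankedTermList("L2", ("Y", "W"))
        merged = merge_rankings([l1, l2])
        by_id = {e.term_id: e for e in merged.entries}
        assert by_id["X"].best_rank == 1 and by_id["X"].source_ranks == {"L1": 1}
        assert by_id["Y"].best_rank == 1
        assert by_id["Y"].source_ranks == {"L1": 2, "L2": 1}
        assert by_id["Z"].best_rank == 3 and by_id["W"].best_rank == 2

    def test_single_list_identity(self):
        lst = RankedTermList("L", ("a", "b", "c"))
        merged = merge_rankings([lst])
        assert merged.term_ids == ["a", "b", "c"]
        assert [e.best_rank for e in merged.entries] == [1, 2, 3]

    def test_best_ranks_invariant_under_list_permutation(self):
        """Brute force over all orderings of a 3-list fixture."""
        lists = [
            RankedTermList("A", ("t1", "t2", "t3")),
            RankedTermList("B", ("t2", "t4")),
            RankedTermList("C", ("t5", "t1", "t4")),
        ]
        reference = {
            e.term_id: (e.best_rank, e.source_ranks)
            for e in merge_rankings(lists).entries
        }
        for perm in itertools.permutations(lists):
            got = {
                e.term_id: (e.best_rank, e.source_ranks)
                for e in merge_rankings(list(perm)).entries
            }
            assert got == reference

    def test_tie_break_follows_list_order(self):
        # t_a and t_b both have best rank 1; list order decides processing order
        l1 = RankedTermList("L1", ("t_a",))
        l2 = RankedTermList("L2", ("t_b",))
        assert merge_rankings([l1, l2]).term_ids == ["t_a", "t_b"]
        assert merge_rankings([l2, l1]).term_ids == ["t_b", "t_a"]

    def test_duplicate_aliases_rejected(self):
        lst = RankedTermList("L", ("a",))
        other = RankedTermList("L", ("b",))
        with pytest.raises(ValueError, match="alias"):
            merge_rankings([lst, other])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_rankings([])


class TestRemoveUndersized:
    def test_strict_threshold(self):
        coll = build_collection(
            {"A": {f"g{i}" for i in range(5)}, "B": {f"g{i}" for i in range(10)}}
        )
        merged = merge_rankings([RankedTermList("L", ("A", "B"))])
        survivors, undersized, unannotated = remove_undersized(merged, coll, 10)
        assert survivors.term_ids == ["B"]  # size 10 survives: strict <
        assert undersized == ("A",)
        assert unannotated == ()

    def test_unannotated_term_warned(self, caplog):
        coll = build_collection({"A": {f"g{i}" for i in range(10)}})
        merged = merge_rankings([RankedTermList("L", ("A", "GHOST"))])
        with caplog.at_level(logging.WARNING, logger="enrichsum.ranking_filter"):
            survivors, undersized, unannotated = remove_undersized(merged, coll, 1)
        assert unannotated == ("GHOST",)
        assert survivors.term_ids == ["A"]
        assert any("GHOST" in rec.getMessage() for rec in caplog.records)

    def test_order_preserved(self):
        sets = {f"t{i}": {f"g{j}" for j in range(i + 1)} for i in range(6)}
        coll = build_collection(sets)
        merged = merge_rankings([RankedTermList("L", tuple(sets))])
        survivors, _, _ = remove_undersized(merged, coll, 3)
        assert survivors.term_ids == ["t2", "t3", "t4", "t5"]


class TestIsCovered:
    @pytest.mark.parametrize(
        "cand, other, expected",
        [
            ("small", "big", True),  # strict superset
            ("off", "big", False),  # partial overlap only
            ("twin1", "twin2", True),  # equal sets count as covered
            ("big", "small", False),
        ],
    )
    def test_coverage(self, cand, other, expected):
        coll = build_collection(
            {
                "big": {"g1", "g2", "g3"},
                "small": {"g1", "g2"},
                "off": {"g1", "g4"},
                "twin1": {"g7", "g8"},
                "twin2": {"g7", "g8"},
            }
        )
        assert is_covered(cand, other, coll) is expected

    def test_unknown_id(self, micro_collection):
        with pytest.raises(KeyError):
            is_covered("A", "nope", micro_collection)


class TestFilterRedundant:
    def test_micro_example(self, micro_collection, micro_list):
        out = filter_enrichment_results(
            [micro_list], micro_collection, FilterConfig(min_term_size=1)
        )
        assert [(g.representative_id, g.represented_ids) for g in out.groups] == [
            ("B", ()),
            ("A", ("C",)),
            ("D", ()),
        ]

    def test_single_term(self):
        coll = build_collection({"only": {"g1"}})
        out = filter_enrichment_results(
            [RankedTermList("L", ("only",))], coll, FilterConfig(min_term_size=1)
        )
        assert out.representative_ids == ["only"]
        assert out.n_represented == 0

    def test_equal_sets_earlier_term_represents(self):
        coll = build_collection({"first": {"g1", "g2"}, "second": {"g1", "g2"}})
        out = filter_enrichment_results(
            [RankedTermList("L", ("first", "second"))],
            coll,
            FilterConfig(min_term_size=1),
        )
        assert out.representative_ids == ["first"]
        assert out.groups[0].represented_ids == ("second",)

    def test_flat_representation_no_chains(self):
        # c2 < c1 < top; both c's go directly to top once c1 is absorbed
        coll = build_collection(
            {
                "top": {"g1", "g2", "g3", "g4"},
                "c1": {"g1", "g2", "g3"},
                "c2": {"g1", "g2"},
            }
        )
        out = filter_enrichment_results(
            [RankedTermList("L", ("top", "c1", "c2"))],
            coll,
            FilterConfig(min_term_size=1),
        )
        assert out.representative_ids == ["top"]
        assert out.groups[0].represented_ids == ("c1", "c2")

    def test_oversized_terms_dropped_by_default(self):
        coll = build_collection(
            {
                "huge": {f"g{i}" for i in range(20)},
                "mid": {f"g{i}" for i in range(5)},
            }
        )
        cfg = FilterConfig(min_term_size=1, max_representative_size=10)
        out = filter_enrichment_results(
            [RankedTermList("L", ("huge", "mid"))], coll, cfg
        )
        assert out.oversized_ids == ("huge",)
        assert out.representative_ids == ["mid"]  # mid no longer absorbed

    def test_oversized_kept_as_self_only_when_configured(self):
        coll = build_collection(
            {
                "huge": {f"g{i}" for i in range(20)},
                "mid": {f"g{i}" for i in range(5)},
            }
        )
        cfg = FilterConfig(
            min_term_size=1, max_representative_size=10, keep_oversized_as_self=True
        )
        out = filter_enrichment_results(
            [RankedTermList("L", ("huge", "mid"))], coll, cfg
        )
        assert out.oversized_ids == ()
        assert out.representative_ids == ["huge", "mid"]
        assert out.groups[0].represented_ids == ()  # huge absorbs nothing

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_naive_reference_on_random_fixtures(self, seed):
        coll, lst = random_collection_and_list(seed, max_terms=120)
        merged = merge_rankings([lst])
        out = filter_redundant(merged, coll, FilterConfig(min_term_size=1))
        expected = naive_filter_reference(list(lst.term_ids), coll)
        got = [(g.representative_id, list(g.represented_ids)) for g in out.groups]
        assert got == expected

    @pytest.mark.parametrize("seed", range(8))
    def test_invariants_on_random_fixtures(self, seed):
        coll, lst = random_collection_and_list(seed + 100, max_terms=150)
        out = filter_enrichment_results([lst], coll, FilterConfig(min_term_size=1))
        reps = out.representative_ids
        # subset-maximality: no surviving representative covers a later one
        for i, a in enumerate(reps):
            for b in reps[i + 1 :]:
                assert not coll[b].genes <= coll[a].genes
        # coverage soundness
        for g in out.groups:
            for t in g.represented_ids:
                assert coll[g.representative_id].genes >= coll[t].genes
        # partition identity
        all_ids = (
            reps
            + [t for g in out.groups for t in g.represented_ids]
            + list(out.undersized_ids)
            + list(out.unannotated_ids)
            + list(out.oversized_ids)
        )
        assert sorted(all_ids) == sorted(lst.term_ids)
        assert out.n_terms == len(lst)
        # monotone reduction
        assert len(reps) <= len(lst)

    @pytest.mark.parametrize("seed", [3, 42, 77])
    def test_idempotence(self, seed):
        """Feeding the representative list back through the filter changes nothing."""
        coll, lst = random_collection_and_list(seed, max_terms=100)
        out = filter_enrichment_results([lst], coll, FilterConfig(min_term_size=1))
        again = filter_enrichment_results(
            [RankedTermList("reps", tuple(out.representative_ids))],
            coll,
            FilterConfig(min_term_size=1),
        )
        assert again.representative_ids == out.representative_ids
        assert again.n_represented == 0

    def test_processing_precedence_respected(self):
        """A representative always precedes its represented terms."""
        coll, lst = random_collection_and_list(7, max_terms=80)
        out = filter_enrichment_results([lst], coll, FilterConfig(min_term_size=1))
        pos = {t: i for i, t in enumerate(lst.term_ids)}
        for g in out.groups:
            for t in g.represented_ids:
                assert pos[g.representative_id] < pos[t]


class TestFilterConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            FilterConfig(min_term_size=0)
        with pytest.raises(ValueError):
            FilterConfig(top_n_plot=51)
        with pytest.raises(ValueError):
            FilterConfig(min_term_size=10, max_representative_size=5)
        cfg = FilterConfig()
        assert cfg.min_term_size == 10
        assert cfg.max_representative_size is None
        assert cfg.top_n_plot == 50
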