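"""Merging of ranked enrichment results and subset-coverage redundancy filtering.

The filtering principle: a term is discarded if a more significant term
annotates at least the same genes; the surviving, more significant term
becomes the *representative* of the discarded term.  Because ancestor terms
in hierarchical annotation databases (GO, Reactome) annotate every gene their
descendants annotate, this amounts to letting significant ancestors stand in
for their less significant descendants — no similarity measure, no threshold.

When several enrichment results are filtered collectively, their term lists
are first merged: each distinct term receives the best (minimum) rank it has
in any input list, and filtering then runs once over the merged ranking.

Processing order
----------------
Terms are processed by ascending best rank.  Ties are broken by
first-appearance order when scanning the input lists position by position
(rank 1 of list 1, rank 1 of list 2, ..., rank 2 of list 1, ...), so the
order the user supplies the result files in is meaningful and the outcome is
fully deterministic.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

from .annotation_io import AnnotationCollection, RankedTermList

logger = logging.getLogger(__name__)

MAX_PLOT_TERMS = 50


@dataclass(frozen=True)
class FilterConfig:
    """Tunable parameters of the filtering pipeline.

    Parameters
    ----------
    min_term_size:
        Terms annotating fewer genes than this are removed before filtering
        (default 10).  Very small terms are often annotated by the same genes
        as many other terms and add little information.
    max_representative_size:
        Optional cap on the gene-set size of terms allowed to *represent*
        others.  Useful when a very general, very significant term would
        otherwise swallow many specific terms.  Unset by default.
    top_n_plot:
        Number of representative terms shown in the heatmap/barplot
        (default and maximum 50).
    keep_oversized_as_self:
        Policy switch for terms larger than ``max_representative_size``: by
        default they are dropped from the output entirely (recorded in
        ``oversized_ids``), which keeps the filtered list specific; when
        True they are kept as self-only representatives that never absorb
        other terms.
    """

    min_term_size: int = 10
    max_representative_size: int | None = None
    top_n_plot: int = MAX_PLOT_TERMS
    keep_oversized_as_self: bool = False

    def __post_init__(self) -> None:
        if self.min_term_size < 1:
            raise ValueError("min_term_size must be >= 1")
        if not (1 <= self.top_n_plot <= MAX_PLOT_TERMS):
            raise ValueError(f"top_n_plot must be in 1..{MAX_PLOT_TERMS}")
        if (
            self.max_representative_size is not None
            and self.max_representative_size < self.min_term_size
        ):
            raise ValueError(
                "max_representative_size must be >= min_term_size when set"
            )


@dataclass(frozen=True)
class MergedEntry:
    """One term of a merged ranking: best rank plus its rank in each source."""

    term_id: str
    best_rank: int
    source_ranks: dict[str, int]


@dataclass
class MergedRanking:
    """Deduplicated union of input lists, sorted in processing order."""

    entries: list[MergedEntry]
    source_aliases: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def term_ids(self) -> list[str]:
        return [e.term_id for e in self.entries]


@dataclass(frozen=True)
class RepresentativeGroup:
    """A surviving term and the discarded terms it stands for (flat, no chains)."""

    representative_id: str
    represented_ids: tuple[str, ...] = ()

    @property
    def member_ids(self) -> tuple[str, ...]:
        return (self.representative_id, *self.represented_ids)


@dataclass
class FilterOutcome:
    """Result of the full filtering pipeline.

    ``groups`` holds the representatives in processing order; the remaining
    fields are the discard ledgers.  Representatives, represented terms and
    the three ledgers partition the merged input term set.
    """

    groups: list[RepresentativeGroup]
    undersized_ids: tuple[str, ...] = ()
    unannotated_ids: tuple[str, ...] = ()
    oversized_ids: tuple[str, ...] = ()
    source_aliases: tuple[str, ...] = ()

    @property
    def representative_ids(self) -> list[str]:
        return [g.representative_id for g in self.groups]

    @property
    def n_represented(self) -> int:
        return sum(len(g.represented_ids) for g in self.groups)

    @property
    def n_terms(self) -> int:
        """Number of distinct input terms accounted for across all buckets."""
        return (
            len(self.groups)
            + self.n_represented
            + len(self.undersized_ids)
            + len(self.unannotated_ids)
            + len(self.oversized_ids)
        )


def merge_rankings(lists: Sequence[RankedTermList]) -> MergedRanking:
    """Merge ranked lists: each distinct term gets its best rank over sources.

    The returned entries are sorted in processing order (best rank ascending,
    ties by position-by-position first appearance across lists in the given
    order).  Merging is symmetric: any permutation of the input lists yields
    the same best ranks, though tie-break order follows the given list order.

    Raises
    ------
    ValueError
        If no list is given or source aliases are not unique.
    """
    if not lists:
        raise ValueError("at least one ranked term list is required")
    aliases = [lst.source_alias for lst in lists]
    if len(set(aliases)) != len(aliases):
        raise ValueError(f"duplicate source aliases: {aliases}")

    source_ranks: dict[str, dict[str, int]] = {}
    first_seen: dict[str, int] = {}
    counter = 0
    longest = max(len(lst) for lst in lists)
    for pos in range(longest):  # round-robin scan fixes the tie-break order
        for lst in lists:
            if pos >= len(lst.term_ids):
                continue
            tid = lst.term_ids[pos]
            if tid not in first_seen:
                first_seen[tid] = counter
                counter += 1
            source_ranks.setdefault(tid, {})[lst.source_alias] = pos + 1

    entries = [
        MergedEntry(term_id=tid, best_rank=min(ranks.values()), source_ranks=ranks)
        for tid, ranks in source_ranks.items()
    ]
    entries.sort(key=lambda e: (e.best_rank, first_seen[e.term_id]))
    return MergedRanking(entries=entries, source_aliases=tuple(aliases))


def remove_undersized(
    merged: MergedRanking,
    annotations: AnnotationCollection,
    min_size: int,
) -> tuple[MergedRanking, tuple[str, ...], tuple[str, ...]]:
    """Drop terms below ``min_size`` genes and terms missing from the GMT.

    Returns the surviving ranking (relative order preserved) plus the IDs
    moved to the undersized and unannotated ledgers.  Terms present in a
    result list but absent from the annotation collection cannot be assessed
    for coverage; they are set aside with a logged warning.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    survivors: list[MergedEntry] = []
    undersized: list[str] = []
    unannotated: list[str] = []
    for entry in merged.entries:
        if entry.term_id not in annotations:
            unannotated.append(entry.term_id)
        elif annotations.size_of(entry.term_id) < min_size:
            undersized.append(entry.term_id)
        else:
            survivors.append(entry)
    if unannotated:
        logger.warning(
            "%d term(s) from the enrichment results are absent from the GMT "
            "and were set aside: %s",
            len(unannotated),
            ", ".join(unannotated[:10]) + ("..." if len(unannotated) > 10 else ""),
        )
    return (
        MergedRanking(entries=survivors, source_aliases=merged.source_aliases),
        tuple(undersized),
        tuple(unannotated),
    )


def is_covered(
    candidate_id: str, other_id: str, annotations: AnnotationCollection
) -> bool:
    """True iff ``other`` annotates at least the same genes as ``candidate``.

    Equality of the two gene sets also counts as coverage.  Raises
    ``KeyError`` when either ID is unknown to the collection.
    """
    if candidate_id not in annotations:
        raise KeyError(f"unknown term ID {candidate_id!r}")
    if other_id not in annotations:
        raise KeyError(f"unknown term ID {other_id!r}")
    return annotations.covers(candidate_id, other_id)


def filter_redundant(
    merged: MergedRanking,
    annotations: AnnotationCollection,
    config: FilterConfig = FilterConfig(),
    *,
    undersized_ids: Iterable[str] = (),
    unannotated_ids: Iterable[str] = (),
) -> FilterOutcome:
    """Apply subset-coverage filtering to a merged ranking.

    Walking the terms in processing order, each term is compared against the
    representatives found so far: the first representative whose gene set
    covers the term absorbs it; otherwise the term starts a new group.
    Comparing only against surviving representatives loses nothing: coverage
    is transitive, so a term covered by an absorbed term is also covered by
    that term's representative.

    When ``config.max_representative_size`` is set, a term larger than the
    cap can never represent another term.  By default such oversized terms
    are excluded from the output entirely (``oversized_ids``); with
    ``config.keep_oversized_as_self`` they stay as self-only representatives.

    ``merged`` is expected to have already passed :func:`remove_undersized`;
    the corresponding ledgers can be passed through so the returned outcome
    accounts for every input term.
    """
    max_rep = config.max_representative_size
    # representatives eligible to absorb other terms, in processing order
    eligible: list[tuple[str, frozenset[str], int]] = []  # (id, genes, group idx)
    groups: list[tuple[str, list[str]]] = []
    oversized: list[str] = []

    for entry in merged.entries:
        tid = entry.term_id
        genes = annotations[tid].genes
        size = len(genes)
        assigned = False
        for _, rep_genes, gidx in eligible:
            if len(rep_genes) >= size and rep_genes >= genes:
                groups[gidx][1].append(tid)
                assigned = True
                break
        if assigned:
            continue
        if max_rep is not None and size > max_rep:
            if config.keep_oversized_as_self:
                groups.append((tid, []))  # self-only; never absorbs others
            else:
                oversized.append(tid)
            continue
        groups.append((tid, []))
        eligible.append((tid, genes, len(groups) - 1))

    return FilterOutcome(
        groups=[
            RepresentativeGroup(representative_id=rep, represented_ids=tuple(rep_ids))
            for rep, rep_ids in groups
        ],
        undersized_ids=tuple(undersized_ids),
        unannotated_ids=tuple(unannotated_ids),
        oversized_ids=tuple(oversized),
        source_aliases=merged.source_aliases,
    )


def filter_enrichment_results(
    lists: Sequence[RankedTermList],
    annotations: AnnotationCollection,
    config: FilterConfig = FilterConfig(),
) -> FilterOutcome:
    """Full pipeline: merge, remove undersized/unannotated, filter redundancy."""
    merged = merge_rankings(lists)
    survivors, undersized, unannotated = remove_undersized(
        merged, annotations, config.min_term_size
    )
    return filter_redundant(
        survivors,
        annotations,
        config,
        undersized_ids=undersized,
        unannotated_ids=unannotated,
    )
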