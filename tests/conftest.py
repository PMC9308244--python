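"""Shared fixtures: tiny hand-built collections and random fixture factories.

The random-ontology factory here is deliberately simple and independent of
``enrichsum.synthesis``: it builds arbitrary (not necessarily hierarchical)
random gene sets, which is the harder case for the filtering invariants.
"""

from __future__ import annotations

import random

import pytest

from enrichsum import AnnotationCollection, RankedTermList, Term


def build_collection(sets: dict[str, set[str]]) -> AnnotationCollection:
    coll = AnnotationCollection()
    for tid, genes in sets.items():
        coll.add(Term(id=tid, description=f"{tid} desc", genes=frozenset(genes)))
    return coll


@pytest.fixture
def micro_collection() -> AnnotationCollection:
    """Four terms: A covers C; B, D unrelated to everything else."""
    return build_collection(
        {
            "B": {"g1", "g2"},
            "A": {"g1", "g2", "g3", "g4"},
            "C": {"g3", "g4"},
            "D": {"g5", "g6"},
        }
    )


@pytest.fixture
def micro_list() -> RankedTermList:
    """Processing order B, A, C, D — the worked micro-example."""
    return RankedTermList(source_alias="L1", term_ids=("B", "A", "C", "D"))


def random_collection_and_list(
    seed: int, max_terms: int = 200
) -> tuple[AnnotationCollection, RankedTermList]:
    """A random gene-set collection plus one ranked list over all its terms.

    Sets are sampled so that nesting and equality occur often: some terms are
    fresh random subsets of the universe, others are subsets of an earlier
    term, and a few duplicate an earlier term's gene set exactly.
    """
    rng = random.Random(seed)
    n_terms = rng.randint(2, max_terms)
    universe = [f"g{i}" for i in range(rng.randint(20, 120))]
    sets: dict[str, set[str]] = {}
    ids: list[str] = []
    for i in range(n_terms):
        tid = f"R{i:03d}"
        draw = rng.random()
        if ids and draw < 0.35:  # subset of an earlier term
            parent = sets[rng.choice(ids)]
            k = rng.randint(1, len(parent))
            genes = set(rng.sample(sorted(parent), k))
        elif ids and draw < 0.45:  # exact duplicate gene set
            genes = set(sets[rng.choice(ids)])
        else:
            k = rng.randint(1, min(25, len(universe)))
            genes = set(rng.sample(universe, k))
        sets[tid] = genes
        ids.append(tid)
    order = ids[:]
    rng.shuffle(order)
    coll = build_collection(sets)
    return coll, RankedTermList(source_alias="rand", term_ids=tuple(order))


def naive_filter_reference(
    order: list[str], coll: AnnotationCollection
) -> list[tuple[str, list[str]]]:
    """O(n^2) reference for the redundancy filter, written from the principle.

    For each term in processing order, scan *all earlier surviving terms* and
    assign the term to the first whose gene set is a superset of its own;
    otherwise the term survives.  No size thresholds.
    """
    survivors: list[str] = []
    assigned: dict[str, list[str]] = {}
    for tid in order:
        rep = None
        for s in survivors:
            if coll[s].genes >= coll[tid].genes:
                rep = s
                break
        if rep is None:
            survivors.append(tid)
            assigned[tid] = []
        else:
            assigned[rep].append(tid)
    return [(s, assigned[s]) for s in survivors]
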