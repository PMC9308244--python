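"""Synthetic annotation hierarchies, artificial query gene lists, and ORA.

This module makes the whole pipeline testable without any download.  It
emulates the two structures the filtering method relies on:

* **Hierarchical annotation collections** in which every ancestor term
  annotates all the genes annotated by its descendants (the containment
  property of GO/Reactome that makes subset-coverage filtering meaningful).
  :func:`generate_ontology` builds a forest of terms where each child's gene
  set is a random fraction of its parent's.

* **Ranked enrichment results.**  :func:`generate_artificial_query` builds a
  query gene list seeded from one large annotation term (half of the term's
  genes plus an equal number of random genes), so the query is genuinely
  enriched rather than random noise.  :func:`run_ora` then performs a
  hypergeometric over-representation test per term with Bonferroni
  correction and emits the significant terms as a significance-ordered
  :class:`~enrichsum.annotation_io.RankedTermList` — ranks only, no p-values,
  matching the filter's input contract.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .annotation_io import AnnotationCollection, RankedTermList, Term

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OntologyParams:
    """Shape of a generated annotation forest.

    ``n_roots`` disjoint root terms split a universe of ``universe_size``
    genes; each node at depths 2..``depth`` has ``branching`` children, and a
    child inherits a random ``child_fraction`` of its parent's genes.  The
    generated collection is deterministic for a fixed ``seed``.
    """

    universe_size: int = 2000
    n_roots: int = 4
    depth: int = 4
    branching: int = 3
    child_fraction: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.universe_size, self.n_roots, self.depth, self.branching) < 1:
            raise ValueError("all ontology size parameters must be positive")
        if not 0.0 < self.child_fraction < 1.0:
            raise ValueError("child_fraction must be strictly between 0 and 1")
        root_size = self.universe_size // self.n_roots
        leaf_size = root_size * self.child_fraction ** (self.depth - 1)
        if leaf_size < 1.0:
            raise ValueError(
                "parameters imply empty leaf terms "
                f"(root size {root_size}, expected leaf size {leaf_size:.2f})"
            )


@dataclass(frozen=True)
class OraParams:
    """Over-representation test settings.

    ``alpha`` is the significance level applied after Bonferroni correction
    (adjusted p < alpha).  ``min_source_term_size`` bounds the terms eligible
    to seed an artificial query: strictly more than this many genes
    (default 100).
    """

    alpha: float = 0.05
    correction: str = "bonferroni"
    min_source_term_size: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.correction != "bonferroni":
            raise ValueError(f"unsupported correction {self.correction!r}")


class ArtificialQuery(NamedTuple):
    """A generated query gene list plus the term that seeded it."""

    genes: list[str]
    source_term_id: str


def generate_ontology(params: OntologyParams) -> AnnotationCollection:
    """Generate a forest of terms with the ancestor-superset property.

    Roots receive disjoint, equal-size random slices of the gene universe;
    every child's gene set is a uniformly sampled ``child_fraction`` subset
    of its parent's, so ``genes(child) <= genes(parent)`` holds everywhere by
    construction.  Term IDs encode nothing about the hierarchy; descriptions
    record depth and parent for human inspection.
    """
    rng = np.random.default_rng(params.seed)
    universe = np.array([f"G{i:05d}" for i in range(params.universe_size)])
    rng.shuffle(universe)

    collection = AnnotationCollection()
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"T{counter:04d}"

    root_size = params.universe_size // params.n_roots
    frontier: list[tuple[str, np.ndarray]] = []
    for r in range(params.n_roots):
        genes = universe[r * root_size : (r + 1) * root_size]
        tid = new_id()
        collection.add(
            Term(id=tid, description="depth 1 root", genes=frozenset(genes))
        )
        frontier.append((tid, genes))

    for level in range(2, params.depth + 1):
        next_frontier: list[tuple[str, np.ndarray]] = []
        for parent_id, parent_genes in frontier:
            child_size = max(1, round(params.child_fraction * len(parent_genes)))
            for _ in range(params.branching):
                genes = rng.choice(parent_genes, size=child_size, replace=False)
                tid = new_id()
                collection.add(
                    Term(
                        id=tid,
                        description=f"depth {level} child of {parent_id}",
                        genes=frozenset(genes),
                    )
                )
                next_frontier.append((tid, genes))
        frontier = next_frontier
    return collection


def generate_artificial_query(
    annotations: AnnotationCollection,
    params: OraParams = OraParams(),
    seed: int = 0,
) -> ArtificialQuery:
    """Build an enrichable query list seeded from one large term.

    A term annotating more than ``params.min_source_term_size`` genes is
    chosen uniformly at random.  If it annotates ``n`` genes, the query is
    ``floor(n/2)`` of its genes plus ``ceil(n/2)`` genes drawn from the rest
    of the universe — size exactly ``n``, no duplicates.  The random half is
    sampled from the universe outside the already-chosen genes, so it may by
    chance include other genes of the source term.

    Raises
    ------
    ValueError
        If no term exceeds the size threshold, or the universe cannot supply
        the random half.
    """
    rng = np.random.default_rng(seed)
    eligible = sorted(
        t.id for t in annotations if t.size > params.min_source_term_size
    )
    if not eligible:
        raise ValueError(
            f"no term annotates more than {params.min_source_term_size} genes"
        )
    source_id = eligible[rng.integers(len(eligible))]
    term_genes = sorted(annotations[source_id].genes)
    n = len(term_genes)
    n_annotated = n // 2
    n_random = n - n_annotated  # ceil(n/2)
    chosen = list(rng.choice(term_genes, size=n_annotated, replace=False))
    pool = sorted(annotations.universe - set(chosen))
    if len(pool) < n_random:
        raise ValueError(
            f"universe too small: need {n_random} random genes, pool has {len(pool)}"
        )
    chosen += list(rng.choice(pool, size=n_random, replace=False))
    return ArtificialQuery(genes=chosen, source_term_id=source_id)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` is the universe size, ``K`` the term size, ``n`` the query size and
    ``k`` the observed overlap.  Evaluated through the survival function of
    the hypergeometric distribution, which works in log space and stays
    accurate far into the tail.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"infeasible sizes: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside 0..min(K={K}, n={n})")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def run_ora(
    query: list[str],
    annotations: AnnotationCollection,
    params: OraParams = OraParams(),
    alias: str = "ora",
) -> RankedTermList:
    """Hypergeometric over-representation analysis of a query gene list.

    Every term in the collection is tested against the GMT universe as
    background.  Raw p-values are Bonferroni-adjusted (multiplied by the
    number of tested terms, capped at 1); terms with adjusted p < alpha are
    kept and emitted ordered by ascending raw p, ties broken by term ID.
    Query genes absent from the universe are dropped with a warning.
    """
    universe = annotations.universe
    query_set = set(query)
    if len(query_set) != len(query):
        raise ValueError("query gene list contains duplicates")
    unknown = query_set - universe
    if unknown:
        logger.warning(
            "%d query gene(s) absent from the annotation universe were dropped",
            len(unknown),
        )
        query_set -= unknown
    if not query_set:
        raise ValueError("query is empty after removing unknown genes")

    term_ids = [t.id for t in annotations]
    N = len(universe)
    n = len(query_set)
    ks = np.array([len(annotations[t].genes & query_set) for t in term_ids])
    Ks = np.array([annotations[t].size for t in term_ids])
    # P(X >= k); sf(k-1) so that k = 0 gives exactly 1
    raw_p = stats.hypergeom.sf(ks - 1, N, Ks, n)
    m = len(term_ids)
    adjusted = np.minimum(1.0, raw_p * m)

    significant = [
        (raw_p[i], term_ids[i]) for i in range(m) if adjusted[i] < params.alpha
    ]
    significant.sort(key=lambda pair: (pair[0], pair[1]))
    return RankedTermList(
        source_alias=alias, term_ids=tuple(tid for _, tid in significant)
    )


def bonferroni(raw_p: float, n_tests: int) -> float:
    """Bonferroni-adjusted p-value: raw p times the number of tests, capped at 1."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, raw_p * n_tests)


def exact_hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability by exact combinatorial summation.

    Integer-arithmetic reference: sums C(K,j)·C(N−K,n−j) for j ≥ k and divides
    by C(N,n).  Exact (no floating-point accumulation) but only practical for
    small universes; used to cross-check :func:`hypergeom_tail`.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"infeasible sizes: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside 0..min(K={K}, n={n})")
    numerator = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
        if n - j <= N - K
    )
    return numerator / math.comb(N, n)
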