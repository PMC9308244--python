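"""Filter one ranked enrichment result against a tiny annotation collection.

Builds a four-term GMT in memory where term A annotates a superset of term
C's genes, filters the ranked list [B, A, C, D], and prints the resulting
representative groups.  C disappears from the output because the more
significant A annotates at least the same genes; A becomes its
representative.  B and D survive untouched — nothing above them covers them.
"""

from enrichsum import (
    AnnotationCollection,
    FilterConfig,
    RankedTermList,
    Term,
    filter_enrichment_results,
)

collection = AnnotationCollection()
for tid, desc, genes in [
    ("B", "small early term", {"g1", "g2"}),
    ("A", "general term", {"g1", "g2", "g3", "g4"}),
    ("C", "specific term", {"g3", "g4"}),
    ("D", "unrelated term", {"g5", "g6"}),
]:
    collection.add(Term(id=tid, description=desc, genes=frozenset(genes)))

ranked = RankedTermList(source_alias="demo", term_ids=("B", "A", "C", "D"))
outcome = filter_enrichment_results(
    [ranked], collection, FilterConfig(min_term_size=1)
)

print(f"{len(ranked)} input terms -> {len(outcome.groups)} representatives\n")
for group in outcome.groups:
    term = collection[group.representative_id]
    represented = ", ".join(group.represented_ids) or "-"
    print(f"  {term.id} ({term.description}, {term.size} genes) represents: {represented}")
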