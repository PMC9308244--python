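"""Collectively filter several enrichment results and compare them.

Generates a synthetic hierarchical annotation collection (every ancestor
term annotates all genes of its descendants), derives three enrichment
results from artificial query gene lists via hypergeometric ORA, filters
them collectively, and writes the full report set — Summary/Detailed TSV,
HTML, quartile heatmap and represented-count barplot — to
``example_output/``.  The printed quartile matrix shows, per representative
group and input result, which quarter of that result's ranking the group
falls in (1 = most significant quarter; <NA> = group absent from that
result), which is how shared and condition-specific terms become visible.
"""

from pathlib import Path

from enrichsum import (
    FilterConfig,
    OntologyParams,
    OraParams,
    assign_quartiles,
    filter_enrichment_results,
    generate_artificial_query,
    generate_ontology,
    group_source_ranks,
    render_barplot,
    render_heatmap,
    run_ora,
    write_reports,
)

collection = generate_ontology(OntologyParams(universe_size=2000, seed=8))
ora = OraParams()
lists = [
    run_ora(
        generate_artificial_query(collection, ora, seed=i).genes,
        collection,
        ora,
        alias=f"condition{i + 1}",
    )
    for i in range(3)
]

outcome = filter_enrichment_results(lists, collection, FilterConfig())
print(
    f"merged {outcome.n_terms} distinct terms from {len(lists)} results "
    f"-> {len(outcome.groups)} representatives "
    f"({outcome.n_represented} terms absorbed)\n"
)

ranks = group_source_ranks(outcome, lists)
quartiles = assign_quartiles(ranks, lists)
print("rank quartile of each representative group per result:")
print(quartiles)

out_dir = Path("example_output")
write_reports(outcome, ranks, collection, out_dir, "comparison")
top_n = min(20, len(outcome.groups))
render_heatmap(quartiles, top_n, out_dir / "comparison-Heatmap.png")
render_barplot(outcome, top_n, out_dir / "comparison-Barplot.png")
print(f"\nreports and figures written to {out_dir}/")
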