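# enrichsum

Filter and compare enrichment analysis results with one simple rule:
**a term is discarded when a more significant term annotates at least the
same genes**, and the surviving, more significant term becomes the
*representative* of the discarded one.

## Why

Over-representation analysis of a gene list against GO or Reactome
routinely returns hundreds of significant terms, most of them redundant:
because these databases are hierarchical, an ancestor term annotates every
gene its descendants annotate, so parent and child tend to be significant
together. Long, redundant term lists are painful to interpret, report, and —
when several conditions are analyzed — compare.

enrichsum filters such lists without semantic-similarity measures or
similarity thresholds. The inputs are

1. a **GMT file** (one term per line: ID, description, annotated genes), and
2. one or more **ranked enrichment results**: plain files with one term ID
   per line, ordered most → least significant (no p-values needed).

When several results are given they are filtered *collectively*: the lists
are merged, each distinct term keeps the best (minimum) rank it has in any
input, and filtering runs once over the merged ranking, so the reports show
directly which representative terms are shared between conditions and which
are condition-specific.

## The method

Let `genes(t)` be the gene set a term annotates and process terms by
ascending best rank. A term `t` is assigned to the first already-surviving
term `r` with `genes(r) ⊇ genes(t)`; otherwise `t` survives as a new
representative. Equal gene sets count as covered (the earlier term wins),
and representation is flat: every discarded term maps directly to a
surviving representative. Two optional size parameters:

- **minimum term size** (default 10): terms annotating fewer genes are
  removed before filtering;
- **maximum representative term size** (off by default): terms annotating
  more genes than the cap may not represent others, which keeps specific
  terms in the output when a very general term is very significant.

For the comparison views, each representative group (representative plus
the terms it represents) is located in every input result by the best rank
any member attains there, and that rank is binned into the quartile of the
source list, `ceil(4·rank/L)` for a list of length `L`.

## Worked example

`examples/01_filter_single_result.py` builds a four-term collection in
which term A annotates a superset of term C's genes and filters the ranked
list `[B, A, C, D]`:

```
4 input terms -> 3 representatives

  B (small early term, 2 genes) represents: -
  A (general term, 4 genes) represents: C
  D (unrelated term, 2 genes) represents: -
```

C is gone: A is better ranked and annotates at least C's genes, so A now
stands for both. B and D are untouched because nothing above them covers
them. `examples/02_compare_multiple_results.py` does the same collectively
for three synthetic enrichment results and prints the quartile matrix
behind the heatmap:

```
merged 41 distinct terms from 3 results -> 7 representatives (34 terms absorbed)

rank quartile of each representative group per result:
                condition1  condition2  condition3
representative
T0045                    1        <NA>           2
T0025                 <NA>           1        <NA>
...
```

Row `T0045` is a term group significant in conditions 1 and 3 (top quarter
of condition 1's ranking) but entirely absent from condition 2 — exactly
the kind of shared-versus-specific pattern collective filtering exposes.

## Command line

```bash
# write a synthetic GMT + ranked enrichment results to play with
enrichsum synth --outputFolder fixture --seed 1

# filter them collectively
enrichsum filter --gmt fixture/synthetic.gmt \
    --files fixture/query1.txt --files fixture/query2.txt \
    --outputFolder out --minTermSize 10 --numberOfTermsToPlot 20
```

`filter` writes five artifacts into `--outputFolder`:

| file | content |
| --- | --- |
| `<base>-Summary.tsv` | one row per representative: ID, description, term size, number of represented terms, best group rank per input result |
| `<base>-Detailed.tsv` | Summary rows plus one row per represented term under its representative |
| `<base>.html` | self-contained page; click a representative to expand the terms it represents |
| `<base>-Heatmap.png/.svg` | top representatives × input results, colored by rank quartile (grey = absent) |
| `<base>-Barplot.png/.svg` | how many terms each top representative represents |

The order of `--files` fixes tie-breaking between equal best ranks and the
column order of the reports. Stage counts (merged, undersized, unannotated,
representatives) are logged to stderr.

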