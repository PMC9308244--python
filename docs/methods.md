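# Methods

## The filtering model

enrichsum treats an enrichment result as nothing more than an ordered list
of term IDs (rank 1 = most significant) and an annotation collection as a
mapping from term ID to gene set. The only structural assumption is the one
hierarchical annotation databases guarantee: an ancestor term annotates
every gene its descendants annotate. Coverage — `genes(r) ⊇ genes(t)`,
including equality — is therefore the operational stand-in for "r is an
ancestor of t or annotates at least as much", and no ontology graph is ever
parsed: hierarchy is inferred from gene-set containment alone. For
annotation collections that are *not* hierarchically organized the
principle degenerates (coverage pairs are rare), and clustering-based
summarization is the better tool.

Filtering walks the merged ranking top-down. Each term is compared against
the representatives found so far, in their processing order; the first one
that covers it absorbs it, otherwise the term opens a new group. Comparing
against representatives only (rather than all earlier terms) is lossless:
coverage is transitive, so a term covered by an absorbed term is also
covered by that term's representative. This makes the assignment *flat* —
every discarded term points directly at a surviving representative, never
at another discarded term — which keeps the Detailed report unambiguous.
The whole procedure is O(n²) subset checks in the worst case; at realistic
result sizes (a few thousand terms) this is fractions of a second.

Consequences worth knowing:

- A term more significant than its ancestor survives alongside it: some
  redundancy is retained, but deliberately — the more significant, more
  specific information is never hidden behind a general term.
- Equal gene sets are merged in favor of the better-ranked term.
- The filter has no tunable similarity threshold; its output is exactly
  predictable from ranks and containment.

## Merging multiple results

Lists are merged by taking, per distinct term, the minimum rank over all
inputs. The processing order is best rank ascending, ties broken by
first-appearance order when scanning the inputs position by position
(rank 1 of list 1, rank 1 of list 2, …, rank 2 of list 1, …). The tie-break
is a design choice — the merged ranks themselves do not order terms with
equal best rank — chosen to be deterministic and to respect the order the
user supplies the files in. Merging is symmetric in the best ranks;
only the tie-break depends on the file order.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `min_term_size` | 10 | terms annotating fewer genes (strictly `<`) are removed before filtering; tiny terms are often annotated by the same genes as many others and add noise |
| `max_representative_size` | unset | when set, a term annotating more genes than the cap can never represent others |
| `top_n_plot` | 50 (max 50) | representatives shown in heatmap/barplot |
| `keep_oversized_as_self` | off | policy for terms above the cap, see below |

**Oversized-term policy.** The size cap exists so that specific terms stay
visible in the filtered output. Keeping the oversized terms themselves as
output rows would defeat that purpose, so by default they are removed
entirely and recorded in `oversized_ids`. Because any term covering an
oversized term is at least as large, oversized terms can never be absorbed
either; they form their own discard ledger. The alternative —
keep them as self-only representatives that absorb nothing — is available
behind `keep_oversized_as_self` for users who want the general terms listed
but inert.

**Unannotated terms.** Result terms absent from the GMT cannot be assessed
for coverage; they are set aside into their own ledger with a warning
rather than silently dropped or kept. Representatives, represented terms,
undersized, unannotated and oversized terms always partition the merged
input — an invariant the test suite asserts on every generated fixture.

## Report semantics

A *group* is a representative plus the terms it represents. Its rank in a
source list is the **best rank over all group members** present there —
a representative stays visible in a condition where only its absorbed
descendants were enriched, which is the point of collective filtering. The
quartile bin of a rank r in a list of length L is `ceil(4r/L)`, clipped to
1..4; a length-1 list therefore puts its only term in Q4 (the formula's
degenerate case, kept as-is for monotonicity rather than special-cased).
"Top N" always means the first N groups in processing order. TSV columns
and the HTML layout are this package's own schema; they are stable and
documented in the README.

The size-vs-representation statistic is the Spearman rank correlation
between `|genes(representative)|` and the number of represented terms,
across all representatives. It is reported only when it is defined: at
least three representatives and non-zero variance on both sides, otherwise
`DegenerateCorrelationError` is raised rather than returning a NaN.

## Synthetic data

`generate_ontology` emulates the containment structure of GO/Reactome as a
forest: roots receive disjoint, equal slices of a gene universe, and each
child inherits a uniformly drawn `child_fraction` of its parent's genes.
Defaults (universe 2000 genes, 4 roots, depth 4, branching 3, fraction
0.45) give 160 terms with root size 500 and leaf size ≈ 45 — large enough
that terms above the 100-gene query-seeding threshold exist at three
depths, small enough that a hundred end-to-end runs finish in seconds.
What it does **not** emulate: multiple parents (GO is a DAG, not a forest),
annotation noise (real child terms are not exact subsets after evidence
filtering), realistic term-size distributions, and inter-branch gene
sharing. Passing tests on this generator therefore certify the logic of
merging/filtering/reporting and the statistical machinery, not performance
on any particular real annotation release.

Artificial queries plant a recoverable signal: pick a term with more than
100 genes uniformly at random (strictly `>`; the eligible-term list is
sorted by ID before the draw, making the choice reproducible per seed),
take `floor(n/2)` of its `n` genes, and fill up to size `n` with genes
drawn from the rest of the universe — which may, by chance, include other
genes of the source term, so the planted overlap is a lower bound. The
floor/ceil split resolves the integer ambiguity of "n/2" for odd `n`.

ORA tests every term in the collection against the GMT universe as
background (the universe is the only gene pool the harness knows; a real
analysis would justify its background separately). The p-value is the
hypergeometric upper tail P(X ≥ k), evaluated via `scipy.stats.hypergeom.sf`
(log-space internals; the test suite pins it against an exact
integer-combinatorics summation to < 1e-9 relative error over the full
N ≤ 60 grid). Bonferroni correction multiplies by the number of tested
terms, capped at 1; terms with adjusted p < 0.05 are kept, ordered by raw
p with ties broken by term ID, and emitted as a rank-only list — the same
contract as real input, including the legal empty result.

## Numerical and degenerate-input choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; identical seeds give byte-identical GMT/TSV/HTML outputs.
- Gene and term IDs are exact strings after whitespace trimming; no case
  folding (GMT dialects differ, and case-merging can conflate genes).
- Duplicate genes within a GMT line collapse silently (benign redundancy);
  duplicate term IDs across lines are an error, as are duplicate term IDs
  within one ranked list — the format gives no way to choose between them.
- An empty survivor set after size filtering is legal; reports then contain
  headers only and plots are skipped.
- `write_gmt` emits genes lexicographically and terms in insertion order,
  so write→parse is the identity and outputs diff cleanly.

## Problem sizes used in the checks

The automated checks run on generated data sized for tight feedback loops:
100 random collections of up to 200 terms for the filter-versus-naive-
reference equivalence, the full feasible hypergeometric grid up to
universe 60 (≈1.2 million tail values), and 100 seeded ORA-plus-filtering
runs on the 160-term default ontology for signal recovery. The four-disease
reproduction check runs only when the original deposited inputs are placed
under `data/usecase/`, as described in the README.

## Known limitations

- Coverage is exact set containment; a child term missing a single gene of
  its parent (annotation-version skew between the enrichment tool and the
  GMT) will not be absorbed. Using the same GMT for analysis and filtering
  avoids this.
- The subset scan is quadratic; beyond ~10⁴ merged terms an inverted index
  over genes would be the next step.
- Rank is the only significance information used; two terms with nearly
  identical p-values are still strictly ordered, and the filter's outcome
  can depend on that ordering.
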