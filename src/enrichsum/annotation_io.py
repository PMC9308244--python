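"""Readers and writers for annotation collections and ranked enrichment results.

Two plain-text formats are supported:

* **GMT** (Gene Matrix Transposed): one annotation term per line, with
  tab-separated fields ``term_id <TAB> description <TAB> gene1 <TAB> gene2 ...``.
  This is the standard exchange format for gene-set collections (GO, Reactome,
  MSigDB exports and the like).
* **Ranked term lists**: one term ID per line, ordered from most to least
  significant.  No significance values are carried — the 1-based line position
  *is* the rank.  Blank lines and lines starting with ``#`` are ignored, and
  only the first tab-separated column of each line is read, so files with
  extra annotation columns pass through unchanged.

Identifiers are compared as exact strings after surrounding-whitespace
trimming; no case folding is applied, because GMT dialects differ and silent
case-merging can conflate distinct genes.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path


class GmtParseError(ValueError):
    """A GMT file violated the format (too few fields, duplicate term ID...)."""


class RankedListError(ValueError):
    """A ranked term list file was empty or contained duplicate IDs."""


@dataclass(frozen=True)
class Term:
    """A named gene set: identifier, free-text description, annotated genes."""

    id: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("term ID must be non-empty")
        if any(not g for g in self.genes):
            raise ValueError(f"term {self.id!r} contains an empty gene identifier")
        object.__setattr__(self, "genes", frozenset(self.genes))

    @property
    def size(self) -> int:
        """Number of genes the term annotates."""
        return len(self.genes)


@dataclass
class AnnotationCollection:
    """A GMT-backed mapping from term ID to :class:`Term`.

    The collection is the coverage oracle for redundancy filtering: term A
    *covers* term B when ``genes(A) >= genes(B)`` (superset or equal).
    Insertion order of terms is preserved and used wherever a deterministic
    iteration order is needed.
    """

    terms: dict[str, Term] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, term in self.terms.items():
            if key != term.id:
                raise ValueError(f"key {key!r} does not match term ID {term.id!r}")

    @property
    def universe(self) -> frozenset[str]:
        """Union of all member gene sets."""
        out: set[str] = set()
        for term in self.terms.values():
            out |= term.genes
        return frozenset(out)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> Term:
        return self.terms[term_id]

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[Term]:
        return iter(self.terms.values())

    def add(self, term: Term) -> None:
        if term.id in self.terms:
            raise ValueError(f"duplicate term ID {term.id!r}")
        self.terms[term.id] = term

    def size_of(self, term_id: str) -> int:
        return self.terms[term_id].size

    def covers(self, candidate_id: str, other_id: str) -> bool:
        """True iff ``other`` annotates at least the same genes as ``candidate``."""
        return self.terms[other_id].genes >= self.terms[candidate_id].genes


@dataclass(frozen=True)
class RankedTermList:
    """One enrichment result: an alias plus term IDs in significance order.

    Rank of a term is its 1-based position; lower is more significant.
    """

    source_alias: str
    term_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "term_ids", tuple(self.term_ids))
        seen: set[str] = set()
        for tid in self.term_ids:
            if tid in seen:
                raise RankedListError(
                    f"duplicate term ID {tid!r} in list {self.source_alias!r}"
                )
            seen.add(tid)

    def __len__(self) -> int:
        return len(self.term_ids)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._ranks

    @property
    def _ranks(self) -> Mapping[str, int]:
        # lazily built rank lookup; cached on first use
        cached = self.__dict__.get("_rank_cache")
        if cached is None:
            cached = {tid: i + 1 for i, tid in enumerate(self.term_ids)}
            self.__dict__["_rank_cache"] = cached
        return cached

    def rank_of(self, term_id: str) -> int | None:
        """1-based rank of ``term_id`` in this list, or None when absent."""
        return self._ranks.get(term_id)


def parse_gmt(path: str | Path) -> AnnotationCollection:
    """Parse a GMT file into an :class:`AnnotationCollection`.

    Each non-empty line must carry at least three tab-separated fields
    (ID, description, >=1 gene).  Gene fields are stripped of surrounding
    whitespace; empty trailing fields are ignored; duplicate genes within a
    line are collapsed into the set.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    GmtParseError
        On a malformed line (names the line number) or a duplicate term ID
        (names the ID).
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"GMT file not found: {path}")
    collection = AnnotationCollection()
    with path.open(encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            # drop empty trailing fields (common in exported GMTs)
            while fields and not fields[-1].strip():
                fields.pop()
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields (ID, description, genes), got {len(fields)}"
                )
            term_id = fields[0].strip()
            description = fields[1].strip()
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if term_id in collection:
                raise GmtParseError(
                    f"{path}: line {lineno}: duplicate term ID {term_id!r}"
                )
            collection.add(Term(id=term_id, description=description, genes=genes))
    return collection


def write_gmt(collection: AnnotationCollection, path: str | Path) -> Path:
    """Write a collection to GMT; genes in lexicographic order for determinism."""
    if len(collection) == 0:
        raise ValueError("refusing to write an empty annotation collection")
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for term in collection:
            genes = "\t".join(sorted(term.genes))
            handle.write(f"{term.id}\t{term.description}\t{genes}\n")
    return path


def read_ranked_terms(path: str | Path, alias: str) -> RankedTermList:
    """Read a significance-ordered term-ID list from ``path``.

    One term ID per line (first tab-separated column), most significant first.
    Blank lines and ``#`` comments are skipped; order is preserved.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    RankedListError
        If the file is empty after skipping, or a term ID repeats.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"ranked term list not found: {path}")
    ids: list[str] = []
    with path.open(encoding="utf-8") as handle:
        for raw in handle:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            ids.append(line.split("\t")[0].strip())
    if not ids:
        raise RankedListError(f"{path}: no term IDs after skipping comments/blanks")
    return RankedTermList(source_alias=alias, term_ids=tuple(ids))


def write_ranked_terms(ranked: RankedTermList, path: str | Path) -> Path:
    """Write a ranked term list, one ID per line, most significant first."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for tid in ranked.term_ids:
            handle.write(tid + "\n")
    return path


def read_ranked_term_files(
    paths: Iterable[str | Path], aliases: Iterable[str] | None = None
) -> list[RankedTermList]:
    """Read several ranked lists; aliases default to file basenames (no suffix)."""
    paths = [Path(p) for p in paths]
    if aliases is None:
        names = [p.stem for p in paths]
    else:
        names = list(aliases)
        if len(names) != len(paths):
            raise ValueError(
                f"{len(names)} aliases given for {len(paths)} result files"
            )
    if len(set(names)) != len(names):
        raise ValueError(f"aliases are not unique: {names}")
    return [read_ranked_terms(p, a) for p, a in zip(paths, names)]
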