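"""Reporting: TSV/HTML tables, quartile heatmap, represented-count barplot.

A filtering outcome is summarised per *group* (a representative plus the
terms it represents).  For the cross-result comparison views, each group is
located in every input result by the best rank any of its members attains
there; that rank is then binned into the quartile of the source list
(``ceil(4 * rank / L)``, clipped to 1..4).  A group whose members never occur
in a source is marked absent for that source.

File outputs follow the ``<base>-Summary.tsv`` / ``<base>-Detailed.tsv``
naming convention; the HTML report is self-contained (no scripts, no network
resources) and uses ``<details>`` elements to expand represented terms.
"""

from __future__ import annotations

import html as _html
import math
from collections.abc import Sequence
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering; must precede pyplot import

import matplotlib.colors as mcolors
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import AnnotationCollection, RankedTermList
from .ranking_filter import FilterOutcome

#: rank-quartile colors (Q1 = most significant) plus the absent color
QUARTILE_COLORS = ["#b2182b", "#ef8a62", "#fddbc7", "#f7f7f7"]
ABSENT_COLOR = "#bdbdbd"


class DegenerateCorrelationError(ValueError):
    """Correlation is undefined: too few representatives or zero variance."""


def _check_aliases(
    outcome: FilterOutcome, lists: Sequence[RankedTermList]
) -> list[str]:
    aliases = [lst.source_alias for lst in lists]
    if outcome.source_aliases and tuple(aliases) != outcome.source_aliases:
        raise ValueError(
            f"source aliases of the lists {aliases} do not match the outcome's "
            f"provenance {list(outcome.source_aliases)}"
        )
    return aliases


def group_source_ranks(
    outcome: FilterOutcome, lists: Sequence[RankedTermList]
) -> pd.DataFrame:
    """Best rank of each representative group in each input result.

    Returns a representatives x sources DataFrame (rows in outcome order).
    A cell holds the minimum 1-based rank over the group's members present in
    that source, or NA when no member occurs there.
    """
    aliases = _check_aliases(outcome, lists)
    rows = {}
    for group in outcome.groups:
        per_source = {}
        for lst in lists:
            ranks = [r for m in group.member_ids if (r := lst.rank_of(m)) is not None]
            per_source[lst.source_alias] = min(ranks) if ranks else pd.NA
        rows[group.representative_id] = per_source
    frame = pd.DataFrame.from_dict(rows, orient="index", dtype="Int64")
    frame.index.name = "representative"
    return frame.reindex(columns=aliases)


def rank_quartile(rank: int, list_length: int) -> int:
    """Quartile bin of a rank within a list of given length: ceil(4r/L) in 1..4."""
    if not 1 <= rank <= list_length:
        raise ValueError(f"rank {rank} outside 1..{list_length}")
    return min(4, max(1, math.ceil(4 * rank / list_length)))


def assign_quartiles(
    ranks: pd.DataFrame, lists: Sequence[RankedTermList]
) -> pd.DataFrame:
    """Convert a group-rank matrix into quartile bins per source list.

    Each non-absent rank is binned by :func:`rank_quartile` using the length
    of its own source list; absent entries stay NA.
    """
    lengths = {lst.source_alias: len(lst) for lst in lists}
    missing = [c for c in ranks.columns if c not in lengths]
    if missing:
        raise ValueError(f"no ranked list supplied for source(s) {missing}")
    out = ranks.copy()
    for col in out.columns:
        length = lengths[col]
        out[col] = out[col].map(
            lambda r: pd.NA if pd.isna(r) else rank_quartile(int(r), length)
        )
    return out.astype("Int64")


def summary_frame(
    outcome: FilterOutcome,
    ranks: pd.DataFrame,
    annotations: AnnotationCollection,
) -> pd.DataFrame:
    """One row per representative: ID, description, size, represented count,
    then the group's best rank per source."""
    records = []
    for group in outcome.groups:
        rep = group.representative_id
        term = annotations[rep]
        rec: dict[str, object] = {
            "Representative term id": rep,
            "Description": term.description,
            "Term size": term.size,
            "Represented term number": len(group.represented_ids),
        }
        for alias in ranks.columns:
            rec[f"{alias} group rank"] = ranks.loc[rep, alias]
        records.append(rec)
    columns = [
        "Representative term id",
        "Description",
        "Term size",
        "Represented term number",
    ] + [f"{alias} group rank" for alias in ranks.columns]
    return pd.DataFrame.from_records(records, columns=columns)


def detailed_frame(
    outcome: FilterOutcome,
    ranks: pd.DataFrame,
    annotations: AnnotationCollection,
) -> pd.DataFrame:
    """Summary rows plus one row per represented term under its representative."""
    records = []
    for group in outcome.groups:
        rep_term = annotations[group.representative_id]
        base = {
            "Representative term id": group.representative_id,
            "Term id": rep_term.id,
            "Description": rep_term.description,
            "Term size": rep_term.size,
            "Role": "representative",
            "Represented term number": len(group.represented_ids),
        }
        for alias in ranks.columns:
            base[f"{alias} group rank"] = ranks.loc[group.representative_id, alias]
        records.append(base)
        for tid in group.represented_ids:
            term = annotations[tid]
            records.append(
                {
                    "Representative term id": group.representative_id,
                    "Term id": term.id,
                    "Description": term.description,
                    "Term size": term.size,
                    "Role": "represented",
                    "Represented term number": pd.NA,
                    **{f"{alias} group rank": pd.NA for alias in ranks.columns},
                }
            )
    columns = [
        "Representative term id",
        "Term id",
        "Description",
        "Term size",
        "Role",
        "Represented term number",
    ] + [f"{alias} group rank" for alias in ranks.columns]
    return pd.DataFrame.from_records(records, columns=columns)


def _render_html(
    outcome: FilterOutcome, annotations: AnnotationCollection
) -> str:
    esc = _html.escape
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>",
        "<title>Representative enrichment terms</title>",
        "<style>body{font-family:sans-serif;margin:2em}"
        "details{margin:0.25em 0}summary{cursor:pointer}"
        "ul{margin:0.2em 0 0.4em 1.5em}</style>",
        "</head><body>",
        f"<h1>Representative terms ({len(outcome.groups)})</h1>",
    ]
    for group in outcome.groups:
        term = annotations[group.representative_id]
        label = (
            f"{esc(term.id)} — {esc(term.description)} "
            f"({term.size} genes, represents {len(group.represented_ids)} terms)"
        )
        if group.represented_ids:
            items = "".join(
                f"<li>{esc(t)} — {esc(annotations[t].description)}</li>"
                for t in group.represented_ids
            )
            parts.append(f"<details><summary>{label}</summary><ul>{items}</ul></details>")
        else:
            parts.append(f"<details><summary>{label}</summary><ul></ul></details>")
    parts.append("</body></html>")
    return "\n".join(parts)


def write_reports(
    outcome: FilterOutcome,
    ranks: pd.DataFrame,
    annotations: AnnotationCollection,
    out_dir: str | Path,
    base_name: str,
) -> dict[str, Path]:
    """Write ``<base>-Summary.tsv``, ``<base>-Detailed.tsv`` and ``<base>.html``.

    The Summary table has one row per representative; the Detailed table
    additionally lists every represented term under its representative, so
    its row count is always the Summary count plus the represented count.
    Returns the written paths keyed by artifact name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = summary_frame(outcome, ranks, annotations)
    detailed = detailed_frame(outcome, ranks, annotations)
    paths = {
        "summary": out_dir / f"{base_name}-Summary.tsv",
        "detailed": out_dir / f"{base_name}-Detailed.tsv",
        "html": out_dir / f"{base_name}.html",
    }
    summary.to_csv(paths["summary"], sep="\t", index=False)
    detailed.to_csv(paths["detailed"], sep="\t", index=False)
    paths["html"].write_text(_render_html(outcome, annotations), encoding="utf-8")
    return paths


def _finalize_figure(fig: plt.Figure, path: Path) -> list[Path]:
    """Save a figure as both SVG and PNG next to each other."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix in {".png", ".svg"} else path
    written = []
    for suffix in (".png", ".svg"):
        target = base.with_suffix(suffix)
        fig.savefig(target, bbox_inches="tight")
        written.append(target)
    plt.close(fig)
    return written


def render_heatmap(
    quartiles: pd.DataFrame, top_n: int, path: str | Path
) -> list[Path]:
    """Plot the quartile matrix for the first ``top_n`` representative groups.

    Rows are representatives in outcome order, columns the input results in
    the order given; cells are colored by rank quartile (Q1 most significant)
    with a distinct color for groups absent from a source.  Written as both
    PNG and SVG; returns the written paths.
    """
    if not 1 <= top_n <= 50:
        raise ValueError("top_n must be in 1..50")
    data = quartiles.iloc[:top_n]
    values = data.to_numpy(dtype=float, na_value=0.0)  # 0 encodes "absent"
    cmap = mcolors.ListedColormap([ABSENT_COLOR] + QUARTILE_COLORS)
    norm = mcolors.BoundaryNorm(np.arange(-0.5, 5.5), cmap.N)
    fig, ax = plt.subplots(
        figsize=(2 + 0.9 * len(data.columns), 1.5 + 0.28 * max(1, len(data)))
    )
    mesh = ax.pcolormesh(values, cmap=cmap, norm=norm, edgecolors="white", lw=0.5)
    ax.set_xticks(np.arange(len(data.columns)) + 0.5, data.columns, rotation=45, ha="right")
    ax.set_yticks(np.arange(len(data)) + 0.5, data.index, fontsize=7)
    ax.invert_yaxis()  # most significant group on top
    cbar = fig.colorbar(mesh, ax=ax, ticks=range(5), shrink=0.6)
    cbar.ax.set_yticklabels(["absent", "Q1", "Q2", "Q3", "Q4"])
    ax.set_title("Rank quartile of each representative group per result")
    return _finalize_figure(fig, Path(path))


def render_barplot(
    outcome: FilterOutcome, top_n: int, path: str | Path
) -> list[Path]:
    """Bar chart of represented-term counts for the first ``top_n`` groups."""
    if not 1 <= top_n <= 50:
        raise ValueError("top_n must be in 1..50")
    groups = outcome.groups[:top_n]
    labels = [g.representative_id for g in groups]
    counts = [len(g.represented_ids) for g in groups]
    fig, ax = plt.subplots(figsize=(6, 1.5 + 0.25 * max(1, len(groups))))
    ax.barh(np.arange(len(groups)), counts, color="#2166ac")
    ax.set_yticks(np.arange(len(groups)), labels, fontsize=7)
    ax.invert_yaxis()
    ax.set_xlabel("Number of represented terms")
    ax.set_title("Terms represented by each representative")
    return _finalize_figure(fig, Path(path))


def size_representation_correlation(
    outcome: FilterOutcome, annotations: AnnotationCollection
) -> tuple[float, float]:
    """Spearman correlation between representative size and represented count.

    Larger (more general) terms are expected to represent more terms; the
    correlation quantifies how strongly this holds in a filtering outcome.
    Returns ``(rho, two-sided p-value)``.

    Raises
    ------
    DegenerateCorrelationError
        With fewer than 3 representatives, or when either variable has zero
        variance (all sizes equal, or all represented counts equal).
    """
    if len(outcome.groups) < 3:
        raise DegenerateCorrelationError(
            f"need >= 3 representatives, got {len(outcome.groups)}"
        )
    sizes = [annotations[g.representative_id].size for g in outcome.groups]
    counts = [len(g.represented_ids) for g in outcome.groups]
    if len(set(sizes)) == 1 or len(set(counts)) == 1:
        raise DegenerateCorrelationError(
            "correlation undefined: zero variance in sizes or represented counts"
        )
    result = stats.spearmanr(sizes, counts)
    return float(result.statistic), float(result.pvalue)
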