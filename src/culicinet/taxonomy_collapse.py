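"""Collapse ASVs sharing taxonomy into genus-level (or shallower) groups.

ASVs assigned at the target rank (default genus) are summed per full
lineage prefix, so homonymous genera under different families stay
separate.  ASVs unassigned at the target rank are pooled at their deepest
assigned rank and labeled "Unclassified <name>"; fully unassigned ASVs
pool into a single "Unassigned" column (or are dropped on request).
Per-sample read totals are conserved, and collapsing is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import RANKS, CountTable, TaxonomyMap

__all__ = ["CollapsedLabel", "collapse"]


@dataclass(frozen=True)
class CollapsedLabel:
    """Display label plus the lineage prefix used as the grouping key."""

    label: str
    rank: str | None          # rank at which collapsing occurred (None = unassigned)
    key: tuple                # lineage prefix through the deepest assigned rank


def _group_key(lineage: tuple, max_idx: int) -> CollapsedLabel:
    prefix = lineage[: max_idx + 1]
    depth = -1
    for i, name in enumerate(prefix):
        if name is None:
            break
        depth = i
    if depth < 0:
        return CollapsedLabel(label="Unassigned", rank=None, key=())
    key = tuple(prefix[: depth + 1])
    if depth == max_idx:
        return CollapsedLabel(label=key[-1], rank=RANKS[depth], key=key)
    return CollapsedLabel(
        label=f"Unclassified {key[-1]}", rank=RANKS[depth], key=key
    )


def collapse(
    table: CountTable,
    taxonomy: TaxonomyMap,
    max_rank: str = "genus",
    drop_unassigned: bool = False,
) -> CountTable:
    """Sum ASV columns sharing a lineage prefix through ``max_rank``.

    Parameters
    ----------
    table :
        ASV-level count table (raw or relative).
    taxonomy :
        Lineages for every ASV in ``table``; a missing ASV is a hard error.
    max_rank :
        Deepest rank to collapse to, one of ``RANKS`` (default "genus").
    drop_unassigned :
        Drop ASVs with no assignment at any rank instead of pooling them
        into an "Unassigned" column.

    Returns
    -------
    CountTable
        Same samples; columns are collapsed-group display labels,
        disambiguated with the parent lineage where two distinct groups
        would otherwise share a label.
    """
    if max_rank not in RANKS:
        raise ValueError(f"unknown rank {max_rank!r}; expected one of {RANKS}")
    max_idx = RANKS.index(max_rank)

    missing = [t for t in table.taxon_ids if t not in taxonomy]
    if missing:
        raise KeyError(f"ASVs missing from taxonomy: {missing}")

    groups: dict[tuple, CollapsedLabel] = {}   # key -> label, insertion ordered
    assignment: dict[str, tuple | None] = {}
    for asv in table.taxon_ids:
        cl = _group_key(taxonomy[asv], max_idx)
        if cl.rank is None and drop_unassigned:
            assignment[asv] = None
            continue
        full_key = (cl.rank, cl.key)
        groups.setdefault(full_key, cl)
        assignment[asv] = full_key

    labels = _unique_labels(groups)
    columns = {}
    for full_key, label in labels.items():
        members = [a for a, k in assignment.items() if k == full_key]
        columns[label] = table.data[members].sum(axis=1)
    out = pd.DataFrame(columns, index=table.data.index)
    if not out.shape[1]:
        out = pd.DataFrame(index=table.data.index)
    return CountTable(out, is_relative=table.is_relative)


def _unique_labels(groups: dict) -> dict:
    """Assign display labels, disambiguating collisions with the parent
    lineage name in parentheses, then a numeric suffix as a last resort."""
    labels: dict = {}
    used: dict[str, int] = {}
    for full_key, cl in groups.items():
        used[cl.label] = used.get(cl.label, 0) + 1
    counters: dict[str, int] = {}
    for full_key, cl in groups.items():
        label = cl.label
        if used[label] > 1:
            parent = cl.key[-2] if len(cl.key) >= 2 else None
            label = f"{cl.label} ({parent})" if parent else cl.label
            counters[label] = counters.get(label, 0) + 1
            if counters[label] > 1 or label in labels.values():
                label = f"{label} [{counters[label]}]"
        labels[full_key] = label
    return labels
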