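"""Rarity filtering and the two normalizations used downstream.

Three operations, applied in this order in the network pipeline:
``filter_rare`` (drop taxa whose pooled reads fall below a fraction of
the grand total, default 0.1%) -> taxonomy collapse -> ``relative_abundance``
(percent per sample).  ``rarefy`` (fixed-depth subsampling without
replacement) normalizes library sizes for the diversity metrics instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CountTable

__all__ = ["FilterReport", "filter_rare", "relative_abundance", "rarefy"]

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Outcome of a rarity filter pass."""

    grand_total: float
    threshold: float            # reads; = fraction * grand_total
    fraction: float
    removed: list = field(default_factory=list)
    retained: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, "removed") for t in self.removed] + [
            (t, "retained") for t in self.retained
        ]
        df = pd.DataFrame(rows, columns=["taxon", "status"])
        df.attrs["grand_total"] = self.grand_total
        df.attrs["threshold"] = self.threshold
        return df


def filter_rare(table: CountTable, fraction: float = 0.001):
    """Remove taxa whose total reads over all samples fall below
    ``fraction`` of the grand total.

    "Lower than" is strict: a taxon exactly at threshold is retained.

    Returns
    -------
    (CountTable, FilterReport)
    """
    if table.is_relative:
        raise ValueError("filter_rare expects raw counts, not relative abundances")
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    totals = table.taxon_totals()
    grand = float(totals.sum())
    threshold = fraction * grand
    keep = totals >= threshold
    removed = list(totals.index[~keep])
    retained = list(totals.index[keep])
    out = CountTable(table.data.loc[:, keep].copy(), is_relative=False)
    report = FilterReport(
        grand_total=grand,
        threshold=threshold,
        fraction=fraction,
        removed=removed,
        retained=retained,
    )
    return out, report


def relative_abundance(table: CountTable) -> CountTable:
    """Convert counts to percent relative abundance per sample
    (each cell becomes 100 * cell / sample total)."""
    totals = table.sample_totals()
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    out = table.data.div(totals, axis=0) * 100.0
    return CountTable(out, is_relative=True)


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample each sample to exactly ``depth`` reads without replacement
    (multivariate hypergeometric draw).

    Samples with fewer than ``depth`` reads are dropped and logged.
    Deterministic given ``seed``.
    """
    if table.is_relative:
        raise ValueError("rarefy expects raw counts, not relative abundances")
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    counts = table.data.to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        if not (counts == np.floor(counts)).all():
            raise ValueError("rarefy requires integer counts")
        counts = counts.astype(np.int64)
    totals = counts.sum(axis=1)
    kept_rows = []
    dropped = []
    out = []
    for i, sample in enumerate(table.sample_ids):
        if totals[i] < depth:
            dropped.append(sample)
            continue
        kept_rows.append(sample)
        if totals[i] == depth:
            out.append(counts[i])
        else:
            out.append(rng.multivariate_hypergeometric(counts[i], depth))
    if dropped:
        logger.warning(
            "rarefy: dropped %d sample(s) shallower than depth %d: %s",
            len(dropped), depth, dropped,
        )
    df = pd.DataFrame(
        np.asarray(out, dtype=np.int64).reshape(len(kept_rows), len(table.taxon_ids)),
        index=kept_rows,
        columns=table.taxon_ids,
    )
    return CountTable(df, is_relative=False)
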