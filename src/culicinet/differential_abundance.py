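"""ANCOM-style compositional differential abundance.

For each taxon i, every additive log ratio log((c_i + pc)/(c_j + pc)) to
the other m-1 taxa is tested across groups with Kruskal-Wallis; the
Benjamini-Hochberg procedure is applied within taxon i's m-1 tests and
W_i counts the rejections.  A taxon is flagged when W_i reaches a fixed
fraction (default 0.7) of m-1.  Because every sample's counts enter only
through within-sample ratios, W is invariant to per-sample rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CountTable

__all__ = ["AncomResult", "ancom"]


@dataclass
class AncomResult:
    """Per-taxon W statistics with the detection cutoff used."""

    table: pd.DataFrame       # index taxon; columns W, detected
    cutoff: float             # rejections needed for detection
    cutoff_fraction: float
    alpha: float

    def detected(self) -> list:
        return list(self.table.index[self.table["detected"]])


def _kw_pvalue(values: np.ndarray, group_slices) -> float:
    if np.all(values == values[0]):
        return 1.0
    try:
        return float(stats.kruskal(*[values[s] for s in group_slices]).pvalue)
    except ValueError:  # all numbers identical inside scipy's tolerance
        return 1.0


def ancom(
    table: CountTable,
    groups,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    cutoff_fraction: float = 0.7,
) -> AncomResult:
    """Run the ANCOM W-statistic procedure on a raw count table.

    Parameters
    ----------
    table :
        Raw counts, samples x taxa (collapse to genus first to mirror the
        usual 16S workflow).
    groups :
        One group label per sample, aligned with ``table.sample_ids``.
    alpha :
        Significance level applied to the BH-adjusted log-ratio tests.
    pseudocount :
        Added to every count before taking logs so zeros stay finite.
    cutoff_fraction :
        Fraction of the m-1 tests that must reject for detection.
    """
    if table.is_relative:
        raise ValueError("ancom expects raw counts")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if not (0.0 < cutoff_fraction <= 1.0):
        raise ValueError("cutoff_fraction must be in (0, 1]")
    m = len(table.taxon_ids)
    if m < 2:
        raise ValueError("need at least 2 taxa")
    groups = np.asarray(list(groups))
    if len(groups) != len(table.sample_ids):
        raise ValueError("one group label per sample required")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    group_slices = [np.flatnonzero(groups == g) for g in labels]

    logc = np.log(table.data.to_numpy(float) + pseudocount)
    # p-values of the pairwise log-ratio tests; symmetric since KW on a
    # negated vector has the same rank structure
    pvals = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            p = _kw_pvalue(logc[:, i] - logc[:, j], group_slices)
            pvals[i, j] = pvals[j, i] = p

    w = np.zeros(m, dtype=int)
    for i in range(m):
        row = np.delete(pvals[i], i)
        reject, *_ = multipletests(row, alpha=alpha, method="fdr_bh")
        w[i] = int(reject.sum())

    cutoff = cutoff_fraction * (m - 1)
    out = pd.DataFrame(
        {"W": w, "detected": w >= cutoff}, index=table.taxon_ids
    )
    return AncomResult(
        table=out, cutoff=float(cutoff), cutoff_fraction=cutoff_fraction,
        alpha=alpha,
    )
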