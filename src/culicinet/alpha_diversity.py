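"""Alpha diversity: Shannon-Weaver index, rarefaction curves, and the
Kruskal-Wallis -> Dunn (Bonferroni) between-species comparison.

Shannon defaults to log base 2 (the convention of common amplicon
pipelines); observed richness is the count of taxa with positive counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountTable

__all__ = [
    "shannon",
    "alpha_table",
    "rarefaction_curve",
    "kruskal_wallis",
    "dunn_posthoc",
    "GroupTestResult",
]


def shannon(counts, base: float = 2.0) -> float:
    """Shannon-Weaver index -sum p_i log_base p_i over positive counts."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all-zero abundance vector")
    p = c / c.sum()
    return float(-(p * (np.log(p) / np.log(base))).sum())


def alpha_table(table: CountTable, base: float = 2.0) -> pd.DataFrame:
    """Per-sample Shannon index and observed richness."""
    rows = {}
    for sample in table.sample_ids:
        v = table.data.loc[sample].to_numpy(float)
        rows[sample] = {
            "shannon": shannon(v, base=base),
            "richness": int((v > 0).sum()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def rarefaction_curve(
    table: CountTable,
    depths,
    iterations: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean observed richness per sample at each subsampling depth.

    Each cell averages ``iterations`` independent without-replacement
    subsamples; a sample shallower than a depth gets NaN there.
    """
    depths = list(depths)
    if depths != sorted(depths):
        raise ValueError("depths must be sorted ascending")
    rng = np.random.default_rng(seed)
    counts = table.data.to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        counts = counts.astype(np.int64)
    totals = counts.sum(axis=1)
    out = np.full((len(table.sample_ids), len(depths)), np.nan)
    for i in range(counts.shape[0]):
        for j, d in enumerate(depths):
            if totals[i] < d:
                continue
            if totals[i] == d:
                out[i, j] = float((counts[i] > 0).sum())
                continue
            rich = [
                (rng.multivariate_hypergeometric(counts[i], d) > 0).sum()
                for _ in range(iterations)
            ]
            out[i, j] = float(np.mean(rich))
    return pd.DataFrame(out, index=table.sample_ids, columns=depths)


def kruskal_wallis(values, groups):
    """Kruskal-Wallis H (tie-corrected) and chi-square p on k-1 df.

    The degenerate all-identical case (tie correction denominator zero)
    is defined as H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


@dataclass
class GroupTestResult:
    """Omnibus Kruskal-Wallis plus the Dunn pairwise table."""

    h: float
    p: float
    pairwise: pd.DataFrame   # group_a, group_b, z, p_raw, p_adjusted


def dunn_posthoc(values, groups, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's post hoc z tests on mean ranks, with tie-corrected SE.

    z = (mean_rank_a - mean_rank_b) / sqrt((N(N+1)/12 - T)(1/n_a + 1/n_b)),
    where T = sum(t^3 - t) / (12 (N - 1)) over tie groups; two-sided normal
    p, Bonferroni-adjusted over all k(k-1)/2 pairs when requested.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    n_total = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    n_pairs = len(labels) * (len(labels) - 1) // 2
    for a, b in combinations(labels, 2):
        ra = ranks[groups == a]
        rb = ranks[groups == b]
        if len(ra) == 0 or len(rb) == 0:
            raise ValueError("empty group")
        se = np.sqrt(var_base * (1.0 / len(ra) + 1.0 / len(rb)))
        z = 0.0 if se == 0 else (ra.mean() - rb.mean()) / se
        p_raw = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * n_pairs) if adjust == "bonferroni" else p_raw
        rows.append((a, b, float(z), float(p_raw), float(p_adj)))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "z", "p_raw", "p_adjusted"]
    )


def compare_groups(values, groups, adjust: str = "bonferroni") -> GroupTestResult:
    """Omnibus Kruskal-Wallis followed by the Dunn pairwise table."""
    h, p = kruskal_wallis(values, groups)
    pairwise = dunn_posthoc(values, groups, adjust=adjust)
    return GroupTestResult(h=h, p=p, pairwise=pairwise)
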