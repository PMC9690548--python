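"""Signed bacterial co-occurrence networks from Spearman correlations.

The pipeline, run independently for each mosquito species: drop ASVs
below 0.1% of total reads, collapse to genus, convert to percent relative
abundance, compute all pairwise Spearman correlations between taxa, and
keep pairs with |rho| > 0.75 and p < 0.05 (strict).  Edges are signed:
positive = co-occurrence, negative = co-exclusion.

Spearman rho uses tie-corrected midranks (Pearson correlation of ranks).
p-values are exact — full enumeration of rank permutations — for n <= 8
samples, where the t approximation is unreliable and the smallest study
group (6 mosquitoes) lives; larger n uses the usual t approximation with
n-2 degrees of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .abundance_filtering import filter_rare, relative_abundance
from .io_formats import CountTable, InteractionNetwork, SampleMetadata, TaxonomyMap
from .taxonomy_collapse import collapse

__all__ = [
    "CorrelationResult",
    "NetworkSummary",
    "spearman_matrix",
    "threshold_edges",
    "network_summary",
    "per_species_networks",
]

logger = logging.getLogger(__name__)

#: n at and below which p-values come from exhaustive permutation of ranks.
EXACT_P_MAX_N = 8

_perm_cache: dict = {}
_null_cache: dict = {}


def _perm_matrix(n: int) -> np.ndarray:
    if n not in _perm_cache:
        _perm_cache[n] = np.array(list(permutations(range(n))), dtype=np.intp)
    return _perm_cache[n]


def _exact_null(rx: np.ndarray, ry: np.ndarray) -> np.ndarray:
    """Sorted |rho| over all n! permutations of one rank vector.

    The null set depends only on the two rank multisets, so results are
    cached on (sorted rx, sorted ry)."""
    key = (tuple(np.round(np.sort(rx), 9)), tuple(np.round(np.sort(ry), 9)))
    if key not in _null_cache:
        a = np.sort(rx) - rx.mean()
        b = np.sort(ry) - ry.mean()
        denom = math.sqrt((a @ a) * (b @ b))
        perms = _perm_matrix(len(rx))
        null = np.abs(a[perms] @ b) / denom
        _null_cache[key] = np.sort(null)
    return _null_cache[key]


def _exact_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    null = _exact_null(rx, ry)
    count = null.size - np.searchsorted(null, abs(rho) - 1e-12, side="left")
    return float(count) / null.size


def _t_approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0 - 1e-15:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass
class CorrelationResult:
    """Upper-triangular Spearman correlations between taxa.

    ``pairs`` holds one row per unordered taxon pair: taxon_a, taxon_b,
    rho, p, n.  Pairs involving a constant (zero-variance) taxon carry
    NaN rho/p and are ignored by thresholding; those taxa are also listed
    in ``constant_taxa``.
    """

    pairs: pd.DataFrame
    taxa: list
    n_samples: int
    constant_taxa: list = field(default_factory=list)
    skipped_taxa: list = field(default_factory=list)


def spearman_matrix(table: CountTable, min_nonzero: int = 0) -> CorrelationResult:
    """All pairwise Spearman correlations between the taxa of ``table``.

    Parameters
    ----------
    table :
        Percent relative abundance (or any) table for a single species;
        needs >= 4 samples.
    min_nonzero :
        Skip taxa observed in fewer than this many samples (0 disables).
    """
    n = len(table.sample_ids)
    if n < 4:
        raise ValueError(f"need at least 4 samples for rank correlation, got {n}")
    data = table.data.to_numpy(float)
    taxa = list(table.taxon_ids)
    nonzero = (data > 0).sum(axis=0)
    skipped = [t for t, nz in zip(taxa, nonzero) if nz < min_nonzero]
    constant = [
        t for j, t in enumerate(taxa)
        if t not in skipped and np.all(data[:, j] == data[0, j])
    ]
    if skipped:
        logger.info("spearman_matrix: skipping %d taxa below min_nonzero", len(skipped))
    dead = set(skipped) | set(constant)
    live = [t for t in taxa if t not in dead]
    live_idx = [taxa.index(t) for t in live]

    ranks = stats.rankdata(data[:, live_idx], axis=0) if live else np.empty((n, 0))
    centered = ranks - ranks.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    with np.errstate(invalid="ignore"):
        rho_mat = (centered.T @ centered) / np.outer(norms, norms)

    exact = n <= EXACT_P_MAX_N
    rows = []
    for a_pos in range(len(live)):
        for b_pos in range(a_pos + 1, len(live)):
            rho = float(np.clip(rho_mat[a_pos, b_pos], -1.0, 1.0))
            if exact:
                p = _exact_p(ranks[:, a_pos], ranks[:, b_pos], rho)
            else:
                p = _t_approx_p(rho, n)
            rows.append((live[a_pos], live[b_pos], rho, p, n))
    keep = [t for t in taxa if t not in set(skipped)]
    if constant:
        const_set = set(constant)
        for i, a in enumerate(keep):
            for b in keep[i + 1:]:
                if a in const_set or b in const_set:
                    rows.append((a, b, np.nan, np.nan, n))
    pairs = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "p", "n"])
    return CorrelationResult(
        pairs=pairs, taxa=keep, n_samples=n,
        constant_taxa=constant, skipped_taxa=skipped,
    )


def threshold_edges(
    corr: CorrelationResult,
    r_min: float = 0.75,
    p_max: float = 0.05,
    use_abs: bool = True,
    p_adjust: str = "none",
) -> InteractionNetwork:
    """Keep pairs with |rho| > r_min and p < p_max (both strict).

    ``use_abs=False`` applies the threshold to rho itself, i.e. the
    literal positive-only reading.  ``p_adjust="bh"`` applies
    Benjamini-Hochberg across all defined pairs before thresholding.
    Isolated taxa are dropped from the graph but remain reported through
    ``candidate_nodes``.
    """
    if p_adjust not in ("none", "bh"):
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    pairs = corr.pairs
    defined = pairs.dropna(subset=["rho", "p"]).copy()
    if p_adjust == "bh" and len(defined):
        _, p_adj, *_ = multipletests(defined["p"].to_numpy(), method="fdr_bh")
        defined["p"] = p_adj
    strength = defined["rho"].abs() if use_abs else defined["rho"]
    keep = defined[(strength > r_min) & (defined["p"] < p_max)]
    edges = [
        (r.taxon_a, r.taxon_b, r.rho, r.p) for r in keep.itertuples()
    ]
    return InteractionNetwork.from_edges(edges, candidate_nodes=corr.taxa)


@dataclass
class NetworkSummary:
    """Edge-sign bookkeeping for one species' network."""

    node_count: int
    positive_edges: int
    negative_edges: int
    per_node: pd.DataFrame      # degree, positive_degree, negative_degree
    isolated_taxa: list = field(default_factory=list)

    @property
    def edge_count(self) -> int:
        return self.positive_edges + self.negative_edges


def network_summary(net: InteractionNetwork) -> NetworkSummary:
    """Count signed edges and per-node signed degrees."""
    pos = neg = 0
    per_node: dict = {node: [0, 0] for node in net.graph.nodes}
    for _, _, d in net.graph.edges(data=True):
        if d["sign"] == "positive":
            pos += 1
        else:
            neg += 1
    for a, b, d in net.graph.edges(data=True):
        slot = 0 if d["sign"] == "positive" else 1
        per_node[a][slot] += 1
        per_node[b][slot] += 1
    df = pd.DataFrame(
        [
            (node, p + m, p, m)
            for node, (p, m) in sorted(per_node.items())
        ],
        columns=["taxon", "degree", "positive_degree", "negative_degree"],
    ).set_index("taxon")
    return NetworkSummary(
        node_count=net.graph.number_of_nodes(),
        positive_edges=pos,
        negative_edges=neg,
        per_node=df,
        isolated_taxa=net.isolated_taxa(),
    )


def per_species_networks(
    table: CountTable,
    taxonomy: TaxonomyMap,
    metadata: SampleMetadata,
    r_min: float = 0.75,
    p_max: float = 0.05,
    use_abs: bool = True,
    p_adjust: str = "none",
    min_fraction: float = 0.001,
    filter_scope: str = "per-species",
    collapse_rank: str = "genus",
    min_samples: int = 4,
    min_nonzero: int = 0,
) -> dict:
    """Build one signed co-occurrence network per mosquito species.

    For each species with >= ``min_samples`` samples: subset samples ->
    rarity filter -> genus collapse -> percent relative abundance ->
    Spearman matrix -> thresholded signed network.  Species below the
    sample minimum are skipped with a warning.

    Returns
    -------
    dict
        species -> (InteractionNetwork, NetworkSummary).
    """
    if filter_scope not in ("per-species", "global"):
        raise ValueError(f"unknown filter_scope {filter_scope!r}")
    if table.is_relative:
        raise ValueError("per_species_networks expects raw ASV counts")
    working = table
    if filter_scope == "global":
        working, _ = filter_rare(table, fraction=min_fraction)
    by_species = metadata.samples_by_species()
    out: dict = {}
    for species in sorted(by_species):
        samples = [s for s in by_species[species] if s in set(table.sample_ids)]
        if len(samples) < min_samples:
            logger.warning(
                "species %s has %d sample(s) (< %d); skipped",
                species, len(samples), min_samples,
            )
            continue
        sub = working.subset_samples(samples)
        if filter_scope == "per-species":
            sub, _ = filter_rare(sub, fraction=min_fraction)
        collapsed = collapse(sub, taxonomy, max_rank=collapse_rank)
        # taxa absent from this species after filtering carry no signal
        present = collapsed.data.columns[collapsed.data.sum(axis=0) > 0]
        collapsed = CountTable(collapsed.data[list(present)].copy())
        percent = relative_abundance(collapsed)
        corr = spearman_matrix(percent, min_nonzero=min_nonzero)
        net = threshold_edges(
            corr, r_min=r_min, p_max=p_max, use_abs=use_abs, p_adjust=p_adjust
        )
        out[species] = (net, network_summary(net))
    return out
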