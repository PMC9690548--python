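"""Beta diversity: UniFrac distances, PCoA ordination, and PERMANOVA.

UniFrac (unweighted presence/absence of branches; weighted = raw,
unnormalized abundance-weighted variant) is computed on a rooted
phylogeny via scikit-bio.  PERMANOVA is computed directly on the
distance matrix (no ordination) with seeded label permutations, with a
pairwise per-group-pair variant reporting raw and Bonferroni-adjusted p.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity as _skbio_beta

from .io_formats import CountTable

__all__ = [
    "unifrac",
    "pcoa",
    "PcoaResult",
    "permanova",
    "pairwise_permanova",
    "PermanovaResult",
]


def unifrac(tree: TreeNode, table: CountTable, weighted: bool,
            normalized: bool = False) -> DistanceMatrix:
    """UniFrac distance matrix between all samples of ``table``.

    Unweighted: fraction of branch length unique to one of the two
    samples' leaf sets.  Weighted (default raw variant): sum over
    branches of length x |p_A(b) - p_B(b)| with p_X(b) the proportion of
    sample X's reads descending from the branch; ``normalized=True``
    rescales to [0, 1].
    """
    tips = {t.name for t in tree.tips()}
    observed = [
        t for t in table.taxon_ids if table.data[t].to_numpy().sum() > 0
    ]
    missing = [t for t in observed if t not in tips]
    if missing:
        raise KeyError(f"taxa with nonzero counts absent from tree: {missing}")
    metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
    kwargs = {}
    if weighted:
        kwargs["normalized"] = normalized
    return _skbio_beta(
        metric,
        table.data.to_numpy(float),
        ids=table.sample_ids,
        taxa=table.taxon_ids,
        tree=tree,
        **kwargs,
    )


@dataclass
class PcoaResult:
    """Classical-scaling embedding of a distance matrix.

    Axes are ordered by descending eigenvalue; only positive eigenvalues
    contribute coordinate axes, but every eigenvalue (including negative
    ones from non-Euclidean distances) is retained in ``eigenvalues``.
    """

    coordinates: pd.DataFrame        # samples x axes (PC1, PC2, ...)
    eigenvalues: np.ndarray          # all eigenvalues, descending
    proportion_explained: np.ndarray  # per retained axis


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    """Principal coordinates analysis (classical multidimensional scaling):
    double-center -D^2/2, eigendecompose, scale eigenvectors by sqrt(λ)."""
    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigvals[0]), 1.0))
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    total = eigvals[pos].sum()
    prop = eigvals[pos] / total if total > 0 else np.zeros(pos.sum())
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


@dataclass
class PermanovaResult:
    """Pseudo-F and permutation p for one grouping comparison."""

    pseudo_f: float
    p: float
    n_permutations: int
    groups: tuple
    n_samples: int
    p_adjusted: float | None = None


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    denom = ss_within / (n - k)
    if denom == 0:
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / (k - 1)) / denom


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """PERMANOVA computed directly on the distance matrix.

    p = (1 + #{permuted F >= observed F}) / (1 + n_perm) under seeded
    uniform label permutations.  Every group needs >= 2 samples.
    """
    groups = np.asarray(list(groups))
    if len(groups) != len(dm.ids):
        raise ValueError("one group label per sample required")
    labels, codes = np.unique(groups, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [labels[i] for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    f_obs = _pseudo_f(d2, codes, k)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, k) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p=float(p),
        n_permutations=n_perm,
        groups=tuple(labels.tolist()),
        n_samples=len(groups),
    )


def pairwise_permanova(dm: DistanceMatrix, groups, n_perm: int = 999,
                       seed: int = 0) -> list[PermanovaResult]:
    """PERMANOVA for every pair of groups on the corresponding submatrix.

    p-values are reported raw and Bonferroni-adjusted over all pairs.
    """
    groups = np.asarray(list(groups))
    labels = list(pd.unique(groups))
    ids = np.asarray(dm.ids)
    results = []
    pairs = list(combinations(labels, 2))
    rng = np.random.default_rng(seed)
    for a, b in pairs:
        mask = (groups == a) | (groups == b)
        sub = dm.filter(ids[mask])
        res = permanova(sub, groups[mask], n_perm=n_perm,
                        seed=int(rng.integers(2**31)))
        res.groups = (a, b)
        results.append(res)
    for res in results:
        res.p_adjusted = min(1.0, res.p * len(pairs))
    return results
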