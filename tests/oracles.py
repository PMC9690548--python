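"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's code paths: midranks are computed
by explicit sorting, Spearman null distributions by literal enumeration
of permutations, and UniFrac by looping over every branch of the tree.
"""

import itertools
import math

import numpy as np


def midranks(v):
    """Average ranks via explicit sort-and-group."""
    v = list(v)
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_rho(x, y):
    """Pearson correlation of midranks, written out longhand."""
    rx, ry = midranks(x), midranks(y)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)


def spearman_exact_p(x, y):
    """Two-sided exact p: fraction of all n! permutations of y whose
    |rho| reaches the observed |rho|."""
    obs = abs(spearman_rho(x, y))
    y = list(y)
    count = 0
    total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(spearman_rho(x, perm)) >= obs - 1e-12:
            count += 1
    return count / total


def unifrac_brute(tree, counts_a, counts_b, weighted, normalized=False):
    """Per-branch enumeration of both UniFrac variants.

    counts_a/counts_b map leaf name -> count for the two samples.
    """
    total_a = sum(counts_a.values())
    total_b = sum(counts_b.values())
    num = 0.0
    union = 0.0
    wsum = 0.0
    norm_den = 0.0
    for node in tree.traverse(include_self=False):
        length = node.length or 0.0
        if node.is_tip():
            leaves = {node.name}
        else:
            leaves = {t.name for t in node.tips()}
        a = sum(counts_a.get(leaf, 0) for leaf in leaves)
        b = sum(counts_b.get(leaf, 0) for leaf in leaves)
        if weighted:
            pa = a / total_a if total_a else 0.0
            pb = b / total_b if total_b else 0.0
            wsum += length * abs(pa - pb)
            norm_den += length * (pa + pb)
        else:
            if (a > 0) != (b > 0):
                num += length
            if a > 0 or b > 0:
                union += length
    if weighted:
        if normalized:
            return wsum / norm_den if norm_den else 0.0
        return wsum
    return num / union if union else 0.0


def random_binary_tree(rng, n_leaves, prefix="L"):
    """Random topology with uniform branch lengths; returns (newick, names)."""
    names = [f"{prefix}{i}" for i in range(n_leaves)]
    nodes = [f"{name}:{rng.uniform(0.1, 2.0):.6f}" for name in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.6f}")
    inner = nodes[0]
    inner = inner[: inner.rfind(":")]  # root carries no length
    return inner + ";", names


def permanova_f(d, codes, k):
    """Pseudo-F computed longhand from a squared-distance double loop."""
    n = len(codes)
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d[i][j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in range(k):
        idx = [i for i in range(n) if codes[i] == g]
        s = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                s += d[idx[a]][idx[b]] ** 2
        if idx:
            ss_within += s / len(idx)
    ss_among = ss_total - ss_within
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def permanova_exact_p(d, codes, k):
    """Exact permutation p over all distinct label orderings (tiny n)."""
    codes = list(codes)
    f_obs = permanova_f(d, codes, k)
    seen = 0
    ge = 0
    for perm in set(itertools.permutations(codes)):
        seen += 1
        if permanova_f(d, list(perm), k) >= f_obs - 1e-12:
            ge += 1
    return ge / seen
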