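"""Synthetic multi-species mosquito microbiome datasets with ground truth.

The generator emulates the shape of a field study of eight mosquito
species (6-30 specimens each, 111 in total) profiled by 16S V4 amplicon
sequencing: per-sample depths spanning roughly 9k-123k reads, a few
hundred ASVs, species-specific community composition, and a handful of
planted positive/negative pairwise taxon associations that the network
stage should recover.

Sampling model, per sample of species s:

1. latent Gaussian vector z with unit marginals; planted pairs (i, j)
   are jointly bivariate normal with correlation rho (Gaussian copula),
   all other coordinates independent;
2. log-abundance  =  global base + species effect + latent_sigma * z,
   plus log-fold boosts for the planted differential taxa;
3. composition by softmax;
4. counts ~ Dirichlet-multinomial at the sample's depth with
   concentration ``overdispersion`` (None gives the plain multinomial
   limit).

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CountTable,
    InteractionNetwork,
    SampleMetadata,
    TaxonomyMap,
    parse_lineage,
    write_count_table,
)

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "evaluate_recovery",
           "write_bundle"]

#: Default per-species sample sizes (8 species, 111 mosquitoes).
DEFAULT_SPECIES = {
    "Ae_scapularis": 8,
    "Ae_serratus": 6,
    "Hg_capricornii": 7,
    "Hg_leucocelaenus": 14,
    "Ke_cruzii": 15,
    "Ps_ferox": 12,
    "Sa_conditus": 30,
    "Wy_confusa": 19,
}

_NAMED_GENERA = [
    "Sphingomonas", "Sphingobium", "Delftia", "Pseudomonas", "Acinetobacter",
    "Acidibacter", "Puia", "Methylobacterium-Methylorubrum", "Enterobacter",
    "Burkholderia", "Serratia", "Cedecea", "Wolbachia", "Asaia", "Afipia",
]

_PHYLA = [
    ("Proteobacteria", "Alphaproteobacteria"),
    ("Proteobacteria", "Gammaproteobacteria"),
    ("Firmicutes", "Bacilli"),
    ("Actinobacteriota", "Actinobacteria"),
    ("Bacteroidota", "Bacteroidia"),
]

_FAMILY_POOL = ["Pseudonocardiaceae"]  # flavor; rest are synthesized


def _default_planted() -> list:
    # six planted associations on taxa 0..11; signs mixed
    return [
        (0, 1, 0.95), (2, 3, 0.90), (4, 5, 0.95),
        (6, 7, 0.90), (8, 9, -0.95), (10, 11, -0.90),
    ]


def _default_differential() -> dict:
    # taxon indices 12/13/14 are Wolbachia/Asaia/Afipia by construction
    return {
        "Hg_leucocelaenus": [(12, 100.0)],
        "Ae_serratus": [(13, 100.0)],
        "Ke_cruzii": [(14, 100.0)],
    }


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults mirror the target study design: 8 species groups of
    6-30 samples, sequencing depths uniform on [8857, 123070], 300 taxa,
    six planted associations with |rho| between 0.9 and 0.95, and three
    species-specific 100x differential taxa.
    """

    species: dict = field(default_factory=lambda: dict(DEFAULT_SPECIES))
    n_taxa: int = 300
    base_sigma: float = 1.5          # sd of global log-abundance prior
    species_sigma: float = 1.0       # sd of per-species composition effects
    latent_sigma: float = 1.0        # sd of the per-sample latent layer
    planted: list = field(default_factory=_default_planted)
    planted_base: float = 4.0        # base log-abundance of planted/differential taxa
    differential: dict = field(default_factory=_default_differential)
    depth_range: tuple = (8857, 123070)
    overdispersion: float | None = 2000.0
    genus_unassigned_fraction: float = 0.1
    shared_genus_pairs: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if not self.species or any(n < 1 for n in self.species.values()):
            raise ValueError("every species needs at least 1 sample")
        lo, hi = self.depth_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad depth range {self.depth_range}")
        seen: set = set()
        for i, j, rho in self.planted:
            if i == j:
                raise ValueError(f"planted self-pair on taxon {i}")
            if not (-1.0 <= rho <= 1.0):
                raise ValueError(f"planted correlation {rho} outside [-1, 1]")
            if i in seen or j in seen:
                raise ValueError("planted pairs must be disjoint")
            if max(i, j) >= self.n_taxa:
                raise ValueError("planted taxon index out of range")
            seen.update((i, j))
        for sp, boosts in self.differential.items():
            if sp not in self.species:
                raise ValueError(f"differential species {sp!r} not in design")
            for idx, fold in boosts:
                if idx >= self.n_taxa or fold <= 0:
                    raise ValueError("bad differential boost")
        if not (0.0 <= self.genus_unassigned_fraction < 1.0):
            raise ValueError("genus_unassigned_fraction must be in [0, 1)")

    def special_taxa(self) -> set:
        out = {i for pair in self.planted for i in pair[:2]}
        for boosts in self.differential.values():
            out.update(idx for idx, _ in boosts)
        return out


@dataclass
class GroundTruth:
    """What the generator planted, expressed in collapsed taxon labels."""

    edges: list                     # (label_a, label_b, rho) with sign(rho) the true sign
    differential: dict              # species -> list of labels
    taxon_labels: dict              # ASV id -> collapsed display label
    tree_newick: str

    def edge_set(self) -> dict:
        return {frozenset((a, b)): rho for a, b, rho in self.edges}


def _make_taxonomy(spec: SyntheticSpec, rng: np.random.Generator):
    """Synthesize SILVA-style lineages; returns (TaxonomyMap, labels dict)."""
    m = spec.n_taxa
    asv_ids = [f"ASV{i + 1:04d}" for i in range(m)]
    special = spec.special_taxa()
    genus_names = []
    named = list(_NAMED_GENERA)
    for i in range(m):
        if i < len(named):
            genus_names.append(named[i])
        else:
            genus_names.append(f"Genus{i + 1:04d}")
    lineages = {}
    labels = {}
    unassigned_flags = rng.random(m) < spec.genus_unassigned_fraction
    for i, asv in enumerate(asv_ids):
        phylum, cls = _PHYLA[i % len(_PHYLA)]
        if i % 37 == 0 and i >= len(named):
            family = _FAMILY_POOL[0]
        else:
            family = f"Family{(i % 60) + 1:03d}"
        order = f"Order{(i % 25) + 1:03d}"
        if unassigned_flags[i] and i not in special and i >= len(named):
            lineage = f"d__Bacteria; p__{phylum}; c__{cls}; o__{order}; f__{family}"
            labels[asv] = f"Unclassified {family}"
        else:
            lineage = (
                f"d__Bacteria; p__{phylum}; c__{cls}; o__{order}; "
                f"f__{family}; g__{genus_names[i]}"
            )
            labels[asv] = genus_names[i]
        lineages[asv] = parse_lineage(lineage)
    # shared-genus ASV pairs: later taxon adopts the earlier one's lineage,
    # exercising the collapse stage; planted/differential taxa keep unique genera
    eligible = [
        i for i in range(len(named), m)
        if i not in special and not unassigned_flags[i]
    ]
    rng.shuffle(eligible)
    for k in range(min(spec.shared_genus_pairs, len(eligible) // 2)):
        a, b = eligible[2 * k], eligible[2 * k + 1]
        lineages[asv_ids[b]] = lineages[asv_ids[a]]
        labels[asv_ids[b]] = labels[asv_ids[a]]
    return asv_ids, TaxonomyMap(lineages), labels


def _coalescent_newick(leaf_names: list, rng: np.random.Generator) -> str:
    """Random sequential-coalescence tree with exponential waiting times."""
    nodes = [(name, 0.0) for name in leaf_names]
    height = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        height += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (na, ha), (nb, hb) = nodes[i], nodes[j]
        merged = f"({na}:{height - ha:.10f},{nb}:{height - hb:.10f})"
        nodes = [nodes[x] for x in range(k) if x not in (i, j)]
        nodes.append((merged, height))
    return nodes[0][0] + ";"


def generate(spec: SyntheticSpec):
    """Generate one dataset.

    Returns
    -------
    (CountTable, TaxonomyMap, SampleMetadata, TreeNode, GroundTruth)
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    m = spec.n_taxa

    asv_ids, taxonomy, labels = _make_taxonomy(spec, rng)

    special = spec.special_taxa()
    base = rng.normal(0.0, spec.base_sigma, size=m)
    for i in special:
        base[i] = spec.planted_base

    species_names = list(spec.species)
    species_effect = {}
    for sp in species_names:
        eff = rng.normal(0.0, spec.species_sigma, size=m)
        eff[list(special)] = 0.0
        for idx, fold in spec.differential.get(sp, []):
            eff[idx] += math.log(fold)
        species_effect[sp] = eff

    depths_lo, depths_hi = spec.depth_range
    sample_ids, sample_species, rows = [], [], []
    for sp in species_names:
        n = spec.species[sp]
        for k in range(n):
            z = rng.normal(size=m)
            for i, j, rho in spec.planted:
                zi = z[i]
                z[j] = rho * zi + math.sqrt(1.0 - rho * rho) * z[j]
            log_abund = base + species_effect[sp] + spec.latent_sigma * z
            x = np.exp(log_abund - log_abund.max())
            x /= x.sum()
            depth = int(rng.integers(depths_lo, depths_hi + 1))
            if spec.overdispersion is None or not np.isfinite(spec.overdispersion):
                p = x
            else:
                p = rng.dirichlet(spec.overdispersion * x)
            counts = rng.multinomial(depth, p)
            sample_id = f"{sp}_{k + 1:02d}"
            sample_ids.append(sample_id)
            sample_species.append(sp)
            rows.append(counts)

    table = CountTable(
        pd.DataFrame(np.asarray(rows, dtype=np.int64),
                     index=sample_ids, columns=asv_ids)
    )
    metadata = SampleMetadata(
        species=dict(zip(sample_ids, sample_species)),
        attributes={s: {} for s in sample_ids},
    )
    newick = _coalescent_newick(asv_ids, rng)
    import io as _io
    from skbio import TreeNode
    tree = TreeNode.read(_io.StringIO(newick))

    truth = GroundTruth(
        edges=[
            (labels[asv_ids[i]], labels[asv_ids[j]], rho)
            for i, j, rho in spec.planted
        ],
        differential={
            sp: [labels[asv_ids[idx]] for idx, _ in boosts]
            for sp, boosts in spec.differential.items()
        },
        taxon_labels=labels,
        tree_newick=newick,
    )
    return table, taxonomy, metadata, tree, truth


def evaluate_recovery(net: InteractionNetwork, truth: GroundTruth):
    """Compare a recovered network to the planted edge set.

    Edges match as unordered label pairs.  Precision is 1.0 for an empty
    network (no false claims); sign accuracy is computed over matched
    edges only (1.0 when nothing matched).

    Returns
    -------
    (precision, recall, sign_accuracy)
    """
    true_edges = truth.edge_set()
    pred = net.edges()
    tp = 0
    sign_ok = 0
    for a, b, rho, _p, sign in pred:
        key = frozenset((a, b))
        if key in true_edges:
            tp += 1
            true_sign = "positive" if true_edges[key] > 0 else "negative"
            if sign == true_sign:
                sign_ok += 1
    precision = 1.0 if not pred else tp / len(pred)
    recall = 1.0 if not true_edges else tp / len(true_edges)
    sign_accuracy = 1.0 if tp == 0 else sign_ok / tp
    return precision, recall, sign_accuracy


def write_bundle(spec: SyntheticSpec, outdir) -> dict:
    """Generate and write the full input bundle (TSVs + newick + truth JSON).

    Returns the mapping of artifact name -> path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, taxonomy, metadata, tree, truth = generate(spec)
    paths = {
        "counts": outdir / "counts.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "metadata": outdir / "metadata.tsv",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.json",
    }
    write_count_table(table, paths["counts"])
    with open(paths["taxonomy"], "w") as fh:
        fh.write("Feature ID\tTaxon\n")
        for asv, lineage in taxonomy.lineages.items():
            parts = [
                f"{pref}__{name}"
                for pref, name in zip("dpcofgs", lineage)
                if name is not None
            ]
            fh.write(f"{asv}\t{'; '.join(parts)}\n")
    with open(paths["metadata"], "w") as fh:
        fh.write("sample_id\tspecies\n")
        for s, sp in metadata.species.items():
            fh.write(f"{s}\t{sp}\n")
    with open(paths["tree"], "w") as fh:
        fh.write(truth.tree_newick + "\n")
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "edges": [[a, b, rho] for a, b, rho in truth.edges],
                "differential": truth.differential,
                "taxon_labels": truth.taxon_labels,
            },
            fh,
            indent=1,
        )
    return paths
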