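"""Readers, writers and shared domain types for the 16S analysis pipeline.

The universal in-memory currency is :class:`CountTable`, a samples x taxa
matrix of read counts (raw integers, or percent relative abundances after
normalization).  Taxonomy lives in :class:`TaxonomyMap`, sample -> mosquito
species assignments in :class:`SampleMetadata`, and thresholded Spearman
networks in :class:`InteractionNetwork`.  Phylogenies are scikit-bio
``TreeNode`` objects, read and validated here.

Canonical orientation is samples as rows, taxa as columns; BIOM-JSON input
(which stores taxa x samples) is transposed on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "RANKS",
    "CountTable",
    "TaxonomyMap",
    "SampleMetadata",
    "InteractionNetwork",
    "parse_lineage",
    "read_count_table",
    "write_count_table",
    "read_taxonomy",
    "read_metadata",
    "read_tree",
    "midpoint_root",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_network",
    "read_network",
]

#: The seven positional taxonomic ranks carried through the pipeline.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_RANK_PREFIXES = ("d__", "k__", "p__", "c__", "o__", "f__", "g__", "s__")


class FormatError(ValueError):
    """Raised for malformed input files or inconsistent tables."""


@dataclass
class CountTable:
    """Samples x taxa abundance matrix.

    Parameters
    ----------
    data :
        DataFrame with sample ids as index and taxon ids as columns.
        Values are non-negative; integers for raw read counts, floats
        after normalization.
    is_relative :
        True once the table holds percent relative abundances, in which
        case every row sums to 100 (within 1e-9).
    """

    data: pd.DataFrame
    is_relative: bool = False

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon ids: {dups}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise FormatError("count table contains non-numeric values")
        if values.size and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative value at sample {idx[i]!r}, taxon {cols[j]!r}"
            )
        if self.is_relative and len(idx):
            sums = values.sum(axis=1)
            if not np.allclose(sums, 100.0, rtol=0, atol=1e-9):
                bad = idx[np.argmax(np.abs(sums - 100.0))]
                raise FormatError(
                    f"relative table rows must sum to 100; sample {bad!r} "
                    f"sums to {sums[np.argmax(np.abs(sums - 100.0))]}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def taxon_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return CountTable(self.data.loc[list(sample_ids)].copy(), self.is_relative)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.is_relative == other.is_relative
            and self.data.index.equals(other.data.index)
            and self.data.columns.equals(other.data.columns)
            and np.allclose(self.data.to_numpy(float), other.data.to_numpy(float),
                            rtol=0, atol=1e-12)
        )


def parse_lineage(lineage: str) -> tuple:
    """Parse a semicolon-delimited SILVA-style lineage into 7 rank slots.

    Rank prefixes (``d__``, ``p__`` ... ``s__``) are stripped; empty or
    missing trailing ranks become ``None`` (unassigned).  An assigned rank
    following an unassigned one violates the prefix property and raises.
    """
    parts = [p.strip() for p in lineage.split(";")]
    slots: list = []
    for part in parts:
        for pref in _RANK_PREFIXES:
            if part.startswith(pref):
                part = part[len(pref):]
                break
        part = part.strip()
        slots.append(part if part else None)
    if len(slots) > len(RANKS):
        raise FormatError(f"lineage has more than {len(RANKS)} ranks: {lineage!r}")
    slots += [None] * (len(RANKS) - len(slots))
    seen_gap = False
    for rank, name in zip(RANKS, slots):
        if name is None:
            seen_gap = True
        elif seen_gap:
            raise FormatError(
                f"assigned rank {rank} {name!r} follows an unassigned rank "
                f"in lineage {lineage!r}"
            )
    return tuple(slots)


@dataclass
class TaxonomyMap:
    """ASV id -> 7-slot ranked lineage (domain ... species).

    Unassigned ranks are ``None``; assignments always form a prefix of the
    rank list (enforced at parse time).
    """

    lineages: dict = field(default_factory=dict)

    def __contains__(self, asv: str) -> bool:
        return asv in self.lineages

    def __getitem__(self, asv: str) -> tuple:
        return self.lineages[asv]

    def __len__(self) -> int:
        return len(self.lineages)

    def deepest_assigned(self, asv: str) -> tuple:
        """Return (rank name, label) of the deepest assigned rank, or
        (None, None) for a fully unassigned ASV."""
        lineage = self.lineages[asv]
        for rank, name in zip(reversed(RANKS), reversed(lineage)):
            if name is not None:
                return rank, name
        return None, None


@dataclass
class SampleMetadata:
    """Sample id -> mosquito species label, plus free-form attributes."""

    species: dict
    attributes: dict = field(default_factory=dict)

    def species_of(self, sample: str) -> str:
        return self.species[sample]

    def groups(self, sample_ids) -> pd.Series:
        missing = [s for s in sample_ids if s not in self.species]
        if missing:
            raise KeyError(f"samples without a species label: {missing}")
        return pd.Series([self.species[s] for s in sample_ids], index=list(sample_ids))

    def samples_by_species(self) -> dict:
        out: dict = {}
        for sample, sp in self.species.items():
            out.setdefault(sp, []).append(sample)
        return out


@dataclass
class InteractionNetwork:
    """Signed, undirected bacterial co-occurrence network.

    Nodes are collapsed taxon labels; each edge carries the Spearman rho
    it was built from, its p-value, and a sign ("positive"/"negative")
    matching the sign of rho.  ``candidate_nodes`` records every taxon
    that entered correlation analysis, so isolated (edge-less) taxa can be
    reported even though they are not graph nodes.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    candidate_nodes: list = field(default_factory=list)

    @classmethod
    def from_edges(cls, edges, candidate_nodes=()) -> "InteractionNetwork":
        """Build from an iterable of (taxon_a, taxon_b, rho, p) tuples."""
        g = nx.Graph()
        for a, b, rho, p in edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if rho == 0:
                raise ValueError("edge with rho == 0 has no sign")
            sign = "positive" if rho > 0 else "negative"
            g.add_edge(a, b, rho=float(rho), p=float(p), sign=sign)
        return cls(graph=g, candidate_nodes=list(candidate_nodes))

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    def edges(self) -> list:
        """Edges as (a, b, rho, p, sign), sorted for deterministic output."""
        out = []
        for a, b, d in self.graph.edges(data=True):
            a, b = sorted((a, b))
            out.append((a, b, d["rho"], d["p"], d["sign"]))
        return sorted(out)

    def isolated_taxa(self) -> list:
        present = set(self.graph.nodes)
        return [t for t in self.candidate_nodes if t not in present]


# ---------------------------------------------------------------------------
# count table I/O
# ---------------------------------------------------------------------------

def read_count_table(path, dialect: str = "tsv",
                     orientation: str = "samples") -> CountTable:
    """Read a count table from TSV or BIOM-JSON (v1).

    TSV layout: header row of taxon ids, first column sample ids (flip
    with ``orientation="taxa"``).  BIOM-JSON stores taxa (rows) x samples
    (columns) and is transposed to the canonical orientation.
    """
    path = Path(path)
    if dialect == "tsv":
        df = _read_tsv_matrix(path)
        if orientation == "taxa":
            df = df.T
        elif orientation != "samples":
            raise ValueError(f"unknown orientation {orientation!r}")
    elif dialect == "biom-json":
        df = _read_biom_json(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return CountTable(df, is_relative=False)


def _read_tsv_matrix(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    col_ids = header[1:]
    dup = {c for c in col_ids if col_ids.count(c) > 1}
    if dup:
        raise FormatError(f"duplicate column ids in {path}: {sorted(dup)}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate row ids in {path}: {dups}")
    bad = df.select_dtypes(exclude=[np.number]).columns.tolist()
    if bad:
        for col in bad:
            for row in df.index:
                v = df.at[row, col]
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"non-numeric value {v!r} at row {row!r}, "
                        f"column {col!r} in {path}"
                    ) from None
        df = df.astype(float)
    neg = df.lt(0)
    if neg.to_numpy().any():
        row = neg.any(axis=1).idxmax()
        col = neg.loc[row].idxmax()
        raise FormatError(f"negative count at row {row!r}, column {col!r} in {path}")
    if (df.to_numpy() == np.floor(df.to_numpy())).all():
        df = df.astype(np.int64)
    return df


def _read_biom_json(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    n_rows, n_cols = doc["shape"]
    mat = np.zeros((n_rows, n_cols))
    if doc.get("matrix_type", "sparse") == "sparse":
        for i, j, v in doc["data"]:
            mat[i, j] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    df = pd.DataFrame(mat.T, index=samples, columns=taxa)  # -> samples x taxa
    if (df.to_numpy() == np.floor(df.to_numpy())).all():
        df = df.astype(np.int64)
    return df


def write_count_table(table: CountTable, path) -> None:
    df = table.data
    if not table.is_relative:
        values = df.to_numpy()
        if values.size and (values == np.floor(values)).all():
            df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# taxonomy / metadata / tree I/O
# ---------------------------------------------------------------------------

def read_taxonomy(path) -> TaxonomyMap:
    """Read a two-column (ASV id, lineage string) TSV mapping.

    A header line whose first field is ``Feature ID``/``OTU ID`` or starts
    with ``#`` is skipped.  The same ASV listed twice with different
    lineages is a hard error.
    """
    lineages: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and (
                fields[0].startswith("#")
                or fields[0].lower() in ("feature id", "otu id", "asv", "asv_id")
            ):
                continue
            if len(fields) < 2:
                raise FormatError(f"line {lineno} of {path}: expected 2 columns")
            asv, lineage_str = fields[0], fields[1]
            lineage = parse_lineage(lineage_str)
            if asv in lineages and lineages[asv] != lineage:
                raise FormatError(
                    f"ASV {asv!r} listed twice with different lineages in {path}"
                )
            lineages[asv] = lineage
    return TaxonomyMap(lineages)


def read_metadata(path) -> SampleMetadata:
    """Read sample metadata: TSV with a header, first column sample id.

    The species label comes from a column named ``species`` (any case),
    falling back to the second column.  Remaining columns become free-form
    attributes.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids in {path}: {dups}")
    species_col = None
    for col in df.columns:
        if col.lower() == "species":
            species_col = col
            break
    if species_col is None:
        if not len(df.columns):
            raise FormatError(f"{path} has no species column")
        species_col = df.columns[0]
    species = df[species_col].to_dict()
    attributes = {
        s: {c: df.at[s, c] for c in df.columns if c != species_col}
        for s in df.index
    }
    return SampleMetadata(species=species, attributes=attributes)


def read_tree(path, require_rooted: bool = True) -> TreeNode:
    """Read a newick tree; validate unique tips and non-negative lengths.

    A basal trifurcation is the usual signature of an unrooted tree, which
    UniFrac cannot use directly; by default this raises with instructions
    to midpoint-root (see :func:`midpoint_root`) or supply a rooted tree.
    """
    tree = TreeNode.read(str(path), format="newick")
    return _validate_tree(tree, require_rooted=require_rooted)


def _validate_tree(tree: TreeNode, require_rooted: bool = True) -> TreeNode:
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise FormatError(f"duplicate leaf labels in tree: {dup}")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise FormatError(f"negative branch length at node {node.name!r}")
    if require_rooted and len(tree.children) == 3:
        raise FormatError(
            "tree looks unrooted (basal trifurcation); midpoint-root it "
            "(culicinet.io_formats.midpoint_root) or supply a rooted tree"
        )
    return tree


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root an unrooted tree at the midpoint of its longest tip-to-tip path."""
    return tree.root_at_midpoint()


def total_branch_length(tree: TreeNode) -> float:
    return sum(n.length or 0.0 for n in tree.traverse(include_self=False))


# ---------------------------------------------------------------------------
# distance matrix / network I/O
# ---------------------------------------------------------------------------

def write_distance_matrix(dm, path) -> None:
    """Write a skbio DistanceMatrix as a labeled square TSV."""
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def read_distance_matrix(path):
    from skbio import DistanceMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(float), ids=list(df.index.astype(str)))


def write_network(network: InteractionNetwork, path, format: str = "edge-list-tsv") -> None:
    """Write an interaction network as edge-list TSV or GraphML.

    Edge-list columns: taxon_a, taxon_b, rho, p, sign.  GraphML edges
    carry "rho", "p" and "sign" attributes.
    """
    path = Path(path)
    if format == "edge-list-tsv":
        rows = network.edges()
        df = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "p", "sign"])
        df.to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        nx.write_graphml(network.graph, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "edge-list-tsv") -> InteractionNetwork:
    path = Path(path)
    if format == "edge-list-tsv":
        df = pd.read_csv(path, sep="\t", dtype={"taxon_a": str, "taxon_b": str})
        edges = [
            (r.taxon_a, r.taxon_b, float(r.rho), float(r.p))
            for r in df.itertuples()
        ]
        return InteractionNetwork.from_edges(edges)
    if format == "graphml":
        g = nx.read_graphml(path)
        edges = [(a, b, float(d["rho"]), float(d["p"])) for a, b, d in g.edges(data=True)]
        return InteractionNetwork.from_edges(edges)
    raise ValueError(f"unknown network format {format!r}")
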