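"""End-to-end orchestration: inputs -> diversity, ANCOM and network outputs.

``run_all`` reads the input bundle (counts, taxonomy, metadata, tree),
executes every stage with per-stage seeds derived from one master seed,
and writes all tabular artifacts plus a JSON manifest.  Stage outputs are
pure functions of (inputs, config, seed); per-stage seeds are derived
from the stage name so adding a stage never perturbs earlier draws.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance_filtering import filter_rare, rarefy, relative_abundance
from .alpha_diversity import alpha_table, compare_groups, rarefaction_curve
from .beta_diversity import pairwise_permanova, pcoa, permanova, unifrac
from .differential_abundance import ancom
from .io_formats import (
    CountTable,
    read_count_table,
    read_metadata,
    read_taxonomy,
    read_tree,
    write_count_table,
    write_distance_matrix,
    write_network,
)
from .network_inference import per_species_networks
from .taxonomy_collapse import collapse

__all__ = ["PipelineConfig", "run_all", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed and the
    stage name (stable across runs and stage additions)."""
    ss = np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """All knobs of the study-replica pipeline, serialized with outputs."""

    counts: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    tree: str | None = None
    outdir: str = "culicinet_out"
    collapse_rank: str = "genus"
    min_fraction: float = 0.001          # rarity filter, fraction of total reads
    filter_scope: str = "per-species"
    rarefaction_depth: int = 10000       # max depth of the rarefaction curve
    rarefaction_iterations: int = 10
    normalization_depth: int | None = None  # None -> min sample total
    shannon_base: float = 2.0
    permutations: int = 999
    r_min: float = 0.75
    p_max: float = 0.05
    use_abs: bool = True
    p_adjust: str = "none"
    min_samples: int = 4
    ancom_alpha: float = 0.05
    ancom_pseudocount: float = 1.0
    ancom_cutoff_fraction: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.min_fraction < 1):
            raise ValueError("min_fraction must be in (0, 1)")
        if not (0 < self.p_max <= 1) or not (0 <= self.r_min < 1):
            raise ValueError("network thresholds out of range")
        if self.filter_scope not in ("per-species", "global"):
            raise ValueError(f"unknown filter_scope {self.filter_scope!r}")
        if self.permutations < 1 or self.rarefaction_iterations < 1:
            raise ValueError("permutations/iterations must be positive")


def _timed(name: str, manifest: dict):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            dt = time.perf_counter() - self.t0
            manifest["stages"][name] = round(dt, 3)
            logger.info("stage=%s wall=%.2fs", name, dt)
            return False

    return _Ctx()


def run_all(config: PipelineConfig) -> Path:
    """Load the input bundle from ``config`` paths and run every stage."""
    config.validate()
    for attr in ("counts", "taxonomy", "metadata", "tree"):
        if getattr(config, attr) is None:
            raise ValueError(f"config.{attr} path is required")
    table = read_count_table(config.counts)
    taxonomy = read_taxonomy(config.taxonomy)
    metadata = read_metadata(config.metadata)
    tree = read_tree(config.tree)
    return run_pipeline(table, taxonomy, metadata, tree, config)


def run_pipeline(table, taxonomy, metadata, tree, config: PipelineConfig) -> Path:
    """Run every stage on in-memory inputs; returns the output directory.

    Emits: per-species filter reports, collapsed tables (raw + percent),
    alpha diversity and group tests, rarefaction curve, UniFrac distance
    matrices + PCoA + PERMANOVA (omnibus and pairwise), the ANCOM table,
    per-species networks (GraphML + edge lists) with summaries, the
    genus x sample percent-abundance heatmap matrix, and a run manifest.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "networks").mkdir(exist_ok=True)
    manifest: dict = {
        "package": "culicinet",
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "artifacts": [],
        "warnings": [],
    }
    groups = metadata.groups(table.sample_ids)

    def emit(name: str) -> Path:
        manifest["artifacts"].append(name)
        return outdir / name

    with _timed("filter", manifest):
        _, global_report = filter_rare(table, fraction=config.min_fraction)
        global_report.to_frame().to_csv(
            emit("filter_report_global.tsv"), sep="\t", index=False
        )
        rows = []
        for species, samples in metadata.samples_by_species().items():
            present = [s for s in samples if s in set(table.sample_ids)]
            if not present:
                continue
            _, rep = filter_rare(
                table.subset_samples(present), fraction=config.min_fraction
            )
            rows.append(
                (species, len(present), rep.grand_total, rep.threshold,
                 len(rep.retained), len(rep.removed))
            )
        pd.DataFrame(
            rows,
            columns=["species", "n_samples", "grand_total", "threshold",
                     "n_retained", "n_removed"],
        ).to_csv(emit("filter_report_per_species.tsv"), sep="\t", index=False)

    with _timed("collapse", manifest):
        collapsed = collapse(table, taxonomy, max_rank=config.collapse_rank)
        write_count_table(collapsed, emit("collapsed_raw.tsv"))
        collapsed_pct = relative_abundance(collapsed)
        write_count_table(collapsed_pct, emit("collapsed_percent.tsv"))
        # heatmap matrix: taxa as rows, samples as columns
        collapsed_pct.data.T.to_csv(
            emit("heatmap_genus_percent.tsv"), sep="\t", index_label="taxon"
        )

    with _timed("rarefy", manifest):
        depth = config.normalization_depth
        if depth is None:
            depth = int(table.sample_totals().min())
        manifest["normalization_depth"] = depth
        rarefied = rarefy(table, depth, seed=stage_seed(config.seed, "rarefy"))
        dropped = sorted(set(table.sample_ids) - set(rarefied.sample_ids))
        if dropped:
            manifest["warnings"].append(f"samples below depth {depth}: {dropped}")

    with _timed("alpha", manifest):
        alpha = alpha_table(rarefied, base=config.shannon_base)
        alpha["species"] = [metadata.species_of(s) for s in alpha.index]
        alpha.to_csv(emit("alpha.tsv"), sep="\t", index_label="sample_id")
        gt = compare_groups(alpha["shannon"].to_numpy(), alpha["species"].to_numpy())
        pd.DataFrame([{"H": gt.h, "p": gt.p}]).to_csv(
            emit("alpha_kruskal.tsv"), sep="\t", index=False
        )
        gt.pairwise.to_csv(emit("alpha_dunn.tsv"), sep="\t", index=False)
        max_depth = min(config.rarefaction_depth, int(table.sample_totals().max()))
        depths = sorted({d for d in
                         [1, 10, 100, 500, 1000, 2500, 5000, 7500,
                          config.rarefaction_depth] if d <= max_depth})
        curve = rarefaction_curve(
            table, depths, iterations=config.rarefaction_iterations,
            seed=stage_seed(config.seed, "rarefaction_curve"),
        )
        curve.to_csv(emit("rarefaction_curve.tsv"), sep="\t",
                     index_label="sample_id")

    with _timed("beta", manifest):
        perma_rows, pair_frames = [], []
        for metric, weighted in (("unweighted_unifrac", False),
                                 ("weighted_unifrac", True)):
            dm = unifrac(tree, rarefied, weighted=weighted)
            write_distance_matrix(dm, emit(f"{metric}.tsv"))
            res = pcoa(dm)
            with open(emit(f"pcoa_{metric}.tsv"), "w") as fh:
                fh.write("# eigenvalues\t" + "\t".join(
                    f"{v:.10g}" for v in res.eigenvalues) + "\n")
                fh.write("# proportion_explained\t" + "\t".join(
                    f"{v:.10g}" for v in res.proportion_explained) + "\n")
                res.coordinates.to_csv(fh, sep="\t", index_label="sample_id")
            g = metadata.groups(list(dm.ids))
            omni = permanova(dm, g, n_perm=config.permutations,
                             seed=stage_seed(config.seed, f"permanova-{metric}"))
            perma_rows.append({"metric": metric, "pseudo_F": omni.pseudo_f,
                               "p": omni.p, "n_permutations": omni.n_permutations,
                               "n_samples": omni.n_samples})
            pw = pairwise_permanova(
                dm, g, n_perm=config.permutations,
                seed=stage_seed(config.seed, f"pairwise-permanova-{metric}"),
            )
            pair_frames.append(pd.DataFrame(
                [{"metric": metric, "group_a": r.groups[0],
                  "group_b": r.groups[1], "pseudo_F": r.pseudo_f, "p": r.p,
                  "p_bonferroni": r.p_adjusted, "n_samples": r.n_samples}
                 for r in pw]
            ))
        pd.DataFrame(perma_rows).to_csv(emit("permanova.tsv"), sep="\t", index=False)
        pd.concat(pair_frames, ignore_index=True).to_csv(
            emit("permanova_pairwise.tsv"), sep="\t", index=False
        )

    with _timed("ancom", manifest):
        res = ancom(
            collapsed, groups.to_numpy(),
            alpha=config.ancom_alpha,
            pseudocount=config.ancom_pseudocount,
            cutoff_fraction=config.ancom_cutoff_fraction,
        )
        res.table.to_csv(emit("ancom.tsv"), sep="\t", index_label="taxon")

    with _timed("network", manifest):
        nets = per_species_networks(
            table, taxonomy, metadata,
            r_min=config.r_min, p_max=config.p_max, use_abs=config.use_abs,
            p_adjust=config.p_adjust, min_fraction=config.min_fraction,
            filter_scope=config.filter_scope,
            collapse_rank=config.collapse_rank,
            min_samples=config.min_samples,
        )
        skipped = sorted(set(metadata.samples_by_species()) - set(nets))
        if skipped:
            manifest["warnings"].append(f"species skipped in networks: {skipped}")
        summary_rows = []
        for species, (net, summ) in nets.items():
            write_network(net, emit(f"networks/{species}_edges.tsv"),
                          format="edge-list-tsv")
            write_network(net, emit(f"networks/{species}.graphml"),
                          format="graphml")
            summ.per_node.to_csv(emit(f"networks/{species}_nodes.tsv"), sep="\t")
            summary_rows.append(
                {"species": species, "nodes": summ.node_count,
                 "positive_edges": summ.positive_edges,
                 "negative_edges": summ.negative_edges,
                 "isolated_taxa": len(summ.isolated_taxa)}
            )
        pd.DataFrame(summary_rows).to_csv(
            emit("network_summary.tsv"), sep="\t", index=False
        )

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    manifest["artifacts"].append("manifest.json")
    return outdir
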