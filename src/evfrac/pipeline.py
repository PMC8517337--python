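"""One-command orchestration: classify -> stats -> conserve -> network -> gsea.

Stages run in dependency order from a single structured config; stages whose
inputs are absent are skipped with a logged notice. The JSON summary is a pure
function of the inputs and seed (keys sorted, no timestamps), so a rerun with
the same config is byte-identical; wall-clock provenance goes to the run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .conservation import attach_conservation, conservation_compare, read_conservation
from .enrichment import (
    gsea_preranked,
    jaccard_overlap_edges,
    rank_balanced_by_abundance,
    rank_by_ratio,
    read_gmt,
)
from .frequency import (
    build_presence_matrix,
    compute_frequencies,
    fisher_differential,
    load_default_marker_panels,
    marker_panel_report,
    partition_by_ratio,
)
from .network import (
    annotate_nodes,
    bait_prey_correlation,
    detect_seed_proteins,
    export_network,
    integrate_networks,
    read_edge_list,
)
from .protocols import classify_table, read_protocols

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    protocols: str
    identifications: str
    outdir: str
    conservation: str | None = None
    edges: list = field(default_factory=list)  # [{"path":..., "assay":...}, ...]
    gene_sets: str | None = None
    markers: str | None = None  # path, or "default" for the bundled panels
    theta: float = 0.1
    min_labeled_degree: int = 10
    min_ic_network: int = 50
    min_ic_correlation: int = 0
    gsea_n_perm: int = 1000
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    gsea_weight: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages whose inputs are configured; return the JSON summary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("evfrac")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"version": __version__, "seed": config.seed, "stages": []}
    try:
        logger.info("evfrac %s starting; config defaults in effect: theta=%s "
                    "min_labeled_degree=%s min_ic_network=%s min_ic_correlation=%s "
                    "gsea(n_perm=%s, size=[%s,%s], weight=%s) seed=%s",
                    __version__, config.theta, config.min_labeled_degree,
                    config.min_ic_network, config.min_ic_correlation,
                    config.gsea_n_perm, config.gsea_min_size, config.gsea_max_size,
                    config.gsea_weight, config.seed)

        # --- classify ---
        records = read_protocols(config.protocols)
        labels, cls_summary = classify_table(records)
        labels.to_csv(out / "labels.tsv", sep="\t", index=False)
        summary["stages"].append("classify")
        summary["classification"] = {
            "n_input": cls_summary.n_input,
            "n_non_human_dropped": cls_summary.n_non_human_dropped,
            "label_counts": cls_summary.label_counts,
            "reason_counts": cls_summary.reason_counts,
        }

        # --- stats ---
        ident = pd.read_csv(config.identifications, sep="\t", dtype=str)
        matrix = build_presence_matrix(ident, labels)
        stats = fisher_differential(compute_frequencies(matrix))
        partition = partition_by_ratio(stats, theta=config.theta)
        stats_out = stats.copy()
        stats_out["partition"] = partition
        stats_out.to_csv(out / "protein_stats.tsv", sep="\t")
        summary["stages"].append("stats")
        summary["partition_sizes"] = partition.value_counts().sort_index().to_dict()
        summary["n_proteins"] = int(len(stats))

        if config.markers:
            panels = (load_default_marker_panels() if config.markers == "default"
                      else load_default_marker_panels(config.markers))
            try:
                markers, panel_tests = marker_panel_report(stats, panels)
                markers.to_csv(out / "marker_report.tsv", sep="\t", index=False)
                panel_tests.to_csv(out / "marker_panel_tests.tsv", sep="\t", index=False)
                summary["marker_panels"] = {
                    r.panel: {"n_present": int(r.n_present), "U": r.U, "p": r.p}
                    for r in panel_tests.itertuples()
                }
                summary["stages"].append("markers")
            except ValueError as exc:
                logger.info("marker stage skipped: %s", exc)

        # --- conservation ---
        if config.conservation:
            cons = read_conservation(config.conservation)
            joined = attach_conservation(stats, cons)
            comparisons = conservation_compare(joined, partition)
            pd.DataFrame([dataclasses.asdict(c) for c in comparisons.values()]).to_csv(
                out / "conservation_compare.tsv", sep="\t", index=False)
            summary["stages"].append("conserve")
            summary["conservation"] = {
                side: dataclasses.asdict(c) for side, c in comparisons.items()
            }
        else:
            logger.info("conservation stage skipped: no input configured")

        # --- network ---
        if config.edges:
            edge_lists = [
                (read_edge_list(e["path"], e.get("assay", "Y2H")), e.get("assay", "Y2H"))
                for e in config.edges
            ]
            network = integrate_networks(edge_lists)
            annotate_nodes(network, stats, partition)
            corr = bait_prey_correlation(network, stats, min_ic=config.min_ic_correlation)
            seeds = detect_seed_proteins(
                network, partition, min_labeled_degree=config.min_labeled_degree)
            seeds.to_csv(out / "seed_candidates.tsv", sep="\t", index=False)
            export_network(network, out / "network.graphml")
            summary["stages"].append("network")
            summary["correlation"] = dataclasses.asdict(corr)
            summary["top_seed_candidates"] = seeds.head(10)[
                ["protein_id", "side", "labeled_degree", "neighbor_fraction", "enrich_q"]
            ].to_dict(orient="records")
        else:
            logger.info("network stage skipped: no edge lists configured")

        # --- enrichment ---
        if config.gene_sets:
            collection = read_gmt(config.gene_sets)
            gsea_summary = {}
            for mode, ranked in (
                ("ratio", rank_by_ratio(stats)),
                ("balanced", None),
            ):
                if mode == "balanced":
                    try:
                        ranked = rank_balanced_by_abundance(stats, theta=config.theta)
                    except ValueError as exc:
                        logger.info("balanced GSEA skipped: %s", exc)
                        continue
                try:
                    res = gsea_preranked(
                        ranked, collection, n_perm=config.gsea_n_perm,
                        min_size=config.gsea_min_size, max_size=config.gsea_max_size,
                        weight=config.gsea_weight, seed=config.seed,
                    )
                except ValueError as exc:
                    logger.info("%s GSEA skipped: %s", mode, exc)
                    continue
                res.table.to_csv(out / f"gsea_{mode}.tsv", sep="\t", index=False)
                sig = res.table[res.table["fdr_q"] < 0.05]
                jaccard_overlap_edges(collection, list(sig["set_name"])).to_csv(
                    out / f"gsea_{mode}_overlap.tsv", sep="\t", index=False)
                gsea_summary[mode] = {
                    "n_tested": int(len(res.table)),
                    "significant": sig[["set_name", "es", "nes", "fdr_q"]]
                    .to_dict(orient="records"),
                }
            if gsea_summary:
                summary["stages"].append("gsea")
                summary["gsea"] = gsea_summary
        else:
            logger.info("enrichment stage skipped: no gene sets configured")

        with open(out / "summary.json", "w") as fh:
            json.dump(_round_floats(summary), fh, indent=2, sort_keys=True)
            fh.write("\n")
        logger.info("pipeline finished: stages %s", summary["stages"])
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()
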