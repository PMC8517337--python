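"""Integrated AP-MS + Y2H interactome analysis of EV-fraction homophily.

AP-MS screens (BioPlex-style) yield directed bait->prey records; Y2H screens
(HuRI-style) yield undirected binary pairs. This module merges such edge lists
into one interactome, measures homophily as the Spearman correlation of the
log2(fsEV/flEV) ratio between interacting partners, and formalises the "seed
protein" idea — a hub whose interactors preferentially belong to one EV
fraction — as a one-sided hypergeometric test of the hub neighbourhood's
fraction composition against the network-wide composition, BH-corrected over
all (node, side) tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .frequency import PartitionClass

logger = logging.getLogger(__name__)

ASSAYS = ("APMS", "Y2H")


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n_edges: int


@dataclass
class IntegratedNetwork:
    """Deduplicated interactome with per-assay provenance.

    ``edges`` has columns bait, prey, assay, directed: self-loops removed,
    duplicate (bait, prey, assay) triples collapsed, undirected Y2H edges
    stored once under lexicographic (min, max) orientation. ``graph`` is the
    undirected simple-graph view used for degrees and neighbourhoods; node
    attributes (log2_ratio, partition, ic_human) are attached by
    :func:`annotate_nodes`.
    """

    edges: pd.DataFrame
    graph: nx.Graph


def integrate_networks(edge_lists: list[tuple[pd.DataFrame, str]]) -> IntegratedNetwork:
    """Merge assay-specific edge lists into one interactome.

    Each element is (frame with columns bait, prey, assay) — the second tuple
    member names the assay used for rows lacking an ``assay`` column.
    """
    frames = []
    for df, assay in edge_lists:
        if assay not in ASSAYS:
            raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
        sub = df.copy()
        if "assay" not in sub.columns:
            sub["assay"] = assay
        frames.append(sub[["bait", "prey", "assay"]])
    if not frames:
        raise ValueError("no edge lists supplied")
    edges = pd.concat(frames, ignore_index=True)
    edges["bait"] = edges["bait"].astype(str).str.upper()
    edges["prey"] = edges["prey"].astype(str).str.upper()
    edges = edges[edges["bait"] != edges["prey"]]
    # undirected Y2H edges canonicalised to (min, max)
    y2h = edges["assay"] == "Y2H"
    lo = edges[["bait", "prey"]].min(axis=1)
    hi = edges[["bait", "prey"]].max(axis=1)
    edges.loc[y2h, "bait"] = lo[y2h]
    edges.loc[y2h, "prey"] = hi[y2h]
    edges = edges.drop_duplicates(["bait", "prey", "assay"]).reset_index(drop=True)
    if edges.empty:
        raise ValueError("integrated network is empty after cleaning")
    edges["directed"] = edges["assay"] == "APMS"
    graph = nx.Graph()
    graph.add_edges_from(edges[["bait", "prey"]].itertuples(index=False, name=None))
    return IntegratedNetwork(edges=edges, graph=graph)


def annotate_nodes(
    network: IntegratedNetwork, stats: pd.DataFrame, partition: pd.Series | None = None
) -> None:
    """Attach log2_ratio / ic_human / partition attributes to network nodes in place."""
    for node in network.graph.nodes:
        if node in stats.index:
            network.graph.nodes[node]["log2_ratio"] = float(stats.at[node, "log2_ratio"])
            network.graph.nodes[node]["ic_human"] = int(stats.at[node, "ic_human"])
        if partition is not None and node in partition.index:
            network.graph.nodes[node]["partition"] = str(partition[node])


def bait_prey_correlation(
    network: IntegratedNetwork, stats: pd.DataFrame, min_ic: int = 0
) -> CorrelationResult:
    """Spearman correlation of the log2(fsEV/flEV) ratio across interacting pairs.

    One (ratio_bait, ratio_prey) pair per unique interacting protein pair, in
    stored orientation (bait->prey for AP-MS, lexicographic for Y2H; pairs
    supported by both assays count once, AP-MS orientation preferred). Edges
    with an unscored endpoint, or an endpoint with ic_human < ``min_ic``, are
    dropped with a logged count. Ties get average ranks; the p-value is the
    large-sample t approximation.
    """
    scored = stats.loc[stats["ic_human"] >= min_ic, "log2_ratio"]
    # unique unordered pairs; directed AP-MS rows take precedence for orientation
    e = network.edges.sort_values("directed", ascending=False)
    key = pd.DataFrame({"lo": e[["bait", "prey"]].min(axis=1), "hi": e[["bait", "prey"]].max(axis=1)})
    e = e.loc[~key.duplicated().to_numpy()]
    ok = e["bait"].isin(scored.index) & e["prey"].isin(scored.index)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d edge(s) with unscored endpoints", n_dropped)
    e = e[ok]
    if len(e) < 3:
        raise ValueError(f"need >= 3 scored edges, have {len(e)}")
    x = scored.loc[e["bait"]].to_numpy()
    y = scored.loc[e["prey"]].to_numpy()
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p=float(p), n_edges=int(len(e)))


def detect_seed_proteins(
    network: IntegratedNetwork,
    partition: pd.Series,
    min_labeled_degree: int = 10,
) -> pd.DataFrame:
    """Rank hub proteins whose neighbourhoods are enriched for one EV fraction.

    For every node with at least ``min_labeled_degree`` neighbours carrying a
    non-BALANCED partition label, a one-sided hypergeometric test asks whether
    its SEV-enriched (resp. LEV-enriched) neighbour count exceeds what drawing
    the neighbourhood from the network-wide labelled-node composition would
    give. BH correction runs across all (node, side) tests; the result is
    sorted by enrich_q, then descending neighbor_fraction.
    """
    labelled = {
        n: partition[n]
        for n in network.graph.nodes
        if n in partition.index
        and partition[n] != PartitionClass.BALANCED.value
    }
    pop_n = len(labelled)
    pop_side = {
        "SEV": sum(1 for v in labelled.values() if v == PartitionClass.SEV_ENRICHED.value),
        "LEV": sum(1 for v in labelled.values() if v == PartitionClass.LEV_ENRICHED.value),
    }
    rows = []
    for node in network.graph.nodes:
        nbrs = list(network.graph.neighbors(node))
        lab_nbrs = [n for n in nbrs if n in labelled]
        if len(lab_nbrs) < min_labeled_degree:
            continue
        k_sev = sum(
            1 for n in lab_nbrs if labelled[n] == PartitionClass.SEV_ENRICHED.value
        )
        for side, k in (("SEV", k_sev), ("LEV", len(lab_nbrs) - k_sev)):
            p = float(sps.hypergeom.sf(k - 1, pop_n, pop_side[side], len(lab_nbrs)))
            rows.append(
                (node, network.graph.degree(node), len(lab_nbrs), side, k,
                 k / len(lab_nbrs), p)
            )
    if not rows:
        raise ValueError(
            f"no node has labelled degree >= {min_labeled_degree}"
        )
    out = pd.DataFrame(
        rows,
        columns=["protein_id", "degree", "labeled_degree", "side", "k_side",
                 "neighbor_fraction", "enrich_p"],
    )
    out["enrich_q"] = multipletests(out["enrich_p"], method="fdr_bh")[1]
    return out.sort_values(
        ["enrich_q", "neighbor_fraction"], ascending=[True, False]
    ).reset_index(drop=True)


def export_network(network: IntegratedNetwork, path) -> None:
    """Write the annotated interactome as GraphML (undirected, assay provenance on edges)."""
    g = nx.Graph()
    g.add_nodes_from(network.graph.nodes(data=True))
    for (b, p), grp in network.edges.groupby(["bait", "prey"], sort=False):
        assays = ",".join(sorted(grp["assay"].unique()))
        if g.has_edge(b, p):  # same pair in both orientations via AP-MS
            assays = ",".join(sorted(set(g.edges[b, p]["assays"].split(",")) | set(grp["assay"])))
        g.add_edge(b, p, assays=assays)
    nx.write_graphml(g, path)


def read_graphml_network(path) -> IntegratedNetwork:
    """Round-trip reader for :func:`export_network` output."""
    g = nx.read_graphml(path)
    rows = []
    for b, p, data in g.edges(data=True):
        for assay in str(data.get("assays", "Y2H")).split(","):
            lo, hi = (b, p) if b <= p else (p, b)
            if assay == "Y2H":
                rows.append((lo, hi, assay, False))
            else:
                rows.append((b, p, assay, True))
    edges = pd.DataFrame(rows, columns=["bait", "prey", "assay", "directed"])
    edges = edges.drop_duplicates(["bait", "prey", "assay"]).reset_index(drop=True)
    graph = nx.Graph()
    graph.add_nodes_from(g.nodes(data=True))
    graph.add_edges_from(edges[["bait", "prey"]].itertuples(index=False, name=None))
    return IntegratedNetwork(edges=edges, graph=graph)


def read_edge_list(path, assay: str) -> pd.DataFrame:
    """Read a TSV edge list with columns bait, prey [, assay]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"bait", "prey"} - set(df.columns)
    if missing:
        raise ValueError(f"edge list missing columns: {sorted(missing)}")
    if "assay" not in df.columns:
        df["assay"] = assay
    return df


def read_psimitab(path, id_map: dict[str, str] | None = None, assay: str = "Y2H") -> pd.DataFrame:
    """Read interactor columns 1-2 of a PSI-MI TAB 2.5 file into a bait/prey frame.

    ``id_map`` translates raw interactor identifiers (after stripping any
    ``db:`` prefix) to gene symbols; unmapped identifiers pass through.
    """
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], names=["bait", "prey"],
                     comment=None, dtype=str)
    df = df[~df["bait"].str.startswith("#")]

    def clean(s: pd.Series) -> pd.Series:
        raw = s.str.split("|").str[0].str.split(":").str[-1]
        if id_map:
            return raw.map(lambda v: id_map.get(v, v))
        return raw

    return pd.DataFrame({"bait": clean(df["bait"]), "prey": clean(df["prey"]), "assay": assay})
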