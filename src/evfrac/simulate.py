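"""Synthetic EV meta-study generator with known ground truth.

Emulates the statistical structure the pipeline's inferences rest on, at desk
scale and fully seeded:

* DUC protocols sampled inside the sEV / lEV rule windows for labelled
  datasets and inside the rejected (20k, 100k) x g pellet window for
  deliberately excluded ones;
* subtype-biased Bernoulli protein identification: each protein belongs to
  one of four generative classes (EXO, ECTO, SHARED, BACKGROUND) with
  class-and-fraction-specific identification probabilities;
* class-dependent ortholog conservation: binomial identification counts over
  the prokaryotic and eukaryotic EV dataset totals (141 and 656), with
  ECTO-class proteins more conserved in prokaryotes and EXO-class proteins in
  eukaryotes;
* a homophilous interactome: stochastic block model over the classes with
  designated recruiter hubs wired preferentially within their own class;
* planted gene sets drawn within the EXO or ECTO class plus uniform decoys.

What it does not model: peptide-level inference, intensity values,
missing-not-at-random mass-spectrometry noise, or species-level phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .protocols import CentrifugationStep, ProtocolRecord, Role

CLASSES = ("EXO", "ECTO", "SHARED", "BACKGROUND")


def _default_proportions():
    return {"EXO": 0.25, "ECTO": 0.25, "SHARED": 0.25, "BACKGROUND": 0.25}


def _default_p_ident():
    return {
        ("EXO", "SEV"): 0.6, ("EXO", "LEV"): 0.1,
        ("ECTO", "SEV"): 0.1, ("ECTO", "LEV"): 0.6,
        ("SHARED", "SEV"): 0.5, ("SHARED", "LEV"): 0.5,
        ("BACKGROUND", "SEV"): 0.05, ("BACKGROUND", "LEV"): 0.05,
    }


def _default_q_pro():
    return {"EXO": 0.05, "ECTO": 0.15, "SHARED": 0.10, "BACKGROUND": 0.05}


def _default_q_eu():
    return {"EXO": 0.5, "ECTO": 0.3, "SHARED": 0.4, "BACKGROUND": 0.2}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic meta-study (all rates per class)."""

    n_sev_datasets: int = 30
    n_lev_datasets: int = 30
    n_excluded_datasets: int = 5
    n_proteins: int = 2000
    class_proportions: dict = field(default_factory=_default_proportions)
    p_ident: dict = field(default_factory=_default_p_ident)
    q_pro: dict = field(default_factory=_default_q_pro)
    q_eu: dict = field(default_factory=_default_q_eu)
    n_pro_datasets: int = 141
    n_eu_datasets: int = 656
    within_class_edge_prob: float = 0.008
    between_class_edge_prob: float = 0.004
    n_seed_hubs: int = 3  # per side (EXO-side and ECTO-side)
    hub_within_prob: float = 0.8
    hub_degree: int = 60
    n_planted_sets: int = 2
    n_decoy_sets: int = 8
    set_size: int = 50
    rng_seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        probs = (
            list(self.p_ident.values())
            + list(self.q_pro.values())
            + list(self.q_eu.values())
            + [self.within_class_edge_prob, self.between_class_edge_prob,
               self.hub_within_prob]
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if min(self.n_sev_datasets, self.n_lev_datasets, self.n_proteins) <= 0:
            raise ValueError("dataset and protein counts must be positive")


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    protocols: list
    dataset_truth: pd.DataFrame  # dataset_id, intended label
    identifications: pd.DataFrame  # dataset_id, protein_id
    conservation: pd.DataFrame  # protein_id, ic_pro, ic_eu
    edges: pd.DataFrame  # bait, prey, assay
    gene_sets: dict
    protein_class: pd.Series  # protein_id -> class
    hub_truth: pd.DataFrame  # protein_id, side
    set_truth: pd.DataFrame  # set_name, planted, side


def _sample_protocols(cfg: SyntheticConfig, rng: np.random.Generator):
    records, truth = [], []

    def add(ds_id, label, preclear, pellet):
        steps = (
            CentrifugationStep(1, float(preclear), Role.PRECLEAR),
            CentrifugationStep(2, float(pellet), Role.PELLET),
        )
        records.append(ProtocolRecord(dataset_id=ds_id, species="human", steps=steps))
        truth.append((ds_id, label))

    for i in range(cfg.n_sev_datasets):
        add(f"SEV{i:03d}", "SEV",
            rng.uniform(10_000, 20_000), rng.uniform(100_000, 200_000))
    for i in range(cfg.n_lev_datasets):
        add(f"LEV{i:03d}", "LEV",
            rng.uniform(500, 9_000), rng.uniform(10_000, 20_000))
    for i in range(cfg.n_excluded_datasets):
        # pellet speed in the window both rules reject
        add(f"EXC{i:03d}", "EXCLUDED",
            rng.uniform(500, 9_000), rng.uniform(20_001, 99_999))
    return records, pd.DataFrame(truth, columns=["dataset_id", "label"])


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a complete synthetic meta-study; fully determined by rng_seed."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    protocols, ds_truth = _sample_protocols(config, rng)
    protein_ids = np.array([f"P{i:05d}" for i in range(config.n_proteins)])
    classes = rng.choice(
        CLASSES, size=config.n_proteins,
        p=[config.class_proportions[c] for c in CLASSES],
    )
    protein_class = pd.Series(classes, index=protein_ids, name="class")
    protein_class.index.name = "protein_id"

    # identification matrix: Bernoulli(p_ident(class, fraction)); excluded
    # datasets identify at the class-mean rate so downstream dropping is exercised
    rows = []
    for ds_id, label in ds_truth.itertuples(index=False):
        if label == "EXCLUDED":
            p = np.array([
                (config.p_ident[(c, "SEV")] + config.p_ident[(c, "LEV")]) / 2
                for c in classes
            ])
        else:
            p = np.array([config.p_ident[(c, label)] for c in classes])
        hit = rng.random(config.n_proteins) < p
        for pid in protein_ids[hit]:
            rows.append((ds_id, pid))
    identifications = pd.DataFrame(rows, columns=["dataset_id", "protein_id"])

    conservation = pd.DataFrame({
        "protein_id": protein_ids,
        "ic_pro": rng.binomial(
            config.n_pro_datasets, [config.q_pro[c] for c in classes]),
        "ic_eu": rng.binomial(
            config.n_eu_datasets, [config.q_eu[c] for c in classes]),
    })

    edges = _sample_interactome(config, rng, protein_ids, classes)
    hub_truth = edges.attrs["hub_truth"]

    gene_sets, set_truth = _sample_gene_sets(config, rng, protein_ids, classes)

    return SyntheticStudy(
        config=config, protocols=protocols, dataset_truth=ds_truth,
        identifications=identifications, conservation=conservation,
        edges=edges, gene_sets=gene_sets, protein_class=protein_class,
        hub_truth=hub_truth, set_truth=set_truth,
    )


def _sample_interactome(cfg, rng, protein_ids, classes) -> pd.DataFrame:
    order = np.argsort(classes, kind="stable")  # group nodes by class for the SBM
    sizes, block_ids = [], []
    for c in sorted(set(classes)):
        members = order[classes[order] == c]
        sizes.append(len(members))
        block_ids.append(members)
    flat = np.concatenate(block_ids)
    n_blocks = len(sizes)
    probs = [
        [cfg.within_class_edge_prob if i == j else cfg.between_class_edge_prob
         for j in range(n_blocks)]
        for i in range(n_blocks)
    ]
    g = nx.stochastic_block_model(sizes, probs, seed=int(rng.integers(2**31)))
    pairs = [(protein_ids[flat[u]], protein_ids[flat[v]]) for u, v in g.edges]

    # recruiter hubs: EXO-class hubs seed the sEV side, ECTO-class the lEV side
    hub_rows = []
    for cls, side in (("EXO", "SEV"), ("ECTO", "LEV")):
        members = protein_ids[classes == cls]
        others = protein_ids[classes != cls]
        hubs = rng.choice(members, size=min(cfg.n_seed_hubs, len(members)), replace=False)
        for hub in hubs:
            hub_rows.append((hub, side))
            within = rng.random(cfg.hub_degree) < cfg.hub_within_prob
            # clamp to the available pools at small study sizes
            n_within = min(int(within.sum()), len(members) - 1)
            n_cross = min(cfg.hub_degree - n_within, len(others))
            nbrs = np.concatenate([
                rng.choice(members[members != hub], size=n_within, replace=False),
                rng.choice(others, size=n_cross, replace=False),
            ])
            pairs.extend((hub, n) for n in nbrs)

    assay = np.where(rng.random(len(pairs)) < 0.5, "APMS", "Y2H")
    edges = pd.DataFrame(pairs, columns=["bait", "prey"])
    edges["assay"] = assay
    edges.attrs["hub_truth"] = pd.DataFrame(hub_rows, columns=["protein_id", "side"])
    return edges


def _sample_gene_sets(cfg, rng, protein_ids, classes):
    gene_sets, truth = {}, []
    for i in range(cfg.n_planted_sets):
        cls, side = (("EXO", "SEV"), ("ECTO", "LEV"))[i % 2]
        members = protein_ids[classes == cls]
        if cfg.set_size > len(members):
            raise ValueError(f"set_size {cfg.set_size} exceeds {cls} class size {len(members)}")
        name = f"PLANTED_{side}_{i:02d}"
        gene_sets[name] = list(rng.choice(members, size=cfg.set_size, replace=False))
        truth.append((name, True, side))
    for i in range(cfg.n_decoy_sets):
        name = f"DECOY_{i:02d}"
        gene_sets[name] = list(rng.choice(protein_ids, size=cfg.set_size, replace=False))
        truth.append((name, False, "NONE"))
    return gene_sets, pd.DataFrame(truth, columns=["set_name", "planted", "side"])


def truth_table(study: SyntheticStudy) -> pd.DataFrame:
    """Flat ground-truth export: one row per protein, hub, and gene set."""
    prot = pd.DataFrame({
        "id": study.protein_class.index,
        "kind": "protein",
        "truth": study.protein_class.to_numpy(),
    })
    hubs = pd.DataFrame({
        "id": study.hub_truth["protein_id"],
        "kind": "hub",
        "truth": study.hub_truth["side"],
    })
    sets = pd.DataFrame({
        "id": study.set_truth["set_name"],
        "kind": "gene_set",
        "truth": np.where(study.set_truth["planted"],
                          "PLANTED_" + study.set_truth["side"], "DECOY"),
    })
    return pd.concat([prot, hubs, sets], ignore_index=True)


def write_study(study: SyntheticStudy, outdir) -> dict[str, Path]:
    """Write the five pipeline input files plus truth tables as TSV/GMT."""
    from .protocols import protocols_to_frame
    from .enrichment import write_gmt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "protocols": out / "protocols.tsv",
        "identifications": out / "identifications.tsv",
        "conservation": out / "conservation.tsv",
        "edges": out / "edges.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "truth.tsv",
    }
    protocols_to_frame(study.protocols).to_csv(paths["protocols"], sep="\t", index=False)
    study.identifications.to_csv(paths["identifications"], sep="\t", index=False)
    study.conservation.to_csv(paths["conservation"], sep="\t", index=False)
    study.edges.to_csv(paths["edges"], sep="\t", index=False)
    write_gmt(study.gene_sets, paths["gene_sets"])
    truth_table(study).to_csv(paths["truth"], sep="\t", index=False)
    return paths
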