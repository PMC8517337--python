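"""Evolutionary-conservation comparison of sEV- vs lEV-enriched proteins.

Conservation of a human EV protein is measured by how many prokaryotic (IC_pro)
and eukaryotic (IC_eu) EV proteomic datasets identified one of its orthologs
(ortholog grouping is precomputed upstream). Because ectosome budding from the
plasma membrane is shared with prokaryotes while exosome biogenesis through the
endomembrane system is eukaryote-specific, the expectation is higher IC_pro for
lEV-enriched proteins and higher IC_eu for sEV-enriched ones. Groups are
compared with a Mann-Whitney U test on raw counts (rank tests are invariant to
the fixed per-kingdom normalisations IC_pro/141 and IC_eu/656, which are still
emitted for plotting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .frequency import PartitionClass, mann_whitney

logger = logging.getLogger(__name__)

#: total prokaryotic / eukaryotic EV dataset counts used for normalised ICs
N_PRO_DATASETS = 141
N_EU_DATASETS = 656


@dataclass(frozen=True)
class ConservationComparison:
    side: str  # "IC_PRO" or "IC_EU"
    n_sev: int
    n_lev: int
    U: float
    p: float
    direction: str  # "SEV", "LEV" or "NONE": which enriched group has greater median


def attach_conservation(
    stats: pd.DataFrame,
    records: pd.DataFrame,
    n_pro_datasets: int = N_PRO_DATASETS,
    n_eu_datasets: int = N_EU_DATASETS,
) -> pd.DataFrame:
    """Left-join ortholog identification counts onto the protein stats table.

    ``records`` needs columns protein_id, ic_pro, ic_eu. Proteins without a
    conservation record keep NaN ICs (logged) and are excluded from tests;
    absence of ortholog data is not evidence of an IC of zero. Normalised
    columns ``ic_pro_norm`` and ``ic_eu_norm`` are added for plotting parity.
    """
    rec = records.copy()
    rec["protein_id"] = rec["protein_id"].astype(str)
    if rec["protein_id"].duplicated().any():
        dupes = rec.loc[rec["protein_id"].duplicated(), "protein_id"].unique()
        raise ValueError(f"duplicate protein_id in conservation records: {list(dupes[:5])}")
    bad = rec[(rec["ic_pro"] > n_pro_datasets) | (rec["ic_eu"] > n_eu_datasets)]
    if len(bad):
        raise ValueError("identification counts exceed dataset totals")
    joined = stats.join(rec.set_index("protein_id")[["ic_pro", "ic_eu"]], how="left")
    n_missing = int(joined["ic_pro"].isna().sum())
    if n_missing:
        logger.info("%d protein(s) lack conservation records; excluded from tests", n_missing)
    joined["ic_pro_norm"] = joined["ic_pro"] / n_pro_datasets
    joined["ic_eu_norm"] = joined["ic_eu"] / n_eu_datasets
    return joined


def conservation_compare(
    joined: pd.DataFrame, partition: pd.Series
) -> dict[str, ConservationComparison]:
    """Mann-Whitney comparison of IC distributions between enriched groups.

    Compares SEV_ENRICHED vs LEV_ENRICHED proteins (BALANCED excluded) for
    each of IC_pro and IC_eu; proteins with missing ICs are dropped listwise.
    Returns {"IC_PRO": ..., "IC_EU": ...}.
    """
    out: dict[str, ConservationComparison] = {}
    for side, col in (("IC_PRO", "ic_pro"), ("IC_EU", "ic_eu")):
        sev = joined.loc[
            (partition == PartitionClass.SEV_ENRICHED.value) & joined[col].notna(), col
        ].to_numpy()
        lev = joined.loc[
            (partition == PartitionClass.LEV_ENRICHED.value) & joined[col].notna(), col
        ].to_numpy()
        if sev.size == 0 or lev.size == 0:
            raise ValueError(
                f"{side}: both enriched groups need conservation data "
                f"(n_sev={sev.size}, n_lev={lev.size})"
            )
        u, p = mann_whitney(sev, lev)
        med_s, med_l = float(pd.Series(sev).median()), float(pd.Series(lev).median())
        if med_s > med_l:
            direction = "SEV"
        elif med_l > med_s:
            direction = "LEV"
        else:
            # medians tie: fall back to the rank statistic, NONE on exact balance
            mu = sev.size * lev.size / 2.0
            direction = "SEV" if u > mu else ("LEV" if u < mu else "NONE")
        out[side] = ConservationComparison(
            side=side, n_sev=int(sev.size), n_lev=int(lev.size), U=u, p=p,
            direction=direction,
        )
    return out


def read_conservation(path) -> pd.DataFrame:
    """Read a conservation TSV with columns protein_id, ic_pro, ic_eu."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = {"protein_id", "ic_pro", "ic_eu"} - set(df.columns)
    if missing:
        raise ValueError(f"conservation table missing columns: {sorted(missing)}")
    return df
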