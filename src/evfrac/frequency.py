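"""Presence/absence identification-frequency statistics for sEV vs lEV datasets.

Each protein's identification frequency in a fraction is the number of
datasets of that fraction in which it was identified, divided by the number of
datasets of the fraction: fsEV = k_sev / n_sev and flEV = k_lev / n_lev. The
per-protein effect measure is log2(fsEV/flEV); zero counts are handled by a
Haldane-Anscombe-style smoothing (+0.5 to counts, +1 to totals) so the ratio
is always finite. Differential identification is tested per protein with
Fisher's exact test (BH-corrected across proteins), marker panels are compared
with a Mann-Whitney U test, and proteins are partitioned into sEV-enriched /
lEV-enriched / balanced at a configurable |log2 ratio| threshold (default 0.1).
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .protocols import Label

logger = logging.getLogger(__name__)

#: default |log2(fsEV/flEV)| partition threshold
DEFAULT_THETA = 0.1
#: per-group size at or below which the Mann-Whitney p is computed by full enumeration
MWU_EXACT_MAX_N = 8


class PartitionClass(str, enum.Enum):
    SEV_ENRICHED = "SEV_ENRICHED"
    LEV_ENRICHED = "LEV_ENRICHED"
    BALANCED = "BALANCED"


@dataclass(frozen=True)
class MarkerPanel:
    """A literature-surveyed marker panel for one EV side."""

    name: str
    side: str  # "EXOSOME" or "ECTOSOME"
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError("marker panel must be non-empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError("marker panel members must be unique")


@dataclass(frozen=True)
class PresenceMatrix:
    """Boolean dataset x protein identification matrix with fraction labels.

    ``cells`` is indexed by dataset_id (rows) and protein_id (columns);
    ``labels`` maps every row to SEV or LEV. EXCLUDED datasets never enter.
    """

    cells: pd.DataFrame
    labels: pd.Series

    @property
    def n_sev(self) -> int:
        return int((self.labels == Label.SEV.value).sum())

    @property
    def n_lev(self) -> int:
        return int((self.labels == Label.LEV.value).sum())


def build_presence_matrix(
    identifications: pd.DataFrame, labels: pd.DataFrame
) -> PresenceMatrix:
    """Pivot a long (dataset_id, protein_id) table into a labelled boolean matrix.

    Duplicate identifications within a dataset collapse to a single TRUE cell.
    EXCLUDED datasets are dropped with a logged count; a dataset id missing
    from the label table is an error. Proteins identified in no retained
    dataset are dropped.
    """
    ident = identifications[["dataset_id", "protein_id"]].astype(str).drop_duplicates()
    lab = labels.set_index(labels["dataset_id"].astype(str))["label"]
    if lab.index.has_duplicates:
        raise ValueError("duplicate dataset_id in label table")
    unlabeled = sorted(set(ident["dataset_id"]) - set(lab.index))
    if unlabeled:
        raise ValueError(f"unlabeled dataset id(s): {unlabeled[:5]}")

    keep_ids = lab[lab.isin([Label.SEV.value, Label.LEV.value])].index
    n_dropped = ident["dataset_id"].nunique() - ident["dataset_id"].isin(keep_ids).groupby(
        ident["dataset_id"]
    ).first().sum()
    dropped_sets = set(ident["dataset_id"]) - set(keep_ids)
    if dropped_sets:
        logger.info("dropped %d EXCLUDED dataset(s) from presence matrix", len(dropped_sets))
    ident = ident[ident["dataset_id"].isin(keep_ids)]
    if ident.empty:
        raise ValueError("no labelled (SEV/LEV) identifications remain")

    cells = (
        ident.assign(v=True)
        .pivot_table(index="dataset_id", columns="protein_id", values="v", fill_value=False)
        .astype(bool)
    )
    # keep every labelled dataset as a row even if it identified nothing that survived
    all_kept = [d for d in lab.index if d in set(keep_ids) and d in set(ident["dataset_id"])]
    cells = cells.reindex(index=all_kept, fill_value=False)
    return PresenceMatrix(cells=cells, labels=lab.loc[cells.index])


def compute_frequencies(matrix: PresenceMatrix) -> pd.DataFrame:
    """Per-protein counts, frequencies and log2 frequency ratios.

    Returns a DataFrame indexed by protein_id with columns ``k_sev, k_lev,
    n_sev, n_lev, f_sev, f_lev, log2_ratio_raw, log2_ratio, ic_human``.
    ``log2_ratio`` uses the smoothing log2(((k_sev+0.5)/(n_sev+1)) /
    ((k_lev+0.5)/(n_lev+1))); ``log2_ratio_raw`` is NaN when either frequency
    is zero. ``ic_human`` is the total identification count across retained
    human datasets (k_sev + k_lev).
    """
    n_sev, n_lev = matrix.n_sev, matrix.n_lev
    if n_sev < 1 or n_lev < 1:
        raise ValueError(
            f"both fractions must be represented (n_sev={n_sev}, n_lev={n_lev})"
        )
    sev_rows = matrix.labels == Label.SEV.value
    k_sev = matrix.cells.loc[sev_rows].sum(axis=0).astype(int)
    k_lev = matrix.cells.loc[~sev_rows].sum(axis=0).astype(int)
    f_sev = k_sev / n_sev
    f_lev = k_lev / n_lev
    smoothed = np.log2(((k_sev + 0.5) / (n_sev + 1)) / ((k_lev + 0.5) / (n_lev + 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.log2(f_sev / f_lev)
    raw = raw.where((f_sev > 0) & (f_lev > 0))
    out = pd.DataFrame(
        {
            "k_sev": k_sev,
            "k_lev": k_lev,
            "n_sev": n_sev,
            "n_lev": n_lev,
            "f_sev": f_sev,
            "f_lev": f_lev,
            "log2_ratio_raw": raw,
            "log2_ratio": smoothed,
            "ic_human": (k_sev + k_lev).astype(int),
        }
    )
    out.index.name = "protein_id"
    return out


def fisher_differential(stats: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Fisher exact test per protein, BH-corrected across the table.

    Tests the 2x2 table [[k_sev, n_sev-k_sev], [k_lev, n_lev-k_lev]]; adds
    ``fisher_p`` and ``fisher_q`` columns.
    """
    out = stats.copy()
    ps = np.empty(len(out))
    cache: dict[tuple[int, int, int, int], float] = {}
    for i, (ks, kl, ns, nl) in enumerate(
        zip(out["k_sev"], out["k_lev"], out["n_sev"], out["n_lev"])
    ):
        key = (int(ks), int(kl), int(ns), int(nl))
        p = cache.get(key)
        if p is None:
            p = sps.fisher_exact(
                [[key[0], key[2] - key[0]], [key[1], key[3] - key[1]]],
                alternative="two-sided",
            ).pvalue
            cache[key] = p
        ps[i] = p
    out["fisher_p"] = ps
    out["fisher_q"] = multipletests(ps, method="fdr_bh")[1] if len(ps) else ps
    return out


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: #(x_i > y_j) + 0.5 #(x_i == y_j)."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U with an exact small-sample path.

    For min(len(x), len(y)) <= 8 with no cross-group ties the two-sided p is
    computed by enumerating all C(n+m, n) group assignments of the pooled
    values and measuring |U - nm/2| >= |u_obs - nm/2|. Otherwise scipy's
    tie-corrected normal approximation is used. Returns (U_x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _u_statistic(x, y)
    n, m = x.size, y.size
    cross_ties = bool(np.intersect1d(x, y).size)
    if min(n, m) <= MWU_EXACT_MAX_N and not cross_ties:
        pooled = np.concatenate([x, y])
        mu = n * m / 2.0
        d_obs = abs(u_obs - mu)
        total = 0
        extreme = 0
        for idx in itertools.combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= d_obs - 1e-12:
                extreme += 1
        return u_obs, extreme / total
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def marker_panel_report(
    stats: pd.DataFrame, panels: list[MarkerPanel]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marker-level frequencies and panel-level Mann-Whitney tests.

    For every panel member present in ``stats`` the report carries f_sev,
    f_lev, log2_ratio and fisher_p; absent members are flagged missing. The
    panel test compares the member frequencies between fractions (the f_sev
    values of the members against their f_lev values).

    Returns (per-marker report, per-panel test table).
    """
    marker_rows, panel_rows = [], []
    for panel in panels:
        present = [m for m in panel.members if m in stats.index]
        if not present:
            raise ValueError(f"panel {panel.name!r} has no overlap with the stats table")
        for m in panel.members:
            if m in stats.index:
                row = stats.loc[m]
                marker_rows.append(
                    (panel.name, panel.side, m, False, row["f_sev"], row["f_lev"],
                     row["log2_ratio"], row.get("fisher_p", np.nan))
                )
            else:
                marker_rows.append(
                    (panel.name, panel.side, m, True, np.nan, np.nan, np.nan, np.nan)
                )
        fs = stats.loc[present, "f_sev"].to_numpy()
        fl = stats.loc[present, "f_lev"].to_numpy()
        u, p = mann_whitney(fs, fl)
        panel_rows.append((panel.name, panel.side, len(present), u, p))
    markers = pd.DataFrame(
        marker_rows,
        columns=["panel", "side", "protein_id", "missing", "f_sev", "f_lev",
                 "log2_ratio", "fisher_p"],
    )
    tests = pd.DataFrame(panel_rows, columns=["panel", "side", "n_present", "U", "p"])
    return markers, tests


def partition_by_ratio(stats: pd.DataFrame, theta: float = DEFAULT_THETA) -> pd.Series:
    """Partition proteins by smoothed log2 ratio: > theta sEV, < -theta lEV, else balanced."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    r = stats["log2_ratio"]
    part = pd.Series(PartitionClass.BALANCED.value, index=stats.index, name="partition")
    part[r > theta] = PartitionClass.SEV_ENRICHED.value
    part[r < -theta] = PartitionClass.LEV_ENRICHED.value
    return part


def load_default_marker_panels(path=None) -> list[MarkerPanel]:
    """The bundled literature marker panels (10 exosomal + 10 ectosomal symbols)."""
    from importlib.resources import files

    src = path if path is not None else files("evfrac.data") / "marker_panels.tsv"
    df = pd.read_csv(src, sep="\t")
    panels = []
    for (name, side), grp in df.groupby(["panel", "side"], sort=False):
        panels.append(MarkerPanel(name=name, side=side, members=tuple(grp["protein_id"])))
    return panels
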