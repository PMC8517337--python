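"""Preranked gene-set enrichment analysis (weighted KS, gene-set permutation).

Two ranked lists drive the analysis: (i) all proteins ordered by the smoothed
log2(fsEV/flEV) ratio, positive pole = sEV, and (ii) the "balanced" proteins
(|log2 ratio| <= 0.1) ordered by mean-centred human identification count. For
a gene set S in a ranked list of N genes, a running sum increases by
|score_i|^w / sum_{hits}|score|^w at members and decreases by 1/(N-|S|) at
non-members; the enrichment score ES is the signed deviation of largest
magnitude. Significance comes from a gene-set permutation null (random
equal-size member sets), NES normalises ES by the mean same-sign null
magnitude, and the FDR is the sign-stratified ratio-of-tails estimator over
pooled null NES values, clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RankedList:
    """Genes with scores in deterministic order: score descending, then id ascending."""

    entries: pd.Series  # index protein_id, values score, already ordered

    def __post_init__(self):
        if self.entries.index.has_duplicates:
            raise ValueError("ranked list ids must be unique")
        if len(self.entries) < 2:
            raise ValueError("ranked list needs >= 2 entries")

    @property
    def ids(self) -> np.ndarray:
        return self.entries.index.to_numpy()

    @property
    def scores(self) -> np.ndarray:
        return self.entries.to_numpy(dtype=float)


def _ordered(series: pd.Series) -> pd.Series:
    df = series.rename("score").rename_axis("id").reset_index()
    df = df.sort_values(["score", "id"], ascending=[False, True], kind="mergesort")
    return df.set_index("id")["score"]


def rank_by_ratio(stats: pd.DataFrame) -> RankedList:
    """Rank all proteins by smoothed log2(fsEV/flEV), sEV-enriched first."""
    return RankedList(_ordered(stats["log2_ratio"].astype(float)))


def rank_balanced_by_abundance(stats: pd.DataFrame, theta: float = 0.1) -> RankedList:
    """Rank the balanced proteins (|log2 ratio| <= theta) by centred ic_human."""
    sub = stats.loc[stats["log2_ratio"].abs() <= theta]
    if sub.empty:
        raise ValueError(f"no protein satisfies |log2_ratio| <= {theta}")
    score = sub["ic_human"].astype(float)
    return RankedList(_ordered(score - score.mean()))


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file (name <tab> description <tab> members...) into a dict."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            if parts[0] in sets:
                raise ValueError(f"duplicate gene-set name {parts[0]!r}")
            members = list(dict.fromkeys(m for m in parts[2:] if m))
            if members:
                sets[parts[0]] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def enrichment_score(
    ranked: RankedList, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray, int]:
    """Weighted KS enrichment score with the full running-sum profile.

    Returns ``(es, running, extremum_index)`` where ``running`` has length N.
    ``weight`` is the exponent on |score| for hit increments; 0 recovers the
    classic unweighted KS statistic.
    """
    ids = ranked.ids
    hit = np.isin(ids, list(gene_set))
    k = int(hit.sum())
    n = len(ids)
    if k == 0:
        raise ValueError("gene set has no member in the ranked list")
    if k == n:
        raise ValueError("gene set covers the whole ranked list")
    w = np.abs(ranked.scores) ** weight
    w_hit = np.where(hit, w, 0.0)
    sum_w = w_hit.sum()
    if sum_w == 0:  # all member scores are exactly 0: fall back to equal weights
        w_hit = hit.astype(float)
        sum_w = float(k)
    running = np.cumsum(w_hit / sum_w - (~hit) / (n - k))
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), running, idx


def _es_only(order_w: np.ndarray, positions: np.ndarray, n: int) -> float:
    """ES from sorted hit positions; O(k) given precomputed |score|^w array."""
    positions = np.sort(positions)
    k = positions.size
    w = order_w[positions]
    sw = w.sum()
    if sw == 0:
        w = np.ones(k)
        sw = float(k)
    cum = np.cumsum(w) / sw
    miss = (positions - np.arange(k)) / (n - k)  # misses before each hit
    after = cum - miss
    before = np.concatenate(([0.0], cum[:-1])) - miss
    hi = after.max()
    lo = min(before.min(), 0.0)
    return float(hi if hi >= -lo else lo)


@dataclass
class GseaResult:
    table: pd.DataFrame
    leading_edges: dict[str, list[str]] = field(default_factory=dict)


def gsea_preranked(
    ranked: RankedList,
    collection: dict[str, list[str]],
    n_perm: int = 1000,
    min_size: int = 5,
    max_size: int = 500,
    weight: float = 1.0,
    seed: int | None = None,
) -> GseaResult:
    """Preranked GSEA over a gene-set collection.

    Sets are intersected with the ranked ids and filtered to
    ``[min_size, max_size]``. The null is a gene-set permutation: for each set
    size, random member sets of that size drawn from the ranked ids. p_perm is
    one-sided against the same-sign null with a +1 correction; nes divides es
    by the mean |null es| of the same sign; fdr_q is the sign-stratified
    ratio-of-tails estimator over pooled null NES. Fully reproducible given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    ids = ranked.ids
    n = len(ids)
    order_w = np.abs(ranked.scores) ** weight
    id_pos = {g: i for i, g in enumerate(ids)}

    used: dict[str, np.ndarray] = {}
    for name in sorted(collection):
        pos = np.array(sorted(id_pos[g] for g in set(collection[name]) if g in id_pos),
                       dtype=int)
        if min_size <= pos.size <= max_size and pos.size < n:
            used[name] = pos
    if not used:
        raise ValueError("no gene set passes the size filter")

    # one shared null per distinct set size
    null_by_size: dict[int, np.ndarray] = {}
    for k in sorted({p.size for p in used.values()}):
        null = np.empty(n_perm)
        for j in range(n_perm):
            null[j] = _es_only(order_w, rng.choice(n, size=k, replace=False), n)
        null_by_size[k] = null

    rows = []
    leading: dict[str, list[str]] = {}
    all_null_nes: list[np.ndarray] = []
    for name, pos in used.items():
        es, running, idx = enrichment_score(ranked, set(ids[pos]), weight=weight)
        null = null_by_size[pos.size]
        if es >= 0:
            same = null[null >= 0]
            p_perm = (np.sum(same >= es) + 1) / (same.size + 1)
        else:
            same = null[null < 0]
            p_perm = (np.sum(same <= es) + 1) / (same.size + 1)
        mean_same = np.abs(same).mean() if same.size else np.nan
        nes = es / mean_same if same.size else np.nan
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        null_nes = np.concatenate([
            pos_null / pos_null.mean() if pos_null.size else pos_null,
            neg_null / np.abs(neg_null).mean() if neg_null.size else neg_null,
        ])
        all_null_nes.append(null_nes)
        hit_mask = np.zeros(n, dtype=bool)
        hit_mask[pos] = True
        if es >= 0:
            le = [g for g in ids[: idx + 1] if hit_mask[id_pos[g]]]
        else:
            le = [g for g in ids[idx:] if hit_mask[id_pos[g]]]
        leading[name] = le
        rows.append((name, pos.size, es, nes, p_perm, len(le)))

    table = pd.DataFrame(
        rows, columns=["set_name", "size_used", "es", "nes", "p_perm", "n_leading_edge"]
    )
    pooled = np.concatenate(all_null_nes)
    obs = table["nes"].to_numpy()
    fdr = np.empty(len(table))
    for i, v in enumerate(obs):
        if np.isnan(v):
            fdr[i] = np.nan
            continue
        if v >= 0:
            num_pool = pooled[pooled >= 0]
            num = np.mean(num_pool >= v) if num_pool.size else 0.0
            obs_side = obs[obs >= 0]
            den = np.mean(obs_side >= v)
        else:
            num_pool = pooled[pooled < 0]
            num = np.mean(num_pool <= v) if num_pool.size else 0.0
            obs_side = obs[obs < 0]
            den = np.mean(obs_side <= v)
        fdr[i] = min(1.0, num / den) if den > 0 else 1.0
    table["fdr_q"] = fdr
    table = table.sort_values(["fdr_q", "p_perm", "set_name"]).reset_index(drop=True)
    return GseaResult(table=table, leading_edges=leading)


def jaccard_overlap_edges(
    collection: dict[str, list[str]], names: list[str], threshold: float = 0.5
) -> pd.DataFrame:
    """Pairwise Jaccard-overlap edges between the named sets (for external viewers)."""
    rows = []
    sets = {nm: set(collection[nm]) for nm in names if nm in collection}
    names = sorted(sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = len(sets[a] & sets[b])
            union = len(sets[a] | sets[b])
            j = inter / union if union else 0.0
            if j >= threshold:
                rows.append((a, b, j))
    return pd.DataFrame(rows, columns=["set_a", "set_b", "jaccard"])
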