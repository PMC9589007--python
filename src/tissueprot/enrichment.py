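"""Dual preranked gene-set enrichment with consensus, over-representation,
and the enrichment-map graph.

Two independent methods score each gene set against the pi-value-ranked
protein list:

* a competitive parametric test (camera-style): the set's mean statistic is
  compared with the rest via a two-sample t-test whose set variance is
  inflated by VIF = 1 + (m - 1) * rho to account for inter-gene correlation
  rho (default 0.01, the preranked default);
* permutation preranked GSEA: the weighted Kolmogorov-Smirnov running sum
  (hits add |stat|^w / sum_set |stat|^w, misses subtract 1/(G - m)) gives the
  enrichment score ES; the null is n_perm random same-size gene sets, with
  the permutation p computed among same-sign null scores and NES = ES over
  the mean same-sign |null ES|.

A set is *consensus-enriched* when both methods reach q < alpha (q-values
computed per method across its own sets) with the same direction of change.
Tissue-specific / tissue-shared protein groups are additionally tested by
hypergeometric over-representation against their stated backgrounds, and
consensus sets are assembled into a similarity graph whose edges carry the
fraction of shared proteins (overlap coefficient).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection
from .differential import fdr_adjust

__all__ = [
    "camera_pr",
    "gsea_preranked",
    "consensus",
    "hypergeom_ora",
    "build_enrichment_graph",
    "graph_to_json",
]

logger = logging.getLogger(__name__)


def _as_ranked(ranked: pd.Series | Mapping[str, float]) -> pd.Series:
    s = pd.Series(ranked, dtype=float)
    if not s.index.is_unique:
        raise ValueError("ranked list has duplicate gene names")
    return s.sort_values(ascending=False, kind="stable")


def camera_pr(
    ranked: pd.Series | Mapping[str, float],
    sets: GeneSetCollection,
    rho: float = 0.01,
) -> pd.DataFrame:
    """Competitive parametric preranked test with inter-gene correlation.

    For a set of size m among G ranked genes, the difference of means
    Delta = mean(stat_set) - mean(stat_rest) is referred to a t distribution
    on G - 2 df with pooled variance and the set's variance contribution
    inflated by VIF = 1 + (m - 1) * rho. Sets overlapping the ranked list in
    fewer than 2 genes are skipped.
    """
    s = _as_ranked(ranked)
    G = len(s)
    if G < 3:
        raise ValueError("need at least 3 ranked genes")
    stat = s.to_numpy()
    pos = {g: i for i, g in enumerate(s.index)}
    rows = []
    for set_name, members in sets.items():
        idx = np.array([pos[g] for g in members if g in pos], dtype=int)
        m = idx.size
        if m < 2:
            continue
        if m >= G:
            raise ValueError(f"set {set_name!r} covers the whole ranked list")
        in_set = np.zeros(G, dtype=bool)
        in_set[idx] = True
        x1, x2 = stat[in_set], stat[~in_set]
        delta = x1.mean() - x2.mean()
        sp2 = ((m - 1) * x1.var(ddof=1) + (G - m - 1) * x2.var(ddof=1)) / (G - 2)
        vif = 1.0 + (m - 1) * rho
        denom = np.sqrt(sp2 * (vif / m + 1.0 / (G - m)))
        t = 0.0 if denom == 0 else delta / denom
        p = 2.0 * stats.t.sf(abs(t), G - 2) if denom != 0 else 1.0
        rows.append(
            {
                "set": set_name,
                "size": m,
                "delta": delta,
                "t": t,
                "p": p,
                "direction": "up" if delta >= 0 else "down",
            }
        )
    return pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["size", "delta", "t", "p", "direction"]
    )


def _es_for_index_sets(
    absw: np.ndarray, idx_sorted: np.ndarray, G: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed maximum deviation of the running sum for each row of sorted
    rank positions. Returns (ES, argmax position, is_positive)."""
    B, m = idx_sorted.shape
    w = absw[idx_sorted]
    cw = np.cumsum(w, axis=1)
    nr = cw[:, -1].copy()
    flat = nr <= 0
    if flat.any():
        # all-zero statistics in the set: fall back to unweighted hits
        cw[flat] = np.arange(1, m + 1)
        nr[flat] = m
    j = np.arange(1, m + 1)
    if G == m:
        es = np.ones(B)
        return es, np.full(B, m - 1), np.ones(B, dtype=bool)
    miss = 1.0 / (G - m)
    # running sum just after hit j and just before hit j
    after = cw / nr[:, None] - (idx_sorted + 1 - j) * miss
    before = (cw - w) / nr[:, None] - (idx_sorted - (j - 1)) * miss
    hi = after.max(axis=1)
    hi_at = after.argmax(axis=1)
    lo = before.min(axis=1)
    lo_at = before.argmin(axis=1)
    # exact +/- ties are structural (e.g. adjacent mid-list hits); prefer the
    # positive excursion so float noise cannot flip the sign
    positive = (hi + lo) >= -1e-9
    es = np.where(positive, hi, lo)
    at = np.where(positive, hi_at, lo_at)
    return es, at, positive


def gsea_preranked(
    ranked: pd.Series | Mapping[str, float],
    sets: GeneSetCollection,
    n_perm: int = 10_000,
    weight: float = 1.0,
    min_size: int = 5,
    max_size: int = 300,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation preranked GSEA.

    Sets are intersected with the ranked list, then filtered to
    [min_size, max_size]. The permutation null for each set size is built
    once from ``n_perm`` random same-size gene sets against the same ranked
    list and shared by all sets of that size; p-values and NES are computed
    among same-sign null scores, so p saturates at 1 / (n_same_sign + 1).
    """
    s = _as_ranked(ranked)
    G = len(s)
    stat = s.to_numpy()
    absw = np.abs(stat) ** weight
    pos = {g: i for i, g in enumerate(s.index)}
    rng = np.random.default_rng(seed)

    surviving: dict[str, np.ndarray] = {}
    for set_name, members in sets.items():
        idx = np.sort(np.array([pos[g] for g in members if g in pos], dtype=int))
        if min_size <= idx.size <= max_size and idx.size < G:
            surviving[set_name] = idx
    if not surviving:
        logger.warning("no gene set survives the [%d, %d] size filter",
                       min_size, max_size)
        return pd.DataFrame(
            columns=["size", "ES", "NES", "p", "direction", "leading_edge"]
        )

    null_cache: dict[int, np.ndarray] = {}

    def null_es(m: int) -> np.ndarray:
        if m not in null_cache:
            u = rng.random((n_perm, G))
            picks = np.argpartition(u, m, axis=1)[:, :m]
            picks.sort(axis=1)
            es, _, _ = _es_for_index_sets(absw, picks, G)
            null_cache[m] = es
        return null_cache[m]

    rows = []
    for set_name, idx in surviving.items():
        m = idx.size
        es_arr, at_arr, pos_arr = _es_for_index_sets(absw, idx[None, :], G)
        es, at, is_pos = float(es_arr[0]), int(at_arr[0]), bool(pos_arr[0])
        null = null_es(m)
        same = null >= 0 if is_pos else null < 0
        n_same = int(same.sum())
        n_extreme = int((np.abs(null[same]) >= abs(es)).sum())
        p = (1 + n_extreme) / (1 + n_same)
        mean_null = float(np.abs(null[same]).mean()) if n_same else np.nan
        nes = es / mean_null if n_same and mean_null > 0 else np.nan
        # `at` indexes the extremal hit within the set's sorted hit positions
        if is_pos:
            leading = [str(s.index[i]) for i in idx[: at + 1]]
        else:
            leading = [str(s.index[i]) for i in idx[at:]]
        rows.append(
            {
                "set": set_name,
                "size": m,
                "ES": es,
                "NES": nes,
                "p": p,
                "direction": "up" if is_pos else "down",
                "leading_edge": leading,
            }
        )
    return pd.DataFrame(rows).set_index("set")


def gsea_es_bruteforce(
    ranked: pd.Series, members: Sequence[str], weight: float = 1.0
) -> float:
    """O(G) loop reference for the running-sum enrichment score."""
    s = _as_ranked(ranked)
    member_set = set(members)
    hits = np.array([g in member_set for g in s.index])
    m = int(hits.sum())
    G = len(s)
    absw = np.abs(s.to_numpy()) ** weight
    nr = absw[hits].sum()
    running, hi, lo = 0.0, 0.0, 0.0
    for i in range(G):
        if hits[i]:
            running += absw[i] / nr if nr > 0 else 1.0 / m
        else:
            running -= 1.0 / (G - m)
        hi = max(hi, running)
        lo = min(lo, running)
    # same tie-break as the vectorized path: positive wins equal magnitude
    return hi if (hi + lo) >= -1e-9 else lo


def consensus(
    camera_results: pd.DataFrame,
    gsea_results: pd.DataFrame,
    alpha: float = 0.05,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Intersect the two methods: consensus iff both q < alpha with the same
    direction of change. q-values are computed per method across its own
    sets before intersecting."""
    cam = camera_results.copy()
    gs = gsea_results.copy()
    if len(cam):
        cam["q"] = fdr_adjust(cam["p"].to_numpy(), method=fdr_method)
    else:
        cam["q"] = []
    if len(gs):
        gs["q"] = fdr_adjust(gs["p"].to_numpy(), method=fdr_method)
    else:
        gs["q"] = []
    shared = cam.index.intersection(gs.index)
    out = pd.DataFrame(index=shared)
    out["size"] = gs.loc[shared, "size"]
    out["camera_p"] = cam.loc[shared, "p"]
    out["camera_q"] = cam.loc[shared, "q"]
    out["camera_direction"] = cam.loc[shared, "direction"]
    out["ES"] = gs.loc[shared, "ES"]
    out["NES"] = gs.loc[shared, "NES"]
    out["gsea_p"] = gs.loc[shared, "p"]
    out["gsea_q"] = gs.loc[shared, "q"]
    out["gsea_direction"] = gs.loc[shared, "direction"]
    out["leading_edge"] = gs.loc[shared, "leading_edge"]
    same_dir = out["camera_direction"] == out["gsea_direction"]
    out["direction"] = out["gsea_direction"].where(same_dir, other="discordant")
    out["consensus"] = (
        (out["camera_q"] < alpha) & (out["gsea_q"] < alpha) & same_dir
    )
    return out


def hypergeom_ora(
    query: Sequence[str],
    sets: GeneSetCollection,
    background: Sequence[str],
    min_size: int = 5,
    max_size: int = 300,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query against a background.

    Sets are intersected with the background before the size filter; the
    upper-tail probability P(X >= k) is computed for overlap k between query
    and set within a background of N genes.
    """
    bg = set(background)
    offenders = sorted(set(query) - bg)
    if offenders:
        raise ValueError(f"query genes outside the background: {offenders[:10]}")
    q = set(query)
    N, n = len(bg), len(q)
    rows = []
    for set_name, members in sets.items():
        inter = set(members) & bg
        K = len(inter)
        if not min_size <= K <= max_size:
            continue
        k = len(q & inter)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": set_name, "set_size": K, "overlap": k, "p": p})
    if not rows:
        return pd.DataFrame(columns=["set_size", "overlap", "p", "q"])
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = fdr_adjust(out["p"].to_numpy(), method=fdr_method)
    return out


def build_enrichment_graph(
    consensus_table: pd.DataFrame,
    sets: GeneSetCollection,
    node_q: float = 0.01,
    threshold: float = 0.5,
) -> nx.Graph:
    """Enrichment map: nodes are consensus sets significant at ``node_q`` in
    both methods; edge weight is the overlap coefficient
    |A & B| / min(|A|, |B|), kept when >= threshold (and the sets share at
    least one gene)."""
    keep = consensus_table[
        consensus_table["consensus"]
        & (consensus_table["camera_q"] < node_q)
        & (consensus_table["gsea_q"] < node_q)
    ]
    graph = nx.Graph()
    for set_name, row in keep.iterrows():
        graph.add_node(
            set_name,
            size=int(row["size"]),
            direction=row["direction"],
            camera_q=float(row["camera_q"]),
            gsea_q=float(row["gsea_q"]),
        )
    names = list(graph.nodes)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sa, sb = set(sets[a]), set(sets[b])
            inter = len(sa & sb)
            if inter == 0:
                continue
            weight = inter / min(len(sa), len(sb))
            if weight >= threshold:
                graph.add_edge(a, b, similarity=weight)
    return graph


def graph_to_json(graph: nx.Graph) -> dict:
    """Node/edge list form importable by standard graph viewers."""
    return {
        "nodes": [{"id": n, **graph.nodes[n]} for n in graph.nodes],
        "edges": [
            {"source": a, "target": b, "similarity": d["similarity"]}
            for a, b, d in graph.edges(data=True)
        ],
    }
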