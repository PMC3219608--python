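"""Signed interaction networks and their summary statistics.

Interaction edges are called from the merged pair table at the calibrated
E-score cutoffs (boundary inclusive: E <= negative cutoff is aggravating,
E >= positive cutoff alleviating), optionally intersected with an FDR filter
on the empirical p-values.  On the resulting simple undirected graphs the
module computes bioprocess crosstalk enrichment per sign, per-gene degree
and exact normalized betweenness, and group contrasts (essential vs
non-essential) by Fisher ratio, rank-sum or KS tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .calibrate import AnnotationMap, bh_adjust, bioprocess_pair_enrichment

__all__ = [
    "call_interactions",
    "crosstalk_matrix",
    "topology_stats",
    "group_compare",
    "GroupCompareResult",
]

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["gene_a", "gene_b", "condition", "E", "p", "adj_p", "sign"]


def call_interactions(pairs: pd.DataFrame, cutoffs: tuple[float, float] = (-2.0, 2.0),
                      fdr_q: float = 0.05, apply_fdr: bool = True) -> pd.DataFrame:
    """Threshold the merged pair table into signed interaction edges.

    ``cutoffs`` is (negative, positive); an edge is emitted iff
    E <= negative or E >= positive, and (when ``apply_fdr``) its BH-adjusted
    empirical p across all testable pairs is <= ``fdr_q``.  An empty edge
    list is a valid outcome.
    """
    neg, pos = cutoffs
    if not (neg < 0 < pos):
        raise ValueError(f"cutoffs must straddle zero, got {cutoffs}")
    df = pairs.loc[np.isfinite(pairs["E"])].copy()
    df = df[~df.get("sign_conflict", pd.Series(False, index=df.index)).astype(bool)]
    if apply_fdr:
        if df["p"].isna().any():
            raise ValueError("p-values required for FDR filtering; attach them first")
        df["adj_p"] = bh_adjust(df["p"]) if len(df) else np.nan
        passed = df["adj_p"] <= fdr_q
    else:
        df["adj_p"] = np.nan
        passed = pd.Series(True, index=df.index)
    called = df[((df["E"] <= neg) | (df["E"] >= pos)) & passed].copy()
    called["sign"] = np.where(called["E"] <= neg, "aggravating", "alleviating")
    cols = [c for c in EDGE_COLUMNS if c in called.columns]
    return called[cols].reset_index(drop=True)


def crosstalk_matrix(edges: pd.DataFrame, universe: pd.DataFrame,
                     annotations: AnnotationMap, alpha: float = 0.05
                     ) -> dict[str, pd.DataFrame]:
    """Label-pair enrichment of aggravating and alleviating edges separately.

    ``universe`` is the testable pair table (annotated pairs with a defined
    E-score).  Returns {sign: enrichment frame} with significant cells
    flagged (BH-adjusted p <= alpha).
    """
    key_universe = universe.assign(
        _key=universe["gene_a"].str.cat(universe["gene_b"], sep="\x00"))
    out = {}
    for sign in ("aggravating", "alleviating"):
        sub = edges[edges["sign"] == sign] if len(edges) else edges
        edge_keys = set(sub["gene_a"].str.cat(sub["gene_b"], sep="\x00")) if len(sub) else set()
        mask = key_universe["_key"].isin(edge_keys).to_numpy()
        out[sign] = bioprocess_pair_enrichment(mask, universe, annotations, alpha=alpha)
    return out


def topology_stats(edges: pd.DataFrame) -> pd.DataFrame:
    """Per-gene degree and exact normalized betweenness centrality.

    Duplicate pair rows are merged into a simple undirected graph.
    Betweenness uses exact all-pairs shortest-path accumulation (unweighted)
    with the standard 2/((n-1)(n-2)) normalization.
    """
    g = nx.Graph()
    for rec in edges.itertuples(index=False):
        g.add_edge(rec.gene_a, rec.gene_b)
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=["gene", "degree", "betweenness"])
    bet = nx.betweenness_centrality(g, normalized=True)
    return pd.DataFrame({
        "gene": list(g.nodes),
        "degree": [g.degree(v) for v in g.nodes],
        "betweenness": [bet[v] for v in g.nodes],
    }).sort_values("gene").reset_index(drop=True)


@dataclass
class GroupCompareResult:
    test: str
    statistic: float
    pvalue: float
    detail: dict


def _pair_group(edges: pd.DataFrame, essential: dict[str, bool]) -> pd.Series:
    """A pair counts as essential when at least one member is essential."""
    ea = edges["gene_a"].map(essential)
    eb = edges["gene_b"].map(essential)
    return (ea.fillna(False) | eb.fillna(False))


def group_compare(data, groups: dict[str, bool], test: str = "wilcoxon",
                  value: str = "degree") -> GroupCompareResult:
    """Contrast essential vs non-essential genes (or gene pairs).

    test='fisher_ratio': ``data`` is an edge table; the 2x2 table of
    alleviating:aggravating counts for essential vs non-essential pairs is
    tested two-sided with Fisher's exact test.

    test='wilcoxon' / 'ks': ``data`` is a per-gene stats table (from
    :func:`topology_stats`); the ``value`` column's distribution is compared
    between groups by the two-sample rank-sum or Kolmogorov-Smirnov test
    (exact enumeration when both samples have <= 12 observations).
    """
    if test == "fisher_ratio":
        ess = _pair_group(data, groups)
        table = np.array([
            [int(((data["sign"] == "alleviating") & ess).sum()),
             int(((data["sign"] == "aggravating") & ess).sum())],
            [int(((data["sign"] == "alleviating") & ~ess).sum()),
             int(((data["sign"] == "aggravating") & ~ess).sum())],
        ])
        if table.sum(axis=1).min() == 0:
            raise ValueError("one of the groups has no edges")
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return GroupCompareResult("fisher_ratio", float(odds), float(p),
                                  {"table": table.tolist()})

    member = data["gene"].map(groups)
    if member.isna().any():
        missing = data.loc[member.isna(), "gene"].tolist()
        raise ValueError(f"genes without group label: {missing[:5]}")
    x = data.loc[member.astype(bool), value].to_numpy(dtype=float)
    y = data.loc[~member.astype(bool), value].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    exact = len(x) <= 12 and len(y) <= 12
    if test == "wilcoxon":
        if np.array_equal(np.sort(x), np.sort(y)):
            return GroupCompareResult("wilcoxon", float(len(x) * len(y) / 2), 1.0,
                                      {"n_x": len(x), "n_y": len(y)})
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact" if exact else "asymptotic")
        return GroupCompareResult("wilcoxon", float(res.statistic), float(res.pvalue),
                                  {"n_x": len(x), "n_y": len(y),
                                   "median_x": float(np.median(x)),
                                   "median_y": float(np.median(y))})
    if test == "ks":
        res = stats.ks_2samp(x, y, method="exact" if exact else "auto")
        return GroupCompareResult("ks", float(res.statistic), float(res.pvalue),
                                  {"n_x": len(x), "n_y": len(y)})
    raise ValueError(f"unknown test {test!r}")
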