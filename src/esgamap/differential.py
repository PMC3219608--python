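"""Condition-specific (differential) genetic interactions.

For every gene pair measured in both growth conditions the differential
score is dE = E_minimal - E_rich, so positive dE reads "more alleviating
under nutrient limitation".  Significance comes from an empirical null
built by condition-label recombination: within each screen row, rich and
minimal E-values of neutral cells (|E| < 4 robust SDs in both conditions)
are independently permuted and re-differenced, pooling ``null_size``
permutations.  Restricting to neutral cells keeps genuine interactions from
inflating the null; recombining across cells (rather than only swapping a
pair's own two labels) gives the pool enough distinct magnitudes for
FDR-scale p-values.  Under the null hypothesis of identical, independent
cells the recombined differences are exchangeable with the observed ones,
so the plus-one-corrected empirical p is calibrated by construction.

Differential pairs are classified from their per-condition calls at the
calibrated cutoffs into five classes (rich-/minimal-specific aggravating or
alleviating, and sign-flip), and per-bioprocess enrichment of differential
pairs is computed with the same Fisher + Benjamini-Hochberg machinery used
elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calibrate import AnnotationMap, bh_adjust
from .scoring import EScoreMatrix, _robust_scale

__all__ = [
    "DifferentialResult",
    "differential_scores",
    "classify_pair",
    "classify_and_enrich",
    "CLASS_TABLE",
]

#: Deterministic class for every per-condition call combination
#: (rich_call, minimal_call); neutral/neutral pairs are never emitted.
CLASS_TABLE = {
    ("aggravating", "neutral"): "rich-specific-aggravating",
    ("alleviating", "neutral"): "rich-specific-alleviating",
    ("neutral", "aggravating"): "minimal-specific-aggravating",
    ("neutral", "alleviating"): "minimal-specific-alleviating",
    ("aggravating", "alleviating"): "sign-flip",
    ("alleviating", "aggravating"): "sign-flip",
    ("aggravating", "aggravating"): "concordant-aggravating",
    ("alleviating", "alleviating"): "concordant-alleviating",
}

#: Classes reported as differential interactions.
DIFFERENTIAL_CLASSES = (
    "minimal-specific-aggravating", "rich-specific-aggravating",
    "minimal-specific-alleviating", "rich-specific-alleviating", "sign-flip",
)


@dataclass
class DifferentialResult:
    """dE matrix with empirical p-values, on the shared query x array axes."""

    queries: list[str]
    arrays: list[str]
    de: np.ndarray
    pvalue: np.ndarray
    e_rich: np.ndarray
    e_minimal: np.ndarray
    single_condition: pd.DataFrame
    null_abs: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def to_pairs(self) -> pd.DataFrame:
        """Merge measurement orientations into an unordered pair table."""
        qi = {q: i for i, q in enumerate(self.queries)}
        ai = {a: i for i, a in enumerate(self.arrays)}
        rows, seen = [], set()
        pool = self.null_abs
        for q in self.queries:
            for a in self.arrays:
                if q == a:
                    continue
                key = (q, a) if q <= a else (a, q)
                if key in seen:
                    continue
                seen.add(key)
                vals, ers, ems = [], [], []
                for g1, g2 in (key, key[::-1]):
                    i, j = qi.get(g1), ai.get(g2)
                    if i is None or j is None or not np.isfinite(self.de[i, j]):
                        continue
                    vals.append(self.de[i, j])
                    ers.append(self.e_rich[i, j])
                    ems.append(self.e_minimal[i, j])
                if not vals:
                    continue
                de = float(np.mean(vals))
                if pool is not None:
                    n = len(pool)
                    cnt = n - np.searchsorted(pool, abs(de), side="left")
                    p = (1.0 + cnt) / (1.0 + n)
                else:  # pragma: no cover
                    p = np.nan
                rows.append({"gene_a": key[0], "gene_b": key[1],
                             "E_rich": float(np.mean(ers)),
                             "E_minimal": float(np.mean(ems)),
                             "dE": de, "p_diff": float(p)})
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "E_rich",
                                           "E_minimal", "dE", "p_diff"])


def differential_scores(e_rich: EScoreMatrix, e_minimal: EScoreMatrix,
                        null_size: int = 100, seed: int = 0,
                        neutral_k: float = 4.0) -> DifferentialResult:
    """dE = E_minimal - E_rich with pooled permutation p-values.

    Matrices are aligned on the intersection of their query and array axes
    (disjoint axes are an error).  Pairs measured in only one condition are
    reported in ``single_condition``, never silently dropped.
    """
    if null_size < 10:
        raise ValueError("null_size must be >= 10")
    queries = [q for q in e_rich.queries if q in set(e_minimal.queries)]
    arrays = [a for a in e_rich.arrays if a in set(e_minimal.arrays)]
    if not queries or not arrays:
        raise ValueError("the two conditions share no query/array axes")

    ir = [e_rich.queries.index(q) for q in queries]
    im = [e_minimal.queries.index(q) for q in queries]
    jr = [e_rich.arrays.index(a) for a in arrays]
    jm = [e_minimal.arrays.index(a) for a in arrays]
    er = e_rich.e[np.ix_(ir, jr)]
    em = e_minimal.e[np.ix_(im, jm)]

    fin_r, fin_m = np.isfinite(er), np.isfinite(em)
    both = fin_r & fin_m
    de = np.where(both, em - er, np.nan)

    # pairs with exactly one condition measured (within the shared axes)
    only = fin_r ^ fin_m
    oi, oj = np.nonzero(only)
    single = pd.DataFrame({
        "query": [queries[i] for i in oi],
        "array": [arrays[j] for j in oj],
        "condition": np.where(fin_r[only], "rich", "minimal"),
        "E": np.where(fin_r[only], er[only], em[only]),
    })

    sr, sm = _robust_scale(er[fin_r]), _robust_scale(em[fin_m])
    neutral = both & (np.abs(er) < neutral_k * sr) & (np.abs(em) < neutral_k * sm)

    rng = np.random.default_rng(seed)
    # assign the two permutation streams by condition name so that swapping
    # the argument order reproduces the identical pool (antisymmetry)
    rich_first = str(e_rich.condition) <= str(e_minimal.condition)
    pools = []
    for i in range(len(queries)):
        idx = np.flatnonzero(neutral[i])
        k = len(idx)
        if k < 3:
            continue
        row_r, row_m = er[i, idx], em[i, idx]
        order_1 = np.argsort(rng.random((null_size, k)), axis=1)
        order_2 = np.argsort(rng.random((null_size, k)), axis=1)
        order_r, order_m = (order_1, order_2) if rich_first else (order_2, order_1)
        pools.append(np.abs(row_m[order_m] - row_r[order_r]).ravel())
    if not pools:
        raise ValueError("no neutral cells available to build the differential null")
    pool = np.sort(np.concatenate(pools))

    n = len(pool)
    count = n - np.searchsorted(pool, np.abs(de), side="left")
    p = (1.0 + count) / (1.0 + n)
    p[~both] = np.nan

    return DifferentialResult(
        queries=queries, arrays=arrays, de=de, pvalue=p,
        e_rich=np.where(fin_r, er, np.nan), e_minimal=np.where(fin_m, em, np.nan),
        single_condition=single, null_abs=pool,
        provenance={"null_size": null_size, "seed": seed, "neutral_k": neutral_k,
                    "null_n": int(n), "n_neutral": int(neutral.sum()),
                    "sign_convention": "dE = E_minimal - E_rich"},
    )


def classify_pair(rich_call: str, minimal_call: str) -> str:
    """Deterministic class for a (rich, minimal) call combination."""
    if rich_call == minimal_call == "neutral":
        raise ValueError("neutral-in-both pairs are not differential candidates")
    return CLASS_TABLE[(rich_call, minimal_call)]


def _call_lookup(edges: pd.DataFrame) -> dict[tuple[str, str], str]:
    return {(a, b): s for a, b, s in zip(edges["gene_a"], edges["gene_b"], edges["sign"])}


def classify_and_enrich(diff_pairs: pd.DataFrame, edges_rich: pd.DataFrame,
                        edges_minimal: pd.DataFrame, annotations: AnnotationMap,
                        fdr_q: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify significant differential pairs and test bioprocess enrichment.

    ``diff_pairs`` is the pair table from :meth:`DifferentialResult.to_pairs`.
    A differential call requires BH-adjusted p_diff <= ``fdr_q`` and a
    non-concordant class.  Enrichment contrasts, per bioprocess, the genes'
    incidence among differential vs non-differential measured pairs
    (one-sided Fisher, BH across bioprocesses).
    """
    df = diff_pairs.copy()
    df["adj_p"] = bh_adjust(df["p_diff"]) if len(df) else np.nan
    rich_call = _call_lookup(edges_rich)
    minimal_call = _call_lookup(edges_minimal)
    keys = list(zip(df["gene_a"], df["gene_b"]))
    df["class"] = [
        CLASS_TABLE.get((rich_call.get(k, "neutral"), minimal_call.get(k, "neutral")))
        for k in keys
    ]
    calls = df[(df["adj_p"] <= fdr_q) & df["class"].isin(DIFFERENTIAL_CLASSES)].copy()
    calls = calls[["gene_a", "gene_b", "E_rich", "E_minimal", "dE",
                   "p_diff", "adj_p", "class"]].reset_index(drop=True)

    # per-bioprocess enrichment of differential pairs (incidence-weighted)
    annotated = df["gene_a"].isin(annotations.label_of) & df["gene_b"].isin(annotations.label_of)
    uni = df.loc[annotated]
    is_diff = (uni["adj_p"] <= fdr_q) & uni["class"].isin(DIFFERENTIAL_CLASSES)
    n_diff, n_tot = int(is_diff.sum()), len(uni)
    rows = []
    for label in annotations.labels:
        in_label = (uni["gene_a"].map(annotations.label_of).eq(label)
                    | uni["gene_b"].map(annotations.label_of).eq(label))
        t_l = int(in_label.sum())
        if t_l == 0:
            rows.append({"label": label, "n_pairs": 0, "n_differential": 0, "p": np.nan})
            continue
        k_l = int((in_label & is_diff).sum())
        p = stats.hypergeom.sf(k_l - 1, n_tot, n_diff, t_l)
        rows.append({"label": label, "n_pairs": t_l, "n_differential": k_l,
                     "p": max(float(p), 1e-300)})
    enrich = pd.DataFrame(rows)
    testable = enrich["p"].notna()
    enrich["adj_p"] = np.nan
    if testable.any():
        enrich.loc[testable, "adj_p"] = bh_adjust(enrich.loc[testable, "p"])
    enrich["enriched"] = enrich["adj_p"] <= 0.05
    return calls, enrich
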