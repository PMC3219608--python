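"""E-score cutoff selection by bioprocess-pair enrichment sweeps.

Interaction calls are only useful at a threshold where they concentrate
within and between functionally related bioprocesses.  For a grid of |E|
thresholds and each sign, every unordered pair of bioprocess labels is
tested for enrichment of interacting gene pairs (one-sided Fisher exact /
hypergeometric tail, Benjamini-Hochberg corrected), and the cutoff chosen
per sign is the smallest threshold attaining the maximum number of enriched
label pairs (ties break toward the smaller threshold, preserving
sensitivity).  A label-shuffled control repeats the sweep with gene ->
bioprocess assignments permuted; a real signal should dwarf it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationMap",
    "CalibrationResult",
    "CalibrationError",
    "bh_adjust",
    "bioprocess_pair_enrichment",
    "threshold_sweep",
]


class CalibrationError(RuntimeError):
    """Raised when no threshold yields any enriched bioprocess pair."""


@dataclass
class AnnotationMap:
    """Gene -> bioprocess label (one label per annotated gene)."""

    label_of: dict[str, str]

    def __post_init__(self) -> None:
        self.labels = sorted(set(self.label_of.values()))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, gene_col: str = "gene",
                   label_col: str = "module") -> "AnnotationMap":
        if df[gene_col].duplicated().any():
            raise ValueError("a gene may carry only one bioprocess label")
        return cls(dict(zip(df[gene_col], df[label_col])))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _label_pair_codes(labels_a: np.ndarray, labels_b: np.ndarray, n_labels: int) -> np.ndarray:
    lo = np.minimum(labels_a, labels_b)
    hi = np.maximum(labels_a, labels_b)
    return lo * n_labels + hi


def bioprocess_pair_enrichment(edge_mask: np.ndarray, universe: pd.DataFrame,
                               annotations: AnnotationMap,
                               alpha: float = 0.05) -> pd.DataFrame:
    """Per label-pair enrichment of edges among the testable pair universe.

    ``universe`` lists unordered annotated gene pairs with a defined E-score
    (gene_a, gene_b columns); ``edge_mask`` marks which of those pairs are
    interaction calls at the current threshold.  For each unordered label
    pair the 2x2 table contrasts edges between the labels against all other
    edges and non-edges; the one-sided (enrichment) p is the hypergeometric
    tail, identical to Fisher's exact test with alternative='greater'.
    Label pairs with no testable gene pair are skipped (recorded with NaN p).
    """
    labels = annotations.labels
    n_labels = len(labels)
    code_of = {lab: i for i, lab in enumerate(labels)}
    la = universe["gene_a"].map(annotations.label_of).map(code_of).to_numpy()
    lb = universe["gene_b"].map(annotations.label_of).map(code_of).to_numpy()
    codes = _label_pair_codes(la, lb, n_labels)

    n_codes = n_labels * n_labels
    total = np.bincount(codes, minlength=n_codes)
    edges = np.bincount(codes[edge_mask], minlength=n_codes)
    big_n = int(total.sum())
    big_k = int(edges.sum())

    rows = []
    for i in range(n_labels):
        for j in range(i, n_labels):
            code = i * n_labels + j
            t_ab, k_ab = int(total[code]), int(edges[code])
            if t_ab == 0:
                rows.append({"label_a": labels[i], "label_b": labels[j],
                             "n_pairs": 0, "n_edges": 0, "p": np.nan})
                continue
            p = stats.hypergeom.sf(k_ab - 1, big_n, big_k, t_ab)
            rows.append({"label_a": labels[i], "label_b": labels[j],
                         "n_pairs": t_ab, "n_edges": k_ab, "p": max(float(p), 1e-300)})
    out = pd.DataFrame(rows)
    testable = out["p"].notna()
    out["adj_p"] = np.nan
    if testable.any():
        out.loc[testable, "adj_p"] = bh_adjust(out.loc[testable, "p"])
    out["enriched"] = out["adj_p"] <= alpha
    return out


def _enriched_count(e_abs_signed: np.ndarray, codes: np.ndarray, n_codes: int,
                    big_n: int, alpha: float) -> int:
    """Count label pairs with BH-adjusted hypergeometric p <= alpha."""
    total = np.bincount(codes, minlength=n_codes)
    edges = np.bincount(codes[e_abs_signed], minlength=n_codes)
    big_k = int(edges.sum())
    sel = total > 0
    if big_k == 0 or not sel.any():
        return 0
    p = stats.hypergeom.sf(edges[sel] - 1, big_n, big_k, total[sel])
    # unordered label pairs only appear once in `codes`, so sel indexes them uniquely
    adj = bh_adjust(np.clip(p, 1e-300, 1.0))
    return int(np.sum(adj <= alpha))


@dataclass
class CalibrationResult:
    """Outcome of a threshold sweep, including the shuffled-label control."""

    thresholds: np.ndarray
    counts: dict                    # sign -> enriched label-pair count per threshold
    shuffled_mean: dict             # sign -> mean control count per threshold
    shuffled_max: dict              # sign -> max control count per threshold
    chosen: dict = field(default_factory=dict)  # sign -> threshold or None
    alpha: float = 0.05

    @property
    def failed(self) -> bool:
        return any(v is None for v in self.chosen.values())

    @property
    def cutoffs(self) -> tuple[float, float]:
        """(negative, positive) cutoffs; raises CalibrationError on failure."""
        if self.failed:
            raise CalibrationError("no threshold produced enriched bioprocess pairs")
        return (-self.chosen["negative"], self.chosen["positive"])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sign in ("negative", "positive"):
            for k, t in enumerate(self.thresholds):
                rows.append({"threshold": t, "sign": sign,
                             "enriched_count": self.counts[sign][k],
                             "shuffled_mean": self.shuffled_mean[sign][k],
                             "shuffled_max": self.shuffled_max[sign][k]})
        return pd.DataFrame(rows)


def threshold_sweep(pairs: pd.DataFrame, annotations: AnnotationMap,
                    grid=None, n_shuffles: int = 20, seed: int = 0,
                    alpha: float = 0.05) -> CalibrationResult:
    """Sweep |E| thresholds, counting enriched label pairs per sign.

    ``pairs`` is a merged pair table (gene_a, gene_b, E).  The testable
    universe is the annotated pairs with finite E.  The chosen cutoff per
    sign is the smallest threshold whose enriched count is statistically
    tied with the maximum (within one Poisson SE), breaking ties toward
    sensitivity; a maximal count of zero marks that sign as failed (no
    silent default).
    """
    grid = np.asarray([1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0] if grid is None else grid,
                      dtype=float)
    if grid.min() > 1.0 or grid.max() < 4.0 or np.max(np.diff(np.sort(grid))) > 0.5 + 1e-9:
        raise ValueError("threshold grid must cover [1, 4] in steps <= 0.5")
    grid = np.sort(grid)

    annotated = (pairs["gene_a"].isin(annotations.label_of)
                 & pairs["gene_b"].isin(annotations.label_of)
                 & np.isfinite(pairs["E"]))
    uni = pairs.loc[annotated, ["gene_a", "gene_b", "E"]].reset_index(drop=True)
    genes = sorted(set(uni["gene_a"]) | set(uni["gene_b"]))
    labels = annotations.labels
    n_labels = len(labels)
    code_of = {lab: i for i, lab in enumerate(labels)}
    gene_idx = {g: i for i, g in enumerate(genes)}
    base_labels = np.array([code_of[annotations.label_of[g]] for g in genes])
    ia = uni["gene_a"].map(gene_idx).to_numpy()
    ib = uni["gene_b"].map(gene_idx).to_numpy()
    e_vals = uni["E"].to_numpy()
    big_n = len(uni)
    n_codes = n_labels * n_labels

    rng = np.random.default_rng(seed)
    labelings = [base_labels] + [base_labels[rng.permutation(len(genes))]
                                 for _ in range(n_shuffles)]

    counts = {"negative": np.zeros(len(grid), dtype=int),
              "positive": np.zeros(len(grid), dtype=int)}
    sh_counts = {"negative": np.zeros((n_shuffles, len(grid)), dtype=int),
                 "positive": np.zeros((n_shuffles, len(grid)), dtype=int)}
    for li, lab in enumerate(labelings):
        codes = _label_pair_codes(lab[ia], lab[ib], n_labels)
        for k, t in enumerate(grid):
            for sign, mask in (("negative", e_vals <= -t), ("positive", e_vals >= t)):
                c = _enriched_count(mask, codes, n_codes, big_n, alpha)
                if li == 0:
                    counts[sign][k] = c
                else:
                    sh_counts[sign][li - 1, k] = c

    chosen = {}
    for sign in ("negative", "positive"):
        best = counts[sign].max() if len(grid) else 0
        if best > 0:
            # enriched-pair counts are Poisson-noisy; thresholds whose count
            # is within one SE (sqrt of the max) of the maximum are treated
            # as tied, and the tie breaks toward the smallest threshold to
            # preserve sensitivity
            eligible = counts[sign] >= best - np.sqrt(best)
            chosen[sign] = float(grid[np.flatnonzero(eligible)[0]])
        else:
            chosen[sign] = None

    return CalibrationResult(
        thresholds=grid,
        counts={s: counts[s] for s in counts},
        shuffled_mean={s: sh_counts[s].mean(axis=0) if n_shuffles else np.zeros(len(grid))
                       for s in sh_counts},
        shuffled_max={s: sh_counts[s].max(axis=0) if n_shuffles else np.zeros(len(grid))
                      for s in sh_counts},
        chosen=chosen,
        alpha=alpha,
    )
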