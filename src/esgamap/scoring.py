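"""Multiplicative-model epistasis scores (E-scores) with empirical p-values.

Under the multiplicative null, the normalized double-mutant fitness of a
non-interacting pair factorizes as ``Wij = Wi * Wj``.  Single-mutant
fitnesses are estimated from the screen matrix itself by robust marginals
(medians), and each cell's deviation from the product expectation is
standardized by a regularized replicate-based error,

    E(i,j) = (Wij - Wi*Wj) / sqrt(replicate_sd^2 / n_obs + (sigma0 * Wi*Wj)^2),

where ``sigma0`` is the modal relative replicate SD of the matrix (colony
noise is multiplicative, so the error floor scales with the expected colony
level).  The regularizer keeps cells with accidentally tiny replicate
variance from exploding (the classic failure mode of standardized colony
scores) and makes |E| ~ 2 interpretable as roughly two typical errors.

Confidence comes from a permutation null: fitness-normalized residuals are
permuted among cells of the same screen row (preserving row structure) and
E recomputed on the recombined values.  Cells outside the neutral peak
(|E| >= 4 robust SD) are excluded from the pool so that genuine interactions
cannot inflate the null — without that exclusion the empirical p of a true
interaction is floored at roughly the interaction density, which destroys
FDR-controlled calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plates import ScreenMatrix

__all__ = [
    "SingleMutantFitness",
    "EScoreMatrix",
    "estimate_single_fitness",
    "compute_escores",
    "attach_pvalues",
    "pair_table",
    "modal_sd",
]

logger = logging.getLogger(__name__)

#: Prior degrees of freedom for shrinking per-cell replicate variances
#: toward the matrix-typical relative variance (empirical-Bayes moderation).
PRIOR_DF = 4.0


@dataclass
class SingleMutantFitness:
    """Median-based single-mutant fitness estimates, per axis of the screen."""

    array_w: pd.Series   # array gene -> W (NaN if excluded)
    query_w: pd.Series   # query gene -> W
    excluded: dict = field(default_factory=dict)  # gene -> reason


def estimate_single_fitness(screen: ScreenMatrix, min_obs: int = 5,
                            w_floor: float = 0.05) -> SingleMutantFitness:
    """Estimate Wi (query) and Wj (array) from the screen matrix itself.

    Wj is the median over queries of each array column; Wi is the median over
    arrays of Wij / Wj.  Medians are robust to a minority of true
    interactions.  Both sets are rescaled (by a single factor and its
    inverse, preserving all products Wi*Wj) so that their medians agree,
    pinning the genome-wide typical fitness at the normalized colony scale.
    Genes with fewer than ``min_obs`` unmasked observations, or with fitness
    below ``w_floor`` (dead in essentially every screen), are excluded.
    """
    w = np.where(screen.mask, np.nan, screen.w)
    excluded: dict[str, str] = {}

    col_n = np.sum(np.isfinite(w), axis=0)
    with np.errstate(all="ignore"):
        wj = np.nanmedian(w, axis=0)
    for j, a in enumerate(screen.arrays):
        if col_n[j] < min_obs:
            wj[j] = np.nan
            excluded[a] = "too_few_observations"
        elif np.isfinite(wj[j]) and wj[j] < w_floor:
            wj[j] = np.nan
            excluded[a] = "dead_array_gene"

    scale = np.nanmedian(wj)
    if not np.isfinite(scale) or scale <= 0:
        raise ValueError("cannot estimate array fitness scale")
    wj = wj / scale

    ratio = w / wj[None, :]
    row_n = np.sum(np.isfinite(ratio), axis=1)
    with np.errstate(all="ignore"):
        wi = np.nanmedian(ratio, axis=1)
    for i, q in enumerate(screen.queries):
        if row_n[i] < min_obs:
            wi[i] = np.nan
            excluded[q] = "too_few_observations"
        elif np.isfinite(wi[i]) and wi[i] < w_floor:
            wi[i] = np.nan
            excluded[q] = "dead_query_gene"

    # balance the free (a, 1/a) scale so query and array medians agree
    mi, mj = np.nanmedian(wi), np.nanmedian(wj)
    if np.isfinite(mi) and np.isfinite(mj) and mi > 0 and mj > 0:
        a = np.sqrt(mi / mj)
        wi, wj = wi / a, wj * a

    return SingleMutantFitness(
        array_w=pd.Series(wj, index=screen.arrays),
        query_w=pd.Series(wi, index=screen.queries),
        excluded=excluded,
    )


def modal_sd(values: np.ndarray, max_bins: int = 200) -> float:
    """Mode of the replicate-SD distribution (histogram mode, FD binning)."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals) & (vals > 0)]
    if len(vals) == 0:
        raise ValueError("no positive replicate SDs to estimate sigma0 from")
    if len(vals) < 20:
        return float(np.median(vals))
    iqr = np.subtract(*np.percentile(vals, [75, 25]))
    if iqr <= 0:
        return float(np.median(vals))
    width = 2 * iqr / len(vals) ** (1 / 3)
    nbins = int(min(max_bins, max(10, np.ceil((vals.max() - vals.min()) / width))))
    counts, edges = np.histogram(vals, bins=nbins)
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


@dataclass
class EScoreMatrix:
    """Query x array E-scores for one condition, optionally with p-values.

    ``evar`` is the estimated sampling variance of each E value (the
    replicate-error share of the squared denominator), used when merging the
    two measurement orientations of a pair.  ``null_abs`` is the sorted
    |E| permutation pool attached by :func:`attach_pvalues`.
    """

    queries: list[str]
    arrays: list[str]
    e: np.ndarray
    evar: np.ndarray
    condition: str = ""
    sigma0: float = np.nan
    pvalue: np.ndarray | None = None
    null_abs: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.e, index=self.queries, columns=self.arrays)

    def empirical_p(self, e_values: np.ndarray) -> np.ndarray:
        """Two-sided empirical p of |E| against the attached null pool."""
        if self.null_abs is None:
            raise ValueError("no null distribution attached; run attach_pvalues first")
        pool = self.null_abs
        n = len(pool)
        count = n - np.searchsorted(pool, np.abs(np.asarray(e_values, dtype=float)),
                                    side="left")
        return (1.0 + count) / (1.0 + n)


def compute_escores(screen: ScreenMatrix, fitness: SingleMutantFitness,
                    sigma0: float | None = None) -> EScoreMatrix:
    """Standardized deviations from the multiplicative expectation.

    E is defined only where the fitness of both genes is defined and the cell
    has at least two replicate observations.  Colony noise is multiplicative
    (replicate SD proportional to the colony's level), so the regularizer is
    proportional too: ``sigma0`` is the modal *relative* replicate SD
    (sd / expectation) and each cell's floor is ``sigma0 * Wi*Wj``.  This
    keeps E homoscedastic across fitness levels — a constant floor would
    under-regularize large colonies and give the null E distribution a heavy
    tail.
    """
    wi = fitness.query_w.reindex(screen.queries).to_numpy()
    wj = fitness.array_w.reindex(screen.arrays).to_numpy()
    expected = np.outer(wi, wj)
    ok = np.isfinite(expected) & (expected > 0) & (screen.n_obs >= 2)
    rel_sd2 = np.where(ok, (screen.sd / np.abs(expected)) ** 2, np.nan)
    if sigma0 is None:
        sigma0 = modal_sd(np.sqrt(rel_sd2[np.isfinite(rel_sd2)]))
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    with np.errstate(all="ignore"):
        # with 2-3 replicates a raw per-cell variance has so few degrees of
        # freedom that its noise dominates the score scale; shrink it toward
        # the typical relative variance (prior df = PRIOR_DF) before use
        df = np.maximum(screen.n_obs - 1, 1)
        sd_mod2 = (df * rel_sd2 + PRIOR_DF * sigma0 ** 2) / (df + PRIOR_DF)
        sem2 = expected ** 2 * sd_mod2 / np.maximum(screen.n_obs, 1)
        denom2 = sem2 + (sigma0 * expected) ** 2
        e = (screen.w - expected) / np.sqrt(denom2)
        evar = sem2 / denom2
    invalid = ~ok | screen.mask
    e[invalid] = np.nan
    evar[invalid] = np.nan
    return EScoreMatrix(queries=list(screen.queries), arrays=list(screen.arrays),
                        e=e, evar=evar, condition=screen.condition,
                        sigma0=float(sigma0),
                        provenance={"sigma0_relative": float(sigma0),
                                    "prior_df": PRIOR_DF})


def _robust_scale(values: np.ndarray) -> float:
    vals = values[np.isfinite(values)]
    mad = np.median(np.abs(vals - np.median(vals)))
    scale = 1.4826 * mad
    return float(scale) if scale > 0 else float(np.std(vals)) or 1.0


def attach_pvalues(e: EScoreMatrix, screen: ScreenMatrix, fitness: SingleMutantFitness,
                   null_size: int = 100, seed: int = 0,
                   neutral_k: float = 4.0) -> EScoreMatrix:
    """Attach two-sided empirical p-values from a within-row permutation null.

    For each screen row, the fitness-normalized residuals ``R = Wij/(Wi*Wj)``
    of neutral cells (|E| below ``neutral_k`` robust SDs) are permuted among
    those cells' positions together with their replicate SDs, and E is
    recomputed on the recombined values; ``null_size`` permutations are
    pooled over the whole matrix.  p = (1 + #{|E_null| >= |E|}) / (1 + N),
    which is monotone non-increasing in |E|.
    """
    if null_size < 10:
        raise ValueError("null_size must be >= 10")
    rng = np.random.default_rng(seed)
    wi = fitness.query_w.reindex(screen.queries).to_numpy()
    wj = fitness.array_w.reindex(screen.arrays).to_numpy()
    expected = np.outer(wi, wj)
    sigma0 = e.sigma0

    scale = _robust_scale(e.e)
    neutral = np.isfinite(e.e) & (np.abs(e.e) < neutral_k * scale)
    valid = neutral & np.isfinite(expected) & (expected > 0) & (screen.n_obs >= 2)

    pools = []
    for i in range(len(screen.queries)):
        idx = np.flatnonzero(valid[i])
        k = len(idx)
        if k < 3:
            continue
        r = screen.w[i, idx] / expected[i, idx]
        sdn = screen.sd[i, idx] / expected[i, idx]
        nobs = screen.n_obs[i, idx].astype(float)
        # null_size independent permutations of the residual triples; the
        # proportional error model makes the target cell's level cancel
        order = np.argsort(rng.random((null_size, k)), axis=1)
        rp, sp, npo = r[order], sdn[order], nobs[order]
        df = np.maximum(npo - 1.0, 1.0)
        sp_mod2 = (df * sp ** 2 + PRIOR_DF * sigma0 ** 2) / (df + PRIOR_DF)
        enull = (rp - 1.0) / np.sqrt(sp_mod2 / npo + sigma0 ** 2)
        pools.append(np.abs(enull).ravel())
    if not pools:
        raise ValueError("no neutral cells available to build the null")
    pool = np.sort(np.concatenate(pools))

    n = len(pool)
    count = n - np.searchsorted(pool, np.abs(e.e), side="left")
    p = (1.0 + count) / (1.0 + n)
    p[~np.isfinite(e.e)] = np.nan

    e.pvalue = p
    e.null_abs = pool
    e.provenance.update({"null_size": null_size, "seed": seed,
                         "neutral_k": neutral_k, "null_n": int(n)})
    return e


def pair_table(e: EScoreMatrix, conflict_delta: float = 4.0) -> pd.DataFrame:
    """Merge the two measurement orientations of each gene pair.

    Each unordered pair (a, b) can be measured with a as query and b as array
    and vice versa; the merged E is the inverse-variance-weighted mean of the
    orientations (weights 1/evar, with a floor so zero-sampling-variance
    cells still combine).  Orientations disagreeing in sign with
    |E1 - E2| > ``conflict_delta`` are flagged.  The merged p-value is
    computed from the merged E against the attached null pool.
    """
    qi = {q: i for i, q in enumerate(e.queries)}
    ai = {a: i for i, a in enumerate(e.arrays)}
    rows = []
    seen = set()
    for q in e.queries:
        for a in e.arrays:
            if q == a:
                continue
            key = (q, a) if q <= a else (a, q)
            if key in seen:
                continue
            seen.add(key)
            vals, variances = [], []
            for g1, g2 in ((key[0], key[1]), (key[1], key[0])):
                i, j = qi.get(g1), ai.get(g2)
                if i is None or j is None or not np.isfinite(e.e[i, j]):
                    continue
                vals.append(e.e[i, j])
                variances.append(max(e.evar[i, j], 1e-6))
            if not vals:
                continue
            wts = 1.0 / np.asarray(variances)
            merged = float(np.sum(wts * np.asarray(vals)) / np.sum(wts))
            conflict = (len(vals) == 2 and np.sign(vals[0]) != np.sign(vals[1])
                        and abs(vals[0] - vals[1]) > conflict_delta)
            rows.append({"gene_a": key[0], "gene_b": key[1], "E": merged,
                         "n_orientations": len(vals),
                         "evar": float(1.0 / np.sum(wts)),
                         "sign_conflict": bool(conflict)})
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "E", "n_orientations",
                                     "evar", "sign_conflict"])
    if e.null_abs is not None and len(df):
        df["p"] = e.empirical_p(df["E"].to_numpy())
    else:
        df["p"] = np.nan
    df["condition"] = e.condition
    n_conflict = int(df["sign_conflict"].sum()) if len(df) else 0
    if n_conflict:
        logger.warning("%d pairs with conflicting orientation signs", n_conflict)
    return df
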