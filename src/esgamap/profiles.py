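"""Genetic-interaction profile correlations and evidence-shift tests.

A gene's interaction profile — its vector of E-scores across all array
partners — is a high-resolution phenotype: genes acting in the same pathway
or complex tend to have correlated profiles.  This module computes pairwise
Pearson (optionally Spearman) correlations between query profiles, excluding
the pair's own cells (a strong direct interaction would otherwise correlate
the two profiles trivially), and tests whether pairs supported by external
evidence (operon co-membership, co-expression, physical interaction) show a
shifted correlation distribution relative to randomly drawn measured pairs
(two-sample Kolmogorov-Smirnov).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import EScoreMatrix

__all__ = ["profile_correlation", "evidence_shift_test", "EvidenceShiftResult"]

logger = logging.getLogger(__name__)


def profile_correlation(e: EScoreMatrix, min_overlap: int = 30,
                        method: str = "pearson") -> pd.DataFrame:
    """Correlations between all query-gene profile pairs.

    Profiles are rows of the E-score matrix over the shared array axis.  For
    a pair (a, b) only array positions measured in both profiles contribute,
    and positions involving a or b themselves are excluded.  Pairs with
    overlap below ``min_overlap``, or with a constant profile, are undefined
    (omitted, logged).  Output columns: gene_a, gene_b, r, n_overlap.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    mat = np.asarray(e.e, dtype=float)
    arrays = np.asarray(e.arrays, dtype=object)
    queries = list(e.queries)
    rows = []
    n_constant = 0
    for i in range(len(queries)):
        for j in range(i + 1, len(queries)):
            a, b = queries[i], queries[j]
            ok = np.isfinite(mat[i]) & np.isfinite(mat[j]) & (arrays != a) & (arrays != b)
            n = int(ok.sum())
            if n < min_overlap:
                continue
            x, y = mat[i, ok], mat[j, ok]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                n_constant += 1
                continue
            if method == "spearman":
                r = stats.spearmanr(x, y).statistic
            else:
                r = np.corrcoef(x, y)[0, 1]
            rows.append({"gene_a": min(a, b), "gene_b": max(a, b),
                         "r": float(r), "n_overlap": n})
    if n_constant:
        logger.warning("%d profile pairs skipped for zero variance", n_constant)
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "n_overlap"])


class EvidenceShiftResult(dict):
    """KS comparison of evidence-pair vs random-pair profile correlations."""

    def __getattr__(self, item):
        try:
            return self[item]
        except KeyError as exc:  # pragma: no cover
            raise AttributeError(item) from exc


def evidence_shift_test(corrs: pd.DataFrame, evidence_pairs, n_random: int | None = None,
                        seed: int = 0, min_evidence: int = 20) -> EvidenceShiftResult:
    """Do evidence-supported pairs have shifted profile correlations?

    ``evidence_pairs`` is an iterable of gene pairs (any order).  Their r
    values are compared against ``n_random`` measured pairs drawn uniformly
    from the non-evidence remainder (default 10x the evidence count, capped
    at the pool size) with a two-sample KS test.
    """
    keyed = {(min(a, b), max(a, b)) for a, b in evidence_pairs}
    pair_key = list(zip(corrs["gene_a"], corrs["gene_b"]))
    is_evidence = np.array([k in keyed for k in pair_key])
    ev = corrs.loc[is_evidence, "r"].to_numpy()
    if len(ev) < min_evidence:
        raise ValueError(
            f"only {len(ev)} evidence pairs with a defined correlation "
            f"(need >= {min_evidence})")
    pool = corrs.loc[~is_evidence, "r"].to_numpy()
    if len(pool) == 0:
        raise ValueError("no non-evidence pairs to draw the random control from")
    rng = np.random.default_rng(seed)
    n_random = min(len(pool), n_random if n_random is not None else 10 * len(ev))
    rand = rng.choice(pool, size=n_random, replace=False)
    res = stats.ks_2samp(ev, rand, method="auto")
    return EvidenceShiftResult(
        statistic=float(res.statistic), pvalue=float(res.pvalue),
        median_evidence=float(np.median(ev)), median_random=float(np.median(rand)),
        n_evidence=int(len(ev)), n_random=int(n_random), seed=seed,
    )
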