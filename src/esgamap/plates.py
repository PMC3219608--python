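"""Colony-table I/O, spatial plate normalization, QC and linkage masking.

Raw input is a per-colony TSV (one row per pinned colony with its plate/grid
coordinates, replicate and condition).  Normalization removes plate-to-plate
scale, row/column gradients and the edge-ring growth advantage, leaving the
typical colony at corrected size 1.0.  Quality control drops screens whose
replicates do not agree, rescues single-replicate pinning failures, and masks
array genes linked to the query on the (circular) chromosome, where
conjugation under-transfers the second mutation.  The result is condensed
into a query x array matrix of normalized double-mutant fitness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthgen import CHROMOSOME_BP

__all__ = [
    "COLONY_COLUMNS",
    "FormatError",
    "PlateQCError",
    "read_colony_table",
    "write_colony_table",
    "normalize_plate",
    "normalize_screens",
    "qc_filter",
    "mask_linked",
    "linkage_mask",
    "ScreenMatrix",
    "build_screen_matrix",
]

logger = logging.getLogger(__name__)

COLONY_COLUMNS = ["query", "array", "plate", "row", "col",
                  "replicate", "condition", "size", "missing_flag"]
_KEY = ["plate", "row", "col", "replicate", "condition"]


class FormatError(ValueError):
    """Malformed colony table (bad header, duplicate keys, inconsistent rows)."""


class PlateQCError(ValueError):
    """A plate failed a normalization precondition (e.g. mostly missing)."""


# ---------------------------------------------------------------------------
# I/O

def read_colony_table(path: str | Path) -> pd.DataFrame:
    """Read a colony TSV, validating schema and key uniqueness.

    Line numbers in error messages refer to the file (header = line 1).
    Unknown columns are preserved.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing_cols = [c for c in COLONY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing required columns {missing_cols}")
    dup = df.duplicated(subset=_KEY, keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise FormatError(
            f"{path}: duplicate (plate,row,col,replicate,condition) keys at lines {lines[:10]}"
        )
    df["size"] = pd.to_numeric(df["size"], errors="coerce")
    flag = df["missing_flag"].astype(int)
    bad = (df["size"].isna() != (flag == 1))
    if bad.any():
        lines = (df.index[bad] + 2).tolist()
        raise FormatError(
            f"{path}: size missing must coincide with missing_flag at lines {lines[:10]}"
        )
    if (df.loc[~df["size"].isna(), "size"] < 0).any():
        raise FormatError(f"{path}: negative colony sizes")
    df["missing_flag"] = flag
    return df


def write_colony_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a colony table as TSV; extra (unknown) columns are written too."""
    ordered = COLONY_COLUMNS + [c for c in df.columns if c not in COLONY_COLUMNS]
    # default float formatting is the shortest exact representation, so the
    # table round-trips losslessly
    df.loc[:, ordered].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# normalization

#: Minimum colonies a row/column needs before its median is used as a
#: correction; medians over fewer colonies mostly reflect the colonies
#: themselves and would absorb real biological deviations.
_POLISH_MIN_COUNT = 6


def _polish_log(logs: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                max_iter: int = 20, tol: float = 1e-12,
                min_count: int = _POLISH_MIN_COUNT) -> np.ndarray:
    """Median polish of log-sizes; returns the fitted row+col effect per colony.

    Rows/columns with fewer than ``min_count`` colonies get no correction: a
    median over a couple of colonies is mostly the colonies themselves, so
    "correcting" it would absorb real biological deviations.
    """
    effect = np.zeros_like(logs)
    resid = logs.copy()
    urows, row_inv = np.unique(rows, return_inverse=True)
    ucols, col_inv = np.unique(cols, return_inverse=True)
    row_ok = np.bincount(row_inv) >= min_count
    col_ok = np.bincount(col_inv) >= min_count
    for _ in range(max_iter):
        shift = 0.0
        rmed = np.array([np.median(resid[row_inv == i]) if row_ok[i] else 0.0
                         for i in range(len(urows))])
        resid -= rmed[row_inv]
        effect += rmed[row_inv]
        shift = max(shift, np.max(np.abs(rmed)) if len(rmed) else 0.0)
        cmed = np.array([np.median(resid[col_inv == i]) if col_ok[i] else 0.0
                         for i in range(len(ucols))])
        resid -= cmed[col_inv]
        effect += cmed[col_inv]
        shift = max(shift, np.max(np.abs(cmed)) if len(cmed) else 0.0)
        if shift < tol:
            break
    return effect


def _gated_edge_factor(values: np.ndarray, edge: np.ndarray,
                       z_gate: float = 3.0) -> float:
    """Edge-ring / interior median ratio, or 1.0 when not significant.

    The gate keeps the correction from chasing sampling noise in the two
    medians, which is what makes the whole normalization idempotent: on an
    already-corrected plate the ratio is statistically indistinguishable
    from 1 and nothing is applied.
    """
    pos = np.isfinite(values) & (values > 0)
    ne, ni = int((pos & edge).sum()), int((pos & ~edge).sum())
    if ne < 3 or ni < 3:
        return 1.0
    le = np.log(values[pos & edge])
    li = np.log(values[pos & ~edge])
    g = np.median(le) - np.median(li)
    # SE of a median ~ 1.2533 * SD/sqrt(n); SD via MAD for robustness
    sd_e = 1.4826 * np.median(np.abs(le - np.median(le)))
    sd_i = 1.4826 * np.median(np.abs(li - np.median(li)))
    se = 1.2533 * np.sqrt(sd_e ** 2 / ne + sd_i ** 2 / ni)
    if se > 0 and abs(g) <= z_gate * se:
        return 1.0
    return float(np.exp(g))


def normalize_plate(plate_df: pd.DataFrame, min_present_frac: float = 0.5) -> pd.DataFrame:
    """Correct one plate's colony sizes for scale, edge and row/column effects.

    One ordered pass: sizes are divided by the plate median (typical colony
    -> 1.0); the outermost occupied ring is divided by the edge/interior
    median ratio when that ratio is statistically significant; row/column
    effects are removed by median polish on log-size iterated to
    convergence; finally the plate median is pinned back to exactly 1.0.
    Corrections are multiplicative factors estimated from positive colonies
    and applied to all, so zero-size (dead) colonies stay exactly zero and
    missing stays missing.  On an already-normalized plate every step is a
    no-op, so the correction is idempotent.
    """
    df = plate_df.copy()
    size = df["size"].to_numpy(dtype=float)
    present = ~np.isnan(size)
    if present.mean() < min_present_frac:
        raise PlateQCError(
            f"plate {df['plate'].iloc[0]!r}: only {present.mean():.0%} of colonies present"
        )
    rows = df["row"].to_numpy(int)
    cols = df["col"].to_numpy(int)
    rmin, rmax = rows[present].min(), rows[present].max()
    cmin, cmax = cols[present].min(), cols[present].max()
    edge = (rows == rmin) | (rows == rmax) | (cols == cmin) | (cols == cmax)

    s = size.copy()
    med = np.nanmedian(s)
    if not np.isfinite(med) or med <= 0:
        raise PlateQCError(f"plate {df['plate'].iloc[0]!r}: non-positive median size")
    s = s / med
    s[edge] = s[edge] / _gated_edge_factor(s, edge)
    pos = present & (s > 0)
    if pos.sum() >= 4:
        # the alternating-median iteration contracts geometrically; run it
        # deep enough that reapplying the polish is a no-op at 1e-9
        effect = _polish_log(np.log(s[pos]), rows[pos], cols[pos],
                             max_iter=2000, tol=1e-12)
        corr = np.ones_like(s)
        corr[pos] = np.exp(effect)
        s = s / np.where(np.isnan(s), 1.0, corr)
    med = np.nanmedian(s)
    if np.isfinite(med) and med > 0:
        s = s / med
    df["size"] = s
    return df


def normalize_screens(records: pd.DataFrame, min_present_frac: float = 0.5,
                      polish_iter: int = 12
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize every plate; reject plates failing QC preconditions.

    Spatial correction is reference-based: within one plate, row/column
    medians confound true spatial artifacts with the fitness composition of
    the array genes that happen to sit in that row/column, so the polish is
    run on each colony's ratio to its array gene's cross-plate typical size
    (the same physical layout recurs on every plate, making the array effect
    separable).  One pass applies, in order: plate-median scaling, per-array
    reference, significance-gated edge-ring correction, and row/column
    median polish of the log-ratio surface (iterated to convergence).
    Corrections are multiplicative factors, so the result is exactly
    scale-invariant per plate and zero/missing colonies are preserved.

    Returns (normalized records, plate report).  Rejected plates (more than
    ``1 - min_present_frac`` missing) are excluded from the output and listed
    in the report with a QC code.
    """
    report = []
    keep_groups = []
    for (condition, plate, rep), group in records.groupby(
            ["condition", "plate", "replicate"], sort=False):
        present = group["size"].notna().mean()
        if present < min_present_frac:
            report.append({"condition": condition, "plate": plate, "replicate": rep,
                           "decision": "rejected",
                           "reason": f"only {present:.0%} of colonies present"})
        else:
            keep_groups.append(group)
            report.append({"condition": condition, "plate": plate, "replicate": rep,
                           "decision": "ok", "reason": ""})
    if not keep_groups:
        return records.iloc[0:0].copy(), pd.DataFrame(report)
    df = pd.concat(keep_groups).copy()

    s = df["size"].to_numpy(dtype=float)
    rows = df["row"].to_numpy(int)
    cols = df["col"].to_numpy(int)
    plate_codes, _ = pd.factorize(
        df["condition"].astype(str) + "\x00" + df["plate"].astype(str)
        + "\x00" + df["replicate"].astype(str))
    ref_codes, _ = pd.factorize(
        df["condition"].astype(str) + "\x00" + df["array"].astype(str))
    key_row = pd.Series(plate_codes.astype(np.int64) * 4096 + rows)
    key_col = pd.Series(plate_codes.astype(np.int64) * 4096 + cols)
    plates_s = pd.Series(plate_codes)
    refs_s = pd.Series(ref_codes)

    # outermost occupied ring per plate (static geometry)
    geo = pd.DataFrame({"p": plate_codes, "row": rows, "col": cols})
    lim = geo.groupby("p").agg(rmin=("row", "min"), rmax=("row", "max"),
                               cmin=("col", "min"), cmax=("col", "max"))
    lim = lim.loc[plate_codes]
    edge = ((rows == lim["rmin"].to_numpy()) | (rows == lim["rmax"].to_numpy())
            | (cols == lim["cmin"].to_numpy()) | (cols == lim["cmax"].to_numpy()))

    def _group_median(values: np.ndarray, keys: pd.Series, min_count: int) -> np.ndarray:
        vs = pd.Series(values)
        med = vs.groupby(keys).transform("median").to_numpy()
        cnt = vs.notna().groupby(keys).transform("sum").to_numpy()
        med[~np.isfinite(med) | (cnt < min_count)] = np.nan
        return med

    # (1) plate scaling: typical colony of each plate -> 1.0
    med = pd.Series(s).groupby(plates_s).transform("median").to_numpy()
    if np.any(~np.isfinite(med) | (med <= 0)):
        raise PlateQCError("non-positive plate median during normalization")
    s = s / med
    # (2) per-array reference across plates of the same condition
    ref = pd.Series(s).groupby(refs_s).transform("median").to_numpy()
    with np.errstate(all="ignore"):
        ratio = np.where(ref > 0, s / ref, np.nan)
    # (3) edge-ring correction per plate on the ratio surface (gated)
    factors = {}
    for code, idx in pd.Series(np.arange(len(s))).groupby(pd.Series(plate_codes)):
        ii = idx.to_numpy()
        factors[code] = _gated_edge_factor(ratio[ii], edge[ii])
    fac = np.array([factors[c] for c in plate_codes])
    s = np.where(edge, s / fac, s)
    with np.errstate(all="ignore"):
        ratio = np.where(edge, ratio / fac, ratio)
        logs = np.where(np.isfinite(ratio) & (ratio > 0), np.log(ratio), np.nan)
    # (4) row/column median polish of the log-ratio surface, all plates at once
    eff = np.zeros(len(s))
    for _ in range(polish_iter):
        rmed = _group_median(logs, key_row, _POLISH_MIN_COUNT)
        rmed = np.where(np.isfinite(rmed), rmed, 0.0)
        logs = logs - rmed
        eff += rmed
        cmed = _group_median(logs, key_col, _POLISH_MIN_COUNT)
        cmed = np.where(np.isfinite(cmed), cmed, 0.0)
        logs = logs - cmed
        eff += cmed
        if max(np.max(np.abs(rmed)), np.max(np.abs(cmed))) < 1e-12:
            break
    s = s / np.exp(eff)

    df["size"] = s
    return df.reset_index(drop=True), pd.DataFrame(report)


# ---------------------------------------------------------------------------
# quality control

def qc_filter(records: pd.DataFrame, min_replicate_corr: float = 0.5,
              size_floor: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen-level replicate-agreement filter plus pinning-failure rescue.

    A screen is one (condition, query).  Screens whose mean between-replicate
    Pearson correlation of corrected sizes falls below ``min_replicate_corr``
    are excluded.  A colony below ``size_floor`` in exactly one replicate
    while at least one other replicate of the same array grew is treated as a
    pinning failure and set missing (a true synthetic-lethal pair is ~0 in
    every replicate and is untouched).
    """
    df = records.copy()
    report = []
    keep_mask = pd.Series(True, index=df.index)
    for (condition, query), group in df.groupby(["condition", "query"], sort=False):
        pivot = group.pivot_table(index="array", columns="replicate",
                                  values="size", aggfunc="mean")
        if pivot.shape[1] < 2:
            keep_mask.loc[group.index] = False
            report.append({"condition": condition, "query": query, "r": np.nan,
                           "decision": "excluded", "reason": "fewer than 2 replicates"})
            continue
        corr = pivot.corr(min_periods=3)
        vals = corr.to_numpy()[np.triu_indices(corr.shape[0], k=1)]
        r = float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan
        if not np.isfinite(r) or r < min_replicate_corr:
            keep_mask.loc[group.index] = False
            report.append({"condition": condition, "query": query, "r": r,
                           "decision": "excluded",
                           "reason": f"replicate correlation {r:.3f} < {min_replicate_corr}"})
            continue

        # pinning-failure rescue
        low = pivot < size_floor
        grown = pivot >= size_floor
        rescue = low.to_numpy() & (low.sum(axis=1).to_numpy() == 1)[:, None] \
            & (grown.sum(axis=1).to_numpy() >= 1)[:, None]
        if rescue.any():
            bad = {(a, rep) for i, a in enumerate(pivot.index)
                   for j, rep in enumerate(pivot.columns) if rescue[i, j]}
            sel = group.apply(lambda rec: (rec["array"], rec["replicate"]) in bad, axis=1)
            df.loc[group.index[sel], "size"] = np.nan
            df.loc[group.index[sel], "missing_flag"] = 1
        report.append({"condition": condition, "query": query, "r": r,
                       "decision": "kept", "reason": ""})
    return df.loc[keep_mask].copy(), pd.DataFrame(report)


# ---------------------------------------------------------------------------
# linkage masking

def circular_distance(a: int, b: int, length: int = CHROMOSOME_BP) -> int:
    d = abs(int(a) - int(b)) % length
    return min(d, length - d)


def mask_linked(query: str, arrays: list[str], positions_bp: dict[str, int],
                window_bp: int = 30_000, chromosome_bp: int = CHROMOSOME_BP) -> set[str]:
    """Array genes within ``window_bp`` of the query on the circular chromosome.

    The query's own gene is always masked.  Genes without a position are left
    unmasked with a logged warning (no silent masking on missing metadata).
    """
    masked = {a for a in arrays if a == query}
    qpos = positions_bp.get(query)
    if qpos is None:
        logger.warning("no genomic position for query %s; linkage masking limited to self", query)
        return masked
    for a in arrays:
        apos = positions_bp.get(a)
        if apos is None:
            if a != query:
                logger.warning("no genomic position for array gene %s; left unmasked", a)
            continue
        if circular_distance(qpos, apos, chromosome_bp) <= window_bp:
            masked.add(a)
    return masked


def linkage_mask(queries: list[str], arrays: list[str], positions_bp: dict[str, int],
                 window_bp: int = 30_000, chromosome_bp: int = CHROMOSOME_BP
                 ) -> set[tuple[str, str]]:
    """All (query, array) cells removed by linkage masking."""
    pairs = set()
    for q in queries:
        for a in mask_linked(q, arrays, positions_bp, window_bp, chromosome_bp):
            pairs.add((q, a))
    return pairs


# ---------------------------------------------------------------------------
# screen matrix

@dataclass
class ScreenMatrix:
    """Query x array matrix of normalized double-mutant fitness.

    ``w`` holds the replicate mean of corrected sizes, ``sd`` the replicate
    sample SD (NaN when fewer than 2 observations), ``n_obs`` the replicate
    count, and ``mask`` flags cells removed by QC/linkage (their ``w`` is NaN
    and ``n_obs`` 0).
    """

    queries: list[str]
    arrays: list[str]
    w: np.ndarray
    sd: np.ndarray
    n_obs: np.ndarray
    mask: np.ndarray
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.w, index=self.queries, columns=self.arrays)


def build_screen_matrix(records: pd.DataFrame,
                        masked_pairs: set[tuple[str, str]] | None = None,
                        condition: str | None = None) -> ScreenMatrix:
    """Aggregate normalized, QC-passed records into a ScreenMatrix."""
    df = records
    if condition is not None:
        df = df[df["condition"] == condition]
    elif df["condition"].nunique() > 1:
        raise ValueError("records span multiple conditions; pass condition=")
    cond = df["condition"].iloc[0] if len(df) else (condition or "")

    grouped = df.groupby(["query", "array"])["size"].agg(["mean", "std", "count"])
    queries = sorted(df["query"].unique())
    arrays = sorted(df["array"].unique())
    qi = {q: i for i, q in enumerate(queries)}
    ai = {a: i for i, a in enumerate(arrays)}
    shape = (len(queries), len(arrays))
    w_f = grouped["mean"].unstack().reindex(index=queries, columns=arrays)
    sd_f = grouped["std"].unstack().reindex(index=queries, columns=arrays)
    n_f = grouped["count"].unstack().reindex(index=queries, columns=arrays).fillna(0)
    w = w_f.to_numpy(dtype=float)
    sd = sd_f.to_numpy(dtype=float)
    n = n_f.to_numpy().astype(int)
    sd[n < 2] = np.nan
    n[~np.isfinite(w)] = 0

    mask = np.zeros(shape, dtype=bool)
    if masked_pairs:
        for q, a in masked_pairs:
            if q in qi and a in ai:
                mask[qi[q], ai[a]] = True
        w[mask] = np.nan
        sd[mask] = np.nan
        n[mask] = 0

    all_masked = mask.all(axis=1)
    if all_masked.any():
        dropped = [queries[i] for i in np.flatnonzero(all_masked)]
        logger.warning("queries with all arrays masked dropped: %s", dropped)
        keep = ~all_masked
        queries = [q for q, k in zip(queries, keep) if k]
        w, sd, n, mask = w[keep], sd[keep], n[keep], mask[keep]

    return ScreenMatrix(queries=queries, arrays=arrays, w=w, sd=sd,
                        n_obs=n, mask=mask, condition=cond)
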