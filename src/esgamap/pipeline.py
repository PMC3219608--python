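"""End-to-end orchestration: colony tables in, networks and reports out.

``run_pipeline`` executes normalization, scoring, cutoff calibration,
network construction, profile correlation and differential analysis for the
conditions present in the input, writing every stage's tables plus a
machine-readable manifest (resolved configuration, per-stage record counts,
seeds) into the run directory.  A single global seed fans out to per-stage
seeds by fixed offsets so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibrate, differential, networks, plates, profiles, scoring
from .synthgen import CHROMOSOME_BP

__all__ = ["PipelineConfig", "ConfigError", "StageError", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ["normalize", "score", "calibrate", "network", "profiles", "differential"]

# fixed seed offsets per stage (global seed + offset, kept below 2**31)
_SEED_OFFSET = {"score": 11, "calibrate": 23, "profiles": 37, "differential": 41}


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration; every parameter has a default."""

    colonies: dict = field(default_factory=dict)   # condition -> colony TSV path
    genes: str | None = None                       # gene metadata TSV
    evidence: dict = field(default_factory=dict)   # evidence name -> pair-list TSV
    linkage_window_bp: int = 30_000
    chromosome_bp: int = CHROMOSOME_BP
    min_replicate_corr: float = 0.5
    size_floor: float = 0.05
    sigma0: float | None = None
    grid: list = field(default_factory=lambda: [1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0])
    null_size: int = 100
    n_shuffles: int = 20
    fdr_q: float = 0.05
    apply_fdr: bool = True
    min_overlap: int = 30
    cutoffs: list | None = None                    # [negative, positive] or None -> calibrate
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 until: str | None = None) -> dict:
    """Run the analysis and return the manifest (also written as JSON).

    ``until`` stops after the named stage (a prefix run).  On stage failure a
    :class:`StageError` is raised; outputs of completed stages remain on disk
    and the manifest marks the failure.
    """
    if until is not None and until not in STAGES:
        raise ConfigError(f"unknown stage {until!r}; stages are {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "conditions": {}}
    want = STAGES[: STAGES.index(until) + 1] if until else STAGES

    gene_meta = pd.read_csv(config.genes, sep="\t") if config.genes else None
    positions = (dict(zip(gene_meta["gene"], gene_meta["genomic_pos_bp"]))
                 if gene_meta is not None and "genomic_pos_bp" in gene_meta else {})
    annotations = (calibrate.AnnotationMap.from_frame(gene_meta)
                   if gene_meta is not None and "module" in gene_meta else None)
    essential = (dict(zip(gene_meta["gene"], gene_meta["essential"].astype(bool)))
                 if gene_meta is not None and "essential" in gene_meta else None)

    conditions = sorted(config.colonies)
    if not conditions:
        raise ConfigError("no colony tables configured")

    state: dict = {}
    try:
        stage = "normalize"
        for cond in conditions:
            records = plates.read_colony_table(config.colonies[cond])
            n_in = len(records)
            normalized, plate_report = plates.normalize_screens(records)
            filtered, qc_report = plates.qc_filter(
                normalized, min_replicate_corr=config.min_replicate_corr,
                size_floor=config.size_floor)
            _write(plate_report, out / f"plate_qc_{cond}.tsv")
            _write(qc_report, out / f"screen_qc_{cond}.tsv")
            plates.write_colony_table(filtered, out / f"normalized_{cond}.tsv")
            queries = sorted(filtered["query"].unique())
            arrays = sorted(filtered["array"].unique())
            masked = plates.linkage_mask(queries, arrays, positions,
                                         config.linkage_window_bp, config.chromosome_bp)
            screen = plates.build_screen_matrix(filtered, masked_pairs=masked,
                                                condition=cond)
            state.setdefault("screens", {})[cond] = screen
            manifest["conditions"][cond] = {
                "colonies_in": n_in,
                "colonies_kept": len(filtered),
                "queries": len(screen.queries),
                "arrays": len(screen.arrays),
                "masked_cells": int(screen.mask.sum()),
            }
        manifest["stages"]["normalize"] = "complete"
        if "normalize" == want[-1]:
            raise _Done()

        stage = "score"
        for cond in conditions:
            screen = state["screens"][cond]
            fitness = scoring.estimate_single_fitness(screen)
            e = scoring.compute_escores(screen, fitness, sigma0=config.sigma0)
            e = scoring.attach_pvalues(e, screen, fitness,
                                       null_size=config.null_size,
                                       seed=config.seed + _SEED_OFFSET["score"])
            pairs = scoring.pair_table(e)
            state.setdefault("escores", {})[cond] = e
            state.setdefault("pairs", {})[cond] = pairs
            e.to_frame().to_csv(out / f"escore_matrix_{cond}.tsv", sep="\t",
                                float_format="%.6g")
            _write(pairs, out / f"escore_pairs_{cond}.tsv")
            manifest["conditions"][cond].update({
                "sigma0": e.sigma0,
                "pairs_measured": int(np.isfinite(pairs["E"]).sum()),
            })
        manifest["stages"]["score"] = "complete"
        if "score" == want[-1]:
            raise _Done()

        stage = "calibrate"
        cutoffs = {}
        for cond in conditions:
            if config.cutoffs is not None:
                cutoffs[cond] = tuple(config.cutoffs)
                continue
            if annotations is None:
                raise ConfigError("calibration requires gene metadata with bioprocess labels")
            result = calibrate.threshold_sweep(
                state["pairs"][cond], annotations, grid=config.grid,
                n_shuffles=config.n_shuffles,
                seed=config.seed + _SEED_OFFSET["calibrate"])
            _write(result.to_frame(), out / f"calibration_{cond}.tsv")
            cutoffs[cond] = result.cutoffs  # raises CalibrationError on failure
        state["cutoffs"] = cutoffs
        manifest["cutoffs"] = {c: list(v) for c, v in cutoffs.items()}
        manifest["stages"]["calibrate"] = "complete"
        if "calibrate" == want[-1]:
            raise _Done()

        stage = "network"
        for cond in conditions:
            pairs = state["pairs"][cond]
            edges = networks.call_interactions(pairs, cutoffs=cutoffs[cond],
                                               fdr_q=config.fdr_q,
                                               apply_fdr=config.apply_fdr)
            edges["condition"] = cond
            state.setdefault("edges", {})[cond] = edges
            _write(edges, out / f"edges_{cond}.tsv")
            stats_df = networks.topology_stats(edges)
            _write(stats_df, out / f"topology_{cond}.tsv")
            if annotations is not None:
                universe = pairs[np.isfinite(pairs["E"])
                                 & pairs["gene_a"].isin(annotations.label_of)
                                 & pairs["gene_b"].isin(annotations.label_of)]
                cross = networks.crosstalk_matrix(edges, universe, annotations)
                for sign, frame in cross.items():
                    _write(frame, out / f"crosstalk_{sign}_{cond}.tsv")
            if essential and len(edges):
                try:
                    fisher = networks.group_compare(edges, essential, test="fisher_ratio")
                    manifest["conditions"][cond]["essential_ratio_p"] = fisher.pvalue
                except ValueError:
                    pass
            # conservation accounting over unordered measured pair universe
            pairs_in = len(pairs)
            called = len(edges)
            screen = state["screens"][cond]
            manifest["conditions"][cond].update({
                "pairs_in": pairs_in,
                "pairs_called": called,
                "pairs_filtered": pairs_in - called,
                "cells_masked": int(screen.mask.sum()),
                "cells_unmeasured": int((~np.isfinite(screen.w) & ~screen.mask).sum()),
            })
        manifest["stages"]["network"] = "complete"
        if "network" == want[-1]:
            raise _Done()

        stage = "profiles"
        for cond in conditions:
            corrs = profiles.profile_correlation(state["escores"][cond],
                                                 min_overlap=config.min_overlap)
            state.setdefault("corrs", {})[cond] = corrs
            _write(corrs, out / f"profile_correlations_{cond}.tsv")
            reports = []
            for name, path in config.evidence.items():
                ev = pd.read_csv(path, sep="\t")
                ev_pairs = list(zip(ev.iloc[:, 0], ev.iloc[:, 1]))
                try:
                    res = profiles.evidence_shift_test(
                        corrs, ev_pairs, seed=config.seed + _SEED_OFFSET["profiles"])
                    reports.append({"evidence": name, **res})
                except ValueError as exc:
                    reports.append({"evidence": name, "error": str(exc)})
            if reports:
                _write(pd.DataFrame(reports), out / f"evidence_shift_{cond}.tsv")
        manifest["stages"]["profiles"] = "complete"
        if "profiles" == want[-1]:
            raise _Done()

        stage = "differential"
        if len(conditions) == 2:
            rich, minimal = ("rich", "minimal") if set(conditions) == {"rich", "minimal"} \
                else (conditions[0], conditions[1])
            diff = differential.differential_scores(
                state["escores"][rich], state["escores"][minimal],
                null_size=config.null_size,
                seed=config.seed + _SEED_OFFSET["differential"])
            diff_pairs = diff.to_pairs()
            if annotations is not None:
                calls, enrich = differential.classify_and_enrich(
                    diff_pairs, state["edges"][rich], state["edges"][minimal],
                    annotations, fdr_q=config.fdr_q)
                _write(calls, out / "differential_calls.tsv")
                _write(enrich, out / "differential_enrichment.tsv")
                manifest["n_differential_calls"] = len(calls)
            _write(diff_pairs, out / "differential_pairs.tsv")
            _write(diff.single_condition, out / "differential_single_condition.tsv")
            manifest["stages"]["differential"] = "complete"
        else:
            manifest["stages"]["differential"] = "skipped (needs exactly 2 conditions)"
    except _Done:
        pass
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise StageError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


class _Done(Exception):
    """Internal control flow: stop after the requested stage."""
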