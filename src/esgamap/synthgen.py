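"""Synthetic double-mutant colony screens with planted genetic interactions.

This module builds ground-truth interaction networks and turns them into raw
colony-size tables with the statistical structure real arrayed screens show:
multiplicative double-mutant fitness, a neutral majority of gene pairs with
signed aggravating/alleviating tails, a detached synthetic-lethal mode,
module- (bioprocess-) structured interactions, condition-dependent rewiring
between rich and minimal medium, plate row/column/edge artifacts, pinning
dropout, and lognormal replicate noise.  Every downstream stage of the
pipeline can therefore be validated by parameter recovery without any
external data.

The double-mutant expectation is multiplicative: the expected colony size of
the (i, j) double mutant is ``base_size * Wi * Wj * (1 + delta_ij)``, where
``Wi`` and ``Wj`` are single-mutant relative fitnesses and ``delta_ij`` is
the planted multiplicative deviation (0 for non-interacting pairs, negative
for aggravating, positive for alleviating).  Planted effects are stored as
target E-scores (standardized deviations) and converted to multiplicative
deltas through the same noise scale the scoring stage will estimate, so the
generator does not depend on the scoring formula's internals.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CHROMOSOME_BP",
    "CONDITIONS",
    "EffectModel",
    "NoiseModel",
    "PlateLayout",
    "GroundTruthNetwork",
    "generate_ground_truth",
    "simulate_screens",
    "simulate_escore_matrices",
    "delta_for_escore",
    "write_fixture",
    "read_truth",
]

#: E. coli K-12 chromosome length used for genomic coordinates (circular).
CHROMOSOME_BP = 4_641_652

#: Default growth conditions screened.
CONDITIONS = ("rich", "minimal")

#: Residual double-mutant fitness of a synthetic-lethal pair (micro-colony).
LETHAL_FITNESS = 0.02


class ParameterError(ValueError):
    """Invalid generator parameter (rates outside [0,1], bad shapes, ...)."""


class LayoutError(ValueError):
    """A gene required by the simulation is absent from the plate layout."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must be a probability in [0, 1], got {value}")


@dataclass
class EffectModel:
    """Distribution of planted interaction effects, on the E-score scale.

    ``magnitude_mean``/``magnitude_sd`` parameterize the |E| of a planted
    interaction; the sign is aggravating (negative) with probability
    ``aggravating_frac``.  Each interacting pair is assigned one of four
    condition classes mirroring condition-dependent rewiring: present in both
    conditions, rich-only, minimal-only, or sign-flip (opposite signs in the
    two conditions).
    """

    magnitude_mean: float = 3.0
    magnitude_sd: float = 0.5
    magnitude_min: float = 1.0
    aggravating_frac: float = 0.65
    p_both: float = 0.7
    p_rich_only: float = 0.1
    p_minimal_only: float = 0.1
    p_sign_flip: float = 0.1

    def __post_init__(self) -> None:
        for name in ("aggravating_frac", "p_both", "p_rich_only", "p_minimal_only", "p_sign_flip"):
            _check_prob(name, getattr(self, name))
        total = self.p_both + self.p_rich_only + self.p_minimal_only + self.p_sign_flip
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"condition-class probabilities must sum to 1, got {total}")


@dataclass
class NoiseModel:
    """Measurement artifacts applied to simulated colony sizes.

    multiplicative_cv : lognormal replicate noise, as a coefficient of
        variation (0.10 is the regime of high-quality screens).
    row_gradient, col_gradient : log-linear spatial gradients per row/column
        index (slope of log colony size).
    edge_boost : multiplicative inflation of the outermost ring of colonies
        (edge colonies have more agar per colony and grow larger).
    dropout_rate : probability that a pinning fails and the colony is missing.
    """

    multiplicative_cv: float = 0.10
    row_gradient: float = 0.0
    col_gradient: float = 0.0
    edge_boost: float = 0.0
    dropout_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("multiplicative_cv", "row_gradient", "col_gradient", "edge_boost"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        _check_prob("dropout_rate", self.dropout_rate)
        if self.dropout_rate >= 0.5:
            raise ParameterError("dropout_rate must be < 0.5")


@dataclass
class PlateLayout:
    """Assignment of array genes to (plate, row, col) positions per replicate.

    Rows and columns are 1-based, matching plate convention.  By default each
    array gene keeps the same position on every replicate plate.
    """

    n_rows: int = 32
    n_cols: int = 48
    replicate_plates: int = 3
    position_of: dict = field(default_factory=dict)  # (array, rep) -> (plate, row, col)

    @classmethod
    def from_arrays(
        cls,
        arrays: list[str],
        n_rows: int = 32,
        n_cols: int = 48,
        replicate_plates: int = 3,
        seed: int = 0,
        shuffle: bool = True,
    ) -> "PlateLayout":
        if replicate_plates < 2:
            raise ParameterError("replicate_plates must be >= 2")
        rng = np.random.default_rng(seed)
        per_plate = n_rows * n_cols
        order = np.array(arrays, dtype=object)
        if shuffle:
            order = order[rng.permutation(len(order))]
        position_of: dict = {}
        for idx, gene in enumerate(order):
            plate = f"P{idx // per_plate + 1:02d}"
            offset = idx % per_plate
            row = offset // n_cols + 1
            col = offset % n_cols + 1
            for rep in range(1, replicate_plates + 1):
                position_of[(gene, rep)] = (plate, row, col)
        return cls(n_rows=n_rows, n_cols=n_cols, replicate_plates=replicate_plates,
                   position_of=position_of)


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class GroundTruthNetwork:
    """Planted single-mutant fitnesses, module labels and interactions.

    ``interactions`` maps an unordered gene pair (lexicographically sorted
    tuple) to ``{condition: target E-score}``; a pair absent from the map (or
    a condition absent from its dict) does not interact there.  Zero effects
    are never stored.  ``lethal_pairs`` is the subset of aggravating pairs
    whose double-mutant fitness is forced to ~0 (synthetic lethal).
    """

    genes: list[str]
    single_fitness: dict[str, float]
    essential_flag: dict[str, bool]
    module_label: dict[str, str]
    position_bp: dict[str, int]
    interactions: dict[tuple[str, str], dict[str, float]]
    lethal_pairs: set[tuple[str, str]]
    condition_set: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        for (a, b), effects in self.interactions.items():
            if a not in gene_set or b not in gene_set:
                raise ParameterError(f"interacting pair ({a},{b}) not in gene list")
            if any(e == 0 for e in effects.values()):
                raise ParameterError("zero effects must not be stored")
        for g, w in self.single_fitness.items():
            if w <= 0:
                raise ParameterError(f"single fitness must be positive ({g}: {w})")

    def effect(self, a: str, b: str, condition: str) -> float:
        return self.interactions.get(_pair_key(a, b), {}).get(condition, 0.0)

    def interacting_pairs(self, condition: str) -> set[tuple[str, str]]:
        return {p for p, eff in self.interactions.items() if condition in eff}

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update(repr(sorted(self.single_fitness.items())).encode())
        h.update(repr(sorted((p, tuple(sorted(e.items()))) for p, e in self.interactions.items())).encode())
        return h.hexdigest()


def generate_ground_truth(
    n_genes: int,
    n_modules: int,
    within_rate: float,
    between_rate: float,
    effect_dist: EffectModel | None = None,
    lethal_fraction: float = 0.10,
    seed: int = 0,
    essential_fraction: float = 0.16,
    essential_rate_boost: float = 1.0,
    crosstalk: dict[tuple[int, int], float] | None = None,
    sign_coherence: float = 0.0,
    conditions: tuple[str, ...] = CONDITIONS,
) -> GroundTruthNetwork:
    """Sample a module-structured interaction network with planted effects.

    Gene pairs within the same module interact with probability
    ``within_rate``, pairs across modules with ``between_rate``
    (``within_rate >= between_rate``); ``crosstalk`` optionally elevates the
    rate of selected module-index pairs, planting bioprocess crosstalk.
    ``essential_rate_boost`` multiplies the interaction probability of pairs
    involving an essential gene, so that essential genes become network hubs
    when > 1.  ``lethal_fraction`` of aggravating pairs is promoted to
    synthetic lethality (double-mutant fitness forced to ~0), producing the
    detached left mode of the E-score distribution.

    ``sign_coherence`` is the probability that an interacting gene pair
    inherits the latent sign and magnitude of its module pair instead of an
    independent draw.  Coherent effects make genes of a module share
    consistently-signed partners, which is what gives functionally related
    genes correlated interaction profiles.
    """
    effect = effect_dist or EffectModel()
    _check_prob("within_rate", within_rate)
    _check_prob("between_rate", between_rate)
    _check_prob("lethal_fraction", lethal_fraction)
    _check_prob("essential_fraction", essential_fraction)
    if within_rate < between_rate:
        raise ParameterError("within_rate must be >= between_rate")
    if n_modules < 1:
        raise ParameterError("n_modules must be >= 1")
    if n_genes < 2 * n_modules:
        raise ParameterError("n_genes must be >= 2 * n_modules")
    if essential_rate_boost < 1.0:
        raise ParameterError("essential_rate_boost must be >= 1")
    _check_prob("sign_coherence", sign_coherence)
    for (ma, mb), rate in (crosstalk or {}).items():
        _check_prob(f"crosstalk[{ma},{mb}]", rate)
        if not (0 <= ma < n_modules and 0 <= mb < n_modules):
            raise ParameterError(f"crosstalk module indices ({ma},{mb}) out of range")

    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]

    modules = np.repeat(np.arange(n_modules), int(np.ceil(n_genes / n_modules)))[:n_genes]
    modules = modules[rng.permutation(n_genes)]
    module_label = {g: f"bioprocess{m + 1:02d}" for g, m in zip(genes, modules)}

    essential = rng.random(n_genes) < essential_fraction
    fitness = np.where(
        essential,
        rng.uniform(0.3, 0.9, n_genes),   # hypomorphic alleles of essentials
        rng.uniform(0.4, 1.1, n_genes),   # whole-gene deletions
    )
    positions = rng.choice(CHROMOSOME_BP, size=n_genes, replace=False)

    idx_a, idx_b = np.triu_indices(n_genes, k=1)
    same_module = modules[idx_a] == modules[idx_b]
    rate = np.where(same_module, within_rate, between_rate).astype(float)
    if crosstalk:
        mlo = np.minimum(modules[idx_a], modules[idx_b])
        mhi = np.maximum(modules[idx_a], modules[idx_b])
        for (ma, mb), xrate in crosstalk.items():
            sel = (mlo == min(ma, mb)) & (mhi == max(ma, mb))
            rate[sel] = xrate
    boosted = essential[idx_a] | essential[idx_b]
    rate = np.minimum(rate * np.where(boosted, essential_rate_boost, 1.0), 1.0)
    hit = rng.random(len(rate)) < rate

    # latent per-module-pair effect, inherited with probability sign_coherence
    latent_sign = np.where(rng.random((n_modules, n_modules)) < effect.aggravating_frac,
                           -1.0, 1.0)
    latent_mag = np.maximum(effect.magnitude_min,
                            rng.normal(effect.magnitude_mean, effect.magnitude_sd,
                                       (n_modules, n_modules)))
    latent_sign = np.triu(latent_sign) + np.triu(latent_sign, 1).T
    latent_mag = np.triu(latent_mag) + np.triu(latent_mag, 1).T

    interactions: dict[tuple[str, str], dict[str, float]] = {}
    lethal_pairs: set[tuple[str, str]] = set()
    class_probs = [effect.p_both, effect.p_rich_only, effect.p_minimal_only, effect.p_sign_flip]
    if len(conditions) == 1:
        class_probs = [1.0, 0.0, 0.0, 0.0]
    for ia, ib in zip(idx_a[hit], idx_b[hit]):
        pair = _pair_key(genes[ia], genes[ib])
        if rng.random() < sign_coherence:
            mag = max(effect.magnitude_min,
                      latent_mag[modules[ia], modules[ib]] + rng.normal(0.0, 0.3))
            sign = latent_sign[modules[ia], modules[ib]]
        else:
            mag = max(effect.magnitude_min,
                      rng.normal(effect.magnitude_mean, effect.magnitude_sd))
            sign = -1.0 if rng.random() < effect.aggravating_frac else 1.0
        cls = rng.choice(4, p=class_probs)
        if cls == 0:
            eff = {c: sign * mag for c in conditions}
        elif cls == 1:
            eff = {conditions[0]: sign * mag}
        elif cls == 2:
            eff = {conditions[-1]: sign * mag}
        else:
            eff = {conditions[0]: sign * mag, conditions[-1]: -sign * mag}
        interactions[pair] = eff
        if any(e < 0 for e in eff.values()) and rng.random() < lethal_fraction:
            lethal_pairs.add(pair)

    return GroundTruthNetwork(
        genes=genes,
        single_fitness=dict(zip(genes, fitness)),
        essential_flag=dict(zip(genes, map(bool, essential))),
        module_label=module_label,
        position_bp=dict(zip(genes, map(int, positions))),
        interactions=interactions,
        lethal_pairs=lethal_pairs,
        condition_set=tuple(conditions),
    )


def delta_for_escore(target_e: float, noise: NoiseModel, n_replicates: int) -> float:
    """Multiplicative deviation (1+delta factor) realizing a target E-score.

    The scoring stage standardizes the deviation of the replicate-mean
    normalized fitness by ``sigma_hat = sqrt(sd^2/n + sigma0^2)`` with
    ``sigma0`` close to the modal replicate SD (~cv on the normalized scale),
    so a deviation ``delta`` in units of the typical colony produces
    ``E ~ delta / (cv * sqrt(1 + 1/n))``.  Inverting that relation plants
    effects whose expected E-score equals ``target_e``.
    """
    cv = noise.multiplicative_cv
    return target_e * cv * np.sqrt(1.0 + 1.0 / n_replicates)


def simulate_screens(
    truth: GroundTruthNetwork,
    layout: PlateLayout | None = None,
    noise: NoiseModel | None = None,
    base_size: float = 1000.0,
    queries: list[str] | None = None,
    conditions: tuple[str, ...] | None = None,
) -> dict[str, pd.DataFrame]:
    """Emit raw colony-size tables, one DataFrame per condition.

    Every (query, array, replicate) combination yields exactly one record;
    dropout colonies are emitted with ``missing_flag=1`` and an empty size,
    never silently omitted.  Columns: query, array, plate, row, col,
    replicate, condition, size, missing_flag.  The plate id concatenates the
    query and the layout plate so that (plate, row, col, replicate,
    condition) is globally unique.
    """
    noise = noise or NoiseModel()
    conditions = tuple(conditions or truth.condition_set)
    queries = list(queries or truth.genes)
    arrays = list(truth.genes)
    layout = layout or PlateLayout.from_arrays(arrays, seed=noise.seed)

    for g in arrays:
        if (g, 1) not in layout.position_of:
            raise LayoutError(f"array gene {g!r} has no position in the layout")
    missing_q = [q for q in queries if q not in truth.single_fitness]
    if missing_q:
        raise LayoutError(f"query genes absent from truth: {missing_q[:5]}")

    rng = np.random.default_rng(noise.seed)
    n_rep = layout.replicate_plates
    sigma_log = np.sqrt(np.log1p(noise.multiplicative_cv ** 2))

    w_arr = np.array([truth.single_fitness[g] for g in arrays])
    pos = {rep: np.array([layout.position_of[(g, rep)] for g in arrays], dtype=object)
           for rep in range(1, n_rep + 1)}

    out: dict[str, pd.DataFrame] = {}
    n_a = len(arrays)
    row_mid = (layout.n_rows + 1) / 2.0
    col_mid = (layout.n_cols + 1) / 2.0
    for condition in conditions:
        frames = []
        # planted multiplicative factors per (query, array)
        for q in queries:
            wq = truth.single_fitness[q]
            factor = np.ones(n_a)
            for j, a in enumerate(arrays):
                if a == q:
                    continue
                pair = _pair_key(q, a)
                eff = truth.interactions.get(pair)
                if eff is None or condition not in eff:
                    continue
                if pair in truth.lethal_pairs and eff[condition] < 0:
                    # synthetic lethal: force double-mutant fitness to ~0
                    factor[j] = LETHAL_FITNESS / (wq * w_arr[j])
                else:
                    factor[j] = 1.0 + delta_for_escore(eff[condition], noise, n_rep)
            expected = base_size * wq * w_arr * np.clip(factor, 0.0, None)
            for rep in range(1, n_rep + 1):
                plates = np.array([p[0] for p in pos[rep]], dtype=object)
                rows = np.array([p[1] for p in pos[rep]], dtype=int)
                cols = np.array([p[2] for p in pos[rep]], dtype=int)
                spatial = np.exp(noise.row_gradient * (rows - row_mid)
                                 + noise.col_gradient * (cols - col_mid))
                edge = (rows == 1) | (rows == layout.n_rows) | (cols == 1) | (cols == layout.n_cols)
                spatial = spatial * np.where(edge, 1.0 + noise.edge_boost, 1.0)
                if sigma_log > 0:
                    eps = np.exp(rng.normal(-0.5 * sigma_log ** 2, sigma_log, n_a))
                else:
                    eps = np.ones(n_a)
                size = expected * spatial * eps
                missing = rng.random(n_a) < noise.dropout_rate
                size = np.where(missing, np.nan, size)
                frames.append(pd.DataFrame({
                    "query": q,
                    "array": arrays,
                    "plate": [f"{q}.{p}" for p in plates],
                    "row": rows,
                    "col": cols,
                    "replicate": rep,
                    "condition": condition,
                    "size": size,
                    "missing_flag": missing.astype(int),
                }))
        out[condition] = pd.concat(frames, ignore_index=True)
    return out


def simulate_escore_matrices(
    truth: GroundTruthNetwork,
    queries: list[str] | None = None,
    noise_sd: float = 0.5,
    sem_frac: float = 1.0,
    seed: int = 0,
    conditions: tuple[str, ...] | None = None,
):
    """Shortcut generator: E-score matrices sampled directly from the truth.

    Used by benchmarks that exercise only post-scoring stages (profiles,
    differential, calibration) where re-simulating colonies adds nothing.
    Each measured cell gets ``E = target + N(0, noise_sd)``; the per-cell
    sampling variance reported to downstream consumers is
    ``(sem_frac * noise_sd)^2``, mirroring the fraction of the score
    denominator that is replicate sampling error rather than the regularizer.
    Returns ``{condition: EScoreMatrix}`` (p-values not attached).
    """
    from .scoring import EScoreMatrix  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    conditions = tuple(conditions or truth.condition_set)
    queries = list(queries or truth.genes)
    arrays = list(truth.genes)
    out = {}
    for condition in conditions:
        target = np.zeros((len(queries), len(arrays)))
        for (a, b), eff in truth.interactions.items():
            e = eff.get(condition)
            if e is None:
                continue
            for qi, ai in ((a, b), (b, a)):
                if qi in queries and ai in arrays:
                    target[queries.index(qi), arrays.index(ai)] = e
        e_mat = target + rng.normal(0.0, noise_sd, target.shape)
        for i, q in enumerate(queries):  # self pairs unmeasured
            if q in arrays:
                e_mat[i, arrays.index(q)] = np.nan
        evar = np.full(e_mat.shape, (sem_frac * noise_sd) ** 2)
        out[condition] = EScoreMatrix(
            queries=list(queries), arrays=list(arrays), e=e_mat, evar=evar,
            condition=condition, sigma0=np.nan,
            provenance={"generator": "simulate_escore_matrices", "noise_sd": noise_sd,
                        "seed": seed},
        )
    return out


# ---------------------------------------------------------------------------
# fixture I/O

def write_fixture(truth: GroundTruthNetwork, records: dict[str, pd.DataFrame],
                  directory: str | Path) -> list[Path]:
    """Write colony tables, planted edges and gene metadata as TSV files."""
    from . import plates  # colony-table writer owns the schema

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for condition, df in records.items():
        path = directory / f"colonies_{condition}.tsv"
        plates.write_colony_table(df, path)
        written.append(path)

    edge_rows = [
        {"gene_a": a, "gene_b": b, "condition": cond, "effect": eff,
         "lethal": int((a, b) in truth.lethal_pairs and eff < 0)}
        for (a, b), effects in sorted(truth.interactions.items())
        for cond, eff in sorted(effects.items())
    ]
    edges = pd.DataFrame(edge_rows, columns=["gene_a", "gene_b", "condition", "effect", "lethal"])
    edges_path = directory / "truth_edges.tsv"
    edges.to_csv(edges_path, sep="\t", index=False)
    written.append(edges_path)

    genes = pd.DataFrame({
        "gene": truth.genes,
        "fitness": [truth.single_fitness[g] for g in truth.genes],
        "essential": [int(truth.essential_flag[g]) for g in truth.genes],
        "module": [truth.module_label[g] for g in truth.genes],
        "genomic_pos_bp": [truth.position_bp[g] for g in truth.genes],
    })
    genes_path = directory / "genes.tsv"
    genes.to_csv(genes_path, sep="\t", index=False)
    written.append(genes_path)
    return written


def read_truth(directory: str | Path) -> GroundTruthNetwork:
    """Re-assemble a GroundTruthNetwork from a fixture directory."""
    directory = Path(directory)
    genes = pd.read_csv(directory / "genes.tsv", sep="\t")
    edges = pd.read_csv(directory / "truth_edges.tsv", sep="\t")
    interactions: dict[tuple[str, str], dict[str, float]] = {}
    lethal: set[tuple[str, str]] = set()
    for rec in edges.itertuples(index=False):
        pair = _pair_key(rec.gene_a, rec.gene_b)
        interactions.setdefault(pair, {})[rec.condition] = float(rec.effect)
        if rec.lethal:
            lethal.add(pair)
    conditions = tuple(sorted(edges["condition"].unique())) if len(edges) else CONDITIONS
    return GroundTruthNetwork(
        genes=list(genes["gene"]),
        single_fitness=dict(zip(genes["gene"], genes["fitness"])),
        essential_flag=dict(zip(genes["gene"], genes["essential"].astype(bool))),
        module_label=dict(zip(genes["gene"], genes["module"])),
        position_bp=dict(zip(genes["gene"], genes["genomic_pos_bp"])),
        interactions=interactions,
        lethal_pairs=lethal,
        condition_set=conditions,
    )
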