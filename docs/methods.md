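# Methods

`esgamap` turns replicate colony-size tables from arrayed double-mutant
screens (conjugation-based synthetic genetic arrays scored under two growth
conditions) into calibrated, signed genetic-interaction networks, and ships
a synthetic-screen generator so that every stage is testable by parameter
recovery.  This note records the models, the parameters that matter, the
numerical choices, and what the synthetic benchmarks do and do not show.

## The multiplicative epistasis model

Relative growth of a double mutant of functionally unrelated genes is
modelled as the product of the single-mutant fitnesses, `Wij = Wi * Wj`.
A genetic interaction is a significant deviation from this expectation:
aggravating (synthetic sick/lethal) when the double mutant grows worse than
predicted, alleviating (buffering, same-pathway) when it grows better.  The
interaction statistic is a standardized deviation

    E(i,j) = (Wij − Wi·Wj) / sqrt( s²(i,j)/n + (σ₀ · Wi·Wj)² )

with `s²` the (moderated) replicate variance of the cell, `n` the replicate
count, and `σ₀` the modal *relative* replicate SD of the whole matrix.

Two numerical choices here deserve justification:

- **Proportional error floor.** Colony noise is multiplicative — replicate
  SDs scale with the colony's size — so a constant additive floor
  under-regularizes large colonies and over-regularizes small ones.  With a
  constant floor the null E distribution acquires a heavy upper tail driven
  entirely by high-fitness cells (we measured ~0.5% of null mass beyond 4
  robust SDs, eighty times the Gaussian expectation), which corrupts both
  the permutation null and FDR calling.  Scaling the floor by the cell's
  expectation makes E homoscedastic across fitness levels.
- **Variance moderation.** With 2–3 replicates a per-cell variance estimate
  has 1–2 degrees of freedom and its sampling noise dominates the score
  scale.  Each relative variance is shrunk toward σ₀² with a prior weight of
  4 pseudo-replicates (empirical-Bayes moderation in the style of
  moderated-t statistics).  This cuts the residual leptokurtosis of null E
  roughly threefold while retaining per-cell confidence information.

Single-mutant fitnesses are estimated from the screen itself: the array
fitness `Wj` is the median of its column, the query fitness `Wi` the median
of `Wij / Wj` across arrays; medians tolerate the minority (<20%) of true
interactions.  The remaining free scale (any `a` applied to queries and
`1/a` to arrays leaves all products unchanged) is fixed by equating the two
marginal medians.  Note that per-plate scaling absorbs most of the query's
own fitness, so query-side estimates sit near 1 by construction; all
downstream quantities depend only on the product `Wi·Wj`.

## Plate normalization

Raw colony sizes carry plate-scale, row/column and edge-ring artifacts.
`normalize_screens` applies, in order: (1) division by the plate median
(typical colony → 1.0); (2) a per-array **reference**: the median of each
array gene's scaled size across all plates of the condition; (3) a
significance-gated edge-ring correction and (4) an iterated row/column
median polish, both computed on the colony/reference *ratio* surface.

The reference step exists because within a single plate, row and column
medians confound genuine spatial artifacts with the fitness composition of
whichever array genes sit in that row or column — on sparsely filled plates
we observed spurious "corrections" of ±40% that both erased real
interactions and fabricated false ones.  Because the same physical layout
recurs on every plate, dividing by the cross-plate typical size removes the
biological component and leaves a surface that is ~1 everywhere except for
spatial artifacts and the sparse interactions.

Further safeguards: rows/columns with fewer than 6 colonies receive no
correction (their median mostly *is* the colonies), corrections are
multiplicative factors estimated on positive colonies and applied to all
(dead colonies stay exactly zero, missing stays missing), and the edge
correction fires only when the edge/interior log-ratio exceeds 3 standard
errors of the two medians — which is also what makes the single-plate
`normalize_plate` idempotent to machine precision: on already-corrected
data, every step is a provable no-op.

Quality control: plates with >50% missing colonies are rejected; screens
(condition × query) whose mean between-replicate Pearson correlation falls
below 0.5 are excluded; a colony below the size floor (0.05 on the
normalized scale) in exactly one replicate while others grew is treated as
a pinning failure and set missing.  Array genes within 30 kb of the query
on the circular 4,641,652-bp chromosome are masked, since conjugation
under-transfers loci linked to the query; the window is a configurable
parameter reported in run metadata, not a literature constant.

## Empirical confidence and the neutral-restricted permutation null

p-values come from a permutation null: within each screen row, the
fitness-normalized residuals `R = Wij/(Wi·Wj)` of cells in the neutral peak
(|E| < 4 robust SDs) are permuted among those cells together with their
replicate SDs, E is recomputed on the recombined triples, and 100
permutations are pooled; `p = (1 + #{|E_null| ≥ |E|}) / (1 + N)`.

Restricting the pool to the neutral peak is essential, not cosmetic: true
interactions contribute their own residuals to an unrestricted pool, which
floors every empirical p at roughly half the interaction density.  Since
Benjamini–Hochberg at q demands `p ≤ q·k/m` for the k-th of m ordered
tests, that floor exceeds the BH threshold by a factor of about `1/(2q)`
*regardless of interaction density* — FDR-controlled calling would return
nothing.  With the neutral-restricted pool the p floor is `1/(1+N)` with
`N ≈ cells × permutations`, and under the no-interaction null the exclusion
removes ~6×10⁻⁵ of genuine mass, far inside the calibration tolerance we
verify (fraction of p < α within the 99% binomial band of α at ~29,000
cells).

The same construction carries to the differential analysis.  For pairs
measured in both conditions, `dE = E_minimal − E_rich` (positive reads
"more alleviating under nutrient limitation").  The null recombines rich
and minimal values of neutral-in-both cells within rows and re-differences
them.  A replicate-level condition swap confined to each pair's own two
measurements was considered and rejected: it generates only sign flips of
the observed `dE`, so the pooled null would be the observed |dE| multiset —
floored at ~1/n and contaminated by true differential pairs, with the same
FDR-killing arithmetic as above.  Cross-cell recombination is exact under
the null (cells are exchangeable) and gives the pool `n × null_size`
distinct magnitudes.

Measurement orientations (gene pair measured with either member as the
query) are merged by inverse-variance weighting of the two E values;
orientation pairs with opposite signs differing by more than 4 are flagged
and excluded from calling.

## Cutoff calibration by bioprocess enrichment

Thresholds are chosen by sweeping |E| over [1, 4] in 0.5 steps and, per
sign, counting bioprocess label pairs enriched for interactions (one-sided
Fisher exact — computed as the hypergeometric tail, which is identical and
vectorizes — with Benjamini–Hochberg across the ~K²/2 label pairs, adjusted
p ≤ 0.05).  Enriched-pair counts are Poisson-noisy, so the chosen cutoff
per sign is the smallest threshold whose count is statistically tied with
the maximum (within one SE, √max), breaking ties toward the smaller
threshold to preserve sensitivity; a maximum of zero is an explicit
calibration failure.  The tie rule matters on the aggravating side, where
synthetic-lethal pairs (|E| ≫ 4) keep high-threshold edge sets pure and
enriched — the count curve there is a broad plateau rather than a sharp
peak, and a strict argmax would wander over it with the seed.  A
control repeats the sweep 20 times with gene→bioprocess labels shuffled.
The enrichment universe is annotated pairs with a defined E-score, so
linkage-masked cells can never masquerade as enrichment.

The apex of the enrichment curve sits at an intermediate threshold only
when permissive thresholds admit enough noise edges to dilute enrichment —
with dense planted signal the count saturates from |E| = 1 onward.  The
benchmark scenario therefore plants *sparse* signal (8% of within-module
pairs, 4% across designated crosstalk module pairs, |E| ~ N(3, 0.5), 600
genes in 20 modules, sized so the per-label-pair Fisher tests are well
powered at the intermediate thresholds), with the rates chosen a priori by
tail-mass arithmetic: at |E| = 1
the per-sign noise rate (~2%) rivals the planted rate and washes out the
Fisher tests, while from 1.5–2.5 planted edges dominate.  This mirrors the
regime of real screens, where true interaction rates per bioprocess pair
are low.

## Network statistics, profiles, differential classes

Interaction calls use the calibrated cutoffs inclusively (E ≤ negative
cutoff aggravating, E ≥ positive cutoff alleviating) intersected with
BH-adjusted empirical p ≤ 0.05 (the FDR intersection is configurable off).
Crosstalk matrices run the same Fisher+BH machinery per sign.  Degree and
betweenness (exact, unweighted, normalized by (n−1)(n−2)/2) come from
networkx on the simple undirected graph; group contrasts between essential
and non-essential genes use a two-sided Fisher ratio test on
alleviating:aggravating counts (a pair counts as essential when at least
one member is), the two-sample rank-sum test, or KS, with exact enumeration
when both samples are ≤ 12.

Profile correlations are Pearson (Spearman by flag) over the shared array
axis, excluding positions involving either gene of the pair and requiring
30 shared measurements; evidence-shift tests compare evidence pairs against
10× randomly drawn measured pairs by two-sample KS.

Differential pairs significant at BH q ≤ 0.05 are classified from their
per-condition calls: rich-/minimal-specific aggravating or alleviating,
and sign-flip; concordant pairs (same sign in both conditions) are mapped
but not emitted as differential interactions.  Per-bioprocess enrichment of
differential pairs counts gene-incidence (a pair is incident to a label if
either member carries it) against the measured-in-both universe.

## The synthetic-screen generator

`synthgen` defines the study conditions under which the pipeline is
validated.  Defaults, chosen once as realistic for this screen format:
32×48 plates with 3 replicate pinnings; lognormal replicate noise with CV
0.10 (the regime of high-quality screens — between-replicate r > 0.8 then
*emerges* from the generator+normalization pair rather than being
asserted); 5% pinning dropout (10% in the recovery benchmark); single-mutant
fitness U(0.4, 1.1) for deletions and U(0.3, 0.9) for hypomorphic alleles
of essentials (deletion fitness effects are broad, and this spread is what
makes replicate correlation informative); 16% essential genes; effect
magnitudes |E| ~ N(3, 0.5) with 65% aggravating; 10% of aggravating pairs
promoted to synthetic lethality (double-mutant fitness forced to ~0.02,
producing the detached left mode of the E histogram); condition classes
both/rich-only/minimal-only/sign-flip with probabilities 0.7/0.1/0.1/0.1.

Planted effects are stored as target E-scores and converted to
multiplicative `(1+δ)` factors through the same noise scale the scoring
stage estimates (`δ ≈ E_target · cv · sqrt(1 + 1/n)`), so the generator
never needs the scoring formula's internals.  Module-structured
interactions use per-pair Bernoulli rates (within/between/crosstalk);
`sign_coherence` controls whether an interacting pair inherits the latent
sign and magnitude of its module pair — coherence is what gives genes of a
module consistently-signed shared partners and hence correlated interaction
profiles, and is set to 1 in the profile benchmarks and 0 where both signs
are needed within each module.

What the generator does *not* emulate: batch effects across days or robot
runs, agar thickness gradients beyond log-linear row/column trends,
neighbour competition between adjacent colonies, image-segmentation
artifacts, and strain cross-contamination.  Passing benchmarks therefore
demonstrate correctness of the statistical machinery under the stated noise
model, not robustness to every failure mode of real plates.

## Benchmark problem sizes

The benchmark battery (`esgamap.benchmarks`, exercised by the acceptance
tests and by `scripts/acceptance.py`) uses: 40 genes for the noiseless
identity; 100 queries × 300 arrays for null calibration (~29,000 cells); 10
seeds × 80 genes × 2 conditions for planted recovery (calls at ±2 with BH
q = 0.05); 600 genes / 20 bioprocesses for the threshold sweep; 100 runs of
40-gene double screens for differential recovery plus 20 interaction-free
runs for p_diff calibration; 100 runs of 50-gene screens for the profile
shift; and one 1536-colony plate with an injected 2%/row gradient and ×1.5
edge ring for the normalization checks.  These sizes give the binomial and
recovery margins quoted above while the whole battery completes in a few
minutes on one CPU.

## Known limitations

- Query-side single-mutant fitness is not recoverable after per-plate
  scaling (only products matter downstream); recovering absolute `Wi`
  requires an external growth assay.
- The permutation null assumes multiplicative, row-exchangeable noise;
  strongly heteroscedastic artifacts that survive normalization would
  miscalibrate it.
- The linkage window (30 kb) and the neutral-peak trim (4 robust SDs) are
  configurable conventions, not estimated quantities.
- With only two conditions, the differential analysis cannot separate
  condition-specific biology from condition-specific measurement error;
  replicate screens across days would be needed for that.
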