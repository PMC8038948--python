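# Methods

## Model and assumptions

The analysis treats a two-color SMLM acquisition of one cell as two planar
point sets of "molecules" and asks whether cross-channel pairs are closer
than local density can explain. The core assumptions are:

- after grouping, molecule positions are independent draws from each
  species' (inhomogeneous) spatial distribution — grouping exists
  precisely to remove the blink-level autocorrelation that would violate
  this;
- the relevant null for a candidate pair is *local*: only molecules within
  the neighborhood radius of the pair centroid inform the expected
  gap, which makes the test robust to large-scale density variation
  (nucleus vs cytoplasm, clusters) without modeling it;
- binding manifests as a cross-channel distance below a physical ceiling
  set by label geometry. With a primary + dye-conjugated secondary
  antibody stack on each side, bound epitopes can put the two fluorophores
  ~50–70 nm apart; 200 nm is the ceiling with allowance for error.

## Pipeline parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| grouping.radius | 34.2 | nm | stage-1 spatial search radius; the physical extent of a flexing antibody stack |
| grouping.temporal_window | 500 | frames | stage-1/2 temporal criterion (5.0 s at 10 ms/frame); bridges long fluorophore off-times |
| grouping.merge_radius | 200 | nm | stage-2 spatial criterion on group mean positions |
| io first/last exclusion | 100 / 10 | frames | discard ramp-in frames (fluorophores not yet dark) and end-of-stack artifacts |
| association.radius | 800 | nm | neighborhood radius r; the knee between sensitivity (small r) and robustness (large r) on radius sweeps |
| association.n_permutations | 10000 | – | Monte Carlo draws per pair |
| association.p_threshold | 0.1 | – | association calls require p(chance association) below this |
| association.max_binding_distance | 200 | nm | association calls require d_min below this |
| simulate.area | 250 | μm² | circular cell area; radius ≈ 8920.6 nm |

The temporal window is interpreted as |Δframe| ≤ window (each side of the
seed). The alternative reading — 500 frames *total*, i.e. |Δframe| ≤ 250 —
is defensible; the parameter is exposed so either convention can be run.

## Design choices where the design was open

**Stage-2 merge keeps the temporal criterion.** Stage 2 reruns the
density-maxima search over stage-1 groups with the 200 nm radius on group
mean positions; merge eligibility additionally requires the gap between
the two groups' frame intervals to be at most the temporal window. A
purely spatial stage 2 was considered and rejected: it makes any two
co-located groups merge unconditionally, so the final molecule count
becomes almost independent of the temporal window — the
molecules-remaining-vs-window diagnostic would be flat and the window
un-tunable. Keeping time in stage 2 is what lets the window size govern
how aggressively temporally separated blink clusters merge. The merge is
iterated to a fixed point, re-evaluating maxima after each merge; chains
of pairwise-eligible groups can therefore collapse across more than
200 nm, a deliberate bias toward merging nearby clusters.

**Stage-1 seeds count only unassigned localizations.** Neighbor counts are
recomputed among unassigned localizations each round, and ties on the
count are broken by lowest id then earliest frame, making the partition
deterministic and independent of row order.

**Null mode.** The default null (`uniform_reposition`) redraws every
neighborhood molecule uniformly in the disc — complete spatial randomness
conditional on channel counts. The alternative (`label_permutation`)
shuffles channel labels over the fixed positions; it is kept for
sensitivity analysis but degenerates for isolated pairs (the two fixed
positions always realize d_min, forcing p = 1), so it is not the default.

**Tie direction.** The null comparison is d_n ≤ d_min (conservative:
larger p); a `strict_inequality` flag switches to d_n < d_min. Both pair
members are force-included in their neighborhood so the null is defined
even for pairs wider than the disc. The association call itself uses
strict `<` on both thresholds.

**Per-pair RNG substreams.** Each pair's draws come from a generator
seeded by (master seed, idA, idB), so p-values are independent of the
order in which pairs are evaluated and stable under parallelization.

**ANOVA on replicate means.** Cells within a replicate are correlated, so
cell values are averaged to one value per replicate × condition before
testing, and the replicate is the subject factor. Within-replicate factors
are tested against their factor × replicate interaction; a between-subject
factor (different cell samples per group) is tested against the
replicate-within-group stratum. Balanced designs only; unbalanced input is
an error rather than silently imputed.

**Generalized ω².** Effect sizes are built from restricted-model
expected-mean-square variance components: for an effect tested against
MS_d, σ²_eff = df·(MS_eff − MS_d)/N, and the denominator adds σ²_eff to
every variance component involving the replicate (replicate stratum, each
treatment × replicate stratum, residual). Components are not truncated at
zero, so null effects can produce small negative values — that sign
behavior is informative and preserved. Verified against an exact
hand-derivation (11/41 on the reference 3 × 2 table) and, for F and p,
against statsmodels' repeated-measures ANOVA.

**Windsorization.** Within each sample, the single most extreme value is
replaced by the most extreme remaining value on the same side of the mean
when its z-score (ddof = 1, computed including the candidate) is ≥ 2.25.
At most one value is altered; constant samples are untouched.

**Knee rule.** The temporal-window choice is formalized as the smallest
window whose outgoing slope of molecules-remaining (per frame) falls below
a configurable tolerance — a mechanical stand-in for the visual
"slope decreases before the plateau" judgement, with the tolerance
exposed because no single value suits all blinking kinetics.

## Numerical notes

- Pairing builds the dense |A| × |B| distance matrix and scans it in
  (distance, idA, idB) order: O(n² log n) time, O(n²) memory — fine up to
  the ~10⁴ molecules/cell this method targets. Exact distance ties are
  broken lexicographically by ids, so output is row-order invariant.
- Monte Carlo draws are evaluated in vectorized chunks capped at ~4×10⁶
  floats to bound memory at high neighborhood occupancy.
- Squared distances are compared with a 10⁻¹² relative tie tolerance: under
  label permutation the observed pair belongs to the pooled set and ties
  d_min exactly, and the comparison must not flip on 1-ulp differences
  between hypot(dx,dy)² and dx²+dy².
- Degenerate inputs: empty channels produce a cell result with zero pairs
  and *missing* (not zero) summaries; a zero interaction mean square
  reports F = ∞ with a warning; grouping of an empty table returns an
  empty partition.
- CSV output uses 17-significant-digit floats and round-trip parsing, so
  write → read is bit-exact.

## What the simulator emulates — and what it does not

`simulate_cell` reproduces the statistical structure the method is
characterized on: n molecules per channel (the studied range spans
10²–10⁴) in a 250 μm² circular cell, a chosen fraction of A–B pairs at an
exact separation with uniform orientation, all unbound molecules
independent and uniform. Bound B partners may overhang the circle edge by
up to the pair separation; exact separation is preferred over strict
containment. `simulate_blinks` adds the blink level for testing grouping:
geometric blink counts, Gaussian position scatter, one uniform-start burst
window per emitter.

Not emulated: clustered or membrane-bound spatial distributions, labeling
efficiency below 100%, fluorophore crosstalk, drift, multi-burst
re-blinking beyond one window, camera noise, or localization-fitting
artifacts. Passing tests therefore demonstrate correctness of the
algorithms and their calibration under CSR-plus-bound-pairs conditions,
not performance on arbitrary real cells — on real data, residual
ungrouped blinks and nonuniform density make the fraction associated a
*relative*, not absolute, measure of binding.

## Problem sizes used by tests and the acceptance script

Desk-scale sizes were chosen so the full suite and script complete in a
few minutes while keeping Monte Carlo standard errors well inside the
asserted tolerances: 10 replicates per condition (the characterization
study used 30), 500–2000 permutations/pair in sweeps (10,000 for single
pairs where the analytic oracle is compared), densities up to 2000 per
channel, and 50-emitter blink fixtures. All random inputs derive from
explicit seeds; sweep cells are seeded by (master seed, condition,
replicate) so any sub-grid reproduces identically.

## Known limitations

- No edge correction: neighborhood discs may overhang the cell boundary,
  biasing the null slightly sparse near edges and making p marginally
  conservative there.
- The grouping merge chains nearby genuine molecules (by design); molecule
  counts are a lower bound in dense regions.
- Greedy pairing is not assignment-optimal; an early wrong match can
  cascade, which is part of the defined statistic rather than a bug.
- The label-permutation null is unreliable for sparse neighborhoods (see
  above) and is provided for sensitivity analysis only.
- Only 2-D positions are supported; axial structure is ignored.
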