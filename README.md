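# smlmpair

Association analysis for two-color single-molecule localization microscopy
(SMLM/dSTORM) data, built around a cross-nearest-neighbor / Monte Carlo
algorithm: it asks, molecule pair by molecule pair, whether two labeled
species (protein–protein or RNA–protein) sit closer together than their
local crowding can explain, and summarizes each cell as a single *fraction
associated*.

It is aimed at microscopists who have localization lists (one row per
blink: channel, x/y in nm, frame) exported from SMLM acquisition software
and want a density-aware, per-cell measure of molecular association, plus
the simulation and statistical machinery to interpret it.

## Method

1. **Grouping.** Blinks are collapsed into "molecules" by a two-stage
   local-density-maxima search: stage 1 joins localizations within 34.2 nm
   and 500 frames of an iteratively chosen density maximum; stage 2 repeats
   the search over the resulting groups with a 200 nm radius. A molecule's
   position is the mean of its member positions; its accuracy is
   mean(member accuracies)/√n.
2. **Pairing.** Channels A and B are matched by the *exclusive
   cross-nearest-neighbor* rule: take the globally closest A–B pair,
   remove both, repeat — producing min(|A|, |B|) pairs with distances
   d_min.
3. **Monte Carlo null.** For each pair, all molecules within r = 800 nm of
   the pair centroid are repositioned uniformly at random in that disc
   10,000 times; the minimum cross-channel distance d_n of each draw is
   compared with the observed d_min. The fraction of draws with
   d_n ≤ d_min is the pair's **p(chance association)** — a percentile rank
   of the observed gap under local complete spatial randomness.
4. **Summary.** A pair is *associated* if p(chance association) < 0.1 and
   d_min < 200 nm (the physical ceiling set by antibody-stack geometry).
   The per-cell **fraction associated** is the fraction of pairs meeting
   both criteria; the naive median pair distance is reported alongside.

The package also provides: a ground-truth simulator (uniform molecules in
a 250 μm² circle with a chosen bound fraction at a chosen separation) and
the density × binding × distance sweep built on it; replicate-blocked
(repeated-measures) ANOVA with generalized ω² effect sizes and z ≥ 2.25
Windsorization; and diagnostics for choosing the temporal window.

## Worked example

```python
import numpy as np
from smlmpair import (SimulationSpec, AssociationParams,
                      simulate_cell, analyze_cell)

rng = np.random.default_rng(7)
spec = SimulationSpec(n_per_channel=200, fraction_bound=0.2, pair_distance=10.0)
A, B, truth = simulate_cell(spec, rng)
res = analyze_cell(A, B, AssociationParams(n_permutations=2000, seed=7))
print(f"fraction associated: {res.fraction_associated:.3f} "
      f"(true bound fraction {spec.fraction_bound})")
print(f"median pair distance: {res.median_distance:.1f} nm")
print(res.pairs.head(5).round(4).to_string(index=False))
```

```
fraction associated: 0.230 (true bound fraction 0.2)
median pair distance: 499.2 nm
 idA  idB  distance         cx         cy  p_chance  associated
  26   26      10.0  5270.6987  3637.9611    0.0005        True
  35   35      10.0  3921.1672  6301.1284    0.0025        True
  11   11      10.0 -2597.7221  4163.4282    0.0025        True
  39   39      10.0 -7489.5425 -3168.7349    0.0000        True
   3    3      10.0 -6027.1618 -5032.3871    0.0015        True
```

A cell simulated with 20% of molecules truly bound at 10 nm comes back
with fraction associated 0.230 — the bound pairs (distance 10 nm,
p(chance association) ≈ 0) plus a small background of coincidentally close
unbound pairs. The median distance (499 nm) is dominated by the 80%
unbound molecules, which is why the fraction associated, not the median,
is the summary of choice.

The same pipeline runs from the shell, one subcommand per stage:

```sh
smlmpair group locs.tsv -o molecules.csv
smlmpair associate molsA.csv molsB.csv -o pairs.csv --summary-out cell.csv --seed 1
smlmpair sweep -o sweep.csv --reduced --seed 1
smlmpair anova sweep.csv -o anova.csv --value fraction_associated --within fraction_bound
smlmpair diagnose locs.tsv -o windows.csv
```

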