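# Methods

## Model and update order

The simulator iterates a synchronous deterministic map on the state
`(H, P, pop_H, pop_P)`: population levels and the two type-proportion
vectors. One step, everything frozen at the time-`t` state:

1. **Aggregate utilities.** Per-type values are linear interpolations
   between the type-1 and type-n endpoint parameters. The cross-utilities
   are `U_HP = H · (pop_H · Ū_H·P)` and `U_PH = P · (pop_P · Ū_P·H)`; the
   baselines `U_bH = pop_H · U_bH·`, `U_bP = pop_P · U_bP·`.
2. **Carrying capacities.** `K_H = U_PH + U_bH`;
   `K_P = min(U_HP + U_bP, MaxArea)`. Only the plant side is capped: plants
   must grow contiguously in a finite area, whereas humans can exploit
   multiple habitats.
3. **Fitness.** `fitness_i = ((n − i) U_b + i U_partner)/(U_b + U_partner)`,
   affine in the type index: the wild extreme wins when other resources
   dominate, the mutualistic extreme when the partner's contribution does.
4. **Population update.** Discrete logistic with the time-`t` capacity.
5. **Type-mix update.** Undirected variation
   `pop ← pop + v(1/n − pop)` — a deterministic relaxation toward the
   uniform mix standing in for mutation/innovation — followed by the
   replicator reweighting `popᵢ ← fᵢ popᵢ / Σ fⱼ popⱼ` with the time-`t`
   fitness.

Variation is applied before the replicator; both use quantities frozen at
time `t`, making the composed map a well-defined synchronous system. No
randomness enters the dynamics anywhere; all run-level tests can be exact.

Initial type distributions default to all mass on type 1 (a wild,
pre-mutualistic start); variation `v > 0` seeds the other types. They can
be overridden per run or in a config file.

## Parameters

Seventeen model parameters plus three run controls, named throughout by
their long R-style names so outputs are self-documenting. The package
defaults are the reference *full-coevolution* fixture:

| group | defaults | why |
|---|---|---|
| initial populations | 10 humans, 100 plants | small forager band beside a wild stand; initial levels have virtually no effect on end-states |
| types `n_H`, `n_P` | 10, 10 | fine enough to resolve gradual shifts; coarse enough to read |
| variation `v` | 0.05 | a few percent of each mix drifts per step; enough to seed pioneer types without washing out selection |
| growth rates `r` | 0.05 (H), 0.1 (P) | well inside the stable regime of the discrete logistic map; humans slower than plants |
| per-capita cross-utilities | `Ū_P1H`=0.4, `Ū_PnH`=1.5, `Ū_H1P`=0.5, `Ū_HnP`=2 | strong enough that the wild equilibrium is *marginally* supercritical — the system settles near its wild plateau before tipping, producing the double-sigmoid |
| baselines | `U_bH1`=80, `U_bHn`=2, `U_bP1`=100, `U_bPn`=20 | mutualistic types forgo most other resources; the falling plant baseline during the shift produces the transient carrying-capacity dip ("bump") |
| `max_area` | 1000 | caps the plant boom at 10× the wild stand |
| controls | `max_iterations`=5000, `ϵ`=6, threshold 0.5 | standard run budget; convergence when every component moves < 10⁻⁶ per step; a mix "has shifted" once its coefficient exceeds 0.5 |

Validation is strict: counts ≥ 2, `v ∈ [0,1]`, utilities and rates ≥ 0,
`max_area > 0` (may be `inf`), threshold in (−1, 1); violations raise a
named error at construction.

## Output statistics and end-state classification

- **Coevolution coefficient** `(Σᵢ popᵢ (i−1)/(n−1))·2 − 1 ∈ [−1, 1]`.
- **Dependency coefficient**: OLS slope of the fitness vector against the
  1-based type index, computed as an actual least-squares fit.
- **Convergence**: absolute change of `H`, `P` and the sup-norm change of
  both mixes all strictly below `10^−ϵ`. The absolute (not relative) form
  is intentional; both population levels *and* type distributions must be
  stable.
- **Timing**: the first step whose coefficient exceeds the threshold and
  never falls back through the end of the run. Persistence matters:
  oscillatory runs cross repeatedly, and a timing is only meaningful for a
  completed shift. Undefined (`None`) when no persistent crossing exists.
- **Classification**: converged runs are `full_coevolution` (both final
  coefficients above threshold), `partial_stationary` (exactly one) or
  `no_coevolution` (neither). A run that hits the iteration cap is
  `oscillatory` when either population's variance over the last 10% of
  steps exceeds `max(10⁻² · mean², 10⁻⁶)` — i.e. a sustained swing above
  10% of the level, with an absolute floor for near-zero populations —
  otherwise it is classified by the stationary rules with a
  non-convergence warning. The cutoff is this package's operational rule;
  no spectral criterion is attempted.

### Degenerate-input rules

- `K = 0`: the logistic density term would divide by zero; the update is
  defined as decay `pop·(1 − r)`, clipped at 0 — zero capacity drives
  extinction, not an error.
- The logistic update is clipped at 0 in general, so populations are
  nonnegative for every valid parameter setting.
- Zero total fitness mass: the replicator limit is undefined; the mix is
  returned unchanged and a stagnation warning is emitted.
- Zero denominator in the fitness scores (both utilities zero): a vector
  of ones, i.e. no selection.
- Type mixes are renormalised after each step to absorb float drift, so
  the sum-to-one invariant holds to 1e−12 over arbitrarily long runs.

## Presets

Four shipped fixtures, one per regime (`full_coevolution`,
`no_coevolution`, `partial_oscillatory`, `decoupled`). Only fragments of
the original illustrative settings are published — the plant baseline
endpoints 100/20 of the coevolution example and the flat human-to-plant
per-capita utility 0.5 of the partial example; every other value is this
package's fixture choice, tuned once so each preset reproduces its
declared regime, then frozen. They are qualitative fixtures, not
replication claims. The partial preset settles in `partial_stationary`
(humans shift, plants stay wild); a genuinely oscillatory
engagement/release cycle appears elsewhere in parameter space (e.g.
lowering both the wild-type human-to-plant utility and the mutualistic
plant-to-human utility from the reference setting) and is exercised in the
tests.

## Phase structure along facilitator axes

Sweeping the per-capita utility of mutualistic plants to humans from the
reference setting, the end-state passes from `no_coevolution` through an
intermediate band (partial, occasionally oscillatory) into
`full_coevolution`. The idealised picture of a single no↔full flip is
therefore tested as a single boundary of the *full/not-full* indicator,
and tipping-point bisection is specified only to separate the classes at
its bracket ends. Durations grow several-fold approaching a boundary
(critical slowing): just below the lower boundary the reference axis shows
`t_end ≈ 2600` against `≈ 500` at the reference value.

## Experiments

- **Sweeps** run one simulation per design point (grid Cartesian products
  or Latin hypercube samples) and return a tidy table, one row per run,
  reproducible byte-for-byte from (design, seed).
- **LHS**: each marginal stratified into `n` equal bins, one sample per
  bin (`scipy.stats.qmc.LatinHypercube`). Twenty candidate hypercubes are
  drawn and the one maximising the minimal pairwise distance in normalised
  coordinates is kept — a space-filling surrogate for point-process design
  optimisation, chosen to avoid a dependency on a spatial-statistics
  stack. Ranges are mandatory configuration; `examples/lhs_ranges.yaml` is
  the documented example (a fixture choice, with cross-utility ceilings of
  order the preset scale so the sampled space straddles the mutualism
  transition and produces diverse end-states).
- **Importance ranking**: a random-forest regressor (scikit-learn) with
  the sweep's parameter columns as predictors; tree count and
  predictors-per-split tuned by 10-fold cross-validation; reported are the
  permutation importance on a held-out quarter of the records (the
  %IncMSE analogue, used for ranking) and the impurity-decrease importance
  (reported alongside, never used for ranking). Initial populations are
  excluded by default. Rows with undefined targets (e.g. missing timings)
  are dropped; a constant target is a named degenerate-target error.
- **Tipping points**: bisection on one parameter axis between two values
  with different end-state classes, narrowing to 10⁻³ of the initial
  bracket width.

## Problem sizes used in the shipped checks

Single-run checks use the presets at the full 5,000-step cap (each well
under a second). The sensitivity check uses 500-point hypercubes over the
15 explorable parameters across five seeds — a reduced-scale version of
the full 10,000-sample exploration, which remains available as a
documented command. Passing at this scale shows the pipeline's ordering is
stable across seeds, not that the full-scale importance values are
reproduced.

## What the fixtures do and do not show

The presets and sampled parameter spaces emulate the study conditions of a
theoretical model: continuous deterministic populations, two species, no
space, no demographic stochasticity, types on a fixed 1..n ladder with
linearly interpolated properties. Passing tests show the implementation
realises this mathematics faithfully and that its qualitative regimes and
sensitivities behave as described; they say nothing about any real
archaeological or ecological trajectory. Known limitations: no
finite-population drift (the replicator is exact), no spatial structure,
no more than two populations, and oscillation detection by a variance
cutoff rather than spectral analysis.
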