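# Methods

## Model

The simulator implements a three-module binary attractor network.
Neurons are ±1 units (+1 active, −1 quiet) updated synchronously by a
sign rule with the convention sgn(0) = +1.  The modules — visual (V,
900 neurons on a 30×30 grid), memory (M, 1200 on 30×40) and perceiving
(P, 900 on 30×30) — are fully interconnected through one global N×N
synaptic matrix whose nine blocks w^(κ,η) carry both intra- and
inter-module projections; nothing distinguishes the blocks except the
lesions applied to them.

Stored content is K limit cycles of period L (default 11 cycles of
period 10).  Within a cycle the visual and memory blocks advance
through L distinct random patterns while the perceiving block stays
fixed, so L stimulus/context pairs map onto one percept.  Weights are
built with the pseudo-inverse (projection) rule: adjoint vectors are
computed from a dense solve of the pattern Gram system over the full
concatenated N-vectors — a single global pseudo-inverse, not one per
block.  This is the only construction under which the embedded cycles
are exact orbits of the coupled three-module map, and exactness is what
the tests assert (every embedded state advances one phase per update;
L-fold application is the identity on each orbit).

Invertibility of the Gram matrix is generic for i.i.d. ±1 patterns when
K·L ≪ N; the generator enforces K·L ≤ N/4 and the adjoint solver treats
a condition number above 1e8 as an error (advice: regenerate patterns)
rather than regularizing silently, since regularization would break the
exact-orbit property the rest of the package relies on.

## Pattern generation

Patterns are i.i.d. equiprobable ±1; the dynamics depend only on the
linear-algebraic structure of the pattern set, so random bitmaps stand
in for meaningful images without loss.  Distinctness (the L visual and
memory blocks within a cycle, and the K perceiving patterns) is
enforced by rejection resampling — astronomically unlikely to trigger
at N = 3000 but guaranteed for the small layouts used in testing.
User-supplied plain-PBM bitmaps can replace generated patterns via the
serialization round-trip (`write_patterns`/`read_patterns`).

## Pathology

* **Necrosis**: dead neurons are drawn uniformly within a module; the
  whole row and column of the connectivity mask ε are zeroed.  A dead
  neuron's state is clamped to −1 for the entire run and excluded from
  overlap normalization: with zero fan-in the sign rule would reduce to
  sgn(−θ), a threshold-sign artifact without physiological meaning.
* **Fan-in pruning**: only incoming connectivity is pruned.  For a
  pooled constraint (e.g. P ← V+M with budget 1050 of 2100) the
  survivors are drawn uniformly without replacement from the pooled
  living candidate set per target neuron, so the per-source split
  fluctuates around the source-size proportions (≈450/600 for V/M).
  Realized fan-in equals the budget exactly for every living target —
  an exhaustively asserted invariant.
* **Threshold fluctuation**: a module-uniform sinusoid
  θ_κ(t) = A·sin(2π(t+φ)/T) evaluated at the pre-update time t (the
  state at t updates to t+1 using θ(t)).  Default experiment values:
  A = 0.02, T = 100 steps on the perceiving module.

## Probes and outcome classification

Two probe types are distinguished because they answer different
questions:

* **Basin probes** (`noisy_probe`) flip a fraction of visual bits of an
  embedded state, leaving M and P intact.  They measure attractor-basin
  size: at full connectivity, 5%-noise probes re-enter the exact orbit
  within a few steps in ≥ 99% of trials.
* **Stimulus-onset probes** (`stimulus_onset_probe`) model a fresh
  stimulus: noisy visual block, intact memory (recalled context), and a
  *random* perceiving block — at stimulus onset the percept has not yet
  formed and must be assembled from bottom-up drive.  These are what
  the experiment runners use: an intact network re-forms the percept in
  a step or two, whereas with basin probes even severely pruned
  networks never err (the percept never has to be rebuilt, so the
  pathology is invisible).

The perceiving trajectory is scored against the K stored percepts by
the overlap order parameter on living neurons.  A step "matches" a
cycle when its best overlap ≥ `match_threshold` (default 0.95, high
enough that exact orbit entry always matches and two random patterns
essentially never do).  With `sustain` = L (default), labels are:
veridical (probed percept held for the final L steps, no earlier
sustained error), transient-error-then-veridical (≥ L consecutive
non-matching or wrong-matching steps earlier, veridical end),
hallucination-like (some single wrong percept held ≥ L consecutive
steps), else non-convergent.  Every trajectory receives exactly one
label.

## Experiments

* **Bottom-up impairment**: pooled P ← V+M fan-in cut to a budget
  (reference severity: 1050 of 2100), realized over many random
  configurations, each probed once per cycle.  At 1050 the network
  mostly still perceives veridically but transient errors appear at
  ~1–2% of probes; the veridical rate falls monotonically through
  budgets 2100, 1575, 1050, 525 (measured means ≈ 1.00, 1.00, 0.96,
  0.47 over 50 configurations each).
* **Threshold fluctuation**: the ±0.02 sinusoid is imperceptible in an
  intact network, where pre-sign fields sit at ±1; it can only act
  where fields pass near zero.  The experiment therefore runs on a
  network lesioned near its destabilization point (default pooled
  budget 525 — at 1050, pilot sweeps showed the sinusoid never changes
  any outcome).  Probes are launched at every integer phase of the
  modulation period; outcome labels then depend on the onset phase,
  and the zero-amplitude control reproduces the lesion-only outcomes
  exactly.
* **Combined necrosis**: a grid of lesion configurations (cell death
  per module plus per-projection pruning) each realized n_config times
  at fixed severity ("typical case" protocol); a (cell, label) pair
  occurring with frequency ≥ 0.5 (config-exposed) is flagged typical.
  The shipped `configs/combined_necrosis.yaml` emulates the qualitative clinical
  pattern — visual-module necrosis plus pruning of the two visual
  outflow pathways with the memory↔perceiving projection intact; its
  severity numbers are illustrative config parameters, not model
  constants.

## Numerical and design choices

* Weights and fields are float64 throughout; embedded-state fields are
  ±1 up to ~1e−15, so sign decisions at attractors are unambiguous.
  Dynamics are bit-deterministic given (patterns, lesion, schedule,
  seeds); sweep runners batch probes column-wise through one masked
  matrix product per step, which changes nothing numerically.
* Cycle detection uses exact state repetition (binary states make
  tolerance-free detection correct); "the percept is veridical" is
  operationalized as exact entry into the embedded orbit for the basin
  criterion and as sustained overlap ≥ 0.95 for experiment probes.
* Every stochastic element (patterns, dead-neuron draws, pruning,
  probe noise) takes an explicit seed; independent streams are spawned
  per configuration via seed sequences, so adding configurations never
  perturbs earlier ones.
* Problem sizes used in the shipped tests: unit tests run 30- and
  120-neuron layouts; full-scale checks use the standard N = 3000
  configuration with 20–50 lesion configurations per severity and
  100-step runs — enough for frequency estimates at the ~percent level
  while keeping the whole suite in a few minutes.

## What the synthetic data does and does not show

Generated patterns are i.i.d. and uncorrelated across phases and
cycles; real visual/memory representations are correlated (rotations,
shared features), which would thicken the Gram matrix's off-diagonal
and could lower the destabilization thresholds.  Passing tests
demonstrate the mechanism — exact cycle storage, graceful-then-abrupt
degradation under targeted pruning, phase-dependent vulnerability under
threshold modulation — not quantitative correspondence to any patient
population.  Necrosis here is spatially unstructured within a module;
no claim is made about anatomically realistic lesion geometry, about
fan-out (presynaptic) pruning, or about clinical hallucination
frequency.
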