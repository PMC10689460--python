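# lamevo

Lamarckian vs. Darwinian evolution of modular robots with lifetime learning,
as a desk-scale simulator.

## The problem

When robots evolve bodies *and* brains together, every newborn inherits a
controller tuned for its parents' morphology, not its own, so it benefits
from a lifetime learning phase that re-tunes the controller to the body it
actually has. The question this framework studies is what happens when the
*learned* controller weights are written back into the heritable genome
(Lamarckian inheritance) versus discarded at reproduction (the classical
Darwinian setup where learning shapes only the phenotype). Comparing the two
regimes requires a genotype-phenotype map for the brain that is exactly
invertible — otherwise there is nothing to write back.

`lamevo` implements the full machinery:

* **Bodies** are trees of modules (one core, passive bricks, active hinges)
  on an integer grid, grown breadth-first from a CPPN — a small feed-forward
  network queried at each candidate position `(x, y, z, d)` that decides the
  module type and rotation by argmax. Bodies cap at 10 non-core modules.
  Bodies reproduce sexually (NEAT-style crossover + mutation of the CPPN).
* **Brains** are networks of central pattern generators, one per hinge:

      dx_i/dt = w_i y_i + sum_{j in N_i} w_ji x_j,     dy_i/dt = -w_i x_i

  with `w_ij = -w_ji`, neighbourhoods N_i given by body-tree distance <= 2,
  initial states sqrt(2)/2, and a tanh output stage keeping joint commands
  in (-1, 1).
* **The reversible brain genotype** is a 440 x 14 table: one row per
  joint-occupiable cell of the 21 x 21 grid (21^2 - 1 = 440), and per row 12
  slots for the Manhattan distance-2 neighbour offsets, one slot for
  same-cell couplings, and one internal CPG weight. Every expressed weight
  has a fixed address, so `develop` and `encode` are exact inverses on the
  used entries — the property that makes Lamarckism implementable. Brains
  reproduce asexually (per-entry Gaussian mutation, p = 0.8, sd = 0.5, of
  the fittest parent's genome).
* **Lifetime learning** is Reversible Differential Evolution (RevDE):
  triplets `(w_i, w_j, w_k)` map invertibly to three candidates
  `v1 = w_i + F(w_j - w_k)`, `v2 = w_j + F(w_k - v1)`,
  `v3 = w_k + F(v1 - v2)`, followed by binomial crossover (CR = 0.9,
  F = 0.5). With K = 10 and 10 iterations, each newborn costs exactly
  10 + 30·9 = 280 reward assessments.
* **The task** is point navigation in a 10 x 10 m arena: pass within 0.01 m
  of P1(1,-1) then P2(0,-2) inside 40 s. With k of N targets reached, final
  position P_T and 5 Hz path length L,

      F = sum_{i<=k} d(P_i, P_{i-1}) + [k < N] (d(P_{k+1}, P_k) - d(P_T, P_{k+1})) - 0.1 L

  so the shortest two-target path scores 1.8·sqrt(2) ≈ 2.54.
* **Evolution** is mu+lambda (defaults mu = 50, lambda = 25, 30
  generations): binary tournaments, lambda newborns per generation — each
  evaluated at birth, learned, evaluated again — and deterministic elitist
  survival. The only difference between the two regimes is one step: the
  Lamarckian mode writes the learned weights back into the newborn's genome.
* **Morphometrics**: ordered tree-edit distance between canonical module
  trees (diversity, parent-child similarity), eight normalized trait
  descriptors, the learning delta (fitness after minus before learning),
  and the random-body control experiment that decouples learning ability
  from heredity.

Locomotion runs on a deterministic kinematic **surrogate backend** (forward
speed from actuation vigour, turning from steered left-right asymmetry); a
physics engine can be plugged in through the same interface. Absolute
fitness levels under real physics are out of scope.

## Worked example

Learn a controller for the four-hinge "+"-shaped robot:

```python
import numpy as np
import lamevo as lv
from lamevo.fixtures import cppn_plus

body = lv.decode_body(cppn_plus())
genome = lv.BrainGenome.random(np.random.default_rng(0))
backend = lv.SurrogateBackend()
task = lv.TaskSpec()

before = lv.evaluate(body, genome, backend, task)
result = lv.learn_brain(body, genome, backend, task,
                        lv.LearnerConfig(), np.random.default_rng(1))
learned = lv.inject_weights(genome, body, result.best)
after = lv.evaluate(body, learned, backend, task)
print(f"modules: {body.module_count}, joints: {len(body.joints())}")
print(f"fitness before learning: {before.fitness:.3f} (targets reached: {before.targets_reached})")
print(f"fitness after learning:  {after.fitness:.3f} (targets reached: {after.targets_reached})")
print(f"learning delta: {after.fitness - before.fitness:.3f} over {result.assessments} assessments")
```

prints

```
modules: 4, joints: 4
fitness before learning: 0.420 (targets reached: 0)
fitness after learning:  1.936 (targets reached: 1)
learning delta: 1.516 over 280 assessments
```

The random inherited brain makes some progress toward the first target
(0.42 out of the 2.55 optimum); one 280-assessment RevDE session re-tunes
the ten expressed weights until the robot actually reaches P1. The learning
delta (+1.52) is the quantity the morphological-intelligence analysis
tracks across generations. In Lamarckian mode those learned weights would
now overwrite the genome's used entries
(`lv.encode_brain(...)` / automatic inside the evolution loop).

Full runs and campaigns, from the shell:

```sh
lamevo run --mode lamarckian --seed 1 --out runs/
lamevo campaign --repetitions 3 --out campaign/
lamevo control --out control/         # random-body control experiment
lamevo budget --gen-equal 14          # the evaluation accounting
lamevo fixtures --out fixtures/
```

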