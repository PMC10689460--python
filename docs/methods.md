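# Methods

This note documents the models implemented in `lamevo`, the parameters that
matter, the numerical choices, and what the shipped tests do and do not
establish.

## Body model and genotype-phenotype map

A body is a rooted tree of modules on the integer grid: one core at the
origin, passive bricks, and active hinges. The decoder expands breadth-first
over open sockets in a fixed order — core: front (+y), back, left, right,
top, bottom; brick: front, left, right, top, bottom (the back face attaches
to the parent); hinge: front only — querying the CPPN at each candidate
position with inputs `(x, y, z, d)`, where `d` is the candidate's tree
distance to the core. The five outputs score {brick, joint, empty} and
{0°, 90°}; decisions are pure argmax (ties break toward the earlier output:
brick before joint before empty, 0° before 90°). A branch ends when "empty"
wins, when the target cell is occupied or outside the ±10 grid, and the
whole expansion stops once 10 non-core modules exist (the cap excludes the
core; a 21-cell-wide grid is exactly what offsets up to ±10 require). The
90° rotation acts about the attachment axis and composes down the subtree
through integer orientation matrices.

One constraint is imposed beyond the argmax rule: a hinge is never placed at
a cell whose 2D projection is the grid centre. The brain genotype (below)
addresses joints by their projected `(x, y)` cell and reserves the centre
for the core, so a joint there would have no address; the decoder treats
such a placement like an occupied cell and ends the branch. Bricks may
occupy the centre column freely.

CPPN genomes are minimal feed-forward networks (4 inputs, 5 linear outputs,
optional hidden nodes with sigmoid/tanh/gaussian/sine/linear activations,
per-node biases). Innovation numbers are a deterministic Cantor pairing of
the `(source, destination)` node ids, and the hidden node created by
splitting a connection takes an id derived from that connection's
innovation. Two lineages that make the same structural move therefore mark
it identically without any shared registry, which keeps crossover alignment
and replays deterministic. Crossover takes matching genes from either parent
at random and disjoint/excess genes from the fitter parent, so a child's
connection set is a subset of the fitter parent's and stays acyclic by
construction.

## Brain phenotype

Each hinge carries one CPG with states `(x_i, y_i)` obeying

    dx_i/dt = w_i y_i + sum_{j in N_i} w_ji x_j
    dy_i/dt = -w_i x_i,

with antisymmetric couplings (`w_ij = -w_ji`) between joints at body-tree
distance ≤ 2 (edges counted in the module tree, bricks included). States
start at `sqrt(2)/2`, so an uncoupled unit-weight CPG traces a sinusoid of
amplitude exactly 1. The output stage is `2/(1+e^{-2x}) - 1`, i.e. tanh,
bounding joint commands to (-1, 1) even when couplings push `x` outside
[-1, 1].

Integration is fixed-step 4th-order Runge-Kutta at `dt = 0.005 s` — chosen
so the uncoupled oscillator's conserved radius drifts by less than 1e-3
over a full 40 s evaluation, which the test suite checks. Because the
system is linear, the surrogate backend instead propagates states with the
exact matrix exponential (via eigendecomposition) at the 5 Hz control tick;
the two agree to ~1e-8 over 500 RK4 steps and the exponential route has no
discretization error at all.

## Reversible brain genotype

The genotype is a 440 x 14 real table. Rows index the 21 x 21 grid minus
the centre in row-major order with x fastest (so (-10,-10) is row 0 and
(10,10) is row 439). Columns 0-11 are the 12 relative offsets with
Manhattan distance 1-2 in lexicographic order (the distance-2 neighbourhood
has Delannoy-number D(2,2) = 13 cells including the centre), column 12 is
the same-2D-cell slot (bodies are 3D; the grid is not), column 13 the
internal CPG weight.

Development reads, for each joint at projected cell `p`, its internal
weight from `[row(p), 13]`, and for each neighbour pair the coupling from
the row of the pair's lower-decode-order joint at the slot of the relative
offset (same-cell slot when the offsets coincide); the reverse coupling is
the negation. Joints sharing a projected cell share a row; couplings that
land on the same table entry are equal by construction. Encoding writes the
expressed entries back and leaves everything else untouched — unexpressed
entries ride along silently and can become expressed in descendants with
different bodies. `develop ∘ encode` and `encode ∘ develop` are bit-exact
identities on the used entries; this exactness is what makes the Lamarckian
write-back well-defined, and it is asserted (not approximately) in the
tests. Weights are not clipped anywhere: the tanh output stage bounds
behaviour regardless.

## Lifetime learner (RevDE)

RevDE draws K triplets per iteration (members distinct within a triplet,
uniform over the current population), maps each triplet through the
invertible linear perturbation

    v1 = w_i + F (w_j - w_k)
    v2 = w_j + F (w_k - v1)
    v3 = w_k + F (v1 - v2),

crosses each candidate with its corresponding triplet member by binomial
crossover (Bernoulli(CR) mask per dimension), assesses the 3K offspring,
and keeps the best K of parents ∪ offspring. Defaults: K = 10, F = 0.5,
CR = 0.9, 10 iterations; the initial population is the inherited weight
vector plus K-1 Gaussian mutants (sd 0.5, matching the brain mutation
operator). The budget is exactly K + 3K(iterations-1) = 280 assessments per
session, and elitism makes the best-so-far reward monotone.

Two numerical points. First, the elitist cut skips bit-identical duplicate
vectors while distinct ones remain (padding with duplicates only if fewer
than K distinct exist): `v1 = w_i` exactly whenever `w_j = w_k`, and once
copies take over the population every difference vector is zero and the
operator freezes. Dropping copies costs nothing (they carry no information)
and changes neither the budget nor monotonicity. Second, truncation
selection at K = 10 contracts the population geometrically, so the default
configuration acts as a strong local improver rather than a precise
optimizer — the same small-population stagnation classical DE shows at
NP ≈ D. The parameter-recovery test therefore spends its 10x budget
(2800 assessments) as K = 40 x 24 iterations, sizing the population at
~6-7x the toy problem's dimension, and recovers a known quadratic optimum
to 1e-2. Within evolutionary runs the default K = 10 x 10 iterations is
kept: there the learner's job is improvement under a 280-assessment budget,
not convergence.

## Task, fitness, and the surrogate backend

Point navigation: targets P1(1,-1), P2(0,-2), reach radius 0.01 m tested
against the 5 Hz samples (not a continuous interpolation), 40 s per
evaluation, 10 x 10 m arena, ω = 0.1. Targets count only in order. The
fitness credits completed inter-target segments at full distance, adds
progress toward the next unreached target (distance of the segment minus
the final position's distance to that target), and subtracts ω times the
sampled path length; with both targets reached by the shortest path this
gives 1.8·sqrt(2) ≈ 2.546. A robot that never moves scores exactly 0. The
learner's reward and evolution's fitness are the same quantity computed by
the same procedure.

The built-in backend is a kinematic surrogate, not physics: per 5 Hz
control tick, forward speed is `speed_gain · efficiency · mean |Δout|/Δt`
(efficiency = hinges / (1 + modules)), the heading turns at `turn_gain`
times the steered left-right vigour asymmetry, and positions clip to the
arena. Steering slows the side of the body facing the target by
`max(0, 1 - gain·|bearing|/π)`, joints classified by the sign of their
body-frame x coordinate (on-axis joints unmodulated); the bearing is the
signed angle from the robot's heading to the current target, positive to
the right. All coefficients (`speed_gain = 0.08`, `turn_gain = 2.0`,
`steering_gain = 1.0`) are package modelling choices exposed in
`SurrogateConfig`; they carry no empirical claim. Consequences: trajectories
are deterministic given the genome, fitness levels are meaningful only
relative to one another within the surrogate, and nothing here reproduces
the absolute fitness of a physics engine. An external backend can be
plugged in through the same `simulate` interface and raises explicitly if
unavailable — there is no silent fallback.

## Evolution loop and inheritance regimes

mu+lambda with binary tournaments (with replacement; ties uniform),
sexual body reproduction (crossover with p = 0.8, then mutation with
p = 0.8), asexual brain reproduction (per-entry Gaussian mutation, p = 0.8,
sd = 0.5, of the fittest parent's brain genome; fitness ties break toward
the lower id). Survivors are the deterministic top mu-lambda, ties broken
by older generation then lower id, so the population maximum after
learning never decreases. Every newborn records fitness before learning,
runs one RevDE session, and records fitness after; selection uses the
post-learning fitness. Generation-0 robots get random CPPN bodies and
brain tables drawn i.i.d. N(0, 0.5²) — the initialization is otherwise
unspecified by the experimental design, and matching the mutation scale
keeps generation 0 statistically comparable to later mutants.

The two regimes differ in exactly one statement: Lamarckian mode replaces
the newborn's brain genome with the learned-weight write-back after its
learning session (each genome therefore changes exactly once, at the end
of infancy); Darwinian mode leaves the genome at its birth state forever.

The evaluation ledger counts evolution-level evaluations, learning
assessments, and pre-learning evaluations separately. The nominal per-run
accounting `lambda·(generations+1)` (775 at defaults) undercounts
initialization, which creates mu robots, not lambda; the budget report
exposes both that nominal figure and the actual
`mu + lambda·generations` (800 at defaults), verifies observed counters
against the actual figure, and surfaces the discrepancy in run manifests.
Pre-learning evaluations (needed for the learning delta) are tracked
outside the evolution budget. Campaign totals use the nominal convention:
775 · 280 · 2 systems = 434,000 evaluations = 4,822 simulated hours at
40 s each; the savings estimate for a quality crossover at generation g is
`lambda · (generations - g) · 280 · repetitions` (2,240,000 at g = 14).

## Morphometrics

Bodies are compared as rooted ordered labelled trees — labels are (module
kind, rotation), children in socket order — under unit-cost tree-edit
distance computed by the Zhang-Shasha keyroot dynamic program (the same
ordered-tree distance APTED computes; rotation labels can be switched off).
Diversity is the mean pairwise distance; parent-child similarity is the
distance to the fittest parent. The eight trait descriptors are this
package's reconstructions (their canonical definitions live outside the
implemented sources) and are documented as such: with m non-core modules —
size m/10; joints = hinges/m; limbs = leaf fraction; limb length = deepest
module / m; branching = fraction of modules with ≥ 3 children; coverage =
modules / 3D-bounding-box cells; proportion = short/long side of the 2D
bounding box; symmetry = the better of the x- and y-mirror matched-cell
fractions over projected (cell, kind) pairs. All lie in [0, 1] and are
mirror-invariant. The random-body control experiment replaces each
newborn's inherited body with a freshly decoded random CPPN while keeping
the inherited brain genome (unexpressed rows make this safe by
construction), then learns and — in Lamarckian mode — writes back as usual.

## Statistical reporting

Campaign aggregation reports per-generation means with 95% confidence
bands (mean ± t · SE across repetitions). Mode comparison uses Welch's
t-test per generation with a Bonferroni-corrected threshold, default
α/6 ≈ 0.0083 for the six trait comparisons (the threshold is computed, not
assumed). Correlations between newborn fitness and parent-child tree-edit
distance are Pearson over pooled newborns.

## Scale of the shipped experiments

The default acceptance campaign runs mu = 8, lambda = 4, 5 generations,
3 repetitions per mode on the surrogate backend — about 47,000 simulations,
minutes on one CPU — while the full-scale configuration (mu = 50,
lambda = 25, 30 generations, 20 repetitions) remains the `EvoConfig`
default, one switch away. Every structural claim the tests make
(reversibility, inheritance mechanics, budget conservation, monotone
elitism, determinism from seeds) is scale-independent.

## Limitations

* The surrogate rewards vigorous, steerable actuation but knows no contact
  dynamics, gravity, or morphology-specific gaits; which bodies evolution
  favours under it need not transfer to a physics engine, and passing
  tests say nothing about absolute task performance of physical robots.
* Trait descriptors are reconstructions; absolute trait values are not
  comparable against other implementations, though within-run trends are.
* MultiNEAT operator parity is not attempted; the CPPN operator set is the
  documented one above.
* Small-population RevDE stagnates before precise convergence by design of
  its selection scheme; see the learner section.
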