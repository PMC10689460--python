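"""Integrated evolution + learning with switchable inheritance.

A mu+lambda evolutionary loop: each generation, lambda children are produced
by binary-tournament parent selection; bodies reproduce sexually (NEAT
crossover then mutation of the CPPN genome), brains asexually (Gaussian
mutation of the fittest parent's brain genome). Every newborn is evaluated
at birth, runs a RevDE learning session, and is evaluated with the learned
weights; selection acts on the post-learning fitness. The best mu - lambda
of the old generation survive deterministically.

The two inheritance regimes differ in one step only:

* lamarckian — after learning, the learned weights overwrite the used
  entries of the newborn's brain genome (the reversible write-back), so its
  offspring inherit what it learned;
* darwinian — the genome keeps its birth state; learning shapes only the
  phenotype, and offspring inherit the weights the parent was born with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .body import (
    BodyMutationRates,
    CppnGenome,
    RobotBody,
    crossover_body,
    decode_body,
    mutate_body,
    random_cppn,
)
from .brain_genotype import BrainGenome, gaussian_mutate_brain, inject_weights
from .env import EvalLedger, SurrogateBackend, TaskSpec, evaluate
from .revde import LearnerConfig, learn_brain

LAMARCKIAN = "lamarckian"
DARWINIAN = "darwinian"


@dataclass(frozen=True)
class EvoConfig:
    """All run parameters; defaults are the full experimental settings."""

    mu: int = 50
    lam: int = 25
    tournament_size: int = 2
    generations: int = 30
    mode: str = LAMARCKIAN
    seed: int = 0
    crossover_rate: float = 0.8       # probability of body crossover
    mutation_rate: float = 0.8        # probability a child body is mutated
    brain_mutation_prob: float = 0.8  # per-entry Gaussian mutation probability
    brain_mutation_sd: float = 0.5
    brain_init_sd: float = 0.5        # generation-0 brain genome N(0, sd^2)
    body_rates: BodyMutationRates = field(default_factory=BodyMutationRates)
    learner: LearnerConfig = field(default_factory=LearnerConfig)
    task: TaskSpec = field(default_factory=TaskSpec)
    body_source: str = "inherited"    # "random" = control experiment

    def __post_init__(self) -> None:
        if self.lam > self.mu:
            raise ValueError("lambda must not exceed mu")
        if self.tournament_size < 1:
            raise ValueError("tournament size must be >= 1")
        if self.mode not in (LAMARCKIAN, DARWINIAN):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class Individual:
    id: int
    body_genome: CppnGenome
    brain_genome_birth: BrainGenome     # as inherited at birth
    brain_genome: BrainGenome           # current (changes once, in lamarckian)
    body: RobotBody
    generation: int
    parents: tuple[int, ...] = ()
    fitness_before: float | None = None
    fitness_after: float | None = None
    learned_weights: np.ndarray | None = None
    parent_child_ted: float | None = None

    @property
    def fitness(self) -> float:
        if self.fitness_after is None:
            raise RuntimeError(f"individual {self.id} not evaluated yet")
        return self.fitness_after


def tournament_select(
    population: list[Individual],
    rng: np.random.Generator,
    size: int = 2,
) -> Individual:
    """Fittest of ``size`` uniform draws with replacement; ties uniform."""
    if not population:
        raise ValueError("empty population")
    picks = [population[int(i)] for i in rng.integers(0, len(population), size)]
    best = max(p.fitness for p in picks)
    winners = [p for p in picks if p.fitness == best]
    return winners[int(rng.integers(len(winners)))]


def _fittest_parent(p1: Individual, p2: Individual) -> Individual:
    if p1.fitness != p2.fitness:
        return p1 if p1.fitness > p2.fitness else p2
    return p1 if p1.id < p2.id else p2  # documented tie-break: lower id


def reproduce(
    p1: Individual,
    p2: Individual,
    mode: str,
    cfg: EvoConfig,
    rng: np.random.Generator,
) -> tuple[CppnGenome, BrainGenome, int]:
    """Child genomes: sexual body, asexual brain from the fittest parent.

    In lamarckian mode the brain source is the parent's genome after
    write-back of its learned weights; in darwinian mode it is the genome
    the parent was born with.
    """
    if p1.fitness_after is None or p2.fitness_after is None:
        raise RuntimeError("parents must be evaluated before reproduction")
    fitter = _fittest_parent(p1, p2)
    other = p2 if fitter is p1 else p1

    body_genome = crossover_body(
        fitter.body_genome,
        other.body_genome,
        rng,
        fitter.fitness,
        other.fitness,
        rate=cfg.crossover_rate,
    )
    if rng.random() < cfg.mutation_rate:
        body_genome = mutate_body(body_genome, cfg.body_rates, rng)

    source = fitter.brain_genome if mode == LAMARCKIAN else fitter.brain_genome_birth
    brain_genome = gaussian_mutate_brain(
        source, rng, cfg.brain_mutation_prob, cfg.brain_mutation_sd
    )
    return body_genome, brain_genome, fitter.id


@dataclass
class RunRecord:
    mode: str
    seed: int
    config: dict
    generation_stats: "object"          # pandas DataFrame
    newborns: "object"                  # pandas DataFrame
    ledger: dict
    best_fitness: float
    population: list[Individual] = field(default_factory=list, repr=False)

    def manifest(self) -> dict:
        return {
            "mode": self.mode,
            "seed": self.seed,
            "config": self.config,
            "best_fitness": self.best_fitness,
            "ledger": self.ledger,
            "note": (
                "nominal evaluation accounting lambda*(generations+1) differs "
                "from the mu + lambda*generations robots actually evaluated; "
                "both are reported by the budget ledger"
            ),
        }


class EvolutionRun:
    """One evolutionary run; create and call :meth:`run`, or step manually."""

    def __init__(self, cfg: EvoConfig, backend=None) -> None:
        self.cfg = cfg
        self.backend = backend or SurrogateBackend()
        self.rng = np.random.default_rng(cfg.seed)
        self.ledger = EvalLedger()
        self._next_id = 0
        self.population: list[Individual] = []
        self.generation = 0
        self._newborn_rows: list[dict] = []
        self._gen_rows: list[dict] = []

    # -- newborn pipeline ---------------------------------------------------

    def _make_newborn(
        self,
        body_genome: CppnGenome,
        brain_genome: BrainGenome,
        parents: tuple[Individual, ...],
        fittest_parent: Individual | None,
    ) -> Individual:
        cfg = self.cfg
        if cfg.body_source == "random":
            # control experiment: the inherited body is replaced by a random
            # one; the inherited brain genome is kept and developed in it
            from .morphometrics import random_body

            body = random_body(self.rng)
        else:
            body = decode_body(body_genome)

        ind = Individual(
            id=self._next_id,
            body_genome=body_genome,
            brain_genome_birth=brain_genome.copy(),
            brain_genome=brain_genome,
            body=body,
            generation=self.generation,
            parents=tuple(p.id for p in parents),
        )
        self._next_id += 1

        ind.fitness_before = evaluate(
            body, brain_genome, self.backend, cfg.task, self.ledger,
            kind="prelearning",
        ).fitness

        result = learn_brain(
            body, brain_genome, self.backend, cfg.task, cfg.learner, self.rng,
            self.ledger,
        )
        ind.learned_weights = result.best

        learned_genome = inject_weights(brain_genome, body, result.best)
        ind.fitness_after = evaluate(
            body, learned_genome, self.backend, cfg.task, self.ledger,
            kind="evaluation",
        ).fitness

        if cfg.mode == LAMARCKIAN:
            ind.brain_genome = learned_genome  # the reversible write-back

        if fittest_parent is not None:
            from .morphometrics import parent_child_distance

            ind.parent_child_ted = parent_child_distance(
                ind.body, fittest_parent.body
            )

        self._newborn_rows.append(
            {
                "generation": self.generation,
                "id": ind.id,
                "parents": ",".join(str(p) for p in ind.parents),
                "fitness_before": ind.fitness_before,
                "fitness_after": ind.fitness_after,
                "learning_delta": ind.fitness_after - ind.fitness_before,
                "parent_child_ted": ind.parent_child_ted,
                "modules": ind.body.module_count,
                "hinges": len(ind.body.joints()),
            }
        )
        return ind

    # -- generation steps ---------------------------------------------------

    def initialize(self) -> None:
        cfg = self.cfg
        for _ in range(cfg.mu):
            seed = int(self.rng.integers(0, 2**31 - 1))
            body_genome = random_cppn(seed)
            brain_genome = BrainGenome.random(self.rng, cfg.brain_init_sd)
            self.population.append(
                self._make_newborn(body_genome, brain_genome, (), None)
            )
        self._record_generation()

    def next_generation(self) -> None:
        cfg = self.cfg
        if len(self.population) != cfg.mu:
            raise RuntimeError("population size drifted from mu")
        self.generation += 1
        children: list[Individual] = []
        by_id = {p.id: p for p in self.population}
        for _ in range(cfg.lam):
            p1 = tournament_select(self.population, self.rng, cfg.tournament_size)
            p2 = tournament_select(self.population, self.rng, cfg.tournament_size)
            body_genome, brain_genome, fittest_id = reproduce(
                p1, p2, cfg.mode, cfg, self.rng
            )
            children.append(
                self._make_newborn(
                    body_genome, brain_genome, (p1, p2), by_id[fittest_id]
                )
            )
        survivors = sorted(
            self.population, key=lambda p: (-p.fitness, p.generation, p.id)
        )[: cfg.mu - cfg.lam]
        self.population = survivors + children
        self._record_generation()

    def _record_generation(self) -> None:
        from .morphometrics import diversity, traits

        pop = self.population
        fits = np.array([p.fitness for p in pop])
        newborns = [p for p in pop if p.generation == self.generation]
        nb_before = np.array([p.fitness_before for p in newborns])
        nb_after = np.array([p.fitness_after for p in newborns])
        div = diversity([p.body for p in pop]) if len(pop) > 1 else 0.0
        mean_traits = np.mean([traits(p.body).as_array() for p in pop], axis=0)
        ted = [p.parent_child_ted for p in pop if p.parent_child_ted is not None]
        row = {
            "generation": self.generation,
            "mean_fitness": float(fits.mean()),
            "max_fitness": float(fits.max()),
            "mean_newborn_before": float(nb_before.mean()),
            "max_newborn_before": float(nb_before.max()),
            "mean_newborn_after": float(nb_after.mean()),
            "max_newborn_after": float(nb_after.max()),
            "mean_learning_delta": float((nb_after - nb_before).mean()),
            "max_learning_delta": float((nb_after - nb_before).max()),
            "diversity": float(div),
            "mean_parent_child_ted": float(np.mean(ted)) if ted else float("nan"),
            "evolution_evaluations": self.ledger.evolution_evaluations,
            "learning_assessments": self.ledger.learning_assessments,
        }
        for name, value in zip(
            ("branching", "limbs", "limb_length", "coverage", "joints",
             "proportion", "symmetry", "size"),
            mean_traits,
        ):
            row[f"trait_{name}"] = float(value)
        self._gen_rows.append(row)

    # -- full run -----------------------------------------------------------

    def run(self) -> RunRecord:
        import pandas as pd

        self.initialize()
        for _ in range(self.cfg.generations):
            self.next_generation()
        stats = pd.DataFrame(self._gen_rows)
        newborns = pd.DataFrame(self._newborn_rows)
        return RunRecord(
            mode=self.cfg.mode,
            seed=self.cfg.seed,
            config=_config_dict(self.cfg),
            generation_stats=stats,
            newborns=newborns,
            ledger=self.ledger.snapshot(),
            best_fitness=float(stats["max_fitness"].iloc[-1]),
            population=self.population,
        )


def run(cfg: EvoConfig, backend=None) -> RunRecord:
    """Run one full evolution+learning experiment, reproducible from its seed."""
    return EvolutionRun(cfg, backend).run()


def _config_dict(cfg: EvoConfig) -> dict:
    return {
        "mu": cfg.mu,
        "lambda": cfg.lam,
        "tournament_size": cfg.tournament_size,
        "generations": cfg.generations,
        "mode": cfg.mode,
        "seed": cfg.seed,
        "crossover_rate": cfg.crossover_rate,
        "mutation_rate": cfg.mutation_rate,
        "brain_mutation_prob": cfg.brain_mutation_prob,
        "brain_mutation_sd": cfg.brain_mutation_sd,
        "learner": {
            "population_size": cfg.learner.population_size,
            "scaling_factor": cfg.learner.scaling_factor,
            "crossover_rate": cfg.learner.crossover_rate,
            "iterations": cfg.learner.iterations,
            "init_noise_sd": cfg.learner.init_noise_sd,
        },
        "task": {
            "targets": [list(t) for t in cfg.task.targets],
            "reach_radius": cfg.task.reach_radius,
            "duration": cfg.task.duration,
            "omega": cfg.task.omega,
        },
        "body_source": cfg.body_source,
    }
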