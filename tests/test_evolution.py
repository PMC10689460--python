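"""Evolution loop: selection, inheritance mechanisms, generation bookkeeping."""

import numpy as np
import pytest

from lamevo.evolution import (
    DARWINIAN,
    LAMARCKIAN,
    EvoConfig,
    EvolutionRun,
    reproduce,
    run,
    tournament_select,
)
from lamevo.revde import LearnerConfig

#: tiny settings used to exercise loop mechanics quickly
TINY = dict(
    mu=4,
    lam=2,
    generations=1,
    learner=LearnerConfig(population_size=4, iterations=2),
)


def tiny_config(**overrides) -> EvoConfig:
    params = dict(TINY)
    params.update(overrides)
    return EvoConfig(**params)


@pytest.fixture(scope="module")
def tiny_runs():
    """One evaluated tiny run per mode, shared across mechanism tests."""
    return {
        mode: EvolutionRun(tiny_config(mode=mode, seed=11))
        for mode in (LAMARCKIAN, DARWINIAN)
    }


class TestTournament:
    def _pop(self, fitnesses):
        class Stub:
            def __init__(self, i, f):
                self.id, self.fitness = i, f

        return [Stub(i, f) for i, f in enumerate(fitnesses)]

    def test_population_of_one(self, rng):
        pop = self._pop([0.5])
        assert tournament_select(pop, rng) is pop[0]

    def test_empty_population_rejected(self, rng):
        with pytest.raises(ValueError):
            tournament_select([], rng)

    def test_binary_tournament_win_probability_of_the_best(self):
        # with replacement over n distinct fitnesses: P(best) = (2n-1)/n^2
        rng = np.random.default_rng(0)
        n, draws = 5, 40_000
        pop = self._pop(np.linspace(0, 1, n))
        wins = sum(
            tournament_select(pop, rng, 2) is pop[-1] for _ in range(draws)
        )
        expected = (2 * n - 1) / n**2
        se = np.sqrt(expected * (1 - expected) / draws)
        assert abs(wins / draws - expected) < 4 * se


class TestInheritanceMechanism:
    def test_lamarckian_child_brain_is_parent_post_learning_genome(
        self, tiny_runs
    ):
        er = tiny_runs[LAMARCKIAN]
        if not er.population:
            er.initialize()
        # write-back only shows on bodies that express weights and learned
        # something different from what they inherited
        changed = [
            i for i in er.population
            if i.learned_weights.size > 0
            and not np.array_equal(
                i.brain_genome.weights, i.brain_genome_birth.weights
            )
        ]
        assert changed, "no individual with an effective write-back"
        p1 = max(changed, key=lambda i: (i.fitness, -i.id))
        cfg = tiny_config(mode=LAMARCKIAN, brain_mutation_prob=0.0)
        # self-pair: the fittest parent is p1 itself (lower-id tie-break)
        _, brain, fittest_id = reproduce(p1, p1, LAMARCKIAN, cfg, er.rng)
        assert fittest_id == p1.id
        fittest = p1
        # the parent's current genome carries the learned write-back
        assert np.array_equal(brain.weights, fittest.brain_genome.weights)
        assert not np.array_equal(
            fittest.brain_genome.weights, fittest.brain_genome_birth.weights
        )

    def test_darwinian_child_brain_is_parent_birth_genome(self, tiny_runs):
        er = tiny_runs[DARWINIAN]
        if not er.population:
            er.initialize()
        p1, p2 = er.population[0], er.population[1]
        cfg = tiny_config(mode=DARWINIAN, brain_mutation_prob=0.0)
        _, brain, fittest_id = reproduce(p1, p2, DARWINIAN, cfg, er.rng)
        fittest = p1 if fittest_id == p1.id else p2
        assert np.array_equal(brain.weights, fittest.brain_genome_birth.weights)

    def test_darwinian_genomes_never_change_after_birth(self, tiny_runs):
        er = tiny_runs[DARWINIAN]
        if not er.population:
            er.initialize()
        for ind in er.population:
            assert np.array_equal(
                ind.brain_genome.weights, ind.brain_genome_birth.weights
            )

    def test_unevaluated_parents_rejected(self, tiny_runs, rng):
        from lamevo.evolution import Individual

        er = tiny_runs[LAMARCKIAN]
        if not er.population:
            er.initialize()
        ghost = Individual(
            id=999,
            body_genome=er.population[0].body_genome,
            brain_genome_birth=er.population[0].brain_genome_birth,
            brain_genome=er.population[0].brain_genome,
            body=er.population[0].body,
            generation=0,
        )
        with pytest.raises(RuntimeError):
            reproduce(ghost, er.population[0], LAMARCKIAN, tiny_config(), rng)


@pytest.fixture(scope="module")
def record():
    return run(tiny_config(mode=LAMARCKIAN, generations=2, seed=5))


class TestGenerationLoop:

    def test_population_size_constant_at_mu(self, record):
        assert len(record.population) == 4

    def test_survivors_plus_newborns(self, record):
        gens = [i.generation for i in record.population]
        assert sum(g == 2 for g in gens) == 2  # lambda newborns

    def test_every_newborn_has_both_fitness_values(self, record):
        nb = record.newborns
        assert nb["fitness_before"].notna().all()
        assert nb["fitness_after"].notna().all()

    def test_max_fitness_monotone_under_elitist_survival(self, record):
        maxf = record.generation_stats["max_fitness"].to_numpy()
        assert np.all(np.diff(maxf) >= 0)

    def test_survivor_fitness_dominates_nonsurvivors(self):
        er = EvolutionRun(tiny_config(mode=DARWINIAN, seed=21))
        er.initialize()
        old = list(er.population)
        er.next_generation()
        survivors = [i for i in er.population if i in old]
        dropped = [i for i in old if i not in er.population]
        assert min(s.fitness for s in survivors) >= max(
            d.fitness for d in dropped
        )

    def test_same_seed_same_mode_identical_run_records(self):
        cfg = tiny_config(mode=LAMARCKIAN, seed=33)
        a, b = run(cfg), run(cfg)
        assert a.generation_stats.equals(b.generation_stats)
        assert a.newborns.equals(b.newborns)
        assert a.ledger == b.ledger

    def test_zero_generations_evaluates_only_the_initial_population(self):
        record = run(tiny_config(generations=0, seed=2))
        assert len(record.generation_stats) == 1
        assert record.ledger["evolution_evaluations"] == 4

    def test_evaluation_accounting_matches_closed_form(self, record):
        cfg = tiny_config(generations=2)
        robots = cfg.mu + cfg.lam * cfg.generations
        assert record.ledger["evolution_evaluations"] == robots
        assert record.ledger["learning_assessments"] == \
            robots * cfg.learner.assessments


class TestConfigValidation:
    def test_lambda_cannot_exceed_mu(self):
        with pytest.raises(ValueError):
            EvoConfig(mu=4, lam=5)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            EvoConfig(mode="baldwinian")
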