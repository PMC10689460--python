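"""Reversible Differential Evolution (RevDE): the lifetime learner.

RevDE perturbs a randomly drawn triplet (w_i, w_j, w_k) of weight vectors
into three candidates,

    v1 = w_i + F * (w_j - w_k)
    v2 = w_j + F * (w_k - v1)
    v3 = w_k + F * (v1 - v2),

an invertible linear map of the triplet (hence "reversible"); candidates are
then combined with their triplet parents by standard DE binomial crossover
(Bernoulli mask with probability CR per dimension). With the default K = 10
population, 10 iterations, F = 0.5 and CR = 0.9, one learning session of a
newborn robot costs exactly 10 + 30 * 9 = 280 reward assessments: the first
iteration assesses the initial population (the inherited weight vector plus
nine Gaussian mutants of it), and each later iteration creates and assesses
3K = 30 candidates before an elitist cut back to K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


@dataclass(frozen=True)
class LearnerConfig:
    population_size: int = 10      # K
    scaling_factor: float = 0.5    # F
    crossover_rate: float = 0.9    # CR
    iterations: int = 10
    init_noise_sd: float = 0.5     # sd of the Gaussian mutants around the
                                   # inherited vector (matches brain mutation)

    def __post_init__(self) -> None:
        if self.crossover_rate <= 0 or self.crossover_rate > 1:
            raise ValueError("CR must be in (0, 1]")
        if self.scaling_factor <= 0:
            raise ValueError("F must be positive")

    @property
    def assessments(self) -> int:
        """Reward assessments per learning session: K + 3K * (iterations - 1)."""
        k = self.population_size
        return k + 3 * k * (self.iterations - 1)


def revde_mutation(
    w_i: np.ndarray, w_j: np.ndarray, w_k: np.ndarray, f: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The reversible three-candidate differential mutation."""
    w_i, w_j, w_k = (np.asarray(w, dtype=float) for w in (w_i, w_j, w_k))
    if not (w_i.shape == w_j.shape == w_k.shape):
        raise ValueError("triplet members must share a dimension")
    v1 = w_i + f * (w_j - w_k)
    v2 = w_j + f * (w_k - v1)
    v3 = w_k + f * (v1 - v2)
    return v1, v2, v3


def revde_mutation_matrix(f: float) -> np.ndarray:
    """The 3x3 block map (w_i, w_j, w_k) -> (v1, v2, v3); invertible for the
    working F values, which is what makes the operator reversible."""
    return np.array(
        [
            [1.0, f, -f],
            [-f, 1.0 - f * f, f + f * f],
            [f + f * f, -f + f * f + f ** 3, 1.0 - 2 * f * f - f ** 3],
        ]
    )


def de_crossover(
    v: np.ndarray, w: np.ndarray, cr: float, rng: np.random.Generator
) -> np.ndarray:
    """Binomial crossover: u = m * v + (1 - m) * w, m ~ Bernoulli(CR)."""
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if v.shape != w.shape:
        raise ValueError("crossover operands must share a dimension")
    mask = rng.random(v.shape) < cr
    return np.where(mask, v, w)


def init_learning_population(
    inherited: np.ndarray, cfg: LearnerConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """The inherited vector itself plus K - 1 Gaussian mutants of it."""
    inherited = np.asarray(inherited, dtype=float)
    pop = [inherited.copy()]
    for _ in range(cfg.population_size - 1):
        pop.append(inherited + rng.normal(0.0, cfg.init_noise_sd, inherited.shape))
    return pop


@dataclass
class LearnResult:
    best: np.ndarray
    best_reward: float
    history: list[dict]            # per iteration: best-so-far and pop mean
    assessments: int


def optimize(
    reward_fn: Callable[[np.ndarray], float],
    inherited: np.ndarray,
    cfg: LearnerConfig,
    rng: np.random.Generator,
) -> LearnResult:
    """Run one RevDE learning session on an arbitrary reward function.

    Iteration 1 assesses the K initial vectors; every later iteration draws K
    random triplets (members distinct within a triplet), produces three
    candidates per triplet, crosses each candidate with its corresponding
    triplet member, assesses the 3K offspring, and keeps the best K of
    parents and offspring (elitist), so the best-so-far reward never drops.
    """
    k = cfg.population_size
    pop = init_learning_population(inherited, cfg, rng)
    rewards = [float(reward_fn(w)) for w in pop]
    assessments = k

    best_idx = int(np.argmax(rewards))
    best, best_reward = pop[best_idx].copy(), rewards[best_idx]
    history = [
        {"iteration": 1, "best": best_reward, "mean": float(np.mean(rewards))}
    ]

    for it in range(2, cfg.iterations + 1):
        offspring: list[np.ndarray] = []
        for _ in range(k):
            i, j, l = rng.choice(k, size=3, replace=False)
            v1, v2, v3 = revde_mutation(
                pop[i], pop[j], pop[l], cfg.scaling_factor
            )
            for v, parent in ((v1, pop[i]), (v2, pop[j]), (v3, pop[l])):
                offspring.append(
                    de_crossover(v, parent, cfg.crossover_rate, rng)
                )
        off_rewards = [float(reward_fn(w)) for w in offspring]
        assessments += len(offspring)

        pool = pop + offspring
        pool_rewards = rewards + off_rewards
        order = np.argsort(-np.asarray(pool_rewards), kind="stable")
        # elitist cut over parents + offspring; exact duplicate vectors are
        # skipped while distinct ones remain — copies carry no information
        # and would freeze the differential operator once they take over
        pop, rewards, seen = [], [], set()
        for i in order:
            key = pool[i].tobytes()
            if key in seen:
                continue
            seen.add(key)
            pop.append(pool[i])
            rewards.append(pool_rewards[i])
            if len(pop) == k:
                break
        idx = 0
        while len(pop) < k:  # degenerate: fewer than K distinct vectors
            pop.append(pool[order[idx]].copy())
            rewards.append(pool_rewards[order[idx]])
            idx += 1

        if rewards[0] > best_reward:
            best, best_reward = pop[0].copy(), rewards[0]
        history.append(
            {"iteration": it, "best": best_reward, "mean": float(np.mean(rewards))}
        )

    return LearnResult(best, best_reward, history, assessments)


def learn_brain(
    body,
    genome,
    backend,
    task,
    cfg: LearnerConfig,
    rng: np.random.Generator,
    ledger=None,
) -> LearnResult:
    """Lifetime learning of one robot's CPG weights.

    The search space is the flat vector of genome entries the body actually
    expresses; each assessment injects a candidate vector into the genome,
    develops the brain, simulates the task, and uses the fitness as reward.
    """
    from .brain_genotype import extract_weights, inject_weights
    from .env import evaluate

    inherited = extract_weights(genome, body)

    def reward(vector: np.ndarray) -> float:
        candidate = inject_weights(genome, body, vector)
        return evaluate(
            body, candidate, backend, task, ledger, kind="assessment"
        ).fitness

    return optimize(reward, inherited, cfg, rng)
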