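"""Point-navigation task, fitness function, and locomotion backends.

A robot starts at the centre of a flat 10 x 10 m arena and must pass through
an ordered sequence of target points (default P1 = (1, -1), P2 = (0, -2))
within 40 s; a target counts as reached when the robot comes within 0.01 m of
it, in order. Positions are sampled at 5 Hz, which also approximates the
travelled path length L. With P_0 = (0, 0), k targets reached out of N, and
final position P_T, the fitness is

    k = N:  F = sum_{i=1..N} d(P_i, P_{i-1}) - omega * L
    k < N:  F = sum_{i=1..k} d(P_i, P_{i-1})
                + (d(P_{k+1}, P_k) - d(P_T, P_{k+1})) - omega * L

i.e. full credit for completed inter-target segments, partial credit for
distance made toward the next unreached target, and a path-length penalty
(omega = 0.1). Reaching both default targets along the shortest path gives
F = 2*sqrt(2) - 0.2*sqrt(2) = 1.8*sqrt(2), approximately 2.54.

The built-in locomotion backend is a deterministic kinematic surrogate, not a
physics engine: forward speed is proportional to actuation vigour (mean
absolute rate of change of the joint commands) times a body-efficiency
factor, and turning follows the left-right actuation asymmetry produced by
the steering rule. Its coefficients are exposed in :class:`SurrogateConfig`
and are a modelling choice of this package. An external physics backend can
be plugged in through the same interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .body import RobotBody
from .cpg import CpgNetwork, output


@dataclass(frozen=True)
class TaskSpec:
    """Point-navigation task definition."""

    targets: tuple[tuple[float, float], ...] = ((1.0, -1.0), (0.0, -2.0))
    reach_radius: float = 0.01      # metres
    duration: float = 40.0          # seconds per evaluation
    arena_size: float = 10.0        # metres, square
    omega: float = 0.1              # path-length penalty weight
    sample_hz: float = 5.0

    def __post_init__(self) -> None:
        if self.reach_radius <= 0:
            raise ValueError("reach radius must be positive")
        if self.omega < 0:
            raise ValueError("omega must be non-negative")


@dataclass
class Trajectory:
    """2D positions sampled at ``sample_hz`` over ``duration`` seconds."""

    samples: np.ndarray             # shape (n, 2), metres
    duration: float
    sample_hz: float = 5.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 2:
            raise ValueError("trajectory samples must be (n, 2)")

    @property
    def final_position(self) -> np.ndarray:
        return self.samples[-1]

    def to_csv(self) -> str:
        lines = ["t,x,y"]
        for i, (x, y) in enumerate(self.samples):
            lines.append(f"{i / self.sample_hz:.3f},{x:.9g},{y:.9g}")
        return "\n".join(lines) + "\n"


@dataclass
class EvaluationResult:
    fitness: float
    targets_reached: int
    path_length: float
    trajectory: Trajectory


def path_length(trajectory: Trajectory) -> float:
    """Sum of consecutive Euclidean segment lengths."""
    if len(trajectory.samples) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(trajectory.samples, axis=0), axis=1).sum())


def count_targets(
    trajectory: Trajectory, task: TaskSpec
) -> tuple[int, list[float]]:
    """Targets reached in order, with the sample times at which each fell
    within the reach radius. Target i only counts after target i-1."""
    times: list[float] = []
    samples = trajectory.samples
    start = 0  # each target is looked for strictly after the previous one
    for target in task.targets:
        d2 = ((samples[start:] - np.asarray(target)) ** 2).sum(axis=1)
        hits = np.nonzero(d2 <= task.reach_radius**2)[0]
        if hits.size == 0:
            break
        reached = start + int(hits[0])
        times.append(reached / trajectory.sample_hz)
        start = reached + 1
    return len(times), times


def _score(k: int, length: float, final: np.ndarray, task: TaskSpec) -> float:
    targets = [np.zeros(2)] + [np.asarray(t, dtype=float) for t in task.targets]
    n = len(task.targets)
    segments = sum(
        float(np.linalg.norm(targets[i] - targets[i - 1])) for i in range(1, k + 1)
    )
    if k < n:
        to_next = float(np.linalg.norm(targets[k + 1] - targets[k]))
        from_final = float(np.linalg.norm(final - targets[k + 1]))
        segments += to_next - from_final
    return segments - task.omega * length


def fitness(trajectory: Trajectory, task: TaskSpec) -> float:
    """Point-navigation fitness (see module docstring)."""
    k, _ = count_targets(trajectory, task)
    return _score(k, path_length(trajectory), trajectory.final_position, task)


# --------------------------------------------------------------------------
# evaluation bookkeeping
# --------------------------------------------------------------------------

@dataclass
class EvalLedger:
    """Counters for every kind of quality test performed during a run.

    Evolution-level evaluations and learning assessments are the same
    simulation procedure under different names (fitness vs. reward); the
    pre-learning evaluations feed the learning-delta analysis and are tracked
    separately from the evolution budget.
    """

    evolution_evaluations: int = 0
    learning_assessments: int = 0
    prelearning_evaluations: int = 0
    simulated_seconds: float = 0.0

    def record(self, kind: str, seconds: float) -> None:
        if kind == "evaluation":
            self.evolution_evaluations += 1
        elif kind == "assessment":
            self.learning_assessments += 1
        elif kind == "prelearning":
            self.prelearning_evaluations += 1
        else:
            raise ValueError(f"unknown evaluation kind {kind!r}")
        self.simulated_seconds += seconds

    @property
    def total_tests(self) -> int:
        return (
            self.evolution_evaluations
            + self.learning_assessments
            + self.prelearning_evaluations
        )

    def snapshot(self) -> dict:
        return {
            "evolution_evaluations": self.evolution_evaluations,
            "learning_assessments": self.learning_assessments,
            "prelearning_evaluations": self.prelearning_evaluations,
            "simulated_seconds": self.simulated_seconds,
        }


# --------------------------------------------------------------------------
# backends
# --------------------------------------------------------------------------

class BackendError(RuntimeError):
    """Raised when a locomotion backend cannot run."""


@dataclass(frozen=True)
class SurrogateConfig:
    """Coefficients of the kinematic surrogate (package modelling choices,
    exposed for calibration; they carry no empirical claim about physics)."""

    speed_gain: float = 0.08        # metres per unit actuation vigour
    turn_gain: float = 2.0          # rad/s per unit left-right asymmetry
    steering_gain: float = 1.0
    control_hz: float = 5.0         # control/steering update rate


class SurrogateBackend:
    """Deterministic kinematic locomotion surrogate.

    The CPG dynamics are linear, so oscillator states are propagated with the
    exact matrix exponential at the control tick; the 2D pose then integrates
    forward speed (proportional to mean |d out/dt|, scaled by a body
    efficiency factor) and a turning rate proportional to the steered
    left-right vigour asymmetry. If the target is to the right, right-side
    joints are slowed, which turns the robot rightward, and vice versa.
    """

    name = "surrogate"

    def __init__(self, config: SurrogateConfig | None = None) -> None:
        self.config = config or SurrogateConfig()

    @staticmethod
    def _efficiency(body: RobotBody) -> float:
        hinges = len(body.joints())
        return hinges / (1.0 + body.module_count) if hinges else 0.0

    def simulate(
        self,
        body: RobotBody,
        network: CpgNetwork,
        task: TaskSpec,
        rng: np.random.Generator | None = None,
    ) -> Trajectory:
        cfg = self.config
        dt = 1.0 / cfg.control_hz
        steps = int(round(task.duration * cfg.control_hz))
        half = task.arena_size / 2.0
        n_samples = int(round(task.duration * task.sample_hz)) + 1

        if network.n == 0:
            return Trajectory(
                np.zeros((n_samples, 2)), task.duration, task.sample_hz
            )

        net = network.copy()
        net.reset_states()
        states = net.state_history_exact(dt, steps)
        outs = output(states[:, : network.n])          # (steps+1, J)
        rates = np.abs(np.diff(outs, axis=0)) / dt     # (steps, J), unsteered

        xs_body = np.array([p[0] for p in network.positions])
        n_joints = network.n
        left_mean = (
            rates[:, xs_body < 0].mean(axis=1) if np.any(xs_body < 0) else
            np.zeros(steps)
        )
        right_mean = (
            rates[:, xs_body > 0].mean(axis=1) if np.any(xs_body > 0) else
            np.zeros(steps)
        )
        n_left = int(np.sum(xs_body < 0))
        n_right = int(np.sum(xs_body > 0))
        total_rate = rates.sum(axis=1)
        eff = self._efficiency(body)
        targets = [tuple(t) for t in task.targets]

        # steering slows the actuation of the side facing the target; the
        # speed uses the steered mean rate, the turn its left-right asymmetry
        px, py = 0.0, 0.0
        heading = math.pi / 2.0                        # facing "front" (+y)
        target_idx = 0
        samples = [(0.0, 0.0)]
        sg, tg, spg = cfg.steering_gain, cfg.turn_gain, cfg.speed_gain
        radius = task.reach_radius
        for t in range(steps):
            tx, ty = targets[min(target_idx, len(targets) - 1)]
            dtx, dty = tx - px, ty - py
            if dtx or dty:
                bearing = _wrap_angle(heading - math.atan2(dty, dtx))
            else:
                bearing = 0.0
            factor = max(0.0, 1.0 - sg * abs(bearing) / math.pi)
            lm, rm = left_mean[t], right_mean[t]
            if bearing > 0.0:
                rm_s, lm_s = rm * factor, lm
            elif bearing < 0.0:
                rm_s, lm_s = rm, lm * factor
            else:
                rm_s, lm_s = rm, lm
            vigour = (
                total_rate[t]
                - (lm - lm_s) * n_left
                - (rm - rm_s) * n_right
            ) / n_joints
            heading += -tg * (lm_s - rm_s) * dt
            speed = spg * eff * vigour
            px += speed * dt * math.cos(heading)
            py += speed * dt * math.sin(heading)
            px = -half if px < -half else (half if px > half else px)
            py = -half if py < -half else (half if py > half else py)
            samples.append((px, py))
            if target_idx < len(targets):
                ddx = px - targets[target_idx][0]
                ddy = py - targets[target_idx][1]
                if ddx * ddx + ddy * ddy <= radius * radius:
                    target_idx += 1

        traj = np.asarray(samples)
        if len(traj) != n_samples:
            # control rate differs from the 5 Hz sampling: resample by index
            idx = np.linspace(0, len(traj) - 1, n_samples).round().astype(int)
            traj = traj[idx]
        return Trajectory(traj, task.duration, task.sample_hz)


class ExternalBackend:
    """Placeholder interface for a physics engine backend.

    This package ships no physics engine; constructing or using this backend
    raises :class:`BackendError` explicitly rather than falling back to the
    surrogate silently.
    """

    name = "external"

    def simulate(self, body, network, task, rng=None):
        raise BackendError(
            "external physics backend is not configured; install and wire a "
            "physics engine, or use backend='surrogate'"
        )


def get_backend(name: str, **kwargs):
    if name == "surrogate":
        return SurrogateBackend(**kwargs)
    if name == "external":
        return ExternalBackend()
    raise BackendError(f"unknown backend {name!r}")


def _wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]."""
    a = (a + math.pi) % (2.0 * math.pi) - math.pi
    return math.pi if a == -math.pi else a


def evaluate(
    body: RobotBody,
    genome,
    backend,
    task: TaskSpec,
    ledger: EvalLedger | None = None,
    kind: str = "evaluation",
) -> EvaluationResult:
    """Develop the brain in the body, simulate, and score the trajectory.

    Increments the ledger counter for ``kind`` exactly once. Rewards used by
    the lifetime learner and fitness used by evolution are the same quantity
    computed by this same procedure.
    """
    from .cpg import build_network

    network = build_network(body, genome)
    trajectory = backend.simulate(body, network, task)
    k, _ = count_targets(trajectory, task)
    length = path_length(trajectory)
    score = _score(k, length, trajectory.final_position, task)
    if ledger is not None:
        ledger.record(kind, task.duration)
    return EvaluationResult(score, k, length, trajectory)
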