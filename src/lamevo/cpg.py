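"""Central pattern generator network: the brain phenotype.

Each active hinge is driven by one CPG with two state neurons (x_i, y_i) and
an output neuron. In isolation a CPG is a harmonic oscillator,

    dx_i/dt = w_i * y_i,    dy_i/dt = -w_i * x_i,

so with the initial state (sqrt(2)/2, sqrt(2)/2) each x_i traces a sine wave
of amplitude 1, matching the hinges' limited rotation range. CPGs of
neighbouring joints (body-tree distance <= 2) are coupled through
antisymmetric weights (w_ij = -w_ji):

    dx_i/dt = w_i * y_i + sum_{j in N_i} w_ji * x_j.

The coupled x neurons are no longer bounded, so the output neuron squashes
them with tanh, written in its logistic form 2 / (1 + exp(-2x)) - 1, keeping
joint commands inside (-1, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

INITIAL_STATE = math.sqrt(2.0) / 2.0
DEFAULT_DT = 0.005  # seconds; fixed-step RK4


class NumericalError(RuntimeError):
    """Raised when network states stop being finite."""


def output(x):
    """Output activation 2 / (1 + e^(-2x)) - 1, algebraically equal to tanh(x)."""
    return 2.0 / (1.0 + np.exp(-2.0 * np.asarray(x, dtype=float))) - 1.0


@dataclass
class CpgNetwork:
    """One oscillator per joint plus an antisymmetric coupling matrix.

    ``coupling[i, j]`` is the coefficient of x_j in dx_i/dt (i.e. w_ji in the
    equation of motion); the matrix satisfies coupling = -coupling.T.
    """

    joints: tuple[int, ...]                  # body module indices, decode order
    positions: tuple[tuple[int, int, int], ...]
    internal_weights: np.ndarray
    coupling: np.ndarray
    x: np.ndarray = field(default=None)
    y: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.internal_weights = np.asarray(self.internal_weights, dtype=float)
        self.coupling = np.asarray(self.coupling, dtype=float)
        if not np.allclose(self.coupling, -self.coupling.T):
            raise ValueError("coupling matrix must be antisymmetric")
        if self.x is None:
            self.reset_states()

    @property
    def n(self) -> int:
        return len(self.joints)

    def neighbour_sets(self) -> list[set[int]]:
        return [
            {j for j in range(self.n) if j != i and self.coupling[i, j] != 0.0}
            for i in range(self.n)
        ]

    def reset_states(self) -> None:
        self.x = np.full(self.n, INITIAL_STATE)
        self.y = np.full(self.n, INITIAL_STATE)

    def copy(self) -> "CpgNetwork":
        net = CpgNetwork(
            self.joints,
            self.positions,
            self.internal_weights.copy(),
            self.coupling.copy(),
            self.x.copy(),
            self.y.copy(),
        )
        return net

    # -- dynamics -----------------------------------------------------------

    def _deriv(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dx = self.internal_weights * y + self.coupling @ x
        dy = -self.internal_weights * x
        return dx, dy

    def step(self, dt: float = DEFAULT_DT) -> None:
        """Advance the states by one fixed-step RK4 integration step."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        x, y = self.x, self.y
        k1x, k1y = self._deriv(x, y)
        k2x, k2y = self._deriv(x + 0.5 * dt * k1x, y + 0.5 * dt * k1y)
        k3x, k3y = self._deriv(x + 0.5 * dt * k2x, y + 0.5 * dt * k2y)
        k4x, k4y = self._deriv(x + dt * k3x, y + dt * k3y)
        self.x = x + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
        self.y = y + dt / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise NumericalError(
                f"non-finite CPG state after step (n={self.n}, dt={dt})"
            )

    def system_matrix(self) -> np.ndarray:
        """The linear system matrix M with d[x; y]/dt = M [x; y]."""
        n = self.n
        m = np.zeros((2 * n, 2 * n))
        m[:n, :n] = self.coupling
        m[:n, n:] = np.diag(self.internal_weights)
        m[n:, :n] = -np.diag(self.internal_weights)
        return m

    def state_history_exact(self, dt: float, steps: int) -> np.ndarray:
        """States at ``steps + 1`` times spaced ``dt`` apart, from the current
        state, via the exact matrix exponential of the (linear) dynamics.

        Returns an array of shape (steps + 1, 2n): columns [:n] are x, [n:] y.
        """
        n = self.n
        if n == 0:
            return np.zeros((steps + 1, 0))
        m = self.system_matrix()
        s0 = np.concatenate([self.x, self.y])
        # eigendecomposition of the (real, essentially skew) system matrix:
        # states at all sample times in one vectorized expression
        evals, vecs = np.linalg.eig(m)
        coeff = np.linalg.solve(vecs, s0.astype(complex))
        t = np.arange(steps + 1) * dt
        phases = np.exp(np.outer(t, evals))            # (steps+1, 2n)
        states = (phases * coeff) @ vecs.T
        return np.ascontiguousarray(states.real)

    def outputs(self) -> np.ndarray:
        """Current joint commands in (-1, 1)."""
        return output(self.x)

    def state_dump(self) -> dict:
        return {
            "joints": list(self.joints),
            "x": self.x.tolist(),
            "y": self.y.tolist(),
        }


def build_network(body, genome) -> CpgNetwork:
    """Develop ``genome`` in ``body``: one CPG per hinge, neighbour couplings
    from tree distance <= 2, states initialised to sqrt(2)/2."""
    from .brain_genotype import develop_brain

    return develop_brain(genome, body)


def step_network(network: CpgNetwork, dt: float = DEFAULT_DT) -> CpgNetwork:
    """Functional single integrator step: returns an advanced copy."""
    out = network.copy()
    out.step(dt)
    return out


def steer(
    commands: np.ndarray,
    bearing: float,
    body,
    positions: tuple[tuple[int, int, int], ...] | None = None,
    gain: float = 1.0,
) -> np.ndarray:
    """Target-steering modulation of joint commands.

    ``bearing`` is the signed angle to the current target relative to the
    robot's heading; positive means the target lies to the right. The joints
    on the side toward the target (classified by the sign of their body-frame
    x coordinate) are slowed by the factor max(0, 1 - gain * |bearing| / pi);
    on-axis joints and the far side are untouched. Zero bearing is a no-op.
    """
    if positions is None:
        positions = tuple(body.modules[i].position for i in body.joints())
    commands = np.array(commands, dtype=float)
    if bearing == 0.0 or commands.size == 0:
        return commands
    factor = max(0.0, 1.0 - gain * abs(bearing) / math.pi)
    xs = np.array([p[0] for p in positions])
    side = xs > 0 if bearing > 0 else xs < 0
    commands[side] *= factor
    return commands
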