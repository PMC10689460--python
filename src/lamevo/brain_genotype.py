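"""Reversible grid-indexed genotype for CPG brain weights.

The brain genotype is a fixed 440 x 14 real table. Rows index the 2D grid
positions a joint can occupy (a 21 x 21 grid minus the centre, where the core
sits: 21*21 - 1 = 440). Columns index weight slots per joint: the 12 relative
offsets in a Manhattan distance-2 neighbourhood (the Delannoy D(2,2) = 13
cells minus the centre), one slot for a coupling with a joint at the same 2D
coordinate (bodies are 3D, the grid is not), and one internal CPG weight.

Because every used weight of a robot's brain has a fixed address in this
table, the genotype-phenotype map is invertible: learned phenotype weights
can be written back into the genome bit-exactly. That reversibility is what
makes Lamarckian inheritance possible. Entries not addressed by a given body
are silently carried along — offspring with different morphologies may
express them later.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import numpy as np

from .body import GRID_RADIUS, RobotBody

GRID_SIZE = 2 * GRID_RADIUS + 1            # 21
N_ROWS = GRID_SIZE * GRID_SIZE - 1         # 440
N_SLOTS = 14
SLOT_SAME_COORD = 12
SLOT_INTERNAL = 13

#: the 12 neighbour offsets at Manhattan distance 1..2, lexicographic order
NEIGHBOUR_OFFSETS: tuple[tuple[int, int], ...] = tuple(
    sorted(
        (dx, dy)
        for dx in range(-2, 3)
        for dy in range(-2, 3)
        if 1 <= abs(dx) + abs(dy) <= 2
    )
)
_OFFSET_TO_SLOT = {off: i for i, off in enumerate(NEIGHBOUR_OFFSETS)}


class GridError(ValueError):
    """Raised for grid positions or offsets outside the encoding's domain."""


class ConsistencyError(ValueError):
    """Raised when a network does not match the body it is encoded against."""


def grid_row(x: int, y: int) -> int:
    """Row index of grid cell (x, y); row-major with x fastest, centre skipped."""
    if not (-GRID_RADIUS <= x <= GRID_RADIUS and -GRID_RADIUS <= y <= GRID_RADIUS):
        raise GridError(f"({x}, {y}) outside the {GRID_SIZE}x{GRID_SIZE} grid")
    if (x, y) == (0, 0):
        raise GridError("the centre cell is reserved for the core")
    idx = (y + GRID_RADIUS) * GRID_SIZE + (x + GRID_RADIUS)
    centre = GRID_RADIUS * GRID_SIZE + GRID_RADIUS
    return idx if idx < centre else idx - 1


def grid_coords(row: int) -> tuple[int, int]:
    """Inverse of :func:`grid_row`."""
    if not 0 <= row < N_ROWS:
        raise GridError(f"row {row} out of [0, {N_ROWS})")
    centre = GRID_RADIUS * GRID_SIZE + GRID_RADIUS
    idx = row if row < centre else row + 1
    return idx % GRID_SIZE - GRID_RADIUS, idx // GRID_SIZE - GRID_RADIUS


def slot_for_offset(dx: int, dy: int, same_coord: bool = False) -> int:
    """Column index for a neighbour at relative 2D offset (dx, dy)."""
    if same_coord:
        return SLOT_SAME_COORD
    if (dx, dy) == (0, 0):
        raise GridError("offset (0, 0) requires same_coord=True")
    if abs(dx) + abs(dy) > 2:
        raise GridError(f"offset ({dx}, {dy}) outside the distance-2 neighbourhood")
    return _OFFSET_TO_SLOT[(dx, dy)]


@dataclass
class BrainGenome:
    """The 440 x 14 weight table."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (N_ROWS, N_SLOTS):
            raise ValueError(f"brain genome must be {N_ROWS}x{N_SLOTS}")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("brain genome entries must be finite")

    @classmethod
    def zeros(cls) -> "BrainGenome":
        return cls(np.zeros((N_ROWS, N_SLOTS)))

    @classmethod
    def random(cls, rng: np.random.Generator, sd: float = 0.5) -> "BrainGenome":
        return cls(rng.normal(0.0, sd, size=(N_ROWS, N_SLOTS)))

    def copy(self) -> "BrainGenome":
        return BrainGenome(self.weights.copy())

    # -- serialization (bit-exact round trips) ------------------------------

    def to_csv(self) -> str:
        buf = io.StringIO()
        np.savetxt(buf, self.weights, delimiter=",", fmt="%.17g")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "BrainGenome":
        return cls(np.loadtxt(io.StringIO(text), delimiter=","))

    def to_json(self) -> str:
        return json.dumps(self.weights.tolist())

    @classmethod
    def from_json(cls, text: str) -> "BrainGenome":
        return cls(np.array(json.loads(text)))


# --------------------------------------------------------------------------
# body-dependent weight addressing
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class JointLayout:
    """Which genome entries a body expresses, and how.

    ``joints`` are hinge module indices in decode order; ``pairs`` are the
    neighbour pairs (i, j), i < j in decode order, at body-tree distance <= 2.
    ``pair_entry[(i, j)]`` is the (row, col) each coupling is read from — the
    row of the lower-decode-order joint, per the documented direction
    convention — and ``internal_entry[i]`` addresses joint i's internal weight.
    """

    joints: tuple[int, ...]
    positions_2d: tuple[tuple[int, int], ...]
    pairs: tuple[tuple[int, int], ...]
    internal_entry: dict[int, tuple[int, int]]
    pair_entry: dict[tuple[int, int], tuple[int, int]]

    @property
    def used_entries(self) -> list[tuple[int, int]]:
        entries = set(self.internal_entry.values()) | set(self.pair_entry.values())
        return sorted(entries)


def joint_layout(body: RobotBody) -> JointLayout:
    joints = tuple(body.joints())
    pos2d = tuple(
        (body.modules[i].position[0], body.modules[i].position[1]) for i in joints
    )
    internal_entry = {
        k: (grid_row(*pos2d[k]), SLOT_INTERNAL) for k in range(len(joints))
    }
    pairs: list[tuple[int, int]] = []
    pair_entry: dict[tuple[int, int], tuple[int, int]] = {}
    for a in range(len(joints)):
        for b in range(a + 1, len(joints)):
            if body.tree_distance(joints[a], joints[b]) > 2:
                continue
            pa, pb = pos2d[a], pos2d[b]
            if pa == pb:
                entry = (grid_row(*pa), SLOT_SAME_COORD)
            else:
                off = (pb[0] - pa[0], pb[1] - pa[1])
                entry = (grid_row(*pa), slot_for_offset(*off))
            pairs.append((a, b))
            pair_entry[(a, b)] = entry
    return JointLayout(joints, pos2d, tuple(pairs), internal_entry, pair_entry)


def develop_brain(genome: BrainGenome, body: RobotBody):
    """Express the genome in a body: build its CPG network phenotype.

    Each joint reads its internal weight from its grid row; each neighbour
    pair (tree distance <= 2) reads one coupling from the row of the
    lower-decode-order joint, and the reverse coupling is its negation.
    """
    from .cpg import CpgNetwork

    layout = joint_layout(body)
    n = len(layout.joints)
    w = np.array([genome.weights[layout.internal_entry[k]] for k in range(n)])
    coupling = np.zeros((n, n))
    for (a, b), entry in layout.pair_entry.items():
        v = genome.weights[entry]
        coupling[a, b] = v
        coupling[b, a] = -v
    return CpgNetwork(
        joints=layout.joints,
        positions=tuple(body.modules[i].position for i in layout.joints),
        internal_weights=w,
        coupling=coupling,
    )


def encode_brain(network, body: RobotBody, genome: BrainGenome) -> BrainGenome:
    """Write a network's weights back into a copy of the genome.

    Only the entries the body expresses are overwritten; everything else is
    untouched. Raises :class:`ConsistencyError` if the network's topology does
    not match the body, or if weights that share a genome entry disagree.
    """
    layout = joint_layout(body)
    n = len(layout.joints)
    if network.n != n or tuple(network.joints) != layout.joints:
        raise ConsistencyError("network topology does not match body")
    child = genome.copy()
    written: dict[tuple[int, int], float] = {}

    def write(entry: tuple[int, int], value: float) -> None:
        if entry in written and written[entry] != value:
            raise ConsistencyError(
                f"conflicting values for shared genome entry {entry}"
            )
        written[entry] = value
        child.weights[entry] = value

    for k in range(n):
        write(layout.internal_entry[k], float(network.internal_weights[k]))
    for (a, b), entry in layout.pair_entry.items():
        write(entry, float(network.coupling[a, b]))
    return child


def extract_weights(genome: BrainGenome, body: RobotBody) -> np.ndarray:
    """The body's used genome entries as a flat vector (sorted entry order)."""
    layout = joint_layout(body)
    return np.array([genome.weights[e] for e in layout.used_entries])


def inject_weights(
    genome: BrainGenome, body: RobotBody, vector: np.ndarray
) -> BrainGenome:
    """Inverse of :func:`extract_weights`: overwrite the used entries."""
    layout = joint_layout(body)
    entries = layout.used_entries
    if len(vector) != len(entries):
        raise ConsistencyError(
            f"weight vector has {len(vector)} entries, body uses {len(entries)}"
        )
    child = genome.copy()
    for e, v in zip(entries, vector):
        child.weights[e] = v
    return child


# --------------------------------------------------------------------------
# variation operators
# --------------------------------------------------------------------------

def uniform_crossover_brain(
    g1: BrainGenome, g2: BrainGenome, rng: np.random.Generator
) -> BrainGenome:
    """Each table entry independently from either parent with p = 0.5."""
    mask = rng.random((N_ROWS, N_SLOTS)) < 0.5
    return BrainGenome(np.where(mask, g1.weights, g2.weights))


def gaussian_mutate_brain(
    g: BrainGenome,
    rng: np.random.Generator,
    prob: float = 0.8,
    sd: float = 0.5,
) -> BrainGenome:
    """Each entry perturbed with probability ``prob`` by N(0, sd^2) noise."""
    if prob <= 0:
        return g.copy()
    mask = rng.random((N_ROWS, N_SLOTS)) < prob
    noise = rng.normal(0.0, sd, size=(N_ROWS, N_SLOTS))
    return BrainGenome(g.weights + mask * noise)
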