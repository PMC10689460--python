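"""CPPN-encoded modular robot bodies.

A robot body is a tree of modules — one core, plus passive bricks and active
hinges — living on an integer grid. The heritable encoding is a compositional
pattern-producing network (CPPN): a small feed-forward network that is queried
at each candidate grid position (x, y, z, tree distance to the core) and
answers which module, if any, should grow there and how it is rotated.

The genotype-to-phenotype mapping expands breadth-first from the core over
open sockets, in a fixed documented socket order, and stops once ten non-core
modules exist. The decision at each slot is the argmax of the CPPN outputs;
no randomness is involved in development.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np

# --------------------------------------------------------------------------
# module kinds and grid conventions
# --------------------------------------------------------------------------

CORE = "core"
BRICK = "brick"
HINGE = "active_hinge"

#: non-core modules per body; the 21x21(x21) grid admits offsets up to +-10
MAX_MODULES = 10
GRID_RADIUS = 10

# local direction vectors ("front" of the core points along +y, so a module
# attached to the front of the core sits at (0, 1, 0))
FRONT = (0, 1, 0)
BACK = (0, -1, 0)
LEFT = (-1, 0, 0)
RIGHT = (1, 0, 0)
UP = (0, 0, 1)
DOWN = (0, 0, -1)

#: open sockets per module kind, in the fixed enumeration order used by the
#: breadth-first decoder. A child attaches through its own back face, so the
#: back never appears among a non-core module's free sockets; a hinge passes
#: straight through.
SOCKETS = {
    CORE: (FRONT, BACK, LEFT, RIGHT, UP, DOWN),
    BRICK: (FRONT, LEFT, RIGHT, UP, DOWN),
    HINGE: (FRONT,),
}


def _rot_z(q: int) -> np.ndarray:
    c, s = [1, 0, -1, 0][q % 4], [0, 1, 0, -1][q % 4]
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=int)


def _rot_x(q: int) -> np.ndarray:
    c, s = [1, 0, -1, 0][q % 4], [0, 1, 0, -1][q % 4]
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=int)


def _rot_y(q: int) -> np.ndarray:
    c, s = [1, 0, -1, 0][q % 4], [0, 1, 0, -1][q % 4]
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=int)


# orientation that maps the local forward axis (+y) onto each socket direction
_ALIGN = {
    FRONT: np.eye(3, dtype=int),
    BACK: _rot_z(2),
    LEFT: _rot_z(1),
    RIGHT: _rot_z(3),
    UP: _rot_x(1),
    DOWN: _rot_x(3),
}

# the optional 90-degree roll about the attachment (forward) axis; it composes
# down the subtree through the orientation matrices
_ROLL = {0: np.eye(3, dtype=int), 90: _rot_y(1)}


# --------------------------------------------------------------------------
# CPPN genome
# --------------------------------------------------------------------------

N_INPUTS = 4   # x, y, z, tree distance to core
N_OUTPUTS = 5  # brick, joint, empty, rotation 0, rotation 90
INPUT_IDS = tuple(range(N_INPUTS))
OUTPUT_IDS = tuple(range(N_INPUTS, N_INPUTS + N_OUTPUTS))
_HIDDEN_BASE = N_INPUTS + N_OUTPUTS


def _sigmoid(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-max(-60.0, min(60.0, v))))


ACTIVATIONS = {
    "sigmoid": _sigmoid,
    "tanh": math.tanh,
    "gaussian": lambda v: math.exp(-min(60.0, v * v)),
    "sine": math.sin,
    "linear": lambda v: v,
}


def innovation_id(src: int, dst: int) -> int:
    """Deterministic historical marking: Cantor pairing of (src, dst).

    Two connections between the same node pair always share an innovation id,
    in any lineage, which keeps crossover alignment well-defined without a
    global mutable counter.
    """
    s = src + dst
    return s * (s + 1) // 2 + dst


def hidden_id_for_split(src: int, dst: int) -> int:
    """Node id of the hidden node created by splitting connection src->dst."""
    return _HIDDEN_BASE + innovation_id(src, dst)


class GenomeError(ValueError):
    """Raised for structurally invalid CPPN genomes."""


@dataclass(frozen=True)
class NodeGene:
    id: int
    activation: str
    bias: float = 0.0


@dataclass(frozen=True)
class ConnectionGene:
    src: int
    dst: int
    weight: float
    enabled: bool = True

    @property
    def innovation(self) -> int:
        return innovation_id(self.src, self.dst)


@dataclass
class CppnGenome:
    """Feed-forward CPPN with 4 inputs and 5 outputs.

    Inputs carry no activation; every other node applies ``activation`` to
    ``bias + sum(weight * upstream)``.
    """

    nodes: dict[int, NodeGene]
    connections: list[ConnectionGene]

    def copy(self) -> "CppnGenome":
        return CppnGenome(dict(self.nodes), list(self.connections))

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for nid in INPUT_IDS + OUTPUT_IDS:
            if nid not in self.nodes:
                raise GenomeError(f"missing fixed node {nid}")
        seen = set()
        for c in self.connections:
            if c.src not in self.nodes or c.dst not in self.nodes:
                raise GenomeError("connection references unknown node")
            if c.dst in INPUT_IDS:
                raise GenomeError("connection into an input node")
            if c.innovation in seen:
                raise GenomeError("duplicate innovation id")
            seen.add(c.innovation)
        self._toposort()  # raises on cycles

    def _toposort(self) -> list[int]:
        edges = [(c.src, c.dst) for c in self.connections if c.enabled]
        indeg = {nid: 0 for nid in self.nodes}
        out: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for s, d in edges:
            indeg[d] += 1
            out[s].append(d)
        ready = sorted(nid for nid, k in indeg.items() if k == 0)
        order: list[int] = []
        queue = deque(ready)
        while queue:
            n = queue.popleft()
            order.append(n)
            for d in sorted(out[n]):
                indeg[d] -= 1
                if indeg[d] == 0:
                    queue.append(d)
        if len(order) != len(self.nodes):
            raise GenomeError("cycle among enabled connections")
        return order

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, inputs: tuple[float, float, float, float]) -> np.ndarray:
        if len(inputs) != N_INPUTS:
            raise GenomeError("CPPN takes exactly 4 inputs")
        order = self._toposort()
        incoming: dict[int, list[ConnectionGene]] = {}
        for c in self.connections:
            if c.enabled:
                incoming.setdefault(c.dst, []).append(c)
        values: dict[int, float] = {}
        for nid in INPUT_IDS:
            values[nid] = float(inputs[nid])
        for nid in order:
            if nid in INPUT_IDS:
                continue
            node = self.nodes[nid]
            total = node.bias
            for c in incoming.get(nid, ()):
                total += c.weight * values[c.src]
            values[nid] = ACTIVATIONS[node.activation](total)
        return np.array([values[o] for o in OUTPUT_IDS])

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": [
                    {"id": n.id, "activation": n.activation, "bias": n.bias}
                    for n in sorted(self.nodes.values(), key=lambda n: n.id)
                ],
                "connections": [
                    {
                        "src": c.src,
                        "dst": c.dst,
                        "weight": c.weight,
                        "enabled": c.enabled,
                    }
                    for c in self.connections
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CppnGenome":
        data = json.loads(text)
        nodes = {
            n["id"]: NodeGene(n["id"], n["activation"], n["bias"])
            for n in data["nodes"]
        }
        conns = [
            ConnectionGene(c["src"], c["dst"], c["weight"], c["enabled"])
            for c in data["connections"]
        ]
        g = cls(nodes, conns)
        g.validate()
        return g


@dataclass(frozen=True)
class CppnInitConfig:
    """How fresh random CPPNs are built."""

    connectivity: str = "full"       # "full" or "sparse"
    sparse_p: float = 0.5
    weight_sd: float = 1.0
    bias_sd: float = 1.0
    output_activation: str = "linear"
    hidden_activations: tuple[str, ...] = (
        "sigmoid",
        "tanh",
        "gaussian",
        "sine",
        "linear",
    )


def random_cppn(seed: int, config: CppnInitConfig | None = None) -> CppnGenome:
    """Minimal random genome: inputs wired to outputs, no hidden nodes."""
    cfg = config or CppnInitConfig()
    rng = np.random.default_rng(seed)
    nodes = {i: NodeGene(i, "linear") for i in INPUT_IDS}
    for o in OUTPUT_IDS:
        nodes[o] = NodeGene(o, cfg.output_activation, float(rng.normal(0, cfg.bias_sd)))
    conns = []
    for i in INPUT_IDS:
        for o in OUTPUT_IDS:
            if cfg.connectivity == "sparse" and rng.random() >= cfg.sparse_p:
                continue
            conns.append(ConnectionGene(i, o, float(rng.normal(0, cfg.weight_sd))))
    g = CppnGenome(nodes, conns)
    g.validate()
    return g


# --------------------------------------------------------------------------
# querying and decoding
# --------------------------------------------------------------------------

def query_cppn(
    g: CppnGenome, x: int, y: int, z: int, d: int
) -> tuple[np.ndarray, np.ndarray]:
    """Module-type and rotation scores at one grid position.

    Returns a 3-vector (brick, joint, empty) and a 2-vector (0deg, 90deg).
    The caller takes the argmax; ties break toward the earlier output.
    """
    out = g.evaluate((float(x), float(y), float(z), float(d)))
    return out[:3], out[3:]


@dataclass
class BodyModule:
    kind: str
    position: tuple[int, int, int]
    rotation: int                      # 0 or 90, about the attachment axis
    parent: int | None                 # index into RobotBody.modules
    socket: int | None                 # socket index on the parent
    depth: int                         # tree distance to the core
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3, dtype=int))
    children: list[int] = field(default_factory=list)


@dataclass
class RobotBody:
    """Tree of modules rooted at the core (index 0, position (0,0,0))."""

    modules: list[BodyModule]

    @property
    def module_count(self) -> int:
        """Non-core module count (the 10-module cap excludes the core)."""
        return len(self.modules) - 1

    def joints(self) -> list[int]:
        return [i for i, m in enumerate(self.modules) if m.kind == HINGE]

    def validate(self) -> None:
        core = self.modules[0]
        assert core.kind == CORE and core.position == (0, 0, 0)
        positions = [m.position for m in self.modules]
        assert len(set(positions)) == len(positions), "positions not unique"
        assert self.module_count <= MAX_MODULES
        for i, m in enumerate(self.modules[1:], start=1):
            assert m.kind in (BRICK, HINGE)
            p = self.modules[m.parent]
            step = np.array(m.position) - np.array(p.position)
            assert np.abs(step).sum() == 1, "not one orthogonal step from parent"
            assert all(abs(c) <= GRID_RADIUS for c in m.position)

    def tree_distance(self, i: int, j: int) -> int:
        """Number of edges between modules i and j in the body tree."""
        anc_i: dict[int, int] = {}
        n, d = i, 0
        while n is not None:
            anc_i[n] = d
            n = self.modules[n].parent
            d += 1
        n, d = j, 0
        while n not in anc_i:
            n = self.modules[n].parent
            d += 1
        return d + anc_i[n]

    # -- serialization ------------------------------------------------------

    def _subtree_dict(self, i: int) -> dict:
        m = self.modules[i]
        return {
            "kind": m.kind,
            "position": list(m.position),
            "rotation": m.rotation,
            "socket": m.socket,
            "children": [self._subtree_dict(c) for c in m.children],
        }

    def to_json(self) -> str:
        return json.dumps(self._subtree_dict(0))

    @classmethod
    def from_json(cls, text: str) -> "RobotBody":
        data = json.loads(text)
        modules: list[BodyModule] = []

        def build(node: dict, parent: int | None, depth: int) -> int:
            idx = len(modules)
            modules.append(
                BodyModule(
                    kind=node["kind"],
                    position=tuple(node["position"]),
                    rotation=node["rotation"],
                    parent=parent,
                    socket=node["socket"],
                    depth=depth,
                )
            )
            for child in node["children"]:
                cidx = build(child, idx, depth + 1)
                modules[idx].children.append(cidx)
            return idx

        build(data, None, 0)
        return cls(modules)

    def ascii_grid(self) -> str:
        """Top-down (z collapsed) sketch for debugging."""
        glyph = {CORE: "O", BRICK: "#", HINGE: "H"}
        xs = [m.position[0] for m in self.modules]
        ys = [m.position[1] for m in self.modules]
        rows = []
        for y in range(max(ys), min(ys) - 1, -1):
            row = []
            for x in range(min(xs), max(xs) + 1):
                cell = "."
                for m in self.modules:
                    if (m.position[0], m.position[1]) == (x, y):
                        cell = glyph[m.kind]
                row.append(cell)
            rows.append("".join(row))
        return "\n".join(rows)


def decode_body(
    g: CppnGenome,
    max_modules: int = MAX_MODULES,
    grid_radius: int = GRID_RADIUS,
) -> RobotBody:
    """Grow a body from a CPPN, breadth-first over open sockets.

    An "empty" decision closes the branch; an occupied or out-of-grid target
    position means the module is simply not placed and the branch ends there.
    Expansion stops once ``max_modules`` non-core modules exist. Decoding
    always succeeds (worst case: a core-only body).
    """
    core = BodyModule(CORE, (0, 0, 0), 0, None, None, 0)
    modules = [core]
    occupied = {(0, 0, 0)}
    queue: deque[tuple[int, int]] = deque(
        (0, s) for s in range(len(SOCKETS[CORE]))
    )
    count = 0
    while queue and count < max_modules:
        pi, s_idx = queue.popleft()
        parent = modules[pi]
        d_loc = SOCKETS[parent.kind][s_idx]
        d_world = parent.orientation @ np.array(d_loc)
        pos = tuple(int(v) for v in (np.array(parent.position) + d_world))
        if any(abs(c) > grid_radius for c in pos) or pos in occupied:
            continue
        tprobs, rprobs = query_cppn(g, pos[0], pos[1], pos[2], parent.depth + 1)
        kind = (BRICK, HINGE, "empty")[int(np.argmax(tprobs))]
        if kind == "empty":
            continue
        if kind == HINGE and pos[0] == 0 and pos[1] == 0:
            # the brain grid cannot address a joint that projects onto the
            # centre cell (reserved for the core), so none may grow there;
            # like an occupied cell, the module is not placed
            continue
        rotation = (0, 90)[int(np.argmax(rprobs))]
        orientation = parent.orientation @ _ALIGN[d_loc] @ _ROLL[rotation]
        idx = len(modules)
        modules.append(
            BodyModule(
                kind=kind,
                position=pos,
                rotation=rotation,
                parent=pi,
                socket=s_idx,
                depth=parent.depth + 1,
                orientation=orientation,
            )
        )
        occupied.add(pos)
        parent.children.append(idx)
        count += 1
        for s in range(len(SOCKETS[kind])):
            queue.append((idx, s))
    body = RobotBody(modules)
    body.validate()
    return body


def project_2d(body: RobotBody) -> dict[tuple[int, int], list[int]]:
    """Joint (active hinge) module indices keyed by their (x, y) grid cell.

    The third dimension is dropped; joints that collide in 2D are kept as a
    list in decode order.
    """
    out: dict[tuple[int, int], list[int]] = {}
    for i in body.joints():
        x, y, _ = body.modules[i].position
        out.setdefault((x, y), []).append(i)
    return out


# --------------------------------------------------------------------------
# variation operators
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BodyMutationRates:
    """Per-operator rates for NEAT-style body mutation.

    The overall 0.8 probability that a child is mutated at all lives in the
    evolution loop; these rates shape what a mutation event does.
    """

    weight_prob: float = 0.8
    weight_sd: float = 0.5
    bias_prob: float = 0.3
    bias_sd: float = 0.5
    add_connection_prob: float = 0.15
    add_node_prob: float = 0.1
    hidden_activations: tuple[str, ...] = (
        "sigmoid",
        "tanh",
        "gaussian",
        "sine",
        "linear",
    )

    @classmethod
    def zero(cls) -> "BodyMutationRates":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def _creates_cycle(g: CppnGenome, src: int, dst: int) -> bool:
    out: dict[int, list[int]] = {}
    for c in g.connections:
        if c.enabled:
            out.setdefault(c.src, []).append(c.dst)
    stack, seen = [dst], set()
    while stack:
        n = stack.pop()
        if n == src:
            return True
        if n in seen:
            continue
        seen.add(n)
        stack.extend(out.get(n, ()))
    return False


def mutate_body(
    g: CppnGenome, rates: BodyMutationRates, rng: np.random.Generator
) -> CppnGenome:
    """NEAT-style mutation: weight/bias perturbation, add-connection, add-node."""
    child = g.copy()

    child.connections = [
        replace(c, weight=c.weight + float(rng.normal(0, rates.weight_sd)))
        if rates.weight_prob > 0 and rng.random() < rates.weight_prob
        else c
        for c in child.connections
    ]
    for nid in list(child.nodes):
        if nid in INPUT_IDS:
            continue
        if rates.bias_prob > 0 and rng.random() < rates.bias_prob:
            node = child.nodes[nid]
            child.nodes[nid] = replace(
                node, bias=node.bias + float(rng.normal(0, rates.bias_sd))
            )

    if rates.add_connection_prob > 0 and rng.random() < rates.add_connection_prob:
        existing = {(c.src, c.dst) for c in child.connections}
        sources = [n for n in sorted(child.nodes) if n not in OUTPUT_IDS]
        dests = [n for n in sorted(child.nodes) if n not in INPUT_IDS]
        candidates = [
            (s, d)
            for s in sources
            for d in dests
            if s != d and (s, d) not in existing and not _creates_cycle(child, s, d)
        ]
        if candidates:
            s, d = candidates[int(rng.integers(len(candidates)))]
            child.connections.append(
                ConnectionGene(s, d, float(rng.normal(0, 1.0)))
            )

    if rates.add_node_prob > 0 and rng.random() < rates.add_node_prob:
        enabled = [i for i, c in enumerate(child.connections) if c.enabled]
        if enabled:
            ci = enabled[int(rng.integers(len(enabled)))]
            conn = child.connections[ci]
            new_id = hidden_id_for_split(conn.src, conn.dst)
            if new_id not in child.nodes:
                act = rates.hidden_activations[
                    int(rng.integers(len(rates.hidden_activations)))
                ]
                child.nodes[new_id] = NodeGene(new_id, act)
                child.connections[ci] = replace(conn, enabled=False)
                child.connections.append(ConnectionGene(conn.src, new_id, 1.0))
                child.connections.append(
                    ConnectionGene(new_id, conn.dst, conn.weight)
                )

    child.validate()
    return child


def crossover_body(
    g1: CppnGenome,
    g2: CppnGenome,
    rng: np.random.Generator,
    fitness1: float = 0.0,
    fitness2: float = 0.0,
    rate: float = 0.8,
) -> CppnGenome:
    """NEAT crossover aligned on innovation ids.

    With probability ``1 - rate`` the child is a clone of the fitter parent
    (ties favour ``g1``; callers pass the lower-id parent first). Matching
    genes are drawn from either parent at random; disjoint and excess genes
    come from the fitter parent, so the child's connection structure is a
    subset of the fitter parent's and stays feed-forward.
    """
    fitter, other = (g1, g2) if fitness1 >= fitness2 else (g2, g1)
    if rng.random() >= rate:
        return fitter.copy()

    by_inn_other = {c.innovation: c for c in other.connections}
    conns: list[ConnectionGene] = []
    for c in fitter.connections:
        match = by_inn_other.get(c.innovation)
        if match is not None and rng.random() < 0.5:
            conns.append(match)
        else:
            conns.append(c)
    nodes: dict[int, NodeGene] = {}
    needed = set(INPUT_IDS) | set(OUTPUT_IDS)
    for c in conns:
        needed.add(c.src)
        needed.add(c.dst)
    for nid in needed:
        nodes[nid] = fitter.nodes.get(nid) or other.nodes[nid]
    child = CppnGenome(nodes, conns)
    child.validate()
    return child
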