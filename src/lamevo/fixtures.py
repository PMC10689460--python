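"""Deterministic hand-built CPPN fixtures.

Three genomes with known decoded bodies, used in tests and available from
the CLI for debugging:

* F1 — every query answers "empty": decodes to a core-only body;
* F2 — "+"-shape: four active hinges around the core at (+-1, 0, 0) and
  (0, +-1, 0), nothing above/below, nothing further out;
* F3 — a straight chain of ten active hinges growing from the core's front.

All decisions are made through the ordinary CPPN query path (linear outputs,
gaussian hidden gates on coordinates), not by special-casing the decoder.
"""

from __future__ import annotations

from .body import ConnectionGene, CppnGenome, NodeGene, INPUT_IDS

# input ids: 0 = x, 1 = y, 2 = z, 3 = tree distance d
# output ids: 4 = brick, 5 = joint, 6 = empty, 7 = rot 0, 8 = rot 90
_X, _Y, _Z, _D = 0, 1, 2, 3
_BRICK, _JOINT, _EMPTY, _ROT0, _ROT90 = 4, 5, 6, 7, 8


def _base_nodes(biases: dict[int, float]) -> dict[int, NodeGene]:
    nodes = {i: NodeGene(i, "linear") for i in INPUT_IDS}
    for o in (_BRICK, _JOINT, _EMPTY, _ROT0, _ROT90):
        nodes[o] = NodeGene(o, "linear", biases.get(o, 0.0))
    return nodes


def cppn_core_only() -> CppnGenome:
    """F1: the empty output carries a large bias, so nothing ever grows."""
    g = CppnGenome(_base_nodes({_EMPTY: 1.0}), [])
    g.validate()
    return g


def cppn_plus() -> CppnGenome:
    """F2: joint at the four in-plane distance-1 slots, empty elsewhere.

    empty score = 4*d - 6*exp(-(5z)^2) + 5, joint score = 5: at d = 1 and
    z = 0 the joint wins (3 < 5); one step further out, or off the plane,
    the empty output wins.
    """
    nodes = _base_nodes({_JOINT: 5.0, _EMPTY: 5.0, _ROT0: 1.0})
    gate = 100  # gaussian gate on z
    nodes[gate] = NodeGene(gate, "gaussian")
    conns = [
        ConnectionGene(_Z, gate, 5.0),
        ConnectionGene(_D, _EMPTY, 4.0),
        ConnectionGene(gate, _EMPTY, -6.0),
    ]
    g = CppnGenome(nodes, conns)
    g.validate()
    return g


def cppn_chain10() -> CppnGenome:
    """F3: joint only on the positive y axis, giving a 10-hinge chain.

    empty score = -5*y - 8*exp(-(5x)^2) - 8*exp(-(5z)^2) + 18.5, joint
    score = 1, brick score = 0: the joint wins only for x = z = 0, y >= 1.
    """
    nodes = _base_nodes({_JOINT: 1.0, _EMPTY: 18.5, _ROT0: 1.0})
    gate_x, gate_z = 101, 102
    nodes[gate_x] = NodeGene(gate_x, "gaussian")
    nodes[gate_z] = NodeGene(gate_z, "gaussian")
    conns = [
        ConnectionGene(_X, gate_x, 5.0),
        ConnectionGene(_Z, gate_z, 5.0),
        ConnectionGene(_Y, _EMPTY, -5.0),
        ConnectionGene(gate_x, _EMPTY, -8.0),
        ConnectionGene(gate_z, _EMPTY, -8.0),
    ]
    g = CppnGenome(nodes, conns)
    g.validate()
    return g


FIXTURES = {
    "F1_core_only": cppn_core_only,
    "F2_plus": cppn_plus,
    "F3_chain10": cppn_chain10,
}


def write_fixtures(directory) -> list[str]:
    """Write each fixture genome as JSON; returns the file paths."""
    import pathlib

    out = []
    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name, builder in FIXTURES.items():
        path = d / f"{name}.json"
        path.write_text(builder().to_json())
        out.append(str(path))
    return out
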