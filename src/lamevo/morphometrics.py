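"""Morphological analysis: tree-edit distance, traits, diversity, learning delta.

Bodies are compared as rooted, ordered, labelled trees (labels are module
kind plus rotation, children in canonical socket order) with the classic
ordered tree-edit distance under unit costs — the minimum number of node
insertions, deletions and relabelings turning one tree into the other. The
implementation is the Zhang-Shasha dynamic program, which computes the same
ordered-tree distance APTED does.

Morphological diversity of a population is the mean pairwise distance;
parent-child similarity is the distance between a child and its fittest
parent. The learning delta — task performance after lifetime learning minus
performance at birth — quantifies how well a body supports learning
("morphological intelligence"); the random-body control experiment uses
:func:`random_body` to decouple it from heredity.

The eight normalized trait descriptors (branching, limbs, limb length,
coverage, joints, proportion, symmetry, size) are this package's documented
reconstructions of the standard modular-robot descriptors; each lies in
[0, 1] and is invariant under mirroring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body import HINGE, MAX_MODULES, RobotBody, decode_body, random_cppn


# --------------------------------------------------------------------------
# canonical morphology trees and tree-edit distance
# --------------------------------------------------------------------------

#: a MorphTree is a nested tuple (label, (child, child, ...))
MorphTree = tuple


def morph_tree(body: RobotBody, include_rotation: bool = True) -> MorphTree:
    """Canonical ordered labelled tree of a body.

    Children are ordered by the socket they occupy on their parent, so two
    structurally identical bodies always map to the same tree.
    """

    def build(i: int) -> MorphTree:
        m = body.modules[i]
        label = (m.kind, m.rotation) if include_rotation else (m.kind,)
        kids = sorted(m.children, key=lambda c: body.modules[c].socket)
        return (label, tuple(build(c) for c in kids))

    return build(0)


def _postorder(tree: MorphTree, nodes: list, lmost: list) -> int:
    """Fill postorder label list and leftmost-leaf indices; return root index."""
    label, children = tree
    first_leaf = None
    for child in children:
        idx = _postorder(child, nodes, lmost)
        if first_leaf is None:
            first_leaf = lmost[idx]
    nodes.append(label)
    my_idx = len(nodes) - 1
    lmost.append(first_leaf if first_leaf is not None else my_idx)
    return my_idx


def tree_edit_distance(a: MorphTree, b: MorphTree) -> int:
    """Ordered tree-edit distance with unit insert/delete/relabel costs
    (Zhang-Shasha dynamic program)."""
    la: list = []
    lla: list = []
    _postorder(a, la, lla)
    lb: list = []
    llb: list = []
    _postorder(b, lb, llb)
    na, nb = len(la), len(lb)

    kr_a = _keyroots(lla)
    kr_b = _keyroots(llb)
    dist = np.zeros((na, nb), dtype=int)

    for i in kr_a:
        for j in kr_b:
            _treedist(i, j, la, lb, lla, llb, dist)
    return int(dist[na - 1, nb - 1])


def _keyroots(lmost: list) -> list:
    seen: dict[int, int] = {}
    for i, l in enumerate(lmost):
        seen[l] = i  # last (highest) node with this leftmost leaf
    return sorted(seen.values())


def _treedist(i, j, la, lb, lla, llb, dist) -> None:
    li, lj = lla[i], llb[j]
    m, n = i - li + 2, j - lj + 2
    fd = np.zeros((m, n), dtype=int)
    fd[:, 0] = np.arange(m)
    fd[0, :] = np.arange(n)
    for x in range(1, m):
        ai = li + x - 1
        for y in range(1, n):
            bj = lj + y - 1
            if lla[ai] == li and llb[bj] == lj:
                cost = 0 if la[ai] == lb[bj] else 1
                fd[x, y] = min(
                    fd[x - 1, y] + 1,
                    fd[x, y - 1] + 1,
                    fd[x - 1, y - 1] + cost,
                )
                dist[ai, bj] = fd[x, y]
            else:
                fd[x, y] = min(
                    fd[x - 1, y] + 1,
                    fd[x, y - 1] + 1,
                    fd[lla[ai] - li, llb[bj] - lj] + dist[ai, bj],
                )


# --------------------------------------------------------------------------
# population-level measures
# --------------------------------------------------------------------------

def diversity(bodies: list[RobotBody], include_rotation: bool = True) -> float:
    """Mean tree-edit distance over all unordered pairs of bodies."""
    if len(bodies) < 2:
        raise ValueError("diversity needs at least two bodies")
    trees = [morph_tree(b, include_rotation) for b in bodies]
    total, count = 0, 0
    for i in range(len(trees)):
        for j in range(i + 1, len(trees)):
            total += tree_edit_distance(trees[i], trees[j])
            count += 1
    return total / count


def parent_child_distance(
    child: RobotBody, parent: RobotBody, include_rotation: bool = True
) -> int:
    """Tree-edit distance between a child's body and its fittest parent's."""
    return tree_edit_distance(
        morph_tree(child, include_rotation), morph_tree(parent, include_rotation)
    )


def learning_delta(individual) -> float:
    """Task performance after learning minus performance at birth."""
    if individual.fitness_before is None or individual.fitness_after is None:
        raise ValueError("individual lacks recorded pre/post-learning fitness")
    return individual.fitness_after - individual.fitness_before


def random_body(rng: np.random.Generator) -> RobotBody:
    """Decode a fresh random CPPN; used by the random-body control
    experiment, which replaces a newborn's inherited body while keeping its
    inherited brain genome (unused rows are tolerated by construction)."""
    seed = int(rng.integers(0, 2**31 - 1))
    return decode_body(random_cppn(seed))


# --------------------------------------------------------------------------
# trait descriptors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitVector:
    branching: float
    limbs: float
    limb_length: float
    coverage: float
    joints: float
    proportion: float
    symmetry: float
    size: float

    NAMES = (
        "branching",
        "limbs",
        "limb_length",
        "coverage",
        "joints",
        "proportion",
        "symmetry",
        "size",
    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.NAMES])

    def as_dict(self) -> dict:
        return {n: getattr(self, n) for n in self.NAMES}


def traits(body: RobotBody) -> TraitVector:
    """Eight normalized morphological descriptors in [0, 1]."""
    non_core = body.modules[1:]
    m = len(non_core)

    size = m / MAX_MODULES
    joints = sum(mm.kind == HINGE for mm in non_core) / m if m else 0.0
    leaves = [i for i in range(1, len(body.modules)) if not body.modules[i].children]
    limbs = len(leaves) / m if m else 0.0

    if m:
        depth = max(mm.depth for mm in non_core)
        limb_length = depth / m
    else:
        limb_length = 0.0

    branch_nodes = sum(len(mm.children) >= 3 for mm in body.modules)
    branching = min(1.0, branch_nodes / m) if m else 0.0

    pos = np.array([mm.position for mm in body.modules])
    span = pos.max(axis=0) - pos.min(axis=0) + 1
    coverage = len(body.modules) / float(np.prod(span))

    w2, h2 = sorted((int(span[0]), int(span[1])))
    proportion = w2 / h2

    cells = {(mm.position[0], mm.position[1], mm.kind) for mm in body.modules}

    def matched(mirror) -> float:
        return sum(1 for c in cells if mirror(c) in cells) / len(cells)

    symmetry = max(
        matched(lambda c: (-c[0], c[1], c[2])),   # mirror across the y axis
        matched(lambda c: (c[0], -c[1], c[2])),   # mirror across the x axis
    )

    return TraitVector(
        branching=branching,
        limbs=limbs,
        limb_length=limb_length,
        coverage=coverage,
        joints=joints,
        proportion=proportion,
        symmetry=symmetry,
        size=size,
    )
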