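"""Morphometrics: tree-edit distance vs. an independent oracle, traits,
diversity, learning delta, random bodies."""

import functools

import numpy as np
import pytest

from lamevo.body import decode_body, random_cppn
from lamevo.fixtures import cppn_plus
from lamevo.morphometrics import (
    diversity,
    learning_delta,
    morph_tree,
    parent_child_distance,
    random_body,
    traits,
    tree_edit_distance,
)


# --------------------------------------------------------------------------
# independent oracle: recursive forest edit distance with memoization
# --------------------------------------------------------------------------

@functools.lru_cache(maxsize=None)
def forest_distance(f1: tuple, f2: tuple) -> int:
    """Exhaustive ordered forest edit distance, unit costs.

    A forest is a tuple of (label, children) trees. Completely independent
    formulation from the keyroot dynamic program under test.
    """
    if not f1 and not f2:
        return 0
    if not f1:
        return sum(_tree_size(t) for t in f2)
    if not f2:
        return sum(_tree_size(t) for t in f1)
    l1, c1 = f1[-1]
    l2, c2 = f2[-1]
    delete = forest_distance(f1[:-1] + c1, f2) + 1
    insert = forest_distance(f1, f2[:-1] + c2) + 1
    match = (
        forest_distance(f1[:-1], f2[:-1])
        + forest_distance(c1, c2)
        + (0 if l1 == l2 else 1)
    )
    return min(delete, insert, match)


def _tree_size(t: tuple) -> int:
    return 1 + sum(_tree_size(c) for c in t[1])


def random_tree(rng, max_nodes: int, labels=("a", "b", "c")) -> tuple:
    """Random ordered labelled tree with at most ``max_nodes`` nodes."""
    budget = int(rng.integers(1, max_nodes + 1))

    def grow(remaining: list[int]) -> tuple:
        remaining[0] -= 1
        label = labels[int(rng.integers(len(labels)))]
        kids = []
        while remaining[0] > 0 and rng.random() < 0.5:
            kids.append(grow(remaining))
        return (label, tuple(kids))

    return grow([budget])


class TestTreeEditDistance:
    def test_identical_trees_distance_zero(self, plus_body):
        t = morph_tree(plus_body)
        assert tree_edit_distance(t, t) == 0

    def test_single_insertion_costs_one(self):
        a = ("a", ())
        b = ("a", (("b", ()),))
        assert tree_edit_distance(a, b) == 1

    def test_relabel_costs_one(self):
        assert tree_edit_distance(("a", ()), ("b", ())) == 1

    def test_matches_exhaustive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a = random_tree(rng, 7)
            b = random_tree(rng, 7)
            assert tree_edit_distance(a, b) == forest_distance((a,), (b,))

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(8)
        for _ in range(60):
            a, b, c = (random_tree(rng, 6) for _ in range(3))
            dab = tree_edit_distance(a, b)
            assert dab == tree_edit_distance(b, a)          # symmetry
            assert (dab == 0) == (a == b)                   # identity
            assert dab <= tree_edit_distance(a, c) + \
                tree_edit_distance(c, b)                    # triangle

    def test_same_body_same_canonical_tree(self):
        g = cppn_plus()
        assert morph_tree(decode_body(g)) == morph_tree(decode_body(g))


class TestDiversity:
    def test_clone_population_has_zero_diversity(self, plus_body):
        assert diversity([plus_body] * 4) == 0.0

    def test_two_bodies_diversity_equals_their_distance(
        self, plus_body, chain_body
    ):
        d = tree_edit_distance(morph_tree(plus_body), morph_tree(chain_body))
        assert diversity([plus_body, chain_body]) == d

    def test_invariant_under_permutation(self, plus_body, chain_body,
                                         core_only_body):
        pops = [
            [plus_body, chain_body, core_only_body],
            [core_only_body, plus_body, chain_body],
        ]
        assert diversity(pops[0]) == diversity(pops[1])

    def test_singleton_population_rejected(self, plus_body):
        with pytest.raises(ValueError):
            diversity([plus_body])

    def test_duplicating_an_individual_never_increases_diversity(
        self, plus_body, chain_body
    ):
        base = [plus_body, chain_body]
        assert diversity(base + [plus_body]) <= diversity(base)


class TestParentChild:
    def test_clone_child_distance_zero(self, plus_body):
        assert parent_child_distance(plus_body, plus_body) == 0

    def test_single_module_difference_costs_one(self, plus_body):
        import copy

        smaller = copy.deepcopy(plus_body)
        # drop the last hinge: one deletion
        smaller.modules[0].children.remove(4)
        smaller.modules = smaller.modules[:4]
        assert parent_child_distance(smaller, plus_body) == 1

    def test_symmetric(self, plus_body, chain_body):
        assert parent_child_distance(plus_body, chain_body) == \
            parent_child_distance(chain_body, plus_body)


class TestLearningDelta:
    class Stub:
        def __init__(self, before, after):
            self.fitness_before = before
            self.fitness_after = after

    def test_difference_and_sign(self):
        assert learning_delta(self.Stub(0.3, 0.8)) == pytest.approx(0.5)
        assert learning_delta(self.Stub(0.5, 0.5)) == 0.0
        assert learning_delta(self.Stub(0.8, 0.3)) == pytest.approx(-0.5)

    def test_missing_pre_learning_fitness_rejected(self):
        with pytest.raises(ValueError):
            learning_delta(self.Stub(None, 0.4))


class TestTraits:
    def test_core_only_body_degenerate_values(self, core_only_body):
        t = traits(core_only_body)
        assert t.size == 0.0
        assert t.limbs == 0.0
        assert t.joints == 0.0
        assert t.symmetry == 1.0

    def test_plus_body_is_fully_symmetric_with_four_limbs(self, plus_body):
        t = traits(plus_body)
        assert t.symmetry == 1.0
        assert t.limbs == 1.0     # all four hinges are leaves
        assert t.joints == 1.0
        assert t.size == pytest.approx(0.4)

    def test_all_traits_bounded_in_unit_interval(self):
        for seed in range(40):
            vec = traits(decode_body(random_cppn(seed))).as_array()
            assert np.all(vec >= 0.0) and np.all(vec <= 1.0)

    def test_mirrored_body_has_identical_traits(self):
        import copy

        # pick decoded bodies that actually extend off the mirror axis
        bodies = [decode_body(random_cppn(s)) for s in range(30)]
        bodies = [
            b for b in bodies if any(m.position[0] != 0 for m in b.modules)
        ]
        assert bodies
        for body in bodies[:5]:
            mirrored = copy.deepcopy(body)
            for m in mirrored.modules:
                x, y, z = m.position
                m.position = (-x, y, z)
            assert np.array_equal(
                traits(mirrored).as_array(), traits(body).as_array()
            )


class TestRandomBody:
    def test_always_valid_and_seed_deterministic(self):
        a = random_body(np.random.default_rng(4))
        b = random_body(np.random.default_rng(4))
        a.validate()
        assert a.to_json() == b.to_json()

    def test_covers_multiple_topologies(self):
        rng = np.random.default_rng(5)
        trees = {morph_tree(random_body(rng)) for _ in range(100)}
        assert len(trees) > 1
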