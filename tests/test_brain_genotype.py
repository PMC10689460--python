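"""Grid-indexed brain genotype: addressing, reversibility, variation."""

import numpy as np
import pytest

from lamevo.body import decode_body, random_cppn
from lamevo.brain_genotype import (
    N_ROWS,
    N_SLOTS,
    NEIGHBOUR_OFFSETS,
    SLOT_INTERNAL,
    SLOT_SAME_COORD,
    BrainGenome,
    ConsistencyError,
    GridError,
    develop_brain,
    encode_brain,
    extract_weights,
    gaussian_mutate_brain,
    grid_coords,
    grid_row,
    inject_weights,
    joint_layout,
    slot_for_offset,
    uniform_crossover_brain,
)

from conftest import make_stacked_joints_body


class TestGridRow:
    def test_corner_cells(self):
        assert grid_row(-10, -10) == 0
        assert grid_row(10, 10) == 439

    def test_bijection_over_all_440_cells(self):
        rows = set()
        for y in range(-10, 11):
            for x in range(-10, 11):
                if (x, y) == (0, 0):
                    continue
                r = grid_row(x, y)
                assert 0 <= r < N_ROWS
                assert grid_coords(r) == (x, y)
                rows.add(r)
        assert rows == set(range(N_ROWS))

    @pytest.mark.parametrize("bad", [(0, 0), (11, 0), (0, -11)])
    def test_centre_and_out_of_range_rejected(self, bad):
        with pytest.raises(GridError):
            grid_row(*bad)


class TestSlotForOffset:
    def test_twelve_distinct_neighbour_slots(self):
        slots = {slot_for_offset(dx, dy) for dx, dy in NEIGHBOUR_OFFSETS}
        assert slots == set(range(12))
        assert len(NEIGHBOUR_OFFSETS) == 12

    def test_same_coordinate_slot(self):
        assert slot_for_offset(0, 0, same_coord=True) == SLOT_SAME_COORD

    @pytest.mark.parametrize("bad", [(0, 0), (0, 3), (2, 1), (-3, 0)])
    def test_out_of_neighbourhood_rejected(self, bad):
        with pytest.raises(GridError):
            slot_for_offset(*bad)


class TestDevelopEncode:
    def test_zero_genome_gives_zero_weights(self, plus_body):
        net = develop_brain(BrainGenome.zeros(), plus_body)
        assert np.all(net.internal_weights == 0)
        assert np.all(net.coupling == 0)

    def test_core_only_body_gives_empty_network(self, core_only_body, rng):
        net = develop_brain(BrainGenome.random(rng), core_only_body)
        assert net.n == 0

    def test_joint_reads_from_its_own_grid_row(self, plus_body, rng):
        genome = BrainGenome.random(rng)
        net = develop_brain(genome, plus_body)
        k = net.joints.index(4)  # the hinge at (1, 0)
        assert net.internal_weights[k] == genome.weights[
            grid_row(1, 0), SLOT_INTERNAL
        ]

    def test_coupling_read_from_lower_decode_order_row_antisymmetric(
        self, plus_body, rng
    ):
        genome = BrainGenome.random(rng)
        net = develop_brain(genome, plus_body)
        layout = joint_layout(plus_body)
        for (a, b), (row, col) in layout.pair_entry.items():
            assert net.coupling[a, b] == genome.weights[row, col]
            assert net.coupling[b, a] == -net.coupling[a, b]
            # the row belongs to the lower-decode-order joint of the pair
            assert row == grid_row(*layout.positions_2d[a])

    def test_round_trips_are_bit_exact(self, rng):
        for seed in range(100):
            body = decode_body(random_cppn(seed))
            genome = BrainGenome.random(rng)
            net = develop_brain(genome, body)
            # encode(develop(g)) returns g exactly
            assert np.array_equal(
                encode_brain(net, body, genome).weights, genome.weights
            )
            # develop(encode(n)) returns n exactly
            net2 = develop_brain(encode_brain(net, body, genome), body)
            assert np.array_equal(net2.internal_weights, net.internal_weights)
            assert np.array_equal(net2.coupling, net.coupling)

    def test_overwrite_touches_exactly_the_used_entries(self, plus_body, rng):
        genome = BrainGenome.zeros()
        net = develop_brain(BrainGenome.random(rng), plus_body)
        written = encode_brain(net, plus_body, genome)
        changed = np.argwhere(written.weights != genome.weights)
        layout = joint_layout(plus_body)
        # 4 internal entries + 6 neighbour-pair entries on the "+" body
        assert len(layout.used_entries) == 4 + 6
        assert {tuple(c) for c in changed} <= set(layout.used_entries)

    def test_stacked_joints_use_the_same_coordinate_slot(self, rng):
        body = make_stacked_joints_body()
        layout = joint_layout(body)
        (entry,) = [layout.pair_entry[p] for p in layout.pairs
                    if layout.positions_2d[p[0]] == layout.positions_2d[p[1]]]
        assert entry == (grid_row(1, 0), SLOT_SAME_COORD)

    def test_topology_mismatch_raises(self, plus_body, chain_body, rng):
        genome = BrainGenome.random(rng)
        net = develop_brain(genome, plus_body)
        with pytest.raises(ConsistencyError):
            encode_brain(net, chain_body, genome)

    def test_inject_is_inverse_of_extract(self, plus_body, rng):
        genome = BrainGenome.random(rng)
        vec = extract_weights(genome, plus_body)
        assert np.array_equal(
            extract_weights(inject_weights(genome, plus_body, vec + 1.0),
                            plus_body),
            vec + 1.0,
        )

    def test_neighbour_offsets_always_representable(self):
        # tree distance <= 2 implies the 2D offset is Manhattan <= 2 or equal
        for seed in range(50):
            body = decode_body(random_cppn(seed))
            joint_layout(body)  # raises GridError if unrepresentable


class TestVariation:
    def test_self_crossover_is_identity(self, rng):
        g = BrainGenome.random(rng)
        assert np.array_equal(
            uniform_crossover_brain(g, g, rng).weights, g.weights
        )

    def test_crossover_mixes_about_half_from_each_parent(self, rng):
        g1 = BrainGenome(np.zeros((N_ROWS, N_SLOTS)))
        g2 = BrainGenome(np.ones((N_ROWS, N_SLOTS)))
        child = uniform_crossover_brain(g1, g2, rng)
        frac = child.weights.mean()  # fraction taken from g2
        n = N_ROWS * N_SLOTS
        assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_crossover_deterministic_under_fixed_seed(self):
        g1 = BrainGenome.random(np.random.default_rng(0))
        g2 = BrainGenome.random(np.random.default_rng(1))
        a = uniform_crossover_brain(g1, g2, np.random.default_rng(7))
        b = uniform_crossover_brain(g1, g2, np.random.default_rng(7))
        assert np.array_equal(a.weights, b.weights)

    def test_zero_probability_mutation_is_identity(self, rng):
        g = BrainGenome.random(rng)
        assert np.array_equal(
            gaussian_mutate_brain(g, rng, prob=0.0).weights, g.weights
        )

    def test_mutation_moments_and_rate(self):
        rng = np.random.default_rng(3)
        g = BrainGenome.zeros()
        deltas = []
        changed = 0
        total = 0
        for _ in range(20):
            m = gaussian_mutate_brain(g, rng, prob=0.8, sd=0.5)
            d = m.weights.ravel()
            deltas.append(d[d != 0])
            changed += int((d != 0).sum())
            total += d.size
        deltas = np.concatenate(deltas)
        rate = changed / total
        assert abs(rate - 0.8) < 4 * np.sqrt(0.8 * 0.2 / total)
        assert abs(deltas.mean()) < 4 * 0.5 / np.sqrt(len(deltas))
        assert abs(deltas.std() - 0.5) < 0.01

    def test_shapes_preserved_and_finite(self, rng):
        g = BrainGenome.random(rng)
        for op in (
            lambda: uniform_crossover_brain(g, BrainGenome.zeros(), rng),
            lambda: gaussian_mutate_brain(g, rng),
        ):
            out = op()
            assert out.weights.shape == (N_ROWS, N_SLOTS)
            assert np.all(np.isfinite(out.weights))

    def test_csv_round_trip_bit_exact(self, rng):
        g = BrainGenome.random(rng)
        assert np.array_equal(BrainGenome.from_csv(g.to_csv()).weights, g.weights)
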