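import random

import pytest

from consortia_logic import (CircuitDesign, DistributionRules, Gate, GateKind,
                             distribute, enumerate_functions, named,
                             plan_cost, reevaluate_plan, synthesize_simplest)
from consortia_logic.distribution import greedy_cost
from consortia_logic.errors import WrongBasisError


class TestXorDecomposition:
    def test_two_cells_one_repressive_wire_not_absorbed(self, fig2a_design):
        plan = distribute(fig2a_design, mode="exact")
        assert plan.n_cells == 2
        assert plan.n_wires == 1
        assert plan.absorbed_nots == frozenset({"not_w"})
        (wire,) = plan.wires
        assert wire.repressive
        assert wire.signal == "and_in"
        # upstream cell carries the AND alone; downstream the OR + output AND
        cells = {cid: set(gids) for cid, gids in plan.cells}
        assert {"and_in"} in cells.values()
        assert {"or_in", "and_out"} in cells.values()

    def test_parallel_rule_forces_the_split(self, fig2a_design):
        # with the shared-input rule relaxed the whole design fits one cell
        relaxed = DistributionRules(forbid_parallel=False,
                                    max_units_per_cell=4, max_depth=3)
        plan = distribute(fig2a_design, rules=relaxed)
        assert plan.n_cells == 1


class TestSmallPlans:
    def test_single_and_gate(self):
        d = CircuitDesign(("a", "b"), (Gate("g1", GateKind.AND, ("a", "b")),),
                          "g1")
        plan = distribute(d)
        assert (plan.n_cells, plan.n_wires) == (1, 0)

    def test_four_not_chain_splits_once(self):
        gates = [Gate("g1", GateKind.NOT, ("a",))]
        for i in range(2, 5):
            gates.append(Gate(f"g{i}", GateKind.NOT, (f"g{i-1}",)))
        d = CircuitDesign(("a",), tuple(gates), "g4")
        plan = distribute(d, mode="exact")
        assert (plan.n_cells, plan.n_wires) == (2, 1)

    def test_equals2_costs_like_xor(self):
        assert plan_cost(synthesize_simplest(named("EQUALS2"))) == (2, 1)
        assert plan_cost(synthesize_simplest(named("XOR2"))) == (2, 1)

    def test_non_basic_design_rejected(self):
        d = CircuitDesign(("a", "b"), (Gate("g1", GateKind.NOR, ("a", "b")),),
                          "g1")
        with pytest.raises(WrongBasisError):
            distribute(d)


class TestPlanInvariants:
    def test_every_gate_in_exactly_one_cell_or_absorbed(self, fixture_pairs):
        for _, design in fixture_pairs[:15]:
            plan = distribute(design, mode="exact")
            placed = [gid for _, gids in plan.cells for gid in gids]
            assert len(placed) == len(set(placed))
            assert set(placed) | set(plan.absorbed_nots) == \
                {g.id for g in design.gates}
            assert not set(placed) & set(plan.absorbed_nots)

    def test_merging_cells_reproduces_the_function(self, fixture_pairs):
        for table, design in fixture_pairs:
            for mode in ("exact", "greedy"):
                plan = distribute(design, mode=mode)
                assert reevaluate_plan(design, plan).bits == table.bits

    def test_zero_wires_iff_single_cell(self, fixture_pairs):
        for _, design in fixture_pairs:
            plan = distribute(design, mode="exact")
            assert (plan.n_wires == 0) == (plan.n_cells == 1)

    def test_environmental_inputs_are_never_wires(self, fixture_pairs):
        for _, design in fixture_pairs:
            plan = distribute(design, mode="exact")
            gate_ids = {g.id for g in design.gates}
            for w in plan.wires:
                assert w.signal in gate_ids

    def test_depth_and_capacity_respected(self, fixture_pairs):
        rules = DistributionRules()
        for _, design in fixture_pairs:
            plan = distribute(design, mode="exact", rules=rules)
            for _, gids in plan.cells:
                assert len(gids) <= rules.max_units_per_cell
            assert design.depth(count_absorbed=False,
                                absorbed=plan.absorbed_nots) <= \
                rules.max_depth * plan.n_cells

    def test_absorbed_nots_really_sit_on_wires(self, fixture_pairs):
        for _, design in fixture_pairs:
            plan = distribute(design, mode="exact")
            by_id = design.gate_map()
            cell_of = {gid: cid for cid, gids in plan.cells for gid in gids}
            for nid in plan.absorbed_nots:
                gate = by_id[nid]
                assert gate.kind is GateKind.NOT
                src = gate.srcs[0]
                assert src in cell_of  # the producer is a gate, not an input
                for consumer, g in by_id.items():
                    if nid in g.srcs:
                        assert cell_of[consumer] != cell_of[src]


class TestGreedyVsExact:
    def test_greedy_never_beats_exact_on_two_input_designs(self):
        for tt in enumerate_functions(2):
            for d in synthesize_simplest(tt).designs:
                assert greedy_cost(d) >= plan_cost(d)

    def test_greedy_never_beats_exact_on_sampled_three_input_designs(self):
        rng = random.Random(5)
        for tt in rng.sample(enumerate_functions(3), 30):
            d = rng.choice(synthesize_simplest(tt).designs)
            assert greedy_cost(d) >= plan_cost(d)

    def test_greedy_matches_exact_on_minimal_two_input_designs(self):
        for tt in enumerate_functions(2):
            res = synthesize_simplest(tt)
            assert min(greedy_cost(d) for d in res.designs) == plan_cost(res)
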