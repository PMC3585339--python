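import itertools
import random

import pytest

from consortia_logic import CircuitDesign, Gate, GateKind, named
from consortia_logic.errors import (DanglingReferenceError,
                                    InvalidCircuitError, WrongBasisError)


def recursive_eval(design, sig, assignment):
    """Independent evaluator: direct recursion over the reference graph."""
    if sig in design.inputs:
        return assignment[design.inputs.index(sig)]
    g = design.gate_map()[sig]
    vals = [recursive_eval(design, s, assignment) for s in g.srcs]
    if g.kind is GateKind.NOT:
        return 1 - vals[0]
    if g.kind is GateKind.AND:
        return vals[0] & vals[1]
    if g.kind is GateKind.OR:
        return vals[0] | vals[1]
    if g.kind is GateKind.NOR:
        return 1 - (vals[0] | vals[1])
    if g.kind is GateKind.NAND:
        return 1 - (vals[0] & vals[1])
    return g.table.evaluate(tuple(vals) if len(vals) == 2 else (vals[0], vals[0]))


class TestRealize:
    def test_published_xor_decomposition(self, fig2a_design):
        assert fig2a_design.realize().bits == named("XOR2").bits

    def test_projection_output(self):
        d = CircuitDesign(("a", "b"), (), "a")
        assert d.realize().bitstring() == "0011"

    def test_nor_self_is_not(self):
        d = CircuitDesign(("a",), (Gate("g1", GateKind.NOR, ("a", "a")),), "g1")
        assert d.realize().bits == named("NOT1").bits

    def test_modular_gate_applies_attached_table(self):
        g = Gate("m", GateKind.MODULAR, ("a", "b"), named("XOR2"))
        d = CircuitDesign(("a", "b"), (g,), "m")
        assert d.realize().bits == named("XOR2").bits

    def test_realize_invariant_under_gate_list_reordering(self, fig2a_design):
        rng = random.Random(7)
        gates = list(fig2a_design.gates)
        for _ in range(5):
            rng.shuffle(gates)
            d = CircuitDesign(fig2a_design.inputs, tuple(gates),
                              fig2a_design.output)
            assert d.realize().bits == named("XOR2").bits

    def test_realize_matches_recursive_eval_on_fixtures(self, fixture_pairs):
        for table, design in fixture_pairs:
            realized = design.realize()
            assert realized.bits == table.bits
            n = len(design.inputs)
            for a in itertools.product((0, 1), repeat=n):
                assert realized.evaluate(a) == \
                    recursive_eval(design, design.output, a)


class TestValidation:
    def test_cycle_detected(self):
        with pytest.raises(InvalidCircuitError):
            CircuitDesign(("a",), (
                Gate("g1", GateKind.AND, ("a", "g2")),
                Gate("g2", GateKind.NOT, ("g1",)),
            ), "g2")

    def test_dangling_reference(self):
        with pytest.raises(DanglingReferenceError):
            CircuitDesign(("a",), (Gate("g1", GateKind.NOT, ("zzz",)),), "g1")

    def test_dead_gate_rejected_not_silently_fixed(self):
        with pytest.raises(InvalidCircuitError, match="dead"):
            CircuitDesign(("a", "b"), (
                Gate("g1", GateKind.AND, ("a", "b")),
                Gate("g2", GateKind.OR, ("a", "b")),
            ), "g1")

    def test_wrong_fan_in(self):
        with pytest.raises(InvalidCircuitError):
            Gate("g1", GateKind.NOT, ("a", "b"))
        with pytest.raises(InvalidCircuitError):
            Gate("g1", GateKind.AND, ("a",))


class TestScoreAndDepth:
    def test_fig2a_score(self, fig2a_design):
        assert fig2a_design.score().as_tuple() == (4, 2)

    def test_single_gates(self):
        not_d = CircuitDesign(("a",), (Gate("g1", GateKind.NOT, ("a",)),), "g1")
        assert not_d.score().as_tuple() == (1, 0)
        and_d = CircuitDesign(("a", "b"),
                              (Gate("g1", GateKind.AND, ("a", "b")),), "g1")
        assert and_d.score().as_tuple() == (1, 1)
        assert and_d.depth() == 1

    def test_score_rejects_non_basic_gates(self):
        d = CircuitDesign(("a", "b"),
                          (Gate("g1", GateKind.NOR, ("a", "b")),), "g1")
        with pytest.raises(WrongBasisError):
            d.score()

    def test_not_chain_depth(self):
        gates = [Gate("g1", GateKind.NOT, ("a",))]
        for i in range(2, 5):
            gates.append(Gate(f"g{i}", GateKind.NOT, (f"g{i-1}",)))
        d = CircuitDesign(("a",), tuple(gates), "g4")
        assert d.depth() == 4

    def test_or_feeding_and_depth_two(self):
        # the downstream cell's subcircuit: OR into the output AND
        d = CircuitDesign(("a", "b", "w"), (
            Gate("or1", GateKind.OR, ("a", "b")),
            Gate("and1", GateKind.AND, ("or1", "w")),
        ), "and1")
        assert d.depth() == 2

    def test_absorbed_nots_can_be_discounted(self, fig2a_design):
        assert fig2a_design.depth() == 3
        assert fig2a_design.depth(count_absorbed=False,
                                  absorbed={"not_w"}) == 2


class TestSerialization:
    def test_netlist_roundtrip(self, fig2a_design):
        rebuilt = CircuitDesign.from_json(fig2a_design.to_json())
        assert rebuilt == fig2a_design

    def test_sorted_gates_are_topological(self, fig2a_design):
        seen = set(fig2a_design.inputs)
        for g in fig2a_design.sorted_gates():
            assert all(s in seen for s in g.srcs)
            seen.add(g.id)

    def test_dot_export_mentions_every_gate(self, fig2a_design):
        dot = fig2a_design.to_dot()
        for g in fig2a_design.gates:
            assert g.id in dot
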