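"""Gate-level circuit DAGs shared by every synthesis method.

A :class:`CircuitDesign` is a DAG of gates over named environmental inputs
with a single output.  AND/OR/NOR/NAND take two operands, NOT takes one, and
a MODULAR gate applies an attached 2-input truth table (the "arbitrary
operator in one cell" of the modular-cells methodology).  Gate outputs may
fan out; whether a particular design stage allows that is a policy of the
synthesizer, not of this container.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

from . import _bits
from .errors import (DanglingReferenceError, InvalidCircuitError, ParseError,
                     WrongBasisError)
from .truthtables import SCHEMA, TruthTable


class GateKind(str, Enum):
    AND = "AND"
    OR = "OR"
    NOT = "NOT"
    NOR = "NOR"
    NAND = "NAND"
    MODULAR = "MODULAR"

    @property
    def fan_in(self) -> int:
        return 1 if self is GateKind.NOT else 2


BASIC = (GateKind.AND, GateKind.OR, GateKind.NOT)


@dataclass(frozen=True)
class Gate:
    id: str
    kind: GateKind
    srcs: Tuple[str, ...]
    table: Optional[TruthTable] = None  # MODULAR only

    def __post_init__(self):
        object.__setattr__(self, "kind", GateKind(self.kind))
        object.__setattr__(self, "srcs", tuple(self.srcs))
        if self.kind is GateKind.MODULAR:
            if self.table is None or self.table.n_inputs != 2:
                raise InvalidCircuitError(
                    f"MODULAR gate {self.id} needs a 2-input table")
            if not 1 <= len(self.srcs) <= 2:
                raise InvalidCircuitError(
                    f"MODULAR gate {self.id} takes 1 or 2 sources")
        elif len(self.srcs) != self.kind.fan_in:
            raise InvalidCircuitError(
                f"{self.kind.value} gate {self.id} takes {self.kind.fan_in} "
                f"source(s), got {len(self.srcs)}")


@dataclass(frozen=True)
class DesignScore:
    total_units: int
    and_count: int

    def __post_init__(self):
        if not 0 <= self.and_count <= self.total_units:
            raise InvalidCircuitError("and_count must be within 0..total_units")

    def as_tuple(self):
        return (self.total_units, self.and_count)


@dataclass(frozen=True)
class CircuitDesign:
    """A validated combinational design over named inputs."""

    inputs: Tuple[str, ...]
    gates: Tuple[Gate, ...]
    output: str

    def __post_init__(self):
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "gates", tuple(
            g if isinstance(g, Gate) else Gate(**g) for g in self.gates))
        self._validate()

    # -- structure ---------------------------------------------------------
    def _validate(self):
        ids = [g.id for g in self.gates]
        if len(set(ids)) != len(ids):
            raise InvalidCircuitError("duplicate gate ids")
        if set(ids) & set(self.inputs):
            raise InvalidCircuitError("gate ids must not shadow input names")
        known = set(self.inputs) | set(ids)
        for g in self.gates:
            for s in g.srcs:
                if s not in known:
                    raise DanglingReferenceError(
                        f"gate {g.id} references unknown signal {s!r}")
        if self.output not in known:
            raise DanglingReferenceError(f"unknown output {self.output!r}")
        self._topo_order()  # raises on cycles
        # every gate must lie on a path to the output
        live = set()
        stack = [self.output]
        by_id = self.gate_map()
        while stack:
            s = stack.pop()
            if s in live or s in self.inputs:
                continue
            live.add(s)
            stack.extend(by_id[s].srcs)
        dead = set(g.id for g in self.gates) - live
        if dead:
            raise InvalidCircuitError(f"dead gates not feeding the output: "
                                      f"{sorted(dead)}")

    def gate_map(self) -> Dict[str, Gate]:
        return {g.id: g for g in self.gates}

    def _topo_order(self) -> List[str]:
        by_id = self.gate_map()
        order, state = [], {}  # state: 1 visiting, 2 done

        def visit(s, chain):
            if s in self.inputs:
                return
            st = state.get(s)
            if st == 2:
                return
            if st == 1:
                raise InvalidCircuitError(f"cycle through gate {s!r}")
            state[s] = 1
            for src in by_id[s].srcs:
                visit(src, chain)
            state[s] = 2
            order.append(s)

        for g in self.gates:
            visit(g.id, [])
        return order

    def consumers(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {g.id: [] for g in self.gates}
        for g in self.gates:
            for s in g.srcs:
                if s in out:
                    out[s].append(g.id)
        return out

    # -- semantics ---------------------------------------------------------
    def realize(self) -> TruthTable:
        """Truth table of the design, evaluating gates in topological order."""
        n = len(self.inputs)
        masks = dict(zip(self.inputs, _bits.input_masks(n)))
        full = _bits.full_mask(n)
        by_id = self.gate_map()
        for gid in self._topo_order():
            g = by_id[gid]
            vals = [masks[s] for s in g.srcs]
            if g.kind is GateKind.NOT:
                v = ~vals[0] & full
            elif g.kind is GateKind.AND:
                v = vals[0] & vals[1]
            elif g.kind is GateKind.OR:
                v = vals[0] | vals[1]
            elif g.kind is GateKind.NOR:
                v = ~(vals[0] | vals[1]) & full
            elif g.kind is GateKind.NAND:
                v = ~(vals[0] & vals[1]) & full
            else:  # MODULAR
                a = vals[0]
                b = vals[1] if len(vals) > 1 else vals[0]
                v = _bits.apply_op2(g.table.mask, a, b, n)
            masks[gid] = v
        return TruthTable.from_mask(masks[self.output], n)

    def score(self) -> DesignScore:
        bad = [g.id for g in self.gates if g.kind not in BASIC]
        if bad:
            raise WrongBasisError(
                f"design scoring is defined for AND/OR/NOT only; offending "
                f"gates: {bad}")
        return DesignScore(len(self.gates),
                           sum(1 for g in self.gates if g.kind is GateKind.AND))

    def depth(self, count_absorbed: bool = True,
              absorbed: Sequence[str] = ()) -> int:
        """Longest input-to-output path in gates.  Gates listed in `absorbed`
        (NOTs realized on a repressive wire) contribute 0 when
        count_absorbed is False."""
        absorbed = set(absorbed)
        by_id = self.gate_map()
        memo: Dict[str, int] = {}

        def d(s: str) -> int:
            if s in self.inputs:
                return 0
            if s in memo:
                return memo[s]
            g = by_id[s]
            own = 0 if (not count_absorbed and s in absorbed) else 1
            memo[s] = own + max((d(x) for x in g.srcs), default=0)
            return memo[s]

        return d(self.output)

    # -- serialization -----------------------------------------------------
    def sorted_gates(self) -> List[Gate]:
        """Topological, then lexicographic order, for reproducible output."""
        pos = {gid: i for i, gid in enumerate(self._topo_order())}
        return sorted(self.gates, key=lambda g: (pos[g.id], g.id))

    def to_json(self) -> dict:
        gates = []
        for g in self.sorted_gates():
            d = {"id": g.id, "kind": g.kind.value, "src": list(g.srcs)}
            if g.table is not None:
                d["table"] = g.table.to_json()
            gates.append(d)
        return {"schema": SCHEMA, "inputs": list(self.inputs),
                "gates": gates, "output": self.output}

    @classmethod
    def from_json(cls, d: dict) -> "CircuitDesign":
        try:
            inputs = tuple(d["inputs"])
            raw = d["gates"]
            output = d["output"]
        except (KeyError, TypeError) as e:
            raise ParseError(f"bad netlist object: {e}", "/") from e
        gates = []
        for i, gd in enumerate(raw):
            try:
                table = (TruthTable.from_json(gd["table"])
                         if "table" in gd else None)
                gates.append(Gate(gd["id"], GateKind(gd["kind"]),
                                  tuple(gd["src"]), table))
            except (KeyError, ValueError, TypeError) as e:
                raise ParseError(f"bad gate: {e}", f"/gates/{i}") from e
        return cls(inputs, tuple(gates), output)

    def to_dot(self, plan=None) -> str:
        """Graphviz source; when a ConsortiumPlan is given, cells are colored
        and repressive wires dashed."""
        lines = ["digraph design {", "  rankdir=LR;"]
        for x in self.inputs:
            lines.append(f'  "{x}" [shape=plaintext];')
        cell_of = {}
        absorbed = set()
        if plan is not None:
            absorbed = set(plan.absorbed_nots)
            for ci, (cid, gids) in enumerate(plan.cells):
                for gid in gids:
                    cell_of[gid] = ci
        palette = ["lightblue", "lightyellow", "lightpink", "lightgreen",
                   "lavender", "wheat", "azure", "mistyrose"]
        for g in self.sorted_gates():
            style = 'shape=box'
            if g.id in absorbed:
                style += ', style=dashed'
            elif g.id in cell_of:
                style += (f', style=filled, fillcolor='
                          f'"{palette[cell_of[g.id] % len(palette)]}"')
            lines.append(f'  "{g.id}" [label="{g.kind.value}\\n{g.id}", {style}];')
        for g in self.gates:
            for s in g.srcs:
                edge = f'  "{s}" -> "{g.id}"'
                if plan is not None and s in absorbed:
                    edge += " [style=dashed, arrowhead=tee]"
                lines.append(edge + ";")
        lines.append(f'  out [shape=doublecircle, label="out"];')
        lines.append(f'  "{self.output}" -> out;')
        lines.append("}")
        return "\n".join(lines)


def single_gate(kind: GateKind, inputs: Sequence[str],
                table: Optional[TruthTable] = None) -> CircuitDesign:
    g = Gate("g1", kind, tuple(inputs), table)
    return CircuitDesign(tuple(dict.fromkeys(inputs)), (g,), "g1")
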