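"""Distribution of a combinational design into logic-operating cells.

The distributor partitions the gates of an AND/OR/NOT design into cells and
turns every inter-cell edge into a chemical wire (a quorum-sensing molecule).
A NOT gate whose input arrives on a wire can be *absorbed* into the wire
itself: the consumer cell senses the molecule through an engineered
repressive promoter, so the inversion costs no intracellular gate.  The
structural rules enforced per cell are:

* at most ``max_units_per_cell`` gates (default 3) and tandem depth at most
  ``max_depth`` (default 3) — too many stacked stages in one cell make the
  output sensitive to intrinsic noise and expression leakage;
* no two gates in one cell may share an input signal (``forbid_parallel``,
  default on) — parallel promoters compete for the same limited pool of
  regulatory protein.

The objective is lexicographic: fewest cells, then fewest wires.  ``exact``
mode proves optimality by branch and bound over partitions and absorption
choices; ``greedy`` is the fast documented heuristic (never better than
exact — tested).  Environmental inputs fan out to any number of cells for
free; wires from one producer output are merged into a single molecule.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Tuple

from . import _bits
from .circuits import BASIC, CircuitDesign, GateKind
from .errors import ConsortiaLogicError, WrongBasisError
from .synthesis import SynthesisResult


@dataclass(frozen=True)
class DistributionRules:
    max_units_per_cell: int = 3
    max_depth: int = 3
    forbid_parallel: bool = True
    allow_absorption: bool = True
    absorbed_count_as_units: bool = False
    max_cells: int = 10


@dataclass(frozen=True)
class Wire:
    producer_cell: str
    signal: str                 # id of the producing gate
    consumers: Tuple[str, ...]  # consuming cell ids
    repressive: bool


@dataclass(frozen=True)
class ConsortiumPlan:
    cells: Tuple[Tuple[str, FrozenSet[str]], ...]
    wires: Tuple[Wire, ...]
    absorbed_nots: FrozenSet[str]
    cost: Tuple[int, int, int]  # (n_cells, n_wires, n_parallel)

    @property
    def n_cells(self) -> int:
        return self.cost[0]

    @property
    def n_wires(self) -> int:
        return self.cost[1]

    def to_json(self) -> dict:
        return {
            "schema": "consortia-logic/1",
            "cells": [{"id": cid, "gates": sorted(gids)}
                      for cid, gids in self.cells],
            "wires": [{"producer_cell": w.producer_cell, "signal": w.signal,
                       "consumers": list(w.consumers),
                       "repressive": w.repressive} for w in self.wires],
            "absorbed_nots": sorted(self.absorbed_nots),
            "cost": {"n_cells": self.cost[0], "n_wires": self.cost[1],
                     "n_parallel": self.cost[2]},
        }

    @classmethod
    def from_json(cls, d: dict) -> "ConsortiumPlan":
        cells = tuple((c["id"], frozenset(c["gates"])) for c in d["cells"])
        wires = tuple(Wire(w["producer_cell"], w["signal"],
                           tuple(w["consumers"]), bool(w["repressive"]))
                      for w in d["wires"])
        cost = (d["cost"]["n_cells"], d["cost"]["n_wires"],
                d["cost"]["n_parallel"])
        return cls(cells, wires, frozenset(d["absorbed_nots"]), cost)


# ----------------------------------------------------------------------
# internal graph form
# ----------------------------------------------------------------------
class _Graph:
    """Flat gate arrays; sources are ('x', input_index) or ('g', gate_index)."""

    __slots__ = ("n", "ops", "srcs", "root", "consumers", "gate_ids",
                 "input_names")

    def __init__(self, n, ops, srcs, root, gate_ids, input_names):
        self.n = n
        self.ops = ops
        self.srcs = srcs
        self.root = root
        self.gate_ids = gate_ids
        self.input_names = input_names
        cons = [[] for _ in ops]
        for i, ss in enumerate(srcs):
            for s in ss:
                if s[0] == "g":
                    cons[s[1]].append(i)
        self.consumers = cons

    @classmethod
    def from_design(cls, design: CircuitDesign) -> "_Graph":
        bad = [g.id for g in design.gates if g.kind not in BASIC]
        if bad:
            raise WrongBasisError(
                f"distribution is defined over AND/OR/NOT designs; "
                f"offending gates: {bad}")
        if design.output in design.inputs:
            raise ConsortiaLogicError(
                "cannot distribute a bare projection (no gates)")
        order = [g for g in design.sorted_gates()]
        idx = {g.id: i for i, g in enumerate(order)}
        in_idx = {name: i for i, name in enumerate(design.inputs)}
        srcs = []
        for g in order:
            srcs.append(tuple(("x", in_idx[s]) if s in in_idx
                              else ("g", idx[s]) for s in g.srcs))
        return cls(len(design.inputs), tuple(g.kind.value for g in order),
                   tuple(srcs), idx[design.output],
                   tuple(g.id for g in order), tuple(design.inputs))

    @classmethod
    def from_tree(cls, tree, n: int) -> "_Graph":
        ops: List[str] = []
        srcs: List[Tuple] = []

        def rec(node):
            if node[0] == "x":
                return ("x", node[1])
            ss = tuple(rec(c) for c in node[1:])
            ops.append(node[0])
            srcs.append(ss)
            return ("g", len(ops) - 1)

        rec(tree)
        gate_ids = tuple(f"g{i + 1}" for i in range(len(ops)))
        from .synthesis import DEFAULT_INPUT_NAMES
        return cls(n, tuple(ops), tuple(srcs), len(ops) - 1, gate_ids,
                   DEFAULT_INPUT_NAMES[:n])

    def canonical_key(self):
        """Serialization minimized over input permutations (costs are
        invariant under input relabeling; used as cache key)."""
        best = None
        for perm in itertools.permutations(range(self.n)):
            ser = []
            for op, ss in zip(self.ops, self.srcs):
                resolved = tuple(sorted(
                    ("x", perm[s[1]]) if s[0] == "x" else s for s in ss))
                ser.append((op, resolved))
            key = (tuple(ser), self.root)
            if best is None or key < best:
                best = key
        return best


# ----------------------------------------------------------------------
# solution checking / costing shared by exact and greedy
# ----------------------------------------------------------------------
def _valid_absorption(g: _Graph, absorbed: FrozenSet[int]) -> bool:
    for a in absorbed:
        if g.ops[a] != "NOT" or a == g.root:
            return False
        src = g.srcs[a][0]
        if src[0] != "g" or src[1] in absorbed:
            return False
    return True


def _check(g: _Graph, cell_of: Dict[int, int], absorbed: FrozenSet[int],
           rules: DistributionRules) -> bool:
    """Full feasibility check of a candidate plan."""
    if not _valid_absorption(g, absorbed):
        return False
    # absorbed NOT: producer cell differs from every consumer's cell
    for a in absorbed:
        child = g.srcs[a][0][1]
        for w in g.consumers[a]:
            if cell_of[w] == cell_of[child]:
                return False
    # capacity
    counts: Dict[int, int] = {}
    for i, c in cell_of.items():
        counts[c] = counts.get(c, 0) + 1
    if rules.absorbed_count_as_units:
        for a in absorbed:
            consumer = g.consumers[a][0]
            counts[cell_of[consumer]] += 1
    if rules.max_units_per_cell and any(v > rules.max_units_per_cell
                                        for v in counts.values()):
        return False
    # tandem depth within cells (absorbed NOTs contribute nothing)
    if rules.max_depth:
        memo: Dict[int, int] = {}

        def depth(i: int) -> int:
            if i in memo:
                return memo[i]
            c = cell_of[i]
            m = 1
            for s in g.srcs[i]:
                if s[0] == "g" and s[1] not in absorbed and cell_of[s[1]] == c:
                    m = max(m, 1 + depth(s[1]))
            memo[i] = m
            return m

        if any(depth(i) > rules.max_depth for i in cell_of):
            return False
    if rules.forbid_parallel and _count_parallel(g, cell_of, absorbed) > 0:
        return False
    return True


def _sources_signature(g: _Graph, i: int, absorbed: FrozenSet[int]):
    """Signals gate i listens to; an absorbed NOT resolves to its producer's
    molecule (same species, sensed repressively)."""
    out = []
    for s in g.srcs[i]:
        if s[0] == "x":
            out.append(s)
        elif s[1] in absorbed:
            out.append(("g", g.srcs[s[1]][0][1]))
        else:
            out.append(s)
    return out


def _count_parallel(g: _Graph, cell_of: Dict[int, int],
                    absorbed: FrozenSet[int]) -> int:
    cells: Dict[int, List[int]] = {}
    for i, c in cell_of.items():
        cells.setdefault(c, []).append(i)
    count = 0
    for members in cells.values():
        for i, j in itertools.combinations(members, 2):
            if set(_sources_signature(g, i, absorbed)) & \
               set(_sources_signature(g, j, absorbed)):
                count += 1
    return count


def _count_wires(g: _Graph, cell_of: Dict[int, int],
                 absorbed: FrozenSet[int]) -> int:
    """Distinct producer outputs consumed across a cell boundary."""
    wires = 0
    for p in range(len(g.ops)):
        if p in absorbed:
            continue
        crosses = any(cell_of[w] != cell_of[p]
                      for w in g.consumers[p] if w not in absorbed)
        crosses = crosses or any(g.srcs[a][0] == ("g", p) for a in absorbed)
        if crosses:
            wires += 1
    return wires


# ----------------------------------------------------------------------
# exact branch and bound
# ----------------------------------------------------------------------
_EXACT_CACHE: Dict = {}


def _exact_solve(g: _Graph, rules: DistributionRules):
    """Optimal (n_cells, n_wires) with a witness assignment."""
    key = (g.canonical_key(), rules)
    witness_key = key in _EXACT_CACHE
    if witness_key:
        return _EXACT_CACHE[key]
    nodes = list(range(len(g.ops)))
    cand = ([i for i in nodes if g.ops[i] == "NOT" and i != g.root
             and g.srcs[i][0][0] == "g"]
            if rules.allow_absorption else [])
    best = None  # ((cells, wires), cell_of, absorbed)
    for k in range(1, rules.max_cells + 1):
        for r in range(len(cand) + 1):
            for chosen in itertools.combinations(cand, r):
                absorbed = frozenset(chosen)
                if not _valid_absorption(g, absorbed):
                    continue
                rest = [i for i in nodes if i not in absorbed]
                if rules.max_units_per_cell and \
                        len(rest) > k * rules.max_units_per_cell:
                    continue
                sol = _assign_search(g, rest, absorbed, k, rules, None)
                if sol is not None:
                    wires, cell_of = sol
                    # ties on (cells, wires) break toward more absorption:
                    # the repressive-wire realization is the preferred device
                    cand_best = ((k, wires, -len(absorbed)),
                                 dict(cell_of), absorbed)
                    if best is None or cand_best[0] < best[0]:
                        best = cand_best
        if best is not None:
            break
    if best is None:
        raise ConsortiaLogicError(
            f"no feasible plan within {rules.max_cells} cells")
    best = ((best[0][0], best[0][1]), best[1], best[2])
    _EXACT_CACHE[key] = best
    return best


def _assign_search(g: _Graph, rest: List[int], absorbed: FrozenSet[int],
                   k: int, rules: DistributionRules,
                   wire_bound: Optional[int]):
    """Backtracking over assignments of `rest` to at most k cells; returns
    the wire-minimal feasible assignment, or None."""
    assign: Dict[int, int] = {}
    best: List = [None, None]  # wires, cell_of

    def partial_ok(i: int, c: int) -> bool:
        if rules.forbid_parallel:
            sig = set(_sources_signature(g, i, absorbed))
            for j, cj in assign.items():
                if cj == c and sig & set(_sources_signature(g, j, absorbed)):
                    return False
        # absorption boundary constraints that are already decidable
        for s in g.srcs[i]:
            if s[0] == "g" and s[1] in absorbed:
                child = g.srcs[s[1]][0][1]
                if child in assign and assign[child] == c:
                    return False
        for a in absorbed:
            if g.srcs[a][0] == ("g", i):
                for w in g.consumers[a]:
                    if w in assign and assign[w] == c:
                        return False
        return True

    def bt(idx: int, used: int):
        if idx == len(rest):
            cell_of = dict(assign)
            if len(set(cell_of.values())) != k:
                return
            if not _check(g, cell_of, absorbed, rules):
                return
            w = _count_wires(g, cell_of, absorbed)
            if best[0] is None or w < best[0]:
                best[0], best[1] = w, cell_of
            return
        i = rest[idx]
        for c in range(min(used + 1, k)):
            if partial_ok(i, c):
                assign[i] = c
                bt(idx + 1, max(used, c + 1))
                del assign[i]

    bt(0, 0)
    if best[0] is None:
        return None
    if wire_bound is not None and best[0] >= wire_bound:
        return None
    return best[0], best[1]


# ----------------------------------------------------------------------
# greedy heuristic
# ----------------------------------------------------------------------
def _greedy_solve(g: _Graph, rules: DistributionRules):
    """Open a cell at the gate nearest the output, grow it backwards along
    tandem chains while the unit budget and the parallel rule allow, repeat;
    finally absorb every NOT whose input arrives on a wire."""
    remaining = set(range(len(g.ops)))
    cell_of: Dict[int, int] = {}
    n_cells = 0
    order = _topo_order(g)
    pos = {i: p for p, i in enumerate(order)}
    cap = rules.max_units_per_cell or len(g.ops)
    while remaining:
        seed = max(remaining, key=lambda i: pos[i])
        cell = [seed]
        remaining.discard(seed)
        frontier = [s[1] for s in g.srcs[seed] if s[0] == "g"
                    and s[1] in remaining]
        while len(cell) < cap and frontier:
            i = frontier.pop()
            if i not in remaining:
                continue
            trial = dict.fromkeys(cell + [i], n_cells)
            if rules.forbid_parallel and \
                    _count_parallel(g, trial, frozenset()) > 0:
                continue
            if rules.max_depth and \
                    _chain_depth(g, trial, frozenset()) > rules.max_depth:
                continue
            cell.append(i)
            remaining.discard(i)
            frontier.extend(s[1] for s in g.srcs[i]
                            if s[0] == "g" and s[1] in remaining)
        for i in cell:
            cell_of[i] = n_cells
        n_cells += 1
    absorbed = set()
    if rules.allow_absorption:
        for i in range(len(g.ops)):
            if g.ops[i] != "NOT" or i == g.root:
                continue
            src = g.srcs[i][0]
            if src[0] != "g" or src[1] in absorbed:
                continue
            child_cell = cell_of[src[1]]
            if cell_of[i] == child_cell:
                continue
            if all(cell_of[w] != child_cell for w in g.consumers[i]):
                absorbed.add(i)
    for a in absorbed:
        del cell_of[a]
    # renumber cells that may have emptied out
    live = sorted(set(cell_of.values()))
    renum = {c: i for i, c in enumerate(live)}
    cell_of = {i: renum[c] for i, c in cell_of.items()}
    absorbed = frozenset(absorbed)
    if not _check(g, cell_of, absorbed, rules):
        # fall back: one gate per cell is always feasible
        cell_of = {i: r for r, i in
                   enumerate(i for i in range(len(g.ops)))}
        absorbed = frozenset()
    return ((len(set(cell_of.values())), _count_wires(g, cell_of, absorbed)),
            cell_of, absorbed)


def _topo_order(g: _Graph) -> List[int]:
    seen: Dict[int, int] = {}
    order: List[int] = []

    def visit(i):
        if seen.get(i):
            return
        seen[i] = 1
        for s in g.srcs[i]:
            if s[0] == "g":
                visit(s[1])
        order.append(i)

    for i in range(len(g.ops)):
        visit(i)
    return order


def _chain_depth(g: _Graph, cell_of: Dict[int, int],
                 absorbed: FrozenSet[int]) -> int:
    memo: Dict[int, int] = {}

    def depth(i: int) -> int:
        if i in memo:
            return memo[i]
        m = 1
        for s in g.srcs[i]:
            if s[0] == "g" and s[1] in cell_of and s[1] not in absorbed \
                    and cell_of[s[1]] == cell_of[i]:
                m = max(m, 1 + depth(s[1]))
        memo[i] = m
        return m

    return max((depth(i) for i in cell_of), default=0)


# ----------------------------------------------------------------------
# public API
# ----------------------------------------------------------------------
def _build_plan(g: _Graph, cell_of: Dict[int, int],
                absorbed: FrozenSet[int]) -> ConsortiumPlan:
    order = _topo_order(g)
    pos = {i: p for p, i in enumerate(order)}
    cell_members: Dict[int, List[int]] = {}
    for i, c in cell_of.items():
        cell_members.setdefault(c, []).append(i)
    ranked = sorted(cell_members.values(),
                    key=lambda ms: max(pos[i] for i in ms), reverse=True)
    cell_name: Dict[int, str] = {}
    cells = []
    for ci, members in enumerate(ranked):
        name = f"c{ci + 1}"
        for i in members:
            cell_name[i] = name
        cells.append((name, frozenset(g.gate_ids[i] for i in members)))
    wires: List[Wire] = []
    for p in range(len(g.ops)):
        if p in absorbed:
            continue
        plain = sorted({cell_name[w] for w in g.consumers[p]
                        if w not in absorbed and cell_name[w] != cell_name[p]})
        inv = sorted({cell_name[w]
                      for a in absorbed if g.srcs[a][0] == ("g", p)
                      for w in g.consumers[a]})
        if plain:
            wires.append(Wire(cell_name[p], g.gate_ids[p], tuple(plain), False))
        if inv:
            wires.append(Wire(cell_name[p], g.gate_ids[p], tuple(inv), True))
    n_wires = _count_wires(g, cell_of, absorbed)
    n_par = _count_parallel(g, cell_of, absorbed)
    return ConsortiumPlan(tuple(cells), tuple(wires),
                          frozenset(g.gate_ids[a] for a in absorbed),
                          (len(cells), n_wires, n_par))


def distribute(design: CircuitDesign, mode: str = "exact",
               rules: DistributionRules = DistributionRules()
               ) -> ConsortiumPlan:
    g = _Graph.from_design(design)
    if mode == "exact":
        (_, cell_of, absorbed) = _exact_solve(g, rules)
    elif mode == "greedy":
        (_, cell_of, absorbed) = _greedy_solve(g, rules)
    else:
        raise ConsortiaLogicError(f"unknown distribution mode {mode!r}")
    return _build_plan(g, cell_of, absorbed)


def plan_cost(design_or_result, rules: DistributionRules = DistributionRules()
              ) -> Tuple[int, int]:
    """(n_cells, n_wires) of the exact-optimal plan; for a SynthesisResult
    the minimum over all rule-optimal designs (the methodology is free to
    pick the best-distributing simplest design)."""
    if isinstance(design_or_result, SynthesisResult):
        designs = design_or_result.designs
    elif isinstance(design_or_result, CircuitDesign):
        designs = (design_or_result,)
    else:
        designs = tuple(design_or_result)
    best = None
    for d in designs:
        g = _Graph.from_design(d)
        cost = _exact_solve(g, rules)[0]
        if best is None or cost < best:
            best = cost
    return best


def plan_cost_masks(mask: int, n: int,
                    rules: DistributionRules = DistributionRules(),
                    mode: str = "tree") -> Tuple[int, int]:
    """Fast path used by the survey: minimal (cells, wires) over the
    rule-optimal design pool of a truth-table mask."""
    if mode == "tree":
        from .synthesis import tree_design_pool
        graphs = [_Graph.from_tree(t, n) for t in tree_design_pool(mask, n)]
    elif mode == "dag":
        from .synthesis import dag_synthesizer
        syn = dag_synthesizer(n)
        syn.min_units(mask, max_units=12)
        graphs = [_chain_graph(d, mask, n)
                  for d in syn.design_pool(mask, max_units=12)]
    else:
        raise ConsortiaLogicError(f"unknown mode {mode!r}")
    return min(_exact_solve(g, rules)[0] for g in graphs)


def _chain_graph(chain: Dict[int, Tuple], root: int, n: int) -> _Graph:
    from .synthesis import chain_to_design
    return _Graph.from_design(chain_to_design(chain, root, n))


def greedy_cost(design: CircuitDesign,
                rules: DistributionRules = DistributionRules()
                ) -> Tuple[int, int]:
    return _greedy_solve(_Graph.from_design(design), rules)[0]


def reevaluate_plan(design: CircuitDesign, plan: ConsortiumPlan):
    """Re-evaluate the distributed circuit honoring wire senses.

    Independent double-check that merging all cells reproduces the design's
    function: gates read environmental inputs, same-cell gate outputs
    directly, and cross-cell signals through wires — repressive wires invert
    the carried value at the consumer's promoter.
    """
    from .truthtables import TruthTable
    n = len(design.inputs)
    full = _bits.full_mask(n)
    masks = dict(zip(design.inputs, _bits.input_masks(n)))
    by_id = design.gate_map()
    absorbed = set(plan.absorbed_nots)
    values: Dict[str, int] = {}

    def value(sig: str) -> int:
        if sig in masks:
            return masks[sig]
        if sig in values:
            return values[sig]
        gate = by_id[sig]
        if sig in absorbed:
            # sensed as the producer's molecule through a repressive promoter
            v = ~value(gate.srcs[0]) & full
        else:
            ops = [value(s) for s in gate.srcs]
            if gate.kind is GateKind.NOT:
                v = ~ops[0] & full
            elif gate.kind is GateKind.AND:
                v = ops[0] & ops[1]
            else:
                v = ops[0] | ops[1]
        values[sig] = v
        return v

    return TruthTable.from_mask(value(design.output), n)
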