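"""Exact search for simplest AND/OR/NOT designs.

Two independent engines answer "what is the cheapest combinational design
realizing a target truth table":

* ``mode="tree"`` — formula synthesis: gate outputs feed exactly one
  consumer (environmental inputs fan out freely).  Minimal sizes come from a
  dynamic program over the whole 2**(2**n) function space; all minimal
  formulas are then reconstructed by enumerating the optimal decompositions.
  This mode reproduces the published multicellular survey statistics.

* ``mode="dag"`` — Boolean-chain synthesis: gate outputs may fan out.  A
  breadth-first search over canonical sets of computed functions (canonical
  under input permutation) finds the minimal chain length, and every minimal
  design is harvested from the frontier states: a state at level k containing
  the target, with u(target)=k, is exactly a minimal node-set, because an
  unused gate would contradict minimality.

Selection follows two rules: fewest total units first, then fewest AND gates
among the size-minimal designs (NOT and OR are the cheap units in cells).

:func:`oracle_min_units` is a deliberately separate, much simpler
pairwise-composition dynamic program used to cross-check the search engines.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from . import _bits
from .circuits import CircuitDesign, DesignScore, Gate, GateKind
from .errors import (BoundExceededError, ConsortiaLogicError,
                     UnreachableError, UnsupportedArityError)
from .truthtables import TruthTable

DEFAULT_INPUT_NAMES = ("x1", "x2", "x3", "x4")

# tree nodes: ('x', i) | ('NOT', t) | ('AND', t1, t2) | ('OR', t1, t2)


# ----------------------------------------------------------------------
# tree (formula) engine
# ----------------------------------------------------------------------
@lru_cache(maxsize=None)
def _formula_sizes(n: int) -> Tuple[int, ...]:
    """Minimal AND/OR/NOT formula size (gate count) for every n-input mask.

    Fixpoint relaxation: size[x_i]=0; size[g op h] <= size[g]+size[h]+1;
    size[~g] <= size[g]+1.  Unreachable (constants) stay at INF.
    """
    full = _bits.full_mask(n)
    INF = 1 << 30
    size = [INF] * (full + 1)
    for v in _bits.input_masks(n):
        size[v] = 0
    changed = True
    while changed:
        changed = False
        known = [(f, s) for f, s in enumerate(size) if s < INF]
        for (f, sf), (g, sg) in itertools.combinations_with_replacement(known, 2):
            s = sf + sg + 1
            for h in (f & g, f | g):
                if s < size[h]:
                    size[h] = s
                    changed = True
        for f, sf in enumerate(size):
            if sf < INF and sf + 1 < size[~f & full]:
                size[~f & full] = sf + 1
                changed = True
    return tuple(size)


_TREE_CACHE: Dict[Tuple[int, int], FrozenSet] = {}


def _min_trees(mask: int, n: int) -> FrozenSet:
    """All size-minimal formulas for `mask`, deduplicated as canonical tuples
    (children of commutative gates sorted)."""
    key = (n, mask)
    if key in _TREE_CACHE:
        return _TREE_CACHE[key]
    size = _formula_sizes(n)
    full = _bits.full_mask(n)
    inputs = {v: i for i, v in enumerate(_bits.input_masks(n))}
    INF = 1 << 30

    if mask in inputs:
        out = frozenset({("x", inputs[mask])})
        _TREE_CACHE[key] = out
        return out
    sf = size[mask]
    if sf >= INF:
        raise UnreachableError(f"mask {mask:#x} not expressible over AND/OR/NOT")
    out = set()
    neg = ~mask & full
    if size[neg] == sf - 1:
        for t in _min_trees(neg, n):
            out.add(("NOT", t))
    for g in range(full + 1):
        sg = size[g]
        if sg >= sf:
            continue
        for h in range(g, full + 1):
            if sg + size[h] + 1 != sf:
                continue
            for op, val in (("AND", g & h), ("OR", g | h)):
                if val != mask:
                    continue
                for t1 in _min_trees(g, n):
                    for t2 in _min_trees(h, n):
                        out.add((op,) + tuple(sorted((t1, t2), key=repr)))
    out = frozenset(out)
    _TREE_CACHE[key] = out
    return out


def _tree_and_count(t) -> int:
    if t[0] == "x":
        return 0
    if t[0] == "NOT":
        return _tree_and_count(t[1])
    return (t[0] == "AND") + _tree_and_count(t[1]) + _tree_and_count(t[2])


def tree_design_pool(mask: int, n: int) -> List[Tuple]:
    """Size-minimal formulas restricted to the minimum AND count (rule ii)."""
    trees = _min_trees(mask, n)
    best_and = min(_tree_and_count(t) for t in trees)
    return sorted((t for t in trees if _tree_and_count(t) == best_and), key=repr)


def tree_to_design(tree, n: int,
                   input_names: Optional[Sequence[str]] = None) -> CircuitDesign:
    names = tuple(input_names or DEFAULT_INPUT_NAMES[:n])
    gates: List[Gate] = []

    def rec(node) -> str:
        if node[0] == "x":
            return names[node[1]]
        srcs = tuple(rec(c) for c in node[1:])
        gid = f"g{len(gates) + 1}"
        gates.append(Gate(gid, GateKind(node[0]), srcs))
        return gid

    out = rec(tree)
    return CircuitDesign(names, tuple(gates), out)


# ----------------------------------------------------------------------
# bounded tree engine for the 4-input survey
# ----------------------------------------------------------------------
@lru_cache(maxsize=None)
def _bounded_size_table(n: int, bound: int) -> Dict[int, int]:
    """Leveled AND/OR/NOT formula-size DP, truncated at `bound` gates.

    The full 2**(2**4) relaxation is wasteful at n=4; the leveled version
    only ever combines functions whose sizes sum below the budget.
    """
    size: Dict[int, int] = {v: 0 for v in _bits.input_masks(n)}
    full = _bits.full_mask(n)
    by_level: Dict[int, List[int]] = {0: list(size)}
    for level in range(1, bound + 1):
        found: List[int] = []

        def record(h):
            if h not in size:
                size[h] = level
                found.append(h)

        for s1 in range(level):
            s2 = level - 1 - s1
            if s2 < s1 or s1 not in by_level or s2 not in by_level:
                continue
            for f in by_level[s1]:
                for g in by_level[s2]:
                    record(f & g)
                    record(f | g)
        for f in by_level.get(level - 1, ()):
            record(~f & full)
        by_level[level] = found
    return size


_BOUNDED_TREES: Dict[Tuple[int, int, int], Tuple] = {}


def _bounded_min_trees(mask: int, n: int, bound: int) -> Tuple:
    key = (n, bound, mask)
    if key in _BOUNDED_TREES:
        return _BOUNDED_TREES[key]
    size = _bounded_size_table(n, bound)
    inputs = {v: i for i, v in enumerate(_bits.input_masks(n))}
    full = _bits.full_mask(n)
    if mask in inputs:
        out = (("x", inputs[mask]),)
        _BOUNDED_TREES[key] = out
        return out
    sf = size[mask]
    found = set()
    neg = ~mask & full
    if size.get(neg, 1 << 30) == sf - 1:
        for t in _bounded_min_trees(neg, n, bound):
            found.add(("NOT", t))
    supers = [g for g, s in size.items() if s < sf and (g & mask) == mask]
    for g in supers:
        for h in supers:
            if h < g or size[g] + size[h] + 1 != sf or (g & h) != mask:
                continue
            for t1 in _bounded_min_trees(g, n, bound):
                for t2 in _bounded_min_trees(h, n, bound):
                    found.add(("AND",) + tuple(sorted((t1, t2), key=repr)))
    subs = [g for g, s in size.items() if s < sf and (g | mask) == mask]
    for g in subs:
        for h in subs:
            if h < g or size[g] + size[h] + 1 != sf or (g | h) != mask:
                continue
            for t1 in _bounded_min_trees(g, n, bound):
                for t2 in _bounded_min_trees(h, n, bound):
                    found.add(("OR",) + tuple(sorted((t1, t2), key=repr)))
    out = tuple(sorted(found, key=repr))
    _BOUNDED_TREES[key] = out
    return out


def bounded_tree_pool(mask: int, n: int, bound: int) -> List[Tuple]:
    """Rule-(i)/(ii)-optimal formulas within a unit budget; empty list when
    the budget is insufficient (the bounded survey reports these as
    unresolved)."""
    size = _bounded_size_table(n, bound)
    if mask not in size:
        return []
    trees = _bounded_min_trees(mask, n, bound)
    best_and = min(_tree_and_count(t) for t in trees)
    return [t for t in trees if _tree_and_count(t) == best_and]


# ----------------------------------------------------------------------
# DAG (Boolean chain) engine
# ----------------------------------------------------------------------
_OPS_AON = "aon"


class DagSynthesizer:
    """Breadth-first search over canonical sets of computed functions.

    Levels are expanded on demand up to ``max_units``; state sets are
    canonicalized under input permutation, which keeps the n=3 search to a
    couple of million states at the deepest useful level (8 gates).
    """

    def __init__(self, n: int):
        if not 1 <= n <= 3:
            raise UnsupportedArityError(
                "exact DAG synthesis is supported for n <= 3 "
                "(the 4-input survey is bounded and tree-based)")
        self.n = n
        self.full = _bits.full_mask(n)
        self.inputs = _bits.input_masks(n)
        self.perms = _bits.permutation_tables(n)
        self.frontiers: List[List[frozenset]] = [[frozenset()]]
        self.seen = {self._canon(frozenset())}
        self.first_reach: Dict[int, int] = {v: 0 for v in self.inputs}

    def _canon(self, fs: frozenset):
        return min(tuple(sorted(t[f] for f in fs)) for _, t in self.perms)

    def _expand_level(self):
        lev = len(self.frontiers)
        new: List[frozenset] = []
        for fs in self.frontiers[-1]:
            signals = self.inputs + tuple(fs)
            exist = set(signals)
            cand = set()
            for a, b in itertools.combinations(signals, 2):
                for h in (a & b, a | b):
                    if h not in exist and h not in (0, self.full):
                        cand.add(h)
            for a in signals:
                h = ~a & self.full
                if h not in exist and h not in (0, self.full):
                    cand.add(h)
            for h in cand:
                st = fs | {h}
                keyc = self._canon(st)
                if keyc not in self.seen:
                    self.seen.add(keyc)
                    new.append(st)
                    for _, t in self.perms:
                        hh = t[h]
                        if hh not in self.first_reach:
                            self.first_reach[hh] = lev
        self.frontiers.append(new)

    def min_units(self, mask: int, max_units: int) -> int:
        while mask not in self.first_reach:
            if len(self.frontiers) > max_units:
                raise BoundExceededError(
                    f"not realizable within {max_units} units", bound=max_units)
            self._expand_level()
        u = self.first_reach[mask]
        if u > max_units:
            raise BoundExceededError(
                f"not realizable within {max_units} units "
                f"(needs {u})", bound=max_units)
        return u

    # -- minimal design harvesting ------------------------------------
    def node_sets(self, mask: int, max_units: int) -> List[frozenset]:
        u = self.min_units(mask, max_units)
        if u == 0:
            return [frozenset()]
        out = set()
        for st in self.frontiers[u]:
            for _, t in self.perms:
                pst = frozenset(t[f] for f in st)
                if mask in pst:
                    out.add(pst)
        return sorted(out, key=sorted)

    def design_pool(self, mask: int, max_units: int) -> List[Dict]:
        """All minimal chain designs as {node: (op, operands...)} covers."""
        designs = []
        for V in self.node_sets(mask, max_units):
            designs.extend(_covers(mask, V, self.n))
        uniq = {frozenset(d.items()): d for d in designs}
        pool = list(uniq.values())
        best_and = min(sum(1 for v in d.values() if v[0] == "AND")
                       for d in pool)
        pool = [d for d in pool
                if sum(1 for v in d.values() if v[0] == "AND") == best_and]
        return sorted(pool, key=lambda d: sorted(d.items()))


@lru_cache(maxsize=None)
def _decomps(mask: int, n: int) -> Tuple:
    """Every way to write `mask` as NOT/AND/OR of other non-constant masks."""
    full = _bits.full_mask(n)
    out = []
    g = ~mask & full
    if g not in (0, full):
        out.append(("NOT", g))
    for g in range(1, full):
        if g == mask:
            continue
        if (mask & ~g) & full == 0:  # g superset: AND candidates
            free = ~mask & ~g & full
            sub = free
            while True:
                h = mask | sub
                if h not in (0, full) and h != mask and h >= g:
                    out.append(("AND", g, h))
                if sub == 0:
                    break
                sub = (sub - 1) & free
        if (g & ~mask) & full == 0:  # g subset: OR candidates
            need = mask & ~g & full
            free = mask & g
            sub = free
            while True:
                h = need | sub
                if h not in (0, full) and h != mask and h >= g:
                    out.append(("OR", g, h))
                if sub == 0:
                    break
                sub = (sub - 1) & free
    return tuple(sorted(set(out)))


def _covers(target: int, V: frozenset, n: int) -> List[Dict]:
    """Acyclic, fully-used assignments of one decomposition per node of V."""
    inputs = set(_bits.input_masks(n))
    avail = set(V) | inputs
    options = {}
    for v in sorted(V):
        opts = [d for d in _decomps(v, n)
                if all(o in avail and o != v for o in d[1:])]
        if not opts:
            return []
        options[v] = opts
    order = sorted(V, key=lambda v: len(options[v]))
    assign: Dict[int, Tuple] = {}
    out = []

    def acyclic_and_used() -> bool:
        state: Dict[int, int] = {}

        def visit(v) -> bool:
            st = state.get(v)
            if st == 1:
                return False
            if st == 2:
                return True
            state[v] = 1
            ok = all(visit(o) for o in assign[v][1:] if o in assign)
            state[v] = 2
            return ok

        if not all(visit(v) for v in V):
            return False
        used = set()
        stack = [target]
        while stack:
            x = stack.pop()
            if x in used or x in inputs:
                continue
            used.add(x)
            stack.extend(assign[x][1:])
        return len(used) == len(V)

    def rec(i):
        if i == len(order):
            if acyclic_and_used():
                out.append(dict(assign))
            return
        v = order[i]
        for d in options[v]:
            assign[v] = d
            rec(i + 1)
            del assign[v]

    rec(0)
    return out


_DAG_CACHE: Dict[int, DagSynthesizer] = {}


def dag_synthesizer(n: int) -> DagSynthesizer:
    if n not in _DAG_CACHE:
        _DAG_CACHE[n] = DagSynthesizer(n)
    return _DAG_CACHE[n]


def chain_to_design(chain: Dict[int, Tuple], root: int, n: int,
                    input_names: Optional[Sequence[str]] = None) -> CircuitDesign:
    names = tuple(input_names or DEFAULT_INPUT_NAMES[:n])
    in_masks = dict(zip(_bits.input_masks(n), names))
    order: List[int] = []
    state: Dict[int, int] = {}

    def visit(v):
        if v in in_masks or state.get(v) == 2:
            return
        state[v] = 1
        for o in chain[v][1:]:
            visit(o)
        state[v] = 2
        order.append(v)

    visit(root)
    gid = {v: f"g{i + 1}" for i, v in enumerate(order)}

    def ref(o):
        return in_masks[o] if o in in_masks else gid[o]

    gates = tuple(Gate(gid[v], GateKind(chain[v][0]),
                       tuple(ref(o) for o in chain[v][1:]))
                  for v in order)
    return CircuitDesign(names, gates, gid[root])


# ----------------------------------------------------------------------
# public entry points
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SynthesisResult:
    target: TruthTable
    optimal_score: DesignScore
    designs: Tuple[CircuitDesign, ...]
    mode: str = "tree"


def synthesize_simplest(target: TruthTable, max_units: int = 12,
                        mode: str = "tree",
                        input_names: Optional[Sequence[str]] = None
                        ) -> SynthesisResult:
    """All simplest designs for `target`: fewest units, then fewest ANDs.

    Raises BoundExceededError when the optimum exceeds ``max_units`` and
    reports the bound; never silently truncates.
    """
    if not target.depends_on_all_inputs():
        raise ConsortiaLogicError(
            "synthesis targets must depend on every declared input "
            "(apply the dependence filter first)")
    if max_units < 1:
        raise ConsortiaLogicError("max_units must be >= 1")
    n = target.n_inputs
    mask = target.mask
    if mode == "tree":
        if n > 3:
            raise UnsupportedArityError(
                "exhaustive tree synthesis is supported for n <= 3")
        size = _formula_sizes(n)[mask]
        if size > max_units:
            raise BoundExceededError(
                f"not realizable within {max_units} units (needs {size})",
                bound=max_units)
        designs = tuple(tree_to_design(t, n, input_names)
                        for t in tree_design_pool(mask, n))
    elif mode == "dag":
        syn = dag_synthesizer(n)
        syn.min_units(mask, max_units)
        designs = tuple(chain_to_design(d, mask, n, input_names)
                        for d in syn.design_pool(mask, max_units))
    else:
        raise ConsortiaLogicError(f"unknown synthesis mode {mode!r}")
    scores = {d.score().as_tuple() for d in designs}
    assert len(scores) == 1, "pool must be score-homogeneous"
    score = DesignScore(*scores.pop())
    return SynthesisResult(target, score, designs, mode)


# ----------------------------------------------------------------------
# independent oracle
# ----------------------------------------------------------------------
_ORACLE_BASES = {
    frozenset({GateKind.AND, GateKind.OR, GateKind.NOT}),
    frozenset({GateKind.NOR}),
    frozenset({GateKind.NAND}),
    frozenset({GateKind.NOR, GateKind.NAND}),
}


def oracle_min_units(target: TruthTable, basis) -> int:
    """Minimal gate count of a formula for `target` over `basis`.

    Dynamic program over the 2**(2**n) function space combining
    previously-reached functions pairwise — an independent code path from the
    search engines, written for clarity rather than speed (n <= 3).
    """
    basis = frozenset(GateKind(b) for b in basis)
    n = target.n_inputs
    if n > 3:
        raise UnsupportedArityError("oracle supports n <= 3")
    sizes = _oracle_sizes(n, basis)
    s = sizes.get(target.mask)
    if s is None:
        raise UnreachableError(
            f"{target} is not expressible over basis "
            f"{sorted(k.value for k in basis)}")
    return s


@lru_cache(maxsize=None)
def _oracle_sizes(n: int, basis: FrozenSet[GateKind]) -> Dict[int, int]:
    full = _bits.full_mask(n)
    best: Dict[int, int] = {v: 0 for v in _bits.input_masks(n)}
    frontier = dict(best)
    while frontier:
        # Dijkstra-flavoured rounds: repeatedly relax through one more gate.
        updated: Dict[int, int] = {}
        items = list(best.items())
        for (f, sf), (g, sg) in itertools.product(items, repeat=2):
            # a cell may wire one molecule to both its input ports, so a
            # self-pairing costs its operand once
            cost = (sf + 1) if f == g else (sf + sg + 1)
            results = []
            if GateKind.AND in basis:
                results.append(f & g)
            if GateKind.OR in basis:
                results.append(f | g)
            if GateKind.NOR in basis:
                results.append(~(f | g) & full)
            if GateKind.NAND in basis:
                results.append(~(f & g) & full)
            for h in results:
                if cost < best.get(h, 1 << 30) and cost < updated.get(h, 1 << 30):
                    updated[h] = cost
        if GateKind.NOT in basis:
            for f, sf in list(best.items()):
                h = ~f & full
                if sf + 1 < best.get(h, 1 << 30) and sf + 1 < updated.get(h, 1 << 30):
                    updated[h] = sf + 1
        frontier = {}
        for h, c in updated.items():
            if c < best.get(h, 1 << 30):
                best[h] = c
                frontier[h] = c
    return best
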