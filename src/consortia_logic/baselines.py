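"""Cost models for the two published alternatives to rules-based design.

* Standard NOR/NAND — every cell hosts exactly one universal 2-input gate
  (the engineered-E. coli NOR-gate methodology).  The default convention is a
  homogeneous NOR basis with formula (tree) composition, which is the one
  that reproduces the published two-cell count; mixed bases and DAG
  composition are available for sensitivity sweeps.

* Modular Cells — every cell computes an arbitrary Boolean function of at
  most two signals (the 16 two-input operators of the yeast methodology),
  where a signal is an environmental input or another cell's output.

Cell counts are exact minima from dynamic programs over the function space;
wire counts equal cells−1 because in a minimal tree composition every
internal output is consumed exactly once.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Tuple

from . import _bits
from .errors import BoundExceededError, ConsortiaLogicError
from .truthtables import TruthTable

NOR_CODE = 0b0001
NAND_CODE = 0b0111
ALL_OPS = tuple(c for c in range(16) if c not in (0, 0b1111))

_BASES = {
    "nor": (NOR_CODE,),
    "nand": (NAND_CODE,),
    "mixed": (NOR_CODE, NAND_CODE),
    "modular": ALL_OPS,
}


@dataclass(frozen=True)
class MethodProfile:
    method: str          # "rules" | "nor_nand" | "modular"
    target: TruthTable
    n_cells: int
    n_wires: int

    def __post_init__(self):
        if self.n_cells < 1 or self.n_wires < 0:
            raise ConsortiaLogicError("invalid profile cost")


@lru_cache(maxsize=None)
def _tree_sizes(n: int, codes: Tuple[int, ...], max_units: int
                ) -> Dict[int, int]:
    """Minimal formula size over 2-input operator codes, by leveled DP:
    size[op(g, h)] <= size[g] + size[h] + 1, and size[op(g, g)] <= size[g]+1
    — a cell may wire the same molecule to both its input ports, which is
    also how 1-input behaviors arise from degenerate tables."""
    full = _bits.full_mask(n)
    size: Dict[int, int] = {v: 0 for v in _bits.input_masks(n)}
    by_level: Dict[int, list] = {0: list(size)}
    for level in range(1, max_units + 1):
        found = []
        for s1 in range(level):
            s2 = level - 1 - s1
            if s2 < s1 or s2 not in by_level or s1 not in by_level:
                continue
            for f in by_level[s1]:
                for g in by_level[s2]:
                    if f == g:
                        continue
                    for code in codes:
                        for h in (_bits.apply_op2(code, f, g, n),
                                  _bits.apply_op2(code, g, f, n)):
                            if h not in size:
                                size[h] = level
                                found.append(h)
        for f in by_level.get(level - 1, ()):
            for code in codes:
                h = _bits.apply_op2(code, f, f, n)
                if h not in size:
                    size[h] = level
                    found.append(h)
        by_level[level] = found
        if len(size) == full + 1:
            break
    return size


def _min_size(target: TruthTable, codes: Tuple[int, ...], max_units: int,
              structure: str) -> int:
    n = target.n_inputs
    if structure == "tree":
        sizes = _tree_sizes(n, codes, max_units)
        s = sizes.get(target.mask)
        if s is None:
            if len(sizes) < _bits.full_mask(n) + 1:
                raise BoundExceededError(
                    f"not realizable within {max_units} gates",
                    bound=max_units)
            raise ConsortiaLogicError("unreachable target")
        return s
    if structure == "dag":
        return _dag_size(n, codes, target.mask, max_units)
    raise ConsortiaLogicError(f"unknown structure {structure!r}")


@lru_cache(maxsize=None)
def _dag_state_search(n: int, codes: Tuple[int, ...], max_level: int):
    """Breadth-first search over canonical sets of computed functions for an
    arbitrary 2-input-operator basis (exact DAG gate counts; small n or
    shallow levels only — the state space grows quickly)."""
    inputs = _bits.input_masks(n)
    full = _bits.full_mask(n)
    perms = _bits.permutation_tables(n)

    def canon(fs):
        return min(tuple(sorted(t[f] for f in fs)) for _, t in perms)

    frontier = [frozenset()]
    seen = {canon(frozenset())}
    first: Dict[int, int] = {v: 0 for v in inputs}
    for lev in range(1, max_level + 1):
        new = []
        for fs in frontier:
            signals = inputs + tuple(fs)
            exist = set(signals)
            cand = set()
            for a, b in itertools.product(signals, repeat=2):
                for code in codes:
                    h = _bits.apply_op2(code, a, b, n)
                    if h not in exist and h not in (0, full):
                        cand.add(h)
            for h in cand:
                st = fs | {h}
                key = canon(st)
                if key not in seen:
                    seen.add(key)
                    new.append(st)
                    for _, t in perms:
                        if t[h] not in first:
                            first[t[h]] = lev
        frontier = new
        if not new:
            break
    return first


def _dag_size(n: int, codes: Tuple[int, ...], mask: int, max_units: int) -> int:
    cap = min(max_units, 6 if n >= 3 else 8)
    first = _dag_state_search(n, codes, cap)
    if mask not in first:
        raise BoundExceededError(
            f"exact DAG search exhausted at {cap} gates", bound=cap)
    return first[mask]


def cost_nor_nand(target: TruthTable, basis: str = "nor",
                  structure: str = "tree", max_units: int = 20
                  ) -> MethodProfile:
    """Minimal one-gate-per-cell consortium in a NOR/NAND basis."""
    if not target.depends_on_all_inputs():
        raise ConsortiaLogicError("target must depend on every input")
    if basis not in ("nor", "nand", "mixed"):
        raise ConsortiaLogicError(f"unknown basis {basis!r}")
    cells = _min_size(target, _BASES[basis], max_units, structure)
    return MethodProfile("nor_nand", target, max(cells, 1), max(cells - 1, 0))


def cost_modular(target: TruthTable, max_units: int = 8,
                 structure: str = "tree") -> MethodProfile:
    """Minimal consortium of cells each computing an arbitrary function of at
    most two signals."""
    if not target.depends_on_all_inputs():
        raise ConsortiaLogicError("target must depend on every input")
    cells = _min_size(target, ALL_OPS, max_units, structure)
    return MethodProfile("modular", target, max(cells, 1), max(cells - 1, 0))
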