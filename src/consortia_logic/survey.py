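"""Sweep every dependence-filtered n-input function under the three
methodologies and tabulate how many cells and chemical wires each needs.

Costs are invariant under input relabeling, so the sweep runs once per
input-permutation orbit and multiplies by the orbit size; together with the
design-pool and partition caches this keeps the full 218-function 3-input
sweep in the seconds range.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from . import _bits
from .baselines import cost_modular, cost_nor_nand
from .distribution import DistributionRules, plan_cost_masks
from .errors import BoundExceededError, ConfigurationError, ConsortiaLogicError
from .truthtables import TruthTable, iter_functions

METHODS = ("rules", "nor_nand", "modular")


@dataclass(frozen=True)
class SurveyBounds:
    max_cells: int = 7
    max_wires: int = 4
    max_units: int = 7   # synthesis budget per function in the bounded sweep


@dataclass
class SurveyTable:
    n_inputs: int
    method: str
    histogram_cells: Dict[int, int]
    histogram_wires: Dict[int, int]
    bounds: Optional[SurveyBounds] = None
    unresolved: int = 0
    convention: str = ""

    @property
    def n_functions(self) -> int:
        return sum(self.histogram_cells.values()) + self.unresolved

    def within_cells(self, k: int) -> int:
        return sum(v for c, v in self.histogram_cells.items() if c <= k)

    def with_wires(self, w: int) -> int:
        return self.histogram_wires.get(w, 0)

    def max_cells(self) -> int:
        return max(self.histogram_cells)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        ks = sorted(set(self.histogram_cells) | set(self.histogram_wires))
        cum = 0
        for k in range(0, max(ks) + 1):
            cum += self.histogram_cells.get(k, 0)
            rows.append({
                "method": self.method, "n": self.n_inputs, "k": k,
                "functions_at_k_cells": self.histogram_cells.get(k, 0),
                "functions_at_k_wires": self.histogram_wires.get(k, 0),
                "cumulative": cum,
            })
        return pd.DataFrame(rows)


def _orbit_sweep(n: int, cost_fn) -> Tuple[Counter, Counter]:
    """Evaluate cost_fn(mask) once per permutation orbit."""
    cells: Counter = Counter()
    wires: Counter = Counter()
    cache: Dict[int, Tuple[int, int]] = {}
    full = _bits.full_mask(n)
    for mask in range(full + 1):
        if not _bits.depends_on_all(mask, n):
            continue
        rep = _bits.orbit_representative(mask, n)
        if rep not in cache:
            cache[rep] = cost_fn(rep)
        c, w = cache[rep]
        cells[c] += 1
        wires[w] += 1
    return cells, wires


def run_survey(n: int, method: str,
               bounds: Optional[SurveyBounds] = None,
               rules: DistributionRules = DistributionRules(),
               mode: str = "tree",
               basis: str = "nor") -> SurveyTable:
    """Histogram of cells- and wires-required over all dependence-filtered
    n-input functions for one methodology.

    For n=4 the sweep is bounded (`bounds` mandatory): functions whose
    bounded synthesis or whose optimal plan exceeds the bounds are counted
    as unresolved rather than silently dropped.
    """
    if method not in METHODS:
        raise ConsortiaLogicError(f"unknown method {method!r}")
    if not 2 <= n <= 4:
        raise ConsortiaLogicError("survey supports n = 2..4")
    if n == 4:
        if bounds is None:
            raise ConfigurationError("bounds are mandatory for the 4-input "
                                     "survey")
        return _bounded_survey_n4(method, bounds, rules, basis)

    if method == "rules":
        def cost(mask):
            return plan_cost_masks(mask, n, rules, mode=mode)
        convention = f"{mode} designs, {rules}"
    elif method == "nor_nand":
        def cost(mask):
            p = cost_nor_nand(TruthTable.from_mask(mask, n), basis=basis,
                              structure=mode)
            return p.n_cells, p.n_wires
        convention = f"{basis} basis, {mode} composition"
    else:
        def cost(mask):
            p = cost_modular(TruthTable.from_mask(mask, n), structure=mode)
            return p.n_cells, p.n_wires
        convention = f"all 16 operators, {mode} composition"

    cells, wires = _orbit_sweep(n, cost)
    return SurveyTable(n, method, dict(sorted(cells.items())),
                       dict(sorted(wires.items())), None, 0, convention)


def _bounded_survey_n4(method: str, bounds: SurveyBounds,
                       rules: DistributionRules, basis: str) -> SurveyTable:
    if method != "rules":
        # baseline tree DP is already bounded by gate count
        cells: Counter = Counter()
        wires: Counter = Counter()
        unresolved = 0
        cache: Dict[int, Optional[Tuple[int, int]]] = {}
        for tt in iter_functions(4, require_all_inputs=True):
            rep = _bits.orbit_representative(tt.mask, 4)
            if rep not in cache:
                try:
                    if method == "nor_nand":
                        p = cost_nor_nand(TruthTable.from_mask(rep, 4),
                                          basis=basis,
                                          max_units=bounds.max_cells)
                    else:
                        p = cost_modular(TruthTable.from_mask(rep, 4),
                                         max_units=bounds.max_cells)
                    cache[rep] = (p.n_cells, p.n_wires)
                except BoundExceededError:
                    cache[rep] = None
            res = cache[rep]
            if res is None or res[0] > bounds.max_cells \
                    or res[1] > bounds.max_wires:
                unresolved += 1
            else:
                cells[res[0]] += 1
                wires[res[1]] += 1
        return SurveyTable(4, method, dict(sorted(cells.items())),
                           dict(sorted(wires.items())), bounds, unresolved,
                           f"bounded, {basis}")

    cells = Counter()
    wires = Counter()
    unresolved = 0
    cache = {}
    for tt in iter_functions(4, require_all_inputs=True):
        rep = _bits.orbit_representative(tt.mask, 4)
        if rep not in cache:
            cache[rep] = _bounded_rules_cost(rep, bounds, rules)
        res = cache[rep]
        if res is None or res[0] > bounds.max_cells \
                or res[1] > bounds.max_wires:
            unresolved += 1
        else:
            cells[res[0]] += 1
            wires[res[1]] += 1
    return SurveyTable(4, "rules", dict(sorted(cells.items())),
                       dict(sorted(wires.items())), bounds, unresolved,
                       "bounded tree designs")


def _bounded_rules_cost(mask: int, bounds: SurveyBounds,
                        rules: DistributionRules):
    from .synthesis import bounded_tree_pool
    from .distribution import _Graph, _exact_solve
    pool = bounded_tree_pool(mask, 4, bounds.max_units)
    if not pool:
        return None
    best = None
    for tree in pool:
        g = _Graph.from_tree(tree, 4)
        cost = _exact_solve(g, rules)[0]
        if best is None or cost < best:
            best = cost
    return best


def compare_methods(n: int, rules: DistributionRules = DistributionRules(),
                    mode: str = "tree", basis: str = "nor"
                    ) -> List[SurveyTable]:
    if n not in (2, 3):
        raise ConsortiaLogicError("compare_methods supports n in {2, 3}")
    return [run_survey(n, m, rules=rules, mode=mode, basis=basis)
            for m in METHODS]


def headline_counts(tables: Iterable[SurveyTable]) -> pd.DataFrame:
    """The cumulative counts quoted in the text for the 3-input comparison."""
    rows = []
    for t in tables:
        rows.append({
            "method": t.method,
            "n": t.n_inputs,
            "functions": t.n_functions,
            "within_2_cells": t.within_cells(2),
            "max_cells": t.max_cells(),
            "zero_wires": t.with_wires(0),
            "one_wire": t.with_wires(1),
            "convention": t.convention,
        })
    return pd.DataFrame(rows)


def survey_to_csv(tables: Iterable[SurveyTable], path) -> None:
    df = pd.concat([t.to_dataframe() for t in tables], ignore_index=True)
    df.to_csv(path, index=False)
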