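"""Serialization round-trips and the seeded fixture generator."""
from __future__ import annotations

import hashlib
import json
import random
from typing import List, Tuple

from . import _bits
from .circuits import CircuitDesign
from .distribution import ConsortiumPlan
from .errors import ConsortiaLogicError
from .synthesis import tree_design_pool, tree_to_design
from .truthtables import TruthTable


def roundtrip(obj):
    """Serialize to JSON and parse back; the result equals the input."""
    if isinstance(obj, TruthTable):
        return TruthTable.from_json(json.loads(json.dumps(obj.to_json())))
    if isinstance(obj, CircuitDesign):
        return CircuitDesign.from_json(json.loads(json.dumps(obj.to_json())))
    if isinstance(obj, ConsortiumPlan):
        return ConsortiumPlan.from_json(json.loads(json.dumps(obj.to_json())))
    raise ConsortiaLogicError(f"cannot round-trip {type(obj).__name__}")


def generate_fixtures(seed: int, n: int, count: int
                      ) -> List[Tuple[TruthTable, CircuitDesign]]:
    """Reproducible (table, realizing circuit) pairs for tests.

    Tables are drawn uniformly from the dependence-filtered set; each paired
    circuit is a seeded choice among the table's rule-optimal designs, so it
    realizes the table by construction.  Duplicate tables are allowed (and
    expected for count near the universe size); callers needing distinct
    tables deduplicate by mask.
    """
    if count < 1:
        raise ConsortiaLogicError("count must be >= 1")
    if not 2 <= n <= 3:
        raise ConsortiaLogicError("fixtures support n in {2, 3}")
    rng = random.Random(seed)
    universe = [m for m in range(_bits.full_mask(n) + 1)
                if _bits.depends_on_all(m, n)]
    out = []
    for _ in range(count):
        mask = rng.choice(universe)
        pool = tree_design_pool(mask, n)
        design = tree_to_design(rng.choice(pool), n)
        out.append((TruthTable.from_mask(mask, n), design))
    return out


def config_hash(config: dict) -> str:
    """Stable short hash embedded in every CSV/JSON artifact."""
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
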