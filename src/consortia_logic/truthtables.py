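"""Truth tables of n-input, 1-output Boolean functions (n = 1..4).

The row convention is fixed once for the whole package: row index
r = sum_i a_i * 2**(n-1-i), so input 1 is the most significant bit and the
serialized bitstring lists outputs for rows 0, 1, 2, ... in order.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from . import _bits
from .errors import InputDimensionError, ParseError, UnsupportedArityError

SCHEMA = "consortia-logic/1"


@dataclass(frozen=True)
class TruthTable:
    """An n-input 1-output Boolean function as a vector of 2**n output bits."""

    n_inputs: int
    bits: tuple
    label: Optional[str] = field(default=None, compare=False)

    def __post_init__(self):
        if not 1 <= self.n_inputs <= _bits.MAX_INPUTS:
            raise UnsupportedArityError(
                f"n_inputs must be 1..{_bits.MAX_INPUTS}, got {self.n_inputs}")
        bits = tuple(int(b) for b in self.bits)
        if len(bits) != _bits.n_rows(self.n_inputs):
            raise InputDimensionError(
                f"expected {_bits.n_rows(self.n_inputs)} bits, got {len(bits)}")
        if any(b not in (0, 1) for b in bits):
            raise InputDimensionError("truth-table entries must be 0 or 1")
        object.__setattr__(self, "bits", bits)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_bitstring(cls, s: str, label: Optional[str] = None) -> "TruthTable":
        n = (len(s) - 1).bit_length()
        if len(s) != 1 << n:
            raise InputDimensionError(f"bitstring length {len(s)} is not a power of 2")
        return cls(n, tuple(int(c) for c in s), label)

    @classmethod
    def from_mask(cls, mask: int, n: int, label: Optional[str] = None) -> "TruthTable":
        return cls(n, _bits.bits_from_mask(mask, n), label)

    @classmethod
    def from_callable(cls, fn, n: int, label: Optional[str] = None) -> "TruthTable":
        bits = []
        for r in range(_bits.n_rows(n)):
            assignment = tuple((r >> (n - 1 - i)) & 1 for i in range(n))
            bits.append(1 if fn(*assignment) else 0)
        return cls(n, tuple(bits), label)

    # -- views -------------------------------------------------------------
    @property
    def mask(self) -> int:
        return _bits.mask_from_bits(self.bits)

    def bitstring(self) -> str:
        return "".join(str(b) for b in self.bits)

    def __str__(self):
        name = self.label or "TruthTable"
        return f"{name}(n={self.n_inputs}, bits={self.bitstring()})"

    # -- operations --------------------------------------------------------
    def evaluate(self, assignment: Sequence[int]) -> int:
        if len(assignment) != self.n_inputs:
            raise InputDimensionError(
                f"assignment has {len(assignment)} values, function takes "
                f"{self.n_inputs}")
        return self.bits[_bits.row_index(assignment)]

    def depends_on_all_inputs(self) -> bool:
        return _bits.depends_on_all(self.mask, self.n_inputs)

    def complement(self) -> "TruthTable":
        return TruthTable(self.n_inputs, tuple(1 - b for b in self.bits))

    # -- serialization -----------------------------------------------------
    def to_json(self) -> dict:
        d = {"schema": SCHEMA, "n": self.n_inputs, "bits": self.bitstring()}
        if self.label:
            d["label"] = self.label
        return d

    @classmethod
    def from_json(cls, d: dict) -> "TruthTable":
        try:
            n = int(d["n"])
            bits = d["bits"]
        except (KeyError, TypeError, ValueError) as e:
            raise ParseError(f"bad truth-table object: {e}", "/") from e
        if not isinstance(bits, str) or any(c not in "01" for c in bits):
            raise ParseError("bits must be a 0/1 string", "/bits")
        if len(bits) != 1 << n:
            raise ParseError(f"bits length {len(bits)} != 2^{n}", "/bits")
        return cls(n, tuple(int(c) for c in bits), d.get("label"))


def iter_functions(n: int, require_all_inputs: bool = True) -> Iterator[TruthTable]:
    """Yield all n-input functions in lexicographic bit order (streamed)."""
    if not 1 <= n <= _bits.MAX_INPUTS:
        raise UnsupportedArityError(f"n must be 1..{_bits.MAX_INPUTS}, got {n}")
    rows = _bits.n_rows(n)
    for code in range(1 << rows):
        # lexicographic on the bit vector (row 0 first)
        mask = 0
        for r in range(rows):
            if (code >> (rows - 1 - r)) & 1:
                mask |= 1 << r
        if require_all_inputs and not _bits.depends_on_all(mask, n):
            continue
        yield TruthTable.from_mask(mask, n)


def enumerate_functions(n: int, require_all_inputs: bool = True) -> list:
    """All n-input functions, optionally filtered to those depending on every
    input.  Materializes the list; use :func:`iter_functions` to stream n=4."""
    return list(iter_functions(n, require_all_inputs))


# named tables used throughout tests and examples
def named(name: str) -> TruthTable:
    tables = {
        "AND2": TruthTable.from_bitstring("0001", "AND2"),
        "OR2": TruthTable.from_bitstring("0111", "OR2"),
        "XOR2": TruthTable.from_bitstring("0110", "XOR2"),
        "EQUALS2": TruthTable.from_bitstring("1001", "EQUALS2"),
        "NAND2": TruthTable.from_bitstring("1110", "NAND2"),
        "NOR2": TruthTable.from_bitstring("1000", "NOR2"),
        "IMPLY2": TruthTable.from_bitstring("1101", "IMPLY2"),
        "NIMPLY2": TruthTable.from_bitstring("0010", "NIMPLY2"),
        "NOT1": TruthTable.from_bitstring("10", "NOT1"),
        "XOR3": TruthTable.from_callable(lambda a, b, c: a ^ b ^ c, 3, "XOR3"),
        "EQUALS3": TruthTable.from_callable(
            lambda a, b, c: 1 - (a ^ b ^ c), 3, "EQUALS3"),
        "MAJ3": TruthTable.from_callable(
            lambda a, b, c: int(a + b + c >= 2), 3, "MAJ3"),
    }
    return tables[name]
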