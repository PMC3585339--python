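"""Bit-mask representation of Boolean functions.

An n-input function is a mask of 2**n bits; bit r holds the output on the
assignment encoded by row index r = sum_i a_i * 2**(n-1-i), i.e. input 1 is
the most significant bit of the row index.  All synthesis engines work on
these masks and convert to/from public objects at the boundary.
"""
from functools import lru_cache
from itertools import permutations

MAX_INPUTS = 4


def n_rows(n: int) -> int:
    return 1 << n


def full_mask(n: int) -> int:
    return (1 << n_rows(n)) - 1


def row_index(assignment) -> int:
    r = 0
    n = len(assignment)
    for i, a in enumerate(assignment):
        if a not in (0, 1, False, True):
            raise ValueError(f"binary assignment expected, got {a!r}")
        r |= int(a) << (n - 1 - i)
    return r


@lru_cache(maxsize=None)
def input_masks(n: int):
    """Mask of each input projection x_i (i = 0 .. n-1)."""
    out = []
    for i in range(n):
        m = 0
        for r in range(n_rows(n)):
            if (r >> (n - 1 - i)) & 1:
                m |= 1 << r
        out.append(m)
    return tuple(out)


def mask_from_bits(bits) -> int:
    m = 0
    for r, b in enumerate(bits):
        if b:
            m |= 1 << r
    return m


def bits_from_mask(mask: int, n: int):
    return tuple((mask >> r) & 1 for r in range(n_rows(n)))


def depends_on_input(mask: int, n: int, i: int) -> bool:
    flip = 1 << (n - 1 - i)
    for r in range(n_rows(n)):
        if ((mask >> r) & 1) != ((mask >> (r ^ flip)) & 1):
            return True
    return False


def depends_on_all(mask: int, n: int) -> bool:
    return all(depends_on_input(mask, n, i) for i in range(n))


@lru_cache(maxsize=None)
def permutation_tables(n: int):
    """For each permutation p of the inputs, the induced map on masks.

    table[f] is f with input i renamed to p[i]; used for canonical forms and
    orbit-level caching (every cost in this package is invariant under input
    relabeling).
    """
    tables = []
    for p in permutations(range(n)):
        t = [0] * (full_mask(n) + 1)
        for f in range(full_mask(n) + 1):
            g = 0
            for r in range(n_rows(n)):
                bits = [(r >> (n - 1 - i)) & 1 for i in range(n)]
                r2 = sum(bits[p[i]] << (n - 1 - i) for i in range(n))
                if (f >> r2) & 1:
                    g |= 1 << r
            t[f] = g
        tables.append((p, tuple(t)))
    return tuple(tables)


def orbit(mask: int, n: int):
    return frozenset(t[mask] for _, t in permutation_tables(n))


def orbit_representative(mask: int, n: int) -> int:
    return min(t[mask] for _, t in permutation_tables(n))


def apply_op2(code: int, a: int, b: int, n: int) -> int:
    """Apply the 2-input Boolean operator `code` pointwise to masks a, b.

    code bit (a_bit*2 + b_bit) is the operator's output on that input pair,
    so code 8 = AND, 14 = OR, 6 = XOR, 1 = NOR, 7 = NAND, etc.
    """
    out = 0
    for r in range(n_rows(n)):
        idx = ((a >> r) & 1) * 2 + ((b >> r) & 1)
        if (code >> idx) & 1:
            out |= 1 << r
    return out
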