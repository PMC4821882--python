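"""IUPAC degenerate-base machinery.

A degenerate DNA sequence is a string over the 15-letter IUPAC nucleotide
alphabet; each symbol denotes a set of 1-4 explicit bases, and the sequence
encodes the Cartesian product of those sets.  Its *degeneracy* (the product
of per-position set sizes) is the number of explicit sequences it encodes,
i.e. the size of the one-pot library a single degenerate oligo yields.

Because per-position set sizes are in {1, 2, 3, 4}, achievable library
sizes are exactly the 3-smooth integers 2^a * 3^b.

This module provides expansion, degeneracy arithmetic, and deterministic
enumeration / closed-form counting of all degenerate sequences of a given
length with a given exact degeneracy (the candidate space of the library
search).
"""

from __future__ import annotations

import itertools
from math import factorial
from typing import Iterator

#: Canonical symbol order: explicit bases first, then two-fold, three-fold
#: and four-fold codes.  All enumeration and tie-breaking in this package is
#: lexicographic with respect to this order.
CANONICAL_ORDER = "ACGTRYSWKMBDHVN"

#: IUPAC code -> explicit bases (sorted A<C<G<T).
IUPAC_BASES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: IUPAC code -> degeneracy (size of its base set).
DEGENERACY: dict[str, int] = {s: len(b) for s, b in IUPAC_BASES.items()}

#: Codes grouped by degeneracy, each group in canonical order.
CODES_BY_DEGENERACY: dict[int, str] = {
    1: "ACGT", 2: "RYSWKM", 3: "BDHV", 4: "N",
}

CANONICAL_RANK: dict[str, int] = {s: i for i, s in enumerate(CANONICAL_ORDER)}

BASE_INDEX: dict[str, int] = {"A": 0, "C": 1, "G": 2, "T": 3}


class AlphabetError(ValueError):
    """A symbol outside the 15-letter IUPAC DNA alphabet."""


class SizeError(ValueError):
    """A requested library size that no degenerate sequence can encode."""


def validate(seq: str) -> str:
    """Validate ``seq`` over the IUPAC alphabet, returning it uppercased.

    Raises :class:`AlphabetError` naming the offending character and its
    (0-based) position.
    """
    seq = seq.upper()
    for i, sym in enumerate(seq):
        if sym not in IUPAC_BASES:
            raise AlphabetError(
                f"invalid IUPAC symbol {sym!r} at position {i} in {seq!r}"
            )
    return seq


def degeneracy(seq: str) -> int:
    """Number of explicit sequences encoded by ``seq``."""
    seq = validate(seq)
    d = 1
    for sym in seq:
        d *= DEGENERACY[sym]
    return d


def expand(seq: str) -> list[str]:
    """All explicit ACGT sequences encoded by ``seq``.

    Returned as a duplicate-free list in lexicographic (A<C<G<T) order;
    its length equals ``degeneracy(seq)``.
    """
    seq = validate(seq)
    return [
        "".join(bases) for bases in itertools.product(*(IUPAC_BASES[s] for s in seq))
    ]


def is_achievable(size: int) -> bool:
    """Whether ``size`` can be a degeneracy product, i.e. is 2^a * 3^b."""
    if size < 1:
        return False
    for p in (2, 3):
        while size % p == 0:
            size //= p
    return size == 1


def valid_sizes(max_size: int) -> list[int]:
    """Ascending list of achievable library sizes up to ``max_size``."""
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    sizes = []
    p2 = 1
    while p2 <= max_size:
        v = p2
        while v <= max_size:
            sizes.append(v)
            v *= 3
        p2 *= 2
    return sorted(sizes)


def _factorizations(size: int) -> list[tuple[int, int, int]]:
    """Multiset factorizations of ``size`` into factors {2, 3, 4}.

    Returns (k2, k3, k4) triples: counts of two-fold, three-fold and
    four-fold positions.  Empty if size is not 3-smooth.
    """
    a = 0
    while size % 2 == 0:
        size //= 2
        a += 1
    b = 0
    while size % 3 == 0:
        size //= 3
        b += 1
    if size != 1:
        return []
    return [(a - 2 * k4, b, k4) for k4 in range(a // 2 + 1)]


def count_degenerate(length: int, size: int) -> int:
    """Number of degenerate sequences of ``length`` with degeneracy ``size``.

    Closed form: sum over factorizations of ``size`` into factors {2,3,4}
    of the multinomial placement of degenerate positions times per-factor
    code multiplicities (6 two-fold, 4 three-fold, 1 four-fold codes) times
    4^(number of explicit positions).  Returns 0 for unachievable sizes so
    that size scans are cheap.
    """
    if length < 1 or size < 1:
        raise ValueError("length and size must be >= 1")
    total = 0
    for k2, k3, k4 in _factorizations(size):
        d = k2 + k3 + k4
        if d > length:
            continue
        placements = factorial(length) // (
            factorial(k2) * factorial(k3) * factorial(k4) * factorial(length - d)
        )
        total += placements * 6**k2 * 4**k3 * 4 ** (length - d)
    return total


def count_all_degenerate(length: int) -> int:
    """Total number of degenerate sequences of ``length``: 15^length."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return 15**length


def _nearest_achievable(size: int) -> tuple[int, int]:
    lo = size - 1
    while lo >= 1 and not is_achievable(lo):
        lo -= 1
    hi = size + 1
    while not is_achievable(hi):
        hi += 1
    return max(lo, 1), hi


def enumerate_degenerate(length: int, size: int) -> Iterator[str]:
    """Yield every degenerate sequence of ``length`` with degeneracy ``size``.

    Each sequence is yielded exactly once, in lexicographic order over
    :data:`CANONICAL_ORDER`.  Lazy; the full stream for (L=8, m=24) has
    70,189,056 members.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not is_achievable(size):
        lo, hi = _nearest_achievable(size)
        raise SizeError(
            f"library size {size} is not a product of per-position "
            f"degeneracies (2^a*3^b); nearest achievable sizes are {lo} and {hi}"
        )
    if size > 4**length:
        raise SizeError(f"library size {size} exceeds 4^{length} = {4**length}")
    yield from _enumerate(length, size, "")


def _enumerate(remaining: int, m_left: int, prefix: str) -> Iterator[str]:
    if remaining == 0:
        if m_left == 1:
            yield prefix
        return
    cap = 4 ** (remaining - 1)
    for sym in CANONICAL_ORDER:
        d = DEGENERACY[sym]
        if m_left % d:
            continue
        q = m_left // d
        if q > cap:
            continue
        yield from _enumerate(remaining - 1, q, prefix + sym)


def enumerate_chunks(length: int, size: int, n_chunks: int) -> Iterator[list[str]]:
    """Partition the enumeration into ``n_chunks`` contiguous chunks.

    Concatenating the yielded lists reproduces ``enumerate_degenerate``
    exactly; chunk sizes differ by at most one.
    """
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    total = count_degenerate(length, size)
    it = enumerate_degenerate(length, size)
    base, extra = divmod(total, n_chunks)
    for i in range(n_chunks):
        yield list(itertools.islice(it, base + (1 if i < extra else 0)))


def write_database(path, length: int, size: int) -> int:
    """Dump the enumeration for (length, size) as plain text, one sequence
    per line, in canonical order.  Returns the number of lines written."""
    n = 0
    with open(path, "w") as fh:
        for seq in enumerate_degenerate(length, size):
            fh.write(seq + "\n")
            n += 1
    return n
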