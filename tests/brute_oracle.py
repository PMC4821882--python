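"""Independent brute-force oracles for the test suite.

Deliberately written from first principles (own IUPAC table, direct
transcription of the H_n/n empirical-CDF definition, full enumeration of
all 15^L degenerate strings) and kept free of any import from the package
paths they check.
"""

import itertools
from math import prod

ORACLE_BASES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
ORACLE_ORDER = "ACGTRYSWKMBDHVN"


def oracle_expand(seq):
    return ["".join(p) for p in itertools.product(*(ORACLE_BASES[s] for s in seq))]


def oracle_degeneracy(seq):
    return prod(len(ORACLE_BASES[s]) for s in seq)


def oracle_ks(values, cdf):
    """sup_x |F_actual(x) - F_target(x)| by direct evaluation.

    F_actual(x) = (# values smaller than x) / n; for a continuous target
    the supremum is attained arbitrarily close to a sample point, so both
    one-sided limits at every sample point are checked.
    """
    xs = sorted(values)
    n = len(xs)
    d = 0.0
    for x in xs:
        below = sum(1 for v in xs if v < x) / n
        at_or_below = sum(1 for v in xs if v <= x) / n
        ft = cdf(x)
        d = max(d, abs(ft - below), abs(ft - at_or_below))
    return d


def oracle_grid_ks(values, cdf, lo, hi, n_grid=100_000):
    """Dense-grid sup of |F_actual - F_target| (approximate to ~1/n_grid)."""
    xs = sorted(values)
    n = len(xs)
    d = 0.0
    for i in range(n_grid + 1):
        x = lo + (hi - lo) * i / n_grid
        h = sum(1 for v in xs if v < x) / n
        d = max(d, abs(cdf(x) - h))
    return d


def oracle_all_degenerate(length):
    """All 15^length degenerate strings (lists materialized; keep L <= 4)."""
    return ["".join(p) for p in itertools.product(ORACLE_ORDER, repeat=length)]


def oracle_best_library(entries, size, cdf):
    """Argmin of the KS distance over every degenerate sequence of the
    window whose degeneracy equals ``size``; ties broken by canonical
    symbol order.  Returns (best_sequence, best_dks)."""
    length = len(next(iter(entries)))
    rank = {s: i for i, s in enumerate(ORACLE_ORDER)}
    best = None
    for seq_tuple in itertools.product(ORACLE_ORDER, repeat=length):
        if oracle_degeneracy(seq_tuple) != size:
            continue
        seq = "".join(seq_tuple)
        members = [entries[m] for m in oracle_expand(seq)]
        d = oracle_ks(members, cdf)
        key = (d, tuple(rank[s] for s in seq))
        if best is None or key < best[0]:
            best = (key, seq, d)
    return best[1], best[2]
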