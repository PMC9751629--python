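"""Independent brute-force oracles, deliberately naive.

These recompute the same quantities as the package by explicit enumeration
and loops, sharing no code path with the implementation they check.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def brute_force_balance(
    compositions: list[dict[str, int]],
    charges: list[int],
    sides: list[str],
    max_coeff: int = 10,
) -> list[int] | None:
    """Smallest conservation-satisfying positive integer coefficients.

    Exhaustive search over coefficient tuples in 1..max_coeff, ordered by
    coefficient sum then lexicographically; returns None when no tuple
    conserves every element and charge.
    """
    elements = sorted({e for comp in compositions for e in comp})
    candidates = []
    for coeffs in itertools.product(range(1, max_coeff + 1), repeat=len(compositions)):
        ok = True
        for e in elements:
            lhs = sum(
                c * comp.get(e, 0)
                for c, comp, side in zip(coeffs, compositions, sides)
                if side == "reactant"
            )
            rhs = sum(
                c * comp.get(e, 0)
                for c, comp, side in zip(coeffs, compositions, sides)
                if side == "product"
            )
            if lhs != rhs:
                ok = False
                break
        if ok:
            lhs_q = sum(
                c * q for c, q, side in zip(coeffs, charges, sides) if side == "reactant"
            )
            rhs_q = sum(
                c * q for c, q, side in zip(coeffs, charges, sides) if side == "product"
            )
            if lhs_q == rhs_q:
                candidates.append(coeffs)
    if not candidates:
        return None
    best = min(candidates, key=lambda t: (sum(t), t))
    g = math.gcd(*best)
    return [c // g for c in best]


def loop_nsaf(
    counts: dict[str, int], lengths: dict[str, int]
) -> dict[str, Fraction]:
    """NSAF for one replicate by explicit loops and exact rationals."""
    safs = {}
    for pid in counts:
        if counts[pid] > 0:
            safs[pid] = Fraction(counts[pid], lengths[pid])
    total = Fraction(0)
    for v in safs.values():
        total += v
    return {pid: v / total for pid, v in safs.items()}
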