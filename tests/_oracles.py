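"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each statistic from first principles —
explicit enumeration of observation pairs for tau-b and explicit 2x2
table construction for the target MCC — and share no code with the
package internals.
"""

from __future__ import annotations

import math
from itertools import combinations


def brute_tau_b(x, y) -> float:
    """Tau-b by classifying all m(m-1)/2 pairs explicitly."""
    m = len(x)
    if m < 2:
        return 0.0
    nc = nd = n1 = n2 = 0
    for i, j in combinations(range(m), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            continue
        if dx == 0:
            n1 += 1
        elif dy == 0:
            n2 += 1
        elif (dx > 0) == (dy > 0):
            nc += 1
        else:
            nd += 1
    denom = math.sqrt((nc + nd + n1) * (nc + nd + n2))
    if denom == 0:
        return 0.0
    return (nc - nd) / denom


def brute_target_mcc(targets_a, targets_b, universe) -> float:
    """MCC from an explicitly enumerated per-protein 2x2 table."""
    tp = fp = fn = tn = 0
    for protein in universe:
        in_a, in_b = protein in targets_a, protein in targets_b
        if in_a and in_b:
            tp += 1
        elif in_a:
            fn += 1
        elif in_b:
            fp += 1
        else:
            tn += 1
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def brute_tanimoto(bits_a: set, bits_b: set) -> float:
    union = bits_a | bits_b
    if not union:
        return 0.0
    return len(bits_a & bits_b) / len(union)
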