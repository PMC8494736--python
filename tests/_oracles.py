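"""Independent brute-force oracles used to validate the fast paths.

Everything here is deliberately naive: exhaustive enumeration and direct
formula evaluation, sharing no code with the package internals.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np


def enumerate_fixed_margin(row_sums, col_sums):
    """All binary matrices with the given row and column sums.

    Recursive enumeration over rows; feasible only for tiny matrices.
    """
    row_sums = list(row_sums)
    col_sums = list(col_sums)
    n_cols = len(col_sums)
    out = []

    def rec(i, remaining_cols, rows):
        if i == len(row_sums):
            if all(c == 0 for c in remaining_cols):
                out.append(np.array(rows, dtype=bool))
            return
        # prune: enough column capacity must remain
        if sum(remaining_cols) < sum(row_sums[i:]):
            return
        avail = [j for j in range(n_cols) if remaining_cols[j] > 0]
        for combo in itertools.combinations(avail, row_sums[i]):
            row = [False] * n_cols
            nxt = list(remaining_cols)
            for j in combo:
                row[j] = True
                nxt[j] -= 1
            rec(i + 1, nxt, rows + [row])

    rec(0, col_sums, [])
    return out


def exact_pair_tail_probs(matrices, a, b, co_obs):
    """Exact P(co >= co_obs) and P(co <= co_obs) for genes a, b over the
    uniform distribution on the enumerated fixed-margin matrices."""
    counts = np.array([int((m[a] & m[b]).sum()) for m in matrices])
    return (np.mean(counts >= co_obs), np.mean(counts <= co_obs))


def brute_force_fdr(observed, null):
    """Literal evaluation of the empirical-FDR definition and the
    suffix-minimum q-value rule, with exact rational arithmetic."""
    observed = list(observed)
    null = list(null)
    fdr = []
    for p_star in observed:
        v = Fraction(sum(1 for q in null if q <= p_star), len(null)) \
            * len(observed)
        r = sum(1 for q in observed if q <= p_star)
        fdr.append(v / r)
    q = []
    for p_star, _ in zip(observed, fdr):
        candidates = [f for p, f in zip(observed, fdr) if p >= p_star]
        q.append(min(min(candidates), Fraction(1)))
    return [float(x) for x in fdr], [float(x) for x in q]


def sequential_wor_inclusion_probs(weights, k):
    """Exact inclusion probability of each item under sequential weighted
    sampling without replacement (renormalizing after each draw), by
    summing over all ordered draw sequences."""
    weights = np.asarray(weights, dtype=float)
    n = len(weights)
    probs = np.zeros(n)
    for seq in itertools.permutations(range(n), k):
        p = 1.0
        mass = 1.0
        for item in seq:
            p *= weights[item] / mass
            mass -= weights[item]
        for item in seq:
            probs[item] += p
    return probs
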