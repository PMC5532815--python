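"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own algorithms: structures are found
by exhaustive enumeration of nested pairings, not dynamic programming.
"""

import numpy as np

WEIGHTS = {("G", "C"): 3, ("C", "G"): 3, ("A", "U"): 2, ("U", "A"): 2,
           ("G", "U"): 1, ("U", "G"): 1}
GU = {("G", "U"), ("U", "G")}


def enumerate_structures(seq, min_loop=3):
    """Yield every pseudoknot-free set of admissible pairs of ``seq``."""
    n = len(seq)

    def rec(i, j):
        if j - i < min_loop + 1:
            yield frozenset()
            return
        yield from rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in WEIGHTS:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        yield frozenset({(i, k)}) | left | right

    return rec(0, n - 1)


def gu_helix_end_legal(seq, pairs):
    """True iff every G-U pair is stacked directly between two other pairs."""
    ps = set(pairs)
    for a, b in pairs:
        if (seq[a], seq[b]) in GU:
            if (a - 1, b + 1) not in ps or (a + 1, b - 1) not in ps:
                return False
    return True


def max_weighted_pairing(seq, min_loop=3):
    """Exhaustive maximum of the weighted-pairing objective under the
    no-terminal-GU rule. Exponential; only for short sequences."""
    best = 0.0
    for pairs in enumerate_structures(seq, min_loop):
        if gu_helix_end_legal(seq, pairs):
            best = max(best, sum(WEIGHTS[(seq[a], seq[b])] for a, b in pairs))
    return best


def bh_step_up(p_values, q):
    """Textbook Benjamini-Hochberg step-up, independent of statsmodels."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / m:
            k = rank
    flags = np.zeros(m, dtype=bool)
    flags[order[:k]] = True
    return flags
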