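"""Independent reference computations used to check the implementation.

Each oracle takes the slow, direct route — explicit pairwise loops, direct
cell sums, exhaustive subset search — so that agreement with the package's
faster code is meaningful.
"""

from itertools import combinations

import numpy as np

from tiestar.independence import g2_test


def pairwise_auc(scores, labels):
    """O(n²) Mann–Whitney AUC: loop over every (case, control) pair."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            if c > d:
                total += 1.0
            elif c == d:
                total += 0.5
    return total / (len(cases) * len(controls))


def g2_from_table(table):
    """Direct 2×2 (or r×c) likelihood-ratio statistic: 2 Σ O ln(O/E) cell by cell."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    g2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            o = table[i, j]
            if o > 0:
                e = table[i, :].sum() * table[:, j].sum() / total
                g2 += 2.0 * o * np.log(o / e)
    return g2


def table_to_columns(table):
    """Expand a contingency table into paired x/y code columns."""
    xs, ys = [], []
    for i, row in enumerate(np.asarray(table)):
        for j, count in enumerate(row):
            xs.extend([i] * int(count))
            ys.extend([j] * int(count))
    return np.array(xs), np.array(ys)


def minimal_sufficient_sets(columns, y, ci_config):
    """Exhaustive search for all minimal sufficient feature sets.

    A set S is sufficient when every feature outside S is rendered
    independent of the outcome by some conditioning subset of S with size
    <= max_k (the same G² criterion the learner uses, with its
    unreliable-test policy).  Minimal sufficient sets are the sufficient
    sets with no sufficient proper subset.  Brute force over all 2^p
    subsets; feasible for p <= 10.
    """
    names = sorted(columns)
    cache = {}

    def independent(f, Z):
        key = (f, Z)
        if key not in cache:
            res = g2_test(columns[f], y, [columns[z] for z in Z], ci_config)
            cache[key] = res.reliable and res.p_value > ci_config.alpha
        return cache[key]

    def sufficient(S):
        for f in names:
            if f in S:
                continue
            hit = False
            for size in range(0, min(ci_config.max_k, len(S)) + 1):
                for Z in combinations(sorted(S), size):
                    if independent(f, Z):
                        hit = True
                        break
                if hit:
                    break
            if not hit:
                return False
        return True

    sufficient_sets = []
    for size in range(0, len(names) + 1):
        for S in combinations(names, size):
            if sufficient(frozenset(S)):
                sufficient_sets.append(frozenset(S))
    return [S for S in sufficient_sets if not any(T < S for T in sufficient_sets)]
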