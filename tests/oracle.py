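"""Plain nested-loop reference implementation of the reproducibility
optimization, independent of the vectorized code under test.

Given the same resampling plans, it recomputes every surface cell (R, R0,
s, Z) and the argmax with Python loops, set arithmetic and the statistics
module only.  Shared with the package: the resampling draws themselves (the
random plans are inputs, not the computation being checked).
"""

import math
import statistics

NEG_INF = float("-inf")
BIG = 1.7976931348623157e308  # finite sentinel for 0/0-variance shifts


def d_values(columns, group1, group2, alpha1, alpha2):
    """d for every feature of a dataset given as a list of rows."""
    out = []
    n1, n2 = len(group1), len(group2)
    for row in columns:
        x1 = [row[j] for j in group1]
        x2 = [row[j] for j in group2]
        m1 = sum(x1) / n1
        m2 = sum(x2) / n2
        ss1 = sum((v - m1) ** 2 for v in x1)
        ss2 = sum((v - m2) ** 2 for v in x2)
        s = math.sqrt((ss1 + ss2) / (n1 + n2 - 2) * (1 / n1 + 1 / n2))
        num = abs(m1 - m2)
        denom = alpha1 + alpha2 * s
        if denom == 0:
            out.append(BIG if num > 0 else 0.0)
        else:
            out.append(num / denom)
    return out


def ranking(d):
    """Indices by decreasing d, ties by original order."""
    return sorted(range(len(d)), key=lambda i: (-d[i], i))


def overlap(rank_a, rank_b, k):
    return len(set(rank_a[:k]) & set(rank_b[:k])) / k


def gather(values, draw):
    """Rows of values restricted/reordered to the drawn columns."""
    return [[row[j] for j in draw] for row in values]


def pair_overlaps(values, draws, group1, group2, alpha1, alpha2, k_grid):
    """One overlap row per disjoint consecutive draw pair."""
    rows = []
    for i in range(len(draws) // 2):
        da = d_values(gather(values, draws[2 * i]), group1, group2,
                      alpha1, alpha2)
        db = d_values(gather(values, draws[2 * i + 1]), group1, group2,
                      alpha1, alpha2)
        ra, rb = ranking(da), ranking(db)
        rows.append([overlap(ra, rb, k) for k in k_grid])
    return rows


def surfaces(values, boot_draws, perm_draws, group1, group2, params, k_grid):
    """R, R0, s, Z keyed by ((alpha1, alpha2), k)."""
    R, R0, S, Z = {}, {}, {}, {}
    for alpha1, alpha2 in params:
        bo = pair_overlaps(values, boot_draws, group1, group2,
                           alpha1, alpha2, k_grid)
        po = pair_overlaps(values, perm_draws, group1, group2,
                           alpha1, alpha2, k_grid)
        for ki, k in enumerate(k_grid):
            bcol = [row[ki] for row in bo]
            pcol = [row[ki] for row in po]
            r = sum(bcol) / len(bcol)
            r0 = sum(pcol) / len(pcol)
            s = statistics.stdev(bcol) if len(bcol) > 1 else 0.0
            key = ((alpha1, alpha2), k)
            R[key], R0[key], S[key] = r, r0, s
            Z[key] = (r - r0) / s if s > 0 else NEG_INF
    return R, R0, S, Z


def argmax(Z):
    """Maximal Z with ties by smallest k, smallest alpha1, alpha2=1 first."""
    best_z = max(Z.values())
    cands = [((a1, a2), k) for ((a1, a2), k), z in Z.items() if z == best_z]
    cands.sort(key=lambda c: (c[1], c[0][0], -c[0][1]))
    return cands[0], best_z
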