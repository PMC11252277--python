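"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: the Ward oracle
agglomerates by exhaustive evaluation of the within-cluster
sum-of-squares increase, and the permutation oracle enumerates the full
permutation group.
"""
from fractions import Fraction
from itertools import combinations, permutations

import numpy as np
from scipy.stats import rankdata


def counting_formula_exact(c, v_c, v_t, n, total_squares=1000) -> Fraction:
    """Literal rational evaluation of C * V_C * total / (V_T * N)."""
    return (
        Fraction(c) * Fraction(v_c) * Fraction(total_squares)
    ) / (Fraction(v_t) * Fraction(n))


def ward_partitions_bruteforce(points: np.ndarray) -> list[set[frozenset]]:
    """Partitions after each merge of exhaustive Ward agglomeration.

    At every step the pair whose merge least increases the total
    within-cluster sum of squares is joined (Ward's criterion:
    |A||B|/(|A|+|B|) * ||mean_A - mean_B||^2).
    """
    clusters = [frozenset([i]) for i in range(len(points))]
    out = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            ma = points[list(clusters[a])].mean(axis=0)
            mb = points[list(clusters[b])].mean(axis=0)
            na, nb = len(clusters[a]), len(clusters[b])
            delta = na * nb / (na + nb) * float(((ma - mb) ** 2).sum())
            if best is None or delta < best[0]:
                best = (delta, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
        out.append(set(clusters))
    return out


def scipy_ward_partitions(linkage: np.ndarray, n: int) -> list[set[frozenset]]:
    """Partition after each merge, reconstructed from a linkage matrix."""
    members = {i: frozenset([i]) for i in range(n)}
    active = set(members)
    out = []
    for step, (i, j, _, _) in enumerate(linkage):
        new_id = n + step
        members[new_id] = members[int(i)] | members[int(j)]
        active -= {int(i), int(j)}
        active.add(new_id)
        out.append({members[k] for k in active})
    return out


def spearman_of_condensed(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def relate_p_exhaustive(d_bio: np.ndarray, d_env: np.ndarray) -> float:
    """Exact one-sided p over all n! joint row/column relabelings."""
    n = d_bio.shape[0]
    iu = np.triu_indices(n, 1)
    obs = spearman_of_condensed(d_bio[iu], d_env[iu])
    count = 0
    total = 0
    for perm in permutations(range(n)):
        p = np.array(perm)
        rho = spearman_of_condensed(d_bio[iu], d_env[p][:, p][iu])
        count += rho >= obs - 1e-12
        total += 1
    return count / total
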