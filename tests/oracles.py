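"""Brute-force / closed-form reference implementations used to pin the
fast library paths.  Everything here is deliberately naive: explicit
loops and textbook formulas, independent of the package internals."""

from __future__ import annotations

import itertools
import math

import numpy as np


def pearson_brute(x, y) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def rank_midrank(v):
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        r = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    return ranks


def spearman_brute(x, y) -> float:
    return pearson_brute(rank_midrank(x), rank_midrank(y))


def kendall_brute(x, y) -> float:
    """tau-b by explicit concordant/discordant pair counting."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            a = int(x[i] > x[j]) - int(x[i] < x[j])
            b = int(y[i] > y[j]) - int(y[i] < y[j])
            if a == 0 and b == 0:
                continue
            if a == 0:
                tx += 1
            elif b == 0:
                ty += 1
            elif a == b:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - count_tie_pairs(x)) * (n0 - count_tie_pairs(y)))
    return (conc - disc) / denom


def count_tie_pairs(v) -> int:
    return sum(1 for i in range(len(v)) for j in range(i + 1, len(v))
               if v[i] == v[j])


def hoeffding_brute(x, y) -> float:
    """Hoeffding's D via explicit per-point loops (midrank ties)."""
    n = len(x)
    R = rank_midrank(x)
    S = rank_midrank(y)
    Q = []
    for i in range(n):
        q = 0.0
        for j in range(n):
            if j == i:
                continue
            lx = 1.0 if x[j] < x[i] else (0.5 if x[j] == x[i] else 0.0)
            ly = 1.0 if y[j] < y[i] else (0.5 if y[j] == y[i] else 0.0)
            q += lx * ly
        Q.append(q)
    d1 = sum(q * (q - 1) for q in Q)
    d2 = sum((R[i] - 1) * (R[i] - 2) * (S[i] - 1) * (S[i] - 2) for i in range(n))
    d3 = sum((R[i] - 2) * (S[i] - 2) * Q[i] for i in range(n))
    return 30.0 * ((n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3) / (
        n * (n - 1) * (n - 2) * (n - 3) * (n - 4))


def dcor_brute(x, y) -> float:
    """Distance correlation via explicit double-centred loops."""
    n = len(x)

    def centred(v):
        d = [[abs(v[i] - v[j]) for j in range(n)] for i in range(n)]
        rm = [sum(row) / n for row in d]
        cm = [sum(d[i][j] for i in range(n)) / n for j in range(n)]
        gm = sum(rm) / n
        return [[d[i][j] - rm[i] - cm[j] + gm for j in range(n)]
                for i in range(n)]

    A, B = centred(x), centred(y)
    dxy = sum(A[i][j] * B[i][j] for i in range(n) for j in range(n)) / n ** 2
    dxx = sum(A[i][j] ** 2 for i in range(n) for j in range(n)) / n ** 2
    dyy = sum(B[i][j] ** 2 for i in range(n) for j in range(n)) / n ** 2
    if dxx * dyy == 0:
        return 0.0
    return math.sqrt(max(0.0, dxy / math.sqrt(dxx * dyy)))


def hypergeom_tail_brute(overlap, universe, k1, k2) -> float:
    """P(X >= overlap) by summing the exact pmf."""
    total = 0.0
    denom = math.comb(universe, k2)
    for x in range(overlap, min(k1, k2) + 1):
        if k1 >= x and universe - k1 >= k2 - x:
            total += math.comb(k1, x) * math.comb(universe - k1, k2 - x) / denom
    return min(1.0, total)


def maximal_bicliques_brute(left: list, right: list,
                            edges: set) -> set[tuple[frozenset, frozenset]]:
    """All maximal bicliques via Galois closure over left-side subsets."""
    nbr = {l: frozenset(r for r in right if (l, r) in edges) for l in left}
    found = set()
    for size in range(1, len(left) + 1):
        for A in itertools.combinations(left, size):
            B = frozenset.intersection(*(nbr[a] for a in A))
            if not B:
                continue
            A_closed = frozenset(l for l in left if B <= nbr[l])
            found.add((A_closed, B))
    return found


def is_biclique(A, B, edges) -> bool:
    return all((a, b) in edges for a in A for b in B)


def is_maximal_biclique(A, B, left, right, edges) -> bool:
    if not is_biclique(A, B, edges):
        return False
    for l in set(left) - set(A):
        if is_biclique(set(A) | {l}, B, edges):
            return False
    for r in set(right) - set(B):
        if is_biclique(A, set(B) | {r}, edges):
            return False
    return True


def partial_corr_first_order(rxy, rxz, ryz) -> float:
    return (rxy - rxz * ryz) / math.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))


def exact_sample_correlation_data(R: np.ndarray, m: int,
                                  seed: int = 0) -> np.ndarray:
    """m x k data whose *sample* correlation matrix equals R exactly
    (empirical whitening followed by colouring)."""
    rng = np.random.default_rng(seed)
    k = R.shape[0]
    W = rng.normal(size=(m, k))
    W -= W.mean(axis=0)
    cov = W.T @ W / m
    Wh = W @ np.linalg.inv(np.linalg.cholesky(cov)).T
    return Wh @ np.linalg.cholesky(R).T
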