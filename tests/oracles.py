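"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the mathematical definitions with plain
loops and ``math`` — deliberately sharing no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def brute_overall_background(matrix: np.ndarray) -> dict[int, float]:
    """Mean of finite entries at each |i-j| via an explicit double loop."""
    n = matrix.shape[0]
    sums: dict[int, list[float]] = {}
    for i in range(n):
        for j in range(i, n):
            v = matrix[i, j]
            if math.isfinite(v):
                sums.setdefault(j - i, []).append(v)
    return {d: sum(vs) / len(vs) for d, vs in sums.items()}


def brute_hamming_similarity(a, b) -> float:
    h = sum(1 for x, y in zip(a, b) if x != y)
    return 1.0 - h / len(a)


def brute_seed_cluster(rows: list[list[int]], threshold: float) -> list[list[int]]:
    """Greedy seeded clustering over pre-ranked rows; returns index clusters."""
    n = len(rows)
    assigned = [False] * n
    clusters = []
    for i in range(n):
        if assigned[i]:
            continue
        members = [i]
        assigned[i] = True
        for j in range(n):
            if not assigned[j] and brute_hamming_similarity(rows[i], rows[j]) >= threshold - 1e-12:
                members.append(j)
                assigned[j] = True
        clusters.append(members)
    return clusters


def brute_jaccard_distance(a, b) -> float:
    inter = sum(1 for x, y in zip(a, b) if x and y)
    union = sum(1 for x, y in zip(a, b) if x or y)
    return 1.0 - inter / union


def brute_complementing_score(counts: dict[str, int]) -> float:
    pairs = [("A>T", "T>A"), ("C>G", "G>C"), ("A>C", "C>A"),
             ("A>G", "G>A"), ("C>T", "T>C"), ("G>T", "T>G")]
    total = sum(counts.values())
    paired = sum(min(counts.get(x, 0), counts.get(y, 0)) for x, y in pairs)
    return 1.0 - 2.0 * paired / total


def brute_entropy_score(seqs: list[str]) -> float:
    """Mean column Shannon entropy (base 2) of equal-length sequences."""
    length = len(seqs[0])
    total = 0.0
    for col in range(length):
        freq: dict[str, int] = {}
        for s in seqs:
            freq[s[col]] = freq.get(s[col], 0) + 1
        ent = 0.0
        for c in freq.values():
            p = c / len(seqs)
            ent -= p * math.log2(p)
        total += ent
    return total / length


def brute_hypergeom_tail(N: int, K: int, n: int, r: int) -> float:
    """P(X >= r) by summing the pmf with exact binomial coefficients."""
    denom = math.comb(N, n)
    total = 0
    for x in range(r, min(n, K) + 1):
        if n - x <= N - K:
            total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / denom


def brute_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson correlation written out long-hand."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)
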