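"""Independent brute-force oracles used to check the library's indices.

These deliberately avoid the library's code paths: per-term python sums for
entropies, a cumulative scan for D50, the pairwise mean-absolute-difference
form of the Gini coefficient, explicit k-mer vectors over the union
vocabulary for the spectrum kernel, and Floyd-Warshall transitive closure
for network components.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def shannon_oracle(freqs) -> float:
    return -sum(p * math.log(p) for p in freqs if p > 0)


def renyi_oracle(freqs, alpha: float) -> float:
    pos = [p for p in freqs if p > 0]
    if alpha == 0:
        return math.log(len(pos))
    if alpha == 1:
        return shannon_oracle(pos)
    if math.isinf(alpha):
        return -math.log(max(pos))
    return math.log(sum(p**alpha for p in pos)) / (1 - alpha)


def d50_oracle(freqs) -> int:
    acc = 0.0
    for k, p in enumerate(sorted((p for p in freqs if p > 0), reverse=True), start=1):
        acc += p
        if acc >= 0.5 - 1e-12:
            return k
    return 0


def clonality_oracle(freqs) -> float:
    n = sum(1 for p in freqs if p > 0)
    if n < 2:
        return 1.0 if n == 1 else float("nan")
    return 1 - shannon_oracle(freqs) / math.log(n)


def gini_oracle(freqs) -> float:
    """Mean absolute difference / (2 * mean), the definitional form."""
    p = np.asarray([x for x in freqs if x > 0], dtype=float)
    if p.size <= 1:
        return 0.0
    mad = np.abs(p[:, None] - p[None, :]).mean()
    return float(mad / (2 * p.mean()))


def spectrum_oracle(x: str, y: str, k: int = 3) -> float:
    if len(x) < k or len(y) < k:
        return 0.0
    cx = Counter(x[i : i + k] for i in range(len(x) - k + 1))
    cy = Counter(y[i : i + k] for i in range(len(y) - k + 1))
    vocab = sorted(set(cx) | set(cy))
    vx = [cx.get(m, 0) for m in vocab]
    vy = [cy.get(m, 0) for m in vocab]
    dot = sum(a * b for a, b in zip(vx, vy))
    nx = math.sqrt(sum(a * a for a in vx))
    ny = math.sqrt(sum(b * b for b in vy))
    return dot / (nx * ny)


def components_oracle(seqs: list[str], threshold: float = 0.8, k: int = 3):
    """Connected components via O(n^3) boolean transitive closure."""
    n = len(seqs)
    adj = [[i == j for j in range(n)] for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if spectrum_oracle(seqs[i], seqs[j], k) > threshold:
                adj[i][j] = adj[j][i] = True
    for m in range(n):
        for i in range(n):
            if adj[i][m]:
                row_m = adj[m]
                row_i = adj[i]
                for j in range(n):
                    if row_m[j]:
                        row_i[j] = True
    comps: list[set[str]] = []
    seen: set[int] = set()
    for i in range(n):
        if i in seen:
            continue
        comp = {j for j in range(n) if adj[i][j]}
        seen |= comp
        comps.append({seqs[j] for j in comp})
    return comps
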