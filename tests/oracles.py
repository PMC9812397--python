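"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the library's own code paths: plain dynamic
programming, exhaustive enumeration, and single-pass recounting.
"""

from __future__ import annotations

import math
from collections import Counter


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook DP edit distance; N mismatches everything including N."""

    def eq(x: str, y: str) -> bool:
        return x == y and x != "N"

    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (0 if eq(ca, cb) else 1)))
        prev = cur
    return prev[-1]


def brute_force_knee(counts: list[int]) -> int:
    """Largest count drop to the next level among collapsed log-log
    vertices above the endpoint chord (falling back to all interior
    vertices); ties to the smaller rank.  Mirrors the documented
    definition by direct enumeration, comparing count ratios instead
    of log differences."""
    levels = []
    for rank, c in enumerate(counts, 1):
        if levels and levels[-1][1] == c:
            levels[-1] = (rank, c)
        else:
            levels.append((rank, c))
    if len(counts) <= 2 or len(levels) == 1:
        return len(counts)
    if len(levels) == 2:
        return levels[0][0]
    pts = [(math.log10(r), math.log10(c)) for r, c in levels]
    p0, p1 = pts[0], pts[-1]
    d = (p1[0] - p0[0], p1[1] - p0[1])
    L2 = d[0] ** 2 + d[1] ** 2

    def residual(i):
        v = (pts[i][0] - p0[0], pts[i][1] - p0[1])
        t = (v[0] * d[0] + v[1] * d[1]) / L2
        return (v[0] - t * d[0], v[1] - t * d[1])

    def above(i):
        # residual points away from the chord on the upper-left side
        rx, ry = residual(i)
        return math.hypot(rx, ry) > 1e-12 and (d[0] * ry - d[1] * rx) > 0

    interior = list(range(1, len(pts) - 1))
    cands = [i for i in interior if above(i)] or interior
    best = max(cands, key=lambda i: (levels[i][1] / levels[i + 1][1], -levels[i][0]))
    return levels[best][0]


def nearest_by_enumeration(seq: str, pool: list[tuple[str, int]], max_dist: int):
    """(target or None) under: min DP distance <= max_dist, ties by
    higher count then lexicographic; exhaustive over the pool."""
    scored = [(dp_levenshtein(seq, cand), -count, cand) for cand, count in pool]
    scored = [s for s in scored if s[0] <= max_dist]
    if not scored:
        return None
    return min(scored)[2]


def single_pass_tally(sequences_by_segment: dict[str, list[str]]) -> dict[str, Counter]:
    return {seg: Counter(seqs) for seg, seqs in sequences_by_segment.items()}


def min_species_per_variable(observations: dict[tuple, list[tuple]]) -> int:
    """Minimum number of value species a topology-preserving
    renumbering needs: by brute force this is the largest number of
    distinct values observed under any single parent path."""
    return max((len(set(vals)) for vals in observations.values()), default=0)
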