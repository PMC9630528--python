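"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's matrix-algebra code paths: the census
oracle enumerates all ordered node triples with set lookups, and the backbone
oracle is a plain sort-and-cumulative-sum.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def brute_force_census(n: int, edges, mode: str):
    """Exhaustive triple enumeration census.

    Returns (ffl_target, zl, nbr_center, total_involvement, edge_participation)
    with the participation dict keyed by (source, target).
    """
    E = {(int(s), int(t)) for s, t in edges}
    ffl = np.zeros(n, dtype=int)
    zl = np.zeros(n, dtype=int)
    nbr = np.zeros(n, dtype=int)
    inv = np.zeros(n, dtype=int)
    part = {e: 0 for e in E}

    def record(nodes, occ_edges):
        for x in nodes:
            inv[x] += 1
        for e in occ_edges:
            part[e] += 1

    for a, b, c in permutations(range(n), 3):
        if (a, b) in E and (b, c) in E and (a, c) in E:
            if mode == "pattern" or not ((b, a) in E or (c, b) in E or (c, a) in E):
                ffl[c] += 1
                record((a, b, c), [(a, b), (b, c), (a, c)])
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in E and (j, i) in E:
                zl[i] += 1
                zl[j] += 1
                record((i, j), [(i, j), (j, i)])
    for s, c, p in permutations(range(n), 3):
        if (c, p) in E and (p, c) in E and (s, c) in E:
            if mode == "pattern" or not ((c, s) in E or (s, p) in E or (p, s) in E):
                nbr[c] += 1
                record((s, c, p), [(s, c), (c, p), (p, c)])
    return ffl, zl, nbr, inv, part


def sort_cumsum_backbone(pairs: dict[tuple[int, int], float], rho: float):
    """Reference backbone: drop self-loops, sort by (-flow, src, tgt), take the
    shortest prefix whose cumulative flow reaches rho * total."""
    items = sorted(
        ((s, t, v) for (s, t), v in pairs.items() if s != t),
        key=lambda x: (-x[2], x[0], x[1]),
    )
    total = sum(v for _, _, v in items)
    acc = 0.0
    edges = []
    for s, t, v in items:
        edges.append((s, t))
        acc += v
        if acc >= rho * total - 1e-12 * total:
            break
    return set(edges), acc / total
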