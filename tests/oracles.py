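"""Independent reference implementations used as test oracles.

These deliberately share no code with the package: a quadratic
three-state Gotoh dynamic program for local alignment scores, an
unpruned dense-matrix Markov clustering reference, and brute-force
recount/union-find helpers for the host network.
"""

from __future__ import annotations

import numpy as np

from tbssr.records import AA_ALPHABET_X


def gotoh_local_score(a: str, b: str, sub: np.ndarray, go: int, ge: int) -> int:
    """Brute-force affine-gap Smith-Waterman score (gap k costs go+k*ge)."""
    idx = {c: i for i, c in enumerate(AA_ALPHABET_X)}
    n, m = len(a), len(b)
    NEG = -(10 ** 9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - go - ge, E[i][j - 1] - ge)
            F[i][j] = max(H[i - 1][j] - go - ge, F[i - 1][j] - ge)
            s = sub[idx[a[i - 1]], idx[b[j - 1]]]
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def dense_mcl_reference(
    weights: np.ndarray,
    inflation: float,
    tol: float = 1e-12,
    max_iter: int = 1000,
    eps: float = 1e-5,
) -> list[frozenset[int]]:
    """Unpruned dense MCL; clusters as frozensets of node indices.

    Self loops at the maximum incident weight (unit for isolated
    nodes); limit matrix read through attractor rows, overlapping
    attractor supports merged, remaining nodes assigned to the system
    holding their largest limit weight.
    """
    n = weights.shape[0]
    a = weights.astype(float).copy()
    loops = a.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(a, loops)
    m = a / a.sum(axis=0)
    for _ in range(max_iter):
        prev = m
        m = m @ m
        m = np.power(m, inflation)
        m = m / m.sum(axis=0)
        if np.abs(m - prev).max() < tol:
            break
    diag = np.diag(m)
    attractors = [i for i in range(n) if diag[i] >= eps]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    aset = set(attractors)
    for i in attractors:
        for j in range(n):
            if m[i, j] >= eps and j in aset:
                union(i, j)
    system_of: dict[int, int] = {i: find(i) for i in attractors}
    assigned: dict[int, int] = dict(system_of)
    for j in range(n):
        if j in assigned:
            continue
        best_w, best_s = 0.0, None
        for i in attractors:
            if m[i, j] >= eps:
                s = system_of[i]
                if m[i, j] > best_w or (m[i, j] == best_w and (best_s is None or s < best_s)):
                    best_w, best_s = m[i, j], s
        assigned[j] = best_s if best_s is not None else -j - 1
    groups: dict[int, set[int]] = {}
    for node, s in assigned.items():
        groups.setdefault(s, set()).add(node)
    return [frozenset(g) for g in groups.values()]


def union_find_components(labels: list[str], edges: list[tuple[str, str]]):
    """Independent union-find component computation."""
    parent = {x: x for x in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    comps: dict[str, set[str]] = {}
    for x in labels:
        comps.setdefault(find(x), set()).add(x)
    return sorted(
        (sorted(c) for c in comps.values()), key=lambda c: (-len(c), c[0])
    )


def partition_to_sets(assignment: dict[str, int]) -> set[frozenset[str]]:
    groups: dict[int, set[str]] = {}
    for k, v in assignment.items():
        groups.setdefault(v, set()).add(k)
    return {frozenset(g) for g in groups.values()}
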