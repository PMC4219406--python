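"""Independent reference implementations used only to check the package.

Everything here is deliberately naive: plain-Python dynamic programs,
dense-list Markov clustering, explicit tree enumeration.  None of it shares
code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np

from symbioscreen.phylo import PhyloTree


def sw_local_score(a: str, b: str, submat, gap_open: float = 11, gap_extend: float = 1) -> float:
    """Exhaustive Smith–Waterman with affine gaps; returns the optimal
    local score.  Opening a gap costs gap_open + gap_extend."""
    la, lb = len(a), len(b)
    neg = -1e30
    go = gap_open + gap_extend
    ge = gap_extend
    M = [[0.0] * (lb + 1) for _ in range(la + 1)]
    X = [[neg] * (lb + 1) for _ in range(la + 1)]
    Y = [[neg] * (lb + 1) for _ in range(la + 1)]
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = float(submat[a[i - 1], b[j - 1]])
            M[i][j] = max(0.0, s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]))
            X[i][j] = max(M[i][j - 1] - go, X[i][j - 1] - ge)
            Y[i][j] = max(M[i - 1][j] - go, Y[i - 1][j] - ge)
            best = max(best, M[i][j])
    return best


def nw_global_align(a: str, b: str, submat, gap_open: float = 11, gap_extend: float = 1):
    """Plain Needleman–Wunsch/Gotoh; returns (score, aligned_a, aligned_b)."""
    la, lb = len(a), len(b)
    neg = -1e30
    go = gap_open + gap_extend
    ge = gap_extend
    M = [[neg] * (lb + 1) for _ in range(la + 1)]
    X = [[neg] * (lb + 1) for _ in range(la + 1)]
    Y = [[neg] * (lb + 1) for _ in range(la + 1)]
    M[0][0] = 0.0
    for j in range(1, lb + 1):
        X[0][j] = -go - ge * (j - 1)
    for i in range(1, la + 1):
        Y[i][0] = -go - ge * (i - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = float(submat[a[i - 1], b[j - 1]])
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i][j - 1] - go, X[i][j - 1] - ge)
            Y[i][j] = max(M[i - 1][j] - go, Y[i - 1][j] - ge)
    score = max(M[la][lb], X[la][lb], Y[la][lb])
    # traceback
    out_a, out_b = [], []
    i, j = la, lb
    state = max((M[i][j], "M"), (Y[i][j], "Y"), (X[i][j], "X"))[1]
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = M[i][j] - float(submat[a[i - 1], b[j - 1]])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = next(
                st for val, st in ((M[i][j], "M"), (X[i][j], "X"), (Y[i][j], "Y"))
                if abs(val - prev) < 1e-6
            )
        elif state == "Y":
            out_a.append(a[i - 1])
            out_b.append("-")
            val = Y[i][j]
            i -= 1
            state = "M" if abs(M[i][j] - go - val) < 1e-6 else "Y"
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            val = X[i][j]
            j -= 1
            state = "M" if abs(M[i][j] - go - val) < 1e-6 else "X"
    return score, "".join(reversed(out_a)), "".join(reversed(out_b))


def naive_mcl(n: int, edges: list[tuple[int, int, float]], inflation: float = 1.5,
              max_iter: int = 100, tol: float = 1e-6, prune: float = 1e-5) -> list[frozenset[int]]:
    """Unoptimized dense Markov clustering: self-loops at max incident
    weight, column normalization, expansion/inflation with pruning, clusters
    as connected components of the symmetrized limit."""
    M = [[0.0] * n for _ in range(n)]
    for i, j, w in edges:
        M[i][j] = w
        M[j][i] = w
    for i in range(n):
        loop = max((M[i][j] for j in range(n)), default=0.0)
        M[i][i] = loop if loop > 0 else 1.0

    def normalize(mat):
        for j in range(n):
            colsum = sum(mat[i][j] for i in range(n))
            if colsum > 0:
                for i in range(n):
                    mat[i][j] /= colsum
        return mat

    M = normalize(M)
    for _ in range(max_iter):
        sq = [[sum(M[i][k] * M[k][j] for k in range(n)) for j in range(n)]
              for i in range(n)]
        infl = [[sq[i][j] ** inflation for j in range(n)] for i in range(n)]
        for i in range(n):
            for j in range(n):
                if infl[i][j] < prune:
                    infl[i][j] = 0.0
        infl = normalize(infl)
        diff = max(abs(infl[i][j] - M[i][j]) for i in range(n) for j in range(n))
        M = infl
        if diff < tol:
            break

    # connected components of the symmetrized nonzero structure
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(n):
            if M[i][j] > 0 or M[j][i] > 0:
                parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]


def random_unrooted_tree(rng: np.random.Generator, n_leaves: int,
                         min_bl: float = 0.5, max_bl: float = 2.0):
    """Random unrooted binary tree by sequential edge attachment.

    Returns (adjacency {node: [(nbr, length)]}, leaf node ids 0..n-1).
    """
    assert n_leaves >= 3
    adjacency: dict[int, list] = {}

    def bl() -> float:
        return float(rng.uniform(min_bl, max_bl))

    def connect(a, b, length):
        adjacency.setdefault(a, []).append([b, length])
        adjacency.setdefault(b, []).append([a, length])

    center = n_leaves  # first internal node
    for leaf in range(3):
        connect(leaf, center, bl())
    next_node = n_leaves + 1
    for leaf in range(3, n_leaves):
        edges = [
            (a, b) for a in adjacency for b, _ in adjacency[a] if a < b
        ]
        a, b = edges[rng.integers(0, len(edges))]
        length = next(l for nb, l in adjacency[a] if nb == b)
        adjacency[a] = [e for e in adjacency[a] if e[0] != b]
        adjacency[b] = [e for e in adjacency[b] if e[0] != a]
        mid = next_node
        next_node += 1
        split = float(rng.uniform(0.2, 0.8)) * length
        connect(a, mid, split)
        connect(mid, b, length - split)
        connect(leaf, mid, bl())
    adjacency = {k: [tuple(e) for e in v] for k, v in adjacency.items()}
    return adjacency, list(range(n_leaves))


def tree_leaf_distances(adjacency, leaves) -> np.ndarray:
    """All-pairs path lengths between leaves by per-leaf DFS."""
    n = len(leaves)
    D = np.zeros((n, n))
    for i, start in enumerate(leaves):
        dist = {start: 0.0}
        stack = [start]
        while stack:
            node = stack.pop()
            for nbr, length in adjacency[node]:
                if nbr not in dist:
                    dist[nbr] = dist[node] + length
                    stack.append(nbr)
        for j, leaf in enumerate(leaves):
            D[i, j] = dist[leaf]
    return D


def tree_splits(adjacency, leaves, labels) -> set[frozenset]:
    """Normalized nontrivial bipartitions (as frozensets of frozensets of
    leaf labels), one per internal edge."""
    leafset = set(leaves)
    splits = set()
    for a in adjacency:
        for b, _ in adjacency[a]:
            if a >= b:
                continue
            side = set()
            stack = [a]
            seen = {a, b}
            while stack:
                node = stack.pop()
                if node in leafset:
                    side.add(node)
                for nbr, _ in adjacency[node]:
                    if nbr not in seen:
                        seen.add(nbr)
                        stack.append(nbr)
            side.discard(b)
            other = leafset - side
            if len(side) >= 2 and len(other) >= 2:
                splits.add(
                    frozenset(
                        (frozenset(labels[x] for x in side),
                         frozenset(labels[x] for x in other))
                    )
                )
    return splits


def phylo_tree_from_adjacency(adjacency, leaves, labels, genome_map) -> PhyloTree:
    adj = {node: [(nbr, length) for nbr, length in nbrs]
           for node, nbrs in adjacency.items()}
    return PhyloTree(
        adjacency=adj,
        leaf_labels={leaf: labels[leaf] for leaf in leaves},
        genome_map=genome_map,
    )


def brute_force_exclusive(adjacency, leaves, labels, genome_map, group: set[str]) -> bool:
    """Exhaustive bipartition check, written independently of the package:
    enumerate every edge, collect the leaf genomes on each side, and test
    the exclusivity-and-coverage condition."""
    leaf_genomes = {leaf: genome_map[labels[leaf]] for leaf in leaves}
    if not group <= set(leaf_genomes.values()):
        return False
    for a in adjacency:
        for b, _ in adjacency[a]:
            if a >= b:
                continue
            for s, t in ((a, b), (b, a)):
                side = set()
                stack = [s]
                seen = {s, t}
                while stack:
                    node = stack.pop()
                    if node in leaf_genomes:
                        side.add(node)
                    for nbr, _ in adjacency[node]:
                        if nbr not in seen:
                            seen.add(nbr)
                            stack.append(nbr)
                side.discard(t)
                genomes = {leaf_genomes[x] for x in side}
                if genomes and genomes <= group and group <= genomes:
                    return True
    return False


def two_leaf_difference_probability(path_lengths: list[float], rate: float) -> float:
    """Exact probability that two leaves differ at a site when each branch
    substitutes a site with probability 1 − e^(−rate·l), replacement
    uniform over the other 19 residues (transition-matrix composition)."""
    T = np.eye(20)
    for l in path_lengths:
        p = 1.0 - math.exp(-rate * l)
        step = (1 - p) * np.eye(20) + p * (np.ones((20, 20)) - np.eye(20)) / 19.0
        T = T @ step
    return 1.0 - float(T[0, 0])
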