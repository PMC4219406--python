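"""Neighbor-joining trees, the exclusive-clade test and bootstrap support.

Group "monophyly" on an unrooted tree is formalized as an *exclusive
bipartition*: an edge whose removal yields a leaf side whose genomes are all
group members and that covers every group member at least once.  Extra
paralogs of group genomes outside the clade do not disqualify a candidate
edge.  The criterion is rooting-invariant, which is the right reading of a
"terminal node" on an unrooted NJ tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from symbioscreen.io import DataError, TaxonGroup
from symbioscreen.msa import DistanceMatrix, MultipleAlignment, pairwise_distances

logger = logging.getLogger(__name__)


@dataclass
class PhyloTree:
    """Unrooted tree as an adjacency map between integer nodes.

    Leaves carry string labels (protein ids); ``genome_map`` sends a leaf
    label to its genome id.  ``supports`` optionally maps an edge (sorted
    node pair) to a value in [0, 1].
    """

    adjacency: dict[int, list[tuple[int, float]]]
    leaf_labels: dict[int, str]
    genome_map: dict[str, str] = field(default_factory=dict)
    supports: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def leaves(self) -> list[int]:
        return sorted(self.leaf_labels)

    @property
    def labels(self) -> list[str]:
        return [self.leaf_labels[n] for n in self.leaves]

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for a, nbrs in self.adjacency.items():
            for b, length in nbrs:
                if a < b:
                    out.append((a, b, length))
        return sorted(out)

    def side_leaves(self, a: int, b: int) -> set[int]:
        """Leaves on the ``a`` side of edge (a, b)."""
        seen = {a}
        stack = [a]
        while stack:
            node = stack.pop()
            for nbr, _ in self.adjacency[node]:
                if nbr != b and nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return {n for n in seen if n in self.leaf_labels}

    def path_length(self, label_a: str, label_b: str) -> float:
        """Sum of branch lengths between two leaves (for additivity checks)."""
        start = next(n for n, lb in self.leaf_labels.items() if lb == label_a)
        goal = next(n for n, lb in self.leaf_labels.items() if lb == label_b)
        dist = {start: 0.0}
        stack = [start]
        while stack:
            node = stack.pop()
            if node == goal:
                return dist[node]
            for nbr, length in self.adjacency[node]:
                if nbr not in dist:
                    dist[nbr] = dist[node] + length
                    stack.append(nbr)
        raise DataError("leaves not connected")

    def bipartitions(self) -> list[frozenset[str]]:
        """Leaf-label sets of one side of every edge (pendant edges included)."""
        return [
            frozenset(self.leaf_labels[n] for n in self.side_leaves(a, b))
            for a, b, _ in self.edges()
        ]

    def to_newick(self) -> str:
        """Serialize rooted at the highest-degree internal node (arbitrary,
        as NJ trees are unrooted)."""
        if len(self.leaf_labels) == 1:
            (label,) = self.leaf_labels.values()
            return f"{label};"
        root = max(self.adjacency, key=lambda n: (len(self.adjacency[n]), -n))

        def render(node: int, parent: int | None) -> str:
            children = [
                (nbr, length)
                for nbr, length in sorted(self.adjacency[node])
                if nbr != parent
            ]
            if not children:
                return self.leaf_labels[node]
            parts = [f"{render(c, node)}:{length:.6g}" for c, length in children]
            return "(" + ",".join(parts) + ")"

        return render(root, None) + ";"


def neighbor_joining(dmat: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou–Nei neighbor joining (Studier–Keppler Q-criterion).

    Negative branch-length estimates are clamped to zero with the deficit
    moved to the sister branch.  Ties in Q are broken by the smallest
    (row id, col id) pair, so the output is deterministic.
    """
    n = len(dmat.ids)
    if n < 3:
        raise DataError("neighbor_joining: need >=3 taxa")
    D = dmat.values.copy()
    ids = list(dmat.ids)
    active = list(range(n))  # indices into D
    node_of = {i: i for i in active}  # D index -> tree node id
    adjacency: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    leaf_labels = {i: ids[i] for i in range(n)}
    next_node = n

    def connect(a: int, b: int, length: float) -> None:
        length = max(length, 0.0)
        adjacency.setdefault(a, []).append((b, length))
        adjacency.setdefault(b, []).append((a, length))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # deterministic tie-break on the joined pair's ids
        cand = np.argwhere(q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((ids_label(active[i], leaf_labels, node_of),
                           ids_label(active[j], leaf_labels, node_of)))), i, j)
            for i, j in cand if i < j
        )
        _, bi, bj = best
        i_idx, j_idx = active[bi], active[bj]
        dij = D[i_idx, j_idx]
        li = 0.5 * dij + (totals[bi] - totals[bj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        new_idx = D.shape[0]
        newrow = 0.5 * (D[i_idx] + D[j_idx] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[new_idx, : new_idx] = newrow
        D[: new_idx, new_idx] = newrow
        D[new_idx, new_idx] = 0.0
        node = next_node
        next_node += 1
        adjacency[node] = []
        connect(node, node_of[i_idx], li)
        connect(node, node_of[j_idx], lj)
        node_of[new_idx] = node
        active = [a for a in active if a not in (i_idx, j_idx)] + [new_idx]

    # final star join of the last three
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    center = next_node
    adjacency[center] = []
    for idx, length in ((a, la), (b, lb), (c, lc)):
        connect(center, node_of[idx], length)

    return PhyloTree(adjacency=adjacency, leaf_labels=leaf_labels)


def ids_label(d_index: int, leaf_labels: dict[int, str], node_of: dict[int, int]) -> str:
    """Stable sort key for a working node: its label if a leaf, else a
    placeholder ordered after all labels."""
    node = node_of[d_index]
    return leaf_labels.get(node, f"￿{node:09d}")


def find_exclusive_group_bipartition(
    tree: PhyloTree, group: TaxonGroup, genome_map: dict[str, str]
) -> dict:
    """Test whether some edge isolates exactly the group's genomes.

    ``found`` is true iff removal of some edge yields a leaf side whose
    genome multiset (i) contains only group members and (ii) covers every
    member at least once.  A group member absent from the whole tree gives
    ``found = False`` (logged), not an error.
    """
    leaf_genomes = {label: genome_map.get(label) for label in tree.labels}
    present = set(leaf_genomes.values())
    missing = group.members - present
    if missing:
        logger.info(
            "group %s: members %s absent from tree", group.name, sorted(missing)
        )
        return {"found": False, "edges": []}
    hits = []
    for a, b, _length in tree.edges():
        for side_root, other in ((a, b), (b, a)):
            side = tree.side_leaves(side_root, other)
            genomes = {leaf_genomes[tree.leaf_labels[n]] for n in side}
            if genomes <= group.members and group.members <= genomes:
                hits.append((min(a, b), max(a, b)))
                break
    return {"found": bool(hits), "edges": sorted(set(hits))}


def bootstrap_group_support(
    aln: MultipleAlignment,
    group: TaxonGroup,
    genome_map: dict[str, str],
    n_reps: int,
    seed: int,
) -> float:
    """Fraction of column-resampled replicate NJ trees in which the group
    forms an exclusive bipartition.  Reproducible for a fixed seed.

    A replicate whose resampled columns leave some row pair with no
    comparable sites cannot yield a tree and counts as non-supporting.
    """
    if n_reps < 1:
        raise DataError("bootstrap_group_support: n_reps must be >=1")
    present = {genome_map.get(label) for label in aln.ids}
    if not group.members <= present:
        logger.warning(
            "group %s: member missing from alignment; support = 0", group.name
        )
        return 0.0
    rng = np.random.default_rng(seed)
    n_cols = aln.n_cols
    successes = 0
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, n_cols)
        rep = aln.subsample_columns(cols)
        try:
            dmat = pairwise_distances(rep, model="poisson")
        except DataError:
            continue
        tree = neighbor_joining(dmat)
        if find_exclusive_group_bipartition(tree, group, genome_map)["found"]:
            successes += 1
    return successes / n_reps
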