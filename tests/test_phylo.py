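import numpy as np
import pytest

from oracles import (
    brute_force_exclusive,
    phylo_tree_from_adjacency,
    random_unrooted_tree,
    tree_leaf_distances,
    tree_splits,
)
from symbioscreen.io import DataError, TaxonGroup
from symbioscreen.msa import DistanceMatrix, MultipleAlignment
from symbioscreen.phylo import (
    bootstrap_group_support,
    find_exclusive_group_bipartition,
    neighbor_joining,
)


def labels_for(leaves):
    return {leaf: f"t{leaf:02d}" for leaf in leaves}


def nj_splits(tree):
    """Nontrivial bipartitions of an NJ tree, normalized."""
    labels = set(tree.labels)
    out = set()
    for side in tree.bipartitions():
        other = frozenset(labels - side)
        if len(side) >= 2 and len(other) >= 2:
            out.add(frozenset((side, other)))
    return out


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((a:1,b:2):5,(c:2,d:3)) gives this additive matrix
        D = np.array(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 5], [9, 10, 5, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(ids=list("abcd"), values=D))
        for i, a in enumerate("abcd"):
            for j, b in enumerate("abcd"):
                if i < j:
                    assert tree.path_length(a, b) == pytest.approx(D[i, j])
        assert nj_splits(tree) == {
            frozenset((frozenset("ab"), frozenset("cd")))
        }

    def test_three_taxon_star_closed_form(self):
        D = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
        tree = neighbor_joining(DistanceMatrix(ids=list("ijk"), values=D))
        # b_i = (d_ij + d_ik - d_jk) / 2 etc.
        assert tree.path_length("i", "j") == pytest.approx(4)
        assert tree.path_length("i", "k") == pytest.approx(6)
        assert tree.path_length("j", "k") == pytest.approx(8)
        assert len(tree.adjacency) == 4  # one internal node

    def test_fewer_than_three_taxa_rejected(self):
        D = np.array([[0, 1], [1, 0]], float)
        with pytest.raises(DataError):
            neighbor_joining(DistanceMatrix(ids=["a", "b"], values=D))

    def test_random_additive_matrices_recovered_exactly(self):
        # NJ is consistent on additive matrices: exact topology and lengths
        rng = np.random.default_rng(101)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            adjacency, leaves = random_unrooted_tree(rng, n)
            labels = labels_for(leaves)
            D = tree_leaf_distances(adjacency, leaves)
            ids = [labels[leaf] for leaf in leaves]
            tree = neighbor_joining(DistanceMatrix(ids=ids, values=D))
            assert nj_splits(tree) == tree_splits(adjacency, leaves, labels)
            for i in range(n):
                for j in range(i + 1, n):
                    assert tree.path_length(ids[i], ids[j]) == pytest.approx(
                        D[i, j], abs=1e-9
                    )

    def test_ultrametric_matrix_paths_reproduced(self):
        # perfectly clock-like distances are additive, so NJ reproduces them
        D = np.array(
            [
                [0, 2, 6, 6, 10],
                [2, 0, 6, 6, 10],
                [6, 6, 0, 4, 10],
                [6, 6, 4, 0, 10],
                [10, 10, 10, 10, 0],
            ],
            float,
        )
        ids = list("abcde")
        tree = neighbor_joining(DistanceMatrix(ids=ids, values=D))
        for i in range(5):
            for j in range(i + 1, 5):
                assert abs(tree.path_length(ids[i], ids[j]) - D[i, j]) <= 1e-9

    def test_newick_is_writable(self):
        D = np.array([[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 5], [9, 10, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(ids=list("abcd"), values=D))
        nwk = tree.to_newick()
        assert nwk.endswith(";") and all(x in nwk for x in "abcd")


class TestExclusiveBipartition:
    def _quartet(self):
        # ((a,b),(c,d)) built by NJ from the additive quartet matrix
        D = np.array([[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 5], [9, 10, 5, 0]], float)
        return neighbor_joining(DistanceMatrix(ids=list("abcd"), values=D))

    def test_group_matching_a_clade_is_found(self):
        gm = {"a": "G1", "b": "G2", "c": "X", "d": "Y"}
        res = find_exclusive_group_bipartition(
            self._quartet(), TaxonGroup("g", {"G1", "G2"}), gm
        )
        assert res["found"] is True

    def test_group_straddling_the_split_is_not_found(self):
        gm = {"a": "G1", "b": "G2", "c": "X", "d": "Y"}
        res = find_exclusive_group_bipartition(
            self._quartet(), TaxonGroup("g", {"G1", "X"}), gm
        )
        assert res["found"] is False

    def test_paralogs_outside_the_clade_do_not_disqualify(self):
        # leaves a1,a2 (genome A), b (genome B), c,d: tree ((a1,b),(a2,(c,d)))
        adjacency = {
            0: [(5, 1.0)],  # a1
            1: [(5, 1.0)],  # b
            2: [(6, 1.0)],  # a2
            3: [(7, 1.0)],  # c
            4: [(7, 1.0)],  # d
            5: [(0, 1.0), (1, 1.0), (6, 1.0)],
            6: [(2, 1.0), (5, 1.0), (7, 1.0)],
            7: [(3, 1.0), (4, 1.0), (6, 1.0)],
        }
        labels = {0: "a1", 1: "b", 2: "a2", 3: "c", 4: "d"}
        gm = {"a1": "A", "a2": "A", "b": "B", "c": "C", "d": "D"}
        tree = phylo_tree_from_adjacency(adjacency, list(labels), labels, gm)
        res = find_exclusive_group_bipartition(tree, TaxonGroup("g", {"A", "B"}), gm)
        assert res["found"] is True  # via the {a1, b} clade

    def test_missing_group_member_gives_not_found(self):
        gm = {"a": "G1", "b": "G2", "c": "X", "d": "Y"}
        res = find_exclusive_group_bipartition(
            self._quartet(), TaxonGroup("g", {"G1", "ABSENT"}), gm
        )
        assert res == {"found": False, "edges": []}

    def test_agrees_with_brute_force_on_random_trees(self):
        rng = np.random.default_rng(202)
        for _ in range(300):
            n = int(rng.integers(4, 11))
            adjacency, leaves = random_unrooted_tree(rng, n)
            labels = labels_for(leaves)
            n_genomes = max(2, int(np.ceil(n / 1.5)))
            genome_map = {
                labels[leaf]: f"G{rng.integers(0, n_genomes)}" for leaf in leaves
            }
            genomes = sorted(set(genome_map.values()))
            if len(genomes) < 2:
                continue
            size = int(rng.integers(2, min(4, len(genomes)) + 1))
            group = set(rng.choice(genomes, size, replace=False))
            tree = phylo_tree_from_adjacency(adjacency, leaves, labels, genome_map)
            got = find_exclusive_group_bipartition(
                tree, TaxonGroup("g", group), genome_map
            )["found"]
            expected = brute_force_exclusive(adjacency, leaves, labels, genome_map, group)
            assert got == expected


class TestBootstrapSupport:
    def _two_block_alignment(self, rng, n_group=3, n_other=4, length=120):
        """Group rows identical; every other row an independent random
        sequence, so all non-group distances are far above 0.5."""
        from symbioscreen.align import AA_ORDER

        rows, ids, gm = [], [], {}
        base = "".join(AA_ORDER[i] for i in rng.integers(0, 20, length))
        for k in range(n_group):
            ids.append(f"g{k}")
            rows.append(base)
            gm[f"g{k}"] = f"GRP{k}"
        for k in range(n_other):
            ids.append(f"o{k}")
            rows.append("".join(AA_ORDER[i] for i in rng.integers(0, 20, length)))
            gm[f"o{k}"] = f"OUT{k}"
        return MultipleAlignment(ids=ids, rows=rows), gm

    def test_clean_separation_gives_full_support(self):
        rng = np.random.default_rng(7)
        aln, gm = self._two_block_alignment(rng)
        group = TaxonGroup("grp", {"GRP0", "GRP1", "GRP2"})
        support = bootstrap_group_support(aln, group, gm, n_reps=100, seed=7)
        assert support == 1.0

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(8)
        aln, gm = self._two_block_alignment(rng)
        group = TaxonGroup("grp", {"GRP0", "GRP1", "GRP2"})
        s1 = bootstrap_group_support(aln, group, gm, n_reps=50, seed=7)
        s2 = bootstrap_group_support(aln, group, gm, n_reps=50, seed=7)
        assert s1 == s2

    def test_missing_member_gives_zero_support(self):
        rng = np.random.default_rng(9)
        aln, gm = self._two_block_alignment(rng)
        group = TaxonGroup("grp", {"GRP0", "NOT_THERE"})
        assert bootstrap_group_support(aln, group, gm, n_reps=10, seed=1) == 0.0

    def test_zero_replicates_rejected(self):
        rng = np.random.default_rng(10)
        aln, gm = self._two_block_alignment(rng)
        group = TaxonGroup("grp", {"GRP0", "GRP1"})
        with pytest.raises(DataError):
            bootstrap_group_support(aln, group, gm, n_reps=0, seed=1)

    def test_support_monotone_in_group_separation(self):
        # stronger within-vs-between contrast should never lower support
        from symbioscreen.align import AA_ORDER

        rng = np.random.default_rng(12)
        length = 100
        base = "".join(AA_ORDER[i] for i in rng.integers(0, 20, length))
        group = TaxonGroup("grp", {"GA", "GB"})
        supports = []
        for n_sub in (2, 12, 40):
            arr = list(base)
            idx = rng.choice(length, n_sub, replace=False)
            for pos in idx:
                arr[pos] = AA_ORDER[(AA_ORDER.index(arr[pos]) + 5) % 20]
            far = "".join(arr)
            aln = MultipleAlignment(
                ids=["a", "b", "c", "d"], rows=[base, base, far, far]
            )
            gm = {"a": "GA", "b": "GB", "c": "X", "d": "Y"}
            supports.append(bootstrap_group_support(aln, group, gm, 60, seed=3))
        assert supports == sorted(supports)
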