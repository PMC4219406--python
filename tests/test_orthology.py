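import networkx as nx
import numpy as np
import pytest

from oracles import naive_mcl
from symbioscreen.align import AA_ORDER
from symbioscreen.io import DataError, ProteinRecord
from symbioscreen.msa import MultipleAlignment
from symbioscreen.orthology import (
    COG,
    ClusterParams,
    build_ortholog_graph,
    build_profile,
    capped_neglog10,
    mcl_cluster,
    select_representative,
)


def random_protein(rng, length=120):
    return "".join(AA_ORDER[i] for i in rng.integers(0, 20, length))


def mutate(seq, rng, n_changes):
    arr = list(seq)
    for pos in rng.choice(len(seq), n_changes, replace=False):
        arr[pos] = AA_ORDER[(AA_ORDER.index(arr[pos]) + 1) % 20]
    return "".join(arr)


def make_graph(n, edges):
    g = nx.Graph()
    g.add_nodes_from(f"p{i}" for i in range(n))
    for i, j, w in edges:
        g.add_edge(f"p{i}", f"p{j}", weight=w)
    return g


def partition_of(cogs):
    return {frozenset(pid for _, pid in c.members) for c in cogs}


class TestOrthologGraph:
    def test_reciprocal_strong_hit_gives_single_edge(self):
        rng = np.random.default_rng(5)
        seq = random_protein(rng)
        proteins = [
            ProteinRecord(genome_id="gA", protein_id="a1", residues=seq),
            ProteinRecord(genome_id="gB", protein_id="b1", residues=mutate(seq, rng, 5)),
        ]
        graph = build_ortholog_graph(proteins)
        assert graph.number_of_edges() == 1
        # single between-genome edge normalized by its own pair mean
        assert graph["a1"]["b1"]["weight"] == pytest.approx(1.0)

    def test_zero_evalue_weight_capped(self):
        assert capped_neglog10(0.0) == 300.0
        assert capped_neglog10(1e-400) == 300.0
        assert capped_neglog10(1e-3) == pytest.approx(3.0)

    def test_planted_triple_plus_unrelated_isolate(self):
        rng = np.random.default_rng(9)
        seq = random_protein(rng)
        proteins = [
            ProteinRecord(genome_id="gA", protein_id="a1", residues=seq),
            ProteinRecord(genome_id="gB", protein_id="b1", residues=mutate(seq, rng, 6)),
            ProteinRecord(genome_id="gC", protein_id="c1", residues=mutate(seq, rng, 10)),
            ProteinRecord(genome_id="gC", protein_id="c2", residues=random_protein(rng)),
        ]
        graph = build_ortholog_graph(proteins)
        comps = sorted(nx.connected_components(graph), key=len)
        assert [sorted(c) for c in comps] == [["c2"], ["a1", "b1", "c1"]]

    def test_requires_two_genomes(self):
        rng = np.random.default_rng(0)
        recs = [
            ProteinRecord(genome_id="g", protein_id=f"p{i}", residues=random_protein(rng))
            for i in range(2)
        ]
        with pytest.raises(DataError):
            build_ortholog_graph(recs)


class TestMarkovClustering:
    def test_disjoint_cliques_never_merged(self):
        edges = [(i, j, 50.0) for i in range(3) for j in range(i + 1, 3)]
        edges += [(i, j, 50.0) for i in range(3, 6) for j in range(i + 1, 6)]
        cogs = mcl_cluster(make_graph(6, edges))
        assert partition_of(cogs) == {
            frozenset({"p0", "p1", "p2"}),
            frozenset({"p3", "p4", "p5"}),
        }

    def test_single_clique_stays_one_cluster(self):
        edges = [(i, j, 50.0) for i in range(4) for j in range(i + 1, 4)]
        cogs = mcl_cluster(make_graph(4, edges))
        assert partition_of(cogs) == {frozenset({f"p{i}" for i in range(4)})}
        oracle = naive_mcl(4, edges)
        assert {frozenset(f"p{i}" for i in fs) for fs in oracle} == partition_of(cogs)

    def test_barbell_splits_at_weak_bridge(self):
        edges = [(i, j, 50.0) for i in range(4) for j in range(i + 1, 4)]
        edges += [(i, j, 50.0) for i in range(4, 8) for j in range(i + 1, 8)]
        edges += [(3, 4, 1.0)]
        cogs = mcl_cluster(make_graph(8, edges))
        got = partition_of(cogs)
        assert got == {
            frozenset({f"p{i}" for i in range(4)}),
            frozenset({f"p{i}" for i in range(4, 8)}),
        }
        oracle = naive_mcl(8, edges)
        assert {frozenset(f"p{i}" for i in fs) for fs in oracle} == got

    @pytest.mark.parametrize("inflation", [1.5, 10.0])
    def test_matches_reference_mcl_on_random_graphs(self, inflation):
        rng = np.random.default_rng(17)
        params = ClusterParams(inflation=inflation)
        for _ in range(30):
            n = int(rng.integers(2, 9))
            edges = [
                (i, j, float(rng.integers(1, 51)))
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.4
            ]
            got = partition_of(mcl_cluster(make_graph(n, edges), params))
            expected = {
                frozenset(f"p{i}" for i in fs)
                for fs in naive_mcl(n, edges, inflation=inflation)
            }
            assert got == expected

    def test_output_is_a_partition_with_deterministic_ids(self):
        edges = [(0, 1, 5.0), (2, 3, 9.0), (3, 4, 9.0), (2, 4, 9.0)]
        cogs = mcl_cluster(make_graph(6, edges))
        all_members = [pid for c in cogs for _, pid in c.members]
        assert sorted(all_members) == [f"p{i}" for i in range(6)]
        assert len(set(all_members)) == 6
        # descending size, ties by smallest member id
        sizes = [len(c.members) for c in cogs]
        assert sizes == sorted(sizes, reverse=True)
        assert cogs[0].cog_id == "COG0001"

    def test_nonfinite_weight_rejected(self):
        with pytest.raises(DataError):
            mcl_cluster(make_graph(2, [(0, 1, float("inf"))]))


class TestProfiles:
    def test_single_sequence_consensus_is_the_sequence(self):
        aln = MultipleAlignment(ids=["a"], rows=["MKVLW"])
        assert build_profile(aln).consensus == "MKVLW"

    def test_uniform_column_maximizes_its_residue(self):
        aln = MultipleAlignment(ids=[f"s{i}" for i in range(10)], rows=["A"] * 10)
        prof = build_profile(aln)
        assert prof.log_odds[0].argmax() == 0  # 'A'

    def test_majority_gap_column_is_insert(self):
        rows = ["A-"] * 6 + ["AK"] * 4
        aln = MultipleAlignment(ids=[f"s{i}" for i in range(10)], rows=rows)
        prof = build_profile(aln)
        assert prof.match_columns == [0]

    def test_empty_alignment_rejected(self):
        with pytest.raises(DataError):
            build_profile(MultipleAlignment(ids=[], rows=[]))


class TestRepresentative:
    def _pool(self, seqs):
        return {
            pid: ProteinRecord(
                genome_id="g", protein_id=pid, residues=seq, annotation=f"fn {pid}"
            )
            for pid, seq in seqs.items()
        }

    def test_identical_members_tie_to_smallest_id(self):
        seq = "MKVLITGAGG"
        pool = self._pool({"pb": seq, "pa": seq, "pc": seq})
        cog = COG(cog_id="COG1", members=[("g", p) for p in ("pa", "pb", "pc")])
        aln = MultipleAlignment(ids=["pa", "pb", "pc"], rows=[seq] * 3)
        rep, annotation = select_representative(cog, build_profile(aln), pool)
        assert rep == "pa"
        assert annotation == "fn pa"

    def test_consensus_member_wins(self):
        consensus = "MKVLITGAGGAKKW"
        variants = {
            "p1": consensus,
            "p2": "AKVLITGAGGAKKA",
            "p3": "MKVLITWAGGAKKY",
        }
        pool = self._pool(variants)
        cog = COG(cog_id="COG1", members=[("g", p) for p in variants])
        aln = MultipleAlignment(ids=sorted(variants), rows=[variants[p] for p in sorted(variants)])
        rep, _ = select_representative(cog, build_profile(aln), pool)
        assert rep == "p1"

    def test_representative_may_lie_outside_the_cog(self):
        # each member misses the majority consensus at one column; an outside
        # pool sequence equal to the consensus outscores them all
        consensus = "MKVLITGAGGAKKW"
        members = {
            "m1": "AKVLITGAGGAKKW",
            "m2": "MKVLITWAGGAKKW",
            "m3": "MKVLITGAGGAKKY",
        }
        pool = self._pool({**members, "out": consensus})
        cog = COG(cog_id="COG1", members=[("g", p) for p in sorted(members)])
        aln = MultipleAlignment(ids=sorted(members),
                                rows=[members[p] for p in sorted(members)])
        rep, _ = select_representative(cog, build_profile(aln), pool)
        assert rep == "out"

    def test_empty_pool_rejected(self):
        cog = COG(cog_id="COG1", members=[("g", "p")])
        aln = MultipleAlignment(ids=["p"], rows=["MKVL"])
        with pytest.raises(DataError):
            select_representative(cog, build_profile(aln), {})
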