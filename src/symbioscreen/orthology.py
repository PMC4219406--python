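"""All-vs-all protein similarity, ortholog graph and Markov clustering.

The graph construction follows the published OrthoMCL sketch: reciprocal
hits passing E-value and coverage filters become edges weighted by the
capped mean −log10(E); within-genome pairs are kept only when they are
mutual better-than-any-between-genome matches (in-paralogs); between-genome
weights are normalized by the mean between-genome weight of that genome
pair, in-paralog weights by the mean in-paralog weight of that genome.

Markov clustering iterates expansion (matrix squaring) and inflation
(elementwise power, here 1.5) on the column-stochastic weight matrix until
the column-wise change drops below tolerance; clusters are the connected
components of the symmetrized limit matrix.  Cluster ids are assigned by
descending size, ties by smallest member protein id, so output is diffable.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from symbioscreen.align import (
    AA_INDEX,
    AA_ORDER,
    affine_global_align,
    kmer_set,
    pairwise_local_align,
    shared_kmer_count,
)
from symbioscreen.io import DataError, ProteinRecord
from symbioscreen.msa import GAP, MultipleAlignment

logger = logging.getLogger(__name__)

WEIGHT_CAP = 300.0


@dataclass(frozen=True)
class SimilarityEdge:
    query_id: str
    subject_id: str
    score: float
    evalue: float
    coverage: float

    def __post_init__(self) -> None:
        if self.query_id == self.subject_id:
            raise DataError("self-hit is not a similarity edge")
        if self.evalue < 0 or not 0 <= self.coverage <= 1:
            raise DataError("invalid edge statistics")


@dataclass
class ClusterParams:
    evalue_cutoff: float = 1e-5
    min_coverage: float = 0.5
    inflation: float = 1.5
    mcl_max_iter: int = 100
    mcl_tol: float = 1e-6
    mcl_prune: float = 1e-5
    kmer_prefilter: bool = False
    kmer_prefilter_min_shared: int = 8

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise DataError("inflation must be > 1")
        if self.evalue_cutoff <= 0 or self.min_coverage <= 0:
            raise DataError("cutoffs must be positive")


@dataclass
class COG:
    """A cluster of orthologous proteins across genomes."""

    cog_id: str
    members: list[tuple[str, str]]  # (genome_id, protein_id)
    representative: str | None = None
    annotation: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise DataError(f"{self.cog_id}: empty COG")

    @property
    def protein_ids(self) -> list[str]:
        return [pid for _, pid in self.members]

    @property
    def genomes(self) -> set[str]:
        return {gid for gid, _ in self.members}


def capped_neglog10(evalue: float) -> float:
    if evalue <= 0:
        return WEIGHT_CAP
    return min(-math.log10(evalue), WEIGHT_CAP)


def all_vs_all_hits(proteins: list[ProteinRecord], params: ClusterParams) -> list[SimilarityEdge]:
    """Hits passing the E-value and coverage filters, one per unordered pair.

    Smith–Waterman is symmetric, so one alignment serves both directions.
    The optional 4-mer prefilter skips pairs sharing fewer than
    ``kmer_prefilter_min_shared`` distinct 4-mers; homologous pairs share
    tens, unrelated ones about none, so the surviving edge set is unchanged
    on realistic inputs.
    """
    edges: list[SimilarityEdge] = []
    recs = sorted(proteins, key=lambda r: r.protein_id)
    kmers = None
    if params.kmer_prefilter:
        kmers = [kmer_set(r.residues, 4) for r in recs]
    for i, j in itertools.combinations(range(len(recs)), 2):
        if kmers is not None and (
            shared_kmer_count(kmers[i], kmers[j]) < params.kmer_prefilter_min_shared
        ):
            continue
        hit = pairwise_local_align(recs[i].residues, recs[j].residues)
        if hit.evalue <= params.evalue_cutoff and hit.coverage >= params.min_coverage:
            edges.append(
                SimilarityEdge(
                    query_id=recs[i].protein_id,
                    subject_id=recs[j].protein_id,
                    score=hit.score,
                    evalue=hit.evalue,
                    coverage=hit.coverage,
                )
            )
    return edges


def build_ortholog_graph(
    proteins: list[ProteinRecord],
    params: ClusterParams | None = None,
    hits: list[SimilarityEdge] | None = None,
) -> nx.Graph:
    """Weighted undirected ortholog graph over all input proteins.

    Every protein is a node (isolates become singleton COGs downstream).
    Precomputed ``hits`` may be supplied to skip the all-vs-all stage.
    """
    params = params or ClusterParams()
    genomes = {r.genome_id for r in proteins}
    if len(genomes) < 2:
        raise DataError("build_ortholog_graph: need >=2 genomes")
    genome_of = {r.protein_id: r.genome_id for r in proteins}
    if len(genome_of) != len(proteins):
        raise DataError("duplicate protein ids across input")
    if hits is None:
        hits = all_vs_all_hits(proteins, params)

    graph = nx.Graph()
    graph.add_nodes_from(
        (pid, {"genome_id": genome_of[pid]}) for pid in sorted(genome_of)
    )

    raw: dict[tuple[str, str], float] = {}
    best_between: dict[str, float] = {}
    for e in hits:
        w = capped_neglog10(e.evalue)
        key = tuple(sorted((e.query_id, e.subject_id)))
        raw[key] = w
        if genome_of[e.query_id] != genome_of[e.subject_id]:
            for pid in key:
                best_between[pid] = max(best_between.get(pid, -math.inf), w)

    between: dict[tuple[str, str], float] = {}
    within: dict[tuple[str, str], float] = {}
    for (p, q), w in raw.items():
        if genome_of[p] != genome_of[q]:
            between[(p, q)] = w
        else:
            # in-paralog rule: mutual better-than-any-between-genome match
            if w > best_between.get(p, -math.inf) and w > best_between.get(q, -math.inf):
                within[(p, q)] = w

    # normalization by mean weight per genome pair / per genome
    pair_weights: dict[tuple[str, str], list[float]] = {}
    for (p, q), w in between.items():
        gp = tuple(sorted((genome_of[p], genome_of[q])))
        pair_weights.setdefault(gp, []).append(w)
    pair_mean = {gp: float(np.mean(ws)) for gp, ws in pair_weights.items()}

    within_weights: dict[str, list[float]] = {}
    for (p, q), w in within.items():
        within_weights.setdefault(genome_of[p], []).append(w)
    within_mean = {g: float(np.mean(ws)) for g, ws in within_weights.items()}

    for (p, q), w in between.items():
        gp = tuple(sorted((genome_of[p], genome_of[q])))
        denom = pair_mean[gp]
        graph.add_edge(p, q, weight=w / denom if denom > 0 else w)
    for (p, q), w in within.items():
        denom = within_mean[genome_of[p]]
        graph.add_edge(p, q, weight=w / denom if denom > 0 else w)

    if graph.number_of_edges() == 0:
        logger.info("ortholog graph has no edges")
    return graph


def mcl_cluster(graph: nx.Graph, params: ClusterParams | None = None) -> list[COG]:
    """Markov clustering of the ortholog graph into COGs (a partition)."""
    params = params or ClusterParams()
    nodes = sorted(graph.nodes)
    if not nodes:
        return []
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    loop = np.zeros(n)
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if not math.isfinite(w):
            raise DataError(f"non-finite weight on edge ({u}, {v})")
        if w < 0:
            raise DataError(f"negative weight on edge ({u}, {v})")
        i, j = index[u], index[v]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
        loop[i] = max(loop[i], w)
        loop[j] = max(loop[j], w)
    loop[loop == 0] = 1.0  # isolated nodes: unit self-loop
    rows += list(range(n))
    cols += list(range(n))
    vals += list(loop)
    M = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def normalize(mat: sp.csr_matrix) -> sp.csr_matrix:
        colsum = np.asarray(mat.sum(axis=0)).ravel()
        colsum[colsum == 0] = 1.0
        return mat @ sp.diags(1.0 / colsum)

    M = normalize(M)
    for _ in range(params.mcl_max_iter):
        expanded = M @ M
        inflated = expanded.power(params.inflation)
        inflated.data[inflated.data < params.mcl_prune] = 0.0
        inflated.eliminate_zeros()
        inflated = normalize(inflated.tocsr())
        diff = abs(inflated - M).max()
        M = inflated
        if diff < params.mcl_tol:
            break

    structure = M + M.T
    n_comp, labels = connected_components(structure, directed=False)
    groups: dict[int, list[str]] = {}
    for node, lab in zip(nodes, labels):
        groups.setdefault(int(lab), []).append(node)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    width = max(4, len(str(len(ordered))))
    genome_of = nx.get_node_attributes(graph, "genome_id")
    cogs = []
    for k, members in enumerate(ordered, start=1):
        cogs.append(
            COG(
                cog_id=f"COG{k:0{width}d}",
                members=sorted(
                    (genome_of.get(pid, ""), pid) for pid in members
                ),
            )
        )
    return cogs


@dataclass
class Profile:
    """Per-column log-odds profile of a COG alignment.

    Columns with more than half gaps are insert columns and are excluded
    from match scoring.  Log-odds are against a uniform background with
    add-one pseudocounts.
    """

    match_columns: list[int]
    log_odds: np.ndarray  # (n_match_columns, 20)
    consensus: str

    def score_sequence(self, seq: str,
                       gap_open: float = 4.0, gap_extend: float = 0.5) -> float:
        """Global profile-to-sequence alignment score with affine gaps.

        Penalties are on the log-odds scale (BLOSUM-style 11/1 would be
        meaningless here); defaults keep gaps rare but possible.
        """
        if not seq:
            raise DataError("cannot score empty sequence")
        onehot = np.zeros((len(seq), 20))
        for i, aa in enumerate(seq):
            j = AA_INDEX.get(aa)
            if j is not None:
                onehot[i, j] = 1.0
        scores = self.log_odds @ onehot.T
        best, _ = affine_global_align(scores, gap_open, gap_extend)
        return best


def build_profile(aln: MultipleAlignment) -> Profile:
    """Position-specific log-odds profile from a COG alignment."""
    if aln.n_rows < 1:
        raise DataError("build_profile: empty alignment")
    n_rows = aln.n_rows
    match_columns = []
    logodds_rows = []
    consensus = []
    background = 1.0 / 20.0
    for col in range(aln.n_cols):
        column = [row[col] for row in aln.rows]
        gaps = sum(ch == GAP for ch in column)
        if gaps / n_rows > 0.5:
            continue  # insert column
        counts = np.ones(20)  # add-one pseudocounts
        for ch in column:
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
        freqs = counts / counts.sum()
        logodds_rows.append(np.log2(freqs / background))
        match_columns.append(col)
        consensus.append(AA_ORDER[int(np.argmax(counts))])
    if not match_columns:
        raise DataError("profile has no match columns")
    return Profile(
        match_columns=match_columns,
        log_odds=np.vstack(logodds_rows),
        consensus="".join(consensus),
    )


def select_representative(
    cog: COG,
    profile: Profile,
    taxon_pool: dict[str, ProteinRecord],
    candidates: list[str] | None = None,
) -> tuple[str, str]:
    """Best profile match in the taxon pool; its annotation is retained.

    The winner may lie outside the COG (logged).  Ties go to the
    lexicographically smallest protein id.  ``candidates`` optionally
    restricts the pool scan (the COG's own members are always scored).
    """
    if not taxon_pool:
        raise DataError("select_representative: empty pool")
    pool_ids = sorted(taxon_pool) if candidates is None else sorted(
        set(candidates) | set(pid for pid in cog.protein_ids if pid in taxon_pool)
    )
    best_id, best_score = None, -math.inf
    for pid in pool_ids:  # ascending ids: ties keep the smallest id
        score = profile.score_sequence(taxon_pool[pid].residues)
        if score > best_score + 1e-9:
            best_id, best_score = pid, score
    assert best_id is not None
    if best_id not in set(cog.protein_ids):
        logger.info("%s: representative %s lies outside the COG", cog.cog_id, best_id)
    return best_id, taxon_pool[best_id].annotation
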