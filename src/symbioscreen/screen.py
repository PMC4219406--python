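"""The per-COG phylogenomic screen and genomic locus assignment.

For every eligible COG (>=3 sequences, every group genome represented) the
screen aligns the members, builds a neighbor-joining tree from Poisson
distances, and tests whether the designated taxon group forms an exclusive
bipartition.  First-round positives get bootstrap support (column
resampling, NJ per replicate); hits with support at or above the threshold
(default 0.80, inclusive, under 1000 replicates) are flagged retained.
Support is never computed for first-round negatives.

Hits are then co-located on a reference genome: hits whose genes lie on the
same contig with at most ``locus_max_intervening_genes`` genes between
consecutive members share a locus letter ("A", "B", ... by descending gene
count, then leftmost coordinate); singletons are "lone".
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np

from symbioscreen.io import DataError, ProteinRecord, TaxonGroup
from symbioscreen.msa import MultipleAlignment, pairwise_distances, progressive_msa
from symbioscreen.orthology import COG
from symbioscreen.phylo import (
    PhyloTree,
    bootstrap_group_support,
    find_exclusive_group_bipartition,
    neighbor_joining,
)

logger = logging.getLogger(__name__)


@dataclass
class ScreenParams:
    support_threshold: float = 0.80  # inclusive
    n_bootstrap: int = 1000
    min_taxa_in_cog: int = 2
    locus_max_intervening_genes: int = 5
    locus_same_contig_required: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.support_threshold <= 1:
            raise DataError("support_threshold must be in (0, 1]")
        if self.n_bootstrap < 1:
            raise DataError("n_bootstrap must be >= 1")


@dataclass
class ScreenHit:
    cog_id: str
    group_name: str
    first_round_exclusive: bool
    support: float
    members: list[tuple[str, str]]  # (genome_id, protein_id)
    annotation: str = ""
    locus_label: str = ""
    retained: bool = False
    tree: PhyloTree | None = None
    alignment: MultipleAlignment | None = None

    @property
    def n_taxa(self) -> int:
        return len({g for g, _ in self.members})

    @property
    def group_members_present(self) -> list[str]:
        return sorted({g for g, _ in self.members})


@dataclass
class SkippedCog:
    cog_id: str
    reason: str


def screen_cogs(
    cogs: list[COG],
    proteins: dict[str, ProteinRecord],
    group: TaxonGroup,
    params: ScreenParams | None = None,
    alignments: dict[str, MultipleAlignment] | None = None,
) -> tuple[list[ScreenHit], list[SkippedCog]]:
    """Run the exclusive-clade screen over all COGs for one taxon group.

    Returns first-round hits (support computed, retained flagged) sorted by
    descending support then cog_id, plus the skipped-COG log.
    """
    params = params or ScreenParams()
    if len(group.members) < 2:
        raise DataError("screen group needs >=2 members")
    hits: list[ScreenHit] = []
    skipped: list[SkippedCog] = []
    rng = np.random.default_rng(params.seed)
    for cog in sorted(cogs, key=lambda c: c.cog_id):
        if len(cog.members) < 3:
            skipped.append(SkippedCog(cog.cog_id, "fewer than 3 sequences"))
            continue
        if len(cog.genomes) < params.min_taxa_in_cog:
            skipped.append(SkippedCog(cog.cog_id, "too few taxa"))
            continue
        if not group.members <= cog.genomes:
            skipped.append(SkippedCog(cog.cog_id, "group not co-present"))
            continue
        genome_map = {pid: gid for gid, pid in cog.members}
        if alignments is not None and cog.cog_id in alignments:
            aln = alignments[cog.cog_id]
        else:
            aln = progressive_msa(
                {pid: proteins[pid].residues for pid in cog.protein_ids}
            )
        dmat = pairwise_distances(aln, model="poisson")
        tree = neighbor_joining(dmat)
        tree.genome_map = genome_map
        first_round = find_exclusive_group_bipartition(tree, group, genome_map)
        if not first_round["found"]:
            continue
        support = bootstrap_group_support(
            aln, group, genome_map,
            n_reps=params.n_bootstrap,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        hits.append(
            ScreenHit(
                cog_id=cog.cog_id,
                group_name=group.name,
                first_round_exclusive=True,
                support=support,
                members=list(cog.members),
                annotation=cog.annotation,
                retained=support >= params.support_threshold,
                tree=tree,
                alignment=aln,
            )
        )
    hits.sort(key=lambda h: (-h.support, h.cog_id))
    return hits, skipped


def assign_loci(
    hits: list[ScreenHit],
    gene_coordinates: dict[str, dict],
    reference_genome: str,
    params: ScreenParams | None = None,
) -> list[ScreenHit]:
    """Label hits with shared-locus letters on the reference genome.

    Each hit is anchored at its reference-genome gene (smallest ordinal if
    the genome contributes paralogs).  Hits on one contig with at most
    ``locus_max_intervening_genes`` genes between consecutive anchors share
    a locus; multi-hit loci get letters by descending size then leftmost
    coordinate, singletons are "lone".  A hit without reference coordinates
    is "lone" (warned).
    """
    params = params or ScreenParams()
    anchors: dict[str, tuple[str, int, int]] = {}  # cog_id -> (contig, ordinal, start)
    for hit in hits:
        candidates = []
        for gid, pid in hit.members:
            if gid != reference_genome:
                continue
            info = gene_coordinates.get(pid)
            if info:
                candidates.append((info["ordinal"], info["start"], info["contig_id"]))
        if not candidates:
            hit.locus_label = "lone"
            logger.warning("%s: no reference coordinates; labelled lone", hit.cog_id)
            continue
        ordinal, start, contig = sorted(candidates)[0]
        anchors[hit.cog_id] = (contig, ordinal, start)

    by_contig: dict[str, list[tuple[int, int, str]]] = {}
    for cog_id, (contig, ordinal, start) in anchors.items():
        by_contig.setdefault(contig, []).append((ordinal, start, cog_id))

    clusters: list[tuple[int, int, list[str]]] = []  # (-size, leftmost, cog_ids)
    for contig in sorted(by_contig):
        entries = sorted(by_contig[contig])
        current: list[tuple[int, int, str]] = [entries[0]]
        for entry in entries[1:]:
            if entry[0] - current[-1][0] - 1 <= params.locus_max_intervening_genes:
                current.append(entry)
            else:
                clusters.append((-len(current), current[0][1], [e[2] for e in current]))
                current = [entry]
        clusters.append((-len(current), current[0][1], [e[2] for e in current]))

    label_iter = iter(
        list(string.ascii_uppercase)
        + [a + b for a in string.ascii_uppercase for b in string.ascii_uppercase]
    )
    label_of: dict[str, str] = {}
    for neg_size, _leftmost, cog_ids in sorted(clusters):
        label = next(label_iter) if -neg_size > 1 else "lone"
        for cog_id in cog_ids:
            label_of[cog_id] = label
    for hit in hits:
        if hit.cog_id in anchors:
            hit.locus_label = label_of[hit.cog_id]
    return hits


def summarize_screen(
    hits: list[ScreenHit],
    group: TaxonGroup,
    gene_coordinates: dict[str, dict] | None = None,
    reference_genome: str | None = None,
) -> list[dict]:
    """One report row per hit: locus, predicted function, number of taxa
    with the COG, group members present, bootstrap support in percent.

    Rows are ordered by locus label (letters before "lone"), then by
    reference coordinate, then cog_id.
    """
    rows = []
    for hit in hits:
        start = 0
        if gene_coordinates and reference_genome:
            starts = [
                gene_coordinates[pid]["start"]
                for gid, pid in hit.members
                if gid == reference_genome and pid in gene_coordinates
            ]
            start = min(starts) if starts else 0
        rows.append(
            {
                "locus": hit.locus_label or "lone",
                "predicted_function": hit.annotation,
                "n_taxa_with_cog": hit.n_taxa,
                "group_members_with_cog": ",".join(
                    sorted(set(hit.group_members_present) & group.members)
                ),
                "bootstrap_confidence_pct": int(round(hit.support * 100)),
                "retained": hit.retained,
                "cog_id": hit.cog_id,
                "_start": start,
            }
        )
    rows.sort(
        key=lambda r: (
            (1, "") if r["locus"] == "lone" else (0, r["locus"]),
            r["_start"],
            r["cog_id"],
        )
    )
    for row in rows:
        del row["_start"]
    return rows
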