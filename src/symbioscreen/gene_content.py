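"""Presence/absence matrix over COGs and gene-content comparisons.

Counts are COG counts, not gene counts: paralogous members collapse to one
presence bit, mirroring the construction of taxon-specific gene lists from
ortholog clusters.  The "unique" side of a pairwise comparison is computed
against the pair only, regardless of other genomes in the matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from symbioscreen.io import DataError
from symbioscreen.orthology import COG


@dataclass
class ContentMatrix:
    """Boolean genomes x COGs presence matrix."""

    table: pd.DataFrame  # index: genome ids, columns: cog ids, dtype bool

    @property
    def genomes(self) -> list[str]:
        return list(self.table.index)

    @property
    def cog_ids(self) -> list[str]:
        return list(self.table.columns)

    def presence_counts(self) -> pd.Series:
        """Number of COGs present per genome."""
        return self.table.sum(axis=1)


def build_content_matrix(cogs: list[COG], genomes: list[str]) -> ContentMatrix:
    """Presence matrix: entry true iff the COG has >=1 member from that
    genome.  Singleton COGs are included.  A listed genome contributing no
    protein to any COG is an error."""
    genomes = sorted(genomes)
    data = {}
    for cog in cogs:
        present = cog.genomes
        data[cog.cog_id] = [g in present for g in genomes]
    table = pd.DataFrame(data, index=genomes, dtype=bool)
    table = table[sorted(table.columns)]
    empty = table.index[~table.any(axis=1)].tolist() if len(cogs) else genomes
    if empty:
        raise DataError(f"genomes with zero proteins in any COG: {empty}")
    return ContentMatrix(table=table)


def pairwise_content(matrix: ContentMatrix, a: str, b: str) -> dict:
    """Shared and unique COG counts (and sorted id lists) for one pair."""
    if a == b:
        raise DataError("pairwise_content: A and B must differ")
    row_a = matrix.table.loc[a]
    row_b = matrix.table.loc[b]
    shared = sorted(matrix.table.columns[row_a & row_b])
    unique_a = sorted(matrix.table.columns[row_a & ~row_b])
    unique_b = sorted(matrix.table.columns[~row_a & row_b])
    return {
        "a": a,
        "b": b,
        "shared": len(shared),
        "unique_a": len(unique_a),
        "unique_b": len(unique_b),
        "shared_cogs": shared,
        "unique_a_cogs": unique_a,
        "unique_b_cogs": unique_b,
    }


def group_exclusive_cogs(
    matrix: ContentMatrix, in_group: set[str], out_group: set[str]
) -> list[str]:
    """COGs present in every in-group genome and absent from every
    out-group genome; genomes outside both sets are ignored."""
    in_group, out_group = set(in_group), set(out_group)
    if not in_group or not out_group:
        raise DataError("both groups must be nonempty")
    if in_group & out_group:
        raise DataError(f"groups overlap: {sorted(in_group & out_group)}")
    tbl = matrix.table
    missing = (in_group | out_group) - set(tbl.index)
    if missing:
        raise DataError(f"genomes not in matrix: {sorted(missing)}")
    keep = tbl.loc[sorted(in_group)].all(axis=0) & ~tbl.loc[sorted(out_group)].any(axis=0)
    return sorted(tbl.columns[keep])


@dataclass
class MobileScanParams:
    keywords: tuple[str, ...] = ("plasmid", "par", "phage", "replication")
    contig_review_length: int = 60_000
    flag_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.keywords:
            raise DataError("keywords must be nonempty")


def _annotation_matches(annotation: str, keywords: tuple[str, ...]) -> bool:
    """Case-insensitive word match; a keyword also matches gene-name style
    tokens with one trailing capital (parA, ParB), never inside arbitrary
    words ("preparation" does not match "par")."""
    tokens = re.split(r"[^0-9A-Za-z]+", annotation)
    for token in tokens:
        if not token:
            continue
        low = token.lower()
        for kw in keywords:
            if low == kw:
                return True
            if (
                len(token) == len(kw) + 1
                and low.startswith(kw)
                and token[-1].isupper()
            ):
                return True
    return False


def mobile_element_scan(
    annotations: list[tuple[str, str, str]],
    contig_lengths: dict[str, int],
    params: MobileScanParams | None = None,
) -> pd.DataFrame:
    """Flag putative mobile contigs from annotation keywords.

    ``annotations`` is a list of (gene_id, contig_id, annotation string).
    A contig is flagged "putative mobile" when at least ``flag_fraction`` of
    its genes match a keyword; contigs shorter than ``contig_review_length``
    are additionally listed for review regardless of fraction.  Output is
    sorted by contig id and independent of gene input order.
    """
    params = params or MobileScanParams()
    per_contig: dict[str, list[bool]] = {cid: [] for cid in contig_lengths}
    for _gene_id, contig_id, annotation in annotations:
        per_contig.setdefault(contig_id, []).append(
            _annotation_matches(annotation, params.keywords)
        )
    rows = []
    for contig_id in sorted(per_contig):
        flags = per_contig[contig_id]
        n_genes = len(flags)
        n_match = sum(flags)
        fraction = n_match / n_genes if n_genes else 0.0
        length = contig_lengths.get(contig_id, 0)
        rows.append(
            {
                "contig_id": contig_id,
                "length": length,
                "n_genes": n_genes,
                "n_keyword_genes": n_match,
                "keyword_fraction": round(fraction, 4),
                "putative_mobile": fraction >= params.flag_fraction and n_genes > 0,
                "for_review": length < params.contig_review_length,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig_id",
            "length",
            "n_genes",
            "n_keyword_genes",
            "keyword_fraction",
            "putative_mobile",
            "for_review",
        ],
    )
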