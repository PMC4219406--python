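"""Shared domain types and readers/writers for the standard formats.

Coordinates are 1-based inclusive (GFF3 convention) throughout the package.
Ambiguous amino acids (U, B, Z, J) are mapped to X on input and X scores as
worst case in every alignment, so scoring matrices stay total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
_AMBIGUOUS_AA = str.maketrans({"U": "X", "B": "X", "Z": "X", "J": "X", "*": "X", "O": "X"})
NT_ALPHABET = set("ACGTN")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class ProteinRecord:
    """A protein with its genomic context.

    ``start``/``end`` are 1-based inclusive nucleotide coordinates of the
    encoding gene; ``ordinal`` is the 1-based rank of the gene along its
    contig when sorted by start.  Strand is carried but ignored by all
    analyses.
    """

    genome_id: str
    protein_id: str
    residues: str
    annotation: str = ""
    contig_id: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    ordinal: int = 0

    def __post_init__(self) -> None:
        if not self.residues:
            raise DataError(f"protein {self.protein_id!r}: empty sequence")
        bad = set(self.residues) - AA_ALPHABET
        if bad:
            raise DataError(
                f"protein {self.protein_id!r}: illegal residues {sorted(bad)}"
            )
        if self.start and self.end and self.start > self.end:
            raise DataError(f"protein {self.protein_id!r}: start > end")


@dataclass
class GenomeAssembly:
    """A nucleotide assembly: one or more contigs for one genome."""

    genome_id: str
    contigs: dict[str, str]
    group_tag: str = "other"  # {in_group, out_group, other}

    def __post_init__(self) -> None:
        if not self.contigs:
            raise DataError(f"genome {self.genome_id!r}: no contigs")
        for cid, seq in self.contigs.items():
            if not seq:
                raise DataError(f"genome {self.genome_id!r}: empty contig {cid!r}")

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {cid: len(seq) for cid, seq in self.contigs.items()}

    @property
    def total_length(self) -> int:
        return sum(self.contig_lengths.values())


@dataclass
class TaxonGroup:
    """A named set of >=2 genome ids whose joint monophyly is screened for."""

    name: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if len(self.members) < 2:
            raise DataError(f"group {self.name!r}: needs >=2 members")


def read_protein_fasta(path, genome_id: str) -> list[ProteinRecord]:
    """Read a protein FASTA; one record per entry.

    The protein id is the first whitespace token of the header; the rest of
    the header is kept as the annotation.  Residues are uppercased and
    ambiguity codes mapped to X (logged).
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id
        if pid in seen:
            raise DataError(f"duplicate protein_id {pid!r} in {path}")
        seen.add(pid)
        raw = str(entry.seq).upper()
        residues = raw.translate(_AMBIGUOUS_AA)
        if residues != raw:
            logger.info("protein %s: ambiguous residues mapped to X", pid)
        desc = entry.description.split(None, 1)
        annotation = desc[1] if len(desc) > 1 else ""
        records.append(
            ProteinRecord(
                genome_id=genome_id,
                protein_id=pid,
                residues=residues,
                annotation=annotation,
            )
        )
    if not records:
        raise DataError(f"no FASTA entries in {path}")
    return records


def read_nucleotide_fasta(path, genome_id: str, group_tag: str = "other") -> GenomeAssembly:
    """Read a genome assembly FASTA into a :class:`GenomeAssembly`."""
    contigs: dict[str, str] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        bad = set(seq) - NT_ALPHABET
        if bad:
            raise DataError(f"contig {entry.id!r}: illegal characters {sorted(bad)}")
        contigs[entry.id] = seq
    if not contigs:
        raise DataError(f"no FASTA entries in {path}")
    return GenomeAssembly(genome_id=genome_id, contigs=contigs, group_tag=group_tag)


def read_gff3_genes(path) -> dict[str, dict]:
    """Read CDS/gene features from a GFF3 file.

    Returns a table keyed by protein id (the feature ``ID`` attribute) with
    contig_id, start, end (1-based inclusive), strand and ``ordinal``: the
    1-based rank of the gene along its contig by ascending start, ties broken
    by lexicographic id.
    """
    feats: list[tuple[str, int, int, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise DataError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
            contig, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = parts
            if ftype not in ("CDS", "gene"):
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            fid = attr_map.get("ID")
            if fid is None:
                logger.warning("%s:%d: feature without ID skipped", path, lineno)
                continue
            start, end = int(start_s), int(end_s)
            if start > end:
                raise DataError(f"{path}:{lineno}: start > end for {fid!r}")
            feats.append((contig, start, end, strand, fid))

    table: dict[str, dict] = {}
    by_contig: dict[str, list] = {}
    for contig, start, end, strand, fid in feats:
        by_contig.setdefault(contig, []).append((start, fid, end, strand))
    for contig in sorted(by_contig):
        for ordinal, (start, fid, end, strand) in enumerate(
            sorted(by_contig[contig]), start=1
        ):
            table[fid] = {
                "contig_id": contig,
                "start": start,
                "end": end,
                "strand": strand,
                "ordinal": ordinal,
            }
    return table


def attach_coordinates(records: list[ProteinRecord], coords: dict[str, dict]) -> None:
    """Fill coordinate fields of ``records`` in place from a GFF3 table."""
    for rec in records:
        info = coords.get(rec.protein_id)
        if info is None:
            continue
        rec.contig_id = info["contig_id"]
        rec.start = info["start"]
        rec.end = info["end"]
        rec.strand = info["strand"]
        rec.ordinal = info["ordinal"]


def write_table(rows: list[dict], path, columns: list[str] | None = None) -> None:
    """Write rows sharing one schema as a UTF-8 TSV, header first.

    Tabs or newlines inside a field are replaced by single spaces (logged).
    Row order is preserved as given; callers sort by their report's stated
    key before writing.
    """
    if columns is None:
        if rows:
            columns = list(rows[0].keys())
        else:
            raise DataError("empty row list needs an explicit column list")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            vals = []
            for col in columns:
                val = str(row[col])
                if "\t" in val or "\n" in val:
                    logger.info("field sanitized in column %s", col)
                    val = val.replace("\t", " ").replace("\n", " ")
                vals.append(val)
            fh.write("\t".join(vals) + "\n")


def read_table(path) -> list[dict]:
    """Read a TSV written by :func:`write_table` back into a row list."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        return [dict(zip(header, line.rstrip("\n").split("\t"))) for line in fh]
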