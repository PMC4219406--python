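"""Progressive multiple alignment and alignment-based distances.

The aligner follows the classic guide-tree recipe: pairwise distances from
fractional common 3-mer counts, a UPGMA guide tree, and profile–profile
global alignment (BLOSUM62 mean-of-pairs column scores, affine gaps open
11 / extend 1) at each internal node.  Children are visited in sorted-id
order and the ids are sorted up front, so the output is independent of
input order.

Distances support the p model (mismatch fraction under pairwise deletion)
and the Poisson correction −ln(1−p) with p capped at 0.95 to keep saturated
pairs finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from symbioscreen.align import AA_INDEX, affine_global_align, profile_pair_scores, kmer_set
from symbioscreen.io import DataError

GAP = "-"
P_CAP = 0.95


@dataclass
class MultipleAlignment:
    """Equal-length gapped rows keyed by sequence id."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise DataError("ids and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise DataError("alignment rows have unequal length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def to_int_matrix(self) -> np.ndarray:
        """Residue indices (0..19), −1 for gap or X; shape (n_rows, n_cols)."""
        mat = np.full((self.n_rows, self.n_cols), -1, dtype=np.int8)
        for i, row in enumerate(self.rows):
            for j, ch in enumerate(row):
                mat[i, j] = AA_INDEX.get(ch, -1)
        return mat

    def subsample_columns(self, cols: np.ndarray) -> "MultipleAlignment":
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return MultipleAlignment(ids=list(self.ids), rows=rows)


def write_alignment_fasta(aln: MultipleAlignment, path) -> None:
    with open(path, "w", newline="\n") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")


def read_alignment_fasta(path) -> MultipleAlignment:
    ids: list[str] = []
    rows: list[str] = []
    current: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if ids:
                    rows.append("".join(current))
                ids.append(line[1:].split()[0])
                current = []
            elif line:
                current.append(line)
    if ids:
        rows.append("".join(current))
    return MultipleAlignment(ids=ids, rows=rows)


def _alignment_profile(aln_rows: list[str]) -> np.ndarray:
    """Per-column residue frequencies normalized by row count (L x 20)."""
    n = len(aln_rows)
    length = len(aln_rows[0])
    prof = np.zeros((length, 20))
    for row in aln_rows:
        for j, ch in enumerate(row):
            k = AA_INDEX.get(ch)
            if k is not None:
                prof[j, k] += 1.0
    return prof / n


def _merge(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Align two sub-alignments profile-to-profile and gap them onto the
    merged coordinate system."""
    prof_a = _alignment_profile(rows_a)
    prof_b = _alignment_profile(rows_b)
    _, path = affine_global_align(profile_pair_scores(prof_a, prof_b))
    idx_a = [i for i, _ in path]
    idx_b = [j for _, j in path]

    def gap_rows(rows: list[str], idxs: list[int]) -> list[str]:
        return ["".join("-" if k < 0 else row[k] for k in idxs) for row in rows]

    return gap_rows(rows_a, idx_a), gap_rows(rows_b, idx_b)


def kmer_distance(seq_a: str, seq_b: str, k: int = 3) -> float:
    """1 − (shared distinct k-mers / smaller distinct-k-mer count)."""
    ka, kb = kmer_set(seq_a, k), kmer_set(seq_b, k)
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def progressive_msa(seqs: dict[str, str]) -> MultipleAlignment:
    """Guide-tree progressive alignment of a set of protein sequences."""
    if not seqs:
        raise DataError("progressive_msa: empty sequence set")
    ids = sorted(seqs)
    if len(ids) == 1:
        return MultipleAlignment(ids=ids, rows=[seqs[ids[0]]])

    n = len(ids)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = kmer_distance(seqs[ids[i]], seqs[ids[j]])
    link = linkage(squareform(dmat, checks=False), method="average")

    # cluster index -> (sorted member ids, rows in that order)
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seqs[ids[i]]]) for i in range(n)
    }
    for step, (a, b, _dist, _cnt) in enumerate(link):
        ca, cb = clusters.pop(int(a)), clusters.pop(int(b))
        # visit children in sorted-id order for determinism
        if min(cb[0]) < min(ca[0]):
            ca, cb = cb, ca
        rows_a, rows_b = _merge(ca[1], cb[1])
        merged_ids = ca[0] + cb[0]
        clusters[n + step] = (merged_ids, rows_a + rows_b)

    (final_ids, final_rows), = clusters.values()
    order = np.argsort(final_ids)
    return MultipleAlignment(
        ids=[final_ids[k] for k in order], rows=[final_rows[k] for k in order]
    )


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances over a list of ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise DataError("distance matrix shape mismatch")
        if not np.all(np.isfinite(v)):
            raise DataError("non-finite distances")
        if np.any(v < 0) or not np.allclose(v, v.T) or np.any(np.diag(v) != 0):
            raise DataError("distance matrix must be symmetric, >=0, zero-diagonal")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


def pairwise_distances(aln: MultipleAlignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise-deletion distances between alignment rows.

    Sites where either row has a gap are excluded.  ``p`` is the mismatch
    fraction over used sites; ``poisson`` applies −ln(1−p) with p capped at
    0.95.  A pair with zero comparable sites is an error naming the pair.
    """
    if aln.n_rows < 2:
        raise DataError("pairwise_distances: need >=2 rows")
    if model not in ("p", "poisson"):
        raise DataError(f"unknown distance model {model!r}")
    mat = aln.to_int_matrix()
    valid = mat >= 0
    both = valid[:, None, :] & valid[None, :, :]
    used = both.sum(axis=2)
    diff = ((mat[:, None, :] != mat[None, :, :]) & both).sum(axis=2)
    n = aln.n_rows
    if np.any(used[np.triu_indices(n, k=1)] == 0):
        i, j = next(
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if used[i, j] == 0
        )
        raise DataError(
            f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
        )
    with np.errstate(invalid="ignore"):
        p = diff / used
    np.fill_diagonal(p, 0.0)
    if model == "poisson":
        p = np.minimum(p, P_CAP)
        d = -np.log1p(-p)
    else:
        d = p
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(ids=list(aln.ids), values=d)
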