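"""Pairwise and profile alignment primitives.

Local protein alignment is Smith–Waterman under BLOSUM62 with affine gaps
(open 11, extend 1: a gap of length k costs 11 + k), delegated to
Biopython's C ``PairwiseAligner``.  Significance uses the Karlin–Altschul
form E = K·m·n·e^(−λ·S) with fixed gapped BLOSUM62 constants (λ = 0.267,
K = 0.041), which reproduces the cutoff semantics of classic BLAST defaults
without a database-composition fit.

Profile–profile (and profile–sequence) global alignment is a Gotoh affine
dynamic program vectorized row-by-row with numpy; the horizontal-gap state
is computed with a running-max scan, so no compiled extension is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from symbioscreen.io import DataError

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

KA_LAMBDA = 0.267
KA_K = 0.041

GAP_OPEN = 11  # affine gap: opening a gap costs GAP_OPEN + GAP_EXTEND
GAP_EXTEND = 1


def _blosum62_with_worst_case_x() -> tuple[np.ndarray, str]:
    """BLOSUM62 over the 20 canonical residues plus X scoring worst case."""
    blosum = substitution_matrices.load("BLOSUM62")
    alphabet = AA_ORDER + "X"
    n = len(alphabet)
    mat = np.zeros((n, n))
    worst = min(float(v) for v in np.asarray(blosum).ravel())
    for i, a in enumerate(alphabet):
        for j, b in enumerate(alphabet):
            if a == "X" or b == "X":
                mat[i, j] = worst
            else:
                mat[i, j] = float(blosum[a, b])
    return mat, alphabet

_B62_ARRAY, _B62_ALPHABET = _blosum62_with_worst_case_x()
BLOSUM62X = substitution_matrices.Array(
    alphabet=_B62_ALPHABET, dims=2, data=_B62_ARRAY
)


def _make_local_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = BLOSUM62X
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner

_LOCAL_ALIGNER = _make_local_aligner()


@dataclass(frozen=True)
class LocalHit:
    """Result of one local alignment: score, E-value and traceback stats."""

    score: float
    evalue: float
    identity: float
    coverage: float


def karlin_altschul_evalue(score: float, m: int, n: int) -> float:
    """E = K·m·n·e^(−λS); underflows to 0.0 for very large scores."""
    try:
        return KA_K * m * n * math.exp(-KA_LAMBDA * score)
    except OverflowError:
        return math.inf


def pairwise_local_align(seq_a: str, seq_b: str) -> LocalHit:
    """Optimal Smith–Waterman local alignment of two protein sequences.

    Identity is the fraction of identical positions among aligned residue
    pairs of the optimal traceback; coverage is the aligned fraction of the
    shorter sequence.  Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise DataError("pairwise_local_align: empty sequence")
    score = float(_LOCAL_ALIGNER.score(seq_a, seq_b))
    if score <= 0:
        return LocalHit(score=0.0, evalue=math.inf, identity=0.0, coverage=0.0)
    alignment = _LOCAL_ALIGNER.align(seq_a, seq_b)[0]
    ident = 0
    aligned_pairs = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        aligned_pairs += a1 - a0
        for i, j in zip(range(a0, a1), range(b0, b1)):
            if seq_a[i] == seq_b[j]:
                ident += 1
    identity = ident / aligned_pairs if aligned_pairs else 0.0
    coverage = aligned_pairs / min(len(seq_a), len(seq_b))
    evalue = karlin_altschul_evalue(score, len(seq_a), len(seq_b))
    return LocalHit(score=score, evalue=evalue, identity=identity, coverage=coverage)


def kmer_set(seq: str, k: int = 4) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def shared_kmer_count(a: frozenset[str], b: frozenset[str]) -> int:
    """Number of distinct k-mers two sequences share (prefilter statistic)."""
    if len(a) > len(b):
        a, b = b, a
    return len(a & b)


def seq_to_profile(seq: str) -> np.ndarray:
    """One-hot residue frequency profile of a gapless sequence (L x 20).

    X rows are all-zero: an ambiguous residue contributes nothing to column
    scores, the totalized worst-case handling for profile alignment.
    """
    prof = np.zeros((len(seq), 20))
    for i, aa in enumerate(seq):
        j = AA_INDEX.get(aa)
        if j is not None:
            prof[i, j] = 1.0
    return prof

_B62_20 = _B62_ARRAY[:20, :20]


def profile_pair_scores(prof_a: np.ndarray, prof_b: np.ndarray) -> np.ndarray:
    """Mean-of-pairs BLOSUM62 column-vs-column score matrix (La x Lb).

    Profiles are per-column residue frequency vectors normalized by the
    number of rows, so gaps dilute a column's score toward zero.
    """
    return prof_a @ _B62_20 @ prof_b.T


def affine_global_align(scores: np.ndarray,
                        gap_open: float = float(GAP_OPEN),
                        gap_extend: float = float(GAP_EXTEND),
                        ) -> tuple[float, list[tuple[int, int]]]:
    """Global (Needleman–Wunsch/Gotoh) alignment over a precomputed
    position-pair score matrix.

    Returns the optimal score and the traceback as a list of
    ``(i, j)`` steps where ``i``/``j`` are 0-based positions or -1 for a gap
    in the respective profile.  Deterministic tie-break: match preferred over
    a vertical gap over a horizontal gap.
    """
    la, lb = scores.shape
    go = gap_open + gap_extend  # cost of the first gapped position
    ge = gap_extend
    neg = -1e30

    M = np.full((la + 1, lb + 1), neg)
    Ix = np.full((la + 1, lb + 1), neg)  # gap in A (consumes B columns)
    Iy = np.full((la + 1, lb + 1), neg)  # gap in B (consumes A rows)
    M[0, 0] = 0.0
    if lb:
        Ix[0, 1:] = -go - ge * np.arange(lb)
    if la:
        Iy[1:, 0] = -go - ge * np.arange(la)

    for i in range(1, la + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = scores[i - 1] + prev_best[:-1]
        Iy[i] = np.maximum(M[i - 1] - go, Iy[i - 1] - ge)
        Iy[i, 0] = -go - ge * (i - 1)
        # Ix[i, j] = max(M[i, j-1] - go, Ix[i, j-1] - ge): running-max scan
        t = M[i, :-1] + ge * np.arange(lb)
        run = np.maximum.accumulate(t)
        Ix[i, 1:] = run - go - ge * np.arange(lb)
        Ix[i, 0] = neg

    end_vals = (M[la, lb], Iy[la, lb], Ix[la, lb])
    best = max(end_vals)

    # traceback by predecessor-value matching
    path: list[tuple[int, int]] = []
    eps = 1e-6
    i, j = la, lb
    if abs(M[i, j] - best) < eps:
        state = "M"
    elif abs(Iy[i, j] - best) < eps:
        state = "Iy"
    else:
        state = "Ix"
    while i > 0 or j > 0:
        if state == "M":
            path.append((i - 1, j - 1))
            prev = M[i, j] - scores[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            if abs(M[i, j] - prev) < eps:
                state = "M"
            elif abs(Iy[i, j] - prev) < eps:
                state = "Iy"
            else:
                state = "Ix"
        elif state == "Iy":
            path.append((i - 1, -1))
            val = Iy[i, j]
            i -= 1
            if abs(M[i, j] - go - val) < eps:
                state = "M"
            else:
                state = "Iy"
        else:  # Ix
            path.append((-1, j - 1))
            val = Ix[i, j]
            j -= 1
            if abs(M[i, j] - go - val) < eps:
                state = "M"
            else:
                state = "Ix"
    path.reverse()
    return float(best), path
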