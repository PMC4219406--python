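"""Fragment-based whole-genome average percent nucleotide identity (APNI).

This follows the ANIb convention: each genome is cut into 1020-bp
fragments, every fragment of A is aligned to genome B (and vice versa),
fragments with at least 30% identity over at least 70% of their length are
retained, and APNI is the mean of the two directional mean identities,
as a percent.  95% is the conventional same-species benchmark.

Fragment placement uses exact 15-mer seeds (both strands) into the target,
then an infix (semi-global) alignment of the fragment against a small
candidate window with edlib; identity is 1 − edits / alignment length.
N never matches: fragments more than half N are discarded before alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from symbioscreen.io import DataError, GenomeAssembly

SEED_K = 15
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ApniParams:
    fragment_length: int = 1020
    min_fragment_identity: float = 0.30
    min_fragment_coverage: float = 0.70
    species_cutoff: float = 95.0
    seed_step: int = SEED_K
    window_pad: int = 60

    def __post_init__(self) -> None:
        if self.fragment_length < 100:
            raise DataError("fragment_length must be >= 100")
        for thr in (self.min_fragment_identity, self.min_fragment_coverage):
            if not 0 < thr <= 1:
                raise DataError("retention thresholds must be in (0, 1]")


@dataclass
class ApniResult:
    genome_a: str
    genome_b: str
    apni: float | None  # percent, None when no fragments aligned
    fragments_used: tuple[int, int]
    fragments_total: tuple[int, int]
    same_species: bool
    no_alignment: bool = False


def fragment_genome(assembly: GenomeAssembly, length: int) -> list[str]:
    """Consecutive non-overlapping windows per contig.

    A terminal remainder shorter than length/2 is dropped; a remainder of at
    least length/2 is kept as a short fragment.  Fragments tile each contig
    without overlap.
    """
    if not assembly.contigs:
        raise DataError("fragment_genome: empty assembly")
    fragments: list[str] = []
    for cid in sorted(assembly.contigs):
        seq = assembly.contigs[cid]
        n_full = len(seq) // length
        for k in range(n_full):
            fragments.append(seq[k * length : (k + 1) * length])
        rem = len(seq) - n_full * length
        if rem * 2 >= length:
            fragments.append(seq[n_full * length :])
    return fragments


def _seed_index(assembly: GenomeAssembly, k: int = SEED_K) -> dict[str, tuple[str, int]]:
    """First occurrence of each k-mer: kmer -> (contig_id, position)."""
    index: dict[str, tuple[str, int]] = {}
    for cid in sorted(assembly.contigs):
        seq = assembly.contigs[cid]
        for pos in range(0, len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            if kmer not in index:
                index[kmer] = (cid, pos)
    return index


def _align_fragment(
    fragment: str,
    target: GenomeAssembly,
    index: dict[str, tuple[str, int]],
    params: ApniParams,
) -> tuple[float, float] | None:
    """Best (identity, coverage) of a fragment against the target, trying
    seeds on both strands; None when no seed places the fragment."""
    best: tuple[float, float] | None = None
    for oriented in (fragment, revcomp(fragment)):
        for offset in range(0, len(oriented) - SEED_K + 1, params.seed_step):
            hit = index.get(oriented[offset : offset + SEED_K])
            if hit is None:
                continue
            cid, pos = hit
            contig = target.contigs[cid]
            start = max(0, pos - offset - params.window_pad)
            end = min(len(contig), pos - offset + len(oriented) + params.window_pad)
            window = contig[start:end]
            if len(window) < SEED_K:
                continue
            res = edlib.align(oriented, window, mode="HW", task="path")
            if res["editDistance"] < 0 or not res["cigar"]:
                continue
            aln_len = 0
            query_consumed = 0
            num = ""
            for ch in res["cigar"]:
                if ch.isdigit():
                    num += ch
                else:
                    n = int(num)
                    num = ""
                    aln_len += n
                    if ch != "D":  # =, X, M, I consume the query
                        query_consumed += n
            identity = 1.0 - res["editDistance"] / aln_len
            coverage = query_consumed / len(fragment)
            if best is None or identity > best[0]:
                best = (identity, coverage)
            break  # one seed per strand suffices; window covers the fragment
    return best


def _directional_ani(
    query: GenomeAssembly, target: GenomeAssembly, params: ApniParams
) -> tuple[float | None, int, int]:
    fragments = fragment_genome(query, params.fragment_length)
    fragments = [f for f in fragments if f.count("N") * 2 <= len(f)]
    index = _seed_index(target)
    identities = []
    for frag in fragments:
        result = _align_fragment(frag, target, index, params)
        if result is None:
            continue
        identity, coverage = result
        if identity >= params.min_fragment_identity and coverage >= params.min_fragment_coverage:
            identities.append(identity)
    if not identities:
        return None, 0, len(fragments)
    return (
        100.0 * sum(identities) / len(identities),
        len(identities),
        len(fragments),
    )


def compute_apni(
    genome_a: GenomeAssembly, genome_b: GenomeAssembly, params: ApniParams | None = None
) -> ApniResult:
    """Reciprocal fragment APNI between two assemblies.

    The value is the mean of the two directional ANIs, in percent.  When no
    fragment aligns in either direction the result is flagged
    ``no_alignment`` (APNI undefined, not zero).
    """
    params = params or ApniParams()
    ani_ab, used_ab, total_ab = _directional_ani(genome_a, genome_b, params)
    ani_ba, used_ba, total_ba = _directional_ani(genome_b, genome_a, params)
    if ani_ab is None or ani_ba is None:
        return ApniResult(
            genome_a=genome_a.genome_id,
            genome_b=genome_b.genome_id,
            apni=None,
            fragments_used=(used_ab, used_ba),
            fragments_total=(total_ab, total_ba),
            same_species=False,
            no_alignment=True,
        )
    apni = (ani_ab + ani_ba) / 2.0
    return ApniResult(
        genome_a=genome_a.genome_id,
        genome_b=genome_b.genome_id,
        apni=apni,
        fragments_used=(used_ab, used_ba),
        fragments_total=(total_ab, total_ba),
        same_species=apni >= params.species_cutoff,
    )


def apni_matrix(
    genomes: list[GenomeAssembly], params: ApniParams | None = None
) -> list[ApniResult]:
    """All unordered pairs, sorted by (genome_a, genome_b)."""
    results = []
    ordered = sorted(genomes, key=lambda g: g.genome_id)
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            results.append(compute_apni(ordered[i], ordered[j], params))
    return results
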