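"""Synthetic genome families with ground truth.

The generator emulates the study design the screen assumes: a set of
related genomes descended from a random species tree; per-gene families
(COGs) with variable presence/absence; a planted fraction of families in
which the designated in-group is monophyletic by construction (a clade
re-grafted on a fresh stem of length ``group_separation``), mimicking
niche-specific shared ancestry or transfer; nucleotide genomes at a
controlled pairwise divergence for APNI recovery; and annotation strings
that include mobile-element keywords.

Two constraints keep the truth table exact:

* the species tree is redrawn (bounded, seeded) until the in-group is NOT
  monophyletic in it, so the null families genuinely lack the signal;
* for a non-planted family whose sampled presence pattern would make the
  in-group exclusive in the pruned species tree (all interleaving taxa
  absent by chance), presence is resampled, so the planted flag coincides
  with realized gene-tree monophyly.

All randomness flows from one integer seed; emitted datasets are
byte-identical across runs with the same config.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from symbioscreen.align import AA_ORDER
from symbioscreen.io import DataError, TaxonGroup, write_table

SPACER_LENGTH = 200
NUCS = "ACGT"

# fixed standard codon table, uniform synonymous choice at back-translation
_CODONS: dict[str, list[str]] = {}
_TABLE = {
    "F": ["TTT", "TTC"], "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "I": ["ATT", "ATC", "ATA"], "M": ["ATG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "A": ["GCT", "GCC", "GCA", "GCG"], "Y": ["TAT", "TAC"],
    "H": ["CAT", "CAC"], "Q": ["CAA", "CAG"], "N": ["AAT", "AAC"],
    "K": ["AAA", "AAG"], "D": ["GAT", "GAC"], "E": ["GAA", "GAG"],
    "C": ["TGT", "TGC"], "W": ["TGG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
}
_CODONS.update(_TABLE)


class SimNode:
    """Rooted binary tree node for simulation."""

    __slots__ = ("name", "length", "children")

    def __init__(self, name: str | None = None, length: float = 0.0,
                 children: list["SimNode"] | None = None):
        self.name = name
        self.length = length
        self.children = children or []

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["SimNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def copy(self) -> "SimNode":
        return SimNode(
            name=self.name,
            length=self.length,
            children=[c.copy() for c in self.children],
        )

    def to_newick(self) -> str:
        def render(node: SimNode) -> str:
            if node.is_leaf():
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}):{node.length:.6g}"

        if self.is_leaf():
            return f"{self.name};"
        return "(" + ",".join(render(c) for c in self.children) + ");"


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic data.

    Defaults are the conditions the screen is validated under: 8 genomes of
    which 3 form the in-group, 200 gene families, 10% planted monophyly at
    stem separation 0.5, 300-residue proteins, presence probability 0.85,
    substitution rate 1 per unit branch length, branch-length mean 0.1 and
    a 5% nucleotide divergence pair for APNI recovery.
    """

    n_genomes: int = 8
    in_group: tuple[str, ...] = ("g01", "g02", "g03")
    n_cogs: int = 200
    plant_fraction: float = 0.1
    presence_prob: float = 0.85
    protein_length: int = 300
    substitution_rate: float = 1.0
    group_separation: float = 0.5
    genome_divergence: float = 0.05
    apni_pair_length: int = 100_000
    branch_length_mean: float = 0.1
    mobile_annotation_fraction: float = 0.05
    seed: int = 11

    def __post_init__(self) -> None:
        for p in (self.plant_fraction, self.presence_prob,
                  self.genome_divergence, self.mobile_annotation_fraction):
            if not 0 <= p <= 1:
                raise DataError("probabilities must be in [0, 1]")
        if self.seed is None:
            raise DataError("seed is mandatory")
        if self.plant_fraction > 0 and len(self.in_group) < 2:
            raise DataError("planting requires an in-group of >=2 genomes")

    @property
    def genome_ids(self) -> list[str]:
        return [f"g{i + 1:02d}" for i in range(self.n_genomes)]


def simulate_species_tree(n: int, seed: int, branch_length_mean: float = 0.1) -> SimNode:
    """Random bifurcating tree by sequential uniform edge attachment
    (uniform over labelled topologies), exponential branch lengths."""
    if n < 4:
        raise DataError("simulate_species_tree: need n >= 4")
    rng = np.random.default_rng(seed)

    def bl() -> float:
        return float(rng.exponential(branch_length_mean)) + 1e-6

    names = [f"g{i + 1:02d}" for i in range(n)]
    root = SimNode(children=[SimNode(name=names[0], length=bl()),
                             SimNode(name=names[1], length=bl())])
    for name in names[2:]:
        # collect (parent, child-slot) edges
        edges: list[tuple[SimNode, int]] = []
        stack = [root]
        while stack:
            node = stack.pop()
            for k, child in enumerate(node.children):
                edges.append((node, k))
                stack.append(child)
        parent, slot = edges[rng.integers(0, len(edges))]
        old = parent.children[slot]
        split = rng.uniform(0.0, old.length)
        new_internal = SimNode(length=old.length - split)
        old.length = split
        new_internal.children = [old, SimNode(name=name, length=bl())]
        parent.children[slot] = new_internal
    return root


def prune_to(tree: SimNode, keep: set[str]) -> SimNode | None:
    """Copy of the tree restricted to the named leaves, unifurcations
    suppressed (lengths summed)."""

    def recurse(node: SimNode) -> SimNode | None:
        if node.is_leaf():
            if node.name in keep:
                return SimNode(name=node.name, length=node.length)
            return None
        kept = [c for c in (recurse(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            kept[0].length += node.length
            return kept[0]
        return SimNode(length=node.length, children=kept)

    return recurse(tree)


def _clade_sets(tree: SimNode) -> list[frozenset[str]]:
    out = []

    def recurse(node: SimNode) -> frozenset[str]:
        if node.is_leaf():
            s = frozenset([node.name])
        else:
            s = frozenset().union(*(recurse(c) for c in node.children))
        out.append(s)
        return s

    recurse(tree)
    return out


def group_exclusive_in_tree(tree: SimNode, group: set[str]) -> bool:
    """Does some edge of the (unrooted view of the) tree isolate exactly
    ``group``?  Both a clade and its complement count."""
    leaves = set(tree.leaf_names())
    if not group <= leaves or group == leaves:
        return False
    target = frozenset(group)
    complement = frozenset(leaves - group)
    clades = _clade_sets(tree)
    return target in clades or complement in clades


@dataclass
class CogSpec:
    """One simulated gene family."""

    cog_index: int
    planted: bool
    presence: dict[str, bool]
    gene_tree: SimNode


@dataclass
class SyntheticTruth:
    species_tree_newick: str
    cogs: list[CogSpec]
    realized_divergence: float | None = None
    gene_records: list[dict] = field(default_factory=list)

    def planted_indices(self) -> list[int]:
        return [c.cog_index for c in self.cogs if c.planted]


def simulate_cog_set(
    species_tree: SimNode, config: SimulationConfig, rng: np.random.Generator
) -> list[CogSpec]:
    """Sample presence and build gene trees, planting in-group monophyly in
    a ``plant_fraction`` of families."""
    genomes = config.genome_ids
    in_group = set(config.in_group)
    out_genomes = [g for g in genomes if g not in in_group]
    planted_flags = rng.random(config.n_cogs) < config.plant_fraction
    cogs: list[CogSpec] = []
    for idx in range(config.n_cogs):
        planted = bool(planted_flags[idx]) and len(in_group) >= 2
        presence = {g: True for g in genomes}
        for _attempt in range(60):
            presence = {g: bool(rng.random() < config.presence_prob) for g in genomes}
            if planted:
                for g in in_group:
                    presence[g] = True
                if not any(presence[g] for g in out_genomes):
                    continue  # need an out-group side for a bipartition
            present = {g for g, p in presence.items() if p}
            if sum(presence.values()) < 3:
                if planted:
                    continue
                break  # too small to screen; monophyly is moot
            if not planted and in_group <= present:
                pruned = prune_to(species_tree, present)
                if group_exclusive_in_tree(pruned, in_group):
                    continue  # null family must stay non-exclusive
            break
        present = {g for g, p in presence.items() if p}
        if planted and not present - in_group:
            presence[out_genomes[0]] = True  # resampling bound hit; force
            present.add(out_genomes[0])
        if not planted and in_group <= present and len(present) >= 3:
            pruned = prune_to(species_tree, present)
            if group_exclusive_in_tree(pruned, in_group):
                presence = {g: True for g in genomes}  # full tree is non-exclusive
                present = set(genomes)
        if planted:
            residual = prune_to(species_tree, present - in_group)
            clade = prune_to(species_tree, in_group & present)
            clade.length = config.group_separation
            if residual.is_leaf():
                residual = SimNode(children=[residual])
            gene_tree = SimNode(children=[residual, clade])
            residual.length = 0.0
        elif present:
            gene_tree = prune_to(species_tree, present)
        else:
            gene_tree = None
        cogs.append(
            CogSpec(cog_index=idx, planted=planted, presence=presence, gene_tree=gene_tree)
        )
    return cogs


def evolve_proteins(
    gene_tree: SimNode, length: int, rate: float, seed: int
) -> dict[str, str]:
    """Evolve one protein family down the gene tree.

    The root sequence is uniform over the 20 amino acids; along each branch
    of length l every site substitutes with probability 1 − exp(−rate·l),
    the replacement uniform over the other 19 residues.
    """
    if length < 50:
        raise DataError("evolve_proteins: length must be >= 50")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 20, length)
    out: dict[str, str] = {}

    def descend(node: SimNode, seq: np.ndarray) -> None:
        p = 1.0 - math.exp(-rate * node.length)
        mask = rng.random(length) < p
        seq = seq.copy()
        if mask.any():
            shift = rng.integers(1, 20, int(mask.sum()))
            seq[mask] = (seq[mask] + shift) % 20
        if node.is_leaf():
            out[node.name] = "".join(AA_ORDER[i] for i in seq)
        else:
            for child in node.children:
                descend(child, seq)

    for child in gene_tree.children:
        descend(child, root_seq)
    if gene_tree.is_leaf():
        out[gene_tree.name] = "".join(AA_ORDER[i] for i in root_seq)
    return out


def back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [
        _CODONS[aa][rng.integers(0, len(_CODONS[aa]))] if aa in _CODONS else "NNN"
        for aa in protein
    ]
    return "".join(codons) + "TAA"


def random_nucleotides(n: int, rng: np.random.Generator) -> str:
    return "".join(NUCS[i] for i in rng.integers(0, 4, n))


def mutate_nucleotides(seq: str, divergence: float, rng: np.random.Generator) -> tuple[str, float]:
    """Substitute each site with probability ``divergence`` (uniform other
    base); returns the mutant and the realized substituted fraction."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    code = np.zeros(256, dtype=np.int8)
    for i, b in enumerate(NUCS):
        code[ord(b)] = i
    idx = code[arr]
    mask = rng.random(len(seq)) < divergence
    shift = rng.integers(1, 4, int(mask.sum()))
    idx[mask] = (idx[mask] + shift) % 4
    lut = np.frombuffer(NUCS.encode(), dtype=np.uint8)
    mutant = lut[idx].tobytes().decode()
    return mutant, float(mask.mean())


_MOBILE_ANNOTATIONS = (
    "phage integrase",
    "plasmid replication protein",
    "ParA partition ATPase",
    "phage tail fiber protein",
    "plasmid mobilization protein",
)


def emit_dataset(config: SimulationConfig, outdir, overwrite: bool = False) -> SyntheticTruth:
    """Write the full synthetic dataset and return its ground truth.

    Outputs per genome: a protein FASTA, a nucleotide genome FASTA and a
    GFF3; plus one annotation TSV, one truth TSV, the species tree newick,
    a divergent nucleotide pair for APNI tests, and a config echo.
    Planted-family genes of in-group genomes are placed consecutively on
    contig 1 so that genuine loci exist for the locus-assignment stage.
    """
    outdir = str(outdir)
    if os.path.isdir(outdir) and os.listdir(outdir) and not overwrite:
        raise DataError(f"output directory {outdir!r} is not empty")
    for sub in ("proteins", "genomes", "annotations"):
        os.makedirs(os.path.join(outdir, sub), exist_ok=True)

    # species tree: redraw until the in-group is not monophyletic
    in_group = set(config.in_group)
    tree = None
    for k in range(100):
        cand = simulate_species_tree(
            config.n_genomes, config.seed + k, config.branch_length_mean
        )
        if not group_exclusive_in_tree(cand, in_group):
            tree = cand
            break
    if tree is None:
        raise DataError("could not draw a species tree with a non-monophyletic in-group")

    rng = np.random.default_rng(config.seed + 7_000_003)
    cogs = simulate_cog_set(tree, config, rng)

    # evolve sequences per family
    seqs: dict[int, dict[str, str]] = {}
    for spec in cogs:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if spec.gene_tree is None:
            seqs[spec.cog_index] = {}
            continue
        seqs[spec.cog_index] = evolve_proteins(
            spec.gene_tree, config.protein_length, config.substitution_rate,
            seed=sub_seed,
        )

    # per-genome gene order: planted-family genes first (consecutive block
    # on contig 1 for in-group genomes), then the rest shuffled
    gene_records: list[dict] = []
    annotation_rows: list[dict] = []
    mobile_flags = rng.random(config.n_cogs) < config.mobile_annotation_fraction
    mobile_choice = rng.integers(0, len(_MOBILE_ANNOTATIONS), config.n_cogs)
    for gid in config.genome_ids:
        members = sorted(idx for idx, spec in enumerate(cogs) if spec.presence[gid]
                         and gid in seqs[idx])
        planted_members = [i for i in members if cogs[i].planted]
        other_members = [i for i in members if not cogs[i].planted]
        perm = rng.permutation(len(other_members))
        ordered = planted_members + [other_members[k] for k in perm]
        half = max(1, len(ordered) // 2 + 3)
        contigs: dict[str, list[int]] = {
            f"{gid}_c1": ordered[:half],
            f"{gid}_c2": ordered[half:],
        }
        fasta_path = os.path.join(outdir, "proteins", f"{gid}.faa")
        gff_path = os.path.join(outdir, "annotations", f"{gid}.gff3")
        genome_path = os.path.join(outdir, "genomes", f"{gid}.fna")
        contig_seqs: dict[str, str] = {}
        with open(fasta_path, "w", newline="\n") as faa, \
             open(gff_path, "w", newline="\n") as gff:
            gff.write("##gff-version 3\n")
            for cid, cog_indices in contigs.items():
                pos = 1
                parts = [random_nucleotides(SPACER_LENGTH, rng)]
                pos += SPACER_LENGTH
                for cog_idx in cog_indices:
                    protein = seqs[cog_idx][gid]
                    pid = f"{gid}_C{cog_idx:04d}"
                    if mobile_flags[cog_idx]:
                        annotation = _MOBILE_ANNOTATIONS[mobile_choice[cog_idx]]
                    else:
                        annotation = f"family F{cog_idx:04d} protein"
                    nt = back_translate(protein, rng)
                    start, end = pos, pos + len(nt) - 1
                    strand = "+" if rng.random() < 0.5 else "-"
                    faa.write(f">{pid} {annotation}\n{protein}\n")
                    gff.write(
                        f"{cid}\tsim\tCDS\t{start}\t{end}\t.\t{strand}\t0\t"
                        f"ID={pid};product={annotation}\n"
                    )
                    annotation_rows.append(
                        {"protein_id": pid, "genome_id": gid, "contig_id": cid,
                         "annotation": annotation}
                    )
                    gene_records.append(
                        {"protein_id": pid, "genome_id": gid, "cog_index": cog_idx,
                         "contig_id": cid, "start": start, "end": end,
                         "planted": int(cogs[cog_idx].planted)}
                    )
                    parts.append(nt)
                    parts.append(random_nucleotides(SPACER_LENGTH, rng))
                    pos = end + 1 + SPACER_LENGTH
                contig_seqs[cid] = "".join(parts)
        with open(genome_path, "w", newline="\n") as fna:
            for cid, seq in contig_seqs.items():
                fna.write(f">{cid}\n{seq}\n")

    # divergent nucleotide pair for APNI recovery
    base = random_nucleotides(config.apni_pair_length, rng)
    mutant, realized = mutate_nucleotides(base, config.genome_divergence, rng)
    with open(os.path.join(outdir, "genomes", "apni_pair_a.fna"), "w", newline="\n") as fh:
        fh.write(f">apni_a_c1\n{base}\n")
    with open(os.path.join(outdir, "genomes", "apni_pair_b.fna"), "w", newline="\n") as fh:
        fh.write(f">apni_b_c1\n{mutant}\n")

    write_table(
        annotation_rows,
        os.path.join(outdir, "annotations.tsv"),
        columns=["protein_id", "genome_id", "contig_id", "annotation"],
    )
    truth_rows = [
        {
            "cog_index": spec.cog_index,
            "planted": int(spec.planted),
            "n_present": sum(spec.presence.values()),
            "present_genomes": ",".join(sorted(g for g, p in spec.presence.items() if p)),
        }
        for spec in cogs
    ]
    write_table(
        truth_rows,
        os.path.join(outdir, "truth.tsv"),
        columns=["cog_index", "planted", "n_present", "present_genomes"],
    )
    write_table(
        gene_records,
        os.path.join(outdir, "genes.tsv"),
        columns=["protein_id", "genome_id", "cog_index", "contig_id",
                 "start", "end", "planted"],
    )
    with open(os.path.join(outdir, "species_tree.nwk"), "w", newline="\n") as fh:
        fh.write(tree.to_newick() + "\n")
    with open(os.path.join(outdir, "config.yaml"), "w", newline="\n") as fh:
        yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in vars(config).items()},
            fh, sort_keys=True,
        )

    return SyntheticTruth(
        species_tree_newick=tree.to_newick(),
        cogs=cogs,
        realized_divergence=realized,
        gene_records=gene_records,
    )


def true_family_of(protein_id: str) -> int:
    """Family index encoded in a synthetic protein id (``g01_C0042``)."""
    return int(protein_id.rsplit("_C", 1)[1])


def evaluate_screen(
    hits: list,
    truth: SyntheticTruth,
    cogs: list,
    group: TaxonGroup,
    min_members: int = 3,
) -> dict:
    """Sensitivity and false-positive rate of a screen run against truth.

    Each recovered COG is mapped to the majority true family of its members.
    A planted family counts as detected when some retained hit maps to it;
    the false-positive denominator is the set of screen-eligible (>=3
    members, in-group co-present) non-planted families.
    """
    family_of_cog: dict[str, int] = {}
    for cog in cogs:
        fams = [true_family_of(pid) for pid in cog.protein_ids]
        family_of_cog[cog.cog_id] = max(set(fams), key=fams.count)

    planted = set(truth.planted_indices())
    eligible_null = set()
    for spec in truth.cogs:
        present = {g for g, p in spec.presence.items() if p}
        if (
            not spec.planted
            and len(present) >= min_members
            and group.members <= present
        ):
            eligible_null.add(spec.cog_index)

    detected: set[int] = set()
    false_hits: set[int] = set()
    for hit in hits:
        if not hit.retained:
            continue
        fam = family_of_cog.get(hit.cog_id)
        if fam is None:
            continue
        if fam in planted:
            detected.add(fam)
        else:
            false_hits.add(fam)
    sensitivity = len(detected) / len(planted) if planted else float("nan")
    fpr = len(false_hits & eligible_null) / len(eligible_null) if eligible_null else 0.0
    return {
        "n_planted": len(planted),
        "n_detected": len(detected),
        "n_eligible_null": len(eligible_null),
        "n_false": len(false_hits & eligible_null),
        "sensitivity": sensitivity,
        "false_positive_rate": fpr,
    }
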