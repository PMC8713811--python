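"""Synthetic inputs for every pipeline stage.

Generates (i) protein chains of each of the six MHC chain classes, built
from the schema's frame consensi with the class's diagnostic residues
planted and background positions mutated at a configurable rate; (ii)
alignments evolved along a tree with a planted clade marked by shared
derived residues (the WA-alpha2 + b2m style signal); and (iii) GFF3 loci
containing head-to-head gene pairs among decoys.  Everything is
deterministic for a given :class:`SimConfig` seed, and each generator also
returns a truth record sufficient to score the downstream stage.

The frame consensus backbones are fixed arbitrary sequences shipped with
the package; the generator makes no attempt to mimic real shark or teleost
sequence composition.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .frames import SignatureSchema, default_schema
from .pairs import GeneModel
from .phylo import make_distance_matrix

AA = "ACDEFGHIKLMNPQRSTVWY"

#: domain layout per chain class, N- to C-terminal
LAYOUTS = {
    "I_HEAVY": ("DISTAL_A1TYPE", "DISTAL_A2TYPE", "IG_C1", "TM"),
    "B2M": ("IG_C1",),
    "IIA": ("DISTAL_A1TYPE", "IG_C1", "TM"),
    "WA": ("DISTAL_A1TYPE", "IG_C1", "TM"),
    "IIB": ("DISTAL_A2TYPE", "IG_C1", "TM"),
    "WB": ("DISTAL_A2TYPE", "IG_C1", "TM"),
}

#: short hydrophilic cytoplasmic tail appended after the TM segment
CY_TAIL = "RKSSNEKQ"

#: default diagnostic columns planted on the WA-alpha2 + b2m style clade
#: (Ig frame: Y8, L37, L55, F57, W61)
DEFAULT_CLADE_COLUMNS = {8: "Y", 37: "L", 55: "L", 57: "F", 61: "W"}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generators."""

    seed: int = 0
    mu: float = 0.0              # mutation rate on non-signature positions
    count_per_class: int = 100   # chains per class for batch generation
    branch_scale: float = 1.0    # multiplies all branch lengths
    pair_gap: int = 2_000        # intergenic gap inside a head-to-head pair (bp)
    group_spacing: int = 30_000  # spacing that isolates gene groups (bp)
    decoy_far_gap: int = 25_000  # gap of the "too distant" facing decoys (bp)

    def __post_init__(self):
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mutation rate mu must lie in [0, 1]")
        if self.count_per_class < 0:
            raise ValueError("count_per_class must be >= 0")


def _rng(config: SimConfig, stream: int = 0):
    return np.random.default_rng((int(config.seed), stream))


# ---------------------------------------------------------------------------
# chains


def make_chain(label: str, config: SimConfig, rng=None,
               schema: SignatureSchema | None = None,
               randomize_signatures: bool = False):
    """One synthetic chain of a class, plus its truth record.

    The chain concatenates the frame consensi of the class's domain layout;
    the class's signature columns are overwritten with residues sampled
    uniformly from the allowed set (e.g. F or Y at Ig position 57 of a WA
    chain), indel regions absent in the class are deleted, TM glycines are
    planted, and non-signature positions are mutated at rate ``config.mu``.
    With ``randomize_signatures`` the signature columns are drawn uniformly
    at random instead — a signature-free null chain of MHC-like
    architecture.
    """
    if label not in LAYOUTS:
        raise ValueError(f"unknown chain class {label!r}")
    schema = schema or default_schema()
    rng = _rng(config, stream=1) if rng is None else rng

    planted = []
    deleted_regions = []
    parts = []
    for frame_name in LAYOUTS[label]:
        frame = schema.frame(frame_name)
        residues = list(frame.consensus)
        protected = set()

        for sig in schema.signatures_for(frame=frame_name, chain_class=label):
            idx = sig.position - frame.numbering_origin
            choice = rng.choice(sorted(sig.allowed_residues))
            residues[idx] = str(choice)
            protected.add(idx)
            planted.append((frame_name, sig.position, str(choice)))
        if frame_name == "IG_C1":
            for col in schema.invariant_cysteine_positions:
                idx = col - frame.numbering_origin
                residues[idx] = "C"
                protected.add(idx)
        if frame_name == "TM":
            for col in schema.tm_glycine_patterns.get(label, []):
                idx = col - frame.numbering_origin
                residues[idx] = "G"
                protected.add(idx)
                planted.append((frame_name, col, "G"))

        if randomize_signatures:
            for idx in protected:
                residues[idx] = AA[rng.integers(0, 20)]
            planted.clear()

        # class-absent indel regions are deleted from the domain
        drop = set()
        for region in schema.indel_regions_for(frame_name):
            if label in region.absent_in:
                for col in region.columns:
                    drop.add(col - frame.numbering_origin)
                deleted_regions.append((frame_name, region.start_column, region.end_column))

        # background mutation at rate mu on unprotected, undeleted positions
        for idx in range(len(residues)):
            if idx in protected or idx in drop:
                continue
            if config.mu > 0 and rng.random() < config.mu:
                current = residues[idx]
                alternatives = AA.replace(current, "")
                residues[idx] = alternatives[rng.integers(0, len(alternatives))]

        parts.append("".join(r for i, r in enumerate(residues) if i not in drop))

    sequence = "".join(parts)
    if "TM" in LAYOUTS[label]:
        sequence += CY_TAIL
    truth = {
        "label": label,
        "layout": LAYOUTS[label],
        "planted": planted,
        "deleted_regions": deleted_regions,
        "randomized": randomize_signatures,
        "mu": config.mu,
    }
    return sequence, truth


def make_chain_set(config: SimConfig, labels=tuple(LAYOUTS),
                   schema: SignatureSchema | None = None,
                   randomize_signatures: bool = False):
    """``count_per_class`` chains per label; returns ``{chain_id: (seq, truth)}``."""
    schema = schema or default_schema()
    rng = _rng(config, stream=1)
    out = {}
    for label in labels:
        for k in range(config.count_per_class):
            chain_id = f"{label}_{k:03d}"
            out[chain_id] = make_chain(
                label, config, rng=rng, schema=schema,
                randomize_signatures=randomize_signatures,
            )
    return out


# ---------------------------------------------------------------------------
# alignments with a planted clade


def _evolve(parent: np.ndarray, branch_length: float, rng) -> np.ndarray:
    """Per-site substitution with probability 1 - exp(-b); uniform replacement."""
    child = parent.copy()
    if branch_length <= 0:
        return child
    p = 1.0 - np.exp(-branch_length)
    hits = np.nonzero(rng.random(child.size) < p)[0]
    for idx in hits:
        current = child[idx]
        alternatives = AA.replace(current, "")
        child[idx] = alternatives[rng.integers(0, len(alternatives))]
    return child


def make_alignment_set(tree, config: SimConfig, planted_clade=(),
                       diagnostic_columns=None,
                       schema: SignatureSchema | None = None):
    """Evolve the Ig C1 consensus along a tree and plant a clade signal.

    ``tree`` is a Newick string or a ``skbio.TreeNode`` with labelled leaves
    and branch lengths.  After simulation, the designated diagnostic columns
    of every leaf in ``planted_clade`` are overwritten with the clade
    residues, making them invariant within the clade.  Returns
    ``(alignment dict, truth record)``.
    """
    schema = schema or default_schema()
    if isinstance(tree, str):
        try:
            tree = TreeNode.read(io.StringIO(tree), convert_underscores=False)
        except Exception as exc:
            raise ValueError(f"malformed Newick tree: {exc}") from exc
    diagnostic_columns = dict(diagnostic_columns or DEFAULT_CLADE_COLUMNS)

    frame = schema.frame("IG_C1")
    rng = _rng(config, stream=2)
    root_seq = np.array(list(frame.consensus))

    alignment = {}

    def descend(node, seq):
        for child in node.children:
            b = (child.length or 0.0) * config.branch_scale
            if b < 0:
                raise ValueError("branch lengths must be >= 0")
            child_seq = _evolve(seq, b, rng)
            if child.is_tip():
                alignment[child.name] = child_seq
            else:
                descend(child, child_seq)

    if tree.is_tip():
        raise ValueError("tree has no internal structure")
    descend(tree, root_seq)

    clade = set(planted_clade)
    missing = clade - set(alignment)
    if missing:
        raise ValueError(f"planted clade taxa not in tree: {sorted(missing)}")
    for leaf in clade:
        seq = alignment[leaf]
        for col, residue in diagnostic_columns.items():
            seq[col - frame.numbering_origin] = residue

    alignment = {k: "".join(v) for k, v in alignment.items()}
    truth = {
        "planted_clade": sorted(clade),
        "diagnostic_columns": diagnostic_columns,
        "n_columns": frame.length,
        "seed": config.seed,
    }
    return alignment, truth


#: Newick of the default clade-recovery scenario: a WA-alpha2 + b2m style
#: clade among Ig C1-set relatives and two outgroup-like C1 domains
DEFAULT_SCENARIO_NEWICK = (
    "(((((WAa2_shark:0.08,WAa2_zebrafish:0.08):0.04,WAa2_tetra:0.10):0.04,"
    "(B2M_human:0.08,B2M_shark:0.08):0.05):0.10,"
    "((Ia3_human:0.12,Ia3_shark:0.12):0.06,"
    "(IIBb2_human:0.12,IIBb2_shark:0.12):0.06):0.05):0.05,"
    "(IIAa2_human:0.15,IIAa2_frog:0.15):0.08,"
    "(IGM_C1:0.20,TCRB_C1:0.20):0.10);"
)

DEFAULT_SCENARIO_CLADE = (
    "WAa2_shark", "WAa2_zebrafish", "WAa2_tetra", "B2M_human", "B2M_shark",
)


def default_clade_scenario(config: SimConfig):
    """Alignment + truth for the packaged WA-alpha2/b2m clade scenario."""
    return make_alignment_set(
        DEFAULT_SCENARIO_NEWICK, config, planted_clade=DEFAULT_SCENARIO_CLADE
    )


# ---------------------------------------------------------------------------
# additive distance matrices (for tree-estimation checks)


def make_additive_tree_matrix(n_taxa: int, rng):
    """Random unrooted binary tree and its additive path-length matrix.

    Branch lengths are uniform on [0.1, 1.0].  Returns ``(DistanceMatrix,
    split set)`` where the splits are the tree's non-trivial bipartitions
    (canonicalised as in :mod:`wcat.phylo`).
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    labels = [f"t{i}" for i in range(n_taxa)]
    edges = [(labels[0], 0), (0, labels[1]), (0, labels[2])]
    next_internal = 1
    for taxon in labels[3:]:
        i = int(rng.integers(0, len(edges)))
        a, b = edges.pop(i)
        v = next_internal
        next_internal += 1
        edges.extend([(a, v), (v, b), (v, taxon)])
    lengths = {e: float(rng.uniform(0.1, 1.0)) for e in edges}

    adj = {}
    for (a, b), w in lengths.items():
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))

    import itertools as _it

    n = len(labels)
    mat = np.zeros((n, n))
    for i, j in _it.combinations(range(n), 2):
        # DFS path length in a tree
        stack = [(labels[i], 0.0)]
        seen = {labels[i]}
        dist = None
        while stack:
            node, d = stack.pop()
            if node == labels[j]:
                dist = d
                break
            for nxt, w in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, d + w))
        mat[i, j] = mat[j, i] = dist

    from .phylo import _topology_splits

    splits = _topology_splits(edges, labels)
    return make_distance_matrix(mat, labels), splits


# ---------------------------------------------------------------------------
# genomic loci


#: coding-exon lengths (bp) of a class II-type gene: distal, Ig, TM, CY
CLASS_II_TYPE_EXONS = (264, 276, 120, 90)
INTRON_LENGTH = 300


def _gene(gene_id, contig, strand, start, exon_lengths):
    exons = []
    pos = start
    order = exon_lengths if strand == "+" else tuple(reversed(exon_lengths))
    for L in order:
        exons.append((pos, pos + L))
        pos += L + INTRON_LENGTH
    return GeneModel(gene_id, contig, strand, exons), pos - INTRON_LENGTH


def make_locus_gff(n_pairs: int, n_decoys: int, config: SimConfig,
                   contig: str = "contig1"):
    """Synthetic locus with head-to-head pairs plus decoys.

    Pairs are minus-strand/plus-strand gene couples with facing 5' ends and
    a ``config.pair_gap`` intergenic gap.  Decoys are same-strand neighbours,
    facing genes separated by more than the pairing distance, and genes with
    too few exons; decoy groups are isolated by ``config.group_spacing``.
    Returns ``(genes, truth record)``.
    """
    if n_pairs < 0 or n_decoys < 0:
        raise ValueError("n_pairs and n_decoys must be >= 0")
    genes = []
    truth = {"pairs": [], "decoys": [], "contig": contig}
    cursor = 1_000

    for k in range(n_pairs):
        wb, end = _gene(f"WB_{k:02d}", contig, "-", cursor, CLASS_II_TYPE_EXONS)
        genes.append(wb)
        cursor = end + config.pair_gap
        wa, end = _gene(f"WA_{k:02d}", contig, "+", cursor, CLASS_II_TYPE_EXONS)
        genes.append(wa)
        truth["pairs"].append((wb.gene_id, wa.gene_id))
        cursor = end + config.group_spacing

    # decoys: strand pattern +,+,-,- with alternating close/far spacing, and
    # every third decoy a single-exon gene
    strands = "++--"
    for k in range(n_decoys):
        exons = (500,) if k % 3 == 2 else CLASS_II_TYPE_EXONS
        strand = strands[k % 4]
        gene, end = _gene(f"DECOY_{k:02d}", contig, strand, cursor, exons)
        genes.append(gene)
        truth["decoys"].append(gene.gene_id)
        cursor = end + (config.pair_gap if k % 2 == 0 else config.decoy_far_gap)
    return genes, truth
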