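"""Exon-architecture templates and head-to-head gene-pair detection.

W-category alpha/beta genes, like conventional class II genes, sit adjacent
in the genome on opposite strands with their 5' ends facing each other
across a short intergenic gap (divergent transcription).  This module reads
gene models from GFF3, tests their coding-exon layout against class I or
class II-type templates, and detects such head-to-head pairs among decoys.

Coordinates are converted to 0-based half-open internally; GFF3 emitted by
this module is 1-based, per the format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils

#: default maximum intergenic gap for a head-to-head pair call (bp)
DEFAULT_MAX_DISTANCE = 20_000

#: coding-exon length windows (bp) for template matching
DISTAL_EXON_WINDOW = (200, 350)
IG_EXON_WINDOW = (200, 350)


@dataclass
class GeneModel:
    """One gene: contig, strand and ordered coding exons (0-based half-open)."""

    gene_id: str
    contig: str
    strand: str
    exons: list = field(default_factory=list)  # [(start, end), ...] sorted
    exon_labels: list | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exons_in_transcription_order(self):
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def exon_lengths(self):
        return [e - s for s, e in self.exons_in_transcription_order()]


@dataclass
class PairCall:
    """A head-to-head (divergently transcribed) gene pair."""

    minus_gene: str  # upstream gene on the minus strand
    plus_gene: str   # downstream gene on the plus strand
    contig: str
    distance: int    # intergenic gap, bp
    orientation: str = "HEAD_TO_HEAD"

    @property
    def genes(self):
        return (self.minus_gene, self.plus_gene)


def match_exon_template(gene: GeneModel, template: str,
                        distal_window=DISTAL_EXON_WINDOW,
                        ig_window=IG_EXON_WINDOW):
    """Test a gene's coding-exon layout against a class template.

    ``CLASS_II_TYPE`` needs >= 3 coding exons with the first in the distal
    length window and the second in the Ig window (separate exons for the
    distal domain, the Ig domain and TM/CY).  ``CLASS_I`` needs >= 4 with two
    leading distal-length exons then an Ig-length exon.  Returns
    ``(matched, reasons)``; an unmatched gene gets the failing reasons.
    """
    if template not in ("CLASS_I", "CLASS_II_TYPE"):
        raise ValueError(f"unknown template {template!r}")
    if len(gene.exons) < 2:
        return False, ["too few exons"]
    lengths = gene.exon_lengths()
    reasons = []

    def in_window(value, window, what):
        lo, hi = window
        if lo <= value <= hi:
            return True
        reasons.append(f"{what} length {value} outside [{lo}, {hi}]")
        return False

    if template == "CLASS_II_TYPE":
        if len(lengths) < 3:
            return False, ["too few exons for class II-type layout (need >= 3)"]
        ok = in_window(lengths[0], distal_window, "distal exon")
        ok &= in_window(lengths[1], ig_window, "Ig exon")
        return bool(ok), reasons
    if len(lengths) < 4:
        return False, ["too few exons for class I layout (need >= 4)"]
    ok = in_window(lengths[0], distal_window, "distal exon 1")
    ok &= in_window(lengths[1], distal_window, "distal exon 2")
    ok &= in_window(lengths[2], ig_window, "Ig exon")
    return bool(ok), reasons


def find_head_to_head_pairs(genes, max_distance: int = DEFAULT_MAX_DISTANCE):
    """Head-to-head pairs among gene models.

    A pair is two genes adjacent on their contig (no gene between them), on
    opposite strands with the minus-strand gene upstream so the 5' ends face
    each other, separated by at most ``max_distance`` bp.  Matching is greedy
    by smallest gap and each gene joins at most one pair; the result is
    independent of input order.
    """
    by_contig: dict = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)

    candidates = []
    for contig, group in sorted(by_contig.items()):
        group.sort(key=lambda g: (g.start, g.end, g.gene_id))
        for left, right in zip(group, group[1:]):
            if left.strand == "-" and right.strand == "+":
                gap = right.start - left.end
                if 0 <= gap <= max_distance:
                    candidates.append(PairCall(left.gene_id, right.gene_id, contig, gap))

    candidates.sort(key=lambda p: (p.distance, p.contig, p.minus_gene))
    used, pairs = set(), []
    for cand in candidates:
        if cand.minus_gene in used or cand.plus_gene in used:
            continue
        used.update(cand.genes)
        pairs.append(cand)
    pairs.sort(key=lambda p: (p.contig, p.minus_gene))
    return pairs


# ---------------------------------------------------------------------------
# GFF3 I/O


def read_gff3(path) -> list:
    """Gene models from a GFF3 file (gene features with CDS children)."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for gene in db.features_of_type("gene"):
        exons = [
            (cds.start - 1, cds.end)  # GFF3 is 1-based inclusive
            for cds in db.children(gene, featuretype="CDS", order_by="start")
        ]
        if not exons:
            continue
        genes.append(GeneModel(gene.id, gene.seqid, gene.strand, exons))
    genes.sort(key=lambda g: (g.contig, g.start))
    return genes


def write_gff3(genes, path) -> None:
    """Emit gene + CDS features as 1-based GFF3."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.contig, g.start)):
        lines.append(
            f"{g.contig}\twcat\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
        for k, (s, e) in enumerate(g.exons, start=1):
            lines.append(
                f"{g.contig}\twcat\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}.cds{k};Parent={g.gene_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
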