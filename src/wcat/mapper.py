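"""Domain segmentation and mapping of chains onto canonical position frames.

A chain is segmented into MHC-style domains by (i) locating Ig C1-set
domain(s) with a local alignment against the frame consensus, (ii) locating
membrane-distal domain(s) upstream of the Ig hit the same way, and (iii)
scanning downstream of the last extracellular domain for a transmembrane
segment with a Kyte–Doolittle hydropathy window.  Each located domain is then
globally aligned to its frame consensus to produce a per-column position map,
through which diagnostic residues are read at canonical coordinates.

Alignment scores are normalised by the self-alignment score of the frame
consensus; a mapping is "confident" when the normalised score reaches
``MAPPING_THRESHOLD`` (0.35 — calibrated so fewer than 1% of length-matched
shuffles of a consensus pass).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .frames import PositionFrame, SignatureSchema

#: normalised-score threshold for a confident frame mapping
MAPPING_THRESHOLD = 0.35

#: minimum query/frame length ratio for attempting a global mapping
MIN_LENGTH_FRACTION = 0.40

#: hydropathy scan parameters (Kyte–Doolittle)
TM_WINDOW = 19
TM_HYDROPATHY_THRESHOLD = 1.6

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}


class MappingError(ValueError):
    """No confident mapping of a sequence onto a frame."""


class NotMhcLikeError(ValueError):
    """Chain lacks any confident Ig C1 domain mapping."""


def _make_aligner(mode: str, open_gap: float = -10.0, extend_gap: float = -1.0):
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = mode
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner

_GLOBAL = _make_aligner("global")
_LOCAL = _make_aligner("local")


@dataclass
class DomainHit:
    """One domain located on a chain and mapped onto a frame.

    ``position_map`` sends every frame column (1-based) to a 0-based query
    index, or ``None`` where the column is deleted in the query.
    """

    chain_id: str
    start: int  # 0-based half-open on the input chain
    end: int
    frame: str
    score: float  # normalised to [0, 1]
    position_map: dict = field(repr=False, default_factory=dict)

    def residue_at(self, sequence: str, column: int):
        """Residue of ``sequence`` at a frame column, or None if gapped."""
        idx = self.position_map.get(column)
        return None if idx is None else sequence[idx]


@dataclass
class ChainArchitecture:
    """Domain layout of a single chain."""

    chain_id: str
    hits: list  # extracellular DomainHits, ordered along the chain
    tm_hit: DomainHit | None = None
    tm_interval: tuple | None = None

    @property
    def extracellular_domain_count(self) -> int:
        return len(self.hits)

    @property
    def cptmcy_count(self) -> int:
        return 1 if self.tm_interval is not None else 0

    def hits_for(self, frame: str):
        return [h for h in self.hits if h.frame == frame]

    @property
    def ig_hits(self):
        return self.hits_for("IG_C1")


@dataclass
class MoleculeArchitecture:
    """Architecture facts of an assembled (possibly two-chain) molecule."""

    extracellular_domain_count: int
    cptmcy_count: int


def assemble(*architectures: ChainArchitecture) -> MoleculeArchitecture:
    """Combine per-chain architectures into molecule-level counts.

    A class I molecule (heavy chain + b2m) has one CP/TM/CY region; a class
    II-type molecule (alpha + beta chain) has two.
    """
    return MoleculeArchitecture(
        extracellular_domain_count=sum(a.extracellular_domain_count for a in architectures),
        cptmcy_count=sum(a.cptmcy_count for a in architectures),
    )


def _self_score(frame: PositionFrame) -> float:
    return _GLOBAL.score(frame.consensus, frame.consensus)


def map_to_frame(sequence: str, frame: PositionFrame, chain_id: str = "",
                 offset: int = 0) -> DomainHit:
    """Globally align ``sequence`` onto a frame consensus.

    The alignment is Needleman–Wunsch-style with affine gaps (open 10,
    extend 1) on BLOSUM62; the score is normalised by the consensus
    self-alignment and clamped to [0, 1].  ``offset`` shifts the reported
    query coordinates (used when mapping an excised subsequence).
    """
    if not sequence:
        raise MappingError("empty sequence")
    if len(sequence) < MIN_LENGTH_FRACTION * frame.length:
        raise MappingError(
            f"sequence of length {len(sequence)} too short for frame "
            f"{frame.name} ({frame.length} columns): no confident mapping"
        )
    aln = _GLOBAL.align(sequence, frame.consensus)[0]
    norm = min(1.0, max(0.0, aln.score / _self_score(frame)))

    position_map = {c: None for c in frame.columns}
    qblocks, tblocks = aln.aligned
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        for k in range(te - ts):
            position_map[frame.numbering_origin + ts + k] = offset + qs + k
    return DomainHit(
        chain_id=chain_id,
        start=offset,
        end=offset + len(sequence),
        frame=frame.name,
        score=norm,
        position_map=position_map,
    )


def _local_hits(sequence: str, frame: PositionFrame, threshold: float):
    """Non-overlapping local hits of the frame consensus, best first.

    Searches iteratively: accept the best local alignment, then re-search
    the flanking subsequences.
    """
    self_score = _self_score(frame)
    hits = []
    intervals = [(0, len(sequence))]
    while intervals:
        lo, hi = intervals.pop()
        if hi - lo < MIN_LENGTH_FRACTION * frame.length:
            continue
        sub = sequence[lo:hi]
        aln = _LOCAL.align(sub, frame.consensus)[0]
        norm = aln.score / self_score
        if norm < threshold:
            continue
        qs, qe = int(aln.coordinates[0][0]), int(aln.coordinates[0][-1])
        hits.append((norm, lo + qs, lo + qe))
        intervals.append((lo, lo + qs))
        intervals.append((lo + qe, hi))
    hits.sort(key=lambda h: h[1])
    return hits


def find_tm_segment(sequence: str, start: int = 0):
    """Best transmembrane segment at/after ``start`` by hydropathy scan.

    Returns a 0-based half-open interval, or None.  The segment is the union
    of all overlapping windows of length ``TM_WINDOW`` whose mean
    Kyte–Doolittle hydropathy reaches ``TM_HYDROPATHY_THRESHOLD``, around the
    best-scoring window.
    """
    region = sequence[start:]
    n = len(region)
    if n < TM_WINDOW:
        return None
    values = [KYTE_DOOLITTLE.get(a, 0.0) for a in region]
    window_means = []
    acc = sum(values[:TM_WINDOW])
    window_means.append(acc / TM_WINDOW)
    for i in range(1, n - TM_WINDOW + 1):
        acc += values[i + TM_WINDOW - 1] - values[i - 1]
        window_means.append(acc / TM_WINDOW)
    best = max(range(len(window_means)), key=lambda i: window_means[i])
    if window_means[best] < TM_HYDROPATHY_THRESHOLD:
        return None
    lo = best
    while lo > 0 and window_means[lo - 1] >= TM_HYDROPATHY_THRESHOLD:
        lo -= 1
    hi = best
    while hi + 1 < len(window_means) and window_means[hi + 1] >= TM_HYDROPATHY_THRESHOLD:
        hi += 1
    return (start + lo, start + hi + TM_WINDOW)


def segment_chain(sequence: str, schema: SignatureSchema,
                  chain_id: str = "", threshold: float = MAPPING_THRESHOLD) -> ChainArchitecture:
    """Segment a chain into distal/Ig domains plus a TM segment.

    Raises :class:`NotMhcLikeError` when no confident Ig C1 mapping exists,
    and ``ValueError`` for sequences shorter than 80 residues.
    """
    if len(sequence) < 80:
        raise ValueError(f"sequence too short to segment ({len(sequence)} < 80 residues)")

    ig_frame = schema.frame("IG_C1")
    ig_locals = _local_hits(sequence, ig_frame, threshold)
    if not ig_locals:
        raise NotMhcLikeError(f"{chain_id or 'chain'}: no confident Ig C1 domain mapping")

    hits = []
    for _, qs, qe in ig_locals:
        hits.append(map_to_frame(sequence[qs:qe], ig_frame, chain_id, offset=qs))

    # distal domains upstream of the first Ig hit
    first_ig_start = min(h.start for h in hits)
    upstream = sequence[:first_ig_start]
    distal_frames = [schema.frame("DISTAL_A1TYPE"), schema.frame("DISTAL_A2TYPE")]
    intervals = [(0, len(upstream))]
    while intervals:
        lo, hi = intervals.pop()
        best = None
        for fr in distal_frames:
            if hi - lo < MIN_LENGTH_FRACTION * fr.length:
                continue
            found = _local_hits(upstream[lo:hi], fr, threshold)
            for norm, qs, qe in found:
                if best is None or norm > best[0]:
                    best = (norm, lo + qs, lo + qe, fr)
        if best is None:
            continue
        _, qs, qe, fr = best
        hits.append(map_to_frame(sequence[qs:qe], fr, chain_id, offset=qs))
        intervals.append((lo, qs))
        intervals.append((qe, hi))

    hits.sort(key=lambda h: h.start)

    # TM segment downstream of the last extracellular domain
    last_end = max(h.end for h in hits)
    tm_interval = find_tm_segment(sequence, start=last_end)
    tm_hit = None
    if tm_interval is not None:
        tm_frame = schema.frames.get("TM")
        if tm_frame is not None:
            try:
                tm_hit = map_to_frame(
                    sequence[tm_interval[0]:tm_interval[1]], tm_frame,
                    chain_id, offset=tm_interval[0],
                )
            except MappingError:
                tm_hit = None

    return ChainArchitecture(
        chain_id=chain_id, hits=hits, tm_hit=tm_hit, tm_interval=tm_interval
    )
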