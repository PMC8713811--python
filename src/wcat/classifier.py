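"""Chain classification and interdomain-interface typing.

Each mapped domain is scored against the signature schema: a class score is
the weight of matched diagnostic residues over the weight of residues
readable at non-gap columns.  Chains are first gated by architecture (three
extracellular domains can only be a class I heavy chain, one can only be a
b2m-like light chain, two leave the four class II-architecture candidates),
then labelled by the best-scoring class when it clears both a margin over
the runner-up and an absolute score floor.

Interface typing follows the three interdomain interfaces of a class I
molecule — alpha1alpha2/b2m, alpha1alpha2/alpha3 and alpha3/b2m — and asks
whether an alpha/beta chain pair carries the class I-specific residues at
each one (e.g. the light-chain tryptophan at Ig position 61 for the first,
glycine versus the class II-diagnostic tryptophan at position 61 of the
partner Ig domain for the second, and the P57/Y8 hydrogen-bond pair for the
third).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .frames import CHAIN_CLASSES, SignatureSchema
from .mapper import ChainArchitecture, DomainHit, NotMhcLikeError, segment_chain

#: minimum margin (top minus runner-up score) for a confident label
DEFAULT_TAU = 0.15

#: absolute score floor for a confident label
MIN_LABEL_SCORE = 0.5

#: architecture gating: extracellular domain count -> candidate classes
ARCHITECTURE_CANDIDATES = {
    3: ("I_HEAVY",),
    1: ("B2M",),
    2: ("IIA", "IIB", "WA", "WB"),
}

INTERFACE_NAMES = ("A1A2_B2M", "A1A2_A3", "A3_B2M")

#: chain classes whose Ig domain sits on the alpha (light-chain-like) side
ALPHA_SIDE_CLASSES = frozenset({"B2M", "WA", "IIA"})


@dataclass
class Evidence:
    """One signature lookup: what was expected, what was seen."""

    frame: str
    position: int
    expected: str  # allowed residues, or a descriptive token
    chain_class: str
    observed: str | None  # residue, None when gapped
    matched: bool
    weight: float


@dataclass
class ChainCall:
    """Classification result for one chain."""

    chain_id: str
    architecture: ChainArchitecture | None
    sequence: str = ""
    scores: dict = field(default_factory=dict)  # class -> score in [0, 1]
    label: str = "UNKNOWN"
    margin: float = 0.0
    evidence: list = field(default_factory=list)
    zero_coverage: list = field(default_factory=list)  # classes with no readable signature
    note: str = ""


@dataclass
class InterfaceVerdict:
    verdict: str  # CLASS_I_TYPE | CLASS_II_TYPE | AMBIGUOUS
    matched: list = field(default_factory=list)
    unmatched: list = field(default_factory=list)


@dataclass
class InterfaceReport:
    """Typing of the three class I interdomain interfaces for an alpha/beta pair."""

    alpha_id: str
    beta_id: str
    interfaces: dict = field(default_factory=dict)  # name -> InterfaceVerdict

    def __post_init__(self):
        for name in INTERFACE_NAMES:
            self.interfaces.setdefault(name, InterfaceVerdict("AMBIGUOUS"))

    def verdicts(self) -> dict:
        return {k: v.verdict for k, v in self.interfaces.items()}


def score_domain(hit: DomainHit, sequence: str, schema: SignatureSchema) -> dict:
    """Per-class signature score for one mapped domain.

    Returns ``{class: (matched_weight, readable_weight, evidence_list)}`` for
    the six chain classes.  Signatures at gapped columns are excluded from
    both numerator and denominator.
    """
    out = {c: [0.0, 0.0, []] for c in CHAIN_CLASSES}
    for sig in schema.signatures_for(frame=hit.frame):
        if sig.chain_class not in out:
            continue
        observed = hit.residue_at(sequence, sig.position)
        if observed is None:
            continue  # gapped: unreadable
        matched = sig.matches(observed)
        rec = out[sig.chain_class]
        rec[1] += sig.weight
        if matched:
            rec[0] += sig.weight
        rec[2].append(
            Evidence(hit.frame, sig.position, "".join(sorted(sig.allowed_residues)),
                     sig.chain_class, observed, matched, sig.weight)
        )
    return {c: tuple(v) for c, v in out.items()}


def _indel_evidence(arch: ChainArchitecture, sequence: str, schema: SignatureSchema):
    """Presence/absence of schema indel regions as per-class evidence.

    A region read through a distal hit counts as "present" when every column
    is mapped, "absent" when every column is gapped, and is unreadable when
    mixed.
    """
    per_class = {c: [0.0, 0.0, []] for c in CHAIN_CLASSES}
    for hit in arch.hits:
        for region in schema.indel_regions_for(hit.frame):
            states = [hit.position_map.get(c) is not None for c in region.columns]
            if all(states):
                state = "present"
            elif not any(states):
                state = "absent"
            else:
                continue
            for cls in CHAIN_CLASSES:
                if cls in region.present_in:
                    want = "present"
                elif cls in region.absent_in:
                    want = "absent"
                else:
                    continue
                rec = per_class[cls]
                rec[1] += 1.0
                matched = state == want
                if matched:
                    rec[0] += 1.0
                rec[2].append(
                    Evidence(hit.frame, region.start_column,
                             f"indel {region.start_column}-{region.end_column} {want}",
                             cls, state, matched, 1.0)
                )
    return per_class


def _tm_evidence(arch: ChainArchitecture, sequence: str, schema: SignatureSchema):
    """TM glycine-pattern matches as per-class evidence."""
    per_class = {c: [0.0, 0.0, []] for c in CHAIN_CLASSES}
    hit = arch.tm_hit
    if hit is None:
        return per_class
    for cls, cols in schema.tm_glycine_patterns.items():
        if cls not in per_class:
            continue
        rec = per_class[cls]
        for col in cols:
            observed = hit.residue_at(sequence, col)
            if observed is None:
                continue
            rec[1] += 1.0
            matched = observed == "G"
            if matched:
                rec[0] += 1.0
            rec[2].append(Evidence("TM", col, "G", cls, observed, matched, 1.0))
    return per_class


def classify_chain(architecture: ChainArchitecture, sequence: str,
                   schema: SignatureSchema, tau: float = DEFAULT_TAU,
                   min_score: float = MIN_LABEL_SCORE) -> ChainCall:
    """Assign one of the six chain classes (or UNKNOWN) to a segmented chain.

    Combines architecture gating, per-domain signature scores, TM glycine
    patterns and indel-region presence.  The label is the arg-max class when
    its margin over the runner-up reaches ``tau`` and its score reaches
    ``min_score``; otherwise UNKNOWN.
    """
    n = architecture.extracellular_domain_count
    candidates = ARCHITECTURE_CANDIDATES.get(n)
    if candidates is None:
        return ChainCall(architecture.chain_id, architecture, sequence,
                         note=f"unsupported architecture ({n} extracellular domains)")

    total = {c: [0.0, 0.0, []] for c in CHAIN_CLASSES}
    for hit in architecture.hits:
        for cls, (m, r, ev) in score_domain(hit, sequence, schema).items():
            total[cls][0] += m
            total[cls][1] += r
            total[cls][2].extend(ev)
    for extra in (_tm_evidence(architecture, sequence, schema),
                  _indel_evidence(architecture, sequence, schema)):
        for cls, (m, r, ev) in ((c, tuple(v)) for c, v in extra.items()):
            total[cls][0] += m
            total[cls][1] += r
            total[cls][2].extend(ev)

    scores = {}
    zero_coverage = []
    evidence = []
    for cls in candidates:
        m, r, ev = total[cls]
        if r == 0:
            scores[cls] = 0.0
            zero_coverage.append(cls)
        else:
            scores[cls] = m / r
        evidence.extend(ev)

    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    top_class, top_score = ranked[0]
    runner_up = ranked[1][1] if len(ranked) > 1 else 0.0
    margin = top_score - runner_up

    label = "UNKNOWN"
    note = ""
    if top_class in zero_coverage:
        note = "zero signature coverage for top candidate"
    elif margin >= tau and top_score >= min_score:
        label = top_class
    return ChainCall(
        chain_id=architecture.chain_id,
        architecture=architecture,
        sequence=sequence,
        scores=scores,
        label=label,
        margin=margin,
        evidence=evidence,
        zero_coverage=zero_coverage,
        note=note,
    )


def classify_sequence(sequence: str, schema: SignatureSchema, chain_id: str = "",
                      tau: float = DEFAULT_TAU, min_score: float = MIN_LABEL_SCORE,
                      threshold: float | None = None) -> ChainCall:
    """Segment then classify; chains with no Ig mapping come back UNKNOWN."""
    kwargs = {} if threshold is None else {"threshold": threshold}
    try:
        arch = segment_chain(sequence, schema, chain_id=chain_id, **kwargs)
    except NotMhcLikeError as exc:
        return ChainCall(chain_id, None, sequence, note=str(exc))
    return classify_chain(arch, sequence, schema, tau=tau, min_score=min_score)


# ---------------------------------------------------------------------------
# interface typing


def _interface_positions(schema: SignatureSchema, role: str):
    """Unique interface positions for a role, split into class I evidence and
    class II diagnostics.

    Returns two dicts keyed by (frame, position, side): values are
    (allowed residue union, max weight).  ``side`` is "alpha" or "beta" for
    Ig-frame positions (set by the owning chain class) and "any" for distal
    positions, which may sit on either chain depending on the architecture.
    """
    class_i, class_ii = {}, {}
    for sig in schema.signatures:
        if sig.role != role:
            continue
        if sig.frame == "IG_C1":
            side = "alpha" if sig.chain_class in ALPHA_SIDE_CLASSES else "beta"
        else:
            side = "any"
        bucket = class_ii if sig.chain_class in ("IIA", "IIB") else class_i
        key = (sig.frame, sig.position, side)
        allowed, weight = bucket.get(key, (frozenset(), 0.0))
        bucket[key] = (allowed | sig.allowed_residues, max(weight, sig.weight))
    return class_i, class_ii


def _read_position(alpha: ChainArchitecture, beta: ChainArchitecture,
                   alpha_seq: str, beta_seq: str, frame: str, position: int, side: str):
    """Observed residue at an interface position, or None when unreadable."""
    if frame == "IG_C1":
        arch, seq = (alpha, alpha_seq) if side == "alpha" else (beta, beta_seq)
        for hit in arch.hits_for(frame):
            res = hit.residue_at(seq, position)
            if res is not None:
                return res
        return None
    for arch, seq in ((alpha, alpha_seq), (beta, beta_seq)):
        for hit in arch.hits_for(frame):
            res = hit.residue_at(seq, position)
            if res is not None:
                return res
    return None


def evaluate_interfaces(alpha: ChainCall, beta: ChainCall,
                        schema: SignatureSchema) -> InterfaceReport:
    """Type the three class I interdomain interfaces for an alpha/beta pair.

    Per interface: CLASS_I_TYPE when at least 2/3 of the weighted class I
    signatures readable there match and no class II diagnostic matches;
    CLASS_II_TYPE when a class II diagnostic matches; AMBIGUOUS otherwise.
    """
    if alpha.architecture is None or not alpha.architecture.ig_hits:
        raise NotMhcLikeError(f"alpha chain {alpha.chain_id}: no Ig domain mapping")
    if beta.architecture is None or not beta.architecture.ig_hits:
        raise NotMhcLikeError(f"beta chain {beta.chain_id}: no Ig domain mapping")
    if alpha.architecture.extracellular_domain_count > 2:
        raise ValueError("alpha chain must carry one or two extracellular domains")

    alpha_seq = _sequence_of(alpha)
    beta_seq = _sequence_of(beta)

    report = InterfaceReport(alpha.chain_id, beta.chain_id)
    role_of = {
        "A1A2_B2M": "INTERFACE_A1A2_B2M",
        "A1A2_A3": "INTERFACE_A1A2_A3",
        "A3_B2M": "INTERFACE_A3_B2M",
    }
    for name in INTERFACE_NAMES:
        class_i, class_ii = _interface_positions(schema, role_of[name])
        matched, unmatched = [], []
        matched_w = readable_w = 0.0
        for (frame, pos, side), (allowed, weight) in sorted(class_i.items()):
            observed = _read_position(alpha.architecture, beta.architecture,
                                      alpha_seq, beta_seq, frame, pos, side)
            if observed is None:
                continue
            readable_w += weight
            allowed_txt = "".join(sorted(allowed))
            entry = f"{frame}:{pos} {allowed_txt} observed {observed}"
            if observed in allowed:
                matched_w += weight
                matched.append(entry)
            else:
                unmatched.append(entry)
        ii_matched = False
        ii_readable = False
        for (frame, pos, side), (allowed, weight) in sorted(class_ii.items()):
            observed = _read_position(alpha.architecture, beta.architecture,
                                      alpha_seq, beta_seq, frame, pos, side)
            if observed is None:
                continue
            ii_readable = True
            allowed_txt = "".join(sorted(allowed))
            entry = f"{frame}:{pos} class-II {allowed_txt} observed {observed}"
            if observed in allowed:
                ii_matched = True
                matched.append(entry)
            else:
                unmatched.append(entry)
        if ii_matched:
            verdict = "CLASS_II_TYPE"
        elif readable_w > 0 and matched_w / readable_w >= 2.0 / 3.0 - 1e-9:
            verdict = "CLASS_I_TYPE"
        else:
            verdict = "AMBIGUOUS"
        report.interfaces[name] = InterfaceVerdict(verdict, matched, unmatched)
    return report


def _sequence_of(call: ChainCall) -> str:
    if not call.sequence:
        raise ValueError(f"ChainCall for {call.chain_id} carries no sequence")
    return call.sequence
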