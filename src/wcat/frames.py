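"""Canonical position frames and the declarative residue-signature schema.

MHC-like chains are built from a small number of recurrent domain families:
the membrane-distal (groove-forming) domains, the membrane-proximal Ig-like
C1-set domain, and the transmembrane segment.  Each family is described here
by a :class:`PositionFrame` — a fixed, 1-based column coordinate system with
a consensus residue per column — so that diagnostic residues can be read at
canonical positions regardless of indels in any particular chain.

The diagnostic residues themselves (e.g. the b2m/WA-alpha2 tryptophan at
Ig-frame position 61, or the class I alpha3 glycine at the same column) are
stored declaratively in a :class:`SignatureSchema`, loaded from JSON.  The
packaged default schema encodes the interdomain-interface and core residues
that discriminate the six chain classes; it is user-extensible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: the six assignable chain classes plus the Ig-superfamily core pseudo-class
CHAIN_CLASSES = ("I_HEAVY", "B2M", "IIA", "IIB", "WA", "WB")
ALL_CLASSES = CHAIN_CLASSES + ("IGSF_CORE",)

FRAME_NAMES = ("IG_C1", "DISTAL_A1TYPE", "DISTAL_A2TYPE", "TM")

ROLES = (
    "INTERFACE_A1A2_B2M",
    "INTERFACE_A1A2_A3",
    "INTERFACE_A3_B2M",
    "CORE",
    "DISTAL",
    "TM",
)


class SchemaError(ValueError):
    """Raised when a schema file fails to parse or validate."""


@dataclass(frozen=True)
class PositionFrame:
    """A canonical column coordinate system for one domain family."""

    name: str
    length: int
    consensus: str
    numbering_origin: int = 1

    def __post_init__(self):
        if self.name not in FRAME_NAMES:
            raise SchemaError(f"unknown frame name {self.name!r}")
        if self.length <= 0:
            raise SchemaError(f"frame {self.name}: length must be positive")
        if len(self.consensus) != self.length:
            raise SchemaError(
                f"frame {self.name}: consensus has {len(self.consensus)} residues, "
                f"length says {self.length}"
            )
        bad = set(self.consensus) - AMINO_ACIDS
        if bad:
            raise SchemaError(f"frame {self.name}: non-standard consensus residues {bad}")

    @property
    def columns(self) -> range:
        """All valid column indices (1-based by default)."""
        return range(self.numbering_origin, self.numbering_origin + self.length)

    def consensus_at(self, column: int) -> str:
        return self.consensus[column - self.numbering_origin]


@dataclass(frozen=True)
class ResidueSignature:
    """One diagnostic residue: frame column, allowed residues, class, role."""

    frame: str
    position: int
    allowed_residues: frozenset
    chain_class: str
    role: str
    weight: float = 1.0

    def __post_init__(self):
        if not self.allowed_residues:
            raise SchemaError("signature with empty residue set")
        bad = set(self.allowed_residues) - AMINO_ACIDS
        if bad:
            raise SchemaError(f"signature {self.frame}:{self.position} has non-standard residues {bad}")
        if self.chain_class not in ALL_CLASSES:
            raise SchemaError(f"unknown chain class {self.chain_class!r}")
        if self.role not in ROLES:
            raise SchemaError(f"unknown signature role {self.role!r}")
        if self.weight < 0:
            raise SchemaError("signature weight must be non-negative")

    def matches(self, residue: str) -> bool:
        return residue in self.allowed_residues


@dataclass(frozen=True)
class IndelRegion:
    """A distal-frame column range whose presence/absence separates lineages."""

    frame: str
    start_column: int
    end_column: int
    present_in: frozenset
    absent_in: frozenset
    provisional: bool = False

    def __post_init__(self):
        if self.start_column > self.end_column:
            raise SchemaError("indel region with start_column > end_column")
        if self.present_in & self.absent_in:
            raise SchemaError("indel region with overlapping present_in/absent_in")

    @property
    def columns(self) -> range:
        return range(self.start_column, self.end_column + 1)


@dataclass
class SignatureSchema:
    """Validated bundle of frames, signatures, indels and TM glycine patterns."""

    version: str
    frames: dict = field(default_factory=dict)  # name -> PositionFrame
    signatures: list = field(default_factory=list)
    indel_regions: list = field(default_factory=list)
    tm_glycine_patterns: dict = field(default_factory=dict)  # chain class -> [TM columns]
    tm_patterns_provisional: bool = False
    invariant_cysteine_positions: list = field(default_factory=list)

    # -- queries ---------------------------------------------------------

    def frame(self, name: str) -> PositionFrame:
        try:
            return self.frames[name]
        except KeyError:
            raise SchemaError(f"unknown frame {name!r}") from None

    def signatures_for(self, frame: str | None = None, chain_class: str | None = None):
        """All signatures, optionally restricted to one frame and/or class."""
        out = []
        for s in self.signatures:
            if frame is not None and s.frame != frame:
                continue
            if chain_class is not None and s.chain_class != chain_class:
                continue
            out.append(s)
        return out

    def indel_regions_for(self, frame: str):
        return [r for r in self.indel_regions if r.frame == frame]

    def validate(self) -> None:
        seen = set()
        for s in self.signatures:
            fr = self.frame(s.frame)
            if s.position not in fr.columns:
                raise SchemaError(
                    f"signature {s.chain_class}@{s.frame}:{s.position} outside frame columns"
                )
            key = (s.frame, s.position, s.chain_class)
            if key in seen:
                raise SchemaError(f"duplicate signature for {key}")
            seen.add(key)
        for r in self.indel_regions:
            fr = self.frame(r.frame)
            if r.start_column not in fr.columns or r.end_column not in fr.columns:
                raise SchemaError(
                    f"indel region {r.frame}:{r.start_column}-{r.end_column} outside frame"
                )
            for c in r.present_in | r.absent_in:
                if c not in ALL_CLASSES:
                    raise SchemaError(f"indel region names unknown class {c!r}")
        tm = self.frames.get("TM")
        for cls, cols in self.tm_glycine_patterns.items():
            if cls not in ALL_CLASSES:
                raise SchemaError(f"TM glycine pattern for unknown class {cls!r}")
            if tm is None:
                raise SchemaError("TM glycine patterns given but no TM frame defined")
            for c in cols:
                if c not in tm.columns:
                    raise SchemaError(f"TM glycine column {c} outside TM frame")
        ig = self.frames.get("IG_C1")
        for c in self.invariant_cysteine_positions:
            if ig is None or c not in ig.columns:
                raise SchemaError(f"invariant cysteine column {c} outside IG_C1 frame")

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "frames": [
                {
                    "name": f.name,
                    "length": f.length,
                    "consensus": f.consensus,
                    "numbering_origin": f.numbering_origin,
                }
                for f in self.frames.values()
            ],
            "signatures": [
                {
                    "frame": s.frame,
                    "position": s.position,
                    "allowed_residues": "".join(sorted(s.allowed_residues)),
                    "chain_class": s.chain_class,
                    "role": s.role,
                    "weight": s.weight,
                }
                for s in self.signatures
            ],
            "indel_regions": [
                {
                    "frame": r.frame,
                    "start_column": r.start_column,
                    "end_column": r.end_column,
                    "present_in": sorted(r.present_in),
                    "absent_in": sorted(r.absent_in),
                    "provisional": r.provisional,
                }
                for r in self.indel_regions
            ],
            "tm_glycine_patterns": {
                "provisional": self.tm_patterns_provisional,
                "patterns": {k: list(v) for k, v in self.tm_glycine_patterns.items()},
            },
            "invariant_cysteine_positions": list(self.invariant_cysteine_positions),
        }

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


def schema_from_dict(raw: dict) -> SignatureSchema:
    try:
        frames = {}
        for f in raw["frames"]:
            pf = PositionFrame(
                name=f["name"],
                length=int(f["length"]),
                consensus=f["consensus"],
                numbering_origin=int(f.get("numbering_origin", 1)),
            )
            frames[pf.name] = pf
        sigs = [
            ResidueSignature(
                frame=s["frame"],
                position=int(s["position"]),
                allowed_residues=frozenset(s["allowed_residues"]),
                chain_class=s["chain_class"],
                role=s["role"],
                weight=float(s.get("weight", 1.0)),
            )
            for s in raw.get("signatures", [])
        ]
        indels = [
            IndelRegion(
                frame=r["frame"],
                start_column=int(r["start_column"]),
                end_column=int(r["end_column"]),
                present_in=frozenset(r.get("present_in", [])),
                absent_in=frozenset(r.get("absent_in", [])),
                provisional=bool(r.get("provisional", False)),
            )
            for r in raw.get("indel_regions", [])
        ]
        tm_block = raw.get("tm_glycine_patterns", {})
        if "patterns" in tm_block:
            tm_patterns = {k: [int(c) for c in v] for k, v in tm_block["patterns"].items()}
            tm_prov = bool(tm_block.get("provisional", False))
        else:  # flat form
            tm_patterns = {k: [int(c) for c in v] for k, v in tm_block.items()}
            tm_prov = False
        schema = SignatureSchema(
            version=str(raw.get("version", "unversioned")),
            frames=frames,
            signatures=sigs,
            indel_regions=indels,
            tm_glycine_patterns=tm_patterns,
            tm_patterns_provisional=tm_prov,
            invariant_cysteine_positions=[int(c) for c in raw.get("invariant_cysteine_positions", [])],
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, SchemaError):
            raise
        raise SchemaError(f"malformed schema entry: {exc}") from exc
    schema.validate()
    return schema


def load_schema(path) -> SignatureSchema:
    """Load and validate a signature schema from a JSON file."""
    text = Path(path).read_text()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: top level must be a JSON object")
    return schema_from_dict(raw)


def default_schema() -> SignatureSchema:
    """The packaged default schema (main-text diagnostic residues only)."""
    with resources.files("wcat.data").joinpath("default_schema.json").open() as fh:
        return schema_from_dict(json.load(fh))


def query_signatures(schema: SignatureSchema, frame: str, position: int) -> set:
    """All signatures defined at one frame column (possibly empty)."""
    schema.frame(frame)  # raises on unknown frame
    return {s for s in schema.signatures if s.frame == frame and s.position == position}
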