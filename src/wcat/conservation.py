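"""Per-column conservation profiling of protein alignments.

For multigene-family comparisons the interesting quantity is how strongly
each alignment column is conserved, particularly at groove (ligand-contact)
positions.  A profile records, per column, the modal residue, its fraction,
and the Shannon entropy in bits; gaps are excluded column-wise
(pairwise-deletion convention), and all-gap columns are flagged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import entropy as _scipy_entropy, pearsonr

from .phylo import GAP_CHARS


class ConservationError(ValueError):
    pass


@dataclass
class ConservationProfile:
    n_columns: int
    modal_residue: list = field(default_factory=list)   # None for all-gap columns
    modal_fraction: list = field(default_factory=list)  # np.nan for all-gap columns
    entropy_bits: list = field(default_factory=list)
    all_gap: list = field(default_factory=list)


def column_conservation(alignment: dict) -> ConservationProfile:
    """Column-wise conservation profile of an alignment (>= 2 sequences)."""
    if len(alignment) < 2:
        raise ConservationError("conservation profile requires at least 2 sequences")
    seqs = list(alignment.values())
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ConservationError(f"sequences are not aligned (lengths {sorted(lengths)})")
    ncol = lengths.pop()

    profile = ConservationProfile(n_columns=ncol)
    for c in range(ncol):
        counts = Counter(s[c] for s in seqs if s[c] not in GAP_CHARS)
        if not counts:
            profile.modal_residue.append(None)
            profile.modal_fraction.append(float("nan"))
            profile.entropy_bits.append(float("nan"))
            profile.all_gap.append(True)
            continue
        residue, count = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        total = sum(counts.values())
        profile.modal_residue.append(residue)
        profile.modal_fraction.append(count / total)
        profile.entropy_bits.append(float(_scipy_entropy(list(counts.values()), base=2)))
        profile.all_gap.append(False)
    return profile


@dataclass
class ProfileSimilarity:
    similarity: float  # Pearson r of modal fractions; nan when undefined
    undefined: bool
    n_positions: int


def compare_profiles(p1: ConservationProfile, p2: ConservationProfile,
                     positions) -> ProfileSimilarity:
    """Pearson correlation of modal fractions over a shared position subset.

    ``positions`` are 1-based column indices in the shared coordinate frame.
    A constant profile makes the correlation undefined; this is flagged
    rather than raised.
    """
    positions = list(positions)
    if len(positions) < 3:
        raise ConservationError("profile comparison requires at least 3 positions")
    if p1.n_columns != p2.n_columns:
        raise ConservationError(
            f"profiles have different coordinate frames ({p1.n_columns} vs {p2.n_columns} columns)"
        )
    for pos in positions:
        if not 1 <= pos <= p1.n_columns:
            raise ConservationError(f"position {pos} outside profile columns")
    x = np.array([p1.modal_fraction[p - 1] for p in positions])
    y = np.array([p2.modal_fraction[p - 1] for p in positions])
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise ConservationError("comparison positions include all-gap columns")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return ProfileSimilarity(float("nan"), True, len(positions))
    r, _ = pearsonr(x, y)
    return ProfileSimilarity(float(r), False, len(positions))
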