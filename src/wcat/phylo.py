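"""Distance-based phylogenetics for Ig-like C1-set domain alignments.

Pairwise p-distances (optionally Poisson-corrected), neighbor-joining tree
estimation, non-parametric bootstrap over alignment columns, and bipartition
support queries.  Used to test whether the W-category alpha2 domains cluster
with class I beta2-microglobulin in trees built from the membrane-proximal
Ig-like domains.

Trees are estimated with the Saitou–Nei neighbor-joining agglomeration (via
scikit-bio); support values are tallied on unrooted bipartitions, so any
outgroup rooting is purely a display choice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

GAP_CHARS = frozenset("-.")


class PhyloError(ValueError):
    pass


def _check_alignment(alignment: dict) -> None:
    if len(alignment) < 3:
        raise PhyloError("alignment must contain at least 3 sequences")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise PhyloError(f"sequences are not aligned (lengths {sorted(lengths)})")


def pdistance(alignment: dict, correction: str = "NONE") -> DistanceMatrix:
    """Pairwise proportion of differing sites over mutually ungapped columns.

    ``alignment`` maps taxon label to aligned sequence.  ``correction`` is
    ``"NONE"`` or ``"POISSON"`` (d = -ln(1 - p)).  Raises on a pair with no
    comparable columns, or p >= 1 under the Poisson correction.
    """
    if correction not in ("NONE", "POISSON"):
        raise PhyloError(f"unknown distance correction {correction!r}")
    _check_alignment(alignment)
    labels = list(alignment)
    seqs = [alignment[l] for l in labels]
    n = len(labels)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = seqs[i], seqs[j]
        comparable = diffs = 0
        for x, y in zip(a, b):
            if x in GAP_CHARS or y in GAP_CHARS:
                continue
            comparable += 1
            if x != y:
                diffs += 1
        if comparable == 0:
            raise PhyloError(
                f"no mutually ungapped columns between {labels[i]!r} and {labels[j]!r}"
            )
        p = diffs / comparable
        if correction == "POISSON":
            if p >= 1.0:
                raise PhyloError(
                    f"p-distance {p} between {labels[i]!r} and {labels[j]!r} "
                    "is not Poisson-correctable"
                )
            p = -np.log(1.0 - p)
        mat[i, j] = mat[j, i] = p
    return DistanceMatrix(mat, labels)


def nj(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (Saitou–Nei); negative branch lengths clamped to 0.

    Accepts a :class:`skbio.DistanceMatrix` or anything it can be built from
    (matrix + ids).  The returned tree is unrooted with a root trifurcation.
    """
    if not isinstance(dm, DistanceMatrix):
        raise PhyloError("nj expects a skbio DistanceMatrix")
    if dm.shape[0] < 3:
        raise PhyloError("nj requires at least 3 taxa")
    if np.any(dm.data < 0):
        raise PhyloError("distance matrix has negative entries")
    return _skbio_nj(dm, neg_as_zero=True)


def make_distance_matrix(matrix, labels) -> DistanceMatrix:
    """Validated symmetric, hollow, non-negative distance matrix."""
    arr = np.asarray(matrix, dtype=float)
    if np.any(arr < 0):
        raise PhyloError("distance matrix has negative entries")
    if not np.all(np.isfinite(arr)):
        raise PhyloError("distance matrix has non-finite entries")
    return DistanceMatrix(arr, list(labels))


# ---------------------------------------------------------------------------
# bipartitions and bootstrap


def bipartitions(tree: TreeNode, taxa=None):
    """Non-trivial bipartitions of an unrooted tree, canonicalised.

    Each bipartition is the frozenset of leaf names on the side *not*
    containing the lexicographically smallest taxon.
    """
    if taxa is None:
        taxa = sorted(t.name for t in tree.tips())
    universe = frozenset(taxa)
    ref = min(universe)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = universe - side
        if 1 < len(side) < len(universe) - 1:
            splits.add(side)
    return splits


def _canonical(taxa_subset, universe):
    side = frozenset(taxa_subset)
    ref = min(universe)
    if ref in side:
        side = frozenset(universe) - side
    return side


@dataclass
class SupportMap:
    """Bootstrap bipartition supports for one alignment."""

    taxa: tuple
    supports: dict = field(default_factory=dict)  # frozenset -> percent
    replicates: int = 0
    seed: int | None = None
    generator: str = "numpy.random.default_rng(PCG64), column resampling with replacement"


def bootstrap(alignment: dict, B: int, seed: int,
              correction: str = "NONE") -> SupportMap:
    """Column-resampling bootstrap of the p-distance + NJ pipeline.

    Resamples alignment columns with replacement ``B`` times, rebuilds the NJ
    tree for each replicate and tallies bipartition frequencies (percent).
    Deterministic for a given seed.
    """
    if B < 1:
        raise PhyloError("bootstrap requires B >= 1 replicates")
    _check_alignment(alignment)
    labels = list(alignment)
    seqs = [alignment[l] for l in labels]
    ncol = len(seqs[0])
    rng = np.random.default_rng(seed)
    counts: dict = {}
    for _ in range(B):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = {
            lab: "".join(seq[c] for c in cols) for lab, seq in zip(labels, seqs)
        }
        tree = nj(pdistance(resampled, correction=correction))
        for split in bipartitions(tree, labels):
            counts[split] = counts.get(split, 0) + 1
    supports = {split: 100.0 * c / B for split, c in counts.items()}
    return SupportMap(taxa=tuple(labels), supports=supports, replicates=B, seed=seed)


def clade_support(support: SupportMap, taxa) -> float:
    """Bootstrap support (percent) of the bipartition separating ``taxa``.

    Trivial bipartitions (single taxon, or all but one) are present in every
    tree and return 100.  A never-observed split returns 0.
    """
    subset = frozenset(taxa)
    universe = frozenset(support.taxa)
    if not subset:
        raise PhyloError("empty taxon subset")
    if not subset <= universe:
        raise PhyloError(f"taxa not in support map: {sorted(subset - universe)}")
    if subset == universe:
        raise PhyloError("taxon subset must be a proper subset")
    if len(subset) in (1, len(universe) - 1):
        return 100.0
    return support.supports.get(_canonical(subset, universe), 0.0)


def tree_with_supports(alignment: dict, B: int, seed: int,
                       correction: str = "NONE"):
    """NJ tree on the full alignment plus bootstrap supports on its nodes.

    Support percentages are written as internal node names on a copy of the
    tree (display convention for Newick export).
    """
    dm = pdistance(alignment, correction=correction)
    tree = nj(dm)
    support = bootstrap(alignment, B=B, seed=seed, correction=correction)
    universe = frozenset(support.taxa)
    for node in tree.non_tips(include_self=False):
        side = _canonical({t.name for t in node.tips()}, universe)
        if 1 < len(side) < len(universe) - 1:
            node.name = f"{support.supports.get(side, 0.0):.0f}"
    return tree, support


# ---------------------------------------------------------------------------
# brute-force minimum-evolution oracle (small n)


def _enumerate_topologies(labels):
    """All unrooted binary topologies on the labels, as frozensets of splits.

    Built by sequential insertion of each taxon into every edge of the
    growing tree; practical for n <= 8 (up to 10,395 topologies).
    """
    labels = list(labels)
    if len(labels) < 3:
        raise PhyloError("need at least 3 taxa")

    # a topology is an edge list; leaves are label strings, internal nodes ints
    trees = [([(labels[0], 0), (0, labels[1]), (0, labels[2])], 1)]
    for taxon in labels[3:]:
        grown = []
        for edges, next_internal in trees:
            for i, (a, b) in enumerate(edges):
                v = next_internal
                new_edges = edges[:i] + edges[i + 1:] + [(a, v), (v, b), (v, taxon)]
                grown.append((new_edges, next_internal + 1))
        trees = grown
    return [edges for edges, _ in trees]


def _topology_splits(edges, labels):
    """Non-trivial splits induced by an edge list."""
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    label_set = frozenset(labels)
    ref = min(label_set)
    splits = set()
    for a, b in edges:
        # leaves on b's side when edge (a, b) removed
        stack, seen, side = [b], {a, b}, set()
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                side.add(node)
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        side = frozenset(side)
        if ref in side:
            side = label_set - side
        if 1 < len(side) < len(label_set) - 1:
            splits.add(side)
    return splits


def _ols_tree_length(edges, labels, dm: DistanceMatrix) -> float:
    """Total tree length under ordinary least-squares branch lengths."""
    edge_index = {tuple(sorted(e, key=str)): k for k, e in enumerate(edges)}
    adj = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    def path_edges(u, v):
        # BFS over the tree
        prev = {u: None}
        stack = [u]
        while stack:
            node = stack.pop()
            if node == v:
                break
            for nxt in adj[node]:
                if nxt not in prev:
                    prev[nxt] = node
                    stack.append(nxt)
        path = []
        node = v
        while prev[node] is not None:
            path.append(edge_index[tuple(sorted((node, prev[node]), key=str))])
            node = prev[node]
        return path

    pairs = list(itertools.combinations(labels, 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (u, v) in enumerate(pairs):
        for k in path_edges(u, v):
            A[r, k] = 1.0
        y[r] = dm[u, v]
    lengths, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum(lengths))


def exhaustive_me_tree(dm: DistanceMatrix):
    """Minimum-evolution topology by exhaustive search with OLS branch lengths.

    Independent brute-force reference for NJ on small matrices (n <= 8).
    Returns the winning topology's split set.
    """
    labels = sorted(dm.ids)
    best_len, best_splits = None, None
    for edges in _enumerate_topologies(labels):
        tl = _ols_tree_length(edges, labels, dm)
        if best_len is None or tl < best_len - 1e-12:
            best_len, best_splits = tl, _topology_splits(edges, labels)
    return best_splits, best_len
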