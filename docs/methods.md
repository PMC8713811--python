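# Methods

This note documents the models, conventions and parameter choices behind
`wcat`, in the order the pipeline uses them, together with what the
synthetic-data generators do and do not emulate.

## Position frames and the signature schema

Diagnostic residues are read at canonical columns of four *position frames*:
`DISTAL_A1TYPE` and `DISTAL_A2TYPE` (88 columns each) for the two
membrane-distal domain families, `IG_C1` (94 columns) for the
membrane-proximal Ig C1-set domain, and `TM` (25 columns) for the
transmembrane segment. Columns are numbered from 1 and follow
alignment-style numbering, not mature-protein numbering. Each frame carries
a consensus string; the packaged consensi are fixed arbitrary backbones
(generated once and frozen) with the Ig-superfamily invariants planted — the
core tryptophan at Ig column 37 and cysteines at columns 21 and 76. They are
not derived from real accessions, which keeps the package self-contained and
the generators free of third-party data.

The default schema encodes only the main diagnostic residues of the six
chain classes (class I heavy chain `I_HEAVY`, β2-microglobulin `B2M`, class
II α/β `IIA`/`IIB`, W-category α/β `WA`/`WB`):

| frame | column | class: residues |
|---|---|---|
| DISTAL_A1TYPE | 30 | I_HEAVY: V, WA: V |
| DISTAL_A2TYPE | 6 | I_HEAVY: Q, WB: Q (weight 0.5) |
| DISTAL_A2TYPE | 32/35/37 | I_HEAVY and WB: A / G / D |
| IG_C1 | 8 | B2M: Y, WA: Y |
| IG_C1 | 37 | IGSF core: W; B2M: L; WA: F/L; IIA, IIB, WB, I_HEAVY: W |
| IG_C1 | 55 | B2M: L, WA: L |
| IG_C1 | 57 | B2M: F; WA: F/Y; I_HEAVY: P; WB: P |
| IG_C1 | 61 | B2M: W; WA: W; I_HEAVY: G; WB: G; IIB: W |

Signatures at the three interdomain interfaces carry weight 2.0 and all
others 1.0, reflecting that the interface residues are the strongest
discriminators; the α2-domain Q6 carries 0.5 because it is partially
conserved in class II as well. Users can extend the schema (JSON with
top-level keys `frames`, `signatures`, `indel_regions`,
`tm_glycine_patterns`, `invariant_cysteine_positions`); validation rejects
dangling frame references and duplicate `(frame, position, class)` entries.

Two schema blocks are deliberately marked `provisional`: the three distal
indel-signature regions (columns 44–46 of the α1-type frame and 50–53 and
70–71 of the α2-type frame, present in the class I/W lineage and deleted in
conventional class II) and the TM glycine patterns (α-type chains at TM
columns 8/12/16, β-type at 9/13/17). The published record establishes that
three such indel regions and chain-specific TM glycines exist but not their
exact coordinates, so these defaults are internally consistent placeholders:
the generator and the classifier share them, and users with better
coordinates can replace them in the schema file.

## Domain mapping and segmentation

Chains are mapped onto frames by global (Needleman–Wunsch-style) alignment
with affine gaps — BLOSUM62, gap open 10, gap extend 1 — via Biopython's
`PairwiseAligner`; where several optimal alignments exist the aligner's
first reported alignment is used, which is deterministic for fixed inputs.
Scores are normalised by the self-alignment score of the frame consensus and
clamped to [0, 1]. A mapping is *confident* at a normalised score ≥ 0.35:
in a calibration of 1,000 length-matched shuffles of the Ig consensus the
largest normalised score observed was ≈ 0.12, so the false-mapping rate at
this threshold is well below 1%. Sequences shorter than 40% of the frame
length are refused ("no confident mapping").

Segmentation first locates Ig C1 domains by iterative local alignment
(accept the best hit ≥ 0.35, then re-search the flanks), then finds distal
domains upstream of the first Ig hit the same way, trying both distal
frames and keeping the better. Domain boundaries are the extent of the frame
mapping — true exon borders are unknown for most inputs, so the
mapping extent is the package's convention. The TM segment is the union of
19-residue windows downstream of the last extracellular domain whose mean
Kyte–Doolittle hydropathy is ≥ 1.6, around the best window; signal peptides
are not modelled (synthetic chains are generated without them). Query
coordinates are 0-based half-open; frame columns are 1-based.

## Classification

Per-class evidence is the weighted fraction of matched signatures among
signatures readable at non-gap columns — gapped columns are excluded from
numerator and denominator alike (missing-data convention); a class with no
readable signature is flagged zero-coverage and scored 0. TM glycine
positions and indel-region presence/absence contribute as additional
unit-weight evidence items.

Architecture gates the candidate set first: three extracellular domains →
class I heavy chain only; one → β2m only; two → the four class II-layout
classes. The label is the best-scoring candidate when (i) its margin over
the runner-up is ≥ τ = 0.15 and (ii) its own score is ≥ 0.5; otherwise
UNKNOWN. The margin threshold separates planted classes at 5% background
mutation in calibration simulations. The absolute score floor is needed for
the permutation null: on signature-free chains (random residues at every
diagnostic position) chance matches in a small candidate's denominator can
produce a spurious margin, while requiring half of the weighted evidence
keeps the UNKNOWN rate on such chains above 95% without affecting planted
chains, whose scores stay near 1 because background mutation does not touch
signature columns. Chains with no confident Ig mapping are reported UNKNOWN
with a "not MHC-like" note by the high-level `classify_sequence`; the
low-level `segment_chain` raises instead.

## Interface typing

The three class I interdomain interfaces are typed from an α/β chain pair:

- **α1α2/β2m**: α-side Ig residues L55, F/Y57, W61 plus distal V30 (α1-type
  frame) and Q6/A32/G35/D37 (α2-type frame, read from whichever chain
  carries that frame — the heavy chain in a class I molecule, the β chain in
  a W/class II pair).
- **α1α2/α3**: β-side Ig column 61 — glycine is the class I state, the
  invariant class IIB tryptophan is the class II diagnostic.
- **α3/β2m**: β-side Ig P57 with α-side Ig Y8.

A verdict is CLASS_II_TYPE when a class II diagnostic matches, CLASS_I_TYPE
when at least 2/3 of the weighted class I signatures readable at the
interface match and no class II diagnostic does, and AMBIGUOUS otherwise
(including when key columns are gapped). The 2/3 majority rule is this
package's quantitative rendering of a qualitative sharing observation; the
report always enumerates exactly the three interfaces.

## Phylogenetics

Distances are p-distances over mutually ungapped column pairs, optionally
Poisson-corrected (d = −ln(1 − p); saturated pairs are an error). Trees are
estimated by Saitou–Nei neighbor joining through scikit-bio, with negative
branch lengths clamped to zero; ties are resolved by the library's
deterministic agglomeration order. Maximum-likelihood estimation is out of
scope: the clustering question this package addresses is method-robust, and
NJ gives the same grouping. Bootstrap support resamples alignment columns
with replacement (`numpy.random.default_rng`, recorded in the support map
along with the seed and replicate count), re-runs distance + NJ, and tallies
unrooted bipartitions; trivial bipartitions have support 100 by
construction. Outgroup rooting is display-time only. For small matrices
(n ≤ 8) `exhaustive_me_tree` provides an independent brute-force
minimum-evolution reference: every unrooted topology is enumerated, branch
lengths are fitted by ordinary least squares, and the topology of minimal
total length is returned.

## Conservation profiles

Per-column conservation uses pairwise deletion (gaps excluded column-wise);
all-gap columns are flagged, not scored. Entropy is Shannon entropy in bits
(maximum log₂ 20 ≈ 4.32). Profile comparison is the Pearson correlation of
modal fractions over a user-supplied groove-position list — the package
ships no default position list because the groove-column assignments are
dataset-specific; a constant profile makes the correlation undefined and is
flagged rather than raised. No statistical test of profile resemblance is
attempted.

## Genomic pairs

Gene models come from GFF3 (via gffutils), using gene features with CDS
children; the annotation strand is trusted for orientation. A class II-type
gene needs ≥ 3 coding exons with the first two (in transcription order)
inside the distal and Ig exon-length windows (both 200–350 bp by default,
≈ 90 codons); a class I gene needs ≥ 4 with two distal-length exons before
the Ig exon. Head-to-head pairs are adjacent genes on opposite strands with
the minus-strand gene upstream (so the 5′ ends face across the gap) and an
intergenic gap of at most 20 kb — a deliberately permissive default, since
observed WA/WB gaps are on the kb scale; matching is greedy by smallest gap
with each gene in at most one pair, making the output independent of input
order and symmetric under contig mirroring.

## Synthetic data: what it emulates and what it does not

`make_chain` concatenates the frame consensi of a class's domain layout,
samples each planted signature uniformly within its allowed set (F/Y57,
F/L37), deletes class-absent indel regions, plants TM glycines, and mutates
the remaining positions independently at rate μ (uniform over the 19
alternative residues). `make_alignment_set` evolves the Ig consensus along a
user tree under per-site substitution probability 1 − e^(−b), then overwrites
the five diagnostic columns (Y8, L37, L55, F57, W61) on the designated clade
leaves. The packaged clade scenario has twelve taxa — a five-leaf planted
clade among Ig-tier relatives and two outgroup-like C1 domains — with
branch lengths of 0.04–0.20 substitutions/site, a moderate divergence at
which clade recovery is informative rather than trivial. `make_locus_gff`
plants divergently transcribed gene couples at 2 kb gaps and decoys
(same-strand neighbours at 2 kb, facing genes at 25 kb, single-exon genes)
isolated by 30 kb spacing.

Defaults: μ = 0 (noise-free worked examples; recovery suites sweep μ over
{0, 0.02, 0.05, 0.1}), 100 chains per class, branch scale 1.0. All
generators are deterministic given `SimConfig.seed`, and truth records carry
the planted labels, residues, clade and pairs so downstream stages can be
scored without reading generator internals.

What the generators do **not** emulate: real amino-acid composition or
site-rate heterogeneity, signal peptides, allelic polymorphism, realistic
intron lengths or flanking-gene context, and alignment uncertainty (chain
simulation introduces indels only at the schema's indel regions). Passing
recovery suites therefore demonstrates the internal consistency and
statistical behaviour of the methods under the planted-signal model, not
classifier performance on real, divergent sequences — on real data the
schema should be extended with the fuller lineage-specific residue sets and
the provisional blocks replaced.

## Problem sizes in the test and acceptance suites

Classifier recovery uses 100 chains/class at μ = 0 and 30 chains/class per
rate over three seeds for the monotonicity sweep; clade recovery uses 20
simulations at B = 100 bootstrap replicates; the NJ/minimum-evolution
comparison uses 50 seeded 5-taxon additive matrices plus recovery checks up
to 8 taxa; the pair round trip uses 20 seeded loci with five decoys each.
These sizes give binomial standard errors of a few percent on the reported
rates while keeping a full run in the tens of seconds.

## Known limitations

- Distal-domain boundary placement inherits any ambiguity of the alignment
  extent; exon borders are not used even when available.
- The Ig-frame coordinate system assumes the C1-set fold; V-set or C2-set
  domains will map poorly (by design they fall below the mapping threshold).
- Interface typing reads sequence signatures only; it does not model
  structure and cannot detect compensating substitutions.
- The head-to-head detector requires both genes of a pair to be annotated on
  the same contig; split assemblies will lose pairs.
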