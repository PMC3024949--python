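# Methods

## Scope and model overview

`tfbsevol` infers where in a species phylogeny transcription-factor binding
sites (TFBS) were gained or lost. The unit of inference is a *site
character*: a binary presence/absence vector over species, derived from
motif predictions projected onto a multiple alignment of an orthologous
regulatory region. Characters are reconstructed independently on a rooted
species tree by unweighted small parsimony, and co-gained/co-lost
characters are grouped into candidate cis-regulatory modules ranked by
branch length score. The package also carries the data-curation side of
the workflow: a literature-curated table of experimentally validated sites
with reference-sequence verification and UCSC custom-track export.

## Curated-site tables

Table coordinates are 1-based inclusive, the genome-browser display
convention; BED output converts to 0-based half-open (start−1, end). The
verification states are: `confirmed` (reference slice equals the reported
site sequence, case-insensitive), `revcom_confirmed` (equals its reverse
complement — sites reported on the opposite strand), `mismatch` (neither),
`region_only` (rows that describe conserved regions or unlocalized binding
regions — class `R()` or factor names `CR*`/`N*`/`SRR*` without a
confirmation marker), and `unchecked`. Multi-factor and multi-reference
cells are kept verbatim as printed in their sources; distinct-reference
counting splits citation cells on `;`.

The packaged reference slices are deterministic synthetic stand-ins for
the mm9 assembly (fixed internal seed 20101229), constructed so that each
marked row verifies with its recorded status. They validate the
verification machinery, not mm9 itself; nothing in the package contains
real genome sequence.

## Motif model and exact p-values

Counts plus a background-proportional pseudocount give per-position base
probabilities; scores are log2 odds against the background (bits). The
pseudocount default is 0.8 distributed by background, a common practice
value; background defaults to uniform and is configurable per matrix.

Window score p-values are exact under the i.i.d. background model: the
full score distribution of a random word of length L is computed by
dynamic programming after rounding each matrix entry to a lattice of
1/1000 bit (configurable). The worst-case discretization error of a word
score is L·(granularity)/2 ≈ 0.004 bits at L = 8, far below the score
differences that matter at practical cutoffs. Scores at or below the
matrix minimum return p = 1 exactly and scores above the maximum return 0
exactly, so the lattice never misclassifies the extremes. The test-suite
oracle compares the DP against full 4^L enumeration at thresholds placed
in score gaps wider than the total lattice rounding error, where the
discretized and exact classifications of every word provably coincide; at
those thresholds agreement is required to 1e-6.

Both strands are scanned by default (curated tables contain
opposite-strand sites); a minus-strand hit is reported at its forward
window start. Windows containing non-ACGT characters are skipped and
excluded from the E-value denominator; E = p · 2 · (N-free windows).

## Homology rule

Hits are compared across species in alignment-column space. Two hits are
homologous when (a) their motifs map to the same factor family — supplied
as an explicit motif→family table, since factor homology is curated
knowledge, not something inferred here — and (b) their column projections
overlap reciprocally by at least 0.5. Reciprocal overlap at 0.5 is the
weakest symmetric criterion that still prevents chains of adjacent sites
from merging; it is a parameter (`overlap_fraction`). Clustering is single
linkage; every hit belongs to exactly one character, characters span the
union of member spans, and character ids are deterministic
(`family:column_start`), so output is invariant to input order.

A species whose alignment row is entirely gaps across a character's span
cannot carry the site in the alignment; it is scored absent (0) and
flagged `unalignable` on the character. Treating unalignable sequence as
absence can inflate loss events — the two cases are not distinguishable
from a binary presence vector, and downstream consumers should consult the
flag.

## Parsimony

Reconstruction is binary small parsimony with unit costs, implemented as
the Sankoff dynamic program with explicit backtracking rather than the
classical set-based Fitch pass. The reason is ambiguity resolution:
candidate states at a node are exactly the argmin choices of the DP, so a
tie-break rule applied there cannot leave the space of minimum-change
reconstructions. `DELTRAN` (default) keeps the parent state on ties,
delaying changes toward the leaves and favouring independent late gains;
`ACCTRAN` flips on ties, placing the change on the current edge. (A naive
"flip whenever the Fitch set is ambiguous" rule is *not* safe — for a
cherry with states {0,1} under a 0 root it adds a change — which is why
the DP formulation is used.) An ambiguous root resolves to state 0:
absence is treated as ancestral, so regulatory elements are derived;
this is configurable (`root_state`). Gains are 0→1 edges, losses 1→0;
the score always equals gains + losses, and is invariant under the
resolution rule.

## Branch length score and modules

BLS(presence) = (branch length of the minimal subtree connecting the
present leaves) / (total tree branch length), computed on whatever species
tree is supplied. An edge belongs to the spanning subtree iff the number
of present leaves below it is strictly between 0 and the total present
count. Single-leaf presence scores 0, all-leaf presence 1, and the score
is monotone under absent→present flips.

Modules are the partition of event-bearing characters by (event edge,
event type). The module score is the *minimum* member BLS by default — a
module is only as conserved as its least conserved site — with the mean
behind a flag; which aggregation historical analyses used is not
recoverable, so both are provided. Ranking ties break by member count
(descending) then lexicographic member ids, making the ranked output
byte-deterministic. Singleton groups are reported: a lone site gained on
an edge is evidence in its own right.

## Track output

All outputs are UCSC custom tracks (track line + BED). Hit tracks are
BED6 with scores mapped to UCSC's 0–1000 range by
`round(1000·(S−S_min)/(S_max−S_min))` per matrix. Module tracks are one
track per module in rank order (`module_1` is the top-ranked), each member
character projected from alignment columns onto a chosen reference species
row and anchored to genomic coordinates.

## Simulator

The generator emulates exactly the process the inference assumes: a root
sequence drawn from the background; per-site substitution along each edge
with probability 1−exp(−rate·branch length) (Jukes-Cantor: the new base is
uniform over the other three); planted gains writing the motif consensus
at a fixed offset in the child lineage and planted losses re-randomizing
the site; no indels, so the alignment is the exact column stack. It does
*not* emulate: indels and alignment error, context-dependent mutation
(e.g. CpG), selection on site strength short of the consensus, or
transposon-mediated site insertion. Passing recovery tests therefore shows
the inference chain is correct under its own model assumptions, not that
real alignments are this clean.

Default study conditions (used by the recovery suites): a six-species
mammal-like tree (human, macaque, mouse, rat, dog, opossum) with 0.02
substitutions/site branches (opossum 0.04), a 500 bp region, a 14 bp
motif of ~21 bits information content, substitution rate 1.0 (≈2%
per-site change per branch), gain planted on the `euarchontoglires` edge
at offset 240, and a scan cutoff of p ≤ 1e-4. Under these conditions the
planted edge is recovered in ≥90% of 50 seeded replicates (measured
0.98–1.0 across acceptance seeds); recovery degrades monotonically as the
substitution rate grows, which the suite checks as a non-strict trend over
rates 0.25/2.5/8.0.

## Numerical and interface choices

- p-value lattice granularity 1e-3 bits; exact clamping at score extremes.
- Hit ordering (start, strand, motif id), character ids from
  (family, column start), module tie-breaks as above: all outputs are
  deterministic given inputs and seeds.
- Degenerate inputs: zero-count matrix columns without pseudocount are
  rejected; sequences shorter than the motif scan to an empty hit list
  (not an error); all-absent presence vectors make BLS undefined (error);
  unary internal nodes and multifurcations are handled by the Sankoff DP.
- Problem sizes in the oracle suites (all rooted topologies to 6 leaves ×
  all 2^n labelings for parsimony; 4^L enumeration to L = 8 for p-values;
  all leaf subsets of sampled topologies for BLS) were chosen as the
  largest cases where exhaustive oracles are exact and quick.
- Trees are read with dendropy (newick), sequences and alignments with
  biopython (FASTA, single-block MAF); MAF stitching across blocks is out
  of scope, as is alignment computation itself.

## Known limitations

- Absence vs. unalignability is collapsed to 0 in parsimony (flagged but
  not modelled), biasing toward loss events in poorly aligned regions.
- Characters are treated as independent; no correlated-character
  parsimony and no significance model for module co-occurrence.
- Factor-family homology must be supplied; no nomenclature normalization.
- The E-value cutoff for reporting is configurable and carries no claimed
  historical default.
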