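# Methods

## The discovery model

`ifnscan` operationalizes a four-criterion screen for class II cytokine
genes (interferons, IL-10 family) in unannotated DNA. The target gene
class is defined structurally: five coding exons, all intron phases zero,
a secreted ~120–250 residue protein with an N-terminal signal peptide and
a bundle of alpha helices.

The central engineering observation is that the phase-zero criterion can
be imposed *structurally* rather than filtered post hoc. If every intron
phase is zero, then each coding exon's length is ≡ 0 (mod 3) and no codon
crosses a splice junction. Consequently an exon is admissible iff it is a
multiple of 3 long and stop-free in its own frame 0, and any chain of
admissible exons through GT–AG introns splices into a clean ORF. The
search space collapses from "all possible spliced genes" to a chain
enumeration over a modest set of exon candidates, and the enumeration is
*complete* within the stated bounds: every gene satisfying the structural
criteria is found (verified against a brute-force enumerator in the test
suite). No splice-site strength model is used beyond the GT/AG
dinucleotides; false positives are controlled downstream by the protein
screen, mirroring how the original procedure delegated gene calling to
generic predictors and relied on protein features for specificity.

### Search bounds (SearchParams)

| parameter | default | meaning |
|---|---|---|
| min_exon / max_exon | 30 / 600 nt | coding exon length; multiples of 3 enforced |
| min_intron / max_intron | 60 / 20 000 nt | GT–AG intron length |
| min_protein / max_protein | 120 / 250 aa | encoded protein length (vertebrate IFNs are ~160–200 aa) |
| n_exons | 5 | coding exons per chain (4–6 configurable) |
| strands | both | intergenic DNA is scanned in both orientations |

The pipeline and the synthetic study condition use intron bounds
[60, 70] nt (a compact, fish-like intron class). This is a deliberate
choice: the chain enumeration is exhaustive, and the number of accidental
exon chains in random DNA grows with the fourth power of the allowed
intron-length range. At [60, 70] a 2 Mb background contains a few dozen
accidental chains (handled by the screen and the generator's
verification); at [60, 20 000] it contains millions and the enumeration
itself becomes the bottleneck. Scanning a real genome with large introns
is possible but requires restricting the protein-length window or the
region size accordingly.

Overlapping chains are deduplicated keeping the highest search score
(total coding length − 0.01 × total intron length), with ties broken by
leftmost start, then '+' strand. Output order is deterministic.

## Protein-feature surrogates

The screen's protein criteria are computed by classical, fully documented
sequence methods (no external servers, no learned models):

* **Signal peptide** — tripartite model. (i) net charge of residues 1–5
  ≥ 0 (K,R = +1, D,E = −1); (ii) an h-region: some window of ≥ 8 residues
  within positions 2–20 with mean Kyte–Doolittle hydropathy ≥ 1.5;
  (iii) a cleavage position p ∈ [15, 35] whose −1 and −3 residues are
  small (A, G, S, C, T) — the von Heijne rule; the smallest valid p is
  reported. The call is the conjunction of (i)–(iii); the score is the
  h-region's mean hydropathy.
* **Alpha helices** — Chou–Fasman helix propensities (1978 table),
  centered 7-residue window mean ≥ 1.03 marks a residue helical; maximal
  runs ≥ 7 residues are segments; "multiple alpha helices" means ≥ 4
  segments. Type I IFNs show six helices (A–F); the threshold is set
  below that to avoid over-rejection of shorter family members. Window
  edges (first/last 3 residues) are never marked.
* **Transmembrane segments** — 19-residue Kyte–Doolittle window mean
  ≥ 1.6, runs ≥ 15 residues kept. Windows are truncated at the sequence
  ends so a TM helix flush against a terminus is detected; this matters
  for `trim_intracellular`, which cuts a receptor after its last TM
  segment before tree building (the standard preprocessing for class II
  receptor phylogenies).
* **Motifs** — the interferon cysteine pattern C-x(5)-[WL] and the box1
  receptor motif P-x(2)-L, reported as annotation only; they are not
  among the four gating criteria.

All thresholds live in `FeatureParams` and are configurable; the defaults
above were fixed once, from the cited classical sources, before any
evaluation. The screen is monotone: relaxing any threshold can only turn
failures into passes.

## Alignment and identity

Pairwise alignment is global Needleman–Wunsch with affine gaps
(BLOSUM62, gap open 10, extend 0.5, end gaps penalized — Clustal-flavored
defaults), executed by Biopython's pairwise aligner; an independent
pure-Python Gotoh implementation with the same convention is kept as a
cross-check and verified cell-for-cell in the tests. Percent identity is
100 × identical columns / columns where at least one row has a residue
(terminal gaps count in the denominator). Published identity figures for
the cytokine families use unstated Clustal conventions, so small
systematic offsets against printed percentages are expected; the
convention here is stated and applied uniformly. Multiple alignment is
classic progressive alignment: p-distance guide tree by UPGMA
(scipy average linkage), profile–profile merges scored by expected
BLOSUM62 column score. Distances for tree building are d = 1 −
identity/100 (p-distance) or −ln(1 − p) (Poisson), computed on the MSA.

## Phylogeny

Neighbor joining follows Saitou–Nei exactly: join the pair minimizing
Q(i,j) = (n−2)d(i,j) − Σd(i,·) − Σd(j,·), two-point branch-length
formulas, negative lengths clamped to zero, ties broken by the smallest
(label, label) pair (a merged cluster carries its smallest leaf label).
On additive matrices this recovers the generating topology and all path
lengths to ≈ 1e-15 (asserted at 1e-9 over 500 random trees, n ≤ 8, and
cross-checked once against scikit-bio's NJ). Bootstrap: alignment columns
are resampled with replacement (seeded NumPy generator), distance + NJ are
recomputed per replicate, and each internal edge's support is the
percentage of replicates containing the same leaf bipartition. The
conventional 1000 replicates are the CLI default; tests and the
acceptance script use 100 for runtime, which is ample for the saturated
two-clade fixtures they assert on. Clade assignment of a query leaf is by
minimal mean patristic distance to each labelled reference group, ties
broken alphabetically.

## Synteny

A locus map is the ordered, stranded list of gene symbols around a focal
gene (default k = 5 per side). Two maps are compared by shared non-focal
symbols (Jaccard), a flanking-conservation flag (≥ 1 shared anchor on
each side of the focal gene in both maps) and an inversion flag (shared
anchors in reversed relative order). Interferon locus types are
recognized by fixed anchor sets: type I = {HACD4, ARHGAP27}, type II =
{DYRK2}, type III = {SYCN, SUPT5H}, type IV = {ADARB2, PFKP}; the type
with the largest anchor intersection wins, no anchors → "novel", ties →
"novel" with a warning. Matching is exact on case-folded symbols; no
orthology inference is attempted, and quantitative conservation is the
package's stated operationalization (Jaccard + flanking rule), since no
numeric score accompanies published synteny figures.

## The synthetic-genome generator

The generator is the package's instrument for making every stage testable
without downloads. It emulates: i.i.d. background DNA at a given GC
(default 0.40, 2 Mb); dummy "annotated genes" that define the intergenic
space; planted positives — five exons (lengths ≡ 0 mod 3) reverse-
translated with uniform synonymous codons from a designed protein
(signal peptide per the screen's own rules, 5–6 helix blocks on an
E/A/L/K alphabet separated by G/N/P/S linkers, one C-x(5)-[WL] motif);
and decoys that each violate exactly one criterion
(`wrong_exon_count`, `nonzero_phase` — one internal boundary shifted +1 nt
and compensated, `no_start`, `internal_stop`, `no_signal_peptide`,
`low_helix`). Placement keeps ≥ 1 kb spacing; the annotated genes
flanking each positive are named ADARB2/PFKP so the synteny stage sees a
type IV locus. Everything is a pure function of (parameters, seed).

Two design points deserve emphasis because they were forced by the
mathematics of the exhaustive search:

* **Planted introns are fixed at 70 nt with GT/AG-free interiors.** The
  scanner finds *every* legal segmentation, including alternative
  donor/acceptor choices a few bases away from the planted ones, exon
  merges across an intron, and exon splits around an internal GT…AG
  pair. Any such variant that outscores the planted gene would corrupt
  the truth record. Fixing the intron length at the top of the scanned
  class blocks boundary shifts into exons (the intron would exceed
  max_intron); 70 ≡ 1 (mod 3) frame-breaks merges; interiors free of
  GT/AG offer no alternative splice signals; and structural-decoy
  proteins are kept ≤ 135 aa so any re-segmentation that intronizes
  ≥ 60 nt of coding falls below the 120 aa search floor.
* **The generator verifies itself.** Random background is not free of
  accidental five-exon phase-zero chains — at the default conditions a
  2 Mb genome contains dozens of cluster winners, and a few percent of
  their random proteins even pass the protein screen. After assembly the
  generator therefore runs the scanner + screen on its own output and
  repairs violations: offending background windows are re-drawn, and any
  planted cassette touched by a violating chain is re-rolled in place
  (same protein, same coordinates, fresh synonymous codons and intron
  interiors). The loop converges in a handful of rounds; the number of
  repairs is reported on the truth object (`repaired_collisions`), never
  silently absorbed. If a fixed point is not reached within the round
  budget the generator raises.

What passing tests on this generator do **not** show: performance on real
genomes with long or non-canonical introns, repeat content, codon-usage
bias, pseudogenes, or genes whose signal peptides/helices defeat the
classical surrogates. The generator's proteins are built to satisfy the
same rules the screen tests, so screen recall on synthetic positives is
by construction, not an estimate of sensitivity on real cytokines; what
the synthetic experiments genuinely measure is the *structural* search's
exactness, the screen's specificity against random-DNA proteins, and the
end-to-end bookkeeping (coordinates, strands, determinism).

## Problem sizes and numerics

Tests and the acceptance script use: the full 2 Mb / 8+16 / seed-42
discovery condition; 250–400 kb genomes for fixtures; 500 random additive
matrices (n ≤ 8) at 1e-9 for NJ; 100 bootstrap replicates; 1000-case
oracle sweeps for intron phases and interval complements; 200 random
pairs (len ≤ 30) for alignment-score equality plus exhaustive enumeration
at len ≤ 6. Branch lengths are clamped at 0; bootstrap supports are
integer percentages; identity is reported to one decimal; Newick is
written with 6-decimal branch lengths; all RNG is NumPy's PCG64 seeded
from a single integer.

## Known limitations

* Only canonical GT–AG introns; no splice-strength model, no UTRs, no
  alternative splicing, no non-standard genetic codes.
* The exhaustive chain search is exponential in permissive settings;
  practical scans need bounded intron ranges (see above).
* Feature surrogates are classical approximations of SignalP/PSIPRED/
  TMHMM-class predictors; their thresholds are stated choices, not
  fitted values.
* Identity conventions differ between alignment programs; comparisons to
  figures produced with other tools carry a ±2-point-scale uncertainty.
* Synteny works on curated symbols; it cannot see rearrangements below
  the gene level or resolve paralog naming conflicts.
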