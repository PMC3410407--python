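# Methods

This note documents the models, procedures and numerical choices behind
`ktfam`: a pipeline that inventories potassium-transport protein families
(HAK/KT/KUP transporters, HKT transporters, tandem-pore K⁺ channels,
voltage-gated Shaker-like channels, BK-like channels) across plant
proteomes, and reconstructs the history of each family by gene-tree /
species-tree reconciliation.

## Degenerate-motif screening

Candidate transporters are found by exact positional matching of ten
class-specific degenerate motifs (three for K⁺ channels, two for HKT,
five for HAK), shipped verbatim in `ktfam/data/motifs.txt` in a
dash-separated dialect (`x` wildcard, `[A,B]` allowed set, single fixed
letter). Matching is PROSITE-style: a window of length *m* matches iff
every position's residue is in that position's allowed set. No indels,
no scores. `X` (unknown residue) never satisfies a restricted position
— a conservative choice so that poorly sequenced regions cannot create
hits — while the wildcard matches anything, including `X`.

**Family-call rules.** The original screening procedure does not state
how many motifs of a class must co-occur, so the rules here are an
explicit, configurable reconstruction (`ClassificationRules`):

- HAK: at least 3 of the 5 HAK motifs (default `hak_min = 3`);
- HKT: both HKT motifs;
- channel: the pore motif (motif 1, the selectivity-filter region)
  present at least once. Pore count = leftmost-greedy non-overlapping
  motif-1 hits; 1 pore → single-pore (Shaker-like) subunit, 2 pores →
  tandem-pore (TPK) subunit.
- Precedence on conflict: HAK > HKT > CHANNEL. All hits from all ten
  motifs are retained as evidence regardless of the final label.

Motifs 2 and 3 (voltage-sensor-like and inner-helix-like) are recorded
as evidence but not required for the channel call, because the tandem-
pore channels lack voltage sensors. The inventory stage, however, only
labels a single-pore subunit "Shaker-like" when motif 2 or 3 evidence is
present; single-pore calls without voltage-sensor evidence go to an
`OTHER_VG` review bucket (this is how BK-like subunits surface without a
BLAST stage).

## Six-frame GYG exhaustiveness scan

To check that a channel screen missed nothing, genomic DNA is translated
in all six frames (standard code; codons containing a non-ACGT letter
become `X`, stops `*`), ORFs are taken as maximal stop-free runs
(stop-to-stop; no ATG requirement, so channel fragments are not missed;
default minimum 50 residues), and every G-Y-G tripeptide inside an ORF
is reported with forward-strand coordinates and a configurable peptide
context window (default ±40 residues). The original procedure's manual
inspection of the filter's surroundings is deliberately kept manual:
the scan emits the context for human review and makes no automated
channel call. Coordinates are 0-based half-open internally, 1-based
inclusive in written reports.

## Semi-automatic curation

The screen is permissive by design; curation removes fragments and
coincidental matches in four audited steps:

1. **Length filter.** Per family, the reference span is the mean
   distance between the outermost motif hits in reference proteins
   (references with < 2 hits are skipped; an error is raised if none
   qualify). Candidates shorter than 70% of that span are discarded;
   the boundary case (exactly 70%) is kept, since only strictly shorter
   sequences are excluded.
2. **Pairwise scoring.** All n(n−1)/2 pairs are globally aligned under
   BLOSUM62 with affine gaps (open 10, extend 0.5 — ClustalW-like
   defaults). The score is 100 × identities / min(length), rounded to 2
   decimals. "Identities" is made well-defined under co-optimal
   alignments by taking the maximum identity count over the enumerated
   optimal alignments (deterministic enumeration, capped at 64
   alternates). The underlying percent-identity semantics of the
   original ClustalW-based score are not published; this definition is a
   documented reconstruction.
3. **Pruning and fragmentation.** Pairs scoring 100 are treated as
   duplicates: the lexicographically larger id is dropped from the
   similarity graph (and recorded with its kept twin). Dropping both
   members would discard genuine identical paralogs, which the published
   inventories retain — so the pipeline restores a dropped twin to the
   final inventory whenever its keeper is selected. Edges under 20 are
   deleted; connected components of the remaining graph are the
   candidate groups (isolated ids are singletons).
4. **Group selection.** The component with the highest mean pairwise
   score to the reference proteins is selected; ties break to the larger
   component, then the lexicographically smallest member id, so runs are
   exactly reproducible.

## Alignment and block filtering

Families are aligned with a plain progressive aligner: UPGMA guide tree
on pairwise-identity distances, then profile–profile global alignment
with linear gap cost (−8 per column) and mean-BLOSUM62 column scores
(computed as one matrix product over per-column residue counts). This
is adequate for the low-divergence, indel-free synthetic families this
package simulates; real-data users should align externally and enter
through `msa_from_aligned` / the aligned-FASTA hooks.

Low-quality regions are removed with a GBlocks-style block filter using
the parameter set applied to these families: conserved-position
threshold and flank threshold both "half the number of sequences" —
read as ⌈n/2⌉, a majority-or-tie reading well defined for odd n —
maximum run of contiguous non-conserved positions 20, minimum block
length 2, and gaps counted as an ordinary 21st symbol ("positions with
gaps were not treated differently"). Because both thresholds sit at
half, the usual conserved / highly-conserved distinction collapses and
a single CONSERVED status is used. Columns are labeled, over-long
non-conserved runs deleted, remaining segments trimmed so they start
and end on flank-qualified columns, and segments shorter than the
minimum block length dropped. The filter is idempotent. Note that with
gaps as ordinary symbols a gap-majority column can count as conserved;
such columns are visible in the retained-column report.

Identity distances for tree building: identity is computed over columns
where both rows are non-gap; distance = 1 − identity; pairs with no
comparable columns get distance 1.

## Distance trees and bootstrap

UPGMA (average linkage, merge heights nondecreasing) serves for
identity-based clustering; neighbor joining (Saitou–Nei Q criterion,
negative branch lengths clamped to 0) is the built-in gene-tree builder.
Maximum-likelihood inference is intentionally out of scope: NJ on
identity distances is a desk-scale stand-in, and any externally computed
tree can be imported as newick. All tie-breaks (pair choice in both
agglomerations) are lexicographic on cluster ids (the smallest leaf
label in a cluster), making every build deterministic. Bootstrap
support resamples alignment columns with replacement (seeded NumPy
generator), rebuilds per replicate, and reports the percentage of
replicates containing each internal bipartition of the reference tree.

## Duplication–loss reconciliation

The core analysis. Each gene-tree node is mapped to the lowest
species-tree node containing all its descendant species (LCA mapping,
one post-order pass). An internal node is a **duplication** iff it
shares its image with at least one child, otherwise a **speciation**.
Losses are the minimal set consistent with the mapping: for a gene edge
(u, v) whose images are k species-tree edges apart, a speciation parent
implies k−1 losses and a duplication parent k, each charged to the
species branch the lineage failed to enter (the sibling branch at each
bypassed species node). No losses are charged above the gene root
unless the family's origin is pinned to the species root
(`species_root_constraint`, off by default).

**Rooting.** Unrooted gene trees are rooted by evaluating D+L for every
branch rooting and keeping the minimum; ties break on the canonical
(children-sorted, topology-only) newick string, and all tied rootings
are reported.

**Ancestral copy numbers** use the *copies exiting a species node*
convention: the number of gene lineages present in that ancestral
genome after the duplications mapped to that node. Formally, count gene
edges (u, v) — including a virtual edge above the gene root — whose top
end maps above the node (or to it as a duplication) and whose bottom
end maps below it (or to it as a speciation or leaf). This convention
reproduces all four internally consistent figure-level claims for these
families (one ancestral HKT gene and two TPK genes in the embryophyte
ancestor; one Shaker-like gene in the land-plant ancestor, two in the
tracheophyte ancestor with the K_in copy lost toward *S.
moellendorffii*). The published HAK claim (two embryophyte ancestors)
is not reproducible under the same convention together with the
described placement of three-plus duplications before the tracheophyte
origin; the HAK fixture is therefore shipped and reconciled, but its
ancestral count is reported rather than asserted.

**Fixture gene trees.** The packaged inventory tables fix one leaf per
published locus. Within each ortholog group the topology mirrors the
species tree restricted to the represented species, with same-species
loci attached as species-internal clades; groups join at the base per
the published group structure (HKT: one group; TPK: two; Shaker-like:
the *P. patens* clade against (K_out including Sel-moe-SmORK, angiosperm
K_in); HAK: six groups, V and VI *P. patens*-specific). Per-locus group
assignments beyond the published anchors are a reconstruction; the
asserted copy-number results depend only on each group's species span.
The one partially annotated poplar locus is included by default and can
be excluded with a flag.

Correctness is checked against an independent oracle that enumerates
every valid gene→species mapping and takes the minimum duplication+loss
cost: the implementation agrees on all 26,820 gene-tree/assignment
combinations with ≤ 5 gene leaves over a 3-species tree (one rooted
3-leaf species shape represents all of them up to relabeling).

## Synthetic proteomes and ground truth

The generator stands in for the five real plant proteomes
(*A. thaliana*, *O. sativa*, *P. trichocarpa*, *P. patens*,
*S. moellendorffii*), whose inventories are packaged as fixtures but
whose sequences are not redistributable at desk scale.

- **Species tree:** the packaged 5-species topology with unit branch
  lengths.
- **Families:** one template per family carrying planted motif
  instances at fixed offsets (HAK: motifs 6–10; HKT: 4 and 5; TPK: two
  pore motifs; Shaker-like: pore motif flanked by motifs 2 and 3).
  Template lengths (400 / 280 / 220 / 340 residues) are roughly half
  the real proteins, preserving their relative order. Templates are
  deterministic (fixed internal stream) and validated at load.
- **Gene-family evolution:** a birth–death process along the species
  tree — per copy, duplication rate 0.2 and loss rate 0.05 per branch
  unit by default (modest expansion, a few events per family per tree),
  exponential waiting times, fully extinct families redrawn up to a
  retry cap.
- **Sequence evolution:** independent per-site substitution with
  probability 1−e^(−rt) per branch (default r = 0.03 per site per unit,
  keeping within-family identity near 80%); a substituted site draws a
  uniform different residue. Sites inside planted motifs may only move
  within the motif's allowed set, so every emitted member scans positive
  at the planted offsets — motif conservation is enforced, not
  emergent, guaranteeing a well-defined truth set for the screen.
- **Decoys:** per species, 10 decoys by default; 90% uniform-random
  with a length distribution matched to the family templates (±20), 10%
  near-misses — template copies with one restricted position mutated
  outside its allowed set in exactly as many motif instances as needed
  to defeat the source family's call rule (one for HKT/TPK/Shaker-like,
  three for HAK, whose rule tolerates two missing motifs). Near-misses
  probe specificity right at the decision boundary.
- **Recovery regime:** for event-recovery experiments the generator
  supports species-specific duplications only
  (`terminal_duplications_only`), with duplications placed in the last
  30% of the terminal branch (rate rescaled to preserve the expected
  count). Recent paralogs are clearly less diverged than sister
  species; an early terminal duplication is statistically
  indistinguishable from an ancestral duplication plus loss, so exact
  event recovery is only an identifiable target in this regime.

All randomness flows from one seed through named substreams (family,
sequence, decoy; CRC-based tags), so stages are independently
reproducible across processes.

**What the generator does not emulate:** empirical substitution
matrices (LG/JTT), rate heterogeneity, indels (within-family alignments
are gap-free by construction), codon-level effects, gene structure, and
annotation noise. Passing tests therefore demonstrate the pipeline's
algorithmic correctness and its behavior under clean, well-separated
families — not performance on real, noisy proteomes.

## Numerical and engineering choices

- Gap convention: the first gapped position costs the full open penalty
  (10), each additional position 0.5, matching the pairwise engine used
  for scoring; the test oracle enumerates alignments under the same
  convention.
- Percent identities rounded to 2 decimals before thresholding, so the
  dedup rule (score = 100) is exact.
- Newick serialization prints branch lengths with up to 6 decimals,
  trailing zeros stripped; write∘read∘write is a fixed point. Parsing
  is delegated to dendropy and errors are re-raised as `NewickError`
  (dendropy's message replaces a character offset).
- UPGMA/NJ are implemented in-package rather than taken from a library
  because deterministic lexicographic tie-breaking is part of the
  contract here; both are validated against exact recovery of random
  ultrametric/additive matrices.
- Degenerate inputs: empty filter output is a valid (empty) alignment
  with a warning; all-gap column pairs get identity distance 1;
  single-member families skip alignment and trees; reconciliation
  requires ≥ 3 members.
- Problem sizes in the shipped test-suite and acceptance script —
  1000/300 random proteins for the scanner oracle, 200/100 random
  alignments for the filter oracle, 200/100 tree-recovery instances,
  the full ≤ 5-leaf reconciliation enumeration, 50 simulation seeds,
  2000 calibration replicates — were chosen to exercise each component
  densely while keeping a full run in the low minutes on one CPU.

## Known limitations

- The progressive aligner has no iterative refinement and linear gap
  costs only; it is not a general-purpose aligner.
- The classification rules are a reconstruction of an under-specified
  published procedure; the defaults are calibrated on the synthetic
  families (planted members classify correctly, random/near-miss decoys
  do not), not on real proteomes.
- Reconciliation assumes binary rooted trees on both sides and pure
  duplication–loss histories (no transfers, no incomplete lineage
  sorting); bootstrap-weighted edge thresholds and tree rearrangement,
  as offered by interactive reconciliation tools, are not implemented.
- The real-genome screen is not reproducible here (it requires
  versioned proteome releases); the packaged tables are fixtures, and
  all pipeline claims about recovery are made on the synthetic
  benchmark under the stated conditions.
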