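# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The substitution model

All sequence evolution uses the Kimura 2-parameter (K2P) process: one rate
for transitions (A↔G, C↔T) and one for the four transversions, with
transition/transversion rate ratio `kappa` (default 2, a typical nuclear
value). Given a target depth `K` (expected substitutions/site) and
`kappa`, per-site change probabilities follow the standard closed forms

    P = 1/4 + 1/4·e^(−4βt) − 1/2·e^(−2(α+β)t)
    Q = 1/2 − 1/2·e^(−4βt),     with αt = kappa·βt, βt = K/(kappa+2),

so that the downstream estimator, `K = −½·ln[(1−2P−Q)·√(1−2Q)]`, is the
exact inverse of the generator. The estimator raises an explicit
saturation error when the log argument is non-positive; saturated pairs
propagate as missing values (never as numbers). Columns containing a gap
or ambiguity code are excluded from both numerator and denominator
("pairwise deletion"). Indels are generated separately (per-site
probability `indel_rate`, default 5·10⁻⁴; deletions of single sites and
insertions of geometric length ≤ 10) and are never counted as
substitutions.

Calibration is verified by round-trip tests: mean estimated K over
replicates is within 1–2% relative of the target across K ∈ [0.01, 0.3].

## The synthetic study system

`make_species_tree` draws a random rooted ultrametric binary tree (root
age in Ma; child-clade ages are uniform fractions of the parent's), or a
tree can be supplied as newick. The divergence time of two species is
their MRCA's age.

`make_master_element` builds a family master: ~1.5 kb (allowed range
1,072–2,191), TIR arms of 13–68 bp starting with a CAGTC-type pentamer
(the right arm the reverse complement of the left), TA TSD signature, and
a transposase ORF of 304–350 aa with an initial M, a GRPR motif in the
N-terminal region, and a planted D..D..E triad whose D2–E spacing defines
the family label (35 → DD35E). The catalytic region contains no other D/E
residues, and stop codons in all three frames guard both ORF ends, so
structural detection on the pristine master is unambiguous by
construction.

`simulate_invasion` plants copies on the tree:

* A **vertical** event enters the stem of its recipients' MRCA clade at
  `time_ma` as the master sequence and the active element lineage then
  drifts *along the tree* — shared between descendants until each split,
  species-private on terminal branches. Copies branch off the active
  lineage at exponential-burst insertion times (scale 5 Ma below the entry
  point, or below an optional `burst_time_ma`: an anciently inherited
  element can amplify recently) and decay neutrally as dead copies from
  then on. Consequence: two species split T Ma ago carry copies
  ≈ 2·te_rate·T apart — the same expectation as the host gene scaled by
  the rate ratio — while the within-species landscape peaks at the burst
  depth. A model in which every copy is an independent draw from the
  master would instead make per-species consensuses collapse onto the
  master and fake a horizontal signal for vertically inherited families.
* A **horizontal** event delivers the master into each recipient's
  terminal lineage at the transfer time; several recipients model one
  element spreading across hosts at that time.

The active lineage evolves under crude purifying selection
(`_repair_functional`): substitutions creating ORF stop codons or
destroying the start codon are reverted, triad and GRPR codons and the TIR
terminal pentamers are protected, the right TIR arm is kept the reverse
complement of the drifting left arm (transposase binding maintains arm
complementarity), and 70% of remaining nonsynonymous codon changes are
reverted (`aa_revert`). Dead copies decay with no constraint. Without
this, invasions older than ~150 Ma lose ORF and TIR structure entirely,
contradicting the structurally conserved family regime the analysis
targets.

Rates: TE rate 1.4·10⁻³ subs/site/Ma; host-gene rate 0.3× that. These are
free parameters, not estimates for any real taxon; they are set so that a
RAG1-like host distance reaches ≈ 0.25 at ~300 Ma splits, the magnitude
regime of vertebrate host-gene yardsticks. The host gene (3 kb) evolves
along the tree from a single ancestor.

Other generator choices: i.i.d. uniform background (60 kb default, one
contig per species) — sufficient to exclude spurious hits at these scales;
truncation with probability `p_trunc` = 0.3 removes a uniform prefix
and/or suffix (≥ 100 bp retained), and a truncated side loses its TA TSD
(the deletion is modelled as removing the element edge together with its
duplicated target); insertion sites are uniform; strands are random. Each
species consumes its own seeded random stream derived from the master
seed, so adding a species leaves other genomes byte-identical (the shared
lineage drift of a multi-species vertical event necessarily uses a
per-event stream). Everything is byte-reproducible under a fixed seed.

What the generator does **not** emulate: selection beyond the element
itself, recombination, CpG hypermutability, nested insertions,
within-genome transposition bursts copying from existing copies, assembly
artefacts, or realistic background composition. Tests passing on these
simulations therefore demonstrate algorithmic correctness under the
stated statistical model, not performance on real genomes.

## Search engine

Nucleotide search is seed-and-extend: an exact k-mer index (k = 11) finds
seeds, seeds are clustered into candidate windows (gap > query length
splits clusters), and each window is scanned by an affine-gap local DP
(match +1, mismatch −1, gap of length L costs −4 − L), iteratively taking
the best alignment, recording it, masking it and re-scanning until the
score drops below `max(25, ½·min_length·(2·min_identity − 1))`. Hits then
pass the identity/length filter, and hits sharing > 50% of the shorter
interval on one strand are merged keeping the best score (the analysis
counts loci, not HSPs). Identity is identical columns over all alignment
columns (gaps count as differences). Tie-breaking is fixed — first
maximum in target-then-query scan order; traceback prefers diagonal, then
gap-in-query, then gap-in-target; a gap closes before it extends — so an
independent full-matrix implementation reproduces hits exactly; the test
suite verifies equality with a seed-free exhaustive oracle on 50 random
genomes at 80/90/100% identity. The `xdrop` parameter bounds the DP scan
(a large default keeps it exhaustive).

The protein stage (`translated_scan`) six-frame-translates each contig,
splits frames at stop codons, and runs the same engine at amino-acid level
under BLOSUM62 with gap 11/1 — identity scoring cannot detect the
~50%-identity transposase homologs a TBlastN-style search must find. Hit
coordinates map back to nucleotides of the matched frame.

Copy number follows the published filter exactly: alignments strictly
longer than 1,000 bp **and** ≥ 80% identity. The contamination check maps
a low-copy insertion's flanks (seeded search at 90% identity over at least
half the flank) against the host and related genomes, excluding the home
locus; unmappable flanks mark the copy as likely contamination.

## Boundary refinement

Hits are extracted with 1,000 bp flanks (clipped at contig ends;
minus-strand copies reported in element orientation with flanks swapped
and reverse-complemented). `refine_boundaries` center-star-aligns copies
over flank+element+flank (a `flank_window` restricts alignment to the
region where corrections happen) and walks outward from the hit core,
placing boundaries where per-column agreement collapses. Three
refinements matter in practice:

1. Columns where fewer than half the rows have a residue are treated as
   uninformative (insertions must not stop the walk), and a moving average
   over informative columns (window 8, threshold 0.6) drives the coarse
   walk, with an edge rule (two consecutive columns ≥ 0.8 agreement and a
   strong inward mean) placing the provisional edge.
2. Each copy is re-anchored on the majority sequence of the outermost
   element columns (±6 bp, ≤ 3 mismatches over 12 bp): "once a gap,
   always a gap" alignment lets individual rows wander by a few bp.
3. Edges are re-walked on raw residues, voting only over rows that
   anchored cleanly (truncated copies' random flanks otherwise poison the
   outermost columns), under a maximal-scoring-segment rule (step score =
   majority fraction − 0.7, x-drop 1.5). Finally, when a TSD is given
   (TA), boundaries snap collectively so the duplication abuts the
   element: TSDs are identical across copies, so conservation alone cannot
   separate them from the element — the copies vote for one shift, applied
   only to copies that confirm it.

Accuracy on simulations: exact at 5% copy divergence with TSDs present;
for five identical copies in random flanks the recovery is exact in most
constructions and within a few bp otherwise — with five copies, a chance
(or aligner-induced) agreement of flank bases immediately outside the
element is information-theoretically indistinguishable from element
sequence (~6% per edge from base composition alone). Copies sharing real
flanking homology (e.g. a segmental duplication) extend the boundary into
the shared flank; that failure mode is inherent to conservation-based
calling and is covered by a test.

## Structural annotation and classification

* `detect_tir` scores every candidate arm pair (anchored at the termini by
  default — the family's TIRs abut the TSDs; an offset search within
  120 bp is opt-in) with `length − 3·mismatches`, requiring mismatches
  ≤ 15% of the arm, ties to the longer arm then leftmost offsets. It
  matches an exhaustive enumeration oracle on simulated elements.
* `detect_tsd` reads the last 2 bp of the left flank and first 2 bp of the
  right flank against the expected TA.
* `find_orf` returns the longest ATG-initiated, stop-terminated frame on
  the element strand (ties leftmost; both-strand scan by flag); the
  interval includes the stop codon.
* `detect_dde` scans the C-terminal 60% of the protein for D..D..E with
  D2–E spacing in {34,35,36,37,38,39,41} (sister families are labelled,
  e.g. DD34E) and D1–D2 spacing (residues strictly between) in 60–110;
  the requested family spacing wins, then the nearest spacing, then the
  most N-terminal glutamate, with D1 the aspartate nearest D2.
* `detect_grpr` reports the leftmost exact GRPR in the N-terminal half.

Classification: **full_length** = both TIR arms detected and both TSDs
equal TA; **intact** = full_length and an ORF encoding 303–350 aa
(Table-style printed range; the narrower 304–350 appears in running text —
the wider range is the default) with the family triad; otherwise
**truncated**. Removing evidence can only downgrade (monotonicity is
property-tested).

## Consensus, identity, clusters

Pairwise global alignment is Biopython's `PairwiseAligner` under the same
scoring as the search engine; among co-optimal paths the aligner's first
deterministic path is reported (scores equal the exhaustive enumeration
oracle on small strings). The center-star MSA picks the sequence with
maximal summed pairwise identity as center and merges pairwise alignments
("once a gap, always a gap"); degapping any row recovers its input.
Majority-rule consensus: per column the most frequent residue if it
reaches `min_frac` (0.5) of non-gap rows, IUPAC code of the top ties
otherwise; gap-majority columns are dropped. Identity matrices offer two
denominators — `count_gaps` (default; gaps count as differences) and
`exclude_gaps` — because published matrix conventions are ambiguous; both
are exposed wherever identities are reported. Cluster assignment is
average-linkage hierarchical clustering of 100 − identity, cut at k or an
identity cutoff, with deterministic A/B/C labels by size then lexicographic
member; memberships, not branch supports, feed downstream stages, which is
why a distance method stands in for a likelihood phylogeny.

## Landscapes and the recent-invasion call

Each copy is globally aligned to the reference (consensus or
representative) individually — matching the per-copy alignment workflow of
repeat-landscape tooling — and contributes its length in kb to the 1%-wide
bin containing its K2P divergence. Species with fewer than 10 copies are
marked excluded; saturated copies are counted but contribute no coverage.
The recent-invasion call is true iff the coverage-weighted **median** K is
below 5% (0.05), which handles multimodal landscapes gracefully. No CpG
adjustment is applied (plain K2P only).

## Horizontal-transfer inference

`ht_test` flags a species pair iff divergence time ≥ `min_time_ma` (100)
**and** `d_TE < alpha·d_host` (alpha = 0.5). These two thresholds are
package defaults — the underlying argument in the literature is from
magnitudes, not a stated rule — and are printed with every report. The
flag is monotone in d_TE and time by construction. Pairs missing a host
gene or with a saturated TE distance are reported with an undefined flag.
Dollo patchiness assumes a single gain at the MRCA of present species and
counts maximal absent clades within it; it equals loss-set enumeration on
small trees. On simulated 8-species datasets (one transfer at 5 Ma across
a ≥ 300 Ma split, vertical clade invasion alongside), flagged pairs
recover the truth with precision and recall 1.0 over replicates, and
vertical-only scenarios yield zero flags. Note that when an entire family
is younger than the hosts' splits, *every* deep pair is genuinely
incompatible with vertical descent; the demo scenario shows such extra
flags by design.

## Pipeline

`run_pipeline` mirrors the published retrieval workflow: protein scan →
representative segment around the best hit → nucleotide search → boundary
refinement → per-species consensus → **re-search with the consensus**
(a representative drawn from a single, possibly truncated, copy would
otherwise bias every boundary) → annotation and classification →
identity matrix and clusters → landscapes → HT report, logging every
threshold and writing FASTA/GFF3/BED/TSV plus a JSON summary,
byte-reproducible under a fixed seed. Problem sizes in the bundled demo
(4 species, 30–40 kb contigs, 10–12 copies per recipient) keep a full run
in tens of seconds while exercising every stage; the simulator scales to
larger genomes linearly.

## Known limitations

* The search engine has no E-value statistics; sensitivity is governed by
  exact k-mer seeding (k = 11 nt / 4 aa) and score thresholds, so homologs
  below ~40% amino-acid identity or with very fragmented ORFs can be
  missed.
* Boundary refinement assumes several independent copies; two or fewer
  copies pass through unrefined, and shared flanking homology inflates
  elements.
* Cluster labels come from distance clustering, not phylogeny; no
  bootstrap support is available.
* The HT rule is a deterministic threshold contrast, not a hypothesis
  test; alpha and the minimum time should be reported alongside any
  result.
* Simulator realism limits are listed above; in particular within-species
  copies descend from one active lineage, so copy-number dynamics
  (bursts from multiple source copies) are only approximated by the
  burst-time mixture.
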