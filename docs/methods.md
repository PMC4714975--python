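# Methods

## Scope and data model

`ighrep` analyzes multiplexed paired-end amplicon sequencing of the IgH
variable region. An amplicon spans the V segment through the V(D)J
junction and J into the first ~90 nt of the constant region; the reverse
read carries a 6-nt sample barcode at its 5' end. The pipeline has a
fixed stage order — demultiplex → quality-trim → merge → annotate →
artifact filters → metrics/figures — and every stage writes a count
ledger (in = out + removed per reason), so read attrition is auditable.

## Preprocessing

* **Demultiplexing** requires an exact barcode match at the start of the
  constant-side read. No 1-mismatch rescue is attempted: the
  cross-contamination model downstream treats misassignment as full
  barcode conversion at rate μ, and error-correcting demultiplexing
  would change μ.
* **Quality trimming** scans 2-base windows left to right and truncates
  the read at the start of the first window containing a quality below
  20. Reads shorter than `min_length` (default 100 nt; the protocol
  states no floor, this is the package's choice) are dropped with a
  logged count. Trimming is idempotent.
* **Merging** reverse-complements the reverse mate and accepts the
  longest suffix–prefix overlap of at least `min_overlap` (15 nt) that
  is completely mismatch- and gap-free; any mismatch in the overlap
  discards the pair (no consensus calling). Because acceptance requires
  a perfect overlap, exhaustive shift enumeration is behaviorally
  identical to an overlap alignment and is what is implemented; rejected
  pairs carry a reason code (NO_OVERLAP / MISMATCH / TOO_SHORT).

## Alignment

Segment assignment uses an affine-gap local aligner (Gotoh recurrences)
with match +2, mismatch −2, gap open −5, gap extend −1; a gap of length
k costs 5 + (k−1). The scheme is a conventional nucleotide choice; on
error-free data calls are insensitive to it, and the kernel is held to
an exhaustive dynamic-programming oracle in the test suite (score and
boundaries, 200 random pairs ≤ 30 nt). Ties between equally scoring
alignments are resolved exactly — the kernel propagates, per cell, the
lexicographically smallest (query start, ref start) over all optimal
paths — so calls do not depend on traceback order. A scores-only rolling
kernel ranks candidate segments first (it returns exactly the same
maximum score, ~6× faster); the full kernel then produces boundaries and
the edit string for the winner only. V is the best-scoring segment
overall, J the best hit downstream of the V alignment, the constant
segment (isotype) the best hit downstream of J; V or J below a score
floor makes the read UNMAPPED.

## CDR3 and junction conventions

CDR boundary positions live on the reference sidecar, not in code. For
the synthetic catalog the V's CDR3 mark points just **after** the
conserved Cys codon and the J's mark just **before** the conserved Trp
codon, so CDR3 peptides read the way the field prints them (e.g.
"ARGAY"). Boundaries are migrated onto reads through the alignment edit
strings; positions outside the aligned interval are extrapolated
diagonally, and a boundary projecting outside the read fails the
migration (logged, excluded). Translation uses the standard code in the
V reading frame; out-of-frame or stop-containing CDR3s are kept but
flagged unproductive with an empty peptide.

The decomposition of junction bases into template / P / N is not unique
(an N base equal to the next germline base is indistinguishable from
template), so one canonical convention is fixed and used identically for
simulation ground truth and annotation:

1. template first — germline V and J matches are extended maximally by
   exact matching; within the CDR3 portion of a segment the template
   must be exact and contiguous (a local alignment is not allowed to
   bridge a mismatch there to grab chance matches);
2. P additions are recognized only on untrimmed ends, as ≤2-nt
   reverse-complement mirrors of the adjacent segment terminus;
3. the D call is the catalog segment with the longest exact run in the
   remaining gap, requiring ≥5 nt (shorter runs are unidentifiable among
   D segments; the bases then count as a single N stretch);
4. the remainder is N: n2 at the V–DJ join, n1 at the D–J join.

This convention biases N counts low, which is the conservative choice;
because truth labels are defined under the same convention, simulation
recovery tests measure the pipeline's fidelity rather than the intrinsic
ambiguity of junction parsing.

## Mutation calling

Substitutions are called between the CDR2 start and the CDR3 start
against the best-aligned germline V — the stretch untouched by the
amplification primers and outside the ambiguous junction. Only sequences
with more than 4 copies enter mutation statistics (sequencing-error
suppression); lower-copy records are flagged not-evaluated rather than
zero. Each call is annotated with its germline 4-mer hotspot context:
DGYW (D = A/G/T, Y = C/T, W = A/T) is tested first, then WRCH (R = A/G,
H = T/C/A); a position belongs to a motif if any 4-mer window covering
it matches. Indels are not counted as mutation events.

## Artifact filters

Fixed order: related-read collapse → singleton removal →
cross-contamination filter; record counts are non-increasing at every
stage.

* **V relatedness**: two V genes are related iff a pairwise local
  alignment has >200 matched bases and <6 mismatches (both strict).
* **Collapse**: records with related (or identical) V calls and
  equal-length CDR3s within 1 mismatch are compared; a minor strictly
  below 5% of its dominant partner is removed (exactly 5% survives).
  Processing runs in descending count order, removed records cannot
  remove others, and removed counts are not merged into the major
  ("removed", not "merged", is implemented literally). The source rule
  states "less than 1 mismatch" for CDR3 relatedness, which read
  literally is 0 and would never collapse sequencing-error variants —
  contradicting the rule's purpose — so the default is ≤1 with 0
  available by configuration.
* **Singletons**: every CDR3 nucleotide sequence with total count 1 is
  dropped.
* **Cross-contamination**: for a CDR3 seen n times in a recipient sample
  and N times in its largest co-occurring sample (the most conservative
  single-source model), P(X ≥ n) with X ~ Poisson(N·μ), μ = 1/8000,
  decides retention at α = 0.001. The survival function sums from k = 0;
  a variant summing from k = 1 (which makes P(X≥1) ≡ 1) is available
  behind a flag for comparison. Values are clamped to [0, 1] against
  floating-point drift.

## Metrics

Implemented exactly as defined in the README: D50 (rank ties broken
lexicographically; C = 1 whenever the top clone alone reaches J/2),
unweighted peptide-level sharing (a nucleotide-level variant is provided
but non-default), normalized V_H usage and N-insertion profiles counting
each distinct sequence once, convergence entropy with recombinations
keyed by (V, D, J, CDR3-nt) and read-frequency weights Pᵢ (a
unique-sequence weighting is a switch; both are tested), mutation
percentages over unique eligible sequences, and isotype composition per
mutation stratum {0,1,2,3,4,≥5} with "class-switched" meaning neither
IgM nor IgD. Entropy-bin occupancies are reported both peptide-counted
(default) and read-weighted.

## Treemaps

Three nested levels (V → V–J → V–J–CDR3) are packed with the squarified
heuristic, largest first, then reflected in both axes so the largest
rectangle sits at the bottom right and the smallest at the top left.
Exactness is guaranteed for areas (leaf area / canvas area equals read
frequency to 1e-6 relative), not shapes. Colors are drawn from a seeded
generator: deterministic per seed, intentionally unmatched across maps.
Output is SVG with rounded corners; layouts dump to TSV for testing.

## Simulator

The generator emulates the study conditions the analysis assumes:

* **Reference**: V segments of 294 nt with CDR1/CDR2/CDR3 marks at
  78/150/285 and a Cys codon before the CDR3 mark; D segments 10–25 nt;
  J segments of 48 nt (15-nt CDR3 portion, Trp codon, FR4); one ~90-nt
  constant segment per isotype. The first V family always contains a
  pair differing at exactly 3 positions — related under the >200/<6
  rule — while independently drawn V pairs are not.
* **Rearrangement**: geometric trimming (mean ≈ 1.2 nt, capped at 5),
  optional ≤2-nt P additions on untrimmed ends, N additions with
  geometric length of configurable mean per junction
  (`n_insertion_rate`; 0 reproduces the Tdt-negative neonatal pattern,
  2 is the adult-like default). Junctions are rejection-sampled to keep
  the CDR3 in frame and stop-free before mutation; truth labels are the
  canonical decomposition above.
* **Clone sizes**: Zipf with exponent `abundance_law` (default 1.2)
  scaled to `total_reads`, every clonotype keeping at least one read —
  this reproduces the recurrent-clonotype structure that treemaps and
  D50 are sensitive to without asserting an unobserved law.
* **Mutation**: per-clonotype count ~ Binomial(L, shm_rate), positions
  drawn with weight `hotspot_bias` (default 4) inside DGYW/WRCH
  contexts and 1 elsewhere, so the total load stays `shm_rate` per base
  while concentrating in hotspots. Class switching to a non-IgM/IgD
  isotype occurs with `switch_prob`, optionally restricted to mutated
  clonotypes.
* **Sequencing**: the forward read covers the amplicon 5' end; the
  reverse read is stored as sequenced — barcode, then the
  reverse-complemented 3' end. Errors are injected per base at
  `seq_error_rate`; qualities follow a two-component model (clean bases
  ~Q37; error positions are drawn half ~Q15 — below the trimming
  threshold — and half ~Q25), so quality trimming removes roughly half
  of injected errors, as intended. Barcode bases can also take errors,
  producing realistic unassigned reads. FASTQ output is byte-identical
  for a fixed seed.

What the simulator does **not** model — PCR amplification bias, chimera
formation, UMI structure, light chains, allele-level V variants, indel
sequencing errors — bounds what passing tests show: they demonstrate the
pipeline's correctness under the stated generative model, not robustness
to every artifact of real libraries.

## Problem sizes and numerical choices

Test and acceptance runs use 40–500 clonotypes for behavioral checks,
a 2×400-clonotype / ~5,700-read error-free run for the lossless
round-trip check, and a 5,000-clonotype repertoire (Zipf exponent 1.05
scaled to 2×10⁵ reads so nearly all clonotypes clear the 5-copy mutation
floor) for parameter recovery: N-insertion bins within ±2 percentage
points of truth and the mutation rate per 10⁴ bp within 20% relative
error at `shm_rate` = 5×10⁻⁴. Percentage vectors are asserted to sum to
100 within 1e-9; Poisson tails are clamped to [0,1]; all randomness
flows from explicit seeds (numpy Generator), and FASTQ/SVG/TSV outputs
are reproducible byte-for-byte under a fixed seed.

## Known limitations

* The CNT/CNU accounting is implementation-relative below the mapping
  floor: the score floors (V ≥ 60, J ≥ 20) stand in for an unstated
  "clean read" criterion.
* Template-first parsing undercounts N at junction boundaries by
  construction; comparisons across pipelines with different conventions
  should use the same parser.
* Mutations falling inside the V's CDR3 tail shift the observed junction
  decomposition for that clonotype (~1% of clonotypes at
  shm_rate = 5×10⁻⁴); the recovery tolerances absorb this.
* D assignment ignores substitutions within the D segment; a heavily
  mutated D may be missed and counted as N.
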