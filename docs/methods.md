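# Methods

## Reference model

The synthetic reference emulates the AAV2 genome layout on its forward
strand:

```
[palindrome(left) 125 nt][D 20 nt][body ~4,410 nt][D' 20 nt][palindrome'(right) 125 nt]
```

The palindromic region is `A + internal + spacer + A'`, with the internal
region `B B' C C'` in the flip orientation and `C C' B B'` in flop (primes
are reverse complements). The literature fixes only the 125-nt palindromic
total and the 20-nt D length; the arm partition is a free parameter with
default 2·30 (A) + 2·16 (B) + 2·16 (C) + 1 spacer = 125. The spacer sits
between the internal region and A′ in both orientations, so the internal
region of flop is exactly the reverse complement of flip's while the full
palindromes differ by the 1-nt spacer placement — the orientation caller
therefore only ever consults the internal region. The reverse complement
of a flip palindrome reads as flop; the default genome carries a flip left
ITR and a flop right ITR so that both arrangements are present on both
reference strands, which keeps ITR-only reads alignable regardless of the
orientation of each array copy.

Arm, spacer, D and body sequences are drawn uniformly over {A,C,G,T}
(configurable GC), with homopolymers longer than 5 nt redrawn so exact
k-mer seeding stays well conditioned. Everything is deterministic per
seed. Coordinates are 0-based half-open internally; 1-based inclusive only
at the BLAST-tabular boundary. Enzyme cut offsets follow the
restriction-map convention that a cut at offset c yields monomer fragments
of c and L−c nt (HindIII analog at 1,882 by default). The *trs* is a
position marker only. A real AAV2 sequence can be supplied as FASTA but is
never fetched.

One deliberate exemption: the ITR probe is defined *on* the left ITR's
C/A region, so the no-feature-overlap validation applies only to cut sites
and body probes.

## Simulator

Molecules are assembled from reference components with exact truth labels:

* category 1 (monomer): one full unit, both ITR orientations drawn
  independently;
* category 2 (duplex): a unit plus its reverse complement, fold-back
  joined at one randomly chosen genome end;
* category 3 (HT repeats): same-strand units joined by TRT junctions
  (D′ + palindrome + D, 165 nt by default); one orientation is drawn per
  molecule and shared by every palindrome, the RCR expectation;
* category 4 (alternating): strand-alternating full units concatenated so
  junction ends alternate between the two genome ends; every ITR
  orientation independent (fair coin), the RHR-without-resolution
  expectation;
* category 5 (mixed): units partitioned into same-strand runs (at least
  two runs, at least one of length ≥ 2), TRT junctions inside runs,
  fold-backs between runs;
* category 6 (ITR repeats): tandem `palindrome + D` copies with
  independent orientations and no body sequence;
* category 7 (others): snap-back genomes (a prefix of a unit fused to its
  own reverse complement, fold mid-body) or sub-genomic body fragments.

Orientation truth is recorded as observed on the molecule's forward strand
(embedding a flip palindrome in reverse complement flips the label), which
is exactly what a caller sees.

Circular substrates: HT circles are `(body + TRT) × m`; alternating
circles require an even unit count so the circle closes consistently. RCA
products are tandem traversals of the circle from a random rotation.
Because full digestion would reduce every product to monomer-length
pieces, the in-silico enzyme treatment cuts at the outermost two cut-site
occurrences only (partial-digest emulation), yielding multi-unit reads
that start and end at the cut site — the configuration the dot-plot shape
calls are defined on.

Reads are whole molecules by default (long reads span these intermediates)
with independent per-base substitutions and geometric-length indels
(extension probability 0.3); qualities are a constant Q20 placeholder and
never consulted. Decoy reads are substrings of a random 16.5-kb
"mitochondrial" reference and support the per-10,000-decoy-read
normalization. Default panel sizes are 50 molecules per category.
Concatemer unit counts default to 2–4 (alternating and mixed: 3–5, so the
patterns are unambiguous — a 2-unit alternating molecule *is* a duplex).
ITR arrays default to 22–34 copies so that a default array (~3.2–4.9 kb)
clears the 3,000-nt hit-sum selection rule; shorter arrays can be built
explicitly but fall below the published selection threshold, as they would
in the original analysis.

What the simulator does not model: basecalling signal and
homopolymer-specific errors, library chimeras, adapter artifacts, and the
exclusion mechanism for circular/single-stranded DNA (only linear
double-stranded-representing molecules are emitted). Passing tests
therefore demonstrate correctness of the structural logic under idealized
and uniformly error-corrupted reads, not performance on real nanopore
data.

## Hit layer

Hits come either from 12-column BLAST tabular files (strict parse,
minus-strand rows normalized to forward subject intervals plus a strand
flag) or from the built-in aligner: exact k-mer seeding (k = 12) on both
reference strands, greedy colinear chaining with a 150-nt maximum seed gap
and 30-nt diagonal-drift tolerance, ungapped X-drop end extension with
blastn-like +2/−3 scoring, and edit-distance identity via edlib. Hits
shorter than 100 nt are discarded; same-strand, same-diagonal overlaps are
merged and read-contained hits dropped (longest kept, ties by score, then
leftmost).

The surrogate e-value is monotone decreasing in a bit-like score given the
search-space size. It is calibrated only to keep/discard hits consistently
around the 0.1 threshold; no Karlin–Altschul statistics are claimed, and
blastn scores are not reproduced numerically.

Selection rule: hits with e-value strictly greater than 0.1 are removed;
reads are selected when the summed aligned length of the remaining hits
strictly exceeds 3,000 nt (hit count is available as an alternative
metric; for mini-genomes the threshold scales as 0.64 × reference length).
The rule is idempotent.

## Structure classifier

Segments are the cleaned, read-ordered hits — the machine-readable dot
plot. Same-strand neighbours continuing on the same dot-plot diagonal
(within 80 nt) are fused; this repairs noise-split units while keeping
tandem-repeat staircases apart, whose segments share endpoints but jump
diagonals.

Features and thresholds (all explicit parameters; the original dot plots
were read by eye, so these defaults define the automated reading):

* full unit: subject span ≥ 0.9 of the genome; partial unit: ≥ 0.25
  (counts toward patterns, never toward the full-unit count);
* ITR-only segment: subject interval inside an annotated ITR+D interval
  ± 30 nt;
* junction typing between consecutive unit segments: HT when the subject
  wraps end→start (within 400 nt of the ends — the ITR+D plus margin);
  fold-back when the strand flips and both segments meet at the same end;
  internal fold when the strand flips mid-genome;
* minimum segment length 100 nt.

Decision precedence: ITR-only arrays (≥ 2 segments, all ITR-only) → 6;
single full unit → 1; ≥ 3 full units with both junction types → 5;
≥ 2 full units, uniform strand, all-HT junctions → 3; ≥ 3 full units,
alternating strands, all fold-backs → 4; exactly two full units with one
fold-back → 2; everything else → 7. Category 4 requires three units
because the two-unit case is definitionally a duplex; ITR-only boundary
fragments (produced by the palindrome arrangement changing mid-junction)
are bookkept but never break a unit pattern.

RCA shape calls use the unit-scale segments only: one strand → "parallel",
strict strand alternation with fold-type junctions → "V", anything else
"unresolved".

Ratio tables cover categories 1–7 (zero-filled), sum to 1 within 1e-9,
and the circular-DNA quantification normalizes counts per 10,000 decoy
reads.

## ITR analysis

Occurrences are found by iterative best-match masking: the better of the
flip/flop palindromes is located as an infix (edit distance ≤ 22% of the
palindrome length), masked, and the search repeated. Orientation is then
called per occurrence on the internal region only, flip versus flop by
edit distance with a 4-edit margin (smaller margins are ambiguous;
candidates shorter than 60 nt are ambiguous by definition). The published
multiple-sequence-alignment reading is replaced by these independent
pairwise calls — same decision output, simpler and directly testable.
Occurrences more than 20 nt longer than the palindrome are flagged
anomalous-internal-structure (the "extra CC′" phenomenon is reported, not
given its own category). TRT detection requires a D match (≥ 80%
identity, i.e. edit distance ≤ 4 over the 20-mer, forward or reverse
complement) on *both* flanks.

Uniformity per read: `uniform` (≥ 2 unambiguous calls, all equal),
`mixed`, `single`, or `uncallable`. Under independent fair-coin
orientations the expected mixed fraction for k ITRs is 1 − 2^(1−k), the
yardstick used for alternating reads.

## Digest predictor

A concatemer model is a list of (length, orientation, cut offsets, probe
interval) units plus a topology. Minus units mirror offsets
(cut at length − c) and probe intervals. Fragments are the gaps between
successive absolute cuts (wrapping for circles); sums are exact integer
arithmetic and equal the model length for every topology. A fragment is
probe-visible iff it overlaps a probe interval by ≥ 20 nt. Bands round
half-up to 0.1 kb; whole-kb values display as integers; an exact mode
disables rounding.

Head-to-head is modeled as two units in opposite orientation. A linear
dimer carries one junction — through the cut-distal ends (junction
fragment twice the distal arm) or the cut-proximal ends (twice the
proximal arm) — while a real head-to-head/alternating concatemer
alternates both junction types; the circular dimer is the minimal model
carrying both at once and yields exactly the two junction-fragment sizes.
Digest models use zero-length junctions by default: the 165-nt TRT
insertion exists at the sequence level in the simulator, but including it
in band arithmetic would shift the HT band by a visible 0.1–0.2 kb at
display rounding, contrary to the unit-period convention the predictions
are stated in. Gel migration, partial digestion, band intensity and
single-stranded species are out of scope.

## Problem sizes and determinism

The package's validation panels are 50 molecules per category (noise-free
and at 5% substitutions + 2% indels), 200-read mixtures for composition
recovery, 200-read panels for orientation statistics, 100 seeded toys for
the Smith–Waterman comparison, and 1,000 random models for digest
conservation — sizes at which every simulation completes in seconds to a
couple of minutes on one CPU while keeping binomial confidence bands
tight. All randomness flows from explicit seeds; identical configs
produce byte-identical FASTQ, tables and reports.

## Known limitations

* The built-in aligner is tuned for clean synthetic references; highly
  repetitive or low-complexity references would need the external-BLAST
  path.
* Orientation calls assume the ITR arm partition of the reference spec;
  real AAV2 arm lengths differ from the defaults (they are parameters,
  not assertions).
* The classifier's geometric junction typing assumes reads long enough to
  contain whole units; heavily fragmented reads mostly land in category 7.
* Real-data category ratios depend on infection conditions and library
  prep; the package reproduces the *logic* of the analysis, and its
  simulated ratio tables reflect the configured mixture, not biology.
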