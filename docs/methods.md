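# Methods

## Scope and model

`tc1scope` analyses a Tc1/mariner-type DNA transposon family and the small
RNAs derived from it. The biological model has two halves:

1. **The element.** Tc1/mariner elements are Class II ("cut and paste")
   transposons: a single transposase ORF flanked by terminal inverted repeats
   (IRs), with short direct repeats (DRs) embedded inside the IRs and a
   polyadenylation signal (PAS) upstream of the 3' IR. A recently expanded
   family leaves many near-identical genomic copies (here: >93% pairwise
   identity), most of them inactivated by frameshifts or premature stop
   codons.

2. **The small RNAs.** piRNAs silencing such an element show a characteristic
   signature: ~23–30 nt length with a modal length of 27–28 nt (some families
   24–25 nt), a strong antisense excess relative to the transposase strand,
   uridine enrichment at position 1 of antisense (primary) piRNAs, adenosine
   enrichment at position 10 of sense (secondary) piRNAs, and sense/antisense
   pairs whose 5' ends overlap by exactly 10 nt — the ping-pong amplification
   signature.

The pipeline: (i) generate seeded synthetic fixtures with that structure and
machine-readable truth; (ii) extract and characterize the element family from
a genome; (iii) preprocess and exactly map small-RNA reads; (iv) compute the
signature statistics.

## Synthetic-data generator

### Consensus element

Default architecture: 1,581 bp total, 199-bp IRs, 17-bp DRs, 1,020-nt ORF
(ATG + 338 non-stop codons + stop), PAS `AATAAA` flush against the right IR.
The ORF length is not dictated by the element total; 1,020 nt (~340 codons)
is a typical Tc1-family transposase and leaves realistic spacers inside the
1,581-bp envelope.

Construction details that matter for exact structure recovery:

- The right IR is the exact reverse complement of the left IR.
- A direct repeat must appear at the *same offset of each IR in identical
  orientation*. Since the right IR is the reverse complement of the left,
  this is only possible if the left IR carries both the DR (at offset *o*)
  and its reverse complement (at the mirrored offset). The builder plants
  both, which requires `ir_len >= 2*dr_len + 2` (validated). IR candidates
  are rejection-sampled (deterministically under the seed) until the longest
  same-orientation substring shared by the two IRs is exactly `dr_len`, so a
  chance single-base extension can never inflate the detected DR length.
- The first base inside each IR is forced to break the terminal palindrome,
  so the element's true IR length is exactly `ir_len` by construction (in the
  zero-spacer corner case there is no base to adjust and the guarantee lapses).

### Planted copies

Copies are planted at uniformly drawn non-overlapping loci, fully contained
in one chromosome, on a uniformly random strand, in an i.i.d. uniform A/C/G/T
background. Substitutions are i.i.d. per base at `sub_rate` (default 0.015,
chosen so two copies differ by ~3%, matching a >93%-identity family).
Copies designated intact receive only ORF-safe substitutions (start and stop
codons spared, no stop codon created); every other copy receives one 1-nt
deletion inside the ORF (frameshift) or one premature TAA (each with
probability 1/2), in addition to background substitutions. Truth records
per-copy locus, strand, substitution/indel counts, ORF intactness, and
identity `100*(L - subs - indels)/L`.

### Read library

Strands are drawn Bernoulli(antisense_fraction = 0.943); lengths come from a
categorical distribution over 20–32 nt (default peaked at 27–28 nt with 95%
of mass in 23–30; an alternative preset peaks at 24–25 nt). A fraction of
reads (default `pingpong_fraction = 0.1`, chosen once as a plausible
secondary-piRNA share; the statistics do not depend on it sharply) is
emitted as sense/antisense couples placed so their 5' ends overlap exactly
10 nt; couples are formed from the already-drawn strand pools, so the strand
marginal is exactly Bernoulli and `antisense_fraction = 1` implies no pairs.

Positional bias semantics: the base at position 1 of an antisense read is
drawn as U with probability `u1_prob` (default 0.8) and uniformly over the
other three bases otherwise; likewise A at position 10 of sense reads
(`a10_prob`). This makes the *marginal* frequency equal the parameter, so
parameter recovery is a clean binomial check. Setting the parameter to `None`
disables the bias, making every read an exact substring of the element (or
its reverse complement) — the mode used for exact re-location tests. With the
bias on, a biased read whose drawn base differs from the consensus base no
longer exact-matches; this mimics the real situation only loosely (real
piRNA 1U bias arises from 5'-end selection, not substitution) and is the
main respect in which the generator differs from real genome-matched
libraries. Downstream statistics are computed on the reads that do map,
which is what the real workflow does too.

Background reads are uniform fragments of non-TE "transcripts"; the pipeline
cuts these transcripts out of copy-free genome regions so background reads
exact-match the genome like genuine degradation products.

All randomness flows from one integer seed per operation through tagged
`numpy` `SeedSequence` substreams, so each operation is independently
reproducible and identical seeds give byte-identical outputs.

## Family characterization

- **In-silico PCR**: all occurrences of the primer (and of its reverse
  complement) with at most `max_mismatch` substitutions are located by a
  vectorized per-offset mismatch count; each forward site is paired with the
  nearest downstream reverse site within `max_amplicon`, sites being consumed
  left to right. Because the element is IR-bounded, its terminal 37-mer acts
  as both primers, and both planted strands are recovered. The default
  mismatch allowance is `floor(0.07 * primer_len)`; fixtures at
  `sub_rate = 0.015` are extracted with `max_mismatch = 4` (~3x the expected
  substitution count in a 37-mer, binomial argument), which makes full copy
  recovery robust to sampling noise.
- **Percent identity**: global alignment (match +2, mismatch −1, gap open −5,
  gap extend −1; Biopython `PairwiseAligner`), identity = matches /
  alignment columns, counting internal gap columns and excluding terminal
  overhangs. The pair is canonically ordered before alignment so the function
  is exactly symmetric.
- **Single-linkage clustering** at an identity threshold (default 93) is
  computed with scipy on `100 − identity` distances; it equals the connected
  components of the threshold graph (tested against a union-find oracle).
- **IR detection** is an anchored, ungapped changepoint: compare the 5'
  terminal window base-by-base with the reverse complement of the 3' terminal
  window and report `L* = argmax_L [matches(L) − q·L]` (q = min_identity/100,
  `L >= min_len`, identity at `L*` >= min_identity; largest `L` on ties).
  The naive alternative — longest window whose *overall* identity clears the
  threshold — systematically overshoots: appending ~20 random columns to a
  perfect 199-bp repeat still leaves overall identity above 95%. The
  changepoint form instead requires local match density at the boundary to
  exceed the threshold, and recovers the exact planted length whenever the
  terminal repeat is clean near its inner edge (a substitution within ~19 bp
  of the IR end can shift the boundary; interior substitutions only lower the
  reported identity).
- **DR detection** is an exhaustive seed-and-extend for maximal
  same-orientation substrings of length >= k shared by the two IR intervals,
  reported longest-first.
- **ORF classification** projects the consensus ORF interval onto each copy
  through the global alignment, then checks, in order: net indel length not
  divisible by 3 (frameshift), in-frame stop before the final codon
  (premature stop; Biopython translation), start codon not ATG (missing
  start). A copy that lost only its terminal stop codon is reported intact —
  the generator never produces this case, and flagging it would need a
  fourth reason code.
- Extracted copies are oriented to the consensus by shared 12-mer counts
  (alignment score only on ties); at family-level identity this is
  unambiguous and ~100x cheaper than aligning both orientations.

## Read processing and mapping

Preprocessing clips at the leftmost occurrence (at or after read position 2)
of an adapter prefix of at least 5 nt, then drops reads containing N and
reads shorter than 15 nt, tallying each reason; 20–32 nt selection is
inclusive on both bounds. Mapping is exact and full-length only: distinct
read sequences and their reverse complements are hashed, and windows of each
distinct read length are slid across each reference; minus-strand hits carry
forward-strand coordinates. This is deliberately oracle-testable (a naive
O(n·m) scan) rather than delegated to an aligner binary.

Element assignment: a read counts once for a family iff all its hits fall in
that single family; reads hitting a second family or any non-TE reference
are excluded and logged. The contribution strand is the majority hit strand;
ties — which arise naturally for reads lying inside an IR, since the other
IR offers an antiparallel exact match — are excluded and logged. RPM uses
10^6 × count / normalization_total, the denominator defaulting to the number
of selected reads exact-matching the genome.

## Signature statistics

Length spectra, positional base matrices (reported over reads covering each
position, T shown as U, information content `2 + Σ f log2 f` bits), and
per-strand coverage profiles in two modes (5'-end only: +1 at each read's 5'
position; all-positions: +1 along the read footprint). The ping-pong
spectrum counts, for every sense 5' position s and antisense 5' position a
on the same reference with `a >= s`, the overlap `a − s + 1` in 1..32,
weighted by the product of 5'-end multiplicities; it is computed from
position histograms (linear, not quadratic in reads) and verified against an
all-pairs brute force. Modal statistics break ties toward the smallest
value. Reference-set overlap is exact same-strand sequence membership, per
read instance by default (per distinct sequence optionally).

## Pipeline

One YAML config (unknown keys rejected; empty file = defaults) drives
simulate → famchar → map → signatures. Files are written atomically; the run
report reconciles counts at every filter and echoes the config and seed;
identical config + seed reproduces every output byte-for-byte. Default
fixture sizes (0.5-Mb genome, 30 copies, 2,000 TE + 500 background reads)
keep a full run to roughly ten seconds; the library functions accept the
full study-scale sizes (116 copies, 10,000 ping-pong pairs, 20,000 reads)
directly, as used by `scripts/acceptance.py`.

## Known limitations

- No sequencing-error or quality model (constant FASTQ qualities); adapter
  clipping is exact-prefix only.
- Copies are full-length and non-nested; no truncated or nested insertions.
- The 1U/10A bias is implemented as base substitution at emission, not 5'-end
  selection, so biased reads can fail exact re-mapping (see above).
- IR detection assumes the repeats are anchored at the sequence termini, as
  is the case for primer-bounded amplicons and the generated consensus.
- Mismatch-tolerant or gapped read mapping, piRNA cluster discovery, and
  multiple sequence alignment/consensus reconstruction are out of scope.
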