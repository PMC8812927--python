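# Methods

## Model and assumptions

`repolish` targets haploid bacterial assemblies whose residual errors
are small in scale — substitutions and short (mostly homopolymer)
indels — with no structural errors. The read evidence is short
(Illumina-scale) reads aligned in all-alignments-per-read mode, so a
read drawn from any copy of a repeat is present at *every* copy it
matches within the aligner's tolerance. Two consequences drive the
design:

1. **Evidence must not be diluted in repeats.** Piece counts are raw
   integers: an alignment contributes one full count at each position
   it covers regardless of how many other places its read aligns. In a
   two-copy exact repeat at 50× per-copy depth, an error position in
   one copy receives ~100 corrective votes (reads from both copies),
   which is exactly what makes the error fixable.
2. **Depth must not be inflated in repeats.** The thresholds scale with
   read depth, and summed raw counts would roughly double depth inside
   a two-copy repeat, raising the bar precisely where evidence is
   needed most. Depth is therefore fractional — a read segment with
   `k` alignments adds `1/k` per covered position — approximating the
   depth a best-hit alignment would give. Counts and depth are
   accumulated over the same post-trim position set, so they always
   describe the same evidence.

This count/depth asymmetry is deliberate and load-bearing; weighting
counts by `1/k` as well would re-create the starvation problem in a
different guise.

## Alignment trimming

An alignment that ends inside a homopolymer cannot witness the run's
full length: the read may simply have been cut mid-run. Each alignment
therefore has its terminal run of identical bases, plus one more base,
removed before contributing pieces (minimum two bases; capped at the
aligned length, so a single-letter alignment contributes nothing).
Trimming operates on the aligned sequence in reference-forward
orientation — the stored SAM sequence minus clipped bases. Dropping is
positional: the first covered position whose piece uses any trimmed
read base, and every later position (including trailing deletion
pieces), is removed.

The default trims the alignment end only (`trim_mode=end_only`). The
homopolymer-ambiguity argument applies symmetrically at the alignment
start, so `both_ends` is offered as a documented option; the default
was kept asymmetric to match the established behaviour of this
polishing approach.

## The change rule

With fractional depth `d` at a position:

* valid threshold `T_v = max(min_depth, fraction_valid · d)`
* invalid threshold `T_i = fraction_invalid · d`

Both comparisons are strict (`count > T_v`, `count < T_i`); a count
equal to a threshold falls in the dead zone and blocks a change. A
position is rewritten only when exactly one valid piece exists, it
differs from the assembly base, and all other observed pieces are
invalid. Positions with zero depth keep their base.

Defaults: `fraction_valid = 0.5`, `fraction_invalid = 0.2`,
`min_depth = 5`. The `min_depth` floor stops low-coverage positions
from being rewritten by a handful of reads; `fraction_invalid` caps the
tolerated dissent. These defaults make the polisher conservative by
construction: on every fixture in the test suite, polishing a correct
assembly with its own error-free reads changes nothing, and each
emitted change is re-checked against the thresholds.

One invocation is one round. Multiple rounds require re-aligning reads
against the polished output (the tool does not re-align internally);
on unambiguous evidence the first round already converges and the
second emits zero changes.

An optional `max_errors` filter can drop alignments whose `NM` tag
exceeds a bound. It is off by default — the threshold rule already
tolerates noisy alignments — and exists only as a guard for
pathological inputs.

## SAM handling

Coordinates are 0-based half-open internally; SAM's 1-based `POS` is
converted at the parse boundary (pysam). Secondary alignments are
first-class evidence — they are the entire point of all-per-read input —
and their `*` sequences are recovered from a same-read record,
reverse-complemented when strand flags differ. Supplementary (chimeric)
records are excluded by default: split alignments are rare for short
reads on bacterial assemblies and complicate piece extraction. Multiple
SAM inputs (e.g. R1 and R2 aligned separately) are concatenated before
grouping; mates are never pooled into one alignment count. Read groups
in which no record carries a sequence are dropped with a warning, never
fatally. `=`/`X` CIGAR ops are treated as `M`; `N` is rejected as
meaningless for short reads on bacterial genomes. An insertion before
the first reference-consuming operation has no anchor position and is
discarded.

## The fixture simulator

The simulator emulates the conditions under which repeat starvation
occurs, not a sequencing instrument:

* **Genomes** are i.i.d. uniform random DNA with exact repeat copies
  planted at recorded, non-overlapping positions. Real bacterial
  genomes have compositional bias and imperfect repeats; neither is
  needed to exercise the algorithm, and exact repeats are the hardest
  case for best-hit alignment.
* **Error injection** draws a Binomial(L, rate) number of events per
  class — substitutions, homopolymer insertions/deletions (which extend
  or contract an existing run of ≥ 2 identical bases), and
  non-homopolymer indels — and places them uniformly on the positions
  eligible for the class. The per-class rate defaults to 1e-4
  (0.01 %), the residual error level typical of a long-read assembly
  after long-read polishing, giving ~Q30 input identity.
* **Reads** are error-free, uniformly placed, constant-quality, 150 bp
  unpaired by default (paired and uniform-substitution-noise options
  exist for robustness tests). Error-free reads suffice because
  starvation is an alignment-placement phenomenon, not a read-error
  phenomenon. Defaults of 300× for repeat detection and 50× for
  polishing fixtures reflect deep-but-ordinary Illumina runs.
* **The exhaustive aligner** reports, per read and strand, every
  locally optimal location within `max_edits` (default small, ≤ 5).
  It seeds with `max_edits + 2` evenly spaced exact k-mers
  (pigeonhole: any read within the budget retains one exact seed),
  clusters candidate starts, and verifies each locus with an exact
  edit-distance alignment (edlib) over a padded window, so reported
  distances and CIGARs are exact. Overlapping hits collapse to their
  best, mimicking one-hit-per-locus behaviour of real aligners.
  `all` mode emits one primary (lowest distance, ties broken by a
  seeded RNG) plus `*`-sequence secondaries; `best_only` emits the
  primary alone — the two modes reproduce the `-a` vs. default
  behaviour of a real aligner. Tandem or near-adjacent repeat copies
  closer than half a read length collapse into one locus and are out of
  scope.

What passing tests on these fixtures show is that the algorithm's
mechanics are correct under its stated assumptions. They do not show
robustness to real base-quality profiles, coverage bias, adapter
contamination or structural disagreement between reads and assembly.

## Evaluation

Assessment uses a unit-cost global alignment (edlib `NW`): error count
= non-matching columns, identity = matches / alignment length,
`Q = -10·log10(1 - identity)` with identity 1.0 reported at a numeric
cap of Q90. Repeat regions are detected operationally: deep error-free
simulated reads (150 bp, 300× by default) are aligned in all-per-read
mode and every position covered by a multi-mapping read is flagged;
interval edges therefore taper within a read length of a repeat
boundary, where reads no longer fit wholly inside the repeat.

Confusion matrices project the unpolished and polished sequences onto
reference coordinates through two pairwise global alignments rather
than a three-way multiple alignment: each reference position receives
the assembly content aligned over it (insertion columns attach to their
left-anchoring reference position; a leading insertion folds into
position 0), and the position is classified TP/TN/FP/FN from the
correct/incorrect status before and after polishing. Pairwise
projection was chosen over an MSA for determinism and dependency
economy; where alignments are ambiguous (edits inside homopolymers,
adjacent edits) the column attribution — not the totals' meaning — can
differ between equally optimal alignments, which the tests account for
by using unambiguous fixtures when cross-checking against an
independent Needleman–Wunsch implementation.

## Numerical and determinism notes

* Depth uses double-precision floats; the conservation identity
  Σ depth = Σ retained-positions / k holds to 1e-9 (tested against an
  exact rational oracle).
* All randomness (ambiguity-base replacement, genome/read/error
  generation, alignment tie-breaks) flows through seeded NumPy
  generators; identical inputs and seeds give byte-identical outputs.
* Piece classes are ordered by descending count then lexically wherever
  order could matter.
* Degenerate inputs: empty SAM → zero changes with a warning;
  zero-depth positions keep the assembly base; an alignment trimmed to
  nothing contributes nothing.

## Problem sizes

Test fixtures range from hand-built 20 bp contigs to 100 kbp genomes at
50× (the zero-introduction run); the repeat-repair benchmark uses a
40 kbp genome with a 2 kbp repeat in two copies, and injector
calibration runs on 1 Mbp. These sizes exercise every code path at
bacterial-like local structure while keeping the full suite fast; the
algorithm itself is linear in genome size and read count, and
whole-contig arrays are comfortable at full bacterial scale (several
Mbp).

## Known limitations

* No base-quality weighting; all evidence counts equally.
* Haploid assumption: heterozygous sites would land in the dead zone
  and be left unchanged (safe, but not a diploid caller).
* BAM/CRAM are not read; convert to SAM text first.
* The internal aligner is for fixtures and repeat annotation at desk
  scale, not a general-purpose mapper; use a production aligner's
  report-all mode for real data.
* Change coordinates in the TSV are pre-polish coordinates; applying
  them independently requires offset bookkeeping for indels.
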