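# Methods

## Coordinates and orientation

All coordinates are 0-based half-open internally; reports render 1-based
inclusive `chr:start-end`.  Per-element analyses operate in *element
orientation*: for a minus-strand element the transcriptional 5′ LTR is
the genomically last interval and extracted sequences are
reverse-complemented, so "upstream" always means the 5′ side of the
element.  Overlapping same-family annotations are split at the midpoint
of the overlap with a logged warning (strict mode errors instead); the
split conserves the genomic union and is a deterministic, audit-visible
surrogate for manual curation, not a biological claim.

## Read mapping

The built-in mapper reports **every** genome placement of a read (both
strands) with at most `max_mismatch` substitutions (default 4, ~3% of a
142-nt read), truncated deterministically at `max_hits` placements
(default 1000) after sorting by (chromosome, start, strand).
Completeness is guaranteed by pigeonhole seeding: the read is cut into
`max_mismatch + 1` disjoint exact seeds of `floor(L/(m+1))` bases, so
any placement within the budget leaves at least one seed intact; every
candidate is then verified by full-length Hamming comparison.  The
mapper is substitution-only by design — it is oracle-verifiable against
a slide-and-count brute force, which the test suite does exhaustively.
Gapped alignments enter only via SAM/BAM ingestion (primary +
secondary records and XA tags pooled per read name).

Duplicate removal approximates `samtools rmdup`: reads sharing an
identical *canonical placement* (the lexicographically smallest
(chromosome, start, strand) among a read's placements) collapse to the
single representative with the highest mean base quality, ties broken
by read identifier.  Deduplication precedes all counting.

## Weighted coverage and family accounting

A deduplicated read with *n* placements adds 1/*n* at each base of
every placement.  Total track mass therefore equals the summed length
of mapped reads exactly — asserted as an identity in the tests, and a
useful run-time self-check.  A read "maps to" a family when any
placement overlaps any annotation of that family by ≥ 1 base (no
overlap fraction is imposed); the family Venn counts each Ty-mapping
read once in the cell for the exact family set it touches.  Expected
percentages come from extracting every 142-mer of every annotated Ty
feature, mapping them like reads with the same configuration, and
counting identically; `log2(observed% / expected%)` colours the Venn.
Coverage distributions are binned per feature set over log2-spaced bins
(`[0, 2^-6 … 2^6, ∞)` by default) after removing excluded positions
(telomeres/rDNA analogues supplied as a merged interval set).

An element is flagged an eccDNA **producer** when weighted coverage is
non-zero along ≥ 99.5% of its length *and* at least one deduplicated
read maps uniquely within it; an element meeting the coverage bar whose
sequence contains no genome-unique 142-mer (so unique mapping is
impossible) is **indeterminate**; anything else is **no_evidence**.

## Circle models and expected coverage

- one-LTR circle: genomic slice from the midpoint of the 5′ LTR to the
  midpoint of the 3′ LTR (midpoint = `floor(length/2)` from the LTR
  start, in element orientation), closed into a circle.  For identical
  LTRs the junction reconstitutes one intact LTR, so the circle carries
  the internal sequence plus exactly one LTR equivalent.
- two-LTR circle: the whole element joined end-to-start (the NHEJ
  product); its junction k-mers exist nowhere in the linear genome.
- inter-LTR circles: every ordered same-chromosome pair of LTR features
  (solo LTRs and the LTRs of full-length elements) whose facing-end gap
  lies in [10 bp, 30 kb], extracted midpoint-to-midpoint on the forward
  strand.  The endpoints and orientation convention are a package
  decision; the construction is symmetric with the same-element case.

Circle identity is rotation- and strand-invariant (canonical rotation
of the sequence or its reverse complement, computed with Booth's
algorithm).  Expected coverage extracts all L rotation k-mers of an
L-long circle (one per start, junction-spanning included), maps them
with the standard mapper, weights 1/n and averages across elements in
50-bp windows tiled from the element start, with ten 50-bp flank
windows per side; the last partial window is averaged over its actual
width, and elements of unequal length are averaged window-wise.

Two boundary effects of mismatch-tolerant mapping are worth knowing.
With the default budget, a k-mer whose placement overhangs the element
boundary by up to `max_mismatch` bases can still be placed on the other
LTR copy, leaving a ≤ ~7-bp coverage halo just outside the element;
and even under exact matching a 1–2-base overhang can coincide with
the adjacent background sequence by chance (probability 4^-j for j
overhang bases).  Flank coverage beyond one read length from the
element is always exactly zero.  Geometry checks therefore either use
exact matching or exclude the boundary-adjacent window.

Autointegration circles (inverted segment; truncated circle) are
provided by the synthetic generator for detector validation; they are
not expected-coverage models, since only the three recombination/NHEJ
topologies have distinctive coverage signatures.

## Split-read mosaic detection

Reads ≥ 100 nt are split into their first and last 50 nt; parts are
mapped (substitution budget 2 per 50-mer) onto the extracted
full-length element sequences of one family, not the whole genome.  A
head/tail placement pair is *consistent* when it lies on one element,
one strand, with the tail downstream of the head (mirrored on the
reverse strand) and an inter-part gap in
`[0, read_len − 2·part_len + gap_tolerance]` (tolerance 10 bp;
disable to reproduce the looser order/orientation-only rule).  A read
is mosaic when no pairing is consistent, both parts map, and — by
default — at least one part lies in an LTR.  Classification examines
every same-element pairing and unions the results: an order reversal
across the element end↔start junction is compatible with the 2-LTR
circle ligation (scenario I); flipped orientation with both parts in
LTR sequence points to LTR-targeted autointegration (III), with a part
in internal sequence to internal autointegration (IV).  "Which part is
flipped" is not well defined under read-strand symmetry, so the
region-based rule is used; it is deterministic and strand-symmetric.
Elements of one family placed by the generator are mutually
non-homologous, so cross-element pairings are reported but carry no
scenario.

## Chimeric-LTR breakpoint inference

The 5′ and 3′ LTR of each element are globally aligned
(match +1, mismatch −1, gap open −2, gap extend −1; first optimal
alignment, deterministic).  *Informative columns* are the alignment
columns where the LTRs differ, gaps included; stripping gaps from
either row reconstructs the original LTR exactly.  Chimeras take the
downstream (3′) LTR up to a switch point and the upstream (5′) LTR
after it; switch points between the same two consecutive informative
columns give identical sequences, so the library holds one entry per
informative-column interval (gapless alignments: exactly
n_informative − 1 entries), with parent-equal candidates removed.  A
breakpoint is only ever identifiable as such an interval — strand
heterogeneity makes point assignments meaningless.

A read **supports** an entry when (i) it maps end-to-end to the
chimera within `max_mismatch`, restricted to its minimal-mismatch
(best-hit) chimera placements, (ii) it has no end-to-end genome
placement at the relaxed tolerance `max_mismatch + 2` (inclusive) —
the deterministic stand-in for the original BLAST cross-search against
genomic solo-LTR copies, erring toward exclusion — and (iii) its
matched residues include at least one informative column on each side
of the switch interval.  Calls aggregate support per (element,
interval) and are ranked by support.  An optional quality filter drops
supporting reads with any informative-column base below Q20.  The
U3–R–U5 region model (configuration input; borders as alignment
columns) flags calls whose entire interval lies strictly upstream of
the U3/R border — only those exclude the transpositional origin whose
apparent breakpoint sits at the transcription start site.

**Recoverability.**  The genome-exclusion rule has a hard geometric
consequence: a surviving junction read must differ from *both* parent
LTRs by more than `max_mismatch + 2` bases, i.e. carry ≥ 7 informative
columns on each side of the switch within a single 142-nt read (at the
defaults).  Breakpoints are therefore recoverable only between
sufficiently divergent LTR pairs (roughly ≥ 10% local divergence), and
only when the switch lies ≥ ~7 informative columns away from either
LTR end; at the 2% divergence typical of young Ty1 elements no read
can satisfy the rule and no calls are produced — the method is
conservative by construction, not exhaustive.  The discrimination
tests therefore state a highly divergent world (one substitution every
8 columns) with deep circle coverage (60×, reflecting the strong
amplification of circular templates), where scenario II circles are
called at the U3/R border and scenario V circles at their implanted
switch interval, with zero calls on circle-free controls.

## Synthetic data generator

The generator emulates: a clonal genome of i.i.d. uniform background
sequence with implanted full-length elements (5′ LTR + internal + 3′
LTR, the 3′ LTR a mutated copy of the 5′ at a per-column substitution
rate, default 2%, plus 1-bp indels at 0.1%), solo LTRs (5% divergent
copies), circles for scenarios I–VII, and uniform-start reads (default
142 nt) with Bernoulli substitution errors (default 0.2%) and
two-level quality strings (errored bases low-quality with probability
0.5 — just enough structure to exercise the quality filter).  Reads
from circles start at any rotation, so junction-spanning reads occur;
read count per source is `round(depth · length / read_length)`.
Element geometry defaults (330-bp LTRs, 5300-bp internal) approximate
Ty1; they are configuration, not constants.  Defaults not fixed by the
analysis itself (one 30-kb chromosome, two elements, two solo LTRs,
all plus-strand, elements mutually non-homologous) keep the smallest
world in which every pipeline stage has signal.

Not emulated: phi29 rolling-circle amplification bias and chimeric
amplification artifacts, GC/repeat structure of real genomes, homology
between elements of one family, paired-end reads, indel sequencing
errors.  A green synthetic test therefore establishes algorithmic
correctness on the stated world — complete multi-mapping, exact
weighting, junction detection, breakpoint localization — not
robustness to amplification bias or to the full repeat structure of a
real genome.

Everything is deterministic given the seed: identical FASTA/FASTQ bytes
across runs, and every read carries a truth record (source, start,
strand, injected errors) written as TSV alongside element and circle
truth tables.

## Numerical and degenerate-input conventions

- Placement sorting, hit-cap truncation, duplicate tie-breaks, chimera
  deduplication and call ranking are all deterministic; reruns produce
  byte-identical outputs.
- Track mass identity is asserted at 1e-6 relative tolerance (pure
  float summation); window uniformity checks use exact equality where
  the arithmetic is exact.
- Features shorter than the k-mer are skipped with a warning; circles
  shorter than the k-mer yield no k-mers (warning); elements shorter
  than one window are skipped in profiling; an empty model list or an
  element set without usable full-length members is an error.
- The locus-coverage threshold comparison is `covered_fraction >=
  0.995` on the exact count/length ratio, so 99.5% coverage passes and
  99.4% does not.

## Known limitations

- The built-in mapper does not align gaps; reads spanning indels must
  come through SAM ingestion.
- Breakpoint inference is blind below ~10% LTR divergence and near LTR
  ends (see Recoverability above) — a property of the genome-exclusion
  rule itself, shared by any pipeline that discards genome-mappable
  reads.
- Mosaic classification reports compatibility sets, not proofs; a
  cross-element pairing is surfaced for manual review only.
- The 1000-hit cap biases truncated placement sets toward
  low-coordinate chromosomes (deterministically); raise `max_hits` for
  genomes with extreme tandem repetition.
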