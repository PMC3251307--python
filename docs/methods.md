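# Methods

## The model

genomap treats a genome as an ordered list of chromosomes (or
scaffolds/supercontigs) with known lengths, plus any number of feature
tracks. A track is a typed multiset of records, each anchored to a
chromosome by a 1-based, both-ends-inclusive nucleotide span. The five
track types differ only in payload: a single display colour (`posn`),
a colour plus an E-value retention cut-off with per-record (query id,
E-value) pairs (`blast`), a per-record colour (`expr`), a per-record
numeric value binned through a colour gradient (`freq`), or a
per-record numeric y value drawn as a histogram (`graph`).

Everything is plain UTF-8 text (LF or CRLF). `#`-lines are directives
or comments, blank lines are ignored, fields are TAB-separated. This
makes every input and output diffable, versionable and scriptable.

### Coordinate conventions

All public coordinates are 1-based and inclusive, so a span's length is
`last − first + 1`. The converters are the only place other systems are
translated: BED's 0-based half-open `(start, end)` becomes
`(start+1, end)`; GFF3 and tabular BLAST pass through unchanged apart
from min/max normalisation of reversed (minus-strand) subject spans.

### Tolerant-reader policy

Track files are community-edited, so the parsers repair what can be
repaired and warn rather than die: reversed coordinates are swapped,
unsorted blast E-value pairs are re-sorted, unknown colour names fall
back to mid-grey (`clGray`) at render time, and features overhanging a
chromosome end are kept and clipped only when drawn. Structural defects
(missing headers, short lines, non-numeric fields) are hard errors that
carry the 1-based line number.

Two capacity limits are enforced exactly: at most 1000
chromosomes/scaffolds per genome and at most 20 colours per freq
gradient.

### Gradient binning

For a gradient of k colours with k−1 strictly increasing boundaries,
value `v` gets colour index `= |{b : b ≤ v}|` — half-open bins
`[b_{i-1}, b_i)` with the first bin open below and the last open above.
Whether a boundary belongs to the lower or upper bin is not dictated by
the file format itself; assigning it to the upper bin was chosen so the
mapping is monotone, total and representable with one `bisect`. The
property suite checks monotonicity and agreement with a linear-scan
oracle.

### Blast retention

A blast record is displayed iff its *first* (smallest) E-value is ≤ the
track cut-off. Pairs are required ascending precisely so a single
comparison decides retention; files violating the ordering are
re-sorted with a warning instead of rejected. Records above the cut-off
are dropped at parse time with a count logged — converters still write
them, so tightening a cut-off never requires regenerating the file.

### Genome statistics

`compute_stats` reports, per chromosome, the gene count and
`bp_per_gene = chromosome length / gene count` — the average amount of
chromosome accounted for by each gene, reported as `NA` for gene-free
chromosomes. This genome-density reading (rather than mean gene length)
was chosen because it is the quantity that distinguishes gene-dense
core chromosomes from gene-poor dispensable ones; mean gene length is
emitted alongside as a clearly labelled extra column.

## Queries

Region selection uses any-overlap on closed intervals
(`start ≤ sel.last ∧ end ≥ sel.first`): partially visible features
count, as they do on a drawn map. The implementation indexes each
track with an interval tree; an O(n) brute-force scan is kept in the
test suite as the independent oracle. Gene-id search is exact and
case-sensitive by default (an `ignore_case` flag exists because
real-world gene ids are case-stable but user memory is not); duplicate
ids resolve to the first feature in (chromosome order, start) with a
warning. Found sets persist as `Temp/<name>.posn` tracks so a search is
itself redisplayable.

Sequence extraction slices `_data/<id>.fasta` (random access via
pyfaidx) with the same inclusive convention and writes
`_seqs/<id>_<first>-<last>.fasta`, wrapped at 60 columns.

## Rendering

The interactive zoom of a GUI browser is replaced by an explicit
`Viewport(first_nt, last_nt, width_px, …)` applied globally to every
chromosome; "zoom fully out" is `(1, longest chromosome)`. The pixel
mapping is `x = ⌊(nt − first) / span × width⌋`; a feature block runs
from the pixel of its first nt to the pixel of `last_nt + 1`, with a
minimum width of 1 px, widened rightward to 3 px (then clamped to the
canvas) when `exaggerate` is on. This makes abutting freq windows tile
exactly and keeps bar-length ratios within 2/width of the true
length ratios.

Graph rows map the value range `[min(0, min y), max(0, max y)]`
linearly onto the row height, so a non-negative track puts its maximum
at full height with zero on the baseline, negative values hang below a
shifted baseline with sign preserved, and an all-zero track draws a
flat baseline (no division by zero). No axis or scaling rule is implied
by the file format; this max-normalised affine rule is this package's
definition.

Rendering produces an ordered list of primitives (rects, lines, text)
that serialises to SVG by direct string assembly — a pure function of
its inputs, hence byte-identical across runs — and rasterises to PNG
through Pillow (pixel-identical on one platform). Chromosome labels are
emitted as monospace `<text>` elements with fixed metrics used for
layout; glyph outlines are not embedded, so byte stability never
depends on font discovery. Strand does not alter block placement
(strand is reported in the Gene List instead); layout knobs live in a
`Style` dataclass loadable from a `key=value` file.

## The synthetic generator

`fixtures.make_project` emulates the study conditions this package is
exercised under: a small fungal-style genome of 4 chromosomes of
200–600 kb, 120 genes of ~1.5 kb placed non-overlapping (one gene per
equal-width slot, which keeps interval oracles trivial), uniform-ACGT
chromosome FASTA, a 1e-10 blast cut-off with planted E-values exactly
straddling it (alternating below/above), 400 planted SNP positions
binned at the default 50,000 nt window, and per-window freq values
drawn uniformly over the six-colour gradient's range. One integer seed
drives a single `random.Random` stream (sequences use a numpy
generator seeded from it); the same spec yields a byte-identical tree.

What it deliberately does **not** emulate: realistic base composition,
repeats or N-runs, overlapping/nested gene models, chromosome-scale
length heterogeneity, or correlated feature placement. Passing tests
therefore demonstrate the correctness of parsing, bookkeeping,
queries, arithmetic and rendering — not robustness to biological
messiness beyond the tolerant-reader repairs listed above.

`make_worked_example` is a fixed (seedless) miniature: four
chromosomes, ten 1.2 kb cluster genes at 2 kb spacing in the middle of
chromosome 2 in their own blue posn track, plus background genes kept
clear of the cluster window, so a region selection recovers exactly ten
Gene-List rows.

## Problem sizes and tolerances

The property suites run 1,000 fuzzed tracks per kind (≤ 8–12 records
each) for round-trip identity, 1,000 random selections against the
brute-force overlap oracle, and 1,000 values against the gradient
linear-scan oracle; the whole default test run completes in a few
seconds on one CPU. Render proportionality is asserted within the
discretisation bound 2/width_px per bar-ratio. Numeric serialisation
uses `repr`-based shortest round-trip text, so floats survive
write→parse exactly; integers print without a decimal point.

## Known limitations

* Whole files are read into memory; multi-GB streaming tracks are out
  of scope.
* PNG output is only guaranteed stable within one platform/Pillow
  build; SVG is the canonical byte-stable artifact.
* The freq/graph grammars require the numeric payload in the last
  field; records with fewer than four fields are rejected rather than
  guessed.
* Colour hex values are read in R,G,B order as documented for the
  `colors` table; files exported from toolkits that store reversed
  byte order must be converted.
* No interactive viewing: tooltips, scrolling and undo stacks are
  intentionally replaced by explicit viewport parameters.
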