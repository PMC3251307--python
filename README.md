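# genomap

A scriptable whole-genome map engine for small and medium genomes
(fungi, oomycetes, nematodes, insects — anything from a handful of
chromosomes up to a thousand scaffolds). It models a genome as a set of
chromosomes plus arbitrary feature *tracks* stored as plain tab-delimited
text, answers region and gene queries, extracts sequences, and renders
deterministic, publication-quality whole-genome and zoomed maps to SVG
or PNG.

The design goal is the one most genome browsers miss: every analysis
starts from a single view of the **entire** genome, with any mixture of
data types — gene models, BLAST hits, expression calls, recombination
frequencies, SNP densities — overlaid on the chromosomes and retrievable
as spreadsheet-ready tables at any scale.

## The data model

A project is a directory tree. Three underscore folders are
housekeeping; every other folder becomes a menu of tracks:

```
project/
  _data/            chromosomes, genes, colors, credits, <id>.fasta
  _seqs/            extracted region sequences (output)
  _stats/           per-chromosome gene summaries (regenerated on scan)
  Genes/genes.posn  ...any folders of track files -> the menu tree
```

* `chromosomes` — one `id = length` line per chromosome (order is
  preserved; numbering may follow the genetic map, not size). At most
  1000 chromosomes/scaffolds.
* `genes` — TAB fields: chromosome id, first nt, last nt, strand, gene
  id, then free annotation fields. Coordinates are 1-based inclusive
  everywhere in the package.
* `colors` — `clName = $RRGGBB` entries overlaying the 16 built-in
  Windows colour names.

Five track grammars, chosen by file extension:

| kind    | payload | display |
|---------|---------|---------|
| `.posn` | colour in the first `#`-line | coloured blocks |
| `.blast`| colour + E-value cut-off; per-row (query, E) pairs ascending | blocks for hits with first E ≤ cutoff |
| `.expr` | colour in the **last field of each row** | per-row coloured blocks |
| `.freq` | gradient header: up to 20 colours interleaved with ascending boundaries | value-binned colour blocks |
| `.graph`| numeric y in the last field | histogram along the chromosome |

A freq value `v` falls in bin *i* = number of boundaries ≤ `v`
(half-open bins, first and last unbounded), e.g. with the header
`# clBeige 1 clKhaki 2 clGold 3 clGoldenRod 4 clTomato 8 clCrimson`
a recombination rate of 0.5 renders beige, 1.0 khaki and 9.0 crimson.

## Worked example

```python
from genomap import fixtures, genome, query

example = fixtures.make_worked_example("demo")          # 4 chromosomes,
catalogue = genome.scan_project(example.root)           # 10-gene cluster
track = genome.load_track(catalogue, ("cluster_genes", "cluster_genes"))
rows = query.features_in_region([track], example.cluster_selection)
print(query.gene_list_tsv(rows))
```

prints the Gene List of the selected region (first rows shown):

```
chrom_id  gene_length  first_nt  last_nt  strand  gene_id  annotation                   source_track
2         1200         120000    121199   +       CLU01    cluster gene 1 (synthetic)   cluster_genes
2         1200         122000    123199   -       CLU02    cluster gene 2 (synthetic)   cluster_genes
...                                                        (10 rows in total)
```

Ten rows — exactly the ten planted cluster genes — with `gene_length =
last_nt − first_nt + 1`. The `examples/` directory has one short script
per capability: project scanning and stats, region queries, rendering,
sequence extraction, and format converters; each prints what it
computes and what the numbers mean. The command-line entry point
`genomap` exposes the same operations (`genomap scan|stats|render|
search|region|extract|convert|fixtures`).

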