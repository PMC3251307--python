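"""Generate a synthetic project, scan it and print the genome summary.

A project is a plain directory: `_data` holds the chromosomes/genes
tables, every other folder becomes a menu of displayable tracks.
"""

import tempfile
from pathlib import Path

from genomap import fixtures, genome

tmp = Path(tempfile.mkdtemp())
truth = fixtures.make_project(fixtures.SyntheticSpec(seed=7), tmp / "demo")

catalogue = genome.scan_project(truth.root)
print("menu tracks found by the scan:")
for node_path, file_path in catalogue.iter_leaves():
    print(f"  {'/'.join(node_path):28s} ({file_path.suffix.lstrip('.')})")

g = genome.load_project_genome(catalogue)
stats = genome.compute_stats(g, truth.root)
print("\nper-chromosome summary (also written to _stats/stats):")
print("chrom  length_bp  genes  bp_per_gene")
for row in stats.rows:
    print(f"{row.chrom_id:>5s}  {row.length:>9d}  {row.gene_count:>5d}  "
          f"{row.bp_per_gene:>11.1f}")
print("\nbp_per_gene = chromosome length / gene count: how much chromosome")
print("each gene accounts for on average (smaller = denser gene spacing).")
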