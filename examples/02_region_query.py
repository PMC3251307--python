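"""Select a region and print its Gene List, exactly ten planted genes.

The worked-example project plants a ten-gene cluster in the middle of
chromosome 2; selecting a window over the cluster reproduces the
classic Gene List report (TAB-separated, pasteable into a spreadsheet).
"""

import tempfile
from pathlib import Path

from genomap import fixtures, genome, query

tmp = Path(tempfile.mkdtemp())
example = fixtures.make_worked_example(tmp / "demo")

catalogue = genome.scan_project(example.root)
track = genome.load_track(catalogue, example.menu_path)

sel = example.cluster_selection
print(f"selection: chromosome {sel.chrom_id}, "
      f"{sel.first_nt:,}-{sel.last_nt:,} nt\n")
rows = query.features_in_region([track], sel)
print(query.gene_list_tsv(rows))
print(f"{len(rows)} features overlap the selection; gene_length is the")
print("inclusive span last_nt - first_nt + 1 in nucleotides.")
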