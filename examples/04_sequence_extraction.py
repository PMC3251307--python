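"""Extract the sequence under a selection into the _seqs folder.

The slice convention is 1-based and inclusive at both ends, so the
extracted length is always last_nt - first_nt + 1.
"""

import tempfile
from pathlib import Path

from genomap import fixtures, genome, query

tmp = Path(tempfile.mkdtemp())
example = fixtures.make_worked_example(tmp / "demo")
catalogue = genome.scan_project(example.root)

sel = query.RegionSelection("2", 120_000, 120_059)
(path,) = query.extract_region_sequences(catalogue, [sel])
print(f"wrote {path.name}:")
print(path.read_text())
print(f"sequence length = {sel.last_nt} - {sel.first_nt} + 1 "
      f"= {sel.last_nt - sel.first_nt + 1} nt")
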