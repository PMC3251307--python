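"""Build track files from BED, a SNP position list and FASTA %GC.

Converters are where coordinate systems are translated (BED is 0-based
half-open); every emitted file re-parses through the track grammars.
"""

import random
import tempfile
from pathlib import Path

from genomap import convert, formats

tmp = Path(tempfile.mkdtemp())
rng = random.Random(3)

# BED -> posn: half-open 0-based becomes 1-based inclusive
bed = tmp / "peaks.bed"
bed.write_text("1\t0\t100\tpeakA\n1\t250\t400\tpeakB\t0\t-\n")
track = convert.bed_to_posn(bed, tmp / "peaks.posn")
for r in track.records:
    print(f"posn  {r.chrom_id}:{r.first_nt}-{r.last_nt} {r.strand} "
          f"{r.feature_id}")

# SNP positions -> windowed-count graph (default window 50,000 nt)
chroms = formats.ChromosomeSet((("1", 200_000),))
positions = [("1", rng.randint(1, 200_000)) for _ in range(120)]
graph = convert.positions_to_graph(positions, chroms,
                                   out_path=tmp / "snp.graph")
print("\nSNPs per 50,000 nt window:",
      [int(r.value) for r in graph.records],
      f"(total {int(sum(r.value for r in graph.records))} = planted 120)")

# FASTA -> %GC freq track binned into a colour gradient
fasta = tmp / "chr.fasta"
fasta.write_text(">1\n" + "".join(rng.choice("ACGT") for _ in range(4000))
                 + "\n")
gradient = formats.parse_gradient_header("clBeige\t40\tclGold\t60\tclCrimson")
gc = convert.fasta_to_gc_freq(fasta, 1000, gradient, tmp / "gc.freq")
for r in gc.records:
    colour = formats.assign_gradient_colour(r.value, gradient)
    print(f"freq  {r.chrom_id}:{r.first_nt}-{r.last_nt}  "
          f"GC={r.value:.1f}%  -> {colour}")
print("\nvalues below 40 bin to clBeige, 40-60 to clGold, 60+ to clCrimson.")
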