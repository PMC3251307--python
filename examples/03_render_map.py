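"""Render the whole genome, then zoom into the planted cluster.

Chromosome bars are grey with pixel lengths proportional to base-pair
lengths; the blue blocks are the cluster track.  Rendering is a pure
function of its inputs, so the SVG bytes are identical on every run.
"""

import tempfile
from pathlib import Path

from genomap import fixtures, genome, render

tmp = Path(tempfile.mkdtemp())
example = fixtures.make_worked_example(tmp / "demo")
catalogue = genome.scan_project(example.root)
g = genome.load_project_genome(catalogue)
track = genome.load_track(catalogue, example.menu_path)
colours = genome.load_project_colours(catalogue)

# whole genome: window 1..longest chromosome, features exaggerated to
# at least 3 px so the 1.2 kb genes stay visible at this scale
vp = render.full_genome_viewport(g, width_px=1200, exaggerate=True)
image = render.render_map(g, [track], vp, colours=colours)
whole = render.save_map(image, tmp / "whole_genome.svg")
print(f"whole-genome map:  {whole}  ({image.width}x{image.height} px)")

# zoomed: the cluster region full width
sel = example.cluster_selection
vp_zoom = render.Viewport(first_nt=sel.first_nt, last_nt=sel.last_nt,
                          width_px=1200)
zoom = render.render_map(g, [track], vp_zoom, colours=colours)
zoom_path = render.save_map(zoom, tmp / "cluster_zoom.png", format="png")
print(f"zoomed cluster:    {zoom_path}")

again = render.render_map(g, [track], vp, colours=colours)
print(f"repeat render byte-identical: {again.to_svg() == image.to_svg()}")
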