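"""Deterministic static rendering of whole-genome and zoomed maps.

Chromosomes are drawn as grey horizontal bars with pixel lengths
proportional to their base-pair lengths; each displayed track adds one
sub-row of coloured blocks (posn/blast/expr), gradient-binned regions
(freq) or histogram bars (graph) under every chromosome.  The
interactive zoom of the original screen map is replaced by an explicit
:class:`Viewport`: a global ``first_nt..last_nt`` window applied to all
chromosomes.  Rendering is a pure function of its inputs — repeated
calls produce byte-identical SVG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from xml.sax.saxutils import escape

from PIL import Image, ImageDraw

from .errors import GenomapError
from .formats import (ColouredFeature, ColourTable, Track,
                      assign_gradient_colour, parse_colors)
from .genome import Genome


@dataclass(frozen=True)
class Viewport:
    """The rendering window: global nt span plus pixel geometry.

    ``exaggerate`` widens every feature block to at least
    ``exaggerate_px`` so single-gene features stay visible at
    whole-genome scale.
    """

    first_nt: int
    last_nt: int
    width_px: int = 1600
    row_height_px: int = 14
    exaggerate: bool = False
    min_block_px: int = 1
    exaggerate_px: int = 3

    def __post_init__(self):
        if self.first_nt < 1 or self.first_nt > self.last_nt:
            raise GenomapError(
                f"invalid window {self.first_nt}-{self.last_nt}"
            )
        if self.width_px < 100:
            raise GenomapError("viewport width must be at least 100 px")

    @property
    def span_nt(self) -> int:
        return self.last_nt - self.first_nt + 1


def full_genome_viewport(genome: Genome, **kwargs) -> Viewport:
    """Zoom fully out: window 1..longest chromosome."""
    longest = max(length for _, length in genome.chromosomes.entries)
    return Viewport(first_nt=1, last_nt=longest, **kwargs)


def _x(nt: int, vp: Viewport) -> int:
    return math.floor((nt - vp.first_nt) / vp.span_nt * vp.width_px)


def nt_to_px(nt: int, vp: Viewport) -> int:
    """Pixel x of a nucleotide: floor((nt-first)/span * width)."""
    if nt < vp.first_nt or nt > vp.last_nt:
        raise GenomapError(f"nt {nt} outside window "
                           f"{vp.first_nt}-{vp.last_nt}")
    return _x(nt, vp)


def px_to_nt(x: int, vp: Viewport) -> int:
    """Pseudo-inverse of :func:`nt_to_px` (status-bar readout)."""
    if x < 0 or x >= vp.width_px:
        raise GenomapError(f"x {x} outside canvas 0-{vp.width_px - 1}")
    nt = vp.first_nt + math.floor(x / vp.width_px * vp.span_nt)
    return min(max(nt, vp.first_nt), vp.last_nt)


@dataclass(frozen=True)
class Style:
    """Pixel layout and palette knobs for the map canvas."""

    label_width_px: int = 70
    margin_px: int = 10
    row_gap_px: int = 2
    group_gap_px: int = 8
    font_size_px: int = 10
    bar_colour: tuple[int, int, int] = (150, 150, 150)
    background: tuple[int, int, int] = (255, 255, 255)
    text_colour: tuple[int, int, int] = (0, 0, 0)
    graph_colour_name: str = "clNavy"


def load_style(path: Path | str) -> Style:
    """Read a plain ``key=value`` style file; unknown keys are errors."""
    style = Style()
    for lineno, raw in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise GenomapError(f"style line {lineno}: expected key=value")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if not hasattr(style, key):
            raise GenomapError(f"style line {lineno}: unknown key {key!r}")
        current = getattr(style, key)
        if isinstance(current, tuple):
            parts = [int(v) for v in value.replace(",", " ").split()]
            if len(parts) != 3:
                raise GenomapError(f"style line {lineno}: need R G B")
            style = replace(style, **{key: tuple(parts)})
        elif isinstance(current, int):
            style = replace(style, **{key: int(value)})
        else:
            style = replace(style, **{key: value})
    return style


# A primitive is ("rect", x, y, w, h, rgb), ("line", x1, y1, x2, y2, rgb)
# or ("text", x, y, string, size, rgb); order is the paint order.
Primitive = tuple


@dataclass
class MapImage:
    """An ordered list of drawing primitives plus canvas size."""

    width: int
    height: int
    primitives: list[Primitive] = field(default_factory=list)
    background: tuple[int, int, int] = (255, 255, 255)

    def to_svg(self) -> str:
        out = [
            '<?xml version="1.0" encoding="UTF-8"?>',
            f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'width="{self.width}" height="{self.height}" '
            f'viewBox="0 0 {self.width} {self.height}">',
            f'<rect x="0" y="0" width="{self.width}" height="{self.height}" '
            f'fill="{_hex(self.background)}"/>',
        ]
        for prim in self.primitives:
            kind = prim[0]
            if kind == "rect":
                _, x, y, w, h, rgb = prim
                out.append(f'<rect x="{x}" y="{y}" width="{w}" height="{h}" '
                           f'fill="{_hex(rgb)}"/>')
            elif kind == "line":
                _, x1, y1, x2, y2, rgb = prim
                out.append(f'<line x1="{x1}" y1="{y1}" x2="{x2}" y2="{y2}" '
                           f'stroke="{_hex(rgb)}" stroke-width="1"/>')
            elif kind == "text":
                _, x, y, s, size, rgb = prim
                out.append(f'<text x="{x}" y="{y}" font-family="monospace" '
                           f'font-size="{size}" fill="{_hex(rgb)}">'
                           f'{escape(s)}</text>')
            else:  # pragma: no cover - internal invariant
                raise GenomapError(f"unknown primitive {kind!r}")
        out.append("</svg>")
        return "\n".join(out) + "\n"

    def to_pil(self) -> Image.Image:
        img = Image.new("RGB", (self.width, self.height), self.background)
        draw = ImageDraw.Draw(img)
        for prim in self.primitives:
            kind = prim[0]
            if kind == "rect":
                _, x, y, w, h, rgb = prim
                if w > 0 and h > 0:
                    draw.rectangle([x, y, x + w - 1, y + h - 1], fill=rgb)
            elif kind == "line":
                _, x1, y1, x2, y2, rgb = prim
                draw.line([x1, y1, x2, y2], fill=rgb)
            elif kind == "text":
                _, x, y, s, size, rgb = prim
                # y is the text baseline, as in the SVG output
                draw.text((x, max(y - size, 0)), s, fill=rgb)
        return img


def _hex(rgb: tuple[int, int, int]) -> str:
    return "#{:02X}{:02X}{:02X}".format(*rgb)


def save_map(image: MapImage, path: Path | str,
             format: str | None = None) -> Path:
    """Write the map as SVG (byte-stable) or PNG (platform-stable)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "svg":
        path.write_text(image.to_svg(), encoding="utf-8", newline="\n")
    elif fmt == "png":
        image.to_pil().save(path, format="PNG")
    else:
        raise GenomapError(f"unknown image format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# row renderers
# ---------------------------------------------------------------------------


def _block_px(first_nt: int, last_nt: int, vp: Viewport
              ) -> tuple[int, int] | None:
    """(x, width) of a feature block, or None when outside the window.

    The block runs from the pixel of its first nt to the pixel of
    ``last_nt + 1``, is at least ``min_block_px`` wide, and widens
    rightward to ``exaggerate_px`` when exaggeration is on, clamped to
    the canvas.
    """
    if last_nt < vp.first_nt or first_nt > vp.last_nt:
        return None
    x0 = _x(max(first_nt, vp.first_nt), vp)
    x1 = _x(min(last_nt, vp.last_nt) + 1, vp)
    w = max(x1 - x0, vp.min_block_px)
    if vp.exaggerate:
        w = max(w, vp.exaggerate_px)
    w = min(w, vp.width_px - x0)
    return x0, max(w, 1)


def render_freq_row(track: Track, vp: Viewport, *, chrom_id: str | None = None,
                    x_offset: int = 0, y: int = 0,
                    row_height: int | None = None,
                    colours: ColourTable | None = None) -> list[Primitive]:
    """Gradient-binned blocks: each region filled with its bin colour.

    Regions whose coordinates abut tile without gaps because each block
    ends where the next nucleotide's pixel begins.
    """
    if colours is None:
        colours = parse_colors(None)
    h = row_height if row_height is not None else vp.row_height_px
    prims: list[Primitive] = []
    records = [r for r in track.records
               if chrom_id is None or r.chrom_id == chrom_id]
    for rec in sorted(records, key=lambda r: (r.first_nt, r.last_nt)):
        span = _block_px(rec.first_nt, rec.last_nt, vp)
        if span is None:
            continue
        name = assign_gradient_colour(rec.value, track.gradient)
        x, w = span
        prims.append(("rect", x_offset + x, y, w, h, colours.resolve(name)))
    return prims


def render_graph_row(track: Track, vp: Viewport, row_height: int | None = None,
                     *, chrom_id: str | None = None, x_offset: int = 0,
                     y: int = 0,
                     colours: ColourTable | None = None) -> list[Primitive]:
    """Histogram bars: y values linearly rescaled to the row height.

    The value range [min(0, min y), max(0, max y)] maps onto the row, so
    an all-non-negative track puts its maximum at full height and zero
    on the baseline; negative values hang below a shifted baseline with
    sign preserved.  An all-zero track draws a flat baseline.
    """
    if colours is None:
        colours = parse_colors(None)
    h = row_height if row_height is not None else vp.row_height_px
    rgb = colours.resolve(track.colour or "clNavy")
    records = [r for r in track.records
               if chrom_id is None or r.chrom_id == chrom_id]
    visible = [r for r in records
               if r.last_nt >= vp.first_nt and r.first_nt <= vp.last_nt]
    prims: list[Primitive] = []
    if not records:
        return prims
    values = [r.value for r in records]
    lo = min(0.0, min(values))
    hi = max(0.0, max(values))
    if hi == lo:  # all-zero track: flat baseline, no division by zero
        prims.append(("line", x_offset, y + h - 1,
                      x_offset + vp.width_px - 1, y + h - 1, rgb))
        return prims
    scale = h / (hi - lo)

    def py(v: float) -> int:
        return y + round((hi - v) * scale)

    baseline = py(0.0)
    for rec in sorted(visible, key=lambda r: (r.first_nt, r.last_nt)):
        span = _block_px(rec.first_nt, rec.last_nt, vp)
        if span is None:
            continue
        x, w = span
        top, bottom = sorted((py(rec.value), baseline))
        bar_h = max(bottom - top, 0)
        if bar_h == 0:
            continue
        prims.append(("rect", x_offset + x, top, w, bar_h, rgb))
    return prims


def _blocks_row(track: Track, vp: Viewport, chrom_id: str, x_offset: int,
                y: int, h: int, colours: ColourTable) -> list[Primitive]:
    """posn/blast/expr sub-row: one coloured block per visible record."""
    prims: list[Primitive] = []
    track_rgb = colours.resolve(track.colour) if track.colour else None
    for rec in sorted(track.records_on(chrom_id),
                      key=lambda r: (r.first_nt, r.last_nt, r.feature_id)):
        span = _block_px(rec.first_nt, rec.last_nt, vp)
        if span is None:
            continue
        if isinstance(rec, ColouredFeature):
            rgb = colours.resolve(rec.colour)
        else:
            rgb = track_rgb if track_rgb is not None else colours.resolve(None)
        x, w = span
        prims.append(("rect", x_offset + x, y, w, h, rgb))
    return prims


# ---------------------------------------------------------------------------
# the full map
# ---------------------------------------------------------------------------


def group_height(n_tracks: int, vp: Viewport, style: Style) -> int:
    """Height of one chromosome's row group (bar + track sub-rows + gap)."""
    rows = 1 + n_tracks
    return rows * (vp.row_height_px + style.row_gap_px) + style.group_gap_px


def render_map(genome: Genome, displayed_tracks: list[Track], vp: Viewport,
               style: Style | None = None,
               colours: ColourTable | None = None) -> MapImage:
    """Render the genome with its displayed tracks into a vector scene.

    One row group per chromosome in chromosome-set order; within a
    group, the grey chromosome bar first, then one sub-row per track in
    selection order.  Chromosomes entirely outside the window are
    omitted; it is an error if none is visible.
    """
    if style is None:
        style = Style()
    if colours is None:
        colours = parse_colors(None)

    visible = [(cid, length) for cid, length in genome.chromosomes.entries
               if length >= vp.first_nt]
    if not visible:
        raise GenomapError("no chromosome intersects the viewport")

    gh = group_height(len(displayed_tracks), vp, style)
    width = style.label_width_px + vp.width_px + style.margin_px
    height = 2 * style.margin_px + len(visible) * gh
    image = MapImage(width=width, height=height, background=style.background)
    x_off = style.label_width_px
    h = vp.row_height_px

    y = style.margin_px
    for cid, length in visible:
        image.primitives.append(
            ("text", style.margin_px // 2, y + h - 2, cid,
             style.font_size_px, style.text_colour)
        )
        bar_end_nt = min(length, vp.last_nt)
        bar_w = max(_x(bar_end_nt + 1, vp), 1)
        image.primitives.append(
            ("rect", x_off, y, bar_w, h, style.bar_colour))
        row_y = y + h + style.row_gap_px
        for track in displayed_tracks:
            if track.kind == "freq":
                image.primitives.extend(
                    render_freq_row(track, vp, chrom_id=cid, x_offset=x_off,
                                    y=row_y, row_height=h, colours=colours))
            elif track.kind == "graph":
                image.primitives.extend(
                    render_graph_row(track, vp, h, chrom_id=cid,
                                     x_offset=x_off, y=row_y,
                                     colours=colours))
            else:
                image.primitives.extend(
                    _blocks_row(track, vp, cid, x_off, row_y, h, colours))
            row_y += h + style.row_gap_px
        y += gh
    return image
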