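"""Parsers and writers for the map's tab-delimited file grammars.

A genome map project is plain text throughout.  The ``_data`` folder holds
a *chromosomes* table (``id = length`` per line), an optional *colors*
table (``clName = $RRGGBB``) and a *genes* file (five mandatory TAB fields:
chromosome id, first nt, last nt, strand, gene id, then free annotation
fields).  Displayable tracks come in five grammars distinguished by file
extension:

``posn``
    positioned features drawn in one colour; the first ``#``-line names
    the colour.
``blast``
    sequence-similarity hits; first ``#``-line is the colour, second is
    the E-value cut-off.  Each data line carries one or more
    ``query id, E-value`` pairs in ascending E order; only the first
    (smallest) E-value is compared against the cut-off.
``expr``
    per-row coloured features (e.g. up-regulated genes in red,
    down-regulated in blue); the colour is the last field of each line.
``freq``
    valued regions binned into a colour gradient; the first ``#``-line
    interleaves up to 20 colour names with ascending boundary values.
``graph``
    valued regions drawn as a histogram; the last field is the y value.

Everywhere in this package coordinates are 1-based and inclusive at both
ends.  Lines beginning ``#`` are directives or comments; blank lines are
ignored.  Both LF and CRLF are accepted; files are UTF-8.
"""

from __future__ import annotations

import logging
import math
import re
from bisect import bisect_right
from dataclasses import dataclass, field

from .errors import FormatError

logger = logging.getLogger("genomap")

#: Hard cap on the number of chromosomes/scaffolds in one genome.
MAX_CHROMOSOMES = 1000
#: Hard cap on the number of colours in a freq-track gradient.
MAX_GRADIENT_COLOURS = 20

#: Colour used when a data line names a colour the table does not know.
FALLBACK_COLOUR = "clGray"

TRACK_KINDS = ("posn", "blast", "expr", "freq", "graph")

# The 16 standard Windows colour names, always available as built-ins.
BUILTIN_COLOURS: dict[str, tuple[int, int, int]] = {
    "clBlack": (0x00, 0x00, 0x00),
    "clMaroon": (0x80, 0x00, 0x00),
    "clGreen": (0x00, 0x80, 0x00),
    "clOlive": (0x80, 0x80, 0x00),
    "clNavy": (0x00, 0x00, 0x80),
    "clPurple": (0x80, 0x00, 0x80),
    "clTeal": (0x00, 0x80, 0x80),
    "clGray": (0x80, 0x80, 0x80),
    "clSilver": (0xC0, 0xC0, 0xC0),
    "clRed": (0xFF, 0x00, 0x00),
    "clLime": (0x00, 0xFF, 0x00),
    "clYellow": (0xFF, 0xFF, 0x00),
    "clBlue": (0x00, 0x00, 0xFF),
    "clFuchsia": (0xFF, 0x00, 0xFF),
    "clAqua": (0x00, 0xFF, 0xFF),
    "clWhite": (0xFF, 0xFF, 0xFF),
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChromosomeSet:
    """Ordered chromosomes/scaffolds with their lengths in base pairs.

    Order is preserved from the source file: for some species chromosome
    numbering follows the genetic map, not size order, and the display
    must respect it.
    """

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self):
        ids = [cid for cid, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate chromosome id")
        if not 1 <= len(ids) <= MAX_CHROMOSOMES:
            raise FormatError(
                f"chromosome count {len(ids)} outside 1..{MAX_CHROMOSOMES}"
            )
        for cid, length in self.entries:
            if length < 1:
                raise FormatError(f"chromosome {cid!r}: non-positive length")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(cid for cid, _ in self.entries)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.entries)

    def length_of(self, chrom_id: str) -> int:
        return self.lengths[chrom_id]

    def order_index(self, chrom_id: str) -> int:
        return self.ids.index(chrom_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, chrom_id: str) -> bool:
        return chrom_id in self.lengths


class ColourTable:
    """Named colours: the 16 Windows built-ins plus user additions."""

    def __init__(self, extra: dict[str, tuple[int, int, int]] | None = None):
        self._table = dict(BUILTIN_COLOURS)
        if extra:
            self._table.update(extra)

    def __contains__(self, name: str) -> bool:
        return name in self._table

    def __getitem__(self, name: str) -> tuple[int, int, int]:
        return self._table[name]

    def __len__(self) -> int:
        return len(self._table)

    def names(self) -> list[str]:
        return list(self._table)

    def resolve(self, name: str | None) -> tuple[int, int, int]:
        """RGB for *name*, falling back to mid-grey with a warning."""
        if name is not None and name in self._table:
            return self._table[name]
        logger.warning("unknown colour %r, using %s", name, FALLBACK_COLOUR)
        return self._table[FALLBACK_COLOUR]


@dataclass(frozen=True)
class Feature:
    """One gene or region: 1-based inclusive span on a chromosome."""

    chrom_id: str
    first_nt: int
    last_nt: int
    strand: str = "."
    feature_id: str = ""
    extras: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.chrom_id:
            raise FormatError("empty chromosome id")
        if self.first_nt > self.last_nt:
            raise FormatError(
                f"{self.feature_id or self.chrom_id}: first_nt > last_nt"
            )
        if self.first_nt < 1:
            raise FormatError(f"{self.feature_id}: non-positive coordinate")

    @property
    def length_nt(self) -> int:
        return self.last_nt - self.first_nt + 1

    def overlaps(self, first_nt: int, last_nt: int) -> bool:
        """Any-overlap on closed intervals."""
        return self.first_nt <= last_nt and self.last_nt >= first_nt


@dataclass(frozen=True)
class BlastHit(Feature):
    """A hit region with its (query id, E-value) pairs, ascending in E.

    The gene id ``"seq"`` marks a bare chromosome region rather than a
    known gene.
    """

    pairs: tuple[tuple[str, float], ...] = ()

    def __post_init__(self):
        super().__post_init__()
        if not self.pairs:
            raise FormatError("blast record needs at least one query/E pair")
        es = [e for _, e in self.pairs]
        if any(e < 0 for e in es):
            raise FormatError("negative E-value")
        if es != sorted(es):
            raise FormatError("pairs not ascending in E-value")

    @property
    def best_e(self) -> float:
        return self.pairs[0][1]


@dataclass(frozen=True)
class ColouredFeature(Feature):
    """expr-track row: the feature plus its own display colour."""

    colour: str = FALLBACK_COLOUR


@dataclass(frozen=True)
class ValuedFeature(Feature):
    """freq/graph-track row: the feature plus a numeric value."""

    value: float = 0.0


@dataclass(frozen=True)
class GradientSpec:
    """k ordered colours with k-1 strictly increasing boundary values.

    Value ``v`` falls in bin ``i`` = number of boundaries <= v, i.e. bins
    are half-open ``[b[i-1], b[i])`` with the first open below and the
    last open above.
    """

    colours: tuple[str, ...]
    boundaries: tuple[float, ...]

    def __post_init__(self):
        k = len(self.colours)
        if not 1 <= k <= MAX_GRADIENT_COLOURS:
            raise FormatError(
                f"gradient has {k} colours, allowed 1..{MAX_GRADIENT_COLOURS}"
            )
        if len(self.boundaries) != k - 1:
            raise FormatError(
                f"gradient needs {k - 1} boundaries for {k} colours, "
                f"got {len(self.boundaries)}"
            )
        bs = self.boundaries
        if any(b2 <= b1 for b1, b2 in zip(bs, bs[1:])):
            raise FormatError("gradient boundaries not strictly increasing")


def assign_gradient_colour(value: float, gradient: GradientSpec) -> str:
    """Colour name for *value* under the gradient's half-open bins."""
    if not math.isfinite(value):
        raise FormatError(f"non-finite value {value!r}")
    return gradient.colours[bisect_right(gradient.boundaries, value)]


@dataclass
class Track:
    """A named, typed collection of displayable records plus styling.

    Payload fields are present iff the kind requires them: posn/blast
    carry a track colour, blast an E-value cut-off, freq a gradient;
    expr rows each carry their own colour, freq/graph rows a value.
    """

    name: str
    kind: str
    records: list[Feature] = field(default_factory=list)
    colour: str | None = None
    cutoff: float | None = None
    gradient: GradientSpec | None = None

    def __post_init__(self):
        if self.kind not in TRACK_KINDS:
            raise FormatError(f"unknown track kind {self.kind!r}")
        if self.kind in ("posn", "blast") and self.colour is None:
            raise FormatError(f"{self.kind} track needs a colour")
        if self.kind == "blast" and self.cutoff is None:
            raise FormatError("blast track needs an E-value cut-off")
        if self.kind == "freq" and self.gradient is None:
            raise FormatError("freq track needs a gradient")

    def records_on(self, chrom_id: str) -> list[Feature]:
        return [r for r in self.records if r.chrom_id == chrom_id]

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# line plumbing
# ---------------------------------------------------------------------------


def _lines(text: str):
    """Yield (1-based line number, stripped-of-newline line)."""
    for i, line in enumerate(text.splitlines(), start=1):
        yield i, line.rstrip("\r")


def _data_lines(text: str):
    """Yield (lineno, TAB-split fields) for non-blank, non-# lines."""
    for i, line in _lines(text):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        yield i, line.split("\t")


def _parse_int(token: str, what: str, lineno: int) -> int:
    try:
        return int(token.strip())
    except ValueError:
        raise FormatError(f"{what}: not an integer: {token!r}", lineno) from None


def _parse_float(token: str, what: str, lineno: int) -> float:
    try:
        return float(token.strip())
    except ValueError:
        raise FormatError(f"{what}: not a number: {token!r}", lineno) from None


# ---------------------------------------------------------------------------
# _data folder tables
# ---------------------------------------------------------------------------


def parse_chromosomes(text: str) -> ChromosomeSet:
    """Parse the chromosomes table: one ``id = length`` per line.

    Whitespace around the id, ``=`` and length is tolerated.  Blank
    lines and ``#`` comments are ignored.  Errors: zero entries, more
    than 1000 entries, duplicate ids, non-positive or non-integer
    lengths.
    """
    entries: list[tuple[str, int]] = []
    seen: set[str] = set()
    for i, line in _lines(text):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise FormatError(f"expected 'id = length', got {stripped!r}", i)
        cid, _, length_tok = stripped.partition("=")
        cid = cid.strip()
        if not cid:
            raise FormatError("empty chromosome id", i)
        if cid in seen:
            raise FormatError(f"duplicate chromosome id {cid!r}", i)
        seen.add(cid)
        length = _parse_int(length_tok, f"chromosome {cid!r} length", i)
        if length < 1:
            raise FormatError(f"chromosome {cid!r}: non-positive length", i)
        entries.append((cid, length))
        if len(entries) > MAX_CHROMOSOMES:
            raise FormatError(
                f"chromosome cap exceeded (maximum {MAX_CHROMOSOMES})", i
            )
    if not entries:
        raise FormatError("no chromosomes")
    return ChromosomeSet(tuple(entries))


_HEX_RE = re.compile(r"^\$([0-9A-Fa-f]{6})$")


def parse_colors(text: str | None = None) -> ColourTable:
    """Parse the colors table: ``clName = $RRGGBB`` per line.

    The hex digits are read in Red, Green, Blue order.  The file is
    optional; its entries overlay the 16 built-in Windows colours.  A
    name without the ``cl`` prefix is kept but warned about.
    """
    extra: dict[str, tuple[int, int, int]] = {}
    if text is not None:
        for i, line in _lines(text):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if "=" not in stripped:
                raise FormatError(
                    f"expected 'clName = $RRGGBB', got {stripped!r}", i
                )
            name, _, hex_tok = stripped.partition("=")
            name = name.strip()
            hex_tok = hex_tok.strip()
            m = _HEX_RE.match(hex_tok)
            if not m:
                raise FormatError(f"malformed colour value {hex_tok!r}", i)
            if not name.startswith("cl"):
                logger.warning(
                    "colour name %r lacks the 'cl' prefix (line %d)", name, i
                )
            digits = m.group(1)
            extra[name] = (
                int(digits[0:2], 16),
                int(digits[2:4], 16),
                int(digits[4:6], 16),
            )
    return ColourTable(extra)


def _parse_feature_line(fields: list[str], lineno: int) -> Feature:
    """Map the five mandatory TAB fields (+extras) to a Feature."""
    if len(fields) < 5:
        raise FormatError(
            f"expected at least 5 TAB fields, got {len(fields)}", lineno
        )
    chrom = fields[0].strip()
    first = _parse_int(fields[1], "first nt", lineno)
    last = _parse_int(fields[2], "last nt", lineno)
    if first > last:
        logger.warning(
            "line %d: first nt %d > last nt %d, swapped", lineno, first, last
        )
        first, last = last, first
    return Feature(
        chrom_id=chrom,
        first_nt=first,
        last_nt=last,
        strand=fields[3].strip(),
        feature_id=fields[4].strip(),
        extras=tuple(fields[5:]),
    )


def parse_genes(text: str) -> list[Feature]:
    """Parse the genes table: chrom, first, last, strand, id, annotation.

    Blank lines and ``#`` lines are comments.  Annotation fields beyond
    the fifth are preserved byte-for-byte in ``extras``.  Reversed
    coordinates are swapped with a warning.
    """
    return [_parse_feature_line(f, i) for i, f in _data_lines(text)]


# ---------------------------------------------------------------------------
# the five track grammars
# ---------------------------------------------------------------------------


def _header_lines(text: str) -> list[tuple[int, str]]:
    """The leading run of #-lines (directives), before any data line."""
    headers: list[tuple[int, str]] = []
    for i, line in _lines(text):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            headers.append((i, stripped.lstrip("#").strip()))
        else:
            break
    return headers


def parse_posn(text: str, name: str) -> Track:
    """posn grammar: colour directive then gene-style data lines."""
    headers = _header_lines(text)
    if not headers:
        raise FormatError("missing colour header (first #-line)")
    colour = headers[0][1].split()[0] if headers[0][1] else ""
    if not colour:
        raise FormatError("missing colour header (first #-line)", headers[0][0])
    records = [_parse_feature_line(f, i) for i, f in _data_lines(text)]
    return Track(name=name, kind="posn", colour=colour, records=records)


def parse_blast(text: str, name: str) -> Track:
    """blast grammar: colour and cut-off directives, then hit lines.

    Each data line carries the five feature fields followed by one or
    more (query id, E-value) pairs in ascending E order.  Unsorted pairs
    are re-sorted with a warning.  Records whose first (smallest)
    E-value exceeds the cut-off are dropped, with a count logged: only
    the first E-value needs checking against the cut-off.
    """
    headers = _header_lines(text)
    if not headers:
        raise FormatError("missing colour header (first #-line)")
    if len(headers) < 2:
        raise FormatError("missing E-value cut-off (second #-line)")
    colour = headers[0][1].split()[0]
    cutoff = _parse_float(headers[1][1].split()[0], "E-value cut-off",
                          headers[1][0])
    records: list[Feature] = []
    dropped = 0
    for i, fields in _data_lines(text):
        if len(fields) < 7:
            raise FormatError(
                "blast line needs chrom, first, last, strand, id and at "
                "least one query id + E-value pair", i
            )
        base = _parse_feature_line(fields[:5], i)
        tail = fields[5:]
        if len(tail) % 2 != 0:
            raise FormatError("unpaired query id / E-value fields", i)
        pairs = [
            (tail[j].strip(), _parse_float(tail[j + 1], "E-value", i))
            for j in range(0, len(tail), 2)
        ]
        es = [e for _, e in pairs]
        if es != sorted(es):
            logger.warning("line %d: E-value pairs not ascending, re-sorted", i)
            pairs.sort(key=lambda p: p[1])
        if pairs[0][1] > cutoff:
            dropped += 1
            continue
        records.append(
            BlastHit(
                chrom_id=base.chrom_id,
                first_nt=base.first_nt,
                last_nt=base.last_nt,
                strand=base.strand,
                feature_id=base.feature_id,
                pairs=tuple(pairs),
            )
        )
    if dropped:
        logger.info("track %s: %d records above cut-off dropped", name, dropped)
    return Track(name=name, kind="blast", colour=colour, cutoff=cutoff,
                 records=records)


def _mid_fields(fields: list[str]) -> tuple[str, str, tuple[str, ...]]:
    """strand, id, extras from the fields between coords and payload."""
    mid = fields[3:-1]
    strand = mid[0].strip() if mid else "."
    fid = mid[1].strip() if len(mid) > 1 else ""
    return strand, fid, tuple(mid[2:])


def parse_expr(text: str, name: str,
               colours: ColourTable | None = None) -> Track:
    """expr grammar: all #-lines ignored; last field is the row colour.

    When a colour table is supplied, rows naming an unknown colour get a
    warning (they will render in the fallback grey).
    """
    records: list[Feature] = []
    for i, fields in _data_lines(text):
        if len(fields) < 4:
            raise FormatError(
                "expr line needs chrom, first, last and a colour", i
            )
        chrom = fields[0].strip()
        first = _parse_int(fields[1], "first nt", i)
        last = _parse_int(fields[2], "last nt", i)
        if first > last:
            logger.warning("line %d: coordinates reversed, swapped", i)
            first, last = last, first
        colour = fields[-1].strip()
        if colours is not None and colour not in colours:
            logger.warning(
                "line %d: unknown colour %r, will render as %s",
                i, colour, FALLBACK_COLOUR,
            )
        strand, fid, extras = _mid_fields(fields)
        records.append(
            ColouredFeature(chrom_id=chrom, first_nt=first, last_nt=last,
                            strand=strand, feature_id=fid, extras=extras,
                            colour=colour)
        )
    return Track(name=name, kind="expr", records=records)


_NUM_RE = re.compile(r"^[-+]?(\d+\.?\d*|\.\d+)([eE][-+]?\d+)?$")


def parse_gradient_header(header: str, lineno: int | None = None) -> GradientSpec:
    """Parse ``colour (boundary colour)*`` — TABs or spaces separate."""
    tokens = header.split()
    if not tokens:
        raise FormatError("empty gradient header", lineno)
    colours: list[str] = []
    boundaries: list[float] = []
    expect_colour = True
    for tok in tokens:
        is_number = bool(_NUM_RE.match(tok))
        if expect_colour:
            if is_number:
                raise FormatError(
                    f"expected a colour name, got number {tok!r}", lineno
                )
            colours.append(tok)
        else:
            if not is_number:
                raise FormatError(
                    f"expected a boundary value, got {tok!r}", lineno
                )
            boundaries.append(float(tok))
        expect_colour = not expect_colour
    if expect_colour:  # last token consumed was a boundary
        raise FormatError("gradient header ends with a boundary value", lineno)
    if len(colours) > MAX_GRADIENT_COLOURS:
        raise FormatError(
            f"gradient cap exceeded: {len(colours)} colours "
            f"(maximum {MAX_GRADIENT_COLOURS})", lineno
        )
    return GradientSpec(tuple(colours), tuple(boundaries))


def _parse_valued_line(fields: list[str], lineno: int) -> ValuedFeature:
    if len(fields) < 4:
        raise FormatError(
            "line needs chrom, first, last and a numeric value", lineno
        )
    chrom = fields[0].strip()
    first = _parse_int(fields[1], "first nt", lineno)
    last = _parse_int(fields[2], "last nt", lineno)
    if first > last:
        logger.warning("line %d: coordinates reversed, swapped", lineno)
        first, last = last, first
    value = _parse_float(fields[-1], "value", lineno)
    strand, fid, extras = _mid_fields(fields)
    return ValuedFeature(chrom_id=chrom, first_nt=first, last_nt=last,
                         strand=strand, feature_id=fid, extras=extras,
                         value=value)


def parse_freq(text: str, name: str) -> Track:
    """freq grammar: gradient directive, then valued-region lines."""
    headers = _header_lines(text)
    if not headers:
        raise FormatError("missing gradient header (first #-line)")
    gradient = parse_gradient_header(headers[0][1], headers[0][0])
    records = [_parse_valued_line(f, i) for i, f in _data_lines(text)]
    return Track(name=name, kind="freq", gradient=gradient, records=records)


def parse_graph(text: str, name: str) -> Track:
    """graph grammar: valued-region lines; y = last field.

    An optional first ``#``-line naming a colour sets the bar colour.
    Negative y values are accepted (the axis extends below zero).
    """
    headers = _header_lines(text)
    colour = None
    if headers:
        tok = headers[0][1].split()
        if tok and tok[0].startswith("cl"):
            colour = tok[0]
    records = [_parse_valued_line(f, i) for i, f in _data_lines(text)]
    return Track(name=name, kind="graph", colour=colour, records=records)


_PARSERS = {
    "posn": parse_posn,
    "blast": parse_blast,
    "expr": parse_expr,
    "freq": parse_freq,
    "graph": parse_graph,
}


def parse_track(text: str, name: str, kind: str) -> Track:
    """Dispatch to the parser for *kind* (a track file extension)."""
    try:
        parser = _PARSERS[kind]
    except KeyError:
        raise FormatError(f"unknown track kind {kind!r}") from None
    return parser(text, name)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _fmt_num(v: float) -> str:
    """Shortest decimal text that round-trips the value."""
    if float(v).is_integer() and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def _record_fields(rec: Feature) -> list[str]:
    fields = [rec.chrom_id, str(rec.first_nt), str(rec.last_nt),
              rec.strand, rec.feature_id, *rec.extras]
    if isinstance(rec, BlastHit):
        for qid, e in rec.pairs:
            fields += [qid, _fmt_num(e)]
    elif isinstance(rec, ColouredFeature):
        fields.append(rec.colour)
    elif isinstance(rec, ValuedFeature):
        fields.append(_fmt_num(rec.value))
    return fields


def format_gradient_header(g: GradientSpec) -> str:
    parts: list[str] = [g.colours[0]]
    for b, c in zip(g.boundaries, g.colours[1:]):
        parts += [_fmt_num(b), c]
    return "\t".join(parts)


def track_to_text(track: Track) -> str:
    """Serialise a track; data lines sorted by chromosome id then start."""
    lines: list[str] = []
    if track.kind in ("posn", "blast"):
        lines.append(f"# {track.colour}")
    if track.kind == "blast":
        lines.append(f"# {_fmt_num(track.cutoff)}")
    if track.kind == "freq":
        lines.append("# " + format_gradient_header(track.gradient))
    if track.kind == "graph" and track.colour:
        lines.append(f"# {track.colour}")
    for rec in sorted(track.records, key=lambda r: (r.chrom_id, r.first_nt)):
        lines.append("\t".join(_record_fields(rec)))
    return "\n".join(lines) + "\n"


def write_track(track: Track, path) -> None:
    """Write a track file that re-parses to the same payload and records."""
    from pathlib import Path

    Path(path).write_text(track_to_text(track), encoding="utf-8")


def chromosomes_to_text(chroms: ChromosomeSet) -> str:
    return "".join(f"{cid} = {length}\n" for cid, length in chroms.entries)


def write_chromosomes(chroms: ChromosomeSet, path) -> None:
    from pathlib import Path

    Path(path).write_text(chromosomes_to_text(chroms), encoding="utf-8")


def genes_to_text(genes: list[Feature]) -> str:
    lines = [
        "\t".join([g.chrom_id, str(g.first_nt), str(g.last_nt), g.strand,
                   g.feature_id, *g.extras])
        for g in sorted(genes, key=lambda g: (g.chrom_id, g.first_nt))
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def write_genes(genes: list[Feature], path) -> None:
    from pathlib import Path

    Path(path).write_text(genes_to_text(genes), encoding="utf-8")


def colours_to_text(extra: dict[str, tuple[int, int, int]]) -> str:
    return "".join(
        f"{name} = ${r:02X}{g:02X}{b:02X}\n" for name, (r, g, b) in extra.items()
    )
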