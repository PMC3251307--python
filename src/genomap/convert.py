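"""Builders that turn standard bioinformatics outputs into track files.

The map engine displays results produced by other software; these
converters take GFF3, BED, tabular BLAST, plain position lists and FASTA
and emit the five track grammars.  They are the only place coordinate
systems are translated — everything downstream is uniformly 1-based and
inclusive.
"""

from __future__ import annotations

import logging
from pathlib import Path

from Bio import SeqIO
from gffutils.iterators import DataIterator

from .errors import FormatError, GenomapError
from .formats import (BlastHit, ChromosomeSet, Feature, GradientSpec, Track,
                      ValuedFeature, write_track)

logger = logging.getLogger("genomap")

DEFAULT_DENSITY_WINDOW_NT = 50_000


def gff3_to_posn(gff3_path: Path | str, out_path: Path | str | None = None,
                 feature_type: str = "gene",
                 colour: str = "clBlue") -> Track:
    """Rows of one GFF3 feature type as a posn track.

    GFF3 is already 1-based inclusive, so coordinates pass through
    unchanged.  A row without an ``ID`` attribute gets a synthesised id
    ``type_chrom_start`` and a warning.
    """
    records: list[Feature] = []
    n_rows = 0
    for f in DataIterator(str(gff3_path)):
        n_rows += 1
        if f.featuretype != feature_type:
            continue
        ids = f.attributes.get("ID")
        if ids:
            fid = ids[0]
        else:
            fid = f"{f.featuretype}_{f.seqid}_{f.start}"
            logger.warning("GFF3 row without ID, synthesised %r", fid)
        records.append(Feature(chrom_id=f.seqid, first_nt=f.start,
                               last_nt=f.end, strand=f.strand or ".",
                               feature_id=fid))
    if not records:
        logger.warning("no %r rows among %d GFF3 rows", feature_type, n_rows)
    name = Path(out_path).stem if out_path else Path(gff3_path).stem
    track = Track(name=name, kind="posn", colour=colour, records=records)
    if out_path is not None:
        write_track(track, out_path)
    return track


def bed_to_posn(bed_path: Path | str, out_path: Path | str | None = None,
                colour: str = "clBlue") -> Track:
    """BED (3+ columns) as a posn track.

    BED is 0-based half-open, so ``(chromStart, chromEnd)`` becomes
    ``(chromStart + 1, chromEnd)``.  Strand is taken from column 6 when
    present, the name from column 4.
    """
    records: list[Feature] = []
    text = Path(bed_path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if (not line or line.startswith("#") or line.startswith("track")
                or line.startswith("browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise FormatError("BED row needs at least 3 columns", lineno)
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise FormatError("non-integer BED coordinates", lineno) from None
        if start >= end:
            raise FormatError(
                f"chromStart {start} >= chromEnd {end}", lineno)
        name = fields[3] if len(fields) > 3 else f"{chrom}_{start + 1}"
        strand = fields[5] if len(fields) > 5 else "."
        records.append(Feature(chrom_id=chrom, first_nt=start + 1,
                               last_nt=end, strand=strand, feature_id=name))
    out_name = Path(out_path).stem if out_path else Path(bed_path).stem
    track = Track(name=out_name, kind="posn", colour=colour, records=records)
    if out_path is not None:
        write_track(track, out_path)
    return track


def blast_tab_to_blast(tab_path: Path | str,
                       out_path: Path | str | None = None,
                       cutoff: float = 1e-10, colour: str = "clRed",
                       target: str = "subject") -> Track:
    """12-column tabular BLAST (outfmt 6) as a blast track.

    With ``target="subject"`` the track lives on the subject sequences:
    each aligned subject span becomes a region (gene id ``"seq"``) and
    the query ids with their E-values become the region's pairs, sorted
    ascending.  Minus-strand hits with reversed subject coordinates are
    normalised by min/max.  ``target="query"`` swaps the roles.  Hits
    above the cut-off are still written — the parser drops them at
    display time.
    """
    if target not in ("subject", "query"):
        raise GenomapError(f"target must be subject or query, got {target!r}")
    regions: dict[tuple[str, int, int], list[tuple[str, float]]] = {}
    text = Path(tab_path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise FormatError("expected 12 tabular BLAST columns", lineno)
        qseqid, sseqid = fields[0], fields[1]
        try:
            qstart, qend = int(fields[6]), int(fields[7])
            sstart, send = int(fields[8]), int(fields[9])
            evalue = float(fields[10])
        except ValueError:
            raise FormatError("malformed BLAST coordinates or E-value",
                              lineno) from None
        if target == "subject":
            chrom, lo, hi = sseqid, min(sstart, send), max(sstart, send)
            other = qseqid
        else:
            chrom, lo, hi = qseqid, min(qstart, qend), max(qstart, qend)
            other = sseqid
        regions.setdefault((chrom, lo, hi), []).append((other, evalue))

    records: list[Feature] = []
    for (chrom, lo, hi), pairs in regions.items():
        pairs.sort(key=lambda p: p[1])
        records.append(BlastHit(chrom_id=chrom, first_nt=lo, last_nt=hi,
                                strand=".", feature_id="seq",
                                pairs=tuple(pairs)))
    name = Path(out_path).stem if out_path else Path(tab_path).stem
    track = Track(name=name, kind="blast", colour=colour, cutoff=cutoff,
                  records=records)
    if out_path is not None:
        write_track(track, out_path)
    return track


def tile_windows(length: int, window_nt: int):
    """Yield (first_nt, last_nt) tiling 1..length; last window truncated."""
    first = 1
    while first <= length:
        yield first, min(first + window_nt - 1, length)
        first += window_nt


def positions_to_graph(positions: list[tuple[str, int]],
                       chroms: ChromosomeSet,
                       window_nt: int = DEFAULT_DENSITY_WINDOW_NT,
                       out_path: Path | str | None = None,
                       colour: str | None = None,
                       name: str = "density") -> Track:
    """Windowed position density (e.g. SNPs per 50,000 nt) as a graph track.

    Windows tile each chromosome from nt 1; the final partial window is
    kept with its raw count.  Empty windows are emitted with y = 0 so
    the histogram has no holes.
    """
    if window_nt < 1:
        raise GenomapError("window must be at least 1 nt")
    counts: dict[str, list[int]] = {}
    for cid, length in chroms.entries:
        counts[cid] = [0] * ((length + window_nt - 1) // window_nt)
    for cid, nt in positions:
        if cid not in counts:
            raise GenomapError(f"position on unknown chromosome {cid!r}")
        if nt < 1 or nt > chroms.length_of(cid):
            raise GenomapError(
                f"position {nt} beyond chromosome {cid} "
                f"(length {chroms.length_of(cid)})"
            )
        counts[cid][(nt - 1) // window_nt] += 1
    records: list[Feature] = []
    for cid, length in chroms.entries:
        for i, (first, last) in enumerate(tile_windows(length, window_nt)):
            records.append(ValuedFeature(chrom_id=cid, first_nt=first,
                                         last_nt=last, strand=".",
                                         feature_id=f"w{i + 1}",
                                         value=float(counts[cid][i])))
    track = Track(name=name, kind="graph", colour=colour, records=records)
    if out_path is not None:
        write_track(track, out_path)
    return track


def gc_percent(seq: str) -> float | None:
    """GC percentage over the non-N length; None for an all-N window."""
    s = seq.upper()
    denom = sum(1 for c in s if c != "N")
    if denom == 0:
        return None
    gc = s.count("G") + s.count("C")
    return 100.0 * gc / denom


def fasta_to_gc_freq(fasta_path: Path | str, window_nt: int,
                     gradient: GradientSpec,
                     out_path: Path | str | None = None,
                     name: str = "gc") -> Track:
    """Windowed %GC over every FASTA record as a freq track.

    Each window's value is ``100 * (G+C) / (non-N length)``; windows
    that are entirely N are skipped with a warning.
    """
    if window_nt < 1:
        raise GenomapError("window must be at least 1 nt")
    records: list[Feature] = []
    n_seqs = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        n_seqs += 1
        seq = str(rec.seq)
        if not seq:
            raise GenomapError(f"empty sequence {rec.id!r}")
        for first, last in tile_windows(len(seq), window_nt):
            value = gc_percent(seq[first - 1:last])
            if value is None:
                logger.warning("window %s:%d-%d is all N, skipped",
                               rec.id, first, last)
                continue
            records.append(ValuedFeature(chrom_id=rec.id, first_nt=first,
                                         last_nt=last, strand=".",
                                         feature_id=f"{first}-{last}",
                                         value=value))
    if n_seqs == 0:
        raise GenomapError(f"no sequences in {fasta_path}")
    track = Track(name=name, kind="freq", gradient=gradient, records=records)
    if out_path is not None:
        write_track(track, out_path)
    return track


def concat_contigs(fasta_path: Path | str, spacer_n: int, pseudo_id: str,
                   out_dir: Path | str
                   ) -> tuple[Path, tuple[str, int], Track]:
    """Concatenate unassigned contigs into one pseudo-chromosome.

    Contigs are joined in file order with runs of ``spacer_n`` N between
    them, written as ``<pseudo_id>.fasta``, and a posn track records
    each contig's span so the pseudo-chromosome can be displayed as a
    single unit with its parts identifiable.  Returns the FASTA path,
    the ``(id, length)`` chromosomes-table entry, and the span track.
    """
    if spacer_n < 0:
        raise GenomapError("spacer length must be non-negative")
    contigs = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not contigs:
        raise GenomapError(f"no contigs in {fasta_path}")
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        raise GenomapError("duplicate contig ids")

    parts: list[str] = []
    spans: list[Feature] = []
    offset = 0
    for i, contig in enumerate(contigs):
        if i > 0:
            parts.append("N" * spacer_n)
            offset += spacer_n
        seq = str(contig.seq)
        spans.append(Feature(chrom_id=pseudo_id, first_nt=offset + 1,
                             last_nt=offset + len(seq), strand=".",
                             feature_id=contig.id))
        parts.append(seq)
        offset += len(seq)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_out = out_dir / f"{pseudo_id}.fasta"
    pseudo_seq = "".join(parts)
    lines = [f">{pseudo_id}"]
    lines += [pseudo_seq[i:i + 60] for i in range(0, len(pseudo_seq), 60)]
    fasta_out.write_text("\n".join(lines) + "\n", encoding="utf-8")

    track = Track(name=f"{pseudo_id}_contigs", kind="posn", colour="clOlive",
                  records=spans)
    return fasta_out, (pseudo_id, offset), track
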