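"""Region queries, gene search and sequence extraction.

These are the pure-function equivalents of the interactive map's mouse
selection (Gene List), quick-search / list-search boxes, and the
"extract selected sequences" button.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from intervaltree import IntervalTree
from pyfaidx import Fasta

from . import formats
from .errors import GenomapError, ProjectError
from .formats import (BlastHit, ColouredFeature, Feature, Track,
                      ValuedFeature)
from .genome import Genome, ProjectCatalogue

logger = logging.getLogger("genomap")

FASTA_LINE_WIDTH = 60


@dataclass(frozen=True)
class RegionSelection:
    """A selected span on one chromosome, 1-based inclusive."""

    chrom_id: str
    first_nt: int
    last_nt: int

    def __post_init__(self):
        if self.first_nt < 1 or self.first_nt > self.last_nt:
            raise GenomapError(
                f"invalid selection {self.first_nt}-{self.last_nt}"
            )


@dataclass(frozen=True)
class GeneListRecord:
    """One Gene List row: chromosome id, gene length (nt), first and last
    nt, coding strand, gene id, annotation, plus the source track name."""

    chrom_id: str
    gene_length: int
    first_nt: int
    last_nt: int
    strand: str
    feature_id: str
    annotation: str
    source_track: str

    COLUMNS = ("chrom_id", "gene_length", "first_nt", "last_nt", "strand",
               "gene_id", "annotation", "source_track")

    def fields(self) -> tuple[str, ...]:
        return (self.chrom_id, str(self.gene_length), str(self.first_nt),
                str(self.last_nt), self.strand, self.feature_id,
                self.annotation, self.source_track)


def _annotation_of(rec: Feature) -> str:
    """The Gene List annotation column for any record flavour.

    Valued rows (freq/graph) show their numeric value with the gene
    columns left to the record's own (usually blank) fields; expr rows
    show annotation fields plus their colour; gene/posn rows join their
    annotation fields.
    """
    if isinstance(rec, ValuedFeature):
        return formats._fmt_num(rec.value)
    if isinstance(rec, BlastHit):
        return " ".join(f"{q}:{formats._fmt_num(e)}" for q, e in rec.pairs)
    if isinstance(rec, ColouredFeature):
        return " ".join([*rec.extras, rec.colour]).strip()
    return " ".join(rec.extras)


def _record_row(rec: Feature, track_name: str) -> GeneListRecord:
    return GeneListRecord(
        chrom_id=rec.chrom_id,
        gene_length=rec.length_nt,
        first_nt=rec.first_nt,
        last_nt=rec.last_nt,
        strand=rec.strand,
        feature_id=rec.feature_id,
        annotation=_annotation_of(rec),
        source_track=track_name,
    )


def features_in_region(displayed_tracks: list[Track],
                       sel: RegionSelection) -> list[GeneListRecord]:
    """All displayed records overlapping the selection, one row each.

    Overlap is any-overlap on closed intervals: a record [s, e] is
    reported iff ``s <= sel.last_nt and e >= sel.first_nt`` — partially
    visible features count, as on the drawn map.  Rows are ordered by
    track (selection order) then start position.  An interval index
    provides the fast path; results match a brute-force scan.
    """
    rows: list[GeneListRecord] = []
    for track in displayed_tracks:
        tree = IntervalTree()
        for idx, rec in enumerate(track.records):
            if rec.chrom_id != sel.chrom_id:
                continue
            # closed [first, last] -> half-open [first, last+1)
            tree.addi(rec.first_nt, rec.last_nt + 1, idx)
        hits = [track.records[iv.data]
                for iv in tree.overlap(sel.first_nt, sel.last_nt + 1)]
        hits.sort(key=lambda r: (r.first_nt, r.last_nt, r.feature_id))
        rows.extend(_record_row(r, track.name) for r in hits)
    return rows


def gene_list_tsv(rows: list[GeneListRecord], header: bool = True) -> str:
    """TAB-separated Gene List text, ready to paste into a spreadsheet."""
    out = []
    if header:
        out.append("\t".join(GeneListRecord.COLUMNS))
    out.extend("\t".join(r.fields()) for r in rows)
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# gene search
# ---------------------------------------------------------------------------


def _temp_dir(catalogue: ProjectCatalogue) -> Path:
    d = catalogue.root / "Temp"
    d.mkdir(exist_ok=True)
    return d


def find_gene(genome: Genome, gene_id: str,
              catalogue: ProjectCatalogue | None = None,
              colour: str = "clBlack",
              ignore_case: bool = False) -> Feature | None:
    """Exact-match search for one gene id in the genes table.

    Matching is case-sensitive by default.  Returns ``None`` when
    absent (not an error).  If several features share the id, the first
    in (chromosome order, start) wins and a warning is logged.  When a
    catalogue is given, the result is persisted as a one-record
    ``Temp/temp.posn`` track for redisplay.
    """
    if not gene_id:
        raise GenomapError("empty gene id")
    key = gene_id.lower() if ignore_case else gene_id
    matches = [g for g in genome.all_genes()
               if (g.feature_id.lower() if ignore_case else g.feature_id)
               == key]
    if not matches:
        return None
    if len(matches) > 1:
        logger.warning("gene id %r matches %d features, using the first",
                       gene_id, len(matches))
    hit = matches[0]
    if catalogue is not None:
        track = Track(name="temp", kind="posn", colour=colour, records=[hit])
        formats.write_track(track, _temp_dir(catalogue) / "temp.posn")
    return hit


def search_ids(genome: Genome, ids: list[str], list_name: str,
               colour: str = "clBlack",
               catalogue: ProjectCatalogue | None = None,
               overwrite: bool = False,
               ignore_case: bool = False
               ) -> tuple[list[Feature], list[str]]:
    """Search many ids at once; returns (found features, missing ids).

    Duplicate input ids are de-duplicated with a warning.  When a
    catalogue is given the found set is saved as
    ``Temp/<list_name>.posn`` in the chosen colour, becoming a
    redisplayable named list; an existing list of the same name is only
    replaced when *overwrite* is set.
    """
    if not list_name:
        raise GenomapError("empty list name")
    if not ids:
        raise GenomapError("empty id list")
    unique: list[str] = []
    seen: set[str] = set()
    for gid in ids:
        key = gid.lower() if ignore_case else gid
        if key in seen:
            logger.warning("duplicate id %r in search list, ignored", gid)
            continue
        seen.add(key)
        unique.append(gid)

    found: list[Feature] = []
    missing: list[str] = []
    for gid in unique:
        hit = find_gene(genome, gid, ignore_case=ignore_case)
        if hit is None:
            missing.append(gid)
        else:
            found.append(hit)

    if catalogue is not None:
        out = _temp_dir(catalogue) / f"{list_name}.posn"
        if out.exists() and not overwrite:
            raise ProjectError(
                f"temp list {list_name!r} already exists (use overwrite)"
            )
        formats.write_track(
            Track(name=list_name, kind="posn", colour=colour,
                  records=list(found)),
            out,
        )
    return found, missing


# ---------------------------------------------------------------------------
# sequence extraction
# ---------------------------------------------------------------------------


def extract_region_sequences(catalogue: ProjectCatalogue,
                             selections: list[RegionSelection]
                             ) -> list[Path]:
    """Write each selection's sequence to ``_seqs/id_firstnt-lastnt.fasta``.

    Requires ``_data/id.fasta`` for each selection's chromosome.  The
    slice is 1-based inclusive, so its length is
    ``last_nt - first_nt + 1``; sequences wrap at 60 columns.
    """
    seqs_dir = catalogue.root / "_seqs"
    seqs_dir.mkdir(exist_ok=True)
    written: list[Path] = []
    for sel in selections:
        fasta_path = catalogue.root / "_data" / f"{sel.chrom_id}.fasta"
        if not fasta_path.is_file():
            raise ProjectError(
                f"no sequence for chromosome {sel.chrom_id!r} "
                f"(expected {fasta_path})"
            )
        with Fasta(str(fasta_path)) as fa:
            record = fa[0]
            if sel.last_nt > len(record):
                raise GenomapError(
                    f"selection {sel.first_nt}-{sel.last_nt} out of range "
                    f"for chromosome {sel.chrom_id} (length {len(record)})"
                )
            seq = record[sel.first_nt - 1:sel.last_nt].seq
        out = seqs_dir / f"{sel.chrom_id}_{sel.first_nt}-{sel.last_nt}.fasta"
        lines = [f">{sel.chrom_id}_{sel.first_nt}-{sel.last_nt}"]
        lines += [seq[i:i + FASTA_LINE_WIDTH]
                  for i in range(0, len(seq), FASTA_LINE_WIDTH)]
        out.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(out)
    return written
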