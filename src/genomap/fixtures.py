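"""Seeded synthetic map projects, for tests, examples and benchmarks.

:func:`make_project` emits a complete, self-consistent project
directory — chromosomes, non-overlapping genes, per-chromosome FASTA,
colours, credits and one track file per requested kind — from a single
integer seed, and returns the planted ground truth so downstream
statistics (gene counts, window counts, blast retention) can be checked
against what was actually planted.  The same spec always produces a
byte-identical tree.

:func:`make_worked_example` builds a miniature four-chromosome genome
with a ten-gene cluster in the middle of chromosome 2, mirroring the
classic "gene family highlighted on a whole-genome map" use case.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import convert, formats
from .errors import GenomapError
from .formats import (BlastHit, ColouredFeature, Feature, GradientSpec,
                      Track, ValuedFeature)
from .query import RegionSelection

#: The six-colour recombination-style gradient used by generated freq tracks.
DEFAULT_GRADIENT = GradientSpec(
    colours=("clBeige", "clKhaki", "clGold", "clGoldenRod", "clTomato",
             "clCrimson"),
    boundaries=(1.0, 2.0, 3.0, 4.0, 8.0),
)

#: RGB definitions for the gradient colours (they are not Windows built-ins).
EXTRA_COLOURS: dict[str, tuple[int, int, int]] = {
    "clBeige": (0xF5, 0xF5, 0xDC),
    "clKhaki": (0xF0, 0xE6, 0x8C),
    "clGold": (0xFF, 0xD7, 0x00),
    "clGoldenRod": (0xDA, 0xA5, 0x20),
    "clTomato": (0xFF, 0x63, 0x47),
    "clCrimson": (0xDC, 0x14, 0x3C),
    "clPaleBlue": (0xAF, 0xCF, 0xF0),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic project.

    Defaults sketch a small fungal-style genome: a handful of
    chromosomes a few hundred kb long, ~1.5 kb genes, a 1e-10 blast
    cut-off and 50 kb density windows.
    """

    n_chrom: int = 4
    length_range: tuple[int, int] = (200_000, 600_000)
    n_genes: int = 120
    mean_gene_len: int = 1_500
    seed: int = 0
    track_recipe: tuple[str, ...] = ("posn", "blast", "expr", "freq", "graph")
    blast_cutoff: float = 1e-10
    n_positions: int = 400
    window_nt: int = convert.DEFAULT_DENSITY_WINDOW_NT
    allow_overlap: bool = False

    def __post_init__(self):
        if min(self.n_chrom, self.n_genes, self.mean_gene_len,
               self.n_positions, self.window_nt) < 1:
            raise GenomapError("all synthetic counts must be positive")
        unknown = set(self.track_recipe) - set(formats.TRACK_KINDS)
        if unknown:
            raise GenomapError(f"unknown track kinds {sorted(unknown)}")


@dataclass
class PlantedTruth:
    """What the generator actually planted, for downstream verification."""

    root: Path
    chrom_lengths: dict[str, int]
    genes: list[Feature]
    track_paths: dict[str, Path] = field(default_factory=dict)
    blast_total: int = 0
    blast_retained: int = 0
    positions: list[tuple[str, int]] = field(default_factory=list)
    freq_values: list[float] = field(default_factory=list)

    @property
    def genes_per_chrom(self) -> dict[str, int]:
        out = {cid: 0 for cid in self.chrom_lengths}
        for g in self.genes:
            out[g.chrom_id] += 1
        return out


def _random_sequence(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _write_fasta(path: Path, name: str, seq: str) -> None:
    lines = [f">{name}"]
    lines += [seq[i:i + 60] for i in range(0, len(seq), 60)]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _place_genes(rng: random.Random, chrom_id: str, length: int, count: int,
                 mean_len: int, allow_overlap: bool) -> list[Feature]:
    """Place *count* genes on one chromosome, non-overlapping by default.

    The chromosome is cut into *count* equal slots and one gene is
    placed at a random offset inside each slot, which keeps interval
    oracles trivial.  Packing is infeasible when a slot cannot hold the
    longest possible gene.
    """
    if count == 0:
        return []
    max_len = int(mean_len * 1.5)
    slot = length // count
    if not allow_overlap and slot < max_len + 1:
        raise GenomapError(
            f"infeasible packing: {count} genes of up to {max_len} nt on a "
            f"{length} nt chromosome"
        )
    genes = []
    for i in range(count):
        gene_len = rng.randint(max(mean_len // 2, 1), max_len)
        if allow_overlap:
            first = rng.randint(1, max(length - gene_len, 1))
        else:
            slot_start = i * slot + 1
            first = slot_start + rng.randint(0, slot - gene_len)
        genes.append(Feature(
            chrom_id=chrom_id, first_nt=first, last_nt=first + gene_len - 1,
            strand=rng.choice("+-"),
            feature_id=f"g{chrom_id}_{i + 1:04d}",
            extras=(f"synthetic gene {i + 1} on chromosome {chrom_id}",),
        ))
    return genes


def make_project(spec: SyntheticSpec, out_dir: Path | str) -> PlantedTruth:
    """Write a complete synthetic project directory; return its truth."""
    rng = random.Random(spec.seed)
    root = Path(out_dir)
    data = root / "_data"
    data.mkdir(parents=True, exist_ok=True)

    chrom_ids = [str(i + 1) for i in range(spec.n_chrom)]
    lengths = {cid: rng.randint(*spec.length_range) for cid in chrom_ids}
    chroms = formats.ChromosomeSet(tuple(lengths.items()))
    formats.write_chromosomes(chroms, data / "chromosomes")

    # genes: per-chromosome counts proportional to length
    total_len = sum(lengths.values())
    counts = {cid: (spec.n_genes * lengths[cid]) // total_len
              for cid in chrom_ids}
    short = spec.n_genes - sum(counts.values())
    for cid in chrom_ids[:short]:
        counts[cid] += 1
    genes: list[Feature] = []
    for cid in chrom_ids:
        genes.extend(_place_genes(rng, cid, lengths[cid], counts[cid],
                                  spec.mean_gene_len, spec.allow_overlap))
    formats.write_genes(genes, data / "genes")

    (data / "colors").write_text(formats.colours_to_text(EXTRA_COLOURS),
                                 encoding="utf-8")
    (data / "credits").write_text(
        f"Synthetic project generated by genomap.fixtures "
        f"(seed={spec.seed}).\nAll sequences and features are simulated.\n",
        encoding="utf-8",
    )
    for cid in chrom_ids:
        _write_fasta(data / f"{cid}.fasta", cid,
                     _random_sequence(lengths[cid],
                                      seed=rng.randrange(2**31)))

    truth = PlantedTruth(root=root, chrom_lengths=lengths, genes=genes)

    if "posn" in spec.track_recipe:
        folder = root / "Genes"
        folder.mkdir(exist_ok=True)
        path = folder / "genes.posn"
        formats.write_track(Track(name="genes", kind="posn", colour="clBlue",
                                  records=list(genes)), path)
        truth.track_paths["posn"] = path

    if "blast" in spec.track_recipe:
        folder = root / "Blast"
        folder.mkdir(exist_ok=True)
        hits: list[Feature] = []
        retained = 0
        # E-values planted to straddle the cut-off: even regions below,
        # odd regions above
        for i, g in enumerate(genes[: max(len(genes) // 2, 1)]):
            if i % 2 == 0:
                e1 = spec.blast_cutoff * 10 ** (-rng.uniform(1.0, 10.0))
                retained += 1
            else:
                e1 = spec.blast_cutoff * 10 ** (rng.uniform(1.0, 10.0))
            pairs = [(f"q{i + 1}", e1)]
            for extra in range(rng.randint(0, 2)):
                pairs.append((f"q{i + 1}_{extra + 2}",
                              pairs[-1][1] * 10 ** rng.uniform(0.5, 3.0)))
            hits.append(BlastHit(chrom_id=g.chrom_id, first_nt=g.first_nt,
                                 last_nt=g.last_nt, strand=".",
                                 feature_id="seq", pairs=tuple(pairs)))
        path = folder / "hits.blast"
        formats.write_track(Track(name="hits", kind="blast", colour="clRed",
                                  cutoff=spec.blast_cutoff, records=hits),
                            path)
        truth.track_paths["blast"] = path
        truth.blast_total = len(hits)
        truth.blast_retained = retained

    if "expr" in spec.track_recipe:
        folder = root / "Expression"
        folder.mkdir(exist_ok=True)
        rows = [
            ColouredFeature(chrom_id=g.chrom_id, first_nt=g.first_nt,
                            last_nt=g.last_nt, strand=g.strand,
                            feature_id=g.feature_id,
                            colour=rng.choice(["clRed", "clBlue"]))
            for g in genes
        ]
        path = folder / "expression.expr"
        formats.write_track(Track(name="expression", kind="expr",
                                  records=rows), path)
        truth.track_paths["expr"] = path

    if "freq" in spec.track_recipe:
        folder = root / "Density"
        folder.mkdir(exist_ok=True)
        rows = []
        for cid in chrom_ids:
            for first, last in convert.tile_windows(lengths[cid],
                                                    spec.window_nt):
                value = round(rng.uniform(0.0, 10.0), 3)
                truth.freq_values.append(value)
                rows.append(ValuedFeature(chrom_id=cid, first_nt=first,
                                          last_nt=last, strand=".",
                                          feature_id=f"{first}-{last}",
                                          value=value))
        path = folder / "recombination.freq"
        formats.write_track(Track(name="recombination", kind="freq",
                                  gradient=DEFAULT_GRADIENT, records=rows),
                            path)
        truth.track_paths["freq"] = path

    if "graph" in spec.track_recipe:
        folder = root / "Density"
        folder.mkdir(exist_ok=True)
        positions = []
        for _ in range(spec.n_positions):
            cid = rng.choice(chrom_ids)
            positions.append((cid, rng.randint(1, lengths[cid])))
        positions.sort()
        truth.positions = positions
        path = folder / "snp.graph"
        convert.positions_to_graph(positions, chroms,
                                   window_nt=spec.window_nt, out_path=path,
                                   colour="clNavy", name="snp")
        truth.track_paths["graph"] = path

    return truth


@dataclass
class WorkedExample:
    """The miniature demo project plus handles on its planted layout."""

    root: Path
    cluster_selection: RegionSelection
    cluster_ids: tuple[str, ...]
    menu_path: tuple[str, str]


def make_worked_example(out_dir: Path | str) -> WorkedExample:
    """A four-chromosome genome with a 10-gene cluster mid-chromosome 2.

    The cluster genes live in their own blue posn track (menu
    ``cluster_genes``), so selecting the cluster region reproduces the
    classic Gene List of exactly ten rows, and a whole-genome render
    shows four grey bars with the blue cluster blocks on bar 2.
    """
    root = Path(out_dir)
    data = root / "_data"
    data.mkdir(parents=True, exist_ok=True)

    lengths = {"1": 300_000, "2": 260_000, "3": 280_000, "4": 180_000}
    chroms = formats.ChromosomeSet(tuple(lengths.items()))
    formats.write_chromosomes(chroms, data / "chromosomes")

    cluster: list[Feature] = []
    for i in range(10):
        first = 120_000 + i * 2_000
        cluster.append(Feature(
            chrom_id="2", first_nt=first, last_nt=first + 1_199,
            strand="+" if i % 2 == 0 else "-",
            feature_id=f"CLU{i + 1:02d}",
            extras=(f"cluster gene {i + 1} (synthetic)",),
        ))
    background: list[Feature] = []
    for cid, length in lengths.items():
        for j in range(6):
            first = 10_000 + j * (length - 20_000) // 6
            if cid == "2" and 100_000 <= first <= 160_000:
                first = 170_000 + j * 10_000  # keep clear of the cluster span
            background.append(Feature(
                chrom_id=cid, first_nt=first, last_nt=first + 999,
                strand="+", feature_id=f"bg{cid}_{j + 1}",
                extras=("background gene (synthetic)",),
            ))
    formats.write_genes(cluster + background, data / "genes")
    (data / "colors").write_text(formats.colours_to_text(EXTRA_COLOURS),
                                 encoding="utf-8")
    (data / "credits").write_text(
        "Miniature synthetic demo project: four chromosomes with a ten-gene "
        "cluster in the middle of chromosome 2.\n", encoding="utf-8")
    rng = random.Random(42)
    for cid, length in lengths.items():
        _write_fasta(data / f"{cid}.fasta", cid,
                     _random_sequence(length, seed=rng.randrange(2**31)))

    folder = root / "cluster_genes"
    folder.mkdir(exist_ok=True)
    formats.write_track(Track(name="cluster_genes", kind="posn",
                              colour="clBlue", records=cluster),
                        folder / "cluster_genes.posn")

    return WorkedExample(
        root=root,
        cluster_selection=RegionSelection("2", 115_000, 145_000),
        cluster_ids=tuple(g.feature_id for g in cluster),
        menu_path=("cluster_genes", "cluster_genes"),
    )
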