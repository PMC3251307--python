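"""In-memory genome model, project-directory scanning and summary stats.

A map project is one directory tree.  Three special sub-folders whose
names begin with an underscore hold housekeeping data and never appear
in the menu tree:

``_data``
    chromosomes, genes, colors and credits tables plus optional
    per-chromosome ``id.fasta`` sequence files;
``_seqs``
    FASTA fragments extracted from user-selected regions;
``_stats``
    the per-chromosome gene summaries regenerated on every scan.

Every other sub-folder becomes a menu node; track files inside it
(``.posn``/``.blast``/``.expr``/``.freq``/``.graph``) become leaves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import formats
from .errors import FormatError, ProjectError
from .formats import ChromosomeSet, ColourTable, Feature, Track

logger = logging.getLogger("genomap")

SPECIAL_FOLDERS = ("_data", "_seqs", "_stats")
TRACK_EXTENSIONS = {"." + k: k for k in formats.TRACK_KINDS}


@dataclass
class Genome:
    """Chromosome backbone plus genes partitioned and sorted per chromosome."""

    chromosomes: ChromosomeSet
    genes_by_chrom: dict[str, list[Feature]]
    rejected: list[Feature] = field(default_factory=list)
    overhanging: list[Feature] = field(default_factory=list)
    fasta_available: dict[str, bool] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.genes_by_chrom.values())

    def all_genes(self) -> list[Feature]:
        """Genes in chromosome order, ascending start within each."""
        out: list[Feature] = []
        for cid in self.chromosomes.ids:
            out.extend(self.genes_by_chrom[cid])
        return out


def build_genome(chroms: ChromosomeSet, genes: list[Feature]) -> Genome:
    """Partition genes by chromosome and sort each list by first nt.

    Tolerant: genes naming an unknown chromosome go to ``rejected`` with
    a warning; genes overhanging the chromosome end are kept (clipped
    only at render time) and listed in ``overhanging``.
    """
    by_chrom: dict[str, list[Feature]] = {cid: [] for cid in chroms.ids}
    rejected: list[Feature] = []
    overhanging: list[Feature] = []
    for g in genes:
        if g.chrom_id not in by_chrom:
            logger.warning(
                "gene %r references unknown chromosome %r, rejected",
                g.feature_id, g.chrom_id,
            )
            rejected.append(g)
            continue
        if g.last_nt > chroms.length_of(g.chrom_id):
            logger.warning(
                "gene %r overhangs the end of chromosome %s (%d > %d)",
                g.feature_id, g.chrom_id, g.last_nt,
                chroms.length_of(g.chrom_id),
            )
            overhanging.append(g)
        by_chrom[g.chrom_id].append(g)
    for cid in by_chrom:
        by_chrom[cid].sort(key=lambda f: (f.first_nt, f.last_nt, f.feature_id))
    return Genome(chromosomes=chroms, genes_by_chrom=by_chrom,
                  rejected=rejected, overhanging=overhanging)


@dataclass(frozen=True)
class ChromStats:
    chrom_id: str
    length: int
    gene_count: int
    bp_per_gene: float | None   # chromosome bp per gene; None when no genes
    mean_gene_length: float | None


@dataclass(frozen=True)
class GenomeStats:
    rows: tuple[ChromStats, ...]

    @property
    def total_genes(self) -> int:
        return sum(r.gene_count for r in self.rows)


def compute_stats(genome: Genome, project_root: Path | str | None = None
                  ) -> GenomeStats:
    """Per-chromosome gene count and average base pairs per gene.

    ``bp_per_gene`` is chromosome length divided by gene count — how
    much chromosome each gene accounts for on average — and is reported
    as ``NA`` for gene-free chromosomes.  Mean gene length is emitted as
    an extra, clearly separate column.  When *project_root* is given the
    ``_stats/stats`` table and one ``id.genes.txt`` file per chromosome
    are (re)written.
    """
    rows = []
    for cid, length in genome.chromosomes.entries:
        genes = genome.genes_by_chrom[cid]
        n = len(genes)
        bp_per_gene = length / n if n else None
        mean_len = sum(g.length_nt for g in genes) / n if n else None
        rows.append(ChromStats(cid, length, n, bp_per_gene, mean_len))
    stats = GenomeStats(tuple(rows))

    if project_root is not None:
        stats_dir = Path(project_root) / "_stats"
        stats_dir.mkdir(parents=True, exist_ok=True)
        header = "chrom_id\tlength\tgene_count\tbp_per_gene\tmean_gene_length"
        lines = [header]
        for r in stats.rows:
            lines.append("\t".join([
                r.chrom_id, str(r.length), str(r.gene_count),
                f"{r.bp_per_gene:.1f}" if r.bp_per_gene is not None else "NA",
                f"{r.mean_gene_length:.1f}"
                if r.mean_gene_length is not None else "NA",
            ]))
        (stats_dir / "stats").write_text("\n".join(lines) + "\n",
                                         encoding="utf-8")
        for cid in genome.chromosomes.ids:
            (stats_dir / f"{cid}.genes.txt").write_text(
                formats.genes_to_text(genome.genes_by_chrom[cid]),
                encoding="utf-8",
            )
    return stats


# ---------------------------------------------------------------------------
# project catalogue
# ---------------------------------------------------------------------------


@dataclass
class MenuNode:
    """One menu folder: sub-menus plus track leaves, in sorted name order."""

    name: str
    children: dict[str, "MenuNode"] = field(default_factory=dict)
    leaves: dict[str, Path] = field(default_factory=dict)  # name -> file path
    broken: dict[str, str] = field(default_factory=dict)   # name -> reason


@dataclass
class ProjectCatalogue:
    """Menu tree mirroring a project directory, minus underscore folders."""

    root: Path
    menu: MenuNode
    credits_text: str = ""
    _track_cache: dict[Path, Track] = field(default_factory=dict, repr=False)

    def iter_leaves(self):
        """Yield (node_path tuple, file path) over the whole tree."""
        def walk(node: MenuNode, prefix: tuple[str, ...]):
            for name in sorted(node.leaves):
                yield prefix + (name,), node.leaves[name]
            for name in sorted(node.children):
                yield from walk(node.children[name], prefix + (name,))
        yield from walk(self.menu, ())

    def resolve(self, node_path) -> Path:
        """File path for a menu path like ``("TRI_genes", "TRI_genes")``.

        Accepts a tuple of names or a single ``"A/B/name"`` string.
        """
        if isinstance(node_path, str):
            node_path = tuple(p for p in node_path.replace("\\", "/").split("/")
                              if p)
        if not node_path:
            raise ProjectError("empty menu path")
        node = self.menu
        for part in node_path[:-1]:
            if part not in node.children:
                raise ProjectError(f"no menu folder {part!r}")
            node = node.children[part]
        leaf = node_path[-1]
        if leaf not in node.leaves:
            raise ProjectError(f"no track {leaf!r} under "
                               f"{'/'.join(node_path[:-1]) or '<root>'}")
        return node.leaves[leaf]


def scan_project(root: Path | str) -> ProjectCatalogue:
    """Scan a project directory into a menu catalogue.

    Creates the three special folders when absent.  Folders beginning
    with an underscore never become menu nodes.  Unreadable track files
    are marked broken and the scan continues.  The ``_stats`` summaries
    are regenerated whenever the chromosomes and genes tables parse.
    """
    root = Path(root)
    if not root.is_dir():
        raise ProjectError(f"project root {root} does not exist")
    for special in SPECIAL_FOLDERS:
        (root / special).mkdir(exist_ok=True)

    def scan_dir(path: Path, name: str) -> MenuNode:
        node = MenuNode(name=name)
        for entry in sorted(path.iterdir(), key=lambda p: p.name):
            if entry.name.startswith("_") or entry.name.startswith("."):
                continue
            if entry.is_dir():
                node.children[entry.name] = scan_dir(entry, entry.name)
            elif entry.suffix in TRACK_EXTENSIONS:
                leaf = entry.stem
                try:
                    entry.read_bytes()
                except OSError as exc:  # pragma: no cover - OS dependent
                    node.broken[leaf] = str(exc)
                    logger.warning("track %s unreadable: %s", entry, exc)
                    continue
                node.leaves[leaf] = entry
        return node

    menu = scan_dir(root, root.name)
    # top-level loose track files are not menu items; only folders make menus
    menu.leaves.clear()

    credits_path = root / "_data" / "credits"
    credits_text = ""
    if credits_path.is_file():
        credits_text = credits_path.read_text(encoding="utf-8")

    catalogue = ProjectCatalogue(root=root, menu=menu,
                                 credits_text=credits_text)
    try:
        genome = load_project_genome(catalogue)
    except (FormatError, ProjectError):
        genome = None
    if genome is not None:
        compute_stats(genome, root)
    return catalogue


def load_project_genome(catalogue: ProjectCatalogue) -> Genome:
    """Parse ``_data``'s chromosomes + genes tables into a Genome."""
    data = catalogue.root / "_data"
    chrom_path = data / "chromosomes"
    if not chrom_path.is_file():
        raise ProjectError(f"missing {chrom_path}")
    chroms = formats.parse_chromosomes(
        chrom_path.read_text(encoding="utf-8"))
    genes_path = data / "genes"
    genes: list[Feature] = []
    if genes_path.is_file():
        genes = formats.parse_genes(genes_path.read_text(encoding="utf-8"))
    genome = build_genome(chroms, genes)
    genome.fasta_available = {
        cid: (data / f"{cid}.fasta").is_file() for cid in chroms.ids
    }
    return genome


def load_project_colours(catalogue: ProjectCatalogue) -> ColourTable:
    """The colour table: built-ins overlaid with ``_data/colors`` if present."""
    colors_path = catalogue.root / "_data" / "colors"
    if colors_path.is_file():
        return formats.parse_colors(colors_path.read_text(encoding="utf-8"))
    return formats.parse_colors(None)


def load_track(catalogue: ProjectCatalogue, node_path) -> Track:
    """Load (and cache) the track behind a menu leaf.

    The parser is chosen by file extension; loading the same leaf twice
    returns the cached object.
    """
    path = catalogue.resolve(node_path)
    if path in catalogue._track_cache:
        logger.debug("track cache hit: %s", path)
        return catalogue._track_cache[path]
    kind = TRACK_EXTENSIONS.get(path.suffix)
    if kind is None:
        raise ProjectError(f"unknown track extension {path.suffix!r}")
    track = formats.parse_track(path.read_text(encoding="utf-8"),
                                name=path.stem, kind=kind)
    catalogue._track_cache[path] = track
    return track
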