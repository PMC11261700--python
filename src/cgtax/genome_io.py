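"""Reading, writing and validation of the reference-database formats.

The toolkit touches four plain-text formats: genome assemblies (FASTA),
per-genome core-gene multi-FASTA files (one file per genome, headers are
gene names drawn from a fixed 92-name catalogue), reference 16S rRNA
sequences (FASTA) and a taxonomy table (TSV with a header row, columns
``genome_id`` then ranks phylum..subspecies).

Coordinates in annotations are 0-based, half-open, with strand "+"/"-"
(BED convention).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ._kmers import revcomp

logger = logging.getLogger("cgtax")

#: Taxonomic ranks, highest to lowest, as used throughout the package.
RANKS = ("phylum", "class", "order", "family", "genus", "species", "subspecies")

_VALID_BASES = frozenset("ACGTN")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input."""


class TaxonomyError(ValueError):
    """Raised for malformed or inconsistent taxonomy tables."""


def default_catalogue() -> tuple[str, ...]:
    """The packaged 92-name core-gene catalogue (placeholder names).

    The real up-to-date bacterial core gene (UBCG) names may be substituted
    by passing any 92-name list wherever a catalogue is accepted.
    """
    text = resources.files("cgtax").joinpath("data/ubcg_catalogue.txt").read_text()
    return tuple(text.split())


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeRecord:
    """A genome assembly with optional core-gene / 16S annotations.

    ``core_gene_annotations`` maps gene name -> (contig_id, start, end,
    strand); ``rrna_16s`` is a list of (contig_id, start, end, strand).
    """

    genome_id: str
    contigs: list[tuple[str, str]]
    core_gene_annotations: dict[str, tuple[str, int, int, str]] | None = None
    rrna_16s: list[tuple[str, int, int, str]] | None = None
    taxon_label: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lengths: dict[str, int] = {}
        for cid, seq in self.contigs:
            extra = set(seq) - _VALID_BASES
            if extra:
                raise ValueError(
                    f"{self.genome_id}/{cid}: invalid bases {sorted(extra)!r}"
                )
            if cid in lengths:
                raise ValueError(f"{self.genome_id}: duplicate contig id {cid!r}")
            lengths[cid] = len(seq)
        anns: list[tuple[str, int, int, str]] = []
        if self.core_gene_annotations:
            anns.extend(self.core_gene_annotations.values())
        if self.rrna_16s:
            anns.extend(self.rrna_16s)
        for cid, start, end, strand in anns:
            if cid not in lengths:
                raise ValueError(f"{self.genome_id}: annotation on unknown contig {cid!r}")
            if not (0 <= start < end <= lengths[cid]):
                raise ValueError(
                    f"{self.genome_id}/{cid}: interval [{start}, {end}) outside contig"
                )
            if strand not in ("+", "-"):
                raise ValueError(f"{self.genome_id}: strand must be '+'/'-', got {strand!r}")

    @property
    def contig_map(self) -> dict[str, str]:
        return dict(self.contigs)

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    def region(self, contig_id: str, start: int, end: int, strand: str = "+") -> str:
        """Extract a (coding-strand) region; '-' returns the reverse complement."""
        seq = self.contig_map[contig_id][start:end]
        return revcomp(seq) if strand == "-" else seq

    def gene_sequences(self) -> dict[str, str]:
        """Annotated core-gene sequences on their coding strands."""
        if not self.core_gene_annotations:
            return {}
        return {
            name: self.region(*ann) for name, ann in self.core_gene_annotations.items()
        }

    def sixteen_s_sequences(self) -> list[str]:
        """Annotated 16S rRNA copies on their coding strands."""
        if not self.rrna_16s:
            return []
        return [self.region(*ann) for ann in self.rrna_16s]


@dataclass
class CoreGeneSet:
    """One genome's single-copy core genes, keyed by catalogue gene name."""

    genome_id: str
    genes: dict[str, str]
    catalogue: tuple[str, ...] = field(default_factory=default_catalogue)

    def __post_init__(self) -> None:
        self.catalogue = tuple(self.catalogue)
        cat = set(self.catalogue)
        for name, seq in self.genes.items():
            if name not in cat:
                raise ValueError(f"{self.genome_id}: gene {name!r} not in catalogue")
            if not seq:
                raise ValueError(f"{self.genome_id}: gene {name!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.genes.values())

    def concatenated(self) -> str:
        """Genes concatenated in catalogue order (for sketching)."""
        return "".join(self.genes[g] for g in self.catalogue if g in self.genes)


class TaxonomyTree:
    """Rank-labelled hierarchy phylum -> ... -> species (-> subspecies).

    Lineages are stored as tuples of node names aligned with ``RANKS``;
    every genome maps to exactly one leaf.  Node identity is the full path
    from the root, so equal names under different parents are distinct
    nodes.
    """

    def __init__(self) -> None:
        self._leaf_path: dict[str, tuple[str, ...]] = {}
        self._nodes: set[tuple[str, ...]] = set()

    def add_genome(self, genome_id: str, path: tuple[str, ...]) -> None:
        path = tuple(path)
        if not path or len(path) > len(RANKS):
            raise TaxonomyError(f"{genome_id}: lineage must have 1..{len(RANKS)} ranks")
        if any(not p for p in path):
            raise TaxonomyError(f"{genome_id}: empty rank name in {path!r}")
        known = self._leaf_path.get(genome_id)
        if known is not None:
            if known == path:
                return  # identical duplicate listing
            raise TaxonomyError(
                f"conflicting lineages for {genome_id!r}: {known!r} vs {path!r}"
            )
        self._leaf_path[genome_id] = path
        for i in range(1, len(path) + 1):
            self._nodes.add(path[:i])

    @property
    def n_nodes(self) -> int:
        """Number of distinct named nodes (root excluded)."""
        return len(self._nodes)

    @property
    def genome_ids(self) -> tuple[str, ...]:
        return tuple(self._leaf_path)

    def path_of(self, genome_id: str) -> tuple[str, ...]:
        return self._leaf_path[genome_id]

    def species_path(self, genome_id: str) -> tuple[str, ...]:
        """Lineage truncated at species (drops subspecies if present)."""
        return self._leaf_path[genome_id][: RANKS.index("species") + 1]

    @staticmethod
    def lca(paths: list[tuple[str, ...]]) -> tuple[str, ...]:
        """Longest common prefix of lineages; empty when even phyla differ."""
        if not paths:
            return ()
        prefix = list(paths[0])
        for p in paths[1:]:
            k = 0
            while k < min(len(prefix), len(p)) and prefix[k] == p[k]:
                k += 1
            prefix = prefix[:k]
            if not prefix:
                break
        return tuple(prefix)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse FASTA into (id, uppercased sequence) pairs, order preserved.

    Ids are the first whitespace-delimited token of each header.  An empty
    file yields an empty list; sequence data before the first header raises
    ``FastaFormatError`` naming the offending line.
    """
    path = Path(path)
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaFormatError(
                    f"{path}: line {lineno}: sequence data before first header"
                )
            break
    with _open_text(path) as handle:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]


def write_fasta(records, path, width: int = 80) -> None:
    """Write (id, sequence) pairs as FASTA, wrapping at ``width`` columns."""
    with open(path, "w") as out:
        for rid, seq in records:
            out.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def read_fastq(path) -> list[tuple[str, str]]:
    """Parse FASTQ (plain or gzip) into (id, uppercased sequence) pairs."""
    with _open_text(path) as handle:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fastq")]


def write_fastq(records, path) -> None:
    """Write (id, sequence) pairs as FASTQ with constant placeholder quality."""
    with open(path, "w") as out:
        for rid, seq in records:
            out.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# core-gene table and taxonomy
# ---------------------------------------------------------------------------

_FASTA_EXTS = (".fa", ".fasta", ".fna")


def load_core_gene_table(
    directory, catalogue: tuple[str, ...] | None = None
) -> dict[str, CoreGeneSet]:
    """Load one core-gene multi-FASTA per genome from ``directory``.

    File stems name genomes, headers name genes.  A gene name outside the
    catalogue raises; a gene appearing more than once in a genome is dropped
    entirely (single-copy rule) with a logged warning; a genome retaining
    zero genes is excluded with a warning.
    """
    if catalogue is None:
        catalogue = default_catalogue()
    cat = set(catalogue)
    directory = Path(directory)
    out: dict[str, CoreGeneSet] = {}
    files = sorted(p for p in directory.iterdir() if p.suffix in _FASTA_EXTS)
    for path in files:
        genome_id = path.stem
        records = read_fasta(path)
        unknown = sorted({name for name, _ in records} - cat)
        if unknown:
            raise ValueError(
                f"{path}: gene names not in the {len(catalogue)}-gene catalogue: {unknown}"
            )
        seen: dict[str, int] = {}
        for name, _ in records:
            seen[name] = seen.get(name, 0) + 1
        dupes = {name for name, cnt in seen.items() if cnt > 1}
        if dupes:
            logger.warning(
                "%s: dropping multi-copy genes %s (single-copy rule)",
                genome_id,
                sorted(dupes),
            )
        genes = {name: seq for name, seq in records if name not in dupes}
        if not genes:
            logger.warning("%s: no usable catalogued genes; genome excluded", genome_id)
            continue
        out[genome_id] = CoreGeneSet(genome_id=genome_id, genes=genes, catalogue=catalogue)
    return out


def load_taxonomy(path) -> TaxonomyTree:
    """Load the taxonomy TSV (columns genome_id, phylum..species[, subspecies]).

    Missing intermediate ranks are filled with "<parent>_unclassified"
    placeholder nodes; identical duplicate rows are deduplicated and
    conflicting lineages for one genome raise ``TaxonomyError``.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise TaxonomyError(f"{path}: no records") from None
    if df.empty:
        raise TaxonomyError(f"{path}: no records")
    if "genome_id" not in df.columns:
        raise TaxonomyError(f"{path}: missing required column 'genome_id'")
    ranks = [r for r in RANKS if r in df.columns]
    required = [r for r in RANKS[:-1]]  # subspecies optional
    missing = [r for r in required if r not in df.columns]
    if missing:
        raise TaxonomyError(f"{path}: missing rank columns {missing}")
    tree = TaxonomyTree()
    for _, row in df.iterrows():
        names: list[str] = []
        for rank in ranks:
            value = row[rank]
            if pd.isna(value) or not str(value).strip():
                if rank == "subspecies":
                    continue
                parent = names[-1] if names else "root"
                value = f"{parent}_unclassified"
            names.append(str(value).strip())
        tree.add_genome(str(row["genome_id"]).strip(), tuple(names))
    return tree


def write_taxonomy(tree: TaxonomyTree, path) -> None:
    """Write a TaxonomyTree back to the TSV layout ``load_taxonomy`` reads."""
    rows = []
    for gid in tree.genome_ids:
        p = tree.path_of(gid)
        row = {"genome_id": gid}
        row.update({rank: (p[i] if i < len(p) else "") for i, rank in enumerate(RANKS)})
        rows.append(row)
    pd.DataFrame(rows, columns=["genome_id", *RANKS]).to_csv(path, sep="\t", index=False)
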