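"""The genome classification cascade.

A query assembly is identified against a reference database in three
strictly ordered stages, the first satisfied rule deciding:

1. **ANI** — MinHash prescreen shortlists references; a reference with
   fragment ANI >= 95% at >= 20% query-fragment coverage assigns its
   species.
2. **16S rRNA** — the query's 16S (annotated, or recovered by homology
   search) must be at least 1300 bp; the best reference hit assigns its
   species when identity exceeds 98.7% and coverage of the reference 16S
   gene exceeds 90%.
3. **cgANI placement** — the 10 closest core-gene neighbours (MinHash on
   concatenated core genes) are compared by cgANI, a neighbor-joining tree
   is built on (100 - cgANI)/100 distances, the query is assigned the
   lowest common ancestor of its nearest clade's taxa (capped at genus),
   and it is registered as a new MSSC (Microbiome Strain Sequence Cluster)
   representative so that later queries can match it directly by ANI.

Threshold comparisons: ANI and its coverage are inclusive (>=), the 16S
identity and coverage gates are strict (>), and the 16S length gate is
inclusive at 1300 bp.  All thresholds are configurable.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode
from skbio.tree import nj as _skbio_nj

from . import ani as ani_mod
from . import cgani as cgani_mod
from . import sketch_prescreen as sketch_mod
from ._kmers import forward_kmer_hashes, revcomp
from .genome_io import (
    RANKS,
    CoreGeneSet,
    GenomeRecord,
    TaxonomyTree,
    load_core_gene_table,
    load_taxonomy,
    read_fasta,
    write_fasta,
    write_taxonomy,
)
from .pairwise_align import DEFAULT_SCORING, Scoring, semiglobal_align

logger = logging.getLogger("cgtax")

_GENUS_DEPTH = RANKS.index("genus") + 1
_RANK_SUFFIX = {"phylum": "_p", "class": "_c", "order": "_o", "family": "_f", "genus": "_g"}


class Stage(str, Enum):
    ANI = "ANI"
    SIXTEEN_S = "SIXTEEN_S"
    CGANI_PLACEMENT = "CGANI_PLACEMENT"


@dataclass
class CascadeConfig:
    """Thresholds and sizes governing the cascade decisions."""

    ani_min_pct: float = 95.0  # inclusive
    ani_min_coverage_pct: float = 20.0  # inclusive, query-side
    s16_min_identity_pct: float = 98.7  # strict
    s16_min_coverage_pct: float = 90.0  # strict, of the reference 16S gene
    s16_min_length: int = 1300  # inclusive
    ani_shortlist_size: int = 5
    placement_neighbours: int = 10
    fragment_length: int = ani_mod.DEFAULT_FRAGMENT_LENGTH
    min_frag_identity: float = ani_mod.DEFAULT_MIN_FRAG_IDENTITY
    min_cgani_pairs: int = cgani_mod.DEFAULT_MIN_PAIRS
    scoring: Scoring = DEFAULT_SCORING
    register_new_clusters: bool = True


DEFAULT_CONFIG = CascadeConfig()


@dataclass
class ClassificationOutcome:
    """Which stage decided, the assigned taxon, and the evidence values."""

    query_id: str
    stage: Stage
    assigned_taxon: tuple[str, ...]
    new_cluster_id: str | None = None
    evidence: dict = field(default_factory=dict)

    @property
    def assigned_taxon_str(self) -> str:
        return ";".join(self.assigned_taxon) if self.assigned_taxon else "root/unclassified"


class UnclassifiableError(ValueError):
    """Query has neither a usable 16S nor core genes after stages 1-2 fail."""


def decide_stage(
    ani_pct: float,
    ani_coverage_pct: float,
    s16_length: int,
    s16_identity_pct: float,
    s16_coverage_pct: float,
    cfg: CascadeConfig = DEFAULT_CONFIG,
) -> Stage:
    """Pure decision rule of the cascade given the evidence values.

    NaN evidence (e.g. undefined ANI) never satisfies a gate.
    """
    if (
        not math.isnan(ani_pct)
        and ani_pct >= cfg.ani_min_pct
        and ani_coverage_pct >= cfg.ani_min_coverage_pct
    ):
        return Stage.ANI
    if (
        s16_length >= cfg.s16_min_length
        and s16_identity_pct > cfg.s16_min_identity_pct
        and s16_coverage_pct > cfg.s16_min_coverage_pct
    ):
        return Stage.SIXTEEN_S
    return Stage.CGANI_PLACEMENT


# ---------------------------------------------------------------------------
# reference database
# ---------------------------------------------------------------------------


class ReferenceDB:
    """Genomes, core genes, 16S sequences, taxonomy and sketches.

    Every auxiliary map is keyed by a genome id present in ``genomes``;
    registration of new cluster representatives mutates the database in
    place and bumps ``next_cluster_serial``.
    """

    def __init__(self, taxonomy: TaxonomyTree | None = None) -> None:
        self.genomes: dict[str, GenomeRecord] = {}
        self.core_genes: dict[str, CoreGeneSet] = {}
        self.sixteen_s: dict[str, str] = {}
        self.taxonomy: TaxonomyTree = taxonomy or TaxonomyTree()
        self.sketches: dict[str, sketch_mod.Sketch] = {}
        self.core_sketches: dict[str, sketch_mod.Sketch] = {}
        self.next_cluster_serial: int = 1

    def __len__(self) -> int:
        return len(self.genomes)

    def add_reference(
        self,
        genome: GenomeRecord,
        core_genes: CoreGeneSet | None = None,
        sixteen_s: str | None = None,
        lineage: tuple[str, ...] | None = None,
    ) -> None:
        """Insert a reference genome, computing its sketches.

        ``sixteen_s`` defaults to the longest annotated 16S copy; the
        lineage (phylum..species[..subspecies]) defaults to the genome's
        existing leaf in the taxonomy, which must then already exist.
        """
        gid = genome.genome_id
        if gid in self.genomes:
            raise ValueError(f"genome {gid!r} already in database")
        if lineage is not None:
            self.taxonomy.add_genome(gid, tuple(lineage))
        else:
            self.taxonomy.path_of(gid)  # raises KeyError if absent
        self.genomes[gid] = genome
        seqs = [s for _, s in genome.contigs]
        self.sketches[gid] = sketch_mod.sketch(
            seqs, sketch_mod.GENOME_K, sketch_mod.GENOME_S, source_id=gid
        )
        if core_genes is not None and len(core_genes):
            self.core_genes[gid] = core_genes
            self.core_sketches[gid] = sketch_mod.sketch(
                core_genes.concatenated(),
                sketch_mod.CORE_K,
                sketch_mod.CORE_S,
                source_id=gid,
            )
        if sixteen_s is None:
            copies = genome.sixteen_s_sequences()
            if copies:
                sixteen_s = max(copies, key=len)
        if sixteen_s:
            self.sixteen_s[gid] = sixteen_s

    # -- persistence (directory of FASTA/TSV plus a JSON manifest) ---------

    def save(self, directory) -> None:
        directory = Path(directory)
        (directory / "genomes").mkdir(parents=True, exist_ok=True)
        (directory / "core_genes").mkdir(exist_ok=True)
        for gid, genome in self.genomes.items():
            write_fasta(genome.contigs, directory / "genomes" / f"{gid}.fasta")
        for gid, genes in self.core_genes.items():
            write_fasta(sorted(genes.genes.items()), directory / "core_genes" / f"{gid}.fasta")
        write_fasta(sorted(self.sixteen_s.items()), directory / "sixteen_s.fasta")
        write_taxonomy(self.taxonomy, directory / "taxonomy.tsv")
        manifest = {
            "format_version": 1,
            "next_cluster_serial": self.next_cluster_serial,
            "catalogue": list(
                next(iter(self.core_genes.values())).catalogue
            )
            if self.core_genes
            else None,
        }
        with open(directory / "manifest.json", "w") as out:
            json.dump(manifest, out, indent=2)

    @classmethod
    def load(cls, directory) -> "ReferenceDB":
        directory = Path(directory)
        with open(directory / "manifest.json") as handle:
            manifest = json.load(handle)
        taxonomy = load_taxonomy(directory / "taxonomy.tsv")
        db = cls(taxonomy=taxonomy)
        catalogue = tuple(manifest["catalogue"]) if manifest.get("catalogue") else None
        gene_sets = (
            load_core_gene_table(directory / "core_genes", catalogue)
            if (directory / "core_genes").is_dir()
            else {}
        )
        sixteen = (
            dict(read_fasta(directory / "sixteen_s.fasta"))
            if (directory / "sixteen_s.fasta").exists()
            else {}
        )
        for path in sorted((directory / "genomes").glob("*.fasta")):
            gid = path.stem
            genome = GenomeRecord(genome_id=gid, contigs=read_fasta(path))
            db.add_reference(
                genome,
                core_genes=gene_sets.get(gid),
                sixteen_s=sixteen.get(gid),
                lineage=None,
            )
        db.next_cluster_serial = int(manifest["next_cluster_serial"])
        return db


# ---------------------------------------------------------------------------
# 16S extraction and decision
# ---------------------------------------------------------------------------

_16S_SEED_K = 21
_16S_MIN_IDENTITY = 80.0


def extract_16s(
    query: GenomeRecord,
    reference_16s: list[str],
    scoring: Scoring = DEFAULT_SCORING,
) -> tuple[str, int] | None:
    """The query's 16S rRNA sequence and its length, if one can be found.

    Annotated copies are returned directly (the longest, when several).
    Otherwise a homology search seeds candidate windows by exact 21-mers
    shared with each reference 16S, aligns the window semi-globally, and
    returns the best-matching contig region iff its identity is >= 80%.
    The 1300 bp length gate is the caller's job.
    """
    copies = query.sixteen_s_sequences()
    if copies:
        best = max(copies, key=len)
        return best, len(best)
    if not reference_16s:
        return None

    best_hit: tuple[float, str] | None = None
    for ref in reference_16s:
        ref_hashes = set(int(h) for h in forward_kmer_hashes(ref, _16S_SEED_K))
        for _cid, contig in query.contigs:
            if len(contig) < _16S_SEED_K:
                continue
            for strand in ("+", "-"):
                seq = contig if strand == "+" else revcomp(contig)
                hashes = forward_kmer_hashes(seq, _16S_SEED_K)
                hit_pos = [i for i, h in enumerate(hashes) if int(h) in ref_hashes]
                if not hit_pos:
                    continue
                # pad the seeded span only slightly: trailing window bases
                # must be consumed by the overlap alignment, so boundary
                # precision of the extracted region is about +/- pad
                pad = 25
                lo = max(0, hit_pos[0] - pad)
                hi = min(len(seq), hit_pos[-1] + _16S_SEED_K + pad)
                window = seq[lo:hi]
                res = semiglobal_align(window, ref, scoring)
                if res.identity_pct >= _16S_MIN_IDENTITY:
                    region = window[res.query_span[0] : res.query_span[1]]
                    if best_hit is None or res.identity_pct > best_hit[0]:
                        best_hit = (res.identity_pct, region)
    if best_hit is None:
        return None
    return best_hit[1], len(best_hit[1])


def best_sixteen_s_hit(
    q16: str, db: ReferenceDB, scoring: Scoring = DEFAULT_SCORING
) -> tuple[str, float, float] | None:
    """Best reference by 16S identity: (genome_id, identity_pct, coverage_pct).

    Coverage is aligned columns as a percentage of the reference 16S
    length, so a short query cannot fully cover a full-length reference.
    """
    best: tuple[str, float, float] | None = None
    for gid in sorted(db.sixteen_s):
        ref = db.sixteen_s[gid]
        res = semiglobal_align(q16, ref, scoring)
        coverage = 100.0 * res.aligned_columns / len(ref)
        if best is None or res.identity_pct > best[1]:
            best = (gid, res.identity_pct, coverage)
    return best


def sixteen_s_decision(
    q16: str, db: ReferenceDB, cfg: CascadeConfig = DEFAULT_CONFIG
) -> tuple[str, float, float] | None:
    """The species-level 16S hit, or None when the gates are not met."""
    if len(q16) < cfg.s16_min_length:
        raise ValueError(f"16S query shorter than {cfg.s16_min_length} bp")
    best = best_sixteen_s_hit(q16, db, cfg.scoring)
    if best is None:
        return None
    _gid, identity, coverage = best
    if identity > cfg.s16_min_identity_pct and coverage > cfg.s16_min_coverage_pct:
        return best
    return None


# ---------------------------------------------------------------------------
# tree placement
# ---------------------------------------------------------------------------


def nj_tree(dist: pd.DataFrame) -> TreeNode:
    """Neighbor-joining tree from a labelled symmetric distance matrix."""
    if dist.shape[0] < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if dist.isna().any().any():
        bad = [str(c) for c in dist.columns[dist.isna().any()]]
        raise ValueError(
            f"distance matrix contains NA for taxa {bad}; drop the offending taxon"
        )
    dm = DistanceMatrix(dist.to_numpy(float), [str(c) for c in dist.columns])
    return _skbio_nj(dm)


def lca_assign(
    tree: TreeNode,
    query_label: str,
    neighbour_taxa: dict[str, tuple[str, ...]],
) -> tuple[str, ...]:
    """Taxonomy path for a placed query: LCA of its nearest clade, capped at genus.

    The (unrooted) placement tree is first rooted at the tip farthest from
    the query, so the query's enclosing clades reflect its actual
    neighbourhood rather than the arbitrary root of the neighbor-joining
    output.  The walk then ascends from the query tip to the smallest
    enclosing clade containing at least one neighbour with taxonomy and
    returns the deepest rank shared by all those neighbours (never deeper
    than genus; species is never assigned by placement).  With no
    taxonomized neighbour anywhere, returns the empty path (rendered as
    "root/unclassified").
    """
    query_tip = tree.find(query_label)
    others = [t for t in tree.tips() if t.name != query_label]
    if others:
        far = max(others, key=lambda t: (query_tip.distance(t), t.name))
        if far.parent is not None and not far.parent.is_root():
            tree = tree.root_at(far.parent)
    node = tree.find(query_label)
    while node is not None:
        labels = [
            tip.name
            for tip in node.tips()
            if tip.name != query_label and tip.name in neighbour_taxa
        ]
        if labels:
            paths = [neighbour_taxa[l][:_GENUS_DEPTH] for l in labels]
            return TaxonomyTree.lca(paths)
        node = node.parent
    return ()


# ---------------------------------------------------------------------------
# cluster registration
# ---------------------------------------------------------------------------


def register_cluster(
    db: ReferenceDB,
    query: GenomeRecord,
    query_genes: CoreGeneSet,
    assigned_path: tuple[str, ...],
) -> str:
    """Mint an MSSC placeholder species for the query and add it to the database.

    The name is "MSSCM" + zero-padded 8-digit serial + "_s" (the style of
    the published example MSSCM00191198_s).  Ranks between the assigned
    path and species are filled with rank-suffixed placeholders derived
    from the same serial.  The query becomes a reference representative
    (sketches, core genes, 16S if annotated) so subsequent queries can
    match it at the ANI stage.
    """
    if query.genome_id in db.genomes:
        raise ValueError(f"genome {query.genome_id!r} already registered")
    serial = db.next_cluster_serial
    base = f"MSSCM{serial:08d}"
    name = f"{base}_s"
    lineage = list(assigned_path[:_GENUS_DEPTH])
    for rank in RANKS[len(lineage) : _GENUS_DEPTH]:
        lineage.append(f"{base}{_RANK_SUFFIX[rank]}")
    lineage.append(name)
    db.add_reference(query, core_genes=query_genes, lineage=tuple(lineage))
    db.next_cluster_serial = serial + 1
    return name


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------


def classify_genome(
    query: GenomeRecord,
    query_genes: CoreGeneSet | None,
    db: ReferenceDB,
    cfg: CascadeConfig = DEFAULT_CONFIG,
) -> ClassificationOutcome:
    """Run the full cascade for one query against the reference database."""
    if not len(db):
        raise ValueError("reference database is empty")
    evidence: dict = {}

    # --- stage 1: MinHash prescreen, then fragment ANI -------------------
    qsketch = sketch_mod.sketch(
        [s for _, s in query.contigs],
        sketch_mod.GENOME_K,
        sketch_mod.GENOME_S,
        source_id=query.genome_id,
    )
    shortlist = sketch_mod.top_hits(
        qsketch, list(db.sketches.values()), cfg.ani_shortlist_size
    )
    best_ani: ani_mod.ANIResult | None = None
    for gid, _dist in shortlist:
        res = ani_mod.orthoani(
            query,
            db.genomes[gid],
            cfg.fragment_length,
            cfg.min_frag_identity,
            cfg.scoring,
        )
        if math.isnan(res.ani_pct):
            continue
        if (
            best_ani is None
            or res.ani_pct > best_ani.ani_pct
            or (res.ani_pct == best_ani.ani_pct and res.ref_id < best_ani.ref_id)
        ):
            best_ani = res
    if best_ani is not None:
        evidence["ani_pct"] = best_ani.ani_pct
        evidence["ani_coverage_pct"] = best_ani.coverage_pct
        evidence["ani_best_ref"] = best_ani.ref_id
        if (
            best_ani.ani_pct >= cfg.ani_min_pct
            and best_ani.coverage_pct >= cfg.ani_min_coverage_pct
        ):
            return ClassificationOutcome(
                query_id=query.genome_id,
                stage=Stage.ANI,
                assigned_taxon=db.taxonomy.species_path(best_ani.ref_id),
                evidence=evidence,
            )

    # --- stage 2: 16S rRNA ------------------------------------------------
    extracted = extract_16s(query, list(db.sixteen_s.values()), cfg.scoring)
    if extracted is not None:
        q16, length = extracted
        evidence["s16_length"] = length
        if length >= cfg.s16_min_length and db.sixteen_s:
            best16 = best_sixteen_s_hit(q16, db, cfg.scoring)
            if best16 is not None:
                gid, identity, coverage = best16
                evidence["s16_identity_pct"] = identity
                evidence["s16_coverage_pct"] = coverage
                evidence["s16_best_ref"] = gid
                if (
                    identity > cfg.s16_min_identity_pct
                    and coverage > cfg.s16_min_coverage_pct
                ):
                    return ClassificationOutcome(
                        query_id=query.genome_id,
                        stage=Stage.SIXTEEN_S,
                        assigned_taxon=db.taxonomy.species_path(gid),
                        evidence=evidence,
                    )

    # --- stage 3: cgANI placement ----------------------------------------
    if query_genes is None or not len(query_genes):
        if extracted is None:
            raise UnclassifiableError(
                f"{query.genome_id}: unclassifiable: no 16S and no core genes"
            )
        raise UnclassifiableError(
            f"{query.genome_id}: no core genes for cgANI placement"
        )
    neighbours = _core_gene_neighbours(query_genes, db, cfg.placement_neighbours)
    cg_table: dict[str, float] = {}
    usable: list[str] = []
    for gid in neighbours:
        try:
            r = cgani_mod.cgani(
                query_genes, db.core_genes[gid], cfg.scoring, cfg.min_cgani_pairs
            )
        except ValueError:
            continue
        cg_table[gid] = r.cgani_pct
        usable.append(gid)
    evidence["cgani"] = cg_table

    assigned: tuple[str, ...] = ()
    if len(usable) >= 2:
        dist = _placement_distances(query_genes, usable, cg_table, db, cfg)
        tree = nj_tree(dist)
        evidence["placement_tree_newick"] = str(tree).strip()
        neighbour_taxa = {gid: db.taxonomy.path_of(gid) for gid in usable}
        assigned = lca_assign(tree, query.genome_id, neighbour_taxa)
    elif len(usable) == 1:
        assigned = db.taxonomy.path_of(usable[0])[:_GENUS_DEPTH]
    evidence["lca_rank"] = RANKS[len(assigned) - 1] if assigned else "none"

    new_id = None
    if cfg.register_new_clusters:
        new_id = register_cluster(db, query, query_genes, assigned)
    return ClassificationOutcome(
        query_id=query.genome_id,
        stage=Stage.CGANI_PLACEMENT,
        assigned_taxon=assigned,
        new_cluster_id=new_id,
        evidence=evidence,
    )


def _core_gene_neighbours(
    query_genes: CoreGeneSet, db: ReferenceDB, n: int
) -> list[str]:
    """Top-n closest references by MinHash on concatenated core genes."""
    if not db.core_sketches:
        return []
    qsketch = sketch_mod.sketch(
        query_genes.concatenated(),
        sketch_mod.CORE_K,
        sketch_mod.CORE_S,
        source_id=query_genes.genome_id,
    )
    return [gid for gid, _d in sketch_mod.top_hits(qsketch, list(db.core_sketches.values()), n)]


def _placement_distances(
    query_genes: CoreGeneSet,
    neighbours: list[str],
    query_cgani: dict[str, float],
    db: ReferenceDB,
    cfg: CascadeConfig,
) -> pd.DataFrame:
    """cgANI distance matrix over {query} + neighbours, dropping NA taxa."""
    labels = [query_genes.genome_id, *neighbours]
    n = len(labels)
    d = np.zeros((n, n))
    for i, gid in enumerate(neighbours, start=1):
        d[0, i] = d[i, 0] = cgani_mod.cgani_distance(query_cgani[gid])
    for i in range(1, n):
        for j in range(i + 1, n):
            try:
                r = cgani_mod.cgani(
                    db.core_genes[labels[i]],
                    db.core_genes[labels[j]],
                    cfg.scoring,
                    cfg.min_cgani_pairs,
                )
                d[i, j] = d[j, i] = cgani_mod.cgani_distance(r)
            except ValueError:
                d[i, j] = d[j, i] = np.nan
    df = pd.DataFrame(d, index=labels, columns=labels)
    # drop neighbours causing NA cells (never the query) until clean
    while df.isna().any().any():
        na_counts = df.isna().sum()
        na_counts[labels[0]] = -1
        worst = na_counts.idxmax()
        df = df.drop(index=worst, columns=worst)
    return df
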