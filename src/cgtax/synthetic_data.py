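"""Deterministic simulation of genomes, core genes, 16S copies and reads.

Every other module is testable offline against this generator: it builds
random ancestral genomes with embedded single-copy core genes and a
16S-like locus, evolves them along branches of known length under the
Jukes-Cantor model (closed-form expected identity
p = 1/4 + 3/4 * exp(-4d/3) makes property tests analytic), and samples
single-end reads with known per-read ground truth.

All randomness flows through ``numpy.random.default_rng(seed)``, so equal
seeds reproduce byte-identical outputs.  The 16S-like locus is evolved
from a fixed in-package pseudo-sequence of the canonical 1542 bp length;
it makes no claim of biological realism beyond length and conservation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._kmers import revcomp
from .genome_io import CoreGeneSet, GenomeRecord, default_catalogue

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Canonical 16S rRNA gene length used for the embedded 16S-like locus.
SIXTEEN_S_LENGTH = 1542

#: Default gene-length range (bp) for simulated core genes; bacterial core
#: genes span roughly this range with a median near 1 kb.
DEFAULT_GENE_LENGTH_RANGE = (300, 1500)

#: Default per-genome divergence of the 16S-like locus from the shared
#: packaged pseudo-ancestor (16S is far more conserved than the genome).
DEFAULT_16S_DIVERGENCE = 0.02


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def _sixteen_s_ancestor() -> str:
    # fixed internal seed: the pseudo-16S is part of the package definition
    return _random_seq(np.random.default_rng(160516), SIXTEEN_S_LENGTH)


_SIXTEEN_S = _sixteen_s_ancestor()


def jc_expected_identity(d: float) -> float:
    """Expected per-site identity after a Jukes-Cantor branch of length d."""
    return 0.25 + 0.75 * math.exp(-4.0 * d / 3.0)


def substitution_probability(d: float, model: str = "jc") -> float:
    """Per-site substitution probability for a branch of length d."""
    if model == "jc":
        return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    if model == "uniform":
        return d
    raise ValueError(f"unknown substitution model {model!r}")


@dataclass
class SimulationManifest:
    """Parameters sufficient to regenerate a simulation byte-identically."""

    seed: int
    species_tree: str = ""  # Newick, branch lengths in expected subst./site
    genomes: list[dict] = field(default_factory=list)
    readsets: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as out:
            json.dump(asdict(self), out, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationManifest":
        with open(path) as handle:
            return cls(**json.load(handle))


def mutate(seq: str, p: float, rng: np.random.Generator) -> str:
    """Substitute each A/C/G/T site with probability p to a different base."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    acgt = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )
    hit = acgt & (rng.random(arr.size) < p)
    idx = np.where(hit)[0]
    if idx.size:
        code = np.zeros(arr.size, np.uint8)
        for v, b in enumerate(b"ACGT"):
            code[arr == b] = v
        new = (code[idx] + rng.integers(1, 4, idx.size)) % 4
        arr[idx] = _BASES[new]
    return arr.tobytes().decode("ascii")


def simulate_ancestor(
    n_genes: int = 92,
    gene_length_range: tuple[int, int] = DEFAULT_GENE_LENGTH_RANGE,
    genome_length: int | None = None,
    seed: int = 0,
    *,
    genome_id: str = "ancestor",
    gene_lengths: list[int] | None = None,
    catalogue: tuple[str, ...] | None = None,
    sixteen_s_divergence: float = DEFAULT_16S_DIVERGENCE,
) -> tuple[GenomeRecord, CoreGeneSet]:
    """A random single-contig genome with embedded core genes and a 16S locus.

    Genes (and the 16S-like locus) are placed non-overlapping at recorded
    coordinates with random strands, separated by random intergenic
    spacers.  ``genome_length`` must leave at least 2000 bp of intergenic
    slack; by default it adds ~15% slack plus 2000 bp.
    """
    rng = np.random.default_rng(seed)
    if catalogue is None:
        catalogue = default_catalogue()
    if n_genes > len(catalogue):
        raise ValueError(f"at most {len(catalogue)} genes available in the catalogue")
    if gene_lengths is None:
        lo, hi = gene_length_range
        gene_lengths = [int(x) for x in rng.integers(lo, hi + 1, n_genes)]
    elif len(gene_lengths) != n_genes:
        raise ValueError("gene_lengths must have n_genes entries")
    features = sum(gene_lengths) + SIXTEEN_S_LENGTH
    if genome_length is None:
        genome_length = int(features * 1.15) + 2000
    slack = genome_length - features
    if slack < 2000:
        raise ValueError(
            f"genome_length {genome_length} leaves {slack} bp of intergenic slack (< 2000)"
        )

    # random intergenic spacer widths summing to the slack
    n_slots = n_genes + 2
    cuts = np.sort(rng.integers(0, slack + 1, n_slots - 1))
    gaps = np.diff(np.concatenate(([0], cuts, [slack])))

    names = list(catalogue[:n_genes])
    pieces: list[str] = []
    annotations: dict[str, tuple[str, int, int, str]] = {}
    genes: dict[str, str] = {}
    pos = 0
    sixteen_s_slot = int(rng.integers(0, n_genes + 1))
    sixteen_s_seq = mutate(
        _SIXTEEN_S, substitution_probability(sixteen_s_divergence), rng
    )
    rrna: list[tuple[str, int, int, str]] = []

    def _place(seq: str, strand: str) -> tuple[int, int]:
        nonlocal pos
        placed = revcomp(seq) if strand == "-" else seq
        pieces.append(placed)
        span = (pos, pos + len(seq))
        pos += len(seq)
        return span

    for slot in range(n_genes + 1):
        gap = int(gaps[slot])
        pieces.append(_random_seq(rng, gap))
        pos += gap
        if slot == sixteen_s_slot:
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = _place(sixteen_s_seq, strand)
            rrna.append(("contig_1", start, end, strand))
        if slot < n_genes:
            gene_seq = _random_seq(rng, gene_lengths[slot])
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = _place(gene_seq, strand)
            annotations[names[slot]] = ("contig_1", start, end, strand)
            genes[names[slot]] = gene_seq
    pieces.append(_random_seq(rng, int(gaps[-1])))

    genome = GenomeRecord(
        genome_id=genome_id,
        contigs=[("contig_1", "".join(pieces))],
        core_gene_annotations=annotations,
        rrna_16s=rrna,
    )
    gene_set = CoreGeneSet(genome_id=genome_id, genes=genes, catalogue=catalogue)
    return genome, gene_set


def evolve(
    genome: GenomeRecord,
    genes: CoreGeneSet,
    d: float,
    model: str = "jc",
    indel_rate: float = 0.0,
    seed: int = 0,
    *,
    genome_id: str | None = None,
) -> tuple[GenomeRecord, CoreGeneSet]:
    """Evolve a genome (and its gene set) along a branch of length ``d``.

    Every site is substituted independently with the model's per-site
    probability; optional indels (small, 1-10 bp) are placed in intergenic
    regions only, so gene coordinates stay consistent.  d=0 returns an
    identical copy.
    """
    if not 0.0 <= d <= 0.5:
        raise ValueError("branch length must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    p = substitution_probability(d, model)
    new_id = genome_id or f"{genome.genome_id}_d{d}"

    contigs = []
    for cid, seq in genome.contigs:
        contigs.append((cid, mutate(seq, p, rng) if p > 0 else seq))

    record = GenomeRecord(
        genome_id=new_id,
        contigs=contigs,
        core_gene_annotations=dict(genome.core_gene_annotations or {}) or None,
        rrna_16s=list(genome.rrna_16s or []) or None,
        taxon_label=genome.taxon_label,
    )
    if indel_rate > 0.0:
        record = _apply_intergenic_indels(record, indel_rate, rng)
    new_genes = CoreGeneSet(
        genome_id=new_id, genes=record.gene_sequences(), catalogue=genes.catalogue
    )
    return record, new_genes


def _apply_intergenic_indels(
    genome: GenomeRecord, rate: float, rng: np.random.Generator
) -> GenomeRecord:
    """Insert/delete short tracts between annotated features, shifting coordinates."""
    out_contigs: list[tuple[str, str]] = []
    gene_anns = dict(genome.core_gene_annotations or {})
    rrna = list(genome.rrna_16s or [])
    for cid, seq in genome.contigs:
        feats = sorted(
            [(s, e, ("gene", name)) for name, (c, s, e, st) in gene_anns.items() if c == cid]
            + [(s, e, ("rrna", i)) for i, (c, s, e, st) in enumerate(rrna) if c == cid]
        )
        pieces: list[str] = []
        shift: dict = {}
        pos = 0
        newpos = 0
        for s, e, key in feats:
            inter = seq[pos:s]
            n_events = rng.poisson(rate * max(len(inter), 1))
            for _ in range(n_events):
                size = int(rng.integers(1, 11))
                if rng.random() < 0.5 and len(inter) > size:
                    cut = int(rng.integers(0, len(inter) - size))
                    inter = inter[:cut] + inter[cut + size :]
                else:
                    at = int(rng.integers(0, len(inter) + 1))
                    inter = inter[:at] + _random_seq(rng, size) + inter[at:]
            pieces.append(inter)
            newpos += len(inter)
            shift[key] = newpos - s
            pieces.append(seq[s:e])
            newpos += e - s
            pos = e
        pieces.append(seq[pos:])
        out_contigs.append((cid, "".join(pieces)))
        for name, (c, s, e, st) in list(gene_anns.items()):
            if c == cid:
                delta = shift[("gene", name)]
                gene_anns[name] = (c, s + delta, e + delta, st)
        for i, (c, s, e, st) in enumerate(rrna):
            if c == cid:
                delta = shift[("rrna", i)]
                rrna[i] = (c, s + delta, e + delta, st)
    return GenomeRecord(
        genome_id=genome.genome_id,
        contigs=out_contigs,
        core_gene_annotations=gene_anns or None,
        rrna_16s=rrna or None,
        taxon_label=genome.taxon_label,
    )


def simulate_reads(
    sources: list[tuple[GenomeRecord, float]],
    n_reads: int | None = None,
    depth: float | None = None,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Single-end reads drawn uniformly along each source genome.

    ``sources`` pairs genomes with mixture proportions (must sum to 1);
    reads per genome = round(proportion * n_reads).  Strand is drawn
    uniformly; per-base substitution errors occur at ``error_rate``.
    Returns the reads and a truth table (read_id, genome_id, contig, pos,
    strand).
    """
    props = [p for _, p in sources]
    if abs(sum(props) - 1.0) > 1e-9:
        raise ValueError("mixture proportions must sum to 1")
    if (n_reads is None) == (depth is None):
        raise ValueError("specify exactly one of n_reads or depth")
    if n_reads is None:
        total_len = sum(g.total_length for g, _ in sources)
        n_reads = int(round(depth * total_len / read_length))
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    serial = 0
    for genome, prop in sources:
        count = int(round(prop * n_reads))
        contigs = [(cid, s) for cid, s in genome.contigs if len(s) >= read_length]
        if not contigs:
            raise ValueError(
                f"{genome.genome_id}: read length {read_length} exceeds every contig"
            )
        weights = np.array([len(s) - read_length + 1 for _, s in contigs], float)
        weights /= weights.sum()
        choice = rng.choice(len(contigs), size=count, p=weights)
        for ci in choice:
            cid, cseq = contigs[ci]
            pos = int(rng.integers(0, len(cseq) - read_length + 1))
            seq = cseq[pos : pos + read_length]
            if error_rate > 0.0:
                seq = mutate(seq, error_rate, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                seq = revcomp(seq)
            rid = f"read_{serial:07d}"
            serial += 1
            reads.append((rid, seq))
            truth_rows.append(
                {
                    "read_id": rid,
                    "genome_id": genome.genome_id,
                    "contig": cid,
                    "pos": pos,
                    "strand": strand,
                }
            )
    truth = pd.DataFrame(truth_rows, columns=["read_id", "genome_id", "contig", "pos", "strand"])
    return reads, truth
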