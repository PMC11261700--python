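"""Core-gene metagenome profiling.

Species presence and abundance in a read set are estimated against a
core-gene reference: a k-mer index (k=35) over every species' core genes
screens for candidate species, reads are then assigned to the
best-matching core gene (exact-seed placement with semi-global alignment
fallback), and a species is retained only when its reads cover at least
25% of the concatenated length of its core genes (breadth of coverage,
computed by exact interval union).  Abundance is the mapped read count
normalized by the species' total core-gene length (reads per base),
renormalized to sum to one over the retained species.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field

from scipy import stats

from ._kmers import iter_kmers, mix64, revcomp
from .genome_io import CoreGeneSet
from .pairwise_align import DEFAULT_SCORING, Scoring, semiglobal_align

logger = logging.getLogger("cgtax")

DEFAULT_K = 35
DEFAULT_MIN_HIT_READS = 10
DEFAULT_MIN_BREADTH_PCT = 25.0
#: Read-placement acceptance gates (stand-ins for a short-read mapper's
#: defaults): alignment identity and the fraction of the read aligned.
DEFAULT_MAP_MIN_IDENTITY = 90.0
DEFAULT_MAP_MIN_READ_FRACTION = 0.8
#: At most this many candidate genes are fully evaluated per read.
_MAX_READ_CANDIDATES = 20


@dataclass
class SpeciesMeta:
    gene_names: tuple[str, ...]
    gene_lengths: dict[str, int]
    total_core_length: int


@dataclass
class KmerIndex:
    """Canonical 35-mer index over species core genes.

    ``entries`` maps a 64-bit canonical k-mer hash to the set of species
    containing it (set semantics, no LCA collapsing); ``unique`` is the
    derived hash -> species map restricted to single-species k-mers, used
    by the candidate screen.
    """

    k: int
    entries: dict[int, frozenset[str]]
    species_meta: dict[str, SpeciesMeta]
    unique: dict[int, str] = field(repr=False, default_factory=dict)


@dataclass(frozen=True)
class ProfileRow:
    species_id: str
    read_count: int
    breadth_pct: float
    abundance_raw: float
    abundance_rel: float


@dataclass
class ProfileResult:
    """Retained species rows plus the species dropped by the breadth filter."""

    rows: list[ProfileRow]
    dropped: list[tuple[str, float]]
    n_mapped_reads: int = 0
    n_unmapped_reads: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([r.__dict__ for r in self.rows])


def build_kmer_index(core_genes: dict[str, CoreGeneSet], k: int = DEFAULT_K) -> KmerIndex:
    """Index the canonical k-mers of every species' core genes.

    k must be odd (a canonical k-mer cannot equal its own reverse
    complement) and within [21, 51].
    """
    if k % 2 == 0 or not 21 <= k <= 51:
        raise ValueError(f"k must be odd and in [21, 51], got {k}")
    if not core_genes:
        raise ValueError("empty core-gene set")
    acc: dict[int, set[str]] = defaultdict(set)
    meta: dict[str, SpeciesMeta] = {}
    for sid, gene_set in core_genes.items():
        lengths = {g: len(s) for g, s in gene_set.genes.items()}
        meta[sid] = SpeciesMeta(
            gene_names=tuple(sorted(gene_set.genes)),
            gene_lengths=lengths,
            total_core_length=sum(lengths.values()),
        )
        for seq in gene_set.genes.values():
            for _pos, code, _fwd in iter_kmers(seq, k):
                acc[mix64(code)].add(sid)
    entries = {h: frozenset(s) for h, s in acc.items()}
    unique = {h: next(iter(s)) for h, s in entries.items() if len(s) == 1}
    return KmerIndex(k=k, entries=entries, species_meta=meta, unique=unique)


def screen_candidates(
    reads: list[tuple[str, str]],
    idx: KmerIndex,
    min_hit_reads: int = DEFAULT_MIN_HIT_READS,
) -> list[str]:
    """Species with >= ``min_hit_reads`` reads containing a species-unique k-mer."""
    if not reads:
        raise ValueError("no reads supplied")
    hit_reads: dict[str, int] = defaultdict(int)
    for _rid, seq in reads:
        species_hit: set[str] = set()
        for _pos, code, _fwd in iter_kmers(seq, idx.k):
            sid = idx.unique.get(mix64(code))
            if sid is not None:
                species_hit.add(sid)
        for sid in species_hit:
            hit_reads[sid] += 1
    return sorted(sid for sid, n in hit_reads.items() if n >= min_hit_reads)


@dataclass
class MappingResult:
    """Per-species, per-gene accepted-read counts and covered intervals."""

    read_counts: dict[str, dict[str, int]]
    covered: dict[str, dict[str, list[tuple[int, int]]]]
    n_mapped: int
    n_unmapped: int


def _gene_seed_index(candidates: dict[str, CoreGeneSet], k: int):
    """canonical k-mer hash -> [(species, gene, gene_pos, forward_is_canonical)]"""
    index: dict[int, list[tuple[str, str, int, bool]]] = defaultdict(list)
    for sid in sorted(candidates):
        for gene in sorted(candidates[sid].genes):
            seq = candidates[sid].genes[gene]
            for pos, code, fwd in iter_kmers(seq, k):
                index[mix64(code)].append((sid, gene, pos, fwd))
    return index


def map_reads(
    reads: list[tuple[str, str]],
    candidates: dict[str, CoreGeneSet],
    k: int = DEFAULT_K,
    min_identity_pct: float = DEFAULT_MAP_MIN_IDENTITY,
    min_read_fraction: float = DEFAULT_MAP_MIN_READ_FRACTION,
    scoring: Scoring = DEFAULT_SCORING,
) -> MappingResult:
    """Assign each read to its best-scoring candidate core gene.

    Candidate genes are found by shared k-mers; a seed predicting an exact
    substring placement is accepted immediately, otherwise the read is
    aligned semi-globally against the gene.  A placement is accepted when
    alignment identity >= ``min_identity_pct`` over >= ``min_read_fraction``
    of the read.  Ties are broken by species id, then gene name; each read
    counts once.
    """
    if not candidates:
        raise ValueError("no candidate species supplied")
    seed_index = _gene_seed_index(candidates, k)
    read_counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    covered: dict[str, dict[str, list[tuple[int, int]]]] = defaultdict(
        lambda: defaultdict(list)
    )
    n_mapped = 0
    n_unmapped = 0
    for _rid, seq in reads:
        placement = _place_read(
            seq, seed_index, candidates, k, min_identity_pct, min_read_fraction, scoring
        )
        if placement is None:
            n_unmapped += 1
            continue
        sid, gene, span = placement
        read_counts[sid][gene] += 1
        covered[sid][gene].append(span)
        n_mapped += 1
    if n_unmapped:
        logger.info("map_reads: %d reads unmapped", n_unmapped)
    return MappingResult(
        read_counts={s: dict(g) for s, g in read_counts.items()},
        covered={s: dict(g) for s, g in covered.items()},
        n_mapped=n_mapped,
        n_unmapped=n_unmapped,
    )


def _place_read(
    seq: str,
    seed_index,
    candidates: dict[str, CoreGeneSet],
    k: int,
    min_identity_pct: float,
    min_read_fraction: float,
    scoring: Scoring,
):
    L = len(seq)
    if L < k:
        return None
    rc = revcomp(seq)
    # gather candidate (species, gene, orientation) with one predicted offset
    seen: dict[tuple[str, str, str], int] = {}
    for pos, code, read_fwd in iter_kmers(seq, k):
        for sid, gene, gpos, gene_fwd in seed_index.get(mix64(code), ()):
            if read_fwd == gene_fwd:  # read forward strand matches gene strand
                key = (sid, gene, "+")
                off = gpos - pos
            else:
                key = (sid, gene, "-")
                off = gpos - (L - k - pos)
            if key not in seen:
                seen[key] = off
                if len(seen) >= _MAX_READ_CANDIDATES:
                    break
        if len(seen) >= _MAX_READ_CANDIDATES:
            break
    best = None  # (-score, sid, gene, span)
    for (sid, gene, orient), off in sorted(seen.items()):
        gene_seq = candidates[sid].genes[gene]
        oriented = seq if orient == "+" else rc
        score = None
        span = None
        if 0 <= off and off + L <= len(gene_seq) and gene_seq[off : off + L] == oriented:
            score = scoring.match * L  # exact placement
            span = (off, off + L)
        else:
            # align only a window around the seed-predicted offset; the
            # substitution-dominated error model keeps true placements
            # within a small band of the prediction
            pad = 24
            lo = max(0, off - pad)
            hi = min(len(gene_seq), off + L + pad)
            if hi - lo < k:
                continue
            res = semiglobal_align(oriented, gene_seq[lo:hi], scoring)
            qlen = res.query_span[1] - res.query_span[0]
            if (
                res.identity_pct >= min_identity_pct
                and qlen >= min_read_fraction * L
            ):
                score = res.score
                span = (lo + res.ref_span[0], lo + res.ref_span[1])
        if score is not None:
            cand = (-score, sid, gene, span)
            if best is None or cand[:3] < best[:3]:
                best = cand
    if best is None:
        return None
    _negscore, sid, gene, span = best
    return sid, gene, span


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    end = -1
    for s, e in sorted(intervals):
        if s > end:
            total += e - s
            end = e
        elif e > end:
            total += e - end
            end = e
    return total


def breadth(
    covered: dict[str, list[tuple[int, int]]],
    meta: SpeciesMeta,
    mode: str = "concatenated",
) -> float:
    """Percent of the species' core genes covered >= 1x.

    ``concatenated`` (default): covered bases over the summed core-gene
    length.  ``per_gene_mean``: unweighted mean of per-gene breadths, with
    genes receiving no reads counting as 0.
    """
    if mode == "concatenated":
        covered_bases = sum(_union_length(iv) for iv in covered.values())
        return 100.0 * covered_bases / meta.total_core_length
    if mode == "per_gene_mean":
        per_gene = [
            100.0 * _union_length(covered.get(g, [])) / meta.gene_lengths[g]
            for g in meta.gene_names
        ]
        return sum(per_gene) / len(per_gene)
    raise ValueError(f"unknown breadth mode {mode!r}")


def profile(
    reads: list[tuple[str, str]],
    idx: KmerIndex,
    core_genes: dict[str, CoreGeneSet],
    min_hit_reads: int = DEFAULT_MIN_HIT_READS,
    min_breadth_pct: float = DEFAULT_MIN_BREADTH_PCT,
    min_identity_pct: float = DEFAULT_MAP_MIN_IDENTITY,
    min_read_fraction: float = DEFAULT_MAP_MIN_READ_FRACTION,
    scoring: Scoring = DEFAULT_SCORING,
    breadth_mode: str = "concatenated",
) -> ProfileResult:
    """Screen -> map -> breadth filter -> length-normalized abundances."""
    cands = screen_candidates(reads, idx, min_hit_reads)
    if not cands:
        logger.warning("profile: no candidate species passed the screen")
        return ProfileResult(rows=[], dropped=[], n_unmapped_reads=len(reads))
    mapping = map_reads(
        reads,
        {sid: core_genes[sid] for sid in cands},
        idx.k,
        min_identity_pct,
        min_read_fraction,
        scoring,
    )
    retained: list[tuple[str, int, float]] = []
    dropped: list[tuple[str, float]] = []
    for sid in cands:
        count = sum(mapping.read_counts.get(sid, {}).values())
        b = breadth(mapping.covered.get(sid, {}), idx.species_meta[sid], breadth_mode)
        if b >= min_breadth_pct:
            retained.append((sid, count, b))
        else:
            dropped.append((sid, b))
    if not retained:
        logger.warning("profile: every candidate species fell below the breadth filter")
        return ProfileResult(
            rows=[],
            dropped=dropped,
            n_mapped_reads=mapping.n_mapped,
            n_unmapped_reads=mapping.n_unmapped,
        )
    raws = {
        sid: count / idx.species_meta[sid].total_core_length
        for sid, count, _b in retained
    }
    total_raw = sum(raws.values())
    rows = [
        ProfileRow(
            species_id=sid,
            read_count=count,
            breadth_pct=b,
            abundance_raw=raws[sid],
            abundance_rel=raws[sid] / total_raw,
        )
        for sid, count, b in retained
    ]
    rows.sort(key=lambda r: (-r.abundance_rel, r.species_id))
    return ProfileResult(
        rows=rows,
        dropped=dropped,
        n_mapped_reads=mapping.n_mapped,
        n_unmapped_reads=mapping.n_unmapped,
    )


def gene_length_read_correlation(
    read_counts: dict[str, int], gene_lengths: dict[str, int]
) -> float:
    """Pearson r between gene length and classified read count.

    Genes are paired by name over ``gene_lengths``; genes without reads
    count as zero.  Requires >= 3 genes with nonzero counts; zero variance
    on either axis yields NaN.
    """
    genes = sorted(gene_lengths)
    if sum(1 for g in genes if read_counts.get(g, 0) > 0) < 3:
        raise ValueError("need at least 3 genes with nonzero read counts")
    x = [gene_lengths[g] for g in genes]
    y = [read_counts.get(g, 0) for g in genes]
    if len(set(x)) == 1 or len(set(y)) == 1:
        return math.nan
    return float(stats.pearsonr(x, y).statistic)
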