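"""Core-gene metagenome profiler: index, screen, mapping, breadth, abundance."""

import math

import numpy as np
import pytest

from cgtax import synthetic_data as sim
from cgtax._kmers import revcomp
from cgtax.genome_io import CoreGeneSet, default_catalogue
from cgtax.profiler import (
    SpeciesMeta,
    breadth,
    build_kmer_index,
    gene_length_read_correlation,
    map_reads,
    profile,
    screen_candidates,
)

from ._oracle import random_seq

CAT = default_catalogue()


def _species(seed, n_genes=10, lengths=(300, 500), sid=None):
    sid = sid or f"sp{seed}"
    _g, genes = sim.simulate_ancestor(
        n_genes=n_genes, gene_length_range=lengths, seed=seed, genome_id=sid
    )
    return sid, genes


def _reads_from_genes(genes: CoreGeneSet, n, length, seed, prefix="r"):
    rng = np.random.default_rng(seed)
    seqs = list(genes.genes.values())
    out = []
    for i in range(n):
        s = seqs[int(rng.integers(0, len(seqs)))]
        pos = int(rng.integers(0, len(s) - length + 1))
        read = s[pos : pos + length]
        if rng.random() < 0.5:
            read = revcomp(read)
        out.append((f"{prefix}{i}", read))
    return out


# --- index -------------------------------------------------------------------


def test_index_kmer_count_bound_single_gene():
    rng = np.random.default_rng(0)
    gene = random_seq(rng, 500)
    genes = CoreGeneSet(genome_id="a", genes={CAT[0]: gene})
    idx = build_kmer_index({"a": genes}, k=35)
    assert len(idx.entries) <= 500 - 35 + 1
    assert idx.species_meta["a"].total_core_length == 500


def test_shared_gene_maps_to_both_species():
    rng = np.random.default_rng(1)
    gene = random_seq(rng, 300)
    a = CoreGeneSet(genome_id="a", genes={CAT[0]: gene})
    b = CoreGeneSet(genome_id="b", genes={CAT[0]: gene, CAT[1]: random_seq(rng, 300)})
    idx = build_kmer_index({"a": a, "b": b})
    shared = [s for s in idx.entries.values() if s == frozenset({"a", "b"})]
    assert shared  # the common gene's k-mers carry both species
    assert idx.k == 35  # the default k
    assert all(len(idx.entries[h]) == 1 for h in idx.unique)


def test_index_k_validation_and_empty_input():
    genes = CoreGeneSet(genome_id="a", genes={CAT[0]: "ACGT" * 30})
    with pytest.raises(ValueError):
        build_kmer_index({"a": genes}, k=34)
    with pytest.raises(ValueError):
        build_kmer_index({})


# --- candidate screen --------------------------------------------------------


def test_screen_finds_only_the_source_species():
    sid_a, genes_a = _species(10)
    sid_b, genes_b = _species(11)
    idx = build_kmer_index({sid_a: genes_a, sid_b: genes_b})
    reads = _reads_from_genes(genes_a, 50, 80, seed=2)
    assert screen_candidates(reads, idx) == [sid_a]


def test_screen_threshold_excludes_rare_species():
    sid_a, genes_a = _species(12)
    sid_b, genes_b = _species(13)
    idx = build_kmer_index({sid_a: genes_a, sid_b: genes_b})
    reads = _reads_from_genes(genes_a, 50, 80, seed=3) + _reads_from_genes(
        genes_b, 5, 80, seed=4, prefix="b"
    )
    assert screen_candidates(reads, idx, min_hit_reads=10) == [sid_a]
    assert screen_candidates(reads, idx, min_hit_reads=5) == [sid_a, sid_b]


def test_screen_unrelated_reads_empty():
    sid_a, genes_a = _species(14)
    idx = build_kmer_index({sid_a: genes_a})
    rng = np.random.default_rng(5)
    reads = [(f"r{i}", random_seq(rng, 80)) for i in range(30)]
    assert screen_candidates(reads, idx) == []


# --- read mapping ------------------------------------------------------------


def test_exact_read_assigned_with_covered_interval():
    sid, genes = _species(20)
    gene = sorted(genes.genes)[0]
    seq = genes.genes[gene]
    read = seq[50:150]
    res = map_reads([("r0", read), ("r1", revcomp(read))], {sid: genes})
    assert res.read_counts[sid][gene] == 2
    assert res.covered[sid][gene] == [(50, 150), (50, 150)]
    assert res.n_unmapped == 0


def test_random_read_unmapped():
    sid, genes = _species(21)
    rng = np.random.default_rng(6)
    res = map_reads([("r0", random_seq(rng, 100))], {sid: genes})
    assert res.n_mapped == 0
    assert res.n_unmapped == 1


def test_identical_gene_tie_broken_once_deterministically():
    rng = np.random.default_rng(7)
    gene = random_seq(rng, 400)
    a = CoreGeneSet(genome_id="a", genes={CAT[0]: gene})
    b = CoreGeneSet(genome_id="b", genes={CAT[0]: gene})
    read = gene[100:200]
    res = map_reads([("r0", read)], {"b": b, "a": a})
    assert res.n_mapped == 1
    assert res.read_counts == {"a": {CAT[0]: 1}}  # lowest species id wins


def test_mismatched_read_accepted_within_identity_gate():
    sid, genes = _species(22)
    gene = sorted(genes.genes)[0]
    seq = genes.genes[gene]
    read = list(seq[10:110])
    for pos in (5, 50, 95):  # 3 substitutions -> 97% identity
        read[pos] = "ACGT"[("ACGT".index(read[pos]) + 1) % 4]
    res = map_reads([("r0", "".join(read))], {sid: genes})
    assert res.read_counts[sid][gene] == 1


# --- breadth -----------------------------------------------------------------


def test_breadth_full_half_and_union_semantics():
    meta = SpeciesMeta(
        gene_names=("g1", "g2"), gene_lengths={"g1": 100, "g2": 100}, total_core_length=200
    )
    assert breadth({"g1": [(0, 100)], "g2": [(0, 100)]}, meta) == pytest.approx(100.0)
    assert breadth({"g1": [(0, 100)]}, meta) == pytest.approx(50.0)
    # overlapping intervals are not double-counted
    assert breadth({"g1": [(0, 60), (40, 100)]}, meta) == pytest.approx(50.0)


def test_breadth_per_gene_mean_mode():
    meta = SpeciesMeta(
        gene_names=("g1", "g2"), gene_lengths={"g1": 100, "g2": 300}, total_core_length=400
    )
    covered = {"g1": [(0, 100)]}  # g1 fully covered, g2 untouched
    assert breadth(covered, meta) == pytest.approx(25.0)
    assert breadth(covered, meta, mode="per_gene_mean") == pytest.approx(50.0)
    with pytest.raises(ValueError):
        breadth(covered, meta, mode="nope")


# --- profile -----------------------------------------------------------------


def test_single_species_profile_is_unit_abundance():
    sid, genes = _species(30)
    genome = sim.simulate_ancestor(
        n_genes=10, gene_length_range=(300, 500), seed=30, genome_id=sid
    )[0]
    reads, _ = sim.simulate_reads([(genome, 1.0)], n_reads=2000, seed=8)
    idx = build_kmer_index({sid: genes})
    result = profile(reads, idx, {sid: genes})
    assert [r.species_id for r in result.rows] == [sid]
    assert result.rows[0].abundance_rel == pytest.approx(1.0)
    assert result.rows[0].breadth_pct > 95.0


def test_two_species_mixture_recovers_proportions_and_conserves_counts():
    ga, sa = sim.simulate_ancestor(n_genes=10, gene_lengths=[400] * 10, seed=31, genome_id="A")
    gb, sb = sim.simulate_ancestor(n_genes=10, gene_lengths=[400] * 10, seed=32, genome_id="B")
    reads, _ = sim.simulate_reads([(ga, 0.7), (gb, 0.3)], n_reads=6000, seed=9)
    idx = build_kmer_index({"A": sa, "B": sb})
    result = profile(reads, idx, {"A": sa, "B": sb})
    rel = {r.species_id: r.abundance_rel for r in result.rows}
    assert rel["A"] == pytest.approx(0.7, abs=0.05)
    assert rel["B"] == pytest.approx(0.3, abs=0.05)
    assert sum(r.abundance_rel for r in result.rows) == pytest.approx(1.0)
    assert sum(r.read_count for r in result.rows) == result.n_mapped_reads


def test_low_breadth_species_dropped_by_the_filter():
    sid_a, genes_a = _species(33)
    sid_b, genes_b = _species(34)
    idx = build_kmer_index({sid_a: genes_a, sid_b: genes_b})
    # b's reads come from a single gene: breadth << 25%
    gene_b = sorted(genes_b.genes)[0]
    sub = CoreGeneSet(genome_id=sid_b, genes={gene_b: genes_b.genes[gene_b]})
    reads = _reads_from_genes(genes_a, 1500, 80, seed=10) + _reads_from_genes(
        sub, 300, 80, seed=11, prefix="b"
    )
    result = profile(reads, idx, {sid_a: genes_a, sid_b: genes_b})
    assert [r.species_id for r in result.rows] == [sid_a]
    assert [d[0] for d in result.dropped] == [sid_b]
    assert result.dropped[0][1] < 25.0


def test_raising_breadth_threshold_never_adds_species():
    sid_a, genes_a = _species(35)
    sid_b, genes_b = _species(36)
    idx = build_kmer_index({sid_a: genes_a, sid_b: genes_b})
    gene_b = sorted(genes_b.genes)[0]
    sub = CoreGeneSet(genome_id=sid_b, genes={gene_b: genes_b.genes[gene_b]})
    reads = _reads_from_genes(genes_a, 800, 80, seed=12) + _reads_from_genes(
        sub, 200, 80, seed=13, prefix="b"
    )
    gene_sets = {sid_a: genes_a, sid_b: genes_b}
    kept = [
        {r.species_id for r in profile(reads, idx, gene_sets, min_breadth_pct=t).rows}
        for t in (0.0, 10.0, 25.0, 60.0, 101.0)
    ]
    for low, high in zip(kept, kept[1:]):
        assert high <= low


def test_absent_species_never_retained_with_error_free_reads():
    sid_a, genes_a = _species(37)
    sid_b, genes_b = _species(38)  # in the index, absent from the mixture
    idx = build_kmer_index({sid_a: genes_a, sid_b: genes_b})
    reads = _reads_from_genes(genes_a, 2000, 80, seed=14)
    result = profile(reads, idx, {sid_a: genes_a, sid_b: genes_b})
    assert all(r.species_id != sid_b for r in result.rows)


# --- gene length / read count correlation ------------------------------------


def test_correlation_exact_proportionality():
    lengths = {f"g{i}": 100 * (i + 1) for i in range(6)}
    counts = {g: length // 10 for g, length in lengths.items()}
    assert gene_length_read_correlation(counts, lengths) == pytest.approx(1.0)


def test_correlation_zero_variance_is_nan():
    lengths = {"g1": 100, "g2": 200, "g3": 300}
    counts = {"g1": 7, "g2": 7, "g3": 7}
    assert math.isnan(gene_length_read_correlation(counts, lengths))


def test_correlation_requires_three_nonzero_genes():
    with pytest.raises(ValueError):
        gene_length_read_correlation({"g1": 5, "g2": 3}, {"g1": 100, "g2": 200, "g3": 300})


def test_uniform_coverage_correlation_is_high():
    genome, genes = sim.simulate_ancestor(
        n_genes=30, gene_length_range=(300, 1500), seed=40, genome_id="sp"
    )
    reads, _ = sim.simulate_reads([(genome, 1.0)], depth=15, read_length=100, seed=15)
    res = map_reads(reads, {"sp": genes})
    counts = res.read_counts["sp"]
    lengths = {g: len(s) for g, s in genes.genes.items()}
    assert gene_length_read_correlation(counts, lengths) > 0.9
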