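"""Classification cascade: decision rule, 16S handling, NJ placement, registry."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from skbio.tree import TreeNode

from cgtax import synthetic_data as sim
from cgtax.classify_cascade import (
    CascadeConfig,
    ReferenceDB,
    Stage,
    UnclassifiableError,
    classify_genome,
    decide_stage,
    extract_16s,
    lca_assign,
    nj_tree,
    register_cluster,
    sixteen_s_decision,
)
from cgtax.genome_io import GenomeRecord

from ._oracle import random_seq
from .conftest import make_clade_db

CFG = CascadeConfig()


# --- decision rule ----------------------------------------------------------


@pytest.mark.parametrize("ani", [94.9, 95.0])
@pytest.mark.parametrize("cov", [19.9, 20.0])
@pytest.mark.parametrize("s16len", [1299, 1300])
@pytest.mark.parametrize("s16id", [98.7, 98.71])
@pytest.mark.parametrize("s16cov", [90.0, 90.1])
def test_decision_table_boundary_semantics(ani, cov, s16len, s16id, s16cov):
    """ANI gates are inclusive; 16S identity/coverage strict; length inclusive."""
    if ani >= 95.0 and cov >= 20.0:
        expected = Stage.ANI
    elif s16len >= 1300 and s16id > 98.7 and s16cov > 90.0:
        expected = Stage.SIXTEEN_S
    else:
        expected = Stage.CGANI_PLACEMENT
    assert decide_stage(ani, cov, s16len, s16id, s16cov) is expected


def test_undefined_ani_never_satisfies_the_gate():
    assert decide_stage(math.nan, 100.0, 0, 0.0, 0.0) is Stage.CGANI_PLACEMENT


# --- 16S extraction and decision -------------------------------------------


def test_extract_16s_annotation_passthrough(ancestor_pair):
    genome, _ = ancestor_pair
    seq, length = extract_16s(genome, [])
    assert length == sim.SIXTEEN_S_LENGTH
    assert seq == genome.sixteen_s_sequences()[0]


def test_extract_16s_by_homology(ancestor_pair):
    genome, _ = ancestor_pair
    unannotated = GenomeRecord(genome_id="q", contigs=genome.contigs)
    other, _ = sim.simulate_ancestor(
        n_genes=5, gene_length_range=(200, 300), seed=99, genome_id="ref"
    )
    ref16 = other.sixteen_s_sequences()[0]
    hit = extract_16s(unannotated, [ref16])
    assert hit is not None
    seq, length = hit
    assert abs(length - sim.SIXTEEN_S_LENGTH) <= 30
    true16 = genome.sixteen_s_sequences()[0]
    assert seq in true16 or true16 in seq or seq == true16


def test_extract_16s_absent_region_returns_none():
    rng = np.random.default_rng(12)
    g = GenomeRecord(genome_id="q", contigs=[("c1", random_seq(rng, 30_000))])
    other, _ = sim.simulate_ancestor(
        n_genes=5, gene_length_range=(200, 300), seed=98, genome_id="ref"
    )
    assert extract_16s(g, [other.sixteen_s_sequences()[0]]) is None


def test_extract_16s_short_fragment_reported_at_true_length(ancestor_pair):
    genome, _ = ancestor_pair
    full16 = genome.sixteen_s_sequences()[0]
    rng = np.random.default_rng(13)
    contig = random_seq(rng, 5000) + full16[:700] + random_seq(rng, 5000)
    g = GenomeRecord(genome_id="q", contigs=[("c1", contig)])
    hit = extract_16s(g, [full16])
    assert hit is not None
    _seq, length = hit
    assert abs(length - 700) <= 60  # boundary precision is ~ the window pad
    assert length < 1300  # fails the downstream length gate


def _db_with_16s(ref16: str) -> ReferenceDB:
    rng = np.random.default_rng(77)
    db = ReferenceDB()
    genome = GenomeRecord(genome_id="r1", contigs=[("c1", random_seq(rng, 3000))])
    db.add_reference(genome, sixteen_s=ref16, lineage=("P", "C", "O", "F", "G", "r1_s"))
    return db


def test_sixteen_s_perfect_match_is_a_hit():
    rng = np.random.default_rng(20)
    ref = random_seq(rng, 1500)
    db = _db_with_16s(ref)
    hit = sixteen_s_decision(ref, db)
    assert hit == ("r1", pytest.approx(100.0), pytest.approx(100.0))


def test_sixteen_s_identity_gate_is_strict():
    rng = np.random.default_rng(21)
    ref = random_seq(rng, 2000)
    db = _db_with_16s(ref)
    # exactly 26 substitutions / 2000 columns = 98.70% identity: not a hit
    q = list(ref)
    positions = range(30, 2000, 76)  # 26 spread-out positions
    assert len(list(positions)) == 26
    for pos in positions:
        q[pos] = "ACGT"[("ACGT".index(q[pos]) + 1) % 4]
    assert sixteen_s_decision("".join(q), db) is None
    # one substitution fewer: 98.75% > 98.7 -> hit
    q[30] = ref[30]
    hit = sixteen_s_decision("".join(q), db)
    assert hit is not None and hit[1] == pytest.approx(98.75)


def test_sixteen_s_coverage_gate_short_query():
    rng = np.random.default_rng(22)
    ref = random_seq(rng, 1542)
    db = _db_with_16s(ref)
    # a perfect 1300 bp subsequence covers only 84.3% of the reference gene
    assert sixteen_s_decision(ref[:1300], db) is None
    with pytest.raises(ValueError):
        sixteen_s_decision(ref[:1299], db)


# --- neighbor joining and LCA ----------------------------------------------


def test_nj_three_taxa_closed_form():
    dist = pd.DataFrame(
        [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]],
        index=list("abc"),
        columns=list("abc"),
    )
    tree = nj_tree(dist)
    tips = {t.name: t for t in tree.tips()}
    # three-point formulas: la = (dab + dac - dbc) / 2, etc.
    assert tips["a"].distance(tips["b"]) == pytest.approx(0.2)
    assert tips["a"].distance(tips["c"]) == pytest.approx(0.3)
    assert tips["b"].distance(tips["c"]) == pytest.approx(0.4)


def test_nj_recovers_additive_four_taxon_split():
    # additive matrix with ab|cd structure
    dist = pd.DataFrame(
        [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]],
        index=list("abcd"),
        columns=list("abcd"),
        dtype=float,
    )
    tree = nj_tree(dist)
    tips = {t.name: t for t in tree.tips()}
    for x, y in (("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")):
        assert tips[x].distance(tips[y]) == pytest.approx(dist.loc[x, y])


def test_nj_rejects_na_and_tiny_matrices():
    dist = pd.DataFrame(
        [[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]], index=list("abc"), columns=list("abc")
    )
    with pytest.raises(ValueError, match="drop the offending taxon"):
        nj_tree(dist)
    with pytest.raises(ValueError, match="at least 3"):
        nj_tree(dist.iloc[:2, :2])


def _tree(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick))


PATH = {
    "n1": ("P", "C", "O", "F", "G1", "s1"),
    "n2": ("P", "C", "O", "F", "G1", "s2"),
    "n3": ("P", "C", "O", "F", "G2", "s3"),
    "np": ("P2", "C2", "O2", "F2", "G9", "s9"),
}


def test_lca_same_genus_assigns_genus():
    tree = _tree("((q:1,n1:1):1,(n2:1,n3:1):1);")
    taxa = {"n1": PATH["n1"], "n2": PATH["n2"]}
    assert lca_assign(tree, "q", taxa) == ("P", "C", "O", "F", "G1")


def test_lca_two_genera_assigns_family():
    tree = _tree("((q:1,n1:1,n3:1):1,x:1);")
    taxa = {"n1": PATH["n1"], "n3": PATH["n3"]}
    assert lca_assign(tree, "q", taxa) == ("P", "C", "O", "F")


def test_lca_across_phyla_assigns_empty_path():
    tree = _tree("((q:1,n1:1,np:1):1,x:1);")
    taxa = {"n1": PATH["n1"], "np": PATH["np"]}
    assert lca_assign(tree, "q", taxa) == ()


def test_lca_without_taxonomized_neighbours():
    tree = _tree("((q:1,x:1):1,y:1);")
    assert lca_assign(tree, "q", {}) == ()


def test_lca_never_deeper_than_genus():
    tree = _tree("((q:1,n1:1):1,n2:1);")
    taxa = {"n1": PATH["n1"]}  # single neighbour, species-level path
    assert lca_assign(tree, "q", taxa) == ("P", "C", "O", "F", "G1")


# --- registration and the full cascade -------------------------------------


def test_register_cluster_name_format_and_serials(ancestor_pair):
    db = ReferenceDB()
    rng = np.random.default_rng(31)
    base = GenomeRecord(genome_id="seed", contigs=[("c1", random_seq(rng, 3000))])
    db.add_reference(base, lineage=("P", "C", "O", "F", "G", "seed_s"))
    g1, s1 = sim.simulate_ancestor(n_genes=5, gene_length_range=(200, 300), seed=41, genome_id="q1")
    g2, s2 = sim.simulate_ancestor(n_genes=5, gene_length_range=(200, 300), seed=42, genome_id="q2")
    name1 = register_cluster(db, g1, s1, ("P", "C", "O", "F"))
    name2 = register_cluster(db, g2, s2, ())
    assert name1 == "MSSCM00000001_s"
    assert name2 == "MSSCM00000002_s"
    assert db.taxonomy.path_of("q1") == ("P", "C", "O", "F", "MSSCM00000001_g", name1)
    assert db.taxonomy.path_of("q2")[-1] == name2
    with pytest.raises(ValueError, match="already registered"):
        register_cluster(db, g1, s1, ())


def test_query_identical_to_reference_decided_by_ani(clade_db):
    db, members, _ = clade_db
    genome, genes = members["Ga_sp0"]
    query = GenomeRecord(genome_id="q_same", contigs=genome.contigs)
    out = classify_genome(
        query, genes, db, CascadeConfig(register_new_clusters=False)
    )
    assert out.stage is Stage.ANI
    assert out.assigned_taxon[-1] == "Ga_sp0"
    assert out.evidence["ani_pct"] == pytest.approx(100.0)
    assert out.evidence["ani_coverage_pct"] == pytest.approx(100.0)


def test_sixteen_s_stage_decides_when_ani_fails():
    db, members, genera = make_clade_db(seed=11, n_genes=16)
    ref_genome, _ = members["Gb_sp1"]
    ga_anc, ga_genes = genera["Ga"]
    # a diverged genome (ANI << 95) carrying an exact copy of a reference 16S
    q, q_genes = sim.evolve(ga_anc, ga_genes, 0.08, seed=500, genome_id="q16")
    cid, start, end, strand = q.rrna_16s[0]
    ref16 = ref_genome.sixteen_s_sequences()[0]
    contig = q.contig_map[cid]
    piece = ref16 if strand == "+" else sim.revcomp(ref16)
    new_contig = contig[:start] + piece + contig[end:]
    q2 = GenomeRecord(
        genome_id="q16",
        contigs=[(cid, new_contig)],
        rrna_16s=[(cid, start, start + len(piece), strand)],
    )
    out = classify_genome(q2, q_genes, db, CascadeConfig(register_new_clusters=False))
    assert out.stage is Stage.SIXTEEN_S
    assert out.assigned_taxon[-1] == "Gb_sp1"
    assert out.evidence["s16_identity_pct"] == pytest.approx(100.0)


def test_placement_assigns_genus_and_registers_cluster():
    db, _members, genera = make_clade_db(seed=13)
    ga_anc, ga_genes = genera["Ga"]
    q, q_genes = sim.evolve(ga_anc, ga_genes, 0.04, seed=600, genome_id="q_new")
    out = classify_genome(q, q_genes, db, CFG)
    assert out.stage is Stage.CGANI_PLACEMENT
    assert out.new_cluster_id == "MSSCM00000001_s"
    assert out.assigned_taxon == ("P1", "C1", "O1", "F1", "Ga")
    assert out.evidence["lca_rank"] == "genus"
    assert "q_new" in db.genomes  # registered as a representative

    # idempotence of the growing database: the same genome classifies to its
    # own fresh cluster at the ANI stage on the second pass
    q_again = GenomeRecord(genome_id="q_rerun", contigs=q.contigs)
    out2 = classify_genome(q_again, q_genes, db, CFG)
    assert out2.stage is Stage.ANI
    assert out2.evidence["ani_pct"] == pytest.approx(100.0)
    assert out2.assigned_taxon[-1] == "MSSCM00000001_s"


def test_unclassifiable_without_16s_and_core_genes(clade_db):
    db, _members, _ = clade_db
    rng = np.random.default_rng(71)
    q = GenomeRecord(genome_id="junk", contigs=[("c1", random_seq(rng, 15_000))])
    with pytest.raises(UnclassifiableError, match="no 16S and no core genes"):
        classify_genome(q, None, db, CascadeConfig(register_new_clusters=False))


def test_reference_db_save_load_round_trip(tmp_path, clade_db):
    db, _members, _ = clade_db
    db.save(tmp_path / "db")
    loaded = ReferenceDB.load(tmp_path / "db")
    assert set(loaded.genomes) == set(db.genomes)
    assert loaded.next_cluster_serial == db.next_cluster_serial
    for gid in db.genomes:
        assert loaded.sketches[gid].hashes == db.sketches[gid].hashes
        assert loaded.core_genes[gid].genes == db.core_genes[gid].genes
        assert loaded.sixteen_s[gid] == db.sixteen_s[gid]
        assert loaded.taxonomy.path_of(gid) == db.taxonomy.path_of(gid)
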