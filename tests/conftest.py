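"""Shared fixtures: small simulated reference databases and gene sets."""

from __future__ import annotations

import pytest

from cgtax import synthetic_data as sim
from cgtax.classify_cascade import ReferenceDB


def make_clade_db(
    seed: int,
    n_genes: int = 24,
    gene_length_range: tuple[int, int] = (300, 600),
    genus_branch: float = 0.10,
    species_branch: float = 0.04,
    n_per_genus: int = 3,
):
    """A family with two genera, ``n_per_genus`` reference species each.

    Returns (db, {genome_id: (GenomeRecord, CoreGeneSet)}, genus ancestors)
    so tests can evolve extra query genomes from the same clade.
    """
    anc, anc_genes = sim.simulate_ancestor(
        n_genes=n_genes,
        gene_length_range=gene_length_range,
        seed=seed,
        genome_id="anc",
    )
    ga = sim.evolve(anc, anc_genes, genus_branch, seed=seed * 1000 + 1, genome_id="Ga_anc")
    gb = sim.evolve(anc, anc_genes, genus_branch, seed=seed * 1000 + 2, genome_id="Gb_anc")
    db = ReferenceDB()
    members = {}
    for gi, (genus, (g_anc, g_genes)) in enumerate((("Ga", ga), ("Gb", gb))):
        for i in range(n_per_genus):
            gid = f"{genus}_sp{i}"
            genome, genes = sim.evolve(
                g_anc, g_genes, species_branch, seed=seed * 1000 + 100 + 10 * gi + i, genome_id=gid
            )
            db.add_reference(
                genome, genes, lineage=("P1", "C1", "O1", "F1", genus, gid)
            )
            members[gid] = (genome, genes)
    return db, members, {"Ga": ga, "Gb": gb}


@pytest.fixture(scope="session")
def clade_db():
    return make_clade_db(seed=7)


@pytest.fixture(scope="session")
def ancestor_pair():
    """A small ancestor genome and its core-gene set."""
    return sim.simulate_ancestor(
        n_genes=12, gene_length_range=(300, 600), seed=1, genome_id="anc"
    )
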