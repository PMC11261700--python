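# cgtax

Genome-driven taxonomic identification and quantification of Bacteria and
Archaea. `cgtax` is for people who maintain or use genome-based reference
taxonomies — it classifies new genome assemblies against a reference
database, keeps the database growing by registering provisional species
clusters for lineages no current method can name, and profiles shotgun
metagenome read sets against the references' core genes.

## The methods

Three similarity statistics drive everything:

* **Fragment ANI** (OrthoANI-style): both genomes are cut into 1020 bp
  fragments; reciprocal best semi-globally aligned fragment pairs with
  identity ≥ 70% over at least half the fragment are retained;
  ANI = mean identity of retained pairs, coverage = retained pairs /
  query fragments. ANI ≥ 95% is the conventional species boundary.
* **cgANI** (core-gene ANI): the mean semi-global identity over the
  single-copy core genes (a fixed 92-gene catalogue) shared by two
  genomes, cgANI = (1/n) Σ_g identity(g). Because core genes stay
  alignable long after whole genomes stop overlapping, cgANI remains
  informative for deep, reference-poor lineages where fragment ANI is
  undefined.
* **16S rRNA identity**, with the classical > 98.7% species threshold.

A query genome runs through a strict cascade: MinHash prescreen →
fragment ANI (assign species at ANI ≥ 95%, coverage ≥ 20%) → 16S
(≥ 1300 bp, identity > 98.7%, reference-gene coverage > 90%) → cgANI
placement: neighbor-joining on (100 − cgANI)/100 distances to the ten
closest core-gene neighbours, lowest-common-ancestor assignment capped at
genus, and registration of the query as a new **MSSC** (Microbiome Strain
Sequence Cluster, e.g. `MSSCM00000001_s`) representative so the very next
close relative is caught at the ANI stage.

The metagenome profiler indexes the 35-mers of every species' core
genes, screens candidate species (≥ 10 reads with species-unique
k-mers), maps reads to their best core gene (identity ≥ 90% over ≥ 80%
of the read), drops species whose reads cover < 25% of their summed
core-gene length, and reports abundances as mapped reads per core-gene
base, renormalized over the retained species.

A deterministic simulator (Jukes–Cantor genomes with embedded core genes
and a 16S-like locus, uniform single-end reads with known truth) makes
the whole package testable offline; see `docs/methods.md` for models,
parameter choices and limitations.

## Worked example

Classify a novel isolate against a small simulated database (one family,
two genera, three reference species each), then watch the database update
catch its close relative:

```python
from cgtax import synthetic_data as sim
from cgtax.classify_cascade import CascadeConfig, ReferenceDB, classify_genome

anc, anc_genes = sim.simulate_ancestor(n_genes=24, gene_length_range=(300, 600),
                                       seed=7, genome_id="anc")
db = ReferenceDB()
genera = {}
for gi, genus in enumerate(("Ga", "Gb")):
    genera[genus] = sim.evolve(anc, anc_genes, 0.10, seed=7000 + gi, genome_id=f"{genus}_anc")
    for i in range(3):
        genome, genes = sim.evolve(*genera[genus], 0.04, seed=7100 + 10 * gi + i,
                                   genome_id=f"{genus}_sp{i}")
        db.add_reference(genome, genes, lineage=("P1", "C1", "O1", "F1", genus, f"{genus}_sp{i}"))

query, query_genes = sim.evolve(*genera["Ga"], 0.04, seed=7500, genome_id="isolate_X")
outcome = classify_genome(query, query_genes, db, CascadeConfig())
```

The run prints:

```
stage:           CGANI_PLACEMENT
assigned taxon:  P1;C1;O1;F1;Ga
new cluster id:  MSSCM00000001_s
best ANI:        92.36% at 100% coverage
cgANI to nearest neighbours:
  Ga_sp0: 92.46%
  Ga_sp1: 92.44%
  Ga_sp2: 92.43%
follow-up:       stage=ANI taxon=P1;C1;O1;F1;Ga;MSSCM00000001_s (ANI 99.09%)
```

Reading the numbers: the isolate's best whole-genome ANI is 92.4% —
below the 95% species boundary — and its 16S (diverged along the same
branches) fails the 98.7% gate, so neither classical method can name it.
cgANI places it inside genus `Ga` (its three nearest neighbours sit at
≈ 92.4% cgANI, the other genus far below), so it is registered as the
provisional species `MSSCM00000001_s` under `Ga`. A second isolate
evolved 1% away from the first (`isolate_Y`) is then immediately
identified at the ANI stage — 99.09% ANI to the newly registered
representative — without any placement work.

The same operations are available from a shell: `cgtax db build`,
`cgtax align`, `cgtax sketch`, `cgtax ani`, `cgtax cgani`,
`cgtax cgani-matrix`, `cgtax classify`, `cgtax profile`, `cgtax sim`
(see `cgtax --help`).

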