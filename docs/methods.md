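# Methods

`cgtax` implements a genome-driven identification workflow for Bacteria
and Archaea: pairwise genome similarity statistics (fragment ANI and
core-gene ANI), a staged classification cascade with placeholder-cluster
registration, and a core-gene metagenome profiler. This note records the
models, the parameters that matter, and the design choices made where the
methods left genuine freedom.

## Semi-global alignment and the identity statistic

All identity values in the package come from one primitive: an affine-gap
semi-global (overlap) alignment. Terminal gaps on either sequence are
free; an internal gap of length L costs `gap_open + L*gap_extend`
(defaults: match +2, mismatch −3, gap_open −5, gap_extend −2, so a 1-base
gap costs −7). At least one aligned column is always produced, so hostile
pairs can score negative; the identity filters downstream make such
alignments irrelevant.

**Identity definition.** identity = 100 × matches / aligned columns,
where columns are counted between the first and last aligned pair:
internal gap columns count against identity, terminal overhangs do not.
This makes identity(a, a) = 100 while still penalizing indels. Whether
internal gap columns should count is a genuine open choice; this
definition is used consistently everywhere (fragment ANI, cgANI, 16S).

**Tie-breaking.** Among co-optimal alignments the implementation prefers
more matches, then fewer columns, then the endpoint with the smallest
coordinates. The lexicographic objective is exact under dynamic
programming because every component accumulates additively along an
alignment path. Output is therefore fully deterministic.

**N policy.** N never matches anything, including another N — a
conservative choice that can only lower identity.

**Numerics.** The kernel keeps per-cell state in int32 (scores are bounded
by a few times the sequence length); inputs above 2 Mb per sequence are
rejected. Equivalence with a brute-force full-matrix oracle and score
agreement with Biopython's free-end-gap global aligner are part of the
test suite.

## MinHash prescreening

Genomes are sketched with bottom-s MinHash over canonical k-mers
(lexicographic minimum of a k-mer and its reverse complement, on a 2-bit
A<C<G<T encoding). Hashes are splitmix64 with a fixed recorded seed, so
sketches are reproducible across machines. Defaults: k=21, s=1000 for
genomes; k=16, s=500 for concatenated core genes (shorter sequences need
a smaller k to keep enough distinct k-mers). k is limited to 11–31 (the
packed-uint64 range).

Jaccard is estimated from the merged bottom-s sketch and converted to a
distance with the Mash formula d = −ln(2j/(1+j))/k, capped at 1.0 (and
set to 1.0 when j = 0). The estimator's binomial error is covered by a
property test (within 3·sqrt(j(1−j)/s) of the exact Jaccard in ≥95% of
trials).

The shortlist passed from the sketch screen to fragment ANI is 5 genomes
(configurable); the core-gene neighbourhood used for placement is the
top 10, matching the cascade's design.

## Fragment ANI (OrthoANI-style)

Genomes are cut into non-overlapping 1020 bp windows (trailing remainders
dropped; windows more than half N dropped). Candidate fragment pairs must
share at least one exact 16-mer on either strand (at most 8 candidates
per fragment, ranked by shared-seed count); candidates are aligned
semi-globally on the better strand. A pair is retained when

* each fragment is the other's best hit (reciprocal best, ties to the
  lower fragment index),
* identity ≥ 70%, and
* the alignment covers ≥ 50% of the fragment length.

The last rule is not optional: overlap alignments over a tiny dovetail
(say, 25 bp at the fragment ends) can exceed 70% identity by chance, and
without a minimum aligned length two unrelated genomes occasionally
produce "reciprocal pairs". With it, unrelated random genomes yield
coverage 0 and undefined ANI, as they should.

ANI is the unweighted mean identity over retained pairs. **Coverage is
query-sided**: 100 × retained pairs / query fragments. The cascade's 20%
coverage gate refers to this number; the choice of side is deliberate and
should be kept in mind when the two genomes differ greatly in size.

## Core-gene ANI (cgANI)

cgANI between two genomes is the unweighted arithmetic mean of the
semi-global identities of every core gene present in both genomes' gene
sets (a length-weighted mean is available behind a flag). The gene
catalogue is a fixed list of 92 single-copy core gene names; the package
ships placeholder names (`ubcg_001`..`ubcg_092`) and accepts any 92-name
list, since the statistic depends only on the pairing of genes by name.

cgANI coverage is 100 × shared pairs / 92 — the fixed denominator makes
coverage comparable across pairs regardless of which genes each genome
retains. Results from fewer than 10 shared genes are flagged
low-confidence. Pairs sharing no genes are an error (NaN in matrix form).

The distance used for tree building is (100 − cgANI)/100.

Under Jukes–Cantor evolution at branch length d the expected per-site
identity is 1/4 + 3/4·e^(−4d/3); on gap-free simulated genes the mean
cgANI recovers this closed form within binomial error, which is the main
calibration test of the statistic.

## The classification cascade

Stages run strictly in order; the first satisfied rule decides.

1. **ANI**: MinHash shortlist (5), then fragment ANI; assign the species
   of the best reference with ANI ≥ 95% and query coverage ≥ 20%.
2. **16S rRNA**: the query 16S must be ≥ 1300 bp (annotated copies are
   used directly, the longest when several; otherwise a homology search
   recovers the best region with ≥ 80% identity to a reference 16S —
   seeded by exact 21-mers, candidate window padded ±25 bp, so extraction
   boundary precision is about ±25 bp). Assign the species of the best
   reference when identity > 98.7% and coverage of the reference 16S gene
   > 90%. Note the asymmetry: ANI gates are inclusive (≥), 16S identity
   and coverage are strict (>), the length gate is inclusive. "Coverage"
   here is aligned columns over the reference gene length — the
   interpretation adopted for an ambiguous rule, flagged here on purpose.
3. **cgANI placement**: top-10 core-gene neighbours by MinHash, cgANI to
   each, a neighbor-joining tree (scikit-bio) on the pairwise cgANI
   distances of {query + neighbours} (neighbours causing undefined cells
   are dropped), LCA assignment, and registration of the query as a new
   cluster representative.

**Rooting for LCA.** NJ output is unrooted with an arbitrary root; if the
query happens to attach at that root, its "smallest enclosing clade"
would be the whole tree. The placement tree is therefore rooted at the
tip farthest from the query (deterministic tie-break by label) before
walking up from the query tip to the smallest clade containing a
taxonomized neighbour. The assigned path is the deepest rank shared by
all neighbours in that clade, **capped at genus** — placement never
assigns species. With no usable neighbour the query is registered under
"root/unclassified".

**MSSC registration.** New clusters are named `MSSCM` + zero-padded
8-digit serial + `_s` (e.g. `MSSCM00000001_s`). Ranks between the
assigned path and species are filled with rank-suffixed placeholders
(`MSSCM00000001_g` for genus, etc.). The registered genome immediately
becomes a database representative — sketches, core genes, 16S — so the
next close query is caught at the ANI stage; this update loop is tested
explicitly.

## Metagenome profiler

* **Index**: canonical k-mers (k=35, odd, 21–51 allowed) of every
  species' core genes, hash → species set; k-mers occurring in several
  species keep the full set. The candidate screen uses only
  species-unique k-mers: a species is a candidate when ≥ 10 reads contain
  at least one of its unique k-mers.
* **Mapping**: candidate genes per read come from shared k-mers with a
  predicted offset. An exactly matching placement is accepted directly;
  otherwise the read is aligned semi-globally against a window of the
  gene padded ±24 bp around the prediction (sufficient for the
  substitution-dominated error model). A placement is accepted at
  identity ≥ 90% over ≥ 80% of the read — stand-ins for a short-read
  mapper's defaults, configurable. The best-scoring gene wins; ties break
  by species id then gene name; each read counts once (no fractional
  multi-mapping).
* **Breadth filter**: breadth = covered positions (exact interval union)
  across all of a species' core genes / total core length. Species below
  25% breadth are dropped — this is the false-positive control, and the
  25% threshold is read as breadth (fraction covered ≥1×), not mean
  depth. An unweighted per-gene-mean breadth is available behind a flag
  (`breadth_mode="per_gene_mean"`); the concatenated definition is the
  default because it matches breadth over a merged reference interval
  set.
* **Abundance**: raw = mapped reads / total core length (reads per base),
  renormalized to sum to 1 over retained species.

Under uniform coverage, per-gene read counts are nearly proportional to
gene length (each gene of length L collects reads from about L − 20
start positions at 100 bp reads and the 80%-of-read rule); the Pearson
correlation between gene length and read count is the profiler's
quantification diagnostic and exceeds 0.95 at 20× in the tests.

## Synthetic data

The simulator exists so every statistic can be tested against known
truth, offline:

* Ancestral genomes are i.i.d. uniform nucleotide contigs with
  non-overlapping embedded genes (random strands, recorded 0-based
  half-open coordinates) and one 16S-like locus of 1542 bp evolved at 2%
  from a fixed in-package pseudo-sequence (16S is far more conserved than
  the genome average; the locus claims no biological realism beyond
  length and conservation).
* Evolution is Jukes–Cantor: each site substitutes with probability
  (3/4)(1 − e^(−4d/3)) to a uniformly chosen different base. A `uniform`
  mode substitutes at exactly rate d for tests that want a direct
  per-site rate. Optional small indels are restricted to intergenic
  regions, with coordinates shifted, so gene sets stay exact.
* Reads are single-end, uniformly placed, reverse-complemented with
  probability 1/2, with i.i.d. substitution errors; a truth table records
  the source of every read. Default gene lengths are drawn from
  300–1500 bp (bacterial core genes span roughly this range).
* Everything flows through `numpy.random.default_rng(seed)`: equal seeds
  give byte-identical FASTA/FASTQ.

What the simulator does **not** emulate: rearrangements, horizontal
transfer, repeats, composition bias, quality-score error profiles,
chimeric reads, paired ends. Passing tests therefore demonstrate
correctness of the statistics and decision logic under the stated models,
not robustness to every artefact of real sequencing data.

## Problem sizes used in the tests and acceptance script

Simulated clades use 24 genes of 300–600 bp per genome (≈20 kb genomes)
for placement tests, and the full 92-gene catalogue for the cgANI
closed-form and profiler checks (92 × 450 bp core per species, ≈50 kb
genomes, 50 000 reads per mixture replicate). These sizes keep a full run
on one CPU in minutes while leaving every statistic's sampling error far
below the tolerances being asserted.

## Known limitations

* Core genes must be provided per genome; extraction from raw assemblies
  (HMM search) is out of scope, and partial genes are accepted as-is.
* The fragment-ANI coverage is query-sided by definition; swapping query
  and reference changes coverage (not ANI materially).
* Placement assigns at most a genus; species-level placement is
  deliberately impossible.
* The int32 alignment kernel caps sequences at 2 Mb; contigs are fine,
  whole unfragmented chromosomes of unusual size are not a supported
  alignment input (fragment ANI never needs them).
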