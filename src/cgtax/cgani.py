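"""Core-gene average nucleotide identity (cgANI).

For a pair of genomes, every core gene present in both genomes' gene sets
is aligned semi-globally and the cgANI is the unweighted mean of the
per-gene identities.  Because the genes are single-copy, universal and
well conserved, this statistic stays informative for pairs too diverged
for whole-genome ANI, where almost no genomic fragments align at all.

Coverage here is the number of shared aligned gene pairs as a percentage
of the fixed 92-gene catalogue, so values are comparable across pairs
regardless of which genes each genome happens to retain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import CoreGeneSet
from .pairwise_align import DEFAULT_SCORING, Scoring, semiglobal_align

#: Below this many shared gene pairs a cgANI value is flagged low-confidence.
DEFAULT_MIN_PAIRS = 10


@dataclass(frozen=True)
class CgANIResult:
    """Core-gene ANI between two genomes.

    ``cgani_pct`` is the arithmetic mean of ``per_gene`` identities (or a
    length-weighted mean when requested); ``coverage_pct`` is
    100 * n_pairs / catalogue size.
    """

    genome_a: str
    genome_b: str
    cgani_pct: float
    n_pairs: int
    coverage_pct: float
    per_gene: dict[str, float]
    low_confidence: bool = False


def cgani(
    a: CoreGeneSet,
    b: CoreGeneSet,
    scoring: Scoring = DEFAULT_SCORING,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    length_weighted: bool = False,
) -> CgANIResult:
    """cgANI of two core-gene sets (mean semi-global identity over shared genes).

    Raises ``ValueError`` when the sets share no gene names; with fewer
    than ``min_pairs`` shared genes the result is flagged low-confidence.
    """
    if a.catalogue != b.catalogue:
        raise ValueError("core-gene sets use different catalogues")
    shared = [g for g in a.catalogue if g in a.genes and g in b.genes]
    if not shared:
        raise ValueError(f"no shared core genes between {a.genome_id} and {b.genome_id}")
    per_gene = {
        g: semiglobal_align(a.genes[g], b.genes[g], scoring).identity_pct for g in shared
    }
    if length_weighted:
        weights = {g: (len(a.genes[g]) + len(b.genes[g])) / 2 for g in shared}
        total = sum(weights.values())
        value = sum(per_gene[g] * weights[g] for g in shared) / total
    else:
        value = sum(per_gene.values()) / len(shared)
    return CgANIResult(
        genome_a=a.genome_id,
        genome_b=b.genome_id,
        cgani_pct=value,
        n_pairs=len(shared),
        coverage_pct=100.0 * len(shared) / len(a.catalogue),
        per_gene=per_gene,
        low_confidence=len(shared) < min_pairs,
    )


def cgani_matrix(
    sets: list[CoreGeneSet],
    scoring: Scoring = DEFAULT_SCORING,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-vs-all cgANI identity and coverage matrices.

    Both are symmetric DataFrames indexed by genome id; the identity
    diagonal is 100 and the coverage diagonal is 100 * |genes| / catalogue
    size.  Pairs sharing no genes get NaN in both matrices.
    """
    if len(sets) < 2:
        raise ValueError("cgani_matrix requires at least 2 gene sets")
    ids = [s.genome_id for s in sets]
    n = len(sets)
    ident = np.full((n, n), np.nan)
    cover = np.full((n, n), np.nan)
    for i, s in enumerate(sets):
        ident[i, i] = 100.0
        cover[i, i] = 100.0 * len(s) / len(s.catalogue)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = cgani(sets[i], sets[j], scoring, min_pairs)
            except ValueError:
                continue
            ident[i, j] = ident[j, i] = r.cgani_pct
            cover[i, j] = cover[j, i] = r.coverage_pct
    return (
        pd.DataFrame(ident, index=ids, columns=ids),
        pd.DataFrame(cover, index=ids, columns=ids),
    )


def cgani_distance(result: CgANIResult | float) -> float:
    """Map cgANI percent to a [0, 1] distance, d = (100 - cgANI) / 100."""
    pct = result.cgani_pct if isinstance(result, CgANIResult) else float(result)
    if math.isnan(pct):
        return math.nan
    return (100.0 - pct) / 100.0
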