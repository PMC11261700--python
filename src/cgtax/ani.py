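"""Fragment-based whole-genome average nucleotide identity (ANI).

The genome is cut into non-overlapping windows of a fixed length
(1020 bp, the OrthoANI convention), fragments are paired across genomes by
reciprocal best semi-global alignment, pairs below a minimum identity are
discarded, and ANI is the mean identity over the retained reciprocal
pairs.  Coverage is the fraction of *query* fragments participating in a
retained pair — the classification cascade applies its 20% coverage gate
to this query-side number.

To avoid all-vs-all alignment, fragment pairs must share at least one
exact 16-mer (either strand) before being aligned.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass

from ._kmers import forward_kmer_hashes, revcomp
from .genome_io import GenomeRecord
from .pairwise_align import DEFAULT_SCORING, Scoring, semiglobal_align

logger = logging.getLogger("cgtax")

DEFAULT_FRAGMENT_LENGTH = 1020
DEFAULT_MIN_FRAG_IDENTITY = 70.0
#: A retained fragment pair must align over at least this fraction of the
#: fragment length; identity over a tiny dovetail overlap is meaningless.
MIN_FRAG_ALIGNED_FRACTION = 0.5
PRESCREEN_K = 16
#: At most this many candidate partner fragments are aligned per fragment
#: (those sharing the most 16-mers; ties towards lower fragment index).
MAX_CANDIDATES = 8


@dataclass(frozen=True)
class ANIResult:
    """Pairwise whole-genome ANI with query-side alignment coverage.

    ``ani_pct`` is NaN when no reciprocal fragment pair survives the
    identity filter; ``per_fragment`` lists (query_fragment_index,
    identity_pct) for retained pairs.
    """

    query_id: str
    ref_id: str
    ani_pct: float
    coverage_pct: float
    n_fragments_used: int
    per_fragment: tuple[tuple[int, float], ...]


def fragment_genome(
    genome: GenomeRecord, fragment_length: int = DEFAULT_FRAGMENT_LENGTH
) -> list[tuple[int, str]]:
    """Cut contigs into consecutive windows of exactly ``fragment_length``.

    Trailing remainders shorter than the window are discarded, as are
    windows that are more than half ambiguous (N).  Indices run over the
    retained fragments in genome order.
    """
    if fragment_length < 100:
        raise ValueError("fragment length must be >= 100")
    frags: list[tuple[int, str]] = []
    idx = 0
    for _cid, seq in genome.contigs:
        for start in range(0, len(seq) - fragment_length + 1, fragment_length):
            window = seq[start : start + fragment_length]
            if window.count("N") * 2 > len(window):
                continue
            frags.append((idx, window))
            idx += 1
    if not frags:
        logger.warning(
            "%s: no fragments of length %d (genome too short?)",
            genome.genome_id,
            fragment_length,
        )
    return frags


def _seed_index(frags: list[tuple[int, str]], seed_k: int) -> dict[int, set[int]]:
    index: dict[int, set[int]] = defaultdict(set)
    for idx, seq in frags:
        for h in forward_kmer_hashes(seq, seed_k):
            index[int(h)].add(idx)
    return index


def _candidates(
    seq: str, index: dict[int, set[int]], seed_k: int
) -> list[tuple[int, str]]:
    """Partner fragments sharing >=1 exact seed with ``seq``, by strand."""
    hits: Counter[tuple[int, str]] = Counter()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for h in forward_kmer_hashes(s, seed_k):
            for ridx in index.get(int(h), ()):
                hits[(ridx, strand)] += 1
    ranked = sorted(hits.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    return [key for key, _count in ranked[:MAX_CANDIDATES]]


def orthoani(
    query: GenomeRecord,
    ref: GenomeRecord,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    min_frag_identity: float = DEFAULT_MIN_FRAG_IDENTITY,
    scoring: Scoring = DEFAULT_SCORING,
) -> ANIResult:
    """Reciprocal-best-fragment ANI between two genomes.

    Each query fragment is aligned (semi-globally, better strand kept)
    against ref fragments sharing an exact 16-mer; a fragment pair is
    retained when each is the other's best hit and the identity is at
    least ``min_frag_identity``.  With zero retained pairs the ANI is NaN
    and coverage 0.
    """
    qfrags = fragment_genome(query, fragment_length)
    rfrags = fragment_genome(ref, fragment_length)
    if not qfrags or not rfrags:
        return ANIResult(query.genome_id, ref.genome_id, math.nan, 0.0, 0, ())

    rindex = _seed_index(rfrags, PRESCREEN_K)
    rseqs = dict(rfrags)

    # identity of every prescreened (query, ref) fragment pair, best strand;
    # alignments covering < half the fragment length are ignored outright
    min_cols = int(MIN_FRAG_ALIGNED_FRACTION * fragment_length)
    pair_identity: dict[tuple[int, int], float] = {}
    for qidx, qseq in qfrags:
        for ridx, strand in _candidates(qseq, rindex, PRESCREEN_K):
            key = (qidx, ridx)
            q = qseq if strand == "+" else revcomp(qseq)
            res = semiglobal_align(q, rseqs[ridx], scoring)
            if res.aligned_columns < min_cols:
                continue
            if key not in pair_identity or res.identity_pct > pair_identity[key]:
                pair_identity[key] = res.identity_pct

    # reciprocal best hits (ties towards the lower partner index)
    q_best: dict[int, tuple[float, int]] = {}
    r_best: dict[int, tuple[float, int]] = {}
    for (qidx, ridx), ident in sorted(pair_identity.items()):
        if qidx not in q_best or ident > q_best[qidx][0]:
            q_best[qidx] = (ident, ridx)
        if ridx not in r_best or ident > r_best[ridx][0]:
            r_best[ridx] = (ident, qidx)

    retained: list[tuple[int, float]] = []
    for qidx, (ident, ridx) in sorted(q_best.items()):
        if r_best[ridx][1] == qidx and ident >= min_frag_identity:
            retained.append((qidx, ident))

    if not retained:
        return ANIResult(query.genome_id, ref.genome_id, math.nan, 0.0, 0, ())
    ani = sum(i for _, i in retained) / len(retained)
    coverage = 100.0 * len(retained) / len(qfrags)
    return ANIResult(
        query_id=query.genome_id,
        ref_id=ref.genome_id,
        ani_pct=ani,
        coverage_pct=coverage,
        n_fragments_used=len(retained),
        per_fragment=tuple(retained),
    )
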