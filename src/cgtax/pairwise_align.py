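"""Semi-global (free-end-gap) pairwise nucleotide alignment.

This is the identity statistic underlying both core-gene ANI and the 16S
rRNA decision: sequences are aligned globally but terminal gaps on either
sequence are free, so a shorter sequence (or a gene fragment) is not
penalized for the parts of its partner it does not cover.  Identity is
computed over the overlap region only — every column between the first and
last aligned pair, internal gaps included, terminal overhangs excluded —
which makes identity(a, a) = 100 while still penalizing indels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from ._align_kernel import MAX_LEN, semiglobal_kernel
from ._kmers import encode


class Scoring(NamedTuple):
    """Alignment scoring. A gap of length L costs ``gap_open + L * gap_extend``."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one semi-global alignment.

    ``aligned_columns`` counts columns inside the overlap region (terminal
    gaps excluded, internal gaps included); ``identity_pct`` is
    100 * matches / aligned_columns.  Spans are 0-based half-open.
    """

    identity_pct: float
    matches: int
    aligned_columns: int
    query_span: tuple[int, int]
    ref_span: tuple[int, int]
    score: int
    scoring: Scoring = DEFAULT_SCORING


def semiglobal_align(a: str, b: str, scoring: Scoring = DEFAULT_SCORING) -> AlignmentResult:
    """Optimal affine-gap overlap alignment of nucleotide sequences ``a`` and ``b``.

    Ties among co-optimal alignments are broken deterministically by
    preferring more matches, then fewer aligned columns.  N bases never
    match anything (including other Ns).

    Raises ``ValueError`` on an empty sequence; an all-N sequence yields
    identity 0 with a warning.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if len(a) > MAX_LEN or len(b) > MAX_LEN:
        raise ValueError(f"sequences longer than {MAX_LEN} bases are not supported")
    ac = encode(a)
    bc = encode(b)
    if (ac >= 4).all() or (bc >= 4).all():
        warnings.warn("aligning an all-ambiguous (N) sequence; identity is 0", stacklevel=2)
    sc = Scoring(*scoring)
    score, matches, cols, qs, qe, rs, re_ = semiglobal_kernel(
        ac, bc, sc.match, sc.mismatch, sc.gap_open, sc.gap_extend
    )
    identity = 100.0 * matches / cols if cols > 0 else 0.0
    return AlignmentResult(
        identity_pct=identity,
        matches=int(matches),
        aligned_columns=int(cols),
        query_span=(int(qs), int(qe)),
        ref_span=(int(rs), int(re_)),
        score=int(score),
        scoring=sc,
    )


def identity_matrix(seqs: Sequence[str], scoring: Scoring = DEFAULT_SCORING) -> np.ndarray:
    """All-vs-all semi-global identity matrix (percent), symmetric, diagonal 100."""
    if len(seqs) < 2:
        raise ValueError("identity_matrix requires at least 2 sequences")
    n = len(seqs)
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = semiglobal_align(seqs[i], seqs[j], scoring).identity_pct
            out[i, j] = ident
            out[j, i] = ident
    return out
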