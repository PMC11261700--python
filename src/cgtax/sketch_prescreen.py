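"""MinHash genome sketching and Mash-style distance estimation.

Used to shortlist reference genomes before the (much costlier) fragment
ANI computation, and to pick the closest core-gene neighbours before
cgANI placement.  A sketch keeps the ``s`` smallest 64-bit hash values
over a sequence set's canonical k-mers; the Jaccard index of two genomes
is estimated from the merged bottom-s sketch and converted to a distance
with the Mash formula d = -ln(2j / (1 + j)) / k.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._kmers import DEFAULT_HASH_SEED, canonical_kmer_hashes

logger = logging.getLogger("cgtax")

#: Default sketching parameters for whole genomes.
GENOME_K = 21
GENOME_S = 1000
#: Defaults for the concatenated core-gene prescreen (shorter sequences).
CORE_K = 16
CORE_S = 500

MIN_K = 11
MAX_K = 31  # packed-uint64 encoding limit


@dataclass(frozen=True)
class Sketch:
    """Bottom-s MinHash sketch of a sequence set.

    ``hashes`` is a strictly increasing tuple of at most ``s`` 64-bit
    values; ``seed`` records the hash seed so sketches are only comparable
    when built identically.
    """

    source_id: str
    k: int
    s: int
    hashes: tuple[int, ...]
    seed: int = DEFAULT_HASH_SEED

    def __post_init__(self) -> None:
        if len(self.hashes) > self.s:
            raise ValueError("sketch holds more than s hashes")
        if any(b <= a for a, b in zip(self.hashes, self.hashes[1:])):
            raise ValueError("sketch hashes must be strictly increasing")

    def to_dict(self) -> dict:
        return {
            "source_id": self.source_id,
            "k": self.k,
            "s": self.s,
            "seed": self.seed,
            "hashes": [format(h, "016x") for h in self.hashes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Sketch":
        return cls(
            source_id=d["source_id"],
            k=int(d["k"]),
            s=int(d["s"]),
            seed=int(d["seed"]),
            hashes=tuple(int(h, 16) for h in d["hashes"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as out:
            json.dump(self.to_dict(), out)

    @classmethod
    def load(cls, path) -> "Sketch":
        with open(path) as handle:
            return cls.from_dict(json.load(handle))


def sketch(
    seqs: str | Iterable[str],
    k: int = GENOME_K,
    s: int = GENOME_S,
    *,
    source_id: str = "",
    seed: int = DEFAULT_HASH_SEED,
) -> Sketch:
    """Bottom-s sketch of the canonical k-mers of one or more sequences.

    k-mers containing ambiguous bases are skipped; a sequence set shorter
    than k yields an empty sketch with a warning.
    """
    if not MIN_K <= k <= MAX_K:
        raise ValueError(f"k must be in [{MIN_K}, {MAX_K}], got {k}")
    if s < 1:
        raise ValueError("sketch size must be positive")
    if isinstance(seqs, str):
        seqs = [seqs]
    parts = [canonical_kmer_hashes(seq, k, seed) for seq in seqs]
    hashes = np.concatenate(parts) if parts else np.empty(0, np.uint64)
    if hashes.size == 0:
        logger.warning("%s: no valid %d-mers; sketch is empty", source_id or "<seqs>", k)
        return Sketch(source_id=source_id, k=k, s=s, hashes=(), seed=seed)
    distinct = np.unique(hashes)  # sorted ascending
    bottom = distinct[:s]
    return Sketch(
        source_id=source_id, k=k, s=s, hashes=tuple(int(h) for h in bottom), seed=seed
    )


def jaccard(a: Sketch, b: Sketch) -> float:
    """Jaccard index estimated from the merged bottom-s sketch."""
    if a.k != b.k:
        raise ValueError(f"cannot compare sketches with k={a.k} and k={b.k}")
    if a.seed != b.seed:
        raise ValueError("cannot compare sketches built with different hash seeds")
    if not a.hashes or not b.hashes:
        return 0.0
    s = min(a.s, b.s)
    sa, sb = set(a.hashes), set(b.hashes)
    merged = sorted(sa | sb)[:s]
    shared = sum(1 for h in merged if h in sa and h in sb)
    return shared / len(merged)


def mash_distance(a: Sketch, b: Sketch) -> float:
    """Mash distance d = -ln(2j/(1+j))/k in [0, 1]; j=0 is capped at 1.0."""
    j = jaccard(a, b)
    if j <= 0.0:
        return 1.0
    if j >= 1.0:
        return 0.0
    return min(1.0, -math.log(2.0 * j / (1.0 + j)) / a.k)


def top_hits(
    query: Sketch, refs: Sequence[Sketch], n: int
) -> list[tuple[str, float]]:
    """The ``n`` closest references by Mash distance, ascending.

    Ties are broken lexicographically by source_id; an empty reference list
    yields an empty result.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    scored = sorted(
        ((mash_distance(query, r), r.source_id) for r in refs),
        key=lambda t: (t[0], t[1]),
    )
    return [(sid, d) for d, sid in scored[:n]]
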