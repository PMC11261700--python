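"""Shared k-mer encoding and hashing primitives.

Nucleotides are packed 2 bits per base with A<C<G<T, so the numeric order
of packed k-mers equals lexicographic order and the canonical form of a
k-mer is simply the smaller of its forward and reverse-complement
encodings.  Hash values come from the splitmix64 finalizer with a fixed,
recorded seed, making sketches reproducible across runs and machines.
Windows containing any non-ACGT base are skipped.
"""

from __future__ import annotations

import numpy as np

#: Default seed mixed into every k-mer hash; recorded in sketch metadata.
DEFAULT_HASH_SEED = 42

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase
del _i, _b


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to uint8 codes A=0, C=1, G=2, T=3; other bases -> 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def splitmix64(x) -> np.ndarray:
    """Vectorized splitmix64 finalizer over uint64 values (wraps modulo 2**64)."""
    with np.errstate(over="ignore"):
        z = np.asarray(x, dtype=np.uint64) + np.uint64(0x9E3779B97F4A7C15)
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return z ^ (z >> np.uint64(31))


def mix64(x: int) -> int:
    """splitmix64 finalizer on a Python int reduced to 64 bits."""
    z = (x ^ (x >> 64)) & 0xFFFFFFFFFFFFFFFF
    z = (z + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return z ^ (z >> 31)


def _window_valid(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask over windows: True where the k-window has no ambiguous base."""
    bad = (codes >= 4).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    return (cs[k:] - cs[:-k]) == 0


def _packed_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward and reverse-complement packed codes for every window, plus validity."""
    if not 1 <= k <= 31:
        raise ValueError(f"packed k-mers require 1 <= k <= 31, got {k}")
    codes = encode(seq)
    n = codes.size
    if n < k:
        e = np.empty(0, np.uint64)
        return e, e, np.empty(0, bool)
    m = n - k + 1
    c = codes.astype(np.uint64)
    fwd = np.zeros(m, np.uint64)
    rev = np.zeros(m, np.uint64)
    for t in range(k):
        fwd = (fwd << np.uint64(2)) | c[t : t + m]
        rev |= (np.uint64(3) ^ c[t : t + m]) << np.uint64(2 * t)
    return fwd, rev, _window_valid(codes, k)


def canonical_kmer_hashes(seq: str, k: int, seed: int = DEFAULT_HASH_SEED) -> np.ndarray:
    """splitmix64 hashes of the canonical k-mers of ``seq``, in sequence order.

    Canonical means min(forward, reverse complement) of the packed encoding,
    so a sequence and its reverse complement hash to the same multiset.
    """
    fwd, rev, ok = _packed_kmers(seq, k)
    canon = np.minimum(fwd, rev)[ok]
    return splitmix64(canon ^ np.uint64(seed & 0xFFFFFFFFFFFFFFFF))


def forward_kmer_hashes(seq: str, k: int, seed: int = DEFAULT_HASH_SEED) -> np.ndarray:
    """Strand-specific (non-canonical) k-mer hashes, in sequence order."""
    fwd, _rev, ok = _packed_kmers(seq, k)
    return splitmix64(fwd[ok] ^ np.uint64(seed & 0xFFFFFFFFFFFFFFFF))


def iter_kmers(seq: str, k: int):
    """Yield ``(pos, canonical_code, forward_is_canonical)`` for valid k-mers.

    Works for any k (rolling Python-int encoding); used by the profiler
    where k=35 exceeds the 31-base packed-uint64 limit.
    """
    if k < 1:
        raise ValueError("k must be positive")
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    fwd = rev = 0
    valid = 0
    for i, ch in enumerate(seq):
        c = int(_CODE[ord(ch)])
        if c >= 4:
            valid = 0
            fwd = rev = 0
            continue
        fwd = ((fwd << 2) | c) & mask
        rev = (rev >> 2) | ((3 ^ c) << shift)
        valid += 1
        if valid >= k:
            if fwd <= rev:
                yield i - k + 1, fwd, True
            else:
                yield i - k + 1, rev, False


_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_RC)[::-1]
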