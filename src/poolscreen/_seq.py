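"""Fixed-length DNA sequence helpers (encoding, Hamming distance, tag drawing).

Tags and multiplex indexes are fixed-length, so every comparison here is
positional: no alignment, no indels.
"""
from __future__ import annotations

import numpy as np

BASES = b"ACGT"
_BASE_ARR = np.frombuffer(BASES, dtype=np.uint8)

# byte value -> 0..3 (255 marks a non-ACGT byte)
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _LUT[_b] = _i


def encode(seq: str) -> np.ndarray:
    """Return a 1-D uint8 view of an ASCII DNA string."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def encode_many(seqs) -> np.ndarray:
    """Stack equal-length sequences into an (n, L) uint8 matrix."""
    if isinstance(seqs, np.ndarray):
        if seqs.dtype != np.uint8 or seqs.ndim != 2:
            raise ValueError("expected a 2-D uint8 matrix")
        return seqs
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal length")
    flat = encode("".join(seqs))
    return flat.reshape(len(seqs), lengths.pop())


def decode(row: np.ndarray) -> str:
    return row.tobytes().decode("ascii")


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return int((encode(a) != encode(b)).sum())


def base_indices(mat: np.ndarray) -> np.ndarray:
    """Map ACGT bytes to 0..3; non-ACGT bytes map to 255."""
    return _LUT[mat]


def pack_tags(mat: np.ndarray) -> np.ndarray:
    """Pack each row of an (n, L<=31) ACGT matrix into a uint64 key.

    Rows containing non-ACGT bytes get a sentinel key that collides with
    nothing packable (high bit set).
    """
    idx = base_indices(mat).astype(np.uint64)
    bad = (idx == 255).any(axis=1)
    idx[idx == 255] = 0
    weights = (np.uint64(4) ** np.arange(mat.shape[1], dtype=np.uint64))
    keys = idx @ weights
    keys[bad] = np.uint64(1) << np.uint64(63)
    return keys


def random_sequences(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    return _BASE_ARR[rng.integers(0, 4, size=(n, length))]


def random_unique_tags(
    rng: np.random.Generator,
    n: int,
    length: int = 20,
    min_dist: int = 5,
    max_tries: int | None = None,
) -> list[str]:
    """Draw ``n`` random tags with pairwise Hamming distance >= ``min_dist``.

    Rejection sampling, seeded; the distance floor makes mismatch-tolerant
    mapping unambiguous by construction.
    """
    if min_dist > length:
        raise ValueError("min_dist cannot exceed tag length")
    max_tries = max_tries if max_tries is not None else 200 * n + 1000
    mat = np.empty((n, length), dtype=np.uint8)
    count = 0
    tries = 0
    while count < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not draw {n} tags of length {length} at distance "
                f">= {min_dist} in {max_tries} tries"
            )
        cand = _BASE_ARR[rng.integers(0, 4, size=length)]
        if count and int((mat[:count] != cand).sum(axis=1).min()) < min_dist:
            continue
        mat[count] = cand
        count += 1
    return [decode(row) for row in mat]


def min_pairwise_distance(mat: np.ndarray) -> int:
    """Smallest Hamming distance over all row pairs (len(mat) >= 2)."""
    n = mat.shape[0]
    best = mat.shape[1]
    for i in range(n - 1):
        d = (mat[i + 1:] != mat[i]).sum(axis=1).min()
        best = min(best, int(d))
        if best == 0:
            break
    return best
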