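"""Small shared helpers: seed derivation and DNA encoding tables."""

from __future__ import annotations

import hashlib

import numpy as np

BASES = "ACGT"
BASE_TO_INDEX = {b: i for i, b in enumerate(BASES)}

# ASCII lookup table: base index (0..3) -> byte value of A/C/G/T
_INDEX_TO_ASCII = np.frombuffer(BASES.encode(), dtype=np.uint8)

# byte value -> base index, 255 for anything that is not A/C/G/T (including N).
# A 255 entry can never equal a real code letter, so each such position counts
# as one mismatch in Hamming comparisons.
_ASCII_TO_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ASCII_TO_INDEX[ord(_b)] = _i
    _ASCII_TO_INDEX[ord(_b.lower())] = _i


def derive_seed(seed: int, stage: str) -> int:
    """Derive a stage-specific 31-bit seed from a single run seed.

    Hashing the ``"{seed}:{stage}"`` string means every stochastic stage of a
    run gets an independent, documented stream, and any stage can be rerun in
    isolation reproducibly.
    """
    digest = hashlib.blake2b(f"{seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def encode_sequences(seqs: list[str], length: int, offset: int = 0) -> np.ndarray:
    """Encode the ``[offset, offset+length)`` slice of each sequence as a
    (n, length) uint8 matrix of base indices.

    Sequences too short to cover the slice are filled with 255 so they match
    nothing.
    """
    n = len(seqs)
    out = np.full((n, length), 255, dtype=np.uint8)
    if n == 0:
        return out
    # Fast path: most inputs are homogeneous-length reads.
    blob = ("\n".join(s[offset : offset + length] for s in seqs) + "\n").encode(
        "ascii", errors="replace"
    )
    if len(blob) == n * (length + 1):
        arr = np.frombuffer(blob, dtype=np.uint8).reshape(n, length + 1)
        return _ASCII_TO_INDEX[arr[:, :length]]
    # Ragged fallback
    for i, s in enumerate(seqs):
        piece = s[offset : offset + length]
        if len(piece) == length:
            out[i] = _ASCII_TO_INDEX[
                np.frombuffer(piece.encode("ascii", errors="replace"), dtype=np.uint8)
            ]
    return out


def indices_to_bytes(mat: np.ndarray) -> bytes:
    """Render a (n, k) base-index matrix as one contiguous ASCII byte blob."""
    return _INDEX_TO_ASCII[mat].tobytes()


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))
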