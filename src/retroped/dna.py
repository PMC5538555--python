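"""Low-level nucleotide utilities shared across the package.

Sequences are handled either as Python ``bytes`` (ASCII upper-case) or as
NumPy ``uint8`` code arrays (A=0, C=1, G=2, T=3, N=4).  All coordinates are
0-based, half-open; conversions to 1-based happen only at I/O boundaries.
"""

from __future__ import annotations

import numpy as np

BASES = b"ACGTN"

# ASCII byte -> 2-bit code (N and anything else -> 4)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case

_DECODE = np.frombuffer(BASES, dtype=np.uint8)

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_COMP_ASCII = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMP_ASCII[_a] = _b


def encode(seq: bytes | str) -> np.ndarray:
    """ASCII sequence -> uint8 code array."""
    if isinstance(seq, str):
        seq = seq.encode()
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> bytes:
    """uint8 code array -> ASCII bytes."""
    return _DECODE[codes].tobytes()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def revcomp(seq: bytes | str) -> bytes:
    if isinstance(seq, str):
        seq = seq.encode()
    return _COMP_ASCII[np.frombuffer(seq, dtype=np.uint8)][::-1].tobytes()


def gc_fraction(codes: np.ndarray) -> float:
    """GC fraction over non-N bases; NaN if the window is entirely N."""
    valid = codes < 4
    n = int(valid.sum())
    if n == 0:
        return float("nan")
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / n


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.42) -> np.ndarray:
    """Random code array with the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply random substitutions at the given per-base rate."""
    out = codes.copy()
    n = len(out)
    hit = np.nonzero(rng.random(n) < rate)[0]
    if len(hit):
        # substitute with one of the three other bases
        shift = rng.integers(1, 4, size=len(hit)).astype(np.uint8)
        out[hit] = (out[hit] + shift) % 4
    return out


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mers of a code array packed into uint64, plus a validity mask.

    A k-mer containing an N (code 4) is marked invalid.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    if n <= 4096:
        # short queries: one windowed matmul beats the accumulation loop
        win = np.lib.stride_tricks.sliding_window_view(codes, k)
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.uint64)
        bad_any = codes == 4
        valid = ~np.lib.stride_tricks.sliding_window_view(bad_any, k).any(axis=1)
        vals = (win * np.uint64(1)) @ powers
        return vals, valid
    # horizontal accumulation keeps memory at O(n) for genome-scale input
    vals = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    isn = codes == 4
    for i in range(k):
        vals = vals * np.uint64(4) + np.where(isn[i:i + n], 0,
                                              codes[i:i + n]).astype(np.uint64)
        bad |= isn[i:i + n]
    return vals, ~bad
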