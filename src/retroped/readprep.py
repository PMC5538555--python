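"""Quality trimming and read-pair merging.

Reads are end-trimmed (never internally) to the longest span whose first
and last base have quality >= q_min (default 10).  Pairs are then merged
into contigs by scanning overlaps between read 1 and the reverse
complement of read 2, accepting the overlap with the lowest mismatch
density if it clears ``min_overlap`` / ``max_mismatch_density``
(pinned to 10 / 0.25, the documented defaults of the common overlap-based
pair mergers).  Pairs without an acceptable overlap are retained unmerged
and each mate is analyzed downstream exactly like a contig.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import dna

DEFAULT_Q_MIN = 10
DEFAULT_MIN_OVERLAP = 10
DEFAULT_MAX_MISMATCH_DENSITY = 0.25


@dataclass
class Read:
    id: str
    sequence: bytes
    qualities: np.ndarray  # uint8 Phred scores

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.uint8)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")
        if len(self.qualities) and self.qualities.max() > 60:
            raise ValueError(f"{self.id}: Phred scores must be in [0, 60]")

    @property
    def empty(self) -> bool:
        return len(self.sequence) == 0


@dataclass
class Contig:
    """A merged pair (or a single retained mate) ready for alignment."""

    id: str
    sequence: bytes
    merged: bool
    source_pair: str
    overlap_len: int | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.merged and (self.overlap_len or 0) < 1:
            raise ValueError("merged contig must record its overlap length")


def trim_read(read: Read, q_min: int = DEFAULT_Q_MIN) -> Read:
    """End-trim to the longest span with terminal qualities >= q_min.

    Interior low-quality bases are retained; an all-low-quality read
    becomes empty (flagged for discard via ``Read.empty``).  Idempotent.
    """
    q = read.qualities
    n = len(q)
    if n and q[0] >= q_min and q[-1] >= q_min:
        return read
    ok = q >= q_min
    if not ok.any():
        return Read(read.id, b"", np.empty(0, dtype=np.uint8))
    start = int(np.argmax(ok))
    end = n - int(np.argmax(ok[::-1]))
    return Read(read.id, read.sequence[start:end], read.qualities[start:end])


def _overlap_mismatches(a: np.ndarray, b: np.ndarray,
                        min_overlap: int) -> tuple[np.ndarray, np.ndarray]:
    """Mismatch count for every candidate overlap length.

    Overlap of length L compares the suffix ``a[-L:]`` with the prefix
    ``b[:L]``.  Returns (lengths, mismatch counts), vectorized over all
    candidate lengths.
    """
    n1, n2 = len(a), len(b)
    lengths = np.arange(min_overlap, min(n1, n2) + 1)
    if len(lengths) == 0:
        return lengths, np.empty(0, dtype=int)
    pos, valid = _overlap_index(n1, n2, min_overlap)
    cmp = (a[pos] != b[None, :pos.shape[1]]) & valid
    return lengths, cmp.sum(axis=1)


from functools import lru_cache


@lru_cache(maxsize=64)
def _overlap_index(n1: int, n2: int, min_overlap: int):
    """Gather/validity matrices for the overlap scan (cached per shape)."""
    lengths = np.arange(min_overlap, min(n1, n2) + 1)
    j = np.arange(int(lengths.max()))
    pos = n1 - lengths[:, None] + j[None, :]
    valid = j[None, :] < lengths[:, None]
    pos = np.where(valid, pos, 0).astype(np.intp)
    return pos, valid


def merge_pair(r1: Read, r2: Read,
               min_overlap: int = DEFAULT_MIN_OVERLAP,
               max_mismatch_density: float = DEFAULT_MAX_MISMATCH_DENSITY,
               ) -> Contig | tuple[Read, Read]:
    """Merge a trimmed pair into a contig, or return the mates unmerged.

    All overlap lengths >= min_overlap between r1 and revcomp(r2) are
    scored; the lowest-mismatch-density overlap wins if its density is
    <= max_mismatch_density.  At disagreeing positions the higher-quality
    base is taken; agreeing positions get quality min(q1 + q2, 60).
    """
    if r1.empty or r2.empty:
        return r1, r2
    a = np.frombuffer(r1.sequence, dtype=np.uint8)
    b_seq = dna.revcomp(r2.sequence)
    b = np.frombuffer(b_seq, dtype=np.uint8)
    bq = r2.qualities[::-1]

    lengths, mism = _overlap_mismatches(a, b, min_overlap)
    if len(lengths) == 0:
        return r1, r2
    density = mism / lengths
    best = int(np.argmin(density))
    if density[best] > max_mismatch_density:
        return r1, r2
    L = int(lengths[best])

    n1, n2 = len(a), len(b)
    left = a[:n1 - L]
    ov_a, ov_b = a[n1 - L:], b[:L]
    qa, qb = r1.qualities[n1 - L:], bq[:L]
    take_b = (ov_a != ov_b) & (qb > qa)
    overlap = np.where(take_b, ov_b, ov_a)
    ov_q = np.where(ov_a == ov_b,
                    np.minimum(qa.astype(int) + qb.astype(int), 60),
                    np.maximum(qa, qb)).astype(np.uint8)
    right = b[L:]
    seq = left.tobytes() + overlap.tobytes() + right.tobytes()
    quals = np.concatenate([r1.qualities[:n1 - L], ov_q, bq[L:]])
    return Contig(id=r1.id + "/m", sequence=seq, merged=True,
                  source_pair=r1.id, overlap_len=L)


def prepare_pair(r1: Read, r2: Read,
                 q_min: int = DEFAULT_Q_MIN,
                 min_overlap: int = DEFAULT_MIN_OVERLAP,
                 max_mismatch_density: float = DEFAULT_MAX_MISMATCH_DENSITY,
                 ) -> list[Contig]:
    """Trim then merge one pair; unmerged mates become single-read contigs."""
    t1, t2 = trim_read(r1, q_min), trim_read(r2, q_min)
    if t1.empty and t2.empty:
        return []
    if t1.empty or t2.empty:
        keep = t2 if t1.empty else t1
        seq = keep.sequence if keep is t1 else dna.revcomp(keep.sequence)
        return [Contig(id=keep.id, sequence=seq, merged=False, source_pair=r1.id)]
    result = merge_pair(t1, t2, min_overlap, max_mismatch_density)
    if isinstance(result, Contig):
        return [result]
    u1, u2 = result
    return [
        Contig(id=u1.id + "/1", sequence=u1.sequence, merged=False, source_pair=r1.id),
        Contig(id=u2.id + "/2", sequence=dna.revcomp(u2.sequence), merged=False,
               source_pair=r1.id),
    ]
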