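"""Two-pass alignment: unique genome placement and TE-consensus filtering.

The genome pass is a seed-and-extend mapper with a contract equivalent to
the retained-read semantics of short-read DNA aligners run in unique mode:
k-mer seeds (k=15 by default) vote for candidate diagonals, candidate loci
are verified by gapped alignment (match +1, mismatch -2, gap open -4, gap
extend -1), and a hit is *unique* only if its score exceeds the best
runner-up at a distinct locus by ``uniqueness_margin`` (5 by default).
Hits below ``genome_min_identity`` (0.94) are rejected, so contigs that
straddle an insertion junction come back unmapped and flow to the
consensus pass.

The consensus pass scores terminal-anchored local alignments of a contig
against every element of the capture panel on both strands; a hit passes
iff identity > 0.90 and the alignment spans >= 33 nt measured from one
contig end.  Seeding uses 8-mers: any terminal alignment that can pass the
filter (span >= 33 nt at > 90% identity) necessarily contains an exact
8-mer run, so seeding loses no passing hit.

Verification of gapped candidates delegates the dynamic programming to
``edlib`` (banded bit-parallel edit-distance DP); seeding, candidate
selection, scoring and the uniqueness/identity contracts are implemented
here.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from . import dna

DEFAULT_K = 15
UNIQUENESS_MARGIN = 5
GENOME_MIN_IDENTITY = 0.94
CONSENSUS_MIN_IDENTITY = 0.90
CONSENSUS_MIN_TERMINAL_SPAN = 33

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -2, -4, -1


@dataclass
class AlignmentHit:
    query_id: str
    query_span: tuple[int, int]     # 0-based half-open on the query
    ref_name: str
    ref_span: tuple[int, int]       # 0-based half-open on the reference
    strand: str                     # query strand relative to reference
    matches: int
    columns: int                    # alignment length incl. gaps
    score: int
    unique: bool | None = None      # defined only for genome hits
    base_quality_sum: int = 0

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


class GenomeIndex:
    """Sorted-array k-mer index of the concatenated reference (plus strand).

    Queries are looked up on both contig strands, so indexing one genome
    strand covers both.
    """

    def __init__(self, sequences: dict[str, np.ndarray], k: int = DEFAULT_K):
        if k < 11:
            raise ValueError("k must be >= 11")
        self.k = k
        self.chrom_names = list(sequences)
        lengths = [len(sequences[c]) for c in self.chrom_names]
        if min(lengths) < k:
            raise ValueError("k larger than the shortest reference sequence")
        self.chrom_offsets = np.concatenate([[0], np.cumsum(lengths)])
        self.genome = np.concatenate([sequences[c] for c in self.chrom_names])
        kmers_parts, pos_parts = [], []
        for ci, c in enumerate(self.chrom_names):
            vals, valid = dna.kmer_codes(sequences[c], k)
            pos = np.nonzero(valid)[0].astype(np.int64) + self.chrom_offsets[ci]
            kmers_parts.append(vals[valid])
            pos_parts.append(pos)
        kmers = np.concatenate(kmers_parts)
        positions = np.concatenate(pos_parts)
        order = np.argsort(kmers, kind="stable")
        self.sorted_kmers = kmers[order]
        self.sorted_positions = positions[order]

    def lookup_bounds(self, kmers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self.sorted_kmers, kmers, side="left")
        hi = np.searchsorted(self.sorted_kmers, kmers, side="right")
        return lo, hi

    def gather(self, lo: np.ndarray, hi: np.ndarray,
               qpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Expand (lo, hi) ranges to (query positions, genome positions)."""
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return (np.empty(0, dtype=np.int64),) * 2
        shift = np.concatenate(([0], np.cumsum(counts)[:-1]))
        idx = np.arange(total) + np.repeat(lo - shift, counts)
        return np.repeat(qpos, counts), self.sorted_positions[idx]

    def lookup(self, kmers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Global positions of each query k-mer; returns (qidx, positions)."""
        lo, hi = self.lookup_bounds(kmers)
        return self.gather(lo, hi, np.arange(len(kmers)))

    def to_chrom(self, gpos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(self.chrom_offsets, gpos, side="right")) - 1
        return self.chrom_names[ci], int(gpos - self.chrom_offsets[ci])

    def chrom_bounds(self, gpos: int) -> tuple[int, int]:
        ci = int(np.searchsorted(self.chrom_offsets, gpos, side="right")) - 1
        return int(self.chrom_offsets[ci]), int(self.chrom_offsets[ci + 1])


def index_reference(sequences: dict[str, np.ndarray],
                    k: int = DEFAULT_K) -> GenomeIndex:
    return GenomeIndex(sequences, k)


def _score_from_cigar(cigar: str) -> tuple[int, int, int]:
    """(matches, columns, score) under the package scoring scheme."""
    matches = columns = score = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        columns += n
        if ch == "=":
            matches += n
            score += MATCH * n
        elif ch == "X":
            score += MISMATCH * n
        elif ch in "DI":
            score += GAP_OPEN + GAP_EXTEND * (n - 1)
    return matches, columns, score


def _verify(index: GenomeIndex, q: np.ndarray, gpos_lo: int, gpos_hi: int,
            ) -> tuple[int, int, int, tuple[int, int]] | None:
    """Align query against a reference window; (matches, columns, score, span).

    Fast path: gap-free comparison at the seeded diagonal.  Fallback to
    edlib glocal DP when the gap-free identity is low (possible indel).
    """
    lo, hi = index.chrom_bounds(gpos_lo)
    n = len(q)
    start = max(lo, gpos_lo)
    if start + n <= hi:
        ref = index.genome[start:start + n]
        m = int((ref == q).sum())
        if m >= 0.97 * n:
            score = m * MATCH + (n - m) * MISMATCH
            return m, n, score, (start, start + n)
    wlo = max(lo, gpos_lo - 30)
    whi = min(hi, gpos_lo + n + 30)
    if whi - wlo < n // 2:
        return None
    res = edlib.align(dna.decode(q).decode(),
                      dna.decode(index.genome[wlo:whi]).decode(),
                      mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"] or not res["cigar"]:
        return None
    s, e = res["locations"][0]
    matches, columns, score = _score_from_cigar(res["cigar"])
    return matches, columns, score, (wlo + s, wlo + e + 1)


def map_to_genome(index: GenomeIndex, contig_seq: bytes, contig_id: str = "",
                  uniqueness_margin: int = UNIQUENESS_MARGIN,
                  min_identity: float = GENOME_MIN_IDENTITY,
                  seed_stride: int = 4,
                  quality_sum: int = 0) -> AlignmentHit | None:
    """Best unique genome placement of a contig, or None if unmapped.

    Returns a hit with ``unique=False`` when a distinct locus scores within
    ``uniqueness_margin`` of the best (such contigs are discarded
    downstream, mirroring unique-mode retention).  Returns None when no
    candidate reaches ``min_identity``.
    """
    k = index.k
    if len(contig_seq) < k:
        return None
    q_fwd = dna.encode(contig_seq)
    candidates: list[tuple[int, str, np.ndarray, int]] = []
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.uint64)

    for strand, q in (("+", q_fwd), ("-", dna.revcomp_codes(q_fwd))):
        n_kmers = len(q) - k + 1
        if n_kmers <= 0:
            continue
        sel = np.arange(0, n_kmers, seed_stride)
        win = np.lib.stride_tricks.sliding_window_view(q, k)[sel]
        seed_vals = (win * np.uint64(1)) @ powers
        ok = ~(win == 4).any(axis=1)
        sel, seed_vals = sel[ok], seed_vals[ok]
        if len(sel) == 0:
            continue
        qidx, gpos = index.lookup(seed_vals)
        _collect_candidates(gpos, sel[qidx], strand, q, candidates)

    return _finalize(index, contig_seq, candidates, uniqueness_margin,
                     min_identity, contig_id, quality_sum)


def _collect_candidates(gpos: np.ndarray, qoff: np.ndarray, strand: str,
                        q: np.ndarray, candidates: list) -> None:
    if len(gpos) == 0:
        return
    diags = gpos - qoff
    uniq_diags, votes = np.unique(diags, return_counts=True)
    # merge diagonals within a small band (indel tolerance)
    order = np.argsort(-votes)
    taken: list[int] = []
    for oi in order[:8]:
        d = int(uniq_diags[oi])
        if any(abs(d - t) <= 30 for t in taken):
            continue
        taken.append(d)
        candidates.append((int(votes[oi]), strand, q, d))


def _finalize(index: GenomeIndex, contig_seq: bytes, candidates: list,
              uniqueness_margin: int, min_identity: float,
              contig_id: str, quality_sum: int) -> AlignmentHit | None:
    candidates.sort(key=lambda c: -c[0])
    evaluated: list[tuple[int, int, int, tuple[int, int], str]] = []
    for ci, (votes, strand, q, diag) in enumerate(candidates[:6]):
        # seeds are specific at k=15: a locus with a small fraction of the
        # top candidate's seed support cannot approach its score, so skip
        # verifying it once a near-perfect best hit is in hand
        if ci and evaluated and votes * 3 < candidates[0][0] and \
                evaluated[0][1] >= 0.97 * evaluated[0][2]:
            break
        out = _verify(index, q, diag, diag + len(q))
        if out is None:
            continue
        matches, columns, score, span = out
        evaluated.append((score, matches, columns, span, strand))
        evaluated.sort(key=lambda e: -e[0])

    if not evaluated:
        return None
    evaluated.sort(key=lambda e: -e[0])
    score, matches, columns, span, strand = evaluated[0]
    identity = matches / columns if columns else 0.0
    if identity < min_identity:
        return None
    # runner-up at a distinct locus (>= 1 contig length away or other strand)
    runner = None
    for s2, _m2, _c2, span2, strand2 in evaluated[1:]:
        distinct = strand2 != strand or abs(span2[0] - span[0]) > len(contig_seq)
        if distinct:
            runner = s2
            break
    unique = runner is None or (score - runner) >= uniqueness_margin
    chrom, local = index.to_chrom(span[0])
    return AlignmentHit(
        query_id=contig_id, query_span=(0, len(contig_seq)),
        ref_name=chrom, ref_span=(local, local + (span[1] - span[0])),
        strand=strand, matches=matches, columns=columns, score=score,
        unique=unique, base_quality_sum=quality_sum)


def map_batch(index: GenomeIndex, seqs: list[bytes],
              uniqueness_margin: int = UNIQUENESS_MARGIN,
              min_identity: float = GENOME_MIN_IDENTITY,
              seed_stride: int = 4) -> list[AlignmentHit | None]:
    """Map many contigs at once (bulk k-mer lookup, then per-contig logic).

    Equivalent to calling :func:`map_to_genome` per contig; the k-mer index
    probes for the whole batch are issued as two vectorized searches.
    """
    k = index.k
    n = len(seqs)
    if n == 0:
        return []
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=n)
    width = int(lengths.max())
    mat = np.full((n, width), 4, dtype=np.uint8)
    for i, s in enumerate(seqs):
        mat[i, :len(s)] = dna.encode(s)
    rc = _COMP_BATCH[mat][:, ::-1]   # rc row i is right-aligned in the pad
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.uint64)
    sel = np.arange(0, max(1, width - k + 1), seed_stride)
    gather_idx = sel[:, None] + np.arange(k)[None, :]
    glen = int(index.chrom_offsets[-1])
    span = glen + width + 1   # diagonal range per contig

    # per-contig candidate lists, filled strand by strand in bulk
    cand: list[list] = [[] for _ in range(n)]
    for strand, m in (("+", mat), ("-", rc)):
        win = m[:, gather_idx]                       # n x seeds x k
        vals = (win.reshape(n * len(sel), k) * np.uint64(1)) @ powers
        ok = ~(win == 4).any(axis=2).reshape(-1)
        lo, hi = index.lookup_bounds(vals)
        lo[~ok] = 0
        hi[~ok] = 0
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            continue
        shift = np.concatenate(([0], np.cumsum(counts)[:-1]))
        idx = np.arange(total) + np.repeat(lo - shift, counts)
        gpos = index.sorted_positions[idx]
        flat_seed = np.repeat(np.arange(n * len(sel)), counts)
        row = flat_seed // len(sel)
        qoff = sel[flat_seed % len(sel)]
        if strand == "-":
            qoff = qoff - (width - lengths[row])
        diag = gpos - qoff
        key = row * span + (diag + width)
        ukey, votes = np.unique(key, return_counts=True)
        urow = ukey // span
        udiag = ukey % span - width
        # per-contig segments of the sorted unique keys
        starts = np.searchsorted(urow, np.arange(n + 1))
        for i in range(n):
            s0, s1 = starts[i], starts[i + 1]
            if s0 == s1:
                continue
            v = votes[s0:s1]
            d = udiag[s0:s1]
            order = np.argsort(-v)[:8]
            L = int(lengths[i])
            q = mat[i, :L] if strand == "+" else rc[i, width - L:]
            taken: list[int] = []
            for oi in order:
                dd = int(d[oi])
                if any(abs(dd - t) <= 30 for t in taken):
                    continue
                taken.append(dd)
                cand[i].append((int(v[oi]), strand, q, dd))

    # bulk fast path: a contig whose seeds all vote for one diagonal has no
    # competing locus sharing any k-mer; a near-exact gap-free match there
    # is the unique best placement.  Verify those in one vectorized pass.
    single = np.array([i for i in range(n) if len(cand[i]) == 1])
    out: list[AlignmentHit | None] = [None] * n
    slow = [i for i in range(n) if len(cand[i]) != 1]
    if len(single):
        diags = np.array([cand[i][0][3] for i in single])
        cols = np.arange(width)
        gidx = np.clip(diags[:, None] + cols[None, :], 0, glen - 1)
        ref_rows = index.genome[gidx]
        qmat = np.empty((len(single), width), dtype=np.uint8)
        for j, i in enumerate(single):
            L = int(lengths[i])
            strand = cand[i][0][1]
            qmat[j, :L] = mat[i, :L] if strand == "+" else rc[i, width - L:]
            qmat[j, L:] = 4
        valid = cols[None, :] < lengths[single][:, None]
        matches = ((ref_rows == qmat) & valid).sum(axis=1)
        Ls = lengths[single]
        good = (matches >= 0.97 * Ls) & (diags >= 0) & (diags + Ls <= glen)
        # placement must not straddle a chromosome boundary
        ci_a = np.searchsorted(index.chrom_offsets,
                               np.clip(diags, 0, glen - 1), side="right")
        ci_b = np.searchsorted(index.chrom_offsets,
                               np.clip(diags + Ls - 1, 0, glen - 1),
                               side="right")
        good &= ci_a == ci_b
        for j, i in enumerate(single):
            if not good[j]:
                slow.append(i)
                continue
            L = int(Ls[j])
            m = int(matches[j])
            identity = m / L
            if identity < min_identity:
                out[i] = None
                continue
            chrom, local = index.to_chrom(int(diags[j]))
            out[i] = AlignmentHit(
                query_id="", query_span=(0, L), ref_name=chrom,
                ref_span=(local, local + L), strand=cand[i][0][1],
                matches=m, columns=L,
                score=m * MATCH + (L - m) * MISMATCH, unique=True)
    for i in slow:
        out[i] = _finalize(index, seqs[i], cand[i], uniqueness_margin,
                           min_identity, "", 0)
    return out


_COMP_BATCH = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def remove_duplicates(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Keep one hit per (ref_name, ref_span, strand) key.

    Survivor: highest summed base quality, ties broken by lexicographic
    query id — deterministic regardless of input order.
    """
    best: dict[tuple, AlignmentHit] = {}
    for h in hits:
        key = (h.ref_name, h.ref_span, h.strand)
        prev = best.get(key)
        if prev is None or (h.base_quality_sum, _neg(h.query_id)) > \
                (prev.base_quality_sum, _neg(prev.query_id)):
            best[key] = h
    return sorted(best.values(), key=lambda h: (h.ref_name, h.ref_span, h.strand))


class _neg(str):
    """Inverts string comparison so 'highest quality, then smallest id' works."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# consensus pass
# ---------------------------------------------------------------------------

class ConsensusIndex:
    """8-mer index over the concatenated consensus library (both strands)."""

    K = 8

    def __init__(self, library):
        self.elements = list(library)
        seqs = []
        self.meta: list[tuple[int, str, int]] = []  # (offset, name, strand_len)
        offset = 0
        self.offsets = []
        for el in self.elements:
            for strand in "+-":
                codes = dna.encode(el.sequence)
                if strand == "-":
                    codes = dna.revcomp_codes(codes)
                seqs.append(codes)
                self.offsets.append((offset, offset + len(codes), el.name, strand))
                offset += len(codes)
        self.concat = np.concatenate(seqs)
        vals, valid = dna.kmer_codes(self.concat, self.K)
        # mask k-mers spanning element boundaries
        pos = np.arange(len(vals))
        for o_start, o_end, _n, _s in self.offsets:
            valid &= ~((pos > o_end - self.K) & (pos < o_end))
        self.positions = np.nonzero(valid)[0].astype(np.int64)
        kmers = vals[valid]
        order = np.argsort(kmers, kind="stable")
        self.sorted_kmers = kmers[order]
        self.sorted_positions = self.positions[order]

    def locate(self, gpos: int) -> tuple[str, str, int, int]:
        """(element name, strand, local position, element length)."""
        for o_start, o_end, name, strand in self.offsets:
            if o_start <= gpos < o_end:
                return name, strand, gpos - o_start, o_end - o_start
        raise IndexError(gpos)


def _terminal_extension(q: np.ndarray, ref: np.ndarray) -> tuple[int, int]:
    """Best gap-free terminal-anchored alignment along one diagonal.

    ``q`` and ``ref`` are equal-length arrays already laid out so that
    position 0 is the anchored contig end (sequences reversed for the
    3' end).  Returns (span, matches) of the maximal-score prefix.
    """
    n = min(len(q), len(ref))
    if n == 0:
        return 0, 0
    eq = (q[:n] == ref[:n]).astype(np.int32)
    score = np.cumsum(np.where(eq == 1, MATCH, MISMATCH))
    best = int(np.argmax(score))
    if score[best] <= 0:
        return 0, 0
    span = best + 1
    return span, int(np.cumsum(eq)[best])


def align_to_consensus(contig_seq: bytes, cindex: ConsensusIndex,
                       contig_id: str = "",
                       min_identity: float = CONSENSUS_MIN_IDENTITY,
                       min_terminal_span: int = CONSENSUS_MIN_TERMINAL_SPAN,
                       ) -> list[AlignmentHit]:
    """Terminal-anchored consensus hits passing the >90% / >=33-nt filter.

    For each contig end, seeded diagonals are extended gap-free from the
    end inward; a hit passes iff its identity exceeds ``min_identity`` and
    it covers at least ``min_terminal_span`` nt measured from that end.
    At most one hit per (end, element, strand) is reported.
    """
    q = dna.encode(contig_seq)
    n = len(q)
    if n < cindex.K:
        return []
    vals, valid = dna.kmer_codes(q, cindex.K)
    sel = np.nonzero(valid)[0]
    if len(sel) == 0:
        return []
    km = vals[sel]
    lo = np.searchsorted(cindex.sorted_kmers, km, side="left")
    hi = np.searchsorted(cindex.sorted_kmers, km, side="right")
    counts = hi - lo
    if counts.sum() == 0:
        return []
    qidx = np.repeat(sel, counts)
    gpos = np.concatenate([cindex.sorted_positions[l:h]
                           for l, h in zip(lo, hi) if h > l])
    diags = gpos - qidx
    uniq_diags = np.unique(diags)

    hits: dict[tuple, AlignmentHit] = {}
    concat = cindex.concat
    total = len(concat)
    for d in uniq_diags:
        d = int(d)
        # layout for the 5'-anchored (contig start) extension
        for end in ("start", "end"):
            if end == "start":
                r0 = d
                if r0 < 0 or r0 >= total:
                    continue
                o_start, o_end, name, strand = _find_block(cindex, r0)
                limit = min(n, o_end - r0)
                span, matches = _terminal_extension(q[:limit],
                                                    concat[r0:r0 + limit])
                qspan = (0, span)
                rspan_concat = (r0, r0 + span)
                reaches_terminus = rspan_concat[1] == o_end
            else:
                r_last = d + n - 1
                if r_last < 0 or r_last >= total:
                    continue
                o_start, o_end, name, strand = _find_block(cindex, r_last)
                limit = min(n, r_last - o_start + 1)
                span, matches = _terminal_extension(
                    q[::-1][:limit], concat[max(o_start, r_last - limit + 1):
                                            r_last + 1][::-1])
                qspan = (n - span, n)
                rspan_concat = (r_last + 1 - span, r_last + 1)
                reaches_terminus = rspan_concat[0] == o_start
            if span < min_terminal_span:
                continue
            identity = matches / span
            if identity <= min_identity:
                continue
            # convert to element-local coordinates in element orientation
            local = (rspan_concat[0] - o_start, rspan_concat[1] - o_start)
            el_len = o_end - o_start
            if strand == "-":
                local = (el_len - local[1], el_len - local[0])
            key = (end, name, strand)
            score = matches * MATCH + (span - matches) * MISMATCH
            # tandem 5'-UTR monomers make the diagonal ambiguous by one
            # monomer unit; extensions whose inner endpoint reaches an
            # element terminus get a small selection bonus so junction
            # segments anchor at the element 5' start / 3' end (parsimony)
            eff = score + (3 if reaches_terminus else 0)
            prev = hits.get(key)
            if prev is None or eff > prev[0]:
                hits[key] = (eff, AlignmentHit(
                    query_id=contig_id, query_span=qspan, ref_name=name,
                    ref_span=local, strand=strand, matches=matches,
                    columns=span, score=score))
    return sorted((h for _e, h in hits.values()), key=lambda h: -h.score)


def _find_block(cindex: ConsensusIndex, gpos: int) -> tuple[int, int, str, str]:
    for o_start, o_end, name, strand in cindex.offsets:
        if o_start <= gpos < o_end:
            return o_start, o_end, name, strand
    raise IndexError(gpos)
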