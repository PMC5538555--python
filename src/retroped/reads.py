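"""Capture-enriched paired-end read simulation.

The fragment model reflects hybridization capture: ``coverage_target`` is
the mean read depth over capture-targeted bases (TE-annotated reference
intervals and inserted-element alleles); off-target background is sampled
at ``coverage_target / capture_enrichment``.  Insertion-allele fragments
are drawn from per-insertion alternative windows (the local haplotype
with the insertion applied) at a rate proportional to the tissue allele
fraction, which models mosaicism by per-fragment haplotype sampling.

Artifacts layered on top, each truth-tagged in the read names:

* fragments spanning the element-3'/poly(A) junction are dropped with
  probability ``three_prime_depletion`` (the depletion of L1 3' termini);
* per-base substitution errors at ``per_base_error``;
* PCR duplicates: a ``duplicate_rate`` fraction of fragments re-emitted at
  identical coordinates;
* chimeras: a ``chimera_rate`` fraction of fragments spliced from two
  unrelated loci (one of them biased into TE sequence, because capture
  enriches TE-containing molecules).

Read names encode provenance:
``<sample>|<serial>|<source>|<flags>`` where source is
``ref:<chrom>:<start>`` or ``ins:<insertion_id>:<offset>`` and flags may
include ``dup`` and ``chimera``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dna
from .consensus import ConsensusElement
from .insertions import allele_codes
from .reference import Reference
from .simconfig import SimConfig, PlannedInsertion


@dataclass
class AltWindow:
    """Local haplotype around one insertion: ref flank + allele + ref flank."""

    insertion_id: str
    chrom: str
    codes: np.ndarray
    ref_start: int           # reference coordinate of codes[0]
    allele_start: int        # offset of the inserted cassette within codes
    allele_end: int
    pA_junction: int         # offset of the element-3'/genome boundary


def build_alt_windows(reference: Reference, plan: list[PlannedInsertion],
                      library: list[ConsensusElement],
                      flank: int = 700) -> dict[str, AltWindow]:
    out = {}
    for ev in plan:
        allele = allele_codes(ev, library)
        left = ev.nick_pos + ev.tsd_len
        right = ev.nick_pos
        codes = np.concatenate([
            reference.seq(ev.chrom, left - flank, left),
            allele,
            reference.seq(ev.chrom, right, right + flank),
        ])
        a_start = min(flank, left)
        a_end = a_start + len(allele)
        # poly(A)/genome boundary: right end of cassette for '+' events,
        # left end for '-' events (where the poly(A) reads as poly(T))
        pa = a_end if ev.strand == "+" else a_start
        out[ev.id] = AltWindow(ev.id, ev.chrom, codes, left - a_start,
                               a_start, a_end, pa)
    return out


@dataclass
class SimulatedReads:
    """One sample's read pairs, kept as arrays for fast processing."""

    sample_id: str
    names: list[str]
    r1_seq: list[bytes]
    r1_qual: list[np.ndarray]
    r2_seq: list[bytes]
    r2_qual: list[np.ndarray]

    def __len__(self) -> int:
        return len(self.names)


def _target_intervals(reference: Reference) -> list[tuple[str, int, int]]:
    return [(r.chrom, int(r.start), int(r.end))
            for r in reference.annotation.itertuples()]


def _qualities(n_reads: int, length: int, config: SimConfig,
               rng: np.random.Generator) -> np.ndarray:
    q = np.full((n_reads, length), config.base_quality, dtype=np.uint8)
    tail = rng.random(n_reads) < config.quality_tail_prob
    tail_len = rng.geometric(1.0 / max(1, config.quality_tail_mean), size=n_reads)
    tail_len = np.minimum(tail_len, length // 2)
    for i in np.nonzero(tail)[0]:
        t = int(tail_len[i])
        q[i, length - t:] = rng.integers(2, 9, size=t)
    return q


def _apply_errors(codes: np.ndarray, rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return codes
    return dna.mutate(codes, rate, rng)


def simulate_sample_reads(reference: Reference, alt_windows: dict[str, AltWindow],
                          fractions: dict[str, float], config: SimConfig,
                          rng: np.random.Generator, sample_id: str,
                          coverage: float | None = None) -> SimulatedReads:
    """Simulate one library (animal x tissue).

    ``fractions`` maps insertion id -> allele fraction in this tissue.
    ``coverage`` overrides ``config.coverage_target`` (e.g. deep germ-cell
    libraries).
    """
    cov = coverage if coverage is not None else config.coverage_target
    rl = config.read_length
    inserts = np.array(config.insert_sizes)
    mean_insert = float(inserts.mean())
    genome_len = sum(reference.chrom_lengths().values())
    chrom_names = list(reference.chroms)
    chrom_lens = np.array([len(reference.chroms[c]) for c in chrom_names])
    chrom_cum = np.concatenate([[0], np.cumsum(chrom_lens)])

    base_rate = cov / config.capture_enrichment  # off-target read depth
    # fragments needed for depth d over length L: d * L / (2 * read_length)
    def n_frags(depth: float, length: float) -> int:
        lam = depth * length / (2.0 * rl)
        return int(rng.poisson(lam))

    frag_src: list[tuple] = []   # ("ref", gstart) or ("alt", ins_id, offset)

    # background
    n_bg = n_frags(base_rate, genome_len)
    for g in rng.integers(0, genome_len - int(inserts.max()), size=n_bg):
        frag_src.append(("ref", int(g)))
    # on-target boost over annotated TE intervals (reference alleles)
    boost = cov - base_rate
    for chrom, start, end in _target_intervals(reference):
        goff = int(chrom_cum[chrom_names.index(chrom)])
        span_lo = max(0, start - int(inserts.max()) + rl)
        span_hi = end
        for p in rng.integers(span_lo, span_hi,
                              size=n_frags(boost, end - start)):
            frag_src.append(("ref", goff + int(p)))
    # insertion alleles, proportional to allele fraction
    for ins_id, frac in fractions.items():
        if frac <= 0:
            continue
        win = alt_windows[ins_id]
        a_len = win.allele_end - win.allele_start
        lo = max(0, win.allele_start - int(inserts.max()) + rl)
        hi = min(len(win.codes) - rl, win.allele_end)
        if hi <= lo:
            continue
        for p in rng.integers(lo, hi, size=n_frags(cov * frac, a_len)):
            frag_src.append(("alt", ins_id, int(p)))

    # assemble fragments, applying 3' depletion and duplicates
    names: list[str] = []
    r1_list: list[np.ndarray] = []
    r2_list: list[np.ndarray] = []
    serial = 0
    genome = np.concatenate([reference.chroms[c] for c in chrom_names])

    def emit(codes: np.ndarray, label: str, flag: str = "") -> None:
        nonlocal serial
        insert = int(inserts[rng.integers(len(inserts))])
        if len(codes) < insert:
            return
        r1 = codes[:rl]
        r2 = dna.revcomp_codes(codes[insert - rl:insert])
        serial += 1
        names.append(f"{sample_id}|{serial}|{label}|{flag}")
        r1_list.append(r1)
        r2_list.append(r2)
        if config.duplicate_rate > 0 and rng.random() < config.duplicate_rate:
            serial += 1
            names.append(f"{sample_id}|{serial}|{label}|dup")
            r1_list.append(r1.copy())
            r2_list.append(r2.copy())

    max_insert = int(inserts.max())
    for src in frag_src:
        if src[0] == "ref":
            g = src[1]
            codes = genome[g:g + max_insert]
            ci = int(np.searchsorted(chrom_cum, g, side="right")) - 1
            # skip fragments spanning a chromosome boundary
            if g + max_insert > chrom_cum[ci + 1]:
                continue
            label = f"ref:{chrom_names[ci]}:{g - chrom_cum[ci]}"
        else:
            _, ins_id, p = src
            win = alt_windows[ins_id]
            codes = win.codes[p:p + max_insert]
            if len(codes) < max_insert:
                continue
            # 3' junction depletion
            if p < win.pA_junction < p + max_insert and \
                    rng.random() < config.three_prime_depletion:
                continue
            label = f"ins:{ins_id}:{p}"
        emit(codes, label)

    # chimeric fragments: two spliced halves from unrelated loci
    if config.chimera_rate > 0:
        n_chim = int(rng.binomial(max(len(names), 1), config.chimera_rate))
        te_rows = reference.annotation
        for _ in range(n_chim):
            insert = int(inserts[rng.integers(len(inserts))])
            cut = int(rng.integers(rl // 3, insert - rl // 3))
            g1 = int(rng.integers(0, genome_len - insert))
            part1 = genome[g1:g1 + cut]
            if len(te_rows) and rng.random() < 0.7:
                row = te_rows.iloc[int(rng.integers(len(te_rows)))]
                lo = int(chrom_cum[chrom_names.index(row.chrom)]) + int(row.start)
                hi = int(chrom_cum[chrom_names.index(row.chrom)]) + int(row.end)
                g2 = int(rng.integers(lo, max(lo + 1, hi - (insert - cut))))
            else:
                g2 = int(rng.integers(0, genome_len - insert))
            part2 = genome[g2:g2 + insert - cut]
            codes = np.concatenate([part1, part2])
            if len(codes) < insert:
                continue
            serial += 1
            names.append(f"{sample_id}|{serial}|chim:{g1}:{g2}|chimera")
            r1_list.append(codes[:rl])
            r2_list.append(dna.revcomp_codes(codes[insert - rl:insert]))

    n = len(names)
    if n == 0:
        return SimulatedReads(sample_id, [], [], [], [], [])
    r1 = np.stack(r1_list)
    r2 = np.stack(r2_list)
    if config.per_base_error > 0:
        r1 = _err2d(r1, config.per_base_error, rng)
        r2 = _err2d(r2, config.per_base_error, rng)
    q1 = _qualities(n, rl, config, rng)
    q2 = _qualities(n, rl, config, rng)
    return SimulatedReads(
        sample_id=sample_id, names=names,
        r1_seq=[dna.decode(r1[i]) for i in range(n)],
        r1_qual=[q1[i] for i in range(n)],
        r2_seq=[dna.decode(r2[i]) for i in range(n)],
        r2_qual=[q2[i] for i in range(n)],
    )


def _err2d(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = arr.copy()
    hit = rng.random(out.shape) < rate
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum())).astype(np.uint8)
        out[hit] = (out[hit] + shift) % 4
    return out


def write_fastq_pair(reads: SimulatedReads, path1, path2,
                     gzip_output: bool = True) -> None:
    """Write the pair as Phred+33 FASTQ (optionally gzipped)."""
    import gzip as _gzip
    op = (lambda p: _gzip.open(p, "wt")) if gzip_output else (lambda p: open(p, "w"))
    with op(path1) as f1, op(path2) as f2:
        for i, name in enumerate(reads.names):
            q1 = (reads.r1_qual[i] + 33).tobytes().decode("ascii")
            q2 = (reads.r2_qual[i] + 33).tobytes().decode("ascii")
            f1.write(f"@{name}/1\n{reads.r1_seq[i].decode()}\n+\n{q1}\n")
            f2.write(f"@{name}/2\n{reads.r2_seq[i].decode()}\n+\n{q2}\n")


def read_fastq_pair(path1, path2) -> SimulatedReads:
    """Read a (possibly gzipped) FASTQ pair back into arrays."""
    import gzip as _gzip

    def rd(path):
        opener = _gzip.open if str(path).endswith(".gz") else open
        names, seqs, quals = [], [], []
        with opener(path, "rt") as fh:
            while True:
                h = fh.readline().strip()
                if not h:
                    break
                seq = fh.readline().strip()
                fh.readline()
                q = fh.readline().strip()
                names.append(h[1:].rsplit("/", 1)[0])
                seqs.append(seq.encode())
                quals.append(np.frombuffer(q.encode(), dtype=np.uint8) - 33)
        return names, seqs, quals

    n1, s1, q1 = rd(path1)
    _n2, s2, q2 = rd(path2)
    sample = n1[0].split("|")[0] if n1 else ""
    return SimulatedReads(sample, n1, s1, q1, s2, q2)
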