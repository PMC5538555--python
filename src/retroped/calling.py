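"""Clustered non-reference insertion calls from filtered contig alignments.

A contig that failed unique end-to-end genome placement but carries a
passing terminal consensus hit is split into a TE segment and a genome
remainder; the remainder is re-mapped and, if uniquely placed with a
sufficient anchor (>= 25 nt by default), yields a ``JunctionRead`` whose
``junction_pos`` is the reference coordinate adjacent to the TE segment.
Junction reads are single-linkage clustered (gap <= 100 bp) per
(chrom, side, orientation); clusters with >= 3 supporting reads across the
cohort are primary-call eligible, while 1-2-read clusters are retained as
first-class low-evidence records because the mosaicism logic depends on
them.  5' and 3' clusters within 50 bp merge into one call.  Calls are
annotated (never deleted) as known-polymorphic / founder-polymorphic, and
an automated chimera filter replaces manual inspection.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import (AlignmentHit, GenomeIndex, ConsensusIndex, map_to_genome,
                    align_to_consensus)
from .consensus import MONOMER_LEN

MIN_GENOME_ANCHOR = 25
CLUSTER_WINDOW = 100
PAIR_SEPARATION = 50
MIN_CLUSTER_READS = 3
MATCH_SLOP = 100
OVERLAP_SLOP = 12

#: consensus-coordinate tolerance for calling a TE boundary "terminal"
TERMINAL_TOL = 30


@dataclass
class JunctionRead:
    contig_id: str
    sample_id: str
    genome_hit: AlignmentHit
    te_hit: AlignmentHit
    junction_pos: int
    side: str                  # five_prime | three_prime
    te_orientation: str        # + | - on the reference
    subfamily: str
    te_boundary_local: int     # consensus coordinate adjacent to the junction
    te_len: int
    chimera_tag: bool = False  # truth tag carried through for evaluation


@dataclass
class Cluster:
    chrom: str
    side: str
    te_orientation: str
    subfamily: str
    reads: list[JunctionRead]

    @property
    def positions(self) -> list[int]:
        return [r.junction_pos for r in self.reads]

    @property
    def modal_pos(self) -> int:
        vals, counts = np.unique(self.positions, return_counts=True)
        return int(vals[counts == counts.max()].min())

    def support(self) -> dict[str, int]:
        out: dict[str, int] = defaultdict(int)
        for r in self.reads:
            out[r.sample_id] += 1
        return dict(out)


@dataclass
class InsertionCall:
    id: str
    chrom: str
    pos_5p: int | None
    pos_3p: int | None
    te_orientation: str
    subfamily: str
    support: dict[str, int]
    clusters: list[Cluster] = field(default_factory=list)
    known_polymorphic: bool = False
    founder_polymorphic: bool = False
    chimera_suspect: bool = False
    chimera_rules: tuple[str, ...] = ()
    reference_te: bool = False

    @property
    def primary(self) -> bool:
        return sum(self.support.values()) >= MIN_CLUSTER_READS

    @property
    def pos(self) -> int:
        p5, p3 = self.pos_5p, self.pos_3p
        return p5 if p5 is not None else p3  # type: ignore[return-value]

    def detection_class(self, sample_id: str) -> str:
        n = self.support.get(sample_id, 0)
        if n >= MIN_CLUSTER_READS:
            return "robust"
        return "low" if n > 0 else "absent"


class DiscardLedger(defaultdict):
    """Counts of contigs discarded at each junction-extraction gate."""

    def __init__(self):
        super().__init__(int)


def extract_junctions(contig_seq: bytes, contig_id: str, sample_id: str,
                      te_hits: list[AlignmentHit], gindex: GenomeIndex,
                      element_lengths: dict[str, int],
                      ledger: DiscardLedger | None = None,
                      min_genome_anchor: int = MIN_GENOME_ANCHOR,
                      chimera_tag: bool = False) -> list[JunctionRead]:
    """Junction reads from one unmapped contig with passing consensus hits.

    The best terminal hit per contig end is used; the non-TE remainder must
    map uniquely with >= ``min_genome_anchor`` nt.  For 3'-side junctions
    the poly(A) homopolymer between element and genome is stripped from the
    remainder before anchoring (the anchored coordinate then sits at the
    poly(A)/genome boundary, within a few bases of the true junction).
    """
    ledger = ledger if ledger is not None else DiscardLedger()
    n = len(contig_seq)
    out: list[JunctionRead] = []
    by_end: dict[str, AlignmentHit] = {}
    for h in te_hits:
        end = "start" if h.query_span[0] == 0 else "end"
        if end not in by_end or h.score > by_end[end].score:
            by_end[end] = h
    # a contig whose TE hits cover (almost) everything has no genome anchor
    te_cover = sum(h.query_span[1] - h.query_span[0] for h in by_end.values())
    if n - te_cover < min_genome_anchor:
        ledger["no_genome_anchor"] += 1
        return out

    for end, te in by_end.items():
        el_len = element_lengths.get(te.ref_name, te.ref_span[1])
        side, boundary = _junction_geometry(te, el_len, end)
        if side == "internal":
            # interior junction-adjacent TE boundary: kept as evidence (the
            # chimera filter keys on the -1 sentinel); side approximated
            side = "five_prime" if boundary < el_len / 2 else "three_prime"
            interior = True
        else:
            interior = False
        if end == "start":
            remainder = contig_seq[te.query_span[1]:]
            stripped = _strip_homopolymer(remainder, leading=True) \
                if side == "three_prime" else 0
            remainder = remainder[stripped:]
        else:
            remainder = contig_seq[:te.query_span[0]]
            stripped = _strip_homopolymer(remainder, leading=False) \
                if side == "three_prime" else 0
            remainder = remainder[:len(remainder) - stripped] if stripped \
                else remainder
        if len(remainder) < min_genome_anchor:
            ledger["anchor_too_short"] += 1
            continue
        ghit = map_to_genome(gindex, remainder, contig_id=contig_id)
        if ghit is None:
            ledger["anchor_unmapped"] += 1
            continue
        if not ghit.unique:
            ledger["anchor_not_unique"] += 1
            continue
        if ghit.identity < 0.9 or (ghit.query_span[1] - ghit.query_span[0]
                                   < min_genome_anchor):
            ledger["anchor_poor"] += 1
            continue

        # reference coordinate adjacent to the TE segment
        if (end == "start") == (ghit.strand == "+"):
            junction = ghit.ref_span[0]
        else:
            junction = ghit.ref_span[1]
        orientation = "+" if te.strand == ghit.strand else "-"

        out.append(JunctionRead(
            contig_id=contig_id, sample_id=sample_id, genome_hit=ghit,
            te_hit=te, junction_pos=int(junction), side=side,
            te_orientation=orientation, subfamily=te.ref_name,
            te_boundary_local=-1 if interior else boundary, te_len=el_len,
            chimera_tag=chimera_tag))
    return out


def _strip_homopolymer(seq: bytes, leading: bool, max_strip: int = 80) -> int:
    """Length of the leading/trailing A- or T-run (poly(A) pass-through)."""
    probe = seq[:max_strip] if leading else seq[::-1][:max_strip]
    best = 0
    for base in (ord("A"), ord("T")):
        k = 0
        while k < len(probe) and probe[k] == base:
            k += 1
        best = max(best, k)
    return best if best >= 4 else 0


def _junction_geometry(te: AlignmentHit, el_len: int,
                       end: str) -> tuple[str, int]:
    """(side, consensus boundary coordinate adjacent to the genome).

    ``te.strand`` is the contig strand matching the consensus.  At a
    genuine 5' junction the genome abuts the element 5' start (boundary
    ~0); at a 3' junction it abuts the element 3' end / poly(A) (boundary
    ~element length).  An interior boundary marks the segment as a
    chimera candidate.
    """
    if end == "start":
        boundary = te.ref_span[1] if te.strand == "+" else te.ref_span[0]
    else:
        boundary = te.ref_span[0] if te.strand == "+" else te.ref_span[1]
    if boundary <= TERMINAL_TOL:
        side = "five_prime"
    elif boundary >= el_len - TERMINAL_TOL:
        side = "three_prime"
    else:
        side = "internal"
    return side, int(boundary)


def cluster_junctions(reads: list[JunctionRead],
                      window: int = CLUSTER_WINDOW) -> list[Cluster]:
    """Single-linkage clustering per (chrom, side, orientation, subfamily)."""
    groups: dict[tuple, list[JunctionRead]] = defaultdict(list)
    for r in reads:
        groups[(r.genome_hit.ref_name, r.side, r.te_orientation,
                r.subfamily)].append(r)
    clusters: list[Cluster] = []
    for (chrom, side, orient, subfam), rs in sorted(groups.items()):
        rs.sort(key=lambda r: (r.junction_pos, r.contig_id))
        current: list[JunctionRead] = []
        for r in rs:
            if current and r.junction_pos - current[-1].junction_pos > window:
                clusters.append(Cluster(chrom, side, orient, subfam, current))
                current = []
            current.append(r)
        if current:
            clusters.append(Cluster(chrom, side, orient, subfam, current))
    return clusters


def pair_clusters(clusters: list[Cluster],
                  separation: int = PAIR_SEPARATION) -> list[InsertionCall]:
    """Merge compatible 5'/3' cluster pairs; unpaired become single-junction.

    Many-to-many ambiguity is resolved by nearest-position greedy matching.
    """
    five = [c for c in clusters if c.side == "five_prime"]
    three = [c for c in clusters if c.side == "three_prime"]
    pairs: list[tuple[int, int, int]] = []
    for i, c5 in enumerate(five):
        for j, c3 in enumerate(three):
            if c5.chrom != c3.chrom or c5.te_orientation != c3.te_orientation \
                    or c5.subfamily != c3.subfamily:
                continue
            d = abs(c5.modal_pos - c3.modal_pos)
            if d <= separation:
                pairs.append((d, i, j))
    pairs.sort()
    used5: set[int] = set()
    used3: set[int] = set()
    calls: list[InsertionCall] = []

    def support_of(*cs: Cluster) -> dict[str, int]:
        out: dict[str, int] = defaultdict(int)
        for c in cs:
            for s, n in c.support().items():
                out[s] += n
        return dict(out)

    for d, i, j in pairs:
        if i in used5 or j in used3:
            continue
        used5.add(i)
        used3.add(j)
        c5, c3 = five[i], three[j]
        calls.append(InsertionCall(
            id="", chrom=c5.chrom, pos_5p=c5.modal_pos, pos_3p=c3.modal_pos,
            te_orientation=c5.te_orientation, subfamily=c5.subfamily,
            support=support_of(c5, c3), clusters=[c5, c3]))
    for i, c5 in enumerate(five):
        if i not in used5:
            calls.append(InsertionCall(
                id="", chrom=c5.chrom, pos_5p=c5.modal_pos, pos_3p=None,
                te_orientation=c5.te_orientation, subfamily=c5.subfamily,
                support=support_of(c5), clusters=[c5]))
    for j, c3 in enumerate(three):
        if j not in used3:
            calls.append(InsertionCall(
                id="", chrom=c3.chrom, pos_5p=None, pos_3p=c3.modal_pos,
                te_orientation=c3.te_orientation, subfamily=c3.subfamily,
                support=support_of(c3), clusters=[c3]))
    calls.sort(key=lambda c: (c.chrom, c.pos))
    for n, c in enumerate(calls, 1):
        c.id = f"call_{n:03d}"
    return calls


def filter_known(calls: list[InsertionCall], known_poly: pd.DataFrame,
                 founder_samples: dict[str, list[str]],
                 match_slop: int = MATCH_SLOP) -> list[InsertionCall]:
    """Annotate known-polymorphic and founder-polymorphic calls (flags only).

    ``founder_samples`` maps founder animal id -> list of its library
    sample ids.  A call is founder-polymorphic if robustly detected in
    every library of at least one founder.
    """
    for call in calls:
        for row in known_poly.itertuples():
            if row.chrom == call.chrom and \
                    abs(int(row.start) - call.pos) <= match_slop:
                call.known_polymorphic = True
                break
        for founder, samples in founder_samples.items():
            if samples and all(call.detection_class(s) == "robust"
                               for s in samples):
                call.founder_polymorphic = True
                break
    return calls


#: slop around annotated reference TE copies; junctions inside it are the
#: reference copy's own termini (or its 3' transduction tag), not new events
REFERENCE_TE_SLOP = 350


def filter_reference_te(calls: list[InsertionCall], annotation: pd.DataFrame,
                        slop: int = REFERENCE_TE_SLOP) -> list[InsertionCall]:
    """Flag calls whose junction abuts an annotated reference TE copy.

    Junction clusters at the termini of reference decoy/donor copies (and
    in the transduced tag region downstream of a donor) are signatures of
    the reference copy itself — e.g. reads carrying a 3' transduction
    anchor in the donor's downstream tag — and are not non-reference
    insertions.  Flagged calls are excluded from primary reporting but
    kept for donor tracing.
    """
    for call in calls:
        for row in annotation.itertuples():
            if row.chrom != call.chrom:
                continue
            if int(row.start) - slop <= call.pos <= int(row.end) + slop:
                call.reference_te = True
                break
    return calls


def chimera_filter(calls: list[InsertionCall]) -> list[InsertionCall]:
    """Flag chimera-suspect calls (annotation; excluded from classification).

    Rules: (a) genome anchors of the supporting reads fall into more than
    one locus group (> 1 kb apart); (b) TE segments within one cluster
    disagree on consensus orientation; (c) the supporting reads are a pure
    PCR stack (>= 2 reads, all at identical anchor coordinates, no second
    distinct fragment); (d) the TE-side boundary is interior to the
    consensus — in full-length-only mode a genuine junction abuts the
    element 5' start or its 3' end (within ``TERMINAL_TOL`` plus the
    poly(A)/TSD wobble).
    """
    for call in calls:
        rules: list[str] = []
        reads = [r for c in call.clusters for r in c.reads]
        anchors = sorted(r.genome_hit.ref_span[0] for r in reads)
        if anchors and anchors[-1] - anchors[0] > 1000:
            rules.append("a")
        for c in call.clusters:
            if len({r.te_orientation for r in c.reads}) > 1 or \
                    len({r.te_hit.strand for r in c.reads}) > 1:
                rules.append("b")
                break
        coords = {(r.genome_hit.ref_name, r.genome_hit.ref_span,
                   r.genome_hit.strand) for r in reads}
        if len(reads) >= 2 and len(coords) == 1:
            rules.append("c")
        # rule (d): the far end of a genuine junction segment is terminal on
        # the consensus (full-length-only mode); interior far ends are
        # marked with the -1 sentinel at extraction time
        interior = [r.te_boundary_local < 0 for r in reads]
        if interior and np.mean(interior) > 0.5:
            rules.append("d")
        if rules:
            call.chimera_suspect = True
            call.chimera_rules = tuple(sorted(set(rules)))
    return calls


def build_presence_matrix(calls: list[InsertionCall],
                          samples: list[str]) -> pd.DataFrame:
    """Complete call x sample support-count matrix (explicit zeros)."""
    for call in calls:
        unknown = set(call.support) - set(samples)
        if unknown:
            raise ValueError(f"samples {unknown} missing from the sample sheet")
    data = {s: [call.support.get(s, 0) for call in calls] for s in samples}
    return pd.DataFrame(data, index=[c.id for c in calls])
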