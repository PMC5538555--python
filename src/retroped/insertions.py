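"""Planning and application of TPRT insertion events.

An insertion is planned at a position matching the L1 endonuclease cleavage
motif (5'-TTTT/AA-3', up to a configured mismatch budget), receives a
target-site duplication sampled from the configured range (13-17 bp by
default), a truncated-normal poly(A) length (mean ~64 bp), and optionally a
3' transduction taken from the unique tag region downstream of a donor
element.

Coordinate convention (see ``PlannedInsertion``): the nick position is the
slash of the motif; the TSD is ``ref[nick : nick+tsd]``; the modified
haplotype is ``ref[:nick+tsd] + cassette + ref[nick:]`` so both flanks
retain the TSD.  On the plus strand the cassette reads
``element + transduction + poly(A)``; minus-strand events insert its
reverse complement, so the element poly(A) reads as poly(T) on the
reference plus strand at the left (5'-most) side.
"""

from __future__ import annotations

import numpy as np

from . import dna
from .consensus import ConsensusElement, MONOMER_LEN, A_TAIL_LEN
from .reference import Reference, DONOR_TAG_LEN
from .simconfig import SimConfig, PlannedInsertion, ConfigError


class PlanningError(ConfigError):
    pass


def motif_positions(codes: np.ndarray, motif: str,
                    max_mismatches: int) -> tuple[np.ndarray, np.ndarray]:
    """Nick (slash) positions matching the motif within the mismatch budget.

    Returns plus-strand and minus-strand nick position arrays.  A
    plus-strand nick ``n`` means ``ref[n-4 : n+2]`` matches ``TTTTAA``; a
    minus-strand nick is the mirror on the reverse complement, i.e.
    ``revcomp(ref[n-2 : n+4])`` matches the motif.
    """
    m = dna.encode(motif)
    k = len(m)
    slash = 4  # nick falls between TTTT and AA
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    mm_plus = np.zeros(n, dtype=np.int16)
    mm_minus = np.zeros(n, dtype=np.int16)
    rc = dna.revcomp_codes(m)
    for i in range(k):
        mm_plus += codes[i:i + n] != m[i]
        mm_minus += codes[i:i + n] != rc[i]
    starts_p = np.nonzero(mm_plus <= max_mismatches)[0]
    starts_m = np.nonzero(mm_minus <= max_mismatches)[0]
    # plus: motif occupies [s, s+6), slash after position s+3 -> nick = s+4
    # minus: motif on bottom strand; slash maps to nick = s+2 on top strand
    return starts_p + slash, starts_m + (k - slash)


def plan_insertion(reference: Reference, config: SimConfig, origin_class: str,
                   rng: np.random.Generator,
                   library: list[ConsensusElement],
                   subfamily: str = "L1_TF",
                   exclude: list[tuple[str, int, int]] | None = None,
                   insertion_id: str | None = None,
                   force_transduction_len: int | None = None) -> PlannedInsertion:
    """Plan one insertion at a motif-matching site.

    ``exclude`` lists (chrom, start, end) intervals the nick must avoid
    (existing annotation and previously planned events are excluded by the
    caller).
    """
    el = {e.name: e for e in library}[subfamily]
    chrom_names = list(reference.chroms)
    chrom = chrom_names[rng.integers(len(chrom_names))]
    codes = reference.chroms[chrom]
    pos_p, pos_m = motif_positions(codes, config.en_motif, config.en_max_mismatches)
    cand = np.concatenate([pos_p, pos_m])
    strands = np.concatenate([np.full(len(pos_p), "+"), np.full(len(pos_m), "-")])
    margin = 600
    keep = (cand > margin) & (cand < len(codes) - margin)
    blocked = np.zeros(len(cand), dtype=bool)
    for bchrom, bstart, bend in exclude or []:
        if bchrom == chrom:
            blocked |= (cand >= bstart - margin) & (cand < bend + margin)
    keep &= ~blocked
    if not keep.any():
        raise PlanningError(
            f"no position matching motif {config.en_motif} within "
            f"{config.en_max_mismatches} mismatches is available on {chrom}")
    idx = rng.choice(np.nonzero(keep)[0])
    nick = int(cand[idx])
    strand = str(strands[idx])

    tsd_len = int(rng.integers(config.tsd_range[0], config.tsd_range[1] + 1))
    polyA_len = max(config.polyA_min,
                    int(round(rng.normal(config.polyA_mean, config.polyA_sd))))

    el_len = len(el.sequence)
    if el.te_class == "LINE" and rng.random() < config.truncation_prob:
        start = int(rng.integers(MONOMER_LEN, el_len - 500))
        element_span = (start, el_len)
    else:
        element_span = (0, el_len)
    n_monomers = 0
    if el.monomer_unit is not None and element_span[0] == 0:
        n_monomers = el.sequence.count(el.monomer_unit)

    transduction = None
    donors = reference.donors()
    if len(donors) and rng.random() < config.transduction_prob:
        donor = donors.iloc[int(rng.integers(len(donors)))]
        if force_transduction_len is not None:
            tlen = force_transduction_len
        else:
            tlen = int(rng.integers(config.transduction_len_range[0],
                                    config.transduction_len_range[1] + 1))
        tlen = min(tlen, DONOR_TAG_LEN)
        tchrom, tstart, tend, tstrand = reference.donor_tag(str(donor["name"]))
        if tstrand == "+":
            seg = reference.seq(tchrom, tstart, tstart + tlen)
        else:
            seg = dna.revcomp_codes(reference.seq(tchrom, tend - tlen, tend))
        transduction = (dna.decode(seg), str(donor["name"]))

    return PlannedInsertion(
        id=insertion_id or f"ins_{origin_class}_{nick}",
        chrom=chrom, nick_pos=nick, strand=strand, subfamily=subfamily,
        element_span=element_span, n_monomers=n_monomers, tsd_len=tsd_len,
        polyA_len=polyA_len, transduction=transduction,
        origin_class=origin_class)


def cassette_codes(event: PlannedInsertion,
                   library: list[ConsensusElement]) -> np.ndarray:
    """Inserted sequence in element orientation (5'->3'), excluding the TSD.

    The consensus terminal A-tail is dropped so the poly(A) length of the
    product equals the planned ``polyA_len`` exactly.
    """
    el = {e.name: e for e in library}[event.subfamily]
    seq = dna.encode(el.sequence)[event.element_span[0]:event.element_span[1]]
    if el.te_class in ("LINE", "SINE") and event.element_span[1] == len(el.sequence):
        seq = seq[:len(seq) - A_TAIL_LEN]
    parts = [seq]
    if event.transduction is not None:
        parts.append(dna.encode(event.transduction[0]))
    parts.append(np.zeros(event.polyA_len, dtype=np.uint8))  # code 0 == A
    return np.concatenate(parts)


def allele_codes(event: PlannedInsertion,
                 library: list[ConsensusElement]) -> np.ndarray:
    """Cassette as it appears on the reference plus strand (incl. strand flip)."""
    cas = cassette_codes(event, library)
    return cas if event.strand == "+" else dna.revcomp_codes(cas)


def apply_insertions(haplotype: np.ndarray, events: list[PlannedInsertion],
                     library: list[ConsensusElement]) -> np.ndarray:
    """Apply sorted, non-overlapping events to one chromosome sequence."""
    if not events:
        return haplotype.copy()
    order = sorted(events, key=lambda e: e.nick_pos)
    for a, b in zip(order, order[1:]):
        if b.nick_pos < a.nick_pos + a.tsd_len:
            raise PlanningError(f"overlapping events {a.id} and {b.id}")
    pieces = []
    prev = 0
    for ev in order:
        left = ev.nick_pos + ev.tsd_len
        pieces.append(haplotype[prev:left])
        pieces.append(allele_codes(ev, library))
        prev = ev.nick_pos
    pieces.append(haplotype[prev:])
    return np.concatenate(pieces)
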