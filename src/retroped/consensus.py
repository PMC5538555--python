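"""Synthetic retrotransposon consensus library.

The library emulates the structure of the presently active mouse
retrotransposon families targeted by capture sequencing: the L1 subfamilies
T_F, G_F and A (long, with tandem 5' UTR monomer units), the SINEs B1 and B2
(short), and the LTR elements IAP and ETn.  The sequences themselves are
deterministic pseudo-random stand-ins, NOT real Repbase consensuses: every
element is generated once from a fixed internal seed so that the library is
identical across runs and machines.

Design notes:

* The three L1 subfamilies share a common "body" at ~5% divergence (real
  subfamilies share ORFs) but carry distinct monomer units, so subfamily
  assignment by best average identity is meaningful.
* Each L1 body ends in a GC-rich 3' segment (the depletion of mouse L1
  3' termini during sequencing has been attributed to the GC-rich 3' end)
  followed by a short A-tail.  The A-tail makes 3'-junction read segments
  terminal-anchored on the consensus, as in real capture protocols where
  the poly(A) is part of the junction contig.
* IAP and ETn stand-ins are shorter than the real elements; only their
  presence as decoys matters to the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dna

#: fixed internal seed -- the library is a versioned artifact, not a sample
_LIBRARY_SEED = 614230987

#: length of the A-tail appended to L1/SINE consensus 3' ends
A_TAIL_LEN = 25

MONOMER_LEN = 212


@dataclass(frozen=True)
class ConsensusElement:
    """One consensus sequence of the capture panel."""

    name: str
    sequence: bytes
    te_class: str  # LINE | SINE | LTR
    monomer_unit: bytes | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.name}: empty consensus sequence")
        if set(self.sequence) - set(b"ACGT"):
            raise ValueError(f"{self.name}: consensus must be over ACGT")
        if self.monomer_unit is not None and not self.name.startswith("L1"):
            raise ValueError("monomer_unit only applies to L1 subfamilies")

    def __len__(self) -> int:
        return len(self.sequence)


def _l1(name: str, body: np.ndarray, rng: np.random.Generator,
        n_monomers: int = 3) -> ConsensusElement:
    monomer = dna.random_seq(rng, MONOMER_LEN, gc=0.40)
    utr_spacer = dna.random_seq(rng, 180, gc=0.40)
    gc_rich_3p = dna.random_seq(rng, 220, gc=0.62)
    # pin the 3' terminus to non-A bases so the element/poly(A) boundary of
    # a TPRT product is well defined (mirrors the conserved G-rich L1 3' end)
    gc_rich_3p[-3:] = dna.encode(b"CGC")
    a_tail = np.zeros(A_TAIL_LEN, dtype=np.uint8)  # code 0 == A
    seq = np.concatenate([np.tile(monomer, n_monomers), utr_spacer,
                          body, gc_rich_3p, a_tail])
    return ConsensusElement(name=name, sequence=dna.decode(seq),
                            te_class="LINE", monomer_unit=dna.decode(monomer))


def _sine(rng: np.random.Generator, body_len: int, gc: float) -> bytes:
    body = dna.random_seq(rng, body_len, gc=gc)
    body[-3:] = dna.encode(b"CGC")
    return dna.decode(np.concatenate([body, np.zeros(A_TAIL_LEN,
                                                     dtype=np.uint8)]))


def default_library() -> list[ConsensusElement]:
    """The seven-element synthetic capture panel (deterministic)."""
    rng = np.random.default_rng(_LIBRARY_SEED)
    shared_body = dna.random_seq(rng, 5400, gc=0.41)
    elements = [
        _l1("L1_TF", shared_body, rng),
        _l1("L1_GF", dna.mutate(shared_body, 0.05, rng), rng),
        _l1("L1_A", dna.mutate(shared_body, 0.05, rng), rng),
        ConsensusElement("B1", _sine(rng, 135, 0.5), te_class="SINE"),
        ConsensusElement("B2", _sine(rng, 190, 0.48), te_class="SINE"),
        ConsensusElement("IAP", dna.decode(dna.random_seq(rng, 1400, gc=0.45)),
                         te_class="LTR"),
        ConsensusElement("ETn", dna.decode(dna.random_seq(rng, 1000, gc=0.45)),
                         te_class="LTR"),
    ]
    return elements


def by_name(library: list[ConsensusElement]) -> dict[str, ConsensusElement]:
    return {el.name: el for el in library}
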