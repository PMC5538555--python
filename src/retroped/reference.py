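"""Seeded synthetic reference genome with decoy TE copies and donor L1s.

The reference stands in for a real mouse assembly plus its TE annotation
and a catalogue of known polymorphic insertion loci.  It contains:

* a random AT-biased background (GC ~0.42 by default);
* ``n_decoy_te_copies`` embedded consensus copies mutated by 2-10%
  (L1 decoys are 3'-anchored truncations, as most genomic L1 copies are);
* ``n_donor_elements`` exact full-length L1_TF copies, each followed by a
  unique 300-bp downstream tag region used for 3'-transduction tracing;
* ``n_known_poly_sites`` loci marked as known polymorphic insertion sites.

Annotation records are 0-based half-open with roles in
{decoy, donor, polymorphic_known}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dna
from .consensus import ConsensusElement
from .simconfig import SimConfig, ConfigError

DONOR_TAG_LEN = 300

ANNOT_COLUMNS = ["chrom", "start", "end", "name", "role", "strand", "family"]


class SizingError(ConfigError):
    """chrom_length too small to host the requested element copies."""


@dataclass
class Reference:
    """Genome sequences plus TE annotation and known-polymorphism records."""

    chroms: dict[str, np.ndarray]          # name -> uint8 code array
    annotation: pd.DataFrame               # ANNOT_COLUMNS
    known_poly: pd.DataFrame               # chrom/start/end/name/family

    def seq(self, chrom: str, start: int, end: int) -> np.ndarray:
        arr = self.chroms[chrom]
        return arr[max(0, start):min(len(arr), end)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chroms.items()}

    def donors(self) -> pd.DataFrame:
        return self.annotation[self.annotation.role == "donor"]

    def donor_tag(self, donor_name: str) -> tuple[str, int, int, str]:
        """(chrom, start, end, strand) of the 300-bp tag downstream of a donor."""
        row = self.annotation[self.annotation.name == donor_name].iloc[0]
        if row.strand == "+":
            return row.chrom, int(row.end), int(row.end) + DONOR_TAG_LEN, "+"
        return row.chrom, int(row.start) - DONOR_TAG_LEN, int(row.start), "-"


def build_reference(config: SimConfig,
                    library: list[ConsensusElement]) -> Reference:
    """Deterministically build the synthetic reference for ``config``."""
    if not library:
        raise ConfigError("consensus library must be non-empty")
    rng = config.rng("genome")
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chroms = {name: dna.random_seq(rng, config.chrom_length, config.gc_background)
              for name in chrom_names}

    lib = {el.name: el for el in library}
    l1_tf = lib.get("L1_TF")
    if config.n_donor_elements > 0 and l1_tf is None:
        raise ConfigError("donor elements require an L1_TF consensus")

    records: list[dict] = []
    # occupied intervals per chrom, padded, to keep placements disjoint
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def place(length: int, margin: int = 1500) -> tuple[str, int]:
        for _ in range(200):
            chrom = chrom_names[rng.integers(len(chrom_names))]
            limit = config.chrom_length - length - margin
            if limit <= margin:
                raise SizingError(
                    f"chrom_length {config.chrom_length} too small for a "
                    f"{length}-bp element copy")
            start = int(rng.integers(margin, limit))
            if all(start + length + margin <= s or start >= e + margin
                   for s, e in occupied[chrom]):
                occupied[chrom].append((start, start + length))
                return chrom, start
        raise SizingError("could not place element copies without overlap; "
                          "increase chrom_length or reduce copy numbers")

    # donors: exact full-length L1_TF copies with a unique downstream tag
    for i in range(config.n_donor_elements):
        el = dna.encode(l1_tf.sequence)
        strand = "+" if rng.random() < 0.5 else "-"
        chrom, start = place(len(el) + DONOR_TAG_LEN)
        if strand == "-":
            # element downstream (in element orientation) = lower coordinates;
            # the tag region keeps the unique random background already there
            start += DONOR_TAG_LEN
            chroms[chrom][start:start + len(el)] = dna.revcomp_codes(el)
        else:
            chroms[chrom][start:start + len(el)] = el
        records.append(dict(chrom=chrom, start=start, end=start + len(el),
                            name=f"donor_{i + 1}", role="donor",
                            strand=strand, family="L1_TF"))

    # decoys: mutated, possibly truncated consensus copies
    for i in range(config.n_decoy_te_copies):
        el = library[rng.integers(len(library))]
        codes = dna.encode(el.sequence)
        if el.te_class == "LINE":
            # 3'-anchored truncation mimicking genomic L1 copy structure
            keep = int(rng.integers(300, len(codes) + 1))
            codes = codes[len(codes) - keep:]
        codes = dna.mutate(codes, rng.uniform(0.02, 0.10), rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            codes = dna.revcomp_codes(codes)
        chrom, start = place(len(codes))
        chroms[chrom][start:start + len(codes)] = codes
        records.append(dict(chrom=chrom, start=start, end=start + len(codes),
                            name=f"decoy_{i + 1}", role="decoy",
                            strand=strand, family=el.name))

    annotation = pd.DataFrame(records, columns=ANNOT_COLUMNS)
    if len(annotation):
        annotation = annotation.sort_values(["chrom", "start"]).reset_index(drop=True)

    # known polymorphic insertion loci (point loci in the catalogue)
    poly_records = []
    for i in range(config.n_known_poly_sites):
        chrom = chrom_names[rng.integers(len(chrom_names))]
        pos = int(rng.integers(2000, config.chrom_length - 2000))
        poly_records.append(dict(chrom=chrom, start=pos, end=pos + 1,
                                 name=f"known_poly_{i + 1}", family="L1"))
    known_poly = pd.DataFrame(poly_records,
                              columns=["chrom", "start", "end", "name", "family"])
    if len(known_poly):
        known_poly = known_poly.sort_values(["chrom", "start"]).reset_index(drop=True)

    return Reference(chroms=chroms, annotation=annotation, known_poly=known_poly)
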