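"""Simulation configuration and ground-truth domain types.

``SimConfig`` collects every knob of the synthetic-data generator with the
study conditions as defaults: 450/550-bp insert sizes, 150-bp reads,
13-17-bp target-site duplications, ~64-bp poly(A) tracts, the
5'-TTTT/AA-3' endonuclease motif, and strong depletion of L1 3'-junction
fragments.  A master seed derives independent per-stage RNG streams
(genome, planning, pedigree, reads, qpcr) so any stage can be regenerated
in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

ORIGIN_CLASSES = (
    "polymorphic",
    "heterozygous_de_novo",
    "somatic_germline_mosaic",
    "germline_restricted_mosaic",
    "somatic_restricted_mosaic",
)

TISSUES = ("soma_pool", "brain", "liver", "muscle",
           "gonad_left", "gonad_right", "germ_cell_fraction")

SOMATIC_TISSUES = ("soma_pool", "brain", "liver", "muscle")
GONAD_TISSUES = ("gonad_left", "gonad_right")
GERM_TISSUES = ("germ_cell_fraction",)


class ConfigError(ValueError):
    """Raised when a configuration value is outside its legal range."""


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 2_500_000
    gc_background: float = 0.42
    n_decoy_te_copies: int = 40
    n_donor_elements: int = 2
    n_known_poly_sites: int = 6
    # list of (origin_class, count)
    insertion_plan: list[tuple[str, int]] = field(default_factory=lambda: [
        ("polymorphic", 4),
        ("heterozygous_de_novo", 2),
        ("germline_restricted_mosaic", 2),
        ("somatic_germline_mosaic", 2),
        ("somatic_restricted_mosaic", 2),
    ])
    tsd_range: tuple[int, int] = (13, 17)
    polyA_mean: float = 64.0
    polyA_sd: float = 15.0
    polyA_min: int = 10
    en_motif: str = "TTTTAA"
    en_max_mismatches: int = 1
    transduction_prob: float = 0.25
    transduction_len_range: tuple[int, int] = (50, 200)
    truncation_prob: float = 0.0     # full-length-only by default
    capture_enrichment: float = 20.0
    three_prime_depletion: float = 0.8
    insert_sizes: tuple[int, ...] = (450, 550)
    read_length: int = 150
    per_base_error: float = 0.002
    duplicate_rate: float = 0.03
    chimera_rate: float = 0.01
    coverage_target: float = 30.0
    # pedigree transmission parameters
    germline_fraction_range: tuple[float, float] = (0.20, 0.35)
    somatic_fraction_range: tuple[float, float] = (0.001, 0.015)
    # somatic-restricted events are embryonic and broadly distributed, hence
    # detectable by capture sequencing of the carrier's own tissues
    somatic_restricted_fraction_range: tuple[float, float] = (0.20, 0.40)
    # read-quality model
    base_quality: int = 37
    quality_tail_prob: float = 0.3
    quality_tail_mean: int = 8
    # analysis thresholds (all documented pipeline defaults surfaced)
    q_min: int = 10
    genome_min_identity: float = 0.94
    uniqueness_margin: int = 5
    consensus_min_identity: float = 0.90
    consensus_min_terminal_span: int = 33
    min_genome_anchor: int = 25
    cluster_window: int = 100
    min_cluster_reads: int = 3
    pair_separation: int = 50
    match_slop: int = 100

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        probs = {
            "gc_background": self.gc_background,
            "transduction_prob": self.transduction_prob,
            "three_prime_depletion": self.three_prime_depletion,
            "per_base_error": self.per_base_error,
            "duplicate_rate": self.duplicate_rate,
            "chimera_rate": self.chimera_rate,
            "truncation_prob": self.truncation_prob,
            "quality_tail_prob": self.quality_tail_prob,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.tsd_range
        if not (0 <= lo <= hi <= 50):
            raise ConfigError(f"tsd_range must lie within [0, 50], got {self.tsd_range}")
        if self.polyA_min < 1:
            raise ConfigError("polyA_min must be >= 1")
        if not self.insert_sizes:
            raise ConfigError("insert_sizes must be non-empty")
        if self.read_length >= min(self.insert_sizes):
            raise ConfigError("read_length must be < min(insert_sizes)")
        if self.capture_enrichment < 1:
            raise ConfigError("capture_enrichment must be >= 1")
        if self.coverage_target <= 0:
            raise ConfigError("coverage_target must be > 0")
        if set(self.en_motif) - set("ACGT"):
            raise ConfigError("en_motif must be over ACGT")
        for cls, cnt in self.insertion_plan:
            if cls not in ORIGIN_CLASSES:
                raise ConfigError(f"unknown origin class {cls!r}")
            if cnt < 0:
                raise ConfigError("insertion counts must be >= 0")
        for name, v in (("genome_min_identity", self.genome_min_identity),
                        ("consensus_min_identity", self.consensus_min_identity)):
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        positives = {
            "q_min": self.q_min,
            "consensus_min_terminal_span": self.consensus_min_terminal_span,
            "min_genome_anchor": self.min_genome_anchor,
            "cluster_window": self.cluster_window,
            "min_cluster_reads": self.min_cluster_reads,
            "pair_separation": self.pair_separation,
            "match_slop": self.match_slop,
            "uniqueness_margin": self.uniqueness_margin,
        }
        for name, v in positives.items():
            if v < 1:
                raise ConfigError(f"{name} must be >= 1, got {v}")

    # -- RNG hierarchy ----------------------------------------------------
    _STAGES = ("genome", "planning", "pedigree", "reads", "qpcr")

    def rng(self, stage: str) -> np.random.Generator:
        """Independent per-stage stream derived from the master seed."""
        if stage not in self._STAGES:
            raise ConfigError(f"unknown RNG stage {stage!r}")
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(len(self._STAGES))[
                self._STAGES.index(stage)])

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PedigreeSpec:
    """Pedigree layout plus the tissue panel of each animal.

    ``animals``: list of (id, sex, dam_id | None, sire_id | None, generation);
    parents must precede children.  ``sequenced`` maps animal id to the
    tissue labels with an mRC-seq library; every animal keeps truth allele
    fractions for the full tissue panel regardless.
    """

    animals: list[tuple[str, str, str | None, str | None, int]]
    tissues_per_animal: dict[str, tuple[str, ...]] = field(default_factory=dict)
    sequenced: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for aid, sex, dam, sire, gen in self.animals:
            for parent in (dam, sire):
                if parent is not None and parent not in seen:
                    raise ConfigError(f"parent {parent!r} of {aid!r} not declared first")
            if aid in seen:
                raise ConfigError(f"duplicate animal id {aid!r}")
            seen.add(aid)
        for aid in self.ids():
            tis = self.tissues(aid)
            if not tis:
                raise ConfigError(f"animal {aid!r} has no tissues")
            unknown = set(self.sequenced.get(aid, ())) - set(tis)
            if unknown:
                raise ConfigError(f"sequenced tissues {unknown} not in panel of {aid!r}")

    def ids(self) -> list[str]:
        return [a[0] for a in self.animals]

    def tissues(self, animal: str) -> tuple[str, ...]:
        return self.tissues_per_animal.get(animal, TISSUES)

    def parents(self, animal: str) -> tuple[str | None, str | None]:
        for aid, _sex, dam, sire, _gen in self.animals:
            if aid == animal:
                return dam, sire
        raise KeyError(animal)

    def founders(self) -> list[str]:
        return [a[0] for a in self.animals if a[2] is None and a[3] is None]

    def offspring_of(self, animal: str) -> list[str]:
        return [a[0] for a in self.animals if animal in (a[2], a[3])]

    def sample_id(self, animal: str, tissue: str) -> str:
        return f"{animal}:{tissue}"

    def libraries(self) -> list[tuple[str, str]]:
        """(animal, tissue) pairs that get a sequencing library."""
        out = []
        for aid in self.ids():
            for tissue in self.sequenced.get(aid, ("soma_pool",)):
                out.append((aid, tissue))
        return out


def demo_pedigree(n_offspring: int = 20) -> PedigreeSpec:
    """Two-generation demo pedigree: founders P1 (sire) and P2 (dam).

    Founders carry the full tissue panel and are sequenced on the pooled
    soma and the germ-cell fraction; offspring are sequenced on pooled soma.
    """
    animals: list[tuple[str, str, str | None, str | None, int]] = [
        ("P1", "M", None, None, 0),
        ("P2", "F", None, None, 0),
    ]
    for i in range(1, n_offspring + 1):
        sex = "M" if i % 2 else "F"
        animals.append((f"F1-{i:02d}", sex, "P2", "P1", 1))
    sequenced = {
        "P1": ("soma_pool", "germ_cell_fraction"),
        "P2": ("soma_pool", "germ_cell_fraction"),
    }
    sequenced.update({f"F1-{i:02d}": ("soma_pool",) for i in range(1, n_offspring + 1)})
    return PedigreeSpec(animals=animals, sequenced=sequenced)


@dataclass
class PlannedInsertion:
    """Ground-truth TPRT event with its carrier/prevalence map."""

    id: str
    chrom: str
    nick_pos: int                  # 0-based slash position of the EN motif
    strand: str                    # '+' or '-'
    subfamily: str
    element_span: tuple[int, int]  # consensus interval included (full-length default)
    n_monomers: int
    tsd_len: int
    polyA_len: int
    transduction: tuple[bytes, str] | None   # (sequence, donor annotation id)
    origin_class: str
    origin_animal: str | None = None
    # animal -> tissue -> allele fraction
    prevalence: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ConfigError("strand must be + or -")
        if self.origin_class not in ORIGIN_CLASSES:
            raise ConfigError(f"unknown origin class {self.origin_class!r}")
        if self.tsd_len < 0:
            raise ConfigError("tsd_len must be >= 0")

    # reference coordinates of the two element-genome junctions, using the
    # convention: modified = ref[:nick+tsd] + cassette + ref[nick:], i.e. the
    # TSD is ref[nick : nick+tsd] and appears on both flanks.
    @property
    def left_junction(self) -> int:
        return self.nick_pos + self.tsd_len

    @property
    def right_junction(self) -> int:
        return self.nick_pos

    @property
    def pos_5p(self) -> int:
        """Junction adjacent to the element 5' end on the reference."""
        return self.left_junction if self.strand == "+" else self.right_junction

    @property
    def pos_3p(self) -> int:
        """Junction adjacent to the element 3' (poly(A)) end."""
        return self.right_junction if self.strand == "+" else self.left_junction

    def fraction(self, animal: str, tissue: str) -> float:
        return self.prevalence.get(animal, {}).get(tissue, 0.0)
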