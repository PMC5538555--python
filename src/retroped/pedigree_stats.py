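"""Developmental-origin classification and transmission/rate statistics.

``classify_origin`` turns an insertion's presence pattern across pedigree
samples (read support per library, plus optional qPCR prevalence of
candidate insertions in parental tissues) into one of the developmental
archetypes:

1. known/founder polymorphic;
2. germline-restricted mosaic — carried by offspring and/or the parental
   germ-cell fraction, with no somatic positivity in the parent;
3. somatic+germline mosaic — carried by offspring with low-level (1-2
   read) or sub-heterozygous qPCR positivity in parental somatic tissue;
4. heterozygous de novo — robust at ~constant support in all tissues of
   exactly one animal, absent from its parents everywhere (late-germline
   or zygotic origin);
5. somatic-restricted mosaic — parental somatic mosaicism with no
   germline evidence and no carrier offspring (only assignable when the
   animal produced offspring; otherwise unresolved).

The rules encode, as a deterministic procedure, the case-by-case
genotyping logic used for pedigree tracing of new L1 insertions; rule
order matters and is part of the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .calling import MIN_CLUSTER_READS
from .qpcr_sim import QpcrMeasurement
from .simconfig import (PedigreeSpec, SOMATIC_TISSUES, GONAD_TISSUES,
                        GERM_TISSUES)

#: qPCR prevalence (% of heterozygote) above which a tissue is "positive"
QPCR_POSITIVE_PCT = 0.1
#: qPCR prevalence below which an animal is not considered heterozygous
QPCR_SUBHET_PCT = 60.0
#: siblings needed to infer germline mosaicism without a germ-positive sample
INFERRED_SIBLING_MIN = 2


@dataclass
class OriginCall:
    insertion_id: str
    origin_class: str
    carrier_parent: str | None = None
    carrier_animal: str | None = None
    evidence: list[str] = field(default_factory=list)


@dataclass
class TransmissionTest:
    carriers: int
    offspring: int
    expected_fraction: float
    chi2: float
    p_two_tailed: float


@dataclass
class RateEstimate:
    events: int
    genomes: int
    rate: float
    ci_low: float
    ci_high: float
    poisson_interval: bool = False


def _support(row: dict[str, int], sample: str) -> int:
    return int(row.get(sample, 0))


def _qpcr_pct(qpcr: dict[tuple[str, str], float] | None,
              animal: str, tissue: str) -> float | None:
    if qpcr is None:
        return None
    return qpcr.get((animal, tissue))


def classify_origin(insertion_id: str, row: dict[str, int],
                    ped: PedigreeSpec,
                    known_polymorphic: bool = False,
                    founder_polymorphic: bool = False,
                    qpcr_prevalence: dict[tuple[str, str], float] | None = None,
                    ) -> OriginCall:
    """Classify one insertion from its per-sample support row.

    ``row`` maps library sample id ("animal:tissue") to supporting read
    count and must cover all sequenced libraries (explicit zeros).
    ``qpcr_prevalence`` maps (animal, tissue) to percent prevalence
    relative to a heterozygous calibrator, when a tissue-tracing assay was
    run; it supplies the sub-threshold-prevalence evidence of the rules.
    """
    unknown = set(row) - {ped.sample_id(a, t) for a, t in ped.libraries()}
    if unknown:
        raise ValueError(f"presence row references unknown samples: {unknown}")

    ev: list[str] = []

    # rule 1: polymorphic
    if known_polymorphic or founder_polymorphic:
        ev.append("known database locus" if known_polymorphic
                  else "robust in all libraries of a founder")
        return OriginCall(insertion_id, "polymorphic", evidence=ev)

    seq_map = {a: tuple(ts) for a, ts in
               ((aid, [t for x, t in ped.libraries() if x == aid])
                for aid in ped.ids())}

    def reads(animal: str, tissues) -> int:
        return sum(_support(row, ped.sample_id(animal, t))
                   for t in tissues if t in seq_map.get(animal, ()))

    def qpcr_positive(animal: str, tissues) -> bool:
        vals = [(_qpcr_pct(qpcr_prevalence, animal, t)) for t in tissues]
        return any(v is not None and v > QPCR_POSITIVE_PCT for v in vals)

    def soma_positive(animal: str) -> bool:
        return reads(animal, SOMATIC_TISSUES) > 0 or \
            qpcr_positive(animal, SOMATIC_TISSUES)

    def germline_positive(animal: str) -> bool:
        return reads(animal, GERM_TISSUES) > 0 or \
            qpcr_positive(animal, GONAD_TISSUES + GERM_TISSUES)

    def robust_tissues(animal: str) -> int:
        return sum(_support(row, ped.sample_id(animal, t)) >= MIN_CLUSTER_READS
                   for t in seq_map.get(animal, ()))

    robust_animals = [a for a in ped.ids() if robust_tissues(a) > 0]

    # carriers whose parents exist in the pedigree
    offspring_carriers: dict[tuple[str | None, str | None], list[str]] = {}
    for a in robust_animals:
        dam, sire = ped.parents(a)
        if dam is not None or sire is not None:
            offspring_carriers.setdefault((dam, sire), []).append(a)

    # rule 2: germline-restricted mosaicism in a parent
    for (dam, sire), kids in offspring_carriers.items():
        parents = [p for p in (dam, sire) if p is not None]
        if any(soma_positive(p) for p in parents):
            continue
        germ_pos = [p for p in parents if germline_positive(p)]
        if len(germ_pos) >= 1:
            ev.append(f"carrier offspring {kids}; no parental somatic signal; "
                      f"germline-positive parent {germ_pos[0]}")
            carrier = germ_pos[0] if len(germ_pos) == 1 else None
            return OriginCall(insertion_id, "germline_restricted_mosaic",
                              carrier_parent=carrier, evidence=ev)
        if len(kids) >= INFERRED_SIBLING_MIN and \
                not any(a in robust_animals for a in parents):
            ev.append(f">={INFERRED_SIBLING_MIN} carrier siblings {kids} with "
                      "all-negative parents: germline mosaicism inferred")
            return OriginCall(insertion_id, "germline_restricted_mosaic",
                              carrier_parent=None, evidence=ev)

    # also germline-restricted: germ-only positivity in a sequenced parent
    # even without carrier offspring (deep germ-cell-fraction discovery)
    for a in ped.ids():
        if reads(a, GERM_TISSUES) > 0 and not soma_positive(a) \
                and a not in robust_animals[:0]:
            if not any(k for k in offspring_carriers.values()):
                ev.append(f"germ-cell fraction of {a} positive; soma negative")
                return OriginCall(insertion_id, "germline_restricted_mosaic",
                                  carrier_parent=a, evidence=ev)

    # rule 3: somatic + germline mosaicism in a parent
    for (dam, sire), kids in offspring_carriers.items():
        parents = [p for p in (dam, sire) if p is not None]
        for p in parents:
            if _is_het(qpcr_prevalence, p):
                continue  # tissue tracing says heterozygous, not mosaic
            low_soma = 0 < reads(p, SOMATIC_TISSUES) < MIN_CLUSTER_READS
            sub_prev = qpcr_positive(p, SOMATIC_TISSUES)
            if low_soma or sub_prev:
                ev.append(f"carrier offspring {kids}; parent {p} somatic "
                          f"signal {'1-2 reads' if low_soma else 'sub-het qPCR'}")
                return OriginCall(insertion_id, "somatic_germline_mosaic",
                                  carrier_parent=p, evidence=ev)

    # rule 3b: direct evidence without carrier offspring — sub-heterozygous
    # qPCR somatic positivity plus a positive germ sample show somatic and
    # germline mosaicism even when no offspring happened to inherit
    for a in ped.ids():
        if _is_het(qpcr_prevalence, a):
            continue
        if qpcr_positive(a, SOMATIC_TISSUES) and germline_positive(a):
            ev.append(f"{a}: sub-heterozygous somatic qPCR signal with a "
                      "positive germ sample (no carrier offspring required)")
            return OriginCall(insertion_id, "somatic_germline_mosaic",
                              carrier_parent=a, evidence=ev)

    # rule 4: heterozygous de novo in one animal
    for a in robust_animals:
        libs = seq_map.get(a, ())
        if robust_tissues(a) == len(libs) and len(libs) > 0:
            dam, sire = ped.parents(a)
            parents = [p for p in (dam, sire) if p is not None]
            others = [x for x in robust_animals
                      if x != a and not _descends_from(ped, x, a)]
            if parents and not others and \
                    not any(soma_positive(p) or germline_positive(p)
                            for p in parents):
                ev.append(f"robust in all libraries of {a}; parents negative "
                          "everywhere including germ samples")
                return OriginCall(insertion_id, "heterozygous_de_novo",
                                  carrier_animal=a, evidence=ev)

    # rule 5: somatic-restricted mosaicism.  Read counts alone cannot
    # separate heterozygous from broadly mosaic tissue, so this rule
    # requires qPCR-backed sub-heterozygous somatic prevalence.
    for a in ped.ids():
        somatic_mosaic = qpcr_positive(a, SOMATIC_TISSUES) and \
            not _is_het(qpcr_prevalence, a)
        if somatic_mosaic and not germline_positive(a):
            kids = ped.offspring_of(a)
            carrier_kids = [k for k in kids if k in robust_animals]
            if not carrier_kids:
                if kids:
                    ev.append(f"somatic mosaicism in {a}; no germline signal; "
                              f"0/{len(kids)} carrier offspring (germline "
                              "contribution cannot be ruled out)")
                    return OriginCall(insertion_id, "somatic_restricted_mosaic",
                                      carrier_animal=a, evidence=ev)
                ev.append(f"somatic mosaicism in {a}; no offspring to test")
                return OriginCall(insertion_id, "unresolved",
                                  carrier_animal=a, evidence=ev)

    ev.append("presence pattern fits no archetype")
    return OriginCall(insertion_id, "unresolved", evidence=ev)


def _is_het(qpcr: dict[tuple[str, str], float] | None, animal: str) -> bool:
    """Animal looks heterozygous (~100% prevalence) in every assayed tissue."""
    if qpcr is None:
        return False
    vals = [v for (a, _t), v in qpcr.items() if a == animal]
    return bool(vals) and min(vals) > QPCR_SUBHET_PCT


def _descends_from(ped: PedigreeSpec, animal: str, ancestor: str) -> bool:
    dam, sire = ped.parents(animal)
    for p in (dam, sire):
        if p is None:
            continue
        if p == ancestor or _descends_from(ped, p, ancestor):
            return True
    return False


def transmission_test(carriers: int, offspring: int,
                      expected_fraction: float = 0.5) -> TransmissionTest:
    """One-degree-of-freedom chi-square test of the transmission rate.

    ``chi2 = sum (obs - exp)^2 / exp`` over the carrier and non-carrier
    cells; the two-tailed p-value is the upper tail of chi-square(1), the
    conventional two-sided test for a 1-df statistic.
    """
    if offspring < 1:
        raise ValueError("offspring must be >= 1")
    if not 0 <= carriers <= offspring:
        raise ValueError("carriers must be in [0, offspring]")
    exp_c = offspring * expected_fraction
    exp_n = offspring * (1 - expected_fraction)
    if exp_c == 0 or exp_n == 0:
        raise ValueError("expected cell count of zero")
    chi2 = (carriers - exp_c) ** 2 / exp_c + \
        ((offspring - carriers) - exp_n) ** 2 / exp_n
    p = float(stats.chi2.sf(chi2, df=1))
    return TransmissionTest(carriers, offspring, expected_fraction,
                            float(chi2), p)


def insertion_rate(events: int, genomes: int) -> RateEstimate:
    """Per-genome insertion rate with an exact 95% interval.

    Clopper-Pearson when events <= genomes; exact Poisson interval
    (flagged) when multiple events per genome push events beyond genomes.
    """
    if genomes < 1:
        raise ValueError("genomes must be >= 1")
    rate = events / genomes
    if events <= genomes:
        lo = 0.0 if events == 0 else float(
            stats.beta.ppf(0.025, events, genomes - events + 1))
        hi = 1.0 if events == genomes else float(
            stats.beta.ppf(0.975, events + 1, genomes - events))
        return RateEstimate(events, genomes, rate, lo, hi)
    lo = float(stats.chi2.ppf(0.025, 2 * events) / 2 / genomes)
    hi = float(stats.chi2.ppf(0.975, 2 * events + 2) / 2 / genomes)
    return RateEstimate(events, genomes, rate, lo, hi, poisson_interval=True)


# ---------------------------------------------------------------------------
# qPCR quantification (delta-delta-Ct with 100% efficiency)
# ---------------------------------------------------------------------------

def _dct(m: QpcrMeasurement) -> tuple[float, float]:
    """(mean delta-Ct, replicate SD of delta-Ct in quadrature)."""
    t = np.asarray(m.target_ct, dtype=float)
    r = np.asarray(m.reference_ct, dtype=float)
    dct = float(np.nanmean(t) - np.nanmean(r))
    sd = float(np.sqrt(np.nanvar(t, ddof=1 if len(t) > 1 else 0) +
                       np.nanvar(r, ddof=1 if len(r) > 1 else 0)))
    return dct, sd


def estimate_prevalence(sample: QpcrMeasurement, calibrator: QpcrMeasurement,
                        ) -> tuple[float, float]:
    """Percent prevalence relative to a heterozygous calibrator (= 100%).

    ``prevalence% = 100 * 2^-(dCt_sample - dCt_calibrator)``; the SD is
    propagated from replicate SDs in quadrature on the Ct scale and
    transformed.  A no-amplification sample reports (nan, nan) -- below
    detection.
    """
    if calibrator.no_amplification:
        raise ValueError("calibrator shows no amplification")
    if sample.no_amplification:
        return float("nan"), float("nan")
    ds, sd_s = _dct(sample)
    dc, sd_c = _dct(calibrator)
    ddct = ds - dc
    sd = float(np.sqrt(sd_s ** 2 + sd_c ** 2))
    pct = 100.0 * 2.0 ** (-ddct)
    sd_pct = pct * float(np.log(2)) * sd
    return pct, sd_pct


def copy_number(filled: QpcrMeasurement, empty: QpcrMeasurement,
                het_calibrators_filled: list[QpcrMeasurement],
                het_calibrators_empty: list[QpcrMeasurement],
                ) -> tuple[float, float]:
    """Per-allele copy numbers of the filled and empty site.

    The mean delta-Ct across heterozygous calibrators defines copy = 1 for
    each assay; copies = 2^-(dCt_sample - mean dCt_calibrators).  A
    no-amplification filled assay reports NaN (below detection).
    """
    def one(sample: QpcrMeasurement, calibrators: list[QpcrMeasurement]) -> float:
        if sample.no_amplification:
            return float("nan")
        cal = [c for c in calibrators if not c.no_amplification]
        if not cal:
            raise ValueError("no amplifying calibrator")
        cal_mean = float(np.mean([_dct(c)[0] for c in cal]))
        return float(2.0 ** (-(_dct(sample)[0] - cal_mean)))

    return one(filled, het_calibrators_filled), one(empty, het_calibrators_empty)
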