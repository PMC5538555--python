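"""Transmission of planned insertions through a simulated pedigree.

Each origin class maps onto a developmental archetype:

* ``polymorphic`` -- segregates Mendelianly from designated founder
  genotypes (allele fractions 0, 0.5 or 1 in every tissue);
* ``heterozygous_de_novo`` -- fraction 0.5 in every tissue of one offspring
  (late-germline or zygotic event), transmitted Mendelianly onward;
* ``germline_restricted_mosaic`` -- fraction 0 in all somatic tissues of the
  carrier, fraction f (0 < f < 0.5) in gonads and germ-cell fraction;
  each offspring is a carrier with probability f (an event in early
  primordial germ cells);
* ``somatic_germline_mosaic`` -- low fractions in somatic tissues
  (U(0.001, 0.015) by default), a larger germ/gonad fraction g
  (U(0.20, 0.35) by default), offspring carrier probability g (an event in
  pluripotent embryonic cells);
* ``somatic_restricted_mosaic`` -- somatic fractions only; never transmits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simconfig import (SimConfig, PedigreeSpec, PlannedInsertion, ConfigError,
                        SOMATIC_TISSUES, GONAD_TISSUES, GERM_TISSUES)


def _all_tissues(ped: PedigreeSpec, animal: str, value: float) -> dict[str, float]:
    return {t: value for t in ped.tissues(animal)}


def _mendelian_descend(ped: PedigreeSpec, genotypes: dict[str, int],
                       rng: np.random.Generator) -> dict[str, int]:
    """Propagate allele counts (0/1/2) from assigned animals to descendants."""
    out = dict(genotypes)
    for aid, _sex, dam, sire, _gen in ped.animals:
        if aid in out:
            continue
        if dam is None and sire is None:
            out[aid] = 0
            continue
        alleles = 0
        for parent in (dam, sire):
            g = out.get(parent, 0)
            p = g / 2.0
            alleles += int(rng.random() < p)
        out[aid] = alleles
    return out


def simulate_pedigree(ped: PedigreeSpec, plan: list[PlannedInsertion],
                      config: SimConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Fill each event's prevalence map; return the truth table.

    Events must have ``origin_animal`` set for the de novo classes
    (``polymorphic`` events designate founder genotypes via
    ``origin_animal`` = the founder that is heterozygous; if None, founder
    genotypes are drawn with at least one carrier).

    Returns a tidy DataFrame: insertion_id, animal, tissue, fraction.
    """
    ids = set(ped.ids())
    lo_f, hi_f = config.germline_fraction_range
    lo_s, hi_s = config.somatic_fraction_range

    for ev in plan:
        if ev.origin_animal is not None and ev.origin_animal not in ids:
            raise ConfigError(
                f"origin animal {ev.origin_animal!r} of {ev.id} absent from pedigree")
        prevalence: dict[str, dict[str, float]] = {}

        if ev.origin_class == "polymorphic":
            genotypes: dict[str, int] = {}
            founders = ped.founders()
            if ev.origin_animal is not None:
                for f in founders:
                    genotypes[f] = 1 if f == ev.origin_animal else 0
            else:
                while True:
                    genotypes = {f: int(rng.choice([0, 1, 1, 2])) for f in founders}
                    if any(genotypes.values()):
                        break
            genotypes = _mendelian_descend(ped, genotypes, rng)
            for aid, g in genotypes.items():
                if g:
                    prevalence[aid] = _all_tissues(ped, aid, g / 2.0)

        elif ev.origin_class == "heterozygous_de_novo":
            carrier = ev.origin_animal
            if carrier is None:
                raise ConfigError(f"{ev.id}: heterozygous_de_novo needs origin_animal")
            genotypes = _mendelian_descend(ped, {a: 0 for a in ped.founders()} |
                                           {carrier: 1}, rng)
            # ancestors of the carrier stay non-carriers; only descend from it
            for aid, g in genotypes.items():
                if g and (aid == carrier or _descends(ped, aid, carrier)):
                    prevalence[aid] = _all_tissues(ped, aid, g / 2.0)

        elif ev.origin_class == "germline_restricted_mosaic":
            carrier = _require_origin(ev)
            f = float(rng.uniform(lo_f, hi_f))
            tis = {t: 0.0 for t in ped.tissues(carrier)}
            for t in GONAD_TISSUES + GERM_TISSUES:
                if t in tis:
                    tis[t] = f
            prevalence[carrier] = tis
            _transmit(ped, carrier, f, prevalence, rng)

        elif ev.origin_class == "somatic_germline_mosaic":
            carrier = _require_origin(ev)
            g = float(rng.uniform(lo_f, hi_f))
            tis = {}
            for t in ped.tissues(carrier):
                if t in GONAD_TISSUES + GERM_TISSUES:
                    tis[t] = g
                else:
                    tis[t] = float(rng.uniform(lo_s, hi_s))
            prevalence[carrier] = tis
            _transmit(ped, carrier, g, prevalence, rng)

        elif ev.origin_class == "somatic_restricted_mosaic":
            carrier = _require_origin(ev)
            lo_r, hi_r = config.somatic_restricted_fraction_range
            tis = {t: 0.0 for t in ped.tissues(carrier)}
            for t in SOMATIC_TISSUES:
                if t in tis:
                    tis[t] = float(rng.uniform(lo_r, hi_r))
            prevalence[carrier] = tis

        ev.prevalence = prevalence

    rows = []
    for ev in plan:
        for aid in ped.ids():
            for tissue in ped.tissues(aid):
                rows.append((ev.id, aid, tissue, ev.fraction(aid, tissue)))
    return pd.DataFrame(rows, columns=["insertion_id", "animal", "tissue", "fraction"])


def _require_origin(ev: PlannedInsertion) -> str:
    if ev.origin_animal is None:
        raise ConfigError(f"{ev.id}: class {ev.origin_class} needs origin_animal")
    return ev.origin_animal


def _descends(ped: PedigreeSpec, animal: str, ancestor: str) -> bool:
    dam, sire = ped.parents(animal)
    for p in (dam, sire):
        if p is None:
            continue
        if p == ancestor or _descends(ped, p, ancestor):
            return True
    return False


def _transmit(ped: PedigreeSpec, carrier: str, p_carrier: float,
              prevalence: dict[str, dict[str, float]],
              rng: np.random.Generator) -> None:
    """Offspring of a mosaic carrier become heterozygous with prob p_carrier."""
    for child in ped.offspring_of(carrier):
        if rng.random() < p_carrier:
            genotypes = _mendelian_descend(
                ped, {a: 0 for a in ped.founders()} | {child: 1}, rng)
            for aid, g in genotypes.items():
                if g and (aid == child or _descends(ped, aid, child)):
                    prevalence[aid] = {t: g / 2.0 for t in ped.tissues(aid)}
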