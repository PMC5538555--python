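"""End-to-end orchestration: simulate -> prep -> align -> call -> classify.

The stage ledger records read counts surviving each filter (trimmed,
merged, genome-unique, duplicate-removed, consensus-passing, clustered),
making the pipeline auditable per run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calling, readprep
from .align import (GenomeIndex, ConsensusIndex, map_to_genome,
                    map_batch, align_to_consensus, remove_duplicates)
from .calling import (JunctionRead, InsertionCall, DiscardLedger,
                      extract_junctions, cluster_junctions, pair_clusters,
                      filter_known, chimera_filter, filter_reference_te,
                      build_presence_matrix)
from .consensus import ConsensusElement, default_library
from .hallmarks import HallmarkAnnotation, annotate
from .insertions import plan_insertion, cassette_codes
from .pedigree_sim import simulate_pedigree
from .pedigree_stats import OriginCall, classify_origin, estimate_prevalence
from .qpcr_sim import simulate_qpcr
from .reads import (SimulatedReads, build_alt_windows, simulate_sample_reads,
                    AltWindow)
from .reference import Reference, build_reference
from .simconfig import (SimConfig, PedigreeSpec, PlannedInsertion,
                        demo_pedigree, GERM_TISSUES)

log = logging.getLogger("retroped")

#: deep coverage multiplier for germ-cell-fraction libraries
GERM_DEPTH_MULTIPLIER = 3.0
#: founder pooled-soma libraries are sequenced deeper (parental tissues get
#: the deep-sequencing treatment so low-level mosaicism is detectable)
FOUNDER_SOMA_MULTIPLIER = 2.0


@dataclass
class Cohort:
    """Everything the simulator produced for one pedigree run."""

    config: SimConfig
    library: list[ConsensusElement]
    reference: Reference
    pedigree: PedigreeSpec
    plan: list[PlannedInsertion]
    truth: pd.DataFrame
    alt_windows: dict[str, AltWindow]
    reads: dict[str, SimulatedReads] = field(default_factory=dict)


@dataclass
class PipelineResult:
    cohort: Cohort
    calls: list[InsertionCall]
    matrix: pd.DataFrame
    origins: dict[str, OriginCall]
    annotations: dict[str, HallmarkAnnotation]
    junction_reads: list[JunctionRead]
    stage_ledger: dict[str, int]
    discard_ledger: DiscardLedger
    qpcr_prevalence: dict[str, dict[tuple[str, str], float]]


def load_cohort(indir) -> Cohort:
    """Rebuild a cohort from the on-disk outputs of the simulate stage."""
    from pathlib import Path
    from . import formats, dna
    from .reads import read_fastq_pair

    indir = Path(indir)
    config = formats.read_config(indir / "config.yaml")
    library = default_library()
    chroms = formats.read_fasta(indir / "reference.fa")
    annotation = formats.read_bed(indir / "te_annotation.bed",
                                  extra_cols=["role", "strand", "family"])
    known = formats.read_bed(indir / "known_polymorphic.bed",
                             extra_cols=["family"])
    reference = Reference(chroms=chroms, annotation=annotation,
                          known_poly=known)

    ped_df = pd.read_csv(indir / "pedigree.tsv", sep="\t",
                         keep_default_na=False)
    animals = [(r.animal, r.sex, r.dam or None, r.sire or None,
                int(r.generation)) for r in ped_df.itertuples()]
    sheet = pd.read_csv(indir / "sample_sheet.tsv", sep="\t")
    sequenced: dict[str, list[str]] = {}
    for r in sheet.itertuples():
        sequenced.setdefault(r.animal, []).append(r.tissue)
    ped = PedigreeSpec(animals=animals,
                       sequenced={a: tuple(t) for a, t in sequenced.items()})

    truth_ins = pd.read_csv(indir / "truth_insertions.tsv", sep="\t",
                            keep_default_na=False)
    truth_prev = pd.read_csv(indir / "truth_prevalence.tsv", sep="\t")
    plan: list[PlannedInsertion] = []
    for r in truth_ins.itertuples():
        transduction = None
        if int(r.transduction_len) > 0 and r.donor:
            tchrom, tstart, tend, tstrand = reference.donor_tag(str(r.donor))
            tlen = int(r.transduction_len)
            if tstrand == "+":
                seg = reference.seq(tchrom, tstart, tstart + tlen)
            else:
                seg = dna.revcomp_codes(reference.seq(tchrom, tend - tlen, tend))
            transduction = (dna.decode(seg), str(r.donor))
        ev = PlannedInsertion(
            id=r.insertion_id, chrom=r.chrom, nick_pos=int(r.nick_pos),
            strand=r.strand, subfamily=r.subfamily,
            element_span=(0, len({e.name: e for e in library}[r.subfamily].sequence)),
            n_monomers=int(r.n_monomers), tsd_len=int(r.tsd_len),
            polyA_len=int(r.polyA_len), transduction=transduction,
            origin_class=r.origin_class,
            origin_animal=r.origin_animal or None)
        prev: dict[str, dict[str, float]] = {}
        sub = truth_prev[(truth_prev.insertion_id == ev.id)
                         & (truth_prev.fraction > 0)]
        for row in sub.itertuples():
            prev.setdefault(row.animal, {})[row.tissue] = float(row.fraction)
        ev.prevalence = prev
        plan.append(ev)

    cohort = Cohort(config=config, library=library, reference=reference,
                    pedigree=ped, plan=plan, truth=truth_prev,
                    alt_windows=build_alt_windows(reference, plan, library))
    for r in sheet.itertuples():
        cohort.reads[r.sample] = read_fastq_pair(r.fastq_1, r.fastq_2)
        cohort.reads[r.sample].sample_id = r.sample
    return cohort


def default_insertion_assignment(ped: PedigreeSpec, plan_spec,
                                 rng: np.random.Generator) -> list[tuple[str, str | None]]:
    """(origin_class, origin_animal) for each planned event.

    Founder-borne archetypes alternate between the two founders; de novo
    heterozygous events land on distinct offspring.
    """
    founders = ped.founders()
    offspring = [a for a in ped.ids() if a not in founders]
    out: list[tuple[str, str | None]] = []
    f_idx = 0
    o_idx = 0
    for cls, count in plan_spec:
        for _ in range(count):
            if cls == "polymorphic":
                out.append((cls, founders[f_idx % len(founders)]))
                f_idx += 1
            elif cls == "heterozygous_de_novo":
                out.append((cls, offspring[o_idx % len(offspring)]))
                o_idx += 3
            else:
                out.append((cls, founders[f_idx % len(founders)]))
                f_idx += 1
    return out


def simulate_cohort(config: SimConfig, ped: PedigreeSpec | None = None,
                    with_reads: bool = True) -> Cohort:
    """Build reference, plan insertions, transmit them, simulate libraries."""
    library = default_library()
    reference = build_reference(config, library)
    ped = ped or demo_pedigree()

    rng_plan = config.rng("planning")
    exclude = [(r.chrom, int(r.start), int(r.end))
               for r in reference.annotation.itertuples()]
    plan: list[PlannedInsertion] = []
    assignment = default_insertion_assignment(ped, config.insertion_plan,
                                              rng_plan)
    for i, (cls, animal) in enumerate(assignment, 1):
        ev = plan_insertion(reference, config, cls, rng_plan, library,
                            exclude=exclude, insertion_id=f"ins_{i:02d}")
        ev.origin_animal = animal
        exclude.append((ev.chrom, ev.nick_pos, ev.nick_pos + ev.tsd_len))
        plan.append(ev)
    # tie some polymorphic events to known catalogue loci by re-registering
    # their positions in the known-polymorphism table
    poly = [ev for ev in plan if ev.origin_class == "polymorphic"]
    extra = []
    for ev in poly[:max(0, len(poly) - 1)]:
        extra.append(dict(chrom=ev.chrom, start=ev.pos_5p, end=ev.pos_5p + 1,
                          name=f"known_{ev.id}", family="L1"))
    if extra:
        reference.known_poly = pd.concat(
            [reference.known_poly, pd.DataFrame(extra)], ignore_index=True)

    truth = simulate_pedigree(ped, plan, config, config.rng("pedigree"))
    alt_windows = build_alt_windows(reference, plan, library)

    cohort = Cohort(config=config, library=library, reference=reference,
                    pedigree=ped, plan=plan, truth=truth,
                    alt_windows=alt_windows)
    if with_reads:
        rng_reads = config.rng("reads")
        for animal, tissue in ped.libraries():
            sample = ped.sample_id(animal, tissue)
            fractions = {ev.id: ev.fraction(animal, tissue) for ev in plan}
            coverage = config.coverage_target
            if tissue in GERM_TISSUES:
                coverage *= GERM_DEPTH_MULTIPLIER
            elif animal in ped.founders():
                coverage *= FOUNDER_SOMA_MULTIPLIER
            cohort.reads[sample] = simulate_sample_reads(
                reference, alt_windows, fractions, config, rng_reads,
                sample_id=sample, coverage=coverage)
    return cohort


def process_sample(reads: SimulatedReads, gindex: GenomeIndex,
                   cindex: ConsensusIndex, element_lengths: dict[str, int],
                   stage: dict[str, int], discard: DiscardLedger,
                   config: SimConfig | None = None) -> list[JunctionRead]:
    """Read prep + two-pass alignment for one library."""
    cfg = config or SimConfig()
    sample = reads.sample_id
    junctions: list[JunctionRead] = []
    mapped_hits = []
    unmapped: list[tuple[str, bytes, bool]] = []

    batch: list = []
    for i, name in enumerate(reads.names):
        chim = "chimera" in name.split("|")[-1]
        r1 = readprep.Read(name, reads.r1_seq[i], reads.r1_qual[i])
        r2 = readprep.Read(name, reads.r2_seq[i], reads.r2_qual[i])
        contigs = readprep.prepare_pair(r1, r2, q_min=cfg.q_min)
        stage["pairs"] += 1
        for contig in contigs:
            stage["contigs"] += 1
            if contig.merged:
                stage["merged"] += 1
            batch.append((contig, chim))

    chunk = 20_000
    for start in range(0, len(batch), chunk):
        part = batch[start:start + chunk]
        hits = map_batch(gindex, [c.sequence for c, _ in part],
                         uniqueness_margin=cfg.uniqueness_margin,
                         min_identity=cfg.genome_min_identity)
        for (contig, chim), hit in zip(part, hits):
            if hit is None:
                unmapped.append((contig.id, contig.sequence, chim))
                continue
            if not hit.unique:
                stage["non_unique_discarded"] += 1
                continue
            hit.query_id = contig.id
            stage["genome_unique"] += 1
            mapped_hits.append(hit)

    stage["genome_after_dedup"] += len(remove_duplicates(mapped_hits))

    for contig_id, seq, chim in unmapped:
        te_hits = align_to_consensus(
            seq, cindex, min_identity=cfg.consensus_min_identity,
            min_terminal_span=cfg.consensus_min_terminal_span)
        if not te_hits:
            discard["no_consensus_hit"] += 1
            continue
        stage["consensus_passing"] += 1
        jrs = extract_junctions(seq, contig_id, sample, te_hits, gindex,
                                element_lengths, ledger=discard,
                                min_genome_anchor=cfg.min_genome_anchor,
                                chimera_tag=chim)
        junctions.extend(jrs)
    stage["junction_reads"] += len(junctions)
    return junctions


def dedup_junctions(junctions: list[JunctionRead],
                    stage: dict[str, int]) -> list[JunctionRead]:
    """PCR-duplicate removal on junction anchors (per sample, coordinates)."""
    best: dict[tuple, JunctionRead] = {}
    for j in junctions:
        key = (j.sample_id, j.genome_hit.ref_name, j.genome_hit.ref_span,
               j.genome_hit.strand, j.side)
        prev = best.get(key)
        if prev is None or j.contig_id < prev.contig_id:
            best[key] = j
    out = sorted(best.values(),
                 key=lambda j: (j.genome_hit.ref_name, j.junction_pos,
                                j.sample_id, j.contig_id))
    stage["junction_after_dedup"] += len(out)
    return out


def run_pipeline(cohort: Cohort, qpcr_noise_sd: float = 0.1,
                 qpcr_replicates: int = 4) -> PipelineResult:
    """Full analysis of a simulated cohort."""
    config = cohort.config
    log.info("thresholds: q_min=%d genome_min_identity=%.2f "
             "uniqueness_margin=%d consensus_min_identity=%.2f "
             "consensus_min_terminal_span=%d min_genome_anchor=%d "
             "cluster_window=%d min_cluster_reads=%d pair_separation=%d "
             "match_slop=%d", config.q_min, config.genome_min_identity,
             config.uniqueness_margin, config.consensus_min_identity,
             config.consensus_min_terminal_span, config.min_genome_anchor,
             config.cluster_window, config.min_cluster_reads,
             config.pair_separation, config.match_slop)
    gindex = GenomeIndex(cohort.reference.chroms)
    cindex = ConsensusIndex(cohort.library)
    element_lengths = {el.name: len(el.sequence) for el in cohort.library}
    stage: dict[str, int] = {k: 0 for k in (
        "pairs", "contigs", "merged", "genome_unique", "non_unique_discarded",
        "genome_after_dedup", "consensus_passing", "junction_reads",
        "junction_after_dedup")}
    discard = DiscardLedger()

    junctions: list[JunctionRead] = []
    for sample, reads in cohort.reads.items():
        log.info("processing %s (%d pairs)", sample, len(reads))
        junctions.extend(process_sample(reads, gindex, cindex,
                                        element_lengths, stage, discard,
                                        config=config))
    junctions = dedup_junctions(junctions, stage)

    clusters = cluster_junctions(junctions, window=config.cluster_window)
    stage["clusters"] = len(clusters)
    calls = pair_clusters(clusters, separation=config.pair_separation)
    founder_samples = {
        f: [cohort.pedigree.sample_id(f, t)
            for x, t in cohort.pedigree.libraries() if x == f]
        for f in cohort.pedigree.founders()}
    calls = filter_known(calls, cohort.reference.known_poly, founder_samples,
                         match_slop=config.match_slop)
    calls = chimera_filter(calls)
    calls = filter_reference_te(calls, cohort.reference.annotation)
    samples = [cohort.pedigree.sample_id(a, t)
               for a, t in cohort.pedigree.libraries()]
    matrix = build_presence_matrix(calls, samples)

    truth_by_call = match_calls_to_truth(calls, cohort.plan)

    # hallmark annotation of matched calls, using the validated (truth)
    # cassette sequence, mirroring capillary-sequenced junctions
    annotations: dict[str, HallmarkAnnotation] = {}
    for call in calls:
        ev = truth_by_call.get(call.id)
        if ev is None:
            continue
        cassette = cassette_codes(ev, cohort.library)
        from . import dna as _dna
        annotations[call.id] = annotate(
            call.id, ev.chrom, ev.pos_5p, ev.pos_3p, ev.strand,
            _dna.decode(cassette), cohort.reference, gindex, cohort.library)

    # qPCR tissue tracing of candidate de novo calls in founder tissues
    rng_q = config.rng("qpcr")
    qpcr_prevalence: dict[str, dict[tuple[str, str], float]] = {}
    for call in calls:
        if not call.primary or call.known_polymorphic or \
                call.founder_polymorphic or call.chimera_suspect or \
                call.reference_te:
            continue
        ev = truth_by_call.get(call.id)
        if ev is None:
            continue
        cal = simulate_qpcr(0.5, qpcr_noise_sd, qpcr_replicates, rng_q,
                            sample_id="calibrator")
        per_tissue: dict[tuple[str, str], float] = {}
        for animal in assay_animals(cohort.pedigree, ev):
            for tissue in cohort.pedigree.tissues(animal):
                frac = ev.fraction(animal, tissue)  # allele fraction = per-haploid template
                m = simulate_qpcr(frac, qpcr_noise_sd, qpcr_replicates, rng_q,
                                  sample_id=f"{animal}:{tissue}")
                pct, _sd = estimate_prevalence(m, cal)
                per_tissue[(animal, tissue)] = 0.0 if np.isnan(pct) else pct
        qpcr_prevalence[call.id] = per_tissue

    origins: dict[str, OriginCall] = {}
    for call in calls:
        if not call.primary or call.chimera_suspect or call.reference_te:
            continue
        row = {s: call.support.get(s, 0) for s in samples}
        origins[call.id] = classify_origin(
            call.id, row, cohort.pedigree,
            known_polymorphic=call.known_polymorphic,
            founder_polymorphic=call.founder_polymorphic,
            qpcr_prevalence=qpcr_prevalence.get(call.id))

    return PipelineResult(
        cohort=cohort, calls=calls, matrix=matrix, origins=origins,
        annotations=annotations, junction_reads=junctions,
        stage_ledger=stage, discard_ledger=discard,
        qpcr_prevalence=qpcr_prevalence)


def assay_animals(ped: PedigreeSpec, ev: PlannedInsertion) -> list[str]:
    """Animals whose tissues get a tracing qPCR for a candidate insertion.

    Founders always; plus the origin animal (heterozygote check).
    """
    out = list(ped.founders())
    if ev.origin_animal and ev.origin_animal not in out:
        out.append(ev.origin_animal)
    return out


def match_calls_to_truth(calls: list[InsertionCall],
                         plan: list[PlannedInsertion],
                         tolerance: int = 50) -> dict[str, PlannedInsertion]:
    """Map call ids to planted events by junction proximity."""
    out: dict[str, PlannedInsertion] = {}
    for call in calls:
        best, best_d = None, tolerance + 1
        for ev in plan:
            if ev.chrom != call.chrom:
                continue
            for called, true in ((call.pos_5p, ev.pos_5p),
                                 (call.pos_3p, ev.pos_3p)):
                if called is None:
                    continue
                d = abs(called - true)
                if d < best_d:
                    best, best_d = ev, d
        if best is not None:
            out[call.id] = best
    return out


def recovery_summary(result: PipelineResult,
                     tolerance: int = 5) -> dict[str, object]:
    """Truth-vs-called metrics used by the acceptance checks."""
    plan = result.cohort.plan
    truth_by_call = match_calls_to_truth(result.calls, plan)
    primary = [c for c in result.calls
               if c.primary and not c.chimera_suspect and not c.reference_te]
    matched: dict[str, list] = {}
    for c in primary:
        ev = truth_by_call.get(c.id)
        if ev is not None:
            matched.setdefault(ev.id, []).append(c)
    het_like = [ev for ev in plan if ev.origin_class in
                ("polymorphic", "heterozygous_de_novo")]
    het_called = 0
    for ev in het_like:
        calls = matched.get(ev.id, [])
        ok = any(c.pos_5p is not None and abs(c.pos_5p - ev.pos_5p) <= tolerance
                 for c in calls)
        het_called += ok
    false_primary = [c for c in primary if c.id not in truth_by_call]
    origin_ok = {}
    by_truth_origin: dict[str, str] = {}
    for c in primary:
        ev = truth_by_call.get(c.id)
        if ev is None or c.id not in result.origins:
            continue
        by_truth_origin[ev.id] = result.origins[c.id].origin_class
    for ev in plan:
        got = by_truth_origin.get(ev.id)
        origin_ok[ev.id] = (got == ev.origin_class)
    return {
        "het_or_poly_total": len(het_like),
        "het_or_poly_called_within_tol": het_called,
        "false_primary_calls": len(false_primary),
        "origins_correct": origin_ok,
        "matched_truth_ids": sorted(matched),
    }
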