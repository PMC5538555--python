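"""Synthetic-data generator: reference, insertion planning, transmission,
reads, qPCR."""

import io

import numpy as np
import pytest
from scipy import stats

from retroped import dna
from retroped.consensus import default_library, A_TAIL_LEN
from retroped.insertions import (plan_insertion, apply_insertions,
                                 cassette_codes, allele_codes,
                                 motif_positions, PlanningError)
from retroped.pedigree_sim import simulate_pedigree
from retroped.qpcr_sim import simulate_qpcr
from retroped.reads import build_alt_windows, simulate_sample_reads
from retroped.reference import build_reference, SizingError
from retroped.simconfig import (SimConfig, PlannedInsertion, ConfigError,
                                demo_pedigree)


class TestConfig:
    def test_probability_bounds_enforced(self):
        with pytest.raises(ConfigError):
            SimConfig(per_base_error=1.5)

    def test_read_length_must_fit_inserts(self):
        with pytest.raises(ConfigError):
            SimConfig(read_length=500, insert_sizes=(450,))

    def test_tsd_range_bounds(self):
        with pytest.raises(ConfigError):
            SimConfig(tsd_range=(10, 60))

    def test_stage_streams_are_independent_and_reproducible(self):
        cfg = SimConfig(seed=42)
        a = cfg.rng("genome").integers(0, 1000, 5)
        b = cfg.rng("genome").integers(0, 1000, 5)
        c = cfg.rng("reads").integers(0, 1000, 5)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestBuildReference:
    def test_empty_plan_gives_empty_annotation(self, library):
        cfg = SimConfig(seed=1, n_chromosomes=1, chrom_length=50_000,
                        n_decoy_te_copies=0, n_donor_elements=0,
                        n_known_poly_sites=0)
        ref = build_reference(cfg, library)
        assert len(ref.annotation) == 0
        assert len(ref.chroms["chr1"]) == 50_000

    def test_deterministic_for_fixed_seed(self, small_config, library):
        r1 = build_reference(small_config, library)
        r2 = build_reference(small_config, library)
        for c in r1.chroms:
            assert np.array_equal(r1.chroms[c], r2.chroms[c])
        assert r1.annotation.equals(r2.annotation)
        assert r1.known_poly.equals(r2.known_poly)

    def test_donor_records_span_full_consensus(self, library):
        cfg = SimConfig(seed=2, n_chromosomes=1, chrom_length=300_000,
                        n_decoy_te_copies=0, n_donor_elements=2)
        ref = build_reference(cfg, library)
        donors = ref.donors()
        l1 = len(library[0].sequence)
        assert len(donors) == 2
        assert ((donors.end - donors.start) == l1).all()
        # donor sequence is the exact consensus (per annotated strand)
        for row in donors.itertuples():
            seg = ref.seq(row.chrom, row.start, row.end)
            if row.strand == "-":
                seg = dna.revcomp_codes(seg)
            assert dna.decode(seg) == library[0].sequence

    def test_too_small_chromosome_raises_sizing_error(self, library):
        cfg = SimConfig(seed=3, n_chromosomes=1, chrom_length=7_000,
                        n_decoy_te_copies=0, n_donor_elements=1)
        with pytest.raises(SizingError):
            build_reference(cfg, library)


class TestPlanInsertion:
    def test_exact_motif_when_no_mismatch_allowed(self, small_reference,
                                                  library):
        cfg = SimConfig(seed=5, en_max_mismatches=0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            ev = plan_insertion(small_reference, cfg, "heterozygous_de_novo",
                                rng, library)
            codes = small_reference.chroms[ev.chrom]
            if ev.strand == "+":
                motif = dna.decode(codes[ev.nick_pos - 4:ev.nick_pos + 2])
            else:
                motif = dna.revcomp(
                    dna.decode(codes[ev.nick_pos - 2:ev.nick_pos + 4]))
            assert motif == b"TTTTAA"

    def test_tsd_lengths_stay_in_configured_range(self, small_reference,
                                                  library, small_config):
        rng = np.random.default_rng(1)
        lens = [plan_insertion(small_reference, small_config, "polymorphic",
                               rng, library).tsd_len for _ in range(300)]
        assert set(lens) <= set(range(13, 18))
        assert len(set(lens)) == 5  # all values hit at n=300

    def test_forced_transduction_length(self, small_reference, library):
        cfg = SimConfig(seed=6, transduction_prob=1.0)
        rng = np.random.default_rng(2)
        ev = plan_insertion(small_reference, cfg, "polymorphic", rng, library,
                            force_transduction_len=84)
        assert ev.transduction is not None
        seq, donor = ev.transduction
        assert len(seq) == 84 and donor.startswith("donor_")

    def test_no_motif_site_raises(self, library):
        cfg = SimConfig(seed=7, en_max_mismatches=0)
        ref = build_reference(
            SimConfig(seed=7, n_chromosomes=1, chrom_length=20_000,
                      n_decoy_te_copies=0, n_donor_elements=0,
                      gc_background=0.42), library)
        # make the genome motif-free
        ref.chroms["chr1"][:] = np.tile(
            dna.encode(b"ACGG"), 5_000)
        with pytest.raises(PlanningError):
            plan_insertion(ref, cfg, "polymorphic",
                           np.random.default_rng(0), library)

    def test_motif_positions_plus_and_minus(self):
        codes = dna.encode(b"GGTTTTAAGGGGTTAAAAGG")
        plus, minus = motif_positions(codes, "TTTTAA", 0)
        assert list(plus) == [6]    # slash after TTTT at offset 2..8
        assert list(minus) == [14]  # revcomp of TTAAAA at offset 12..18


class TestApplyInsertions:
    def _event(self, library, strand="+", tsd=15, polyA=64, nick=5000):
        return PlannedInsertion(
            id="e1", chrom="chr1", nick_pos=nick, strand=strand,
            subfamily="L1_TF", element_span=(0, len(library[0].sequence)),
            n_monomers=3, tsd_len=tsd, polyA_len=polyA, transduction=None,
            origin_class="heterozygous_de_novo")

    def test_empty_event_list_is_identity(self, library):
        hap = dna.random_seq(np.random.default_rng(0), 10_000)
        out = apply_insertions(hap, [], library)
        assert np.array_equal(out, hap)

    def test_length_arithmetic(self, library):
        hap = dna.random_seq(np.random.default_rng(1), 10_000)
        ev = self._event(library)
        out = apply_insertions(hap, [ev], library)
        L = len(library[0].sequence) - A_TAIL_LEN  # consensus tail replaced
        assert len(out) == 10_000 + L + 64 + 15

    def test_tsd_flanks_identical(self, library):
        hap = dna.random_seq(np.random.default_rng(2), 10_000)
        ev = self._event(library)
        out = apply_insertions(hap, [ev], library)
        cas = len(cassette_codes(ev, library))
        left = out[ev.nick_pos:ev.nick_pos + 15]
        right = out[ev.nick_pos + 15 + cas:ev.nick_pos + 30 + cas]
        assert np.array_equal(left, right)
        assert np.array_equal(left, hap[ev.nick_pos:ev.nick_pos + 15])

    def test_minus_strand_polyA_reads_as_polyT_on_left(self, library):
        hap = dna.random_seq(np.random.default_rng(3), 10_000)
        ev = self._event(library, strand="-")
        out = apply_insertions(hap, [ev], library)
        cassette_start = ev.nick_pos + 15
        run = out[cassette_start:cassette_start + 64]
        assert dna.decode(run) == b"T" * 64
        # and the element appears reverse-complemented
        allele = allele_codes(ev, library)
        assert np.array_equal(
            allele, dna.revcomp_codes(cassette_codes(ev, library)))

    def test_overlapping_events_rejected(self, library):
        hap = dna.random_seq(np.random.default_rng(4), 10_000)
        e1 = self._event(library, nick=5000)
        e2 = self._event(library, nick=5005)
        with pytest.raises(PlanningError):
            apply_insertions(hap, [e1, e2], library)

    def test_round_trip_reconstruction(self, library):
        """The planted TSD string and poly(A) length are exactly
        recoverable from the modified haplotype plus the event record."""
        hap = dna.random_seq(np.random.default_rng(5), 10_000)
        for strand in "+-":
            ev = self._event(library, strand=strand)
            out = apply_insertions(hap, [ev], library)
            cas = cassette_codes(ev, library)
            allele = allele_codes(ev, library)
            start = ev.nick_pos + ev.tsd_len
            assert np.array_equal(out[start:start + len(allele)], allele)
            assert dna.decode(cas[-64:]) == b"A" * 64


class TestSimulatePedigree:
    def test_polymorphic_het_founder_transmits_binomially(self, library):
        cfg = SimConfig(seed=8)
        ped = demo_pedigree(n_offspring=20)
        carriers = []
        for seed in range(30):
            ev = PlannedInsertion(
                id="p", chrom="chr1", nick_pos=100, strand="+",
                subfamily="L1_TF", element_span=(0, 10), n_monomers=0,
                tsd_len=14, polyA_len=30, transduction=None,
                origin_class="polymorphic", origin_animal="P1")
            simulate_pedigree(ped, [ev], cfg, np.random.default_rng(seed))
            carriers.append(sum(1 for a in ped.ids() if a.startswith("F1")
                                and ev.fraction(a, "soma_pool") > 0))
        # each count within the exact binomial(20, 0.5) 99.9% interval
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 20, 0.5)
        assert all(lo <= c <= hi for c in carriers)

    def test_germline_restricted_has_zero_somatic_fraction(self, library):
        cfg = SimConfig(seed=9)
        ped = demo_pedigree(n_offspring=10)
        ev = PlannedInsertion(
            id="g", chrom="chr1", nick_pos=100, strand="+",
            subfamily="L1_TF", element_span=(0, 10), n_monomers=0,
            tsd_len=14, polyA_len=30, transduction=None,
            origin_class="germline_restricted_mosaic", origin_animal="P1")
        simulate_pedigree(ped, [ev], cfg, np.random.default_rng(0))
        soma = [ev.fraction("P1", t) for t in
                ("soma_pool", "brain", "liver", "muscle")]
        assert max(soma) == 0.0
        assert 0 < ev.fraction("P1", "germ_cell_fraction") < 0.5
        assert ev.fraction("P1", "gonad_left") == \
            ev.fraction("P1", "germ_cell_fraction")

    def test_mosaic_transmission_matches_gonadal_fraction(self):
        """Carrier counts across replicates stay within the exact binomial
        99% envelope for the configured germ fraction (the 4-of-7 scenario:
        gonadal fraction 0.29 -> expected carriers 2.03 of 7)."""
        cfg = SimConfig(seed=10, germline_fraction_range=(0.29, 0.29))
        ped = demo_pedigree(n_offspring=7)
        counts = []
        for seed in range(200):
            ev = PlannedInsertion(
                id="m", chrom="chr1", nick_pos=100, strand="+",
                subfamily="L1_TF", element_span=(0, 10), n_monomers=0,
                tsd_len=14, polyA_len=30, transduction=None,
                origin_class="somatic_germline_mosaic", origin_animal="P2")
            simulate_pedigree(ped, [ev], cfg, np.random.default_rng(1000 + seed))
            counts.append(sum(1 for a in ped.ids() if a.startswith("F1")
                              and ev.fraction(a, "soma_pool") == 0.5))
        assert abs(np.mean(counts) - 7 * 0.29) < 0.35
        lo, hi = stats.binom.ppf([0.005, 0.995], 7, 0.29)
        inside = np.mean([lo <= c <= hi for c in counts])
        assert inside > 0.95

    def test_somatic_restricted_never_transmits(self):
        cfg = SimConfig(seed=11)
        ped = demo_pedigree(n_offspring=20)
        ev = PlannedInsertion(
            id="s", chrom="chr1", nick_pos=100, strand="+",
            subfamily="L1_TF", element_span=(0, 10), n_monomers=0,
            tsd_len=14, polyA_len=30, transduction=None,
            origin_class="somatic_restricted_mosaic", origin_animal="P1")
        simulate_pedigree(ped, [ev], cfg, np.random.default_rng(0))
        assert all(ev.fraction(a, "soma_pool") == 0 for a in ped.ids()
                   if a != "P1")
        assert ev.fraction("P1", "germ_cell_fraction") == 0

    def test_unknown_origin_animal_rejected(self):
        cfg = SimConfig(seed=12)
        ped = demo_pedigree(n_offspring=2)
        ev = PlannedInsertion(
            id="x", chrom="chr1", nick_pos=100, strand="+",
            subfamily="L1_TF", element_span=(0, 10), n_monomers=0,
            tsd_len=14, polyA_len=30, transduction=None,
            origin_class="heterozygous_de_novo", origin_animal="GHOST")
        with pytest.raises(ConfigError):
            simulate_pedigree(ped, [ev], cfg, np.random.default_rng(0))


class TestSimulateReads:
    def _cohort_bits(self, library, error=0.0, dup=0.0, chim=0.0,
                     enrichment=20.0, coverage=10.0, seed=13):
        cfg = SimConfig(seed=seed, n_chromosomes=1, chrom_length=120_000,
                        n_decoy_te_copies=2, n_donor_elements=1,
                        per_base_error=error, duplicate_rate=dup,
                        chimera_rate=chim, capture_enrichment=enrichment,
                        coverage_target=coverage, quality_tail_prob=0.0)
        ref = build_reference(cfg, library)
        rng = np.random.default_rng(0)
        ev = plan_insertion(ref, cfg, "heterozygous_de_novo", rng, library,
                            exclude=[(r.chrom, int(r.start), int(r.end))
                                     for r in ref.annotation.itertuples()])
        ev.prevalence = {"A": {"soma_pool": 0.5}}
        windows = build_alt_windows(ref, [ev], library)
        return cfg, ref, ev, windows

    def test_error_free_reads_match_their_source(self, library):
        cfg, ref, ev, windows = self._cohort_bits(library, enrichment=1.0)
        reads = simulate_sample_reads(ref, windows, {ev.id: 0.0}, cfg,
                                      np.random.default_rng(1), "A:soma_pool")
        genome = ref.chroms["chr1"]
        for i in range(0, len(reads.names), 37):
            src = reads.names[i].split("|")[2]
            _kind, _chrom, pos = src.split(":")
            pos = int(pos)
            r1 = dna.encode(reads.r1_seq[i])
            assert np.array_equal(r1, genome[pos:pos + len(r1)])
            r2 = dna.encode(reads.r2_seq[i])
            found = False
            for insert in cfg.insert_sizes:
                frag = genome[pos:pos + insert]
                if np.array_equal(dna.revcomp_codes(frag[-len(r2):]), r2):
                    found = True
            assert found

    def test_same_seed_gives_identical_reads(self, library):
        cfg, ref, ev, windows = self._cohort_bits(library, error=0.002,
                                                  dup=0.05, chim=0.02)
        a = simulate_sample_reads(ref, windows, {ev.id: 0.5}, cfg,
                                  np.random.default_rng(9), "A:soma_pool")
        b = simulate_sample_reads(ref, windows, {ev.id: 0.5}, cfg,
                                  np.random.default_rng(9), "A:soma_pool")
        assert a.names == b.names
        assert a.r1_seq == b.r1_seq and a.r2_seq == b.r2_seq
        assert all(np.array_equal(x, y) for x, y in zip(a.r1_qual, b.r1_qual))

    def test_capture_enrichment_boosts_junction_depth(self, library):
        """Mean depth over the 5' junction >= 10x the depth of a flanking
        single-copy control window (enrichment 20, coverage 5)."""
        cfg, ref, ev, windows = self._cohort_bits(library, enrichment=20.0,
                                                  coverage=5.0)
        reads = simulate_sample_reads(ref, windows, {ev.id: 1.0}, cfg,
                                      np.random.default_rng(2), "A:soma_pool")
        win = windows[ev.id]
        # element 5' junction (the captured, non-depleted side)
        j_point = win.allele_start if ev.strand == "+" else win.allele_end
        # single-copy control window away from every annotated interval
        blocked = [(int(r.start), int(r.end))
                   for r in ref.annotation.itertuples()]
        ctrl = 20_000
        while any(s - 3000 < ctrl < e + 3000 for s, e in blocked) or \
                abs(ctrl - ev.nick_pos) < 10_000:
            ctrl += 5_000
        j_depth = c_depth = 0
        max_ins = max(cfg.insert_sizes)
        for name in reads.names:
            src = name.split("|")[2]
            kind = src.split(":")[0]
            pos = int(src.split(":")[-1])
            if kind == "ins" and pos < j_point and pos + max_ins > j_point:
                j_depth += 1
            if kind == "ref" and pos < ctrl and pos + max_ins > ctrl:
                c_depth += 1
        assert j_depth >= 10 * max(c_depth, 1)

    def test_duplicates_are_tagged_and_identical(self, library):
        cfg, ref, ev, windows = self._cohort_bits(library, dup=0.2)
        reads = simulate_sample_reads(ref, windows, {ev.id: 0.0}, cfg,
                                      np.random.default_rng(3), "A:soma_pool")
        dups = [i for i, n in enumerate(reads.names) if n.endswith("|dup")]
        assert len(dups) > 10
        for i in dups[:20]:
            assert reads.r1_seq[i] == reads.r1_seq[i - 1]
            assert reads.names[i].split("|")[2] == \
                reads.names[i - 1].split("|")[2]

    def test_three_prime_depletion_removes_3p_junction_fragments(self, library):
        cfg, ref, ev, windows = self._cohort_bits(library)
        cfg_dep = SimConfig(**{**cfg.to_dict(), "three_prime_depletion": 1.0})
        reads = simulate_sample_reads(ref, windows, {ev.id: 1.0}, cfg_dep,
                                      np.random.default_rng(4), "A:soma_pool")
        win = windows[ev.id]
        max_ins = max(cfg.insert_sizes)
        for name in reads.names:
            src = name.split("|")[2]
            if src.startswith("ins:"):
                p = int(src.split(":")[-1])
                assert not (p < win.pA_junction < p + max_ins)


class TestSimulateQpcr:
    def test_no_amplification_sentinel_for_zero_fraction(self):
        m = simulate_qpcr(0.0, 0.0, 4, np.random.default_rng(0))
        assert m.no_amplification

    def test_noise_free_ct_reflects_log2_fraction(self):
        a = simulate_qpcr(0.5, 0.0, 3, np.random.default_rng(0))
        b = simulate_qpcr(0.25, 0.0, 3, np.random.default_rng(0))
        assert b.target_ct[0] - a.target_ct[0] == pytest.approx(1.0)
        assert a.reference_ct == b.reference_ct
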