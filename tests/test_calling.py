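"""Junction extraction, clustering, pairing, known/chimera filtering."""

import numpy as np
import pytest

from retroped import dna
from retroped.align import (GenomeIndex, ConsensusIndex, AlignmentHit,
                            align_to_consensus)
from retroped.calling import (JunctionRead, extract_junctions,
                              cluster_junctions, pair_clusters, filter_known,
                              chimera_filter, filter_reference_te,
                              build_presence_matrix, Cluster, InsertionCall,
                              DiscardLedger)
from retroped.consensus import default_library

import pandas as pd


@pytest.fixture(scope="module")
def setup():
    library = default_library()
    rng = np.random.default_rng(0)
    genome = dna.random_seq(rng, 60_000)
    gindex = GenomeIndex({"chr1": genome})
    cindex = ConsensusIndex(library)
    lengths = {el.name: len(el.sequence) for el in library}
    return library, genome, gindex, cindex, lengths


def _junctions_for(seq: bytes, gindex, cindex, lengths, cid="c1",
                   sample="s1", chim=False):
    te_hits = align_to_consensus(seq, cindex)
    return extract_junctions(seq, cid, sample, te_hits, gindex, lengths,
                             chimera_tag=chim)


class TestExtractJunctions:
    def test_five_prime_junction_from_flank_plus_monomer(self, setup):
        library, genome, gindex, cindex, lengths = setup
        el = dna.encode(library[0].sequence)
        contig = dna.decode(np.concatenate([genome[10_000:10_120], el[:80]]))
        jrs = _junctions_for(contig, gindex, cindex, lengths)
        assert len(jrs) == 1
        j = jrs[0]
        assert j.side == "five_prime"
        assert j.junction_pos == 10_120
        assert j.te_orientation == "+"
        assert j.subfamily == "L1_TF"

    def test_contig_entirely_within_consensus_is_dropped(self, setup):
        library, genome, gindex, cindex, lengths = setup
        el = dna.encode(library[0].sequence)
        ledger = DiscardLedger()
        te_hits = align_to_consensus(dna.decode(el[1000:1150]), cindex)
        out = extract_junctions(dna.decode(el[1000:1150]), "c", "s",
                                te_hits, gindex, lengths, ledger=ledger)
        assert out == []
        assert ledger["no_genome_anchor"] == 1

    def test_three_prime_minus_orientation_junction(self, setup):
        """Genome flank + poly(A) + element 3' end in minus orientation."""
        library, genome, gindex, cindex, lengths = setup
        el = dna.encode(library[0].sequence)
        # cassette on reference: revcomp(element-with-polyA); the read
        # covering the left cassette edge shows flank, then poly(T), then
        # the reverse complement of the element 3' end
        cassette_left = dna.revcomp_codes(
            np.concatenate([el[-120:-25], np.zeros(60, dtype=np.uint8)]))
        contig = dna.decode(np.concatenate([genome[20_000:20_100],
                                            cassette_left]))
        jrs = _junctions_for(contig, gindex, cindex, lengths)
        assert len(jrs) == 1
        j = jrs[0]
        assert j.side == "three_prime"
        assert j.te_orientation == "-"
        assert abs(j.junction_pos - 20_100) <= 3  # poly(T)-stripping wobble


class TestClusterJunctions:
    def _jr(self, pos, sample="s1", side="five_prime", orient="+",
            cid="c", boundary=0):
        ghit = AlignmentHit(cid, (0, 100), "chr1", (pos - 100, pos), "+",
                            100, 100, 100, unique=True)
        tehit = AlignmentHit(cid, (100, 150), "L1_TF", (0, 50), "+",
                             50, 50, 50)
        return JunctionRead(cid, sample, ghit, tehit, pos, side, orient,
                            "L1_TF", boundary, 6461)

    def test_three_close_reads_form_primary_cluster(self):
        reads = [self._jr(1000), self._jr(1004), self._jr(1010)]
        cl = cluster_junctions(reads)
        assert len(cl) == 1 and len(cl[0].reads) == 3
        assert cl[0].modal_pos == 1000  # tie -> smallest coordinate

    def test_two_reads_stay_low_evidence(self):
        calls = pair_clusters(cluster_junctions([self._jr(1000),
                                                 self._jr(1002)]))
        assert len(calls) == 1 and not calls[0].primary

    def test_distant_read_splits_off(self):
        reads = [self._jr(1000), self._jr(1004), self._jr(1010),
                 self._jr(6000)]
        cl = cluster_junctions(reads)
        assert sorted(len(c.reads) for c in cl) == [1, 3]

    def test_modal_position_uses_mode(self):
        reads = [self._jr(1000), self._jr(1003), self._jr(1003)]
        assert cluster_junctions(reads)[0].modal_pos == 1003

    def test_order_invariance(self):
        reads = [self._jr(p, cid=f"c{p}") for p in (1010, 1000, 1004, 990)]
        a = cluster_junctions(reads)
        b = cluster_junctions(list(reversed(reads)))
        assert [[r.contig_id for r in c.reads] for c in a] == \
            [[r.contig_id for r in c.reads] for c in b]


class TestPairClusters:
    def _cluster(self, pos, side, orient="+", n=3, sample="s1"):
        reads = [JunctionRead(
            f"c{pos}_{i}", sample,
            AlignmentHit("q", (0, 100), "chr1", (pos - 100 + i, pos), "+",
                         100, 100, 100, unique=True),
            AlignmentHit("q", (100, 150), "L1_TF", (0, 50), "+", 50, 50, 50),
            pos, side, orient, "L1_TF", 0, 6461) for i in range(n)]
        return Cluster("chr1", side, orient, "L1_TF", reads)

    def test_matched_pair_merges_with_tsd_candidate_separation(self):
        calls = pair_clusters([self._cluster(1015, "five_prime"),
                               self._cluster(1000, "three_prime")])
        assert len(calls) == 1
        c = calls[0]
        assert (c.pos_5p, c.pos_3p) == (1015, 1000)
        assert sum(c.support.values()) == 6

    def test_unpaired_five_prime_becomes_single_junction_call(self):
        calls = pair_clusters([self._cluster(1015, "five_prime")])
        assert len(calls) == 1
        assert calls[0].pos_3p is None and calls[0].pos_5p == 1015

    def test_nearest_greedy_resolution(self):
        c5a = self._cluster(1015, "five_prime")
        c5b = self._cluster(1060, "five_prime")
        c3 = self._cluster(1020, "three_prime")
        calls = pair_clusters([c5a, c5b, c3])
        paired = [c for c in calls if c.pos_5p and c.pos_3p]
        single = [c for c in calls if c.pos_3p is None]
        assert len(paired) == 1 and paired[0].pos_5p == 1015
        assert len(single) == 1 and single[0].pos_5p == 1060

    def test_far_apart_clusters_stay_separate(self):
        calls = pair_clusters([self._cluster(1100, "five_prime"),
                               self._cluster(1000, "three_prime")])
        assert len(calls) == 2


class TestFilterKnown:
    def _call(self, pos=5000, support=None):
        return InsertionCall("c1", "chr1", pos, None, "+", "L1_TF",
                             support or {"s1": 4})

    def test_database_locus_flagged(self):
        call = self._call()
        db = pd.DataFrame([dict(chrom="chr1", start=5050, end=5051,
                                name="k1", family="L1")])
        filter_known([call], db, {})
        assert call.known_polymorphic

    def test_robust_in_all_founder_libraries_flagged(self):
        call = self._call(support={"P1:soma_pool": 5,
                                   "P1:germ_cell_fraction": 4})
        filter_known([call], pd.DataFrame(columns=["chrom", "start", "end",
                                                   "name", "family"]),
                     {"P1": ["P1:soma_pool", "P1:germ_cell_fraction"]})
        assert call.founder_polymorphic

    def test_offspring_only_call_keeps_both_flags_false(self):
        call = self._call(support={"F1:soma_pool": 6, "P1:soma_pool": 0})
        filter_known([call], pd.DataFrame(columns=["chrom", "start", "end",
                                                   "name", "family"]),
                     {"P1": ["P1:soma_pool"]})
        assert not call.known_polymorphic and not call.founder_polymorphic


class TestChimeraFilter:
    def _call_with_boundaries(self, boundaries, orients=None, coords=None):
        orients = orients or ["+"] * len(boundaries)
        reads = []
        for i, (b, o) in enumerate(zip(boundaries, orients)):
            span = coords[i] if coords else (1000 + i, 1100 + i)
            reads.append(JunctionRead(
                f"c{i}", "s1",
                AlignmentHit("q", (0, 100), "chr1", span, "+",
                             100, 100, 100, unique=True),
                AlignmentHit("q", (100, 150), "L1_TF", (0, 50), o,
                             50, 50, 50),
                1100, "five_prime", o, "L1_TF", b, 6461))
        cl = Cluster("chr1", "five_prime", orients[0], "L1_TF", reads)
        call = InsertionCall("c1", "chr1", 1100, None, orients[0], "L1_TF",
                             {"s1": len(reads)}, clusters=[cl])
        return call

    def test_orientation_disagreement_flags_rule_b(self):
        call = self._call_with_boundaries([0, 0, 0], orients=["+", "-", "+"])
        chimera_filter([call])
        assert call.chimera_suspect and "b" in call.chimera_rules

    def test_interior_boundary_flags_rule_d(self):
        call = self._call_with_boundaries([-1, -1, 0])
        chimera_filter([call])
        assert call.chimera_suspect and "d" in call.chimera_rules

    def test_pcr_stack_flags_rule_c(self):
        call = self._call_with_boundaries([0, 0, 0],
                                          coords=[(1000, 1100)] * 3)
        chimera_filter([call])
        assert "c" in call.chimera_rules

    def test_clean_call_not_flagged(self):
        call = self._call_with_boundaries([0, 0, 0])
        chimera_filter([call])
        assert not call.chimera_suspect


class TestReferenceTeFilter:
    def test_junction_at_reference_copy_terminus_flagged(self):
        call = InsertionCall("c1", "chr1", 10_050, None, "+", "L1_TF",
                             {"s1": 5})
        annot = pd.DataFrame([dict(chrom="chr1", start=10_000, end=16_000,
                                   name="donor_1", role="donor", strand="+",
                                   family="L1_TF")])
        filter_reference_te([call], annot)
        assert call.reference_te

    def test_distant_call_unflagged(self):
        call = InsertionCall("c1", "chr1", 30_000, None, "+", "L1_TF",
                             {"s1": 5})
        annot = pd.DataFrame([dict(chrom="chr1", start=10_000, end=16_000,
                                   name="donor_1", role="donor", strand="+",
                                   family="L1_TF")])
        filter_reference_te([call], annot)
        assert not call.reference_te


class TestPresenceMatrix:
    def test_thresholds_and_explicit_zeros(self):
        call = InsertionCall("c1", "chr1", 100, None, "+", "L1_TF",
                             {"a": 4, "c": 2})
        m = build_presence_matrix([call], ["a", "b", "c"])
        assert m.loc["c1", "a"] == 4 and m.loc["c1", "b"] == 0
        assert call.detection_class("a") == "robust"
        assert call.detection_class("b") == "absent"
        assert call.detection_class("c") == "low"

    def test_empty_call_set(self):
        m = build_presence_matrix([], ["a", "b"])
        assert m.shape == (0, 2) and list(m.columns) == ["a", "b"]

    def test_unknown_sample_rejected(self):
        call = InsertionCall("c1", "chr1", 100, None, "+", "L1_TF",
                             {"ghost": 4})
        with pytest.raises(ValueError):
            build_presence_matrix([call], ["a"])

    def test_row_sums_conserve_read_support(self):
        calls = [InsertionCall(f"c{i}", "chr1", 100 * i, None, "+", "L1_TF",
                               {"a": i, "b": 2 * i}) for i in range(1, 4)]
        m = build_presence_matrix(calls, ["a", "b"])
        for i, c in enumerate(calls):
            assert m.iloc[i].sum() == sum(c.support.values())
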