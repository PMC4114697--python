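from dataclasses import dataclass

import pytest

from srnaevo import annotate
from srnaevo.annotate import HitRecord, SiteInterval


class TestEvalueNormalization:
    @pytest.mark.parametrize(
        "e,glen,expected",
        [(5.0, 2_000_000, 10.0), (7.3, 4_000_000, 7.3), (0.0, 1_000_000, 0.0)],
    )
    def test_linear_scaling(self, e, glen, expected):
        assert annotate.normalize_evalue(e, glen) == pytest.approx(expected)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            annotate.normalize_evalue(1.0, 0)


class TestPresenceFromHits:
    GENOMES = ["g1", "g2", "g3"]

    def hit(self, genome, e, ident):
        return HitRecord("q1", genome, e, ident, 4_000_000)

    def test_boundary_values_are_inclusive(self):
        prof = annotate.call_presence_from_hits(
            [self.hit("g1", 10.0, 0.30)], "fam", self.GENOMES
        )
        assert prof.states == {"g1": 1, "g2": 0, "g3": 0}

    def test_below_threshold_absent(self):
        prof = annotate.call_presence_from_hits(
            [self.hit("g1", 9.0, 0.29)], "fam", self.GENOMES
        )
        assert prof.states["g1"] == 0

    def test_any_family_member_suffices(self):
        hits = [
            HitRecord("q1", "g2", 50.0, 0.9, 4_000_000),
            HitRecord("q2", "g2", 1.0, 0.5, 4_000_000),
        ]
        prof = annotate.call_presence_from_hits(hits, "fam", self.GENOMES)
        assert prof.states["g2"] == 1

    def test_monotone_in_identity_threshold(self):
        import numpy as np

        rng = np.random.default_rng(0)
        hits = [
            HitRecord("q", f"g{i}", float(rng.uniform(0, 20)),
                      float(rng.uniform()), 4_000_000)
            for i in range(50)
        ]
        genomes = [f"g{i}" for i in range(50)]
        present = {}
        for id_min in (0.70, 0.50, 0.30):
            prof = annotate.call_presence_from_hits(hits, "f", genomes, id_min=id_min)
            present[id_min] = {g for g, s in prof.states.items() if s == 1}
        assert present[0.70] <= present[0.50] <= present[0.30]


class TestExtractWindow:
    def test_forward_window(self):
        seq = "A" * 50 + "C" * 150 + "G" * 60
        win = annotate.extract_window(seq, cds_start=200, strand="+")
        assert win == seq[50:250]
        assert len(win) == 200

    def test_truncated_at_contig_start(self):
        seq = "ACGT" * 60
        win = annotate.extract_window(seq, cds_start=100, strand="+")
        assert win == seq[0:150]

    def test_reverse_strand_is_mirrored_revcomp(self):
        import numpy as np

        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 400))
        cds = 200
        win = annotate.extract_window(seq, cds_start=cds, strand="-")
        from Bio.Seq import Seq

        expected = str(Seq(seq[cds - 49: cds + 151]).reverse_complement())
        assert win == expected

    def test_out_of_range_start_rejected(self):
        with pytest.raises(ValueError):
            annotate.extract_window("ACGT", cds_start=10)


class TestMapSiteColumns:
    def test_gapless_alignment_extracts_padded_site(self):
        msa = {"ref": "ACGUACGUACGUACGUACGUACGUACGU", "o1": "GCGUACGUACGUACGUACGUACGUACGC"}
        ex = annotate.map_site_columns(msa, "ref", SiteInterval("m", 10, 20))
        assert ex.rows["ref"][0] == msa["ref"][5:25]
        assert not ex.rows["ref"][1] and not ex.rows["o1"][1]

    def test_gap_in_core_sets_flag_but_pad_gap_does_not(self):
        #            pads  core       pads
        ref = "AAAAACCCCCGGGGGUUUUUAAAAA"
        core_gap = ref[:12] + "-" + ref[13:]
        pad_gap = "-" + ref[1:]
        msa = {"ref": ref, "core": core_gap, "pad": pad_gap}
        ex = annotate.map_site_columns(msa, "ref", SiteInterval("m", 10, 15))
        assert ex.rows["core"][1] is True
        assert ex.rows["pad"][1] is False

    def test_reference_gap_columns_are_retained(self):
        msa = {"ref": "AC--GUACGU", "o1": "ACGGGUACGU"}
        ex = annotate.map_site_columns(msa, "ref", SiteInterval("m", 1, 4), pad=0)
        # ref ungapped positions 1..3 span MSA columns 1..5 inclusive
        assert ex.rows["o1"][0] == "CGGGU"
        assert ex.rows["ref"][0] == "CGU"

    def test_pad_clipped_at_sequence_start(self):
        msa = {"ref": "ACGUACGUAC"}
        ex = annotate.map_site_columns(msa, "ref", SiteInterval("m", 2, 6))
        assert ex.rows["ref"][0] == msa["ref"][0:10]  # left pad clipped to 0

    def test_degapping_reproduces_reference_site(self):
        msa = {"ref": "A-CGU-ACGUA", "o1": "AACGUUACGUA"}
        site = SiteInterval("m", 3, 7)
        ex = annotate.map_site_columns(msa, "ref", site, pad=2)
        ref_ungapped = msa["ref"].replace("-", "")
        assert ex.rows["ref"][0] == ref_ungapped[1:9]


class TestConsensus:
    def test_identical_rows(self):
        assert annotate.consensus_site(["ACGU", "ACGU"]) == "ACGU"

    def test_majority_and_tie_break(self):
        assert annotate.consensus_site(["AAG", "AAG", "GAG"]) == "AAG"
        assert annotate.consensus_site(["AC", "GC"]) == "AC"  # tie -> alphabetical

    def test_gaps_do_not_vote_and_all_gap_dropped(self):
        assert annotate.consensus_site(["A-C", "A-C", "AG-"]) == "AGC"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            annotate.consensus_site([])


@dataclass(frozen=True)
class Rec:
    sbs: SiteInterval
    mbs: SiteInterval


def rec(s0, s1, m0, m1):
    return Rec(SiteInterval("s", s0, s1), SiteInterval("m", m0, m1))


class TestDistinctInteractions:
    def test_close_records_merge_to_union(self):
        a = rec(0, 10, 100, 110)
        b = rec(2, 12, 112, 120)  # mRNA edge distance 2 < 10
        merged = annotate.distinct_interactions([a, b])
        assert len(merged) == 1
        assert (merged[0].mbs.start, merged[0].mbs.end) == (100, 120)

    def test_exactly_ten_apart_stay_distinct(self):
        a = rec(0, 10, 100, 110)
        b = rec(0, 10, 120, 130)  # edge distance exactly 10
        assert len(annotate.distinct_interactions([a, b])) == 2

    def test_must_be_close_on_both_molecules(self):
        a = rec(0, 10, 100, 110)
        b = rec(50, 60, 100, 110)  # far on the sRNA
        assert len(annotate.distinct_interactions([a, b])) == 2

    def test_transitive_closure(self):
        a = rec(0, 10, 100, 110)
        b = rec(0, 10, 115, 125)
        c = rec(0, 10, 130, 140)  # close to b, not to a
        merged = annotate.distinct_interactions([a, b, c])
        assert len(merged) == 1
        assert (merged[0].mbs.start, merged[0].mbs.end) == (100, 140)

    def test_idempotent_and_order_independent(self):
        recs = [rec(0, 10, 100, 110), rec(2, 12, 112, 120), rec(40, 50, 300, 310)]
        m1 = annotate.distinct_interactions(recs)
        m2 = annotate.distinct_interactions(list(reversed(recs)))
        assert [(r.sbs.start, r.mbs.start) for r in m1] == [
            (r.sbs.start, r.mbs.start) for r in m2
        ]
        assert annotate.distinct_interactions(m1) == m1
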