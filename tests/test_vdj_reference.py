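"""Reference parsing, segment QC, filtering, and primer auditing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rmtcr import vdj_reference as vr
from conftest import brute_force_primer_scan, brute_force_stop_scan, random_dna

REVCOMP = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------- FASTA dialect


class TestParseImgtFasta:
    def test_header_fields_mapped_positionally(self):
        text = ">340|TRAC*01 IMGT|TRAC|C-REGION|TR|TRA|None|01\nATGAAA\n"
        ref = vr.parse_imgt_fasta(text)
        (rec,) = ref.records
        assert rec.record_id == 340
        assert rec.allele == "TRAC*01"
        assert rec.source_note == "IMGT"
        assert rec.gene == "TRAC"
        assert rec.region is vr.Region.C
        assert rec.chain is vr.Chain.TRA
        assert rec.sequence == "ATGAAA"

    def test_empty_input_gives_empty_set(self):
        assert len(vr.parse_imgt_fasta("")) == 0

    def test_bundled_cregions_counts(self, cregions):
        assert len(cregions) == 9
        assert sum(r.gene == "TRAC" for r in cregions) == 6
        assert sum(r.chain is vr.Chain.TRB for r in cregions) == 3

    def test_wrapped_and_lowercase_sequence_is_concatenated_uppercased(self):
        text = ">1|X*01 note|X|V-REGION|TR|TRA|None|01\nacg\nTAC\n"
        assert vr.parse_imgt_fasta(text).records[0].sequence == "ACGTAC"

    def test_malformed_header_rejected_with_reason(self):
        text = ">1|X*01|X|V-REGION\nACGT\n>2|Y*01 n|Y|V-REGION|TR|TRA|None|01\nACGT\n"
        ref = vr.parse_imgt_fasta(text)
        assert [r.allele for r in ref.records] == ["Y*01"]
        assert len(ref.skipped) == 1 and "field" in ref.skipped[0][1]

    def test_empty_sequence_rejected(self):
        text = ">1|X*01 n|X|V-REGION|TR|TRA|None|01\n\n>2|Y*01 n|Y|V-REGION|TR|TRA|None|01\nACGT\n"
        ref = vr.parse_imgt_fasta(text)
        assert len(ref.records) == 1 and len(ref.skipped) == 1

    def test_unknown_region_maps_to_other_but_roundtrips(self, tmp_path):
        text = ">1|X*01 n|X|WEIRD-REGION|TR|TRG|None|01\nACGT\n"
        ref = vr.parse_imgt_fasta(text)
        rec = ref.records[0]
        assert rec.region is vr.Region.OTHER and rec.region_raw == "WEIRD-REGION"
        out = tmp_path / "w.fasta"
        vr.write_reference_fasta(ref, out)
        assert vr.parse_imgt_fasta(out).records[0].region_raw == "WEIRD-REGION"

    def test_roundtrip_is_identity_on_bundled_records(self, cregions, tmp_path):
        out = tmp_path / "rt.fasta"
        vr.write_reference_fasta(cregions, out)
        back = vr.parse_imgt_fasta(out)
        assert len(back) == len(cregions)
        for a, b in zip(cregions, back):
            assert a == b


# ------------------------------------------------------------------ segment QC


def _rec(seq, region=vr.Region.C, allele="X*01"):
    return vr.SegmentRecord(
        record_id=1, allele=allele, gene="X", region=region,
        chain=vr.Chain.TRA, sequence=seq,
    )


class TestQcSegment:
    def test_internal_stop_codon_is_flagged(self):
        flags = vr.qc_segment(_rec("ATGTAAGGGCCC"), frame_offset=0)
        stop_flags = [f for f in flags if f.code is vr.FlagCode.PREMATURE_STOP]
        assert len(stop_flags) == 1 and stop_flags[0].position == 3

    def test_clean_in_frame_sequence_has_no_flags(self):
        assert vr.qc_segment(_rec("ATGGGGATGGGGATGGGGATGGGGATGGGG")) == []

    def test_terminal_stop_is_not_premature(self):
        flags = vr.qc_segment(_rec("ATGGGGATGGGGATGGGGATGGGGATGTGA"))
        assert not any(f.code is vr.FlagCode.PREMATURE_STOP for f in flags)

    def test_frame_length_flag_for_non_codon_multiple_c_region(self):
        flags = vr.qc_segment(_rec("ATGGGGATGGGGATGGGGATGGGGATGGGGC"))
        assert any(f.code is vr.FlagCode.FRAME_LENGTH for f in flags)

    def test_partial_c_region_is_exempt_from_frame_length(self):
        rec = vr.SegmentRecord(
            record_id=1, allele="X*01", gene="X", region=vr.Region.C,
            chain=vr.Chain.TRA, partial=True,
            sequence="ATGGGGATGGGGATGGGGATGGGGATGGGGC",
        )
        assert not any(
            f.code is vr.FlagCode.FRAME_LENGTH for f in vr.qc_segment(rec)
        )

    def test_ambiguous_base_and_short_sequence_flagged(self):
        flags = vr.qc_segment(_rec("ATGNGGATG", region=vr.Region.V))
        codes = {f.code for f in flags}
        assert codes == {vr.FlagCode.AMBIGUOUS_BASE, vr.FlagCode.TOO_SHORT}
        npos = [f.position for f in flags if f.code is vr.FlagCode.AMBIGUOUS_BASE]
        assert npos == [3]

    def test_bad_frame_offset_rejected(self):
        with pytest.raises(ValueError):
            vr.qc_segment(_rec("ATGGGG"), frame_offset=3)

    @pytest.mark.parametrize("frame", [0, 1, 2])
    def test_stop_positions_match_codon_walk_oracle_on_all_cregions(
        self, cregions, frame
    ):
        for rec in cregions:
            expected = brute_force_stop_scan(rec.sequence, frame)
            got = [
                f.position
                for f in vr.qc_segment(rec, frame_offset=frame)
                if f.code is vr.FlagCode.PREMATURE_STOP
            ]
            assert got == expected, rec.allele

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(
        # codons for a stop-free protein
        ["ATG", "GCC", "AAA", "TTT", "CTG", "GAC", "TGG", "CAT"]
    ), min_size=10, max_size=60))
    def test_stop_free_coding_sequence_never_flagged_for_stops(self, codons):
        rec = _rec("".join(codons))
        assert not any(
            f.code is vr.FlagCode.PREMATURE_STOP for f in vr.qc_segment(rec)
        )


class TestFilterReference:
    def test_all_clean_fixture_removes_nothing(self):
        ref = vr.ReferenceSet(records=[
            vr.SegmentRecord(
                record_id=i, allele=f"X*0{i}", gene="X", region=vr.Region.C,
                chain=vr.Chain.TRA, sequence="ATGGGGATGGGGATGGGGATGGGGATGGGG",
            )
            for i in range(3)
        ])
        kept, removed = vr.filter_reference(ref)
        assert len(kept) == 3 and removed == []

    def test_planted_stops_are_removed_exactly(self):
        clean = "ATGGGGATGGGGATGGGGATGGGGATGGGG"
        dirty = "ATGTAAATGGGGATGGGGATGGGGATGGGG"
        seqs = [clean, dirty, clean, dirty, clean]
        ref = vr.ReferenceSet(records=[
            vr.SegmentRecord(record_id=i, allele=f"X*0{i}", gene="X",
                             region=vr.Region.C, chain=vr.Chain.TRA, sequence=s)
            for i, s in enumerate(seqs)
        ])
        kept, removed = vr.filter_reference(ref)
        assert len(kept) == 3 and len(removed) == 2
        assert [r.record_id for r, _ in removed] == [1, 3]
        assert [r.record_id for r in kept] == [0, 2, 4]

    def test_partition_matches_oracle_on_bundled_cregions(self, cregions):
        kept, removed = vr.filter_reference(cregions)
        assert len(kept) + len(removed) == len(cregions)
        for rec in cregions:
            bad = bool(brute_force_stop_scan(rec.sequence, 0)) or len(rec) % 3 != 0
            assert (rec.allele in [r.allele for r, _ in removed]) == bad

    def test_ambiguous_base_only_warns(self):
        seq = "ATGGGGATGGGGATGGGGATGGGGATGNGG"
        ref = vr.ReferenceSet(records=[vr.SegmentRecord(
            record_id=1, allele="X*01", gene="X", region=vr.Region.V,
            chain=vr.Chain.TRA, sequence=seq)])
        kept, removed = vr.filter_reference(ref)
        assert len(kept) == 1 and not removed


# ---------------------------------------------------------------- primer audit


class TestFindPrimerSites:
    def test_v1_beta_inner_has_one_antisense_site_on_trbc1(self, cregions):
        primer = vr.ENRICHMENT_PRIMERS["v1"]["beta_inner"]
        rec = cregions.get("TRBC1*01")
        sites = vr.find_primer_sites(primer, rec, max_mismatch=0)
        assert len(sites) == 1 and sites[0].strand == "antisense"
        rc = primer.translate(REVCOMP)[::-1]
        (start, mm), = brute_force_primer_scan(rec.sequence, rc, 0)
        assert (sites[0].start, sites[0].mismatches) == (start, mm)
        assert sites[0].end - sites[0].start == len(primer)

    def test_v2_alpha_inner_has_one_antisense_site_on_trac1(self, cregions):
        primer = vr.ENRICHMENT_PRIMERS["v2"]["alpha_inner"]
        sites = vr.find_primer_sites(primer, cregions.get("TRAC*01"), 0)
        assert len(sites) == 1 and sites[0].strand == "antisense"

    def test_absent_motif_gives_empty_list(self, cregions):
        assert vr.find_primer_sites("AAAAAAAAAA", cregions.get("TRAC*01"), 0) == []

    def test_non_dna_primer_rejected(self, cregions):
        with pytest.raises(ValueError):
            vr.find_primer_sites("ACGTACGRYN", cregions.get("TRAC*01"), 0)

    def test_short_primer_rejected(self, cregions):
        with pytest.raises(ValueError):
            vr.find_primer_sites("ACGTACGTA", cregions.get("TRAC*01"), 0)

    def test_agrees_with_sliding_window_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            template = random_dna(rng, int(rng.integers(30, 120)))
            primer = random_dna(rng, int(rng.integers(10, 16)))
            rec = vr.SegmentRecord(
                record_id=1, allele="R*01", gene="R", region=vr.Region.V,
                chain=vr.Chain.TRA, sequence=template,
            )
            sites = vr.find_primer_sites(primer, rec, max_mismatch=0)
            rc = primer.translate(REVCOMP)[::-1]
            expect = sorted(
                [(s, "sense") for s, _ in brute_force_primer_scan(template, primer, 0)]
                + [(s, "antisense") for s, _ in brute_force_primer_scan(template, rc, 0)]
            )
            assert sorted((s.start, s.strand) for s in sites) == expect


class TestNestedDistance:
    def test_antisense_site_arithmetic(self):
        outer = vr.PrimerSite("TRAC*01", 300, 320, "antisense", 0)
        inner = vr.PrimerSite("TRAC*01", 100, 124, "antisense", 0)
        assert vr.nested_distance(outer, inner) == 200

    def test_identical_sites_have_distance_zero(self):
        s = vr.PrimerSite("TRAC*01", 100, 124, "antisense", 0)
        assert vr.nested_distance(s, s) == 0

    def test_different_segments_rejected(self):
        a = vr.PrimerSite("TRAC*01", 100, 124, "antisense", 0)
        b = vr.PrimerSite("TRAC*02", 100, 124, "antisense", 0)
        with pytest.raises(ValueError):
            vr.nested_distance(a, b)

    def test_v1_alpha_pair_distance_from_scan_coordinates(self, cregions):
        # the v1 alpha inner primer needs 2 mismatches to sit on TRAC*01; the
        # outer sits exactly. Distance is whatever the scan coordinates give
        # (the assay's quoted amplicon spacing spans the mRNA, not only the
        # C segment, so no particular printed value is assumed here).
        rec = cregions.get("TRAC*01")
        outer = vr.find_primer_sites(vr.ENRICHMENT_PRIMERS["v1"]["alpha_outer"], rec, 0)
        inner = vr.find_primer_sites(vr.ENRICHMENT_PRIMERS["v1"]["alpha_inner"], rec, 2)
        assert len(outer) == 1 and len(inner) == 1
        d = vr.nested_distance(outer[0], inner[0])
        assert d == outer[0].start - inner[0].start > 0


class TestPrimerProperties:
    @pytest.mark.parametrize(
        "primer, gc, tm",
        [
            ("ATAT", 0.0, 8.0),
            ("GCGC", 1.0, 16.0),
            # v1 alpha outer: 21 nt, 14 G/C -> GC 2/3, Tm 2*7 + 4*14 = 70
            ("CCGGCCACTTTCAGGAGGAGG", 14 / 21, 70.0),
        ],
    )
    def test_known_values(self, primer, gc, tm):
        got_gc, got_tm = vr.primer_properties(primer)
        assert got_gc == pytest.approx(gc, abs=1e-12)
        assert got_tm == pytest.approx(tm, abs=1e-9)

    def test_empty_primer_rejected(self):
        with pytest.raises(ValueError):
            vr.primer_properties("")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=40))
    def test_gc_fraction_invariant_under_reverse_complement(self, primer):
        rc = primer.translate(REVCOMP)[::-1]
        assert vr.primer_properties(primer)[0] == pytest.approx(
            vr.primer_properties(rc)[0], abs=1e-12
        )
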