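import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recessmap.consequence import (CodingVariant, annotate, apply_coding_variant,
                                   normalize_3prime, translate, truncation_summary)
from recessmap.errors import DomainError
from recessmap.simulate import (build_synthetic_transcript,
                                synthetic_cubn_like_transcript,
                                synthetic_mrc1_like_transcript)

_SENSE = ["GCT", "GAA", "CTG", "AAA", "GGC", "TTC", "CCA", "GAT", "ACC", "GTG"]


class TestTranslate:
    @pytest.mark.parametrize("cds,protein", [
        ("ATGTGA", "M"),
        ("ATGCGATAA", "MR"),
        ("ATGAAACG", "MK"),          # trailing 2-mer ignored
    ])
    def test_examples(self, cds, protein):
        assert translate(cds) == protein

    def test_stops_at_first_stop(self):
        assert translate("ATGTAAATGCGA") == "M"

    def test_non_acgt_rejected(self):
        with pytest.raises(DomainError):
            translate("ATGNNNTAA")


class TestAnnotateKnownVariants:
    def test_nonsense_at_codon_715(self):
        tm, cv = synthetic_mrc1_like_transcript()
        call = annotate(tm, cv)
        assert call.hgvs_c == "c.2143C>T"
        assert call.hgvs_p == "p.R715*"
        assert call.effect == "nonsense"
        assert (call.wt_orf_codons, call.mut_orf_codons) == (1456, 714)

    def test_frameshift_deletion_at_codon_2798(self):
        tm, cv = synthetic_cubn_like_transcript()
        call = annotate(tm, cv)
        assert call.hgvs_c == "c.8392delC"
        assert call.hgvs_p == "p.Q2798Rfs*3"
        assert call.effect == "frameshift"
        assert call.mut_orf_codons == 2799

    def test_missense_at_codon_3072(self):
        tm = build_synthetic_transcript(3620, {3072: "AGC"}, "CUBN-SYNTH-2",
                                        "CUBN", seed=9215)
        call = annotate(tm, CodingVariant("CUBN-SYNTH-2", 9215, "G", "C"))
        assert call.hgvs_p == "p.S3072T"
        assert call.effect == "missense"
        assert call.mut_orf_codons == call.wt_orf_codons

    def test_identity_variant_is_synonymous_noop(self):
        tm, _ = synthetic_mrc1_like_transcript()
        call = annotate(tm, CodingVariant(tm.transcript_id, 10, tm.cds[9], tm.cds[9]))
        assert call.effect == "synonymous"
        assert call.wt_orf_codons == call.mut_orf_codons

    def test_ref_mismatch_rejected(self):
        tm, _ = synthetic_mrc1_like_transcript()
        wrong = "A" if tm.cds[99] != "A" else "C"
        with pytest.raises(DomainError, match="does not match"):
            annotate(tm, CodingVariant(tm.transcript_id, 100, wrong, "G"))

    def test_position_beyond_stop_rejected(self):
        tm = build_synthetic_transcript(10, seed=1)
        with pytest.raises(DomainError):
            annotate(tm, CodingVariant(tm.transcript_id, 34, "A", "G"))


class TestTruncationSummary:
    def test_frameshift_loses_821_codons(self):
        tm, cv = synthetic_cubn_like_transcript()
        delta, fraction = truncation_summary(annotate(tm, cv))
        assert delta == 821
        assert fraction == pytest.approx(821 / 3620)

    def test_nonsense_truncates_majority_of_protein(self):
        tm, cv = synthetic_mrc1_like_transcript()
        _, fraction = truncation_summary(annotate(tm, cv))
        assert fraction == pytest.approx((1456 - 714) / 1456)
        assert fraction > 0.5

    def test_non_truncating_call_rejected(self):
        tm, _ = synthetic_mrc1_like_transcript()
        call = annotate(tm, CodingVariant(tm.transcript_id, 10, tm.cds[9], tm.cds[9]))
        with pytest.raises(DomainError):
            truncation_summary(call)


class TestThreePrimeNormalization:
    def test_deletion_in_homopolymer_names_3prime_copy(self):
        # codons 2-3 are AAA AAG: the A-run spans c.4..c.9 minus the final G
        tm = build_synthetic_transcript(6, {2: "AAA", 3: "AAG"}, seed=4)
        cds = tm.cds
        run_start = 4
        run_end = run_start
        while cds[run_end] == "A":           # 0-based scan of the homopolymer
            run_end += 1
        for pos in range(run_start, run_end + 1):
            cv = normalize_3prime(cds, CodingVariant(tm.transcript_id, pos, "A", ""))
            assert cv.c_position == run_end  # 1-based 3'-most A of the run
            assert cv.ref == "A"

    def test_normalized_hgvs_is_position_independent(self):
        tm = build_synthetic_transcript(8, {4: "CCC", 5: "CCA"}, seed=11)
        calls = {annotate(tm, CodingVariant(tm.transcript_id, pos, "C", "")).hgvs_c
                 for pos in (10, 11, 12, 13, 14)}    # any C of the CCCCC run
        assert len(calls) == 1

    def test_snv_not_shifted(self):
        tm = build_synthetic_transcript(6, seed=2)
        cv = CodingVariant(tm.transcript_id, 5, tm.cds[4], "A" if tm.cds[4] != "A" else "G")
        assert normalize_3prime(tm.cds, cv) == cv


@st.composite
def _cds_and_indel(draw):
    n_codons = draw(st.integers(8, 40))
    codons = [draw(st.sampled_from(_SENSE)) for _ in range(n_codons)]
    cds = "ATG" + "".join(codons) + "TAA"
    kind = draw(st.sampled_from(["del1", "del2", "snv"]))
    pos = draw(st.integers(4, 3 * n_codons - 3))
    if kind == "snv":
        alt = draw(st.sampled_from("ACGT"))
        return cds, CodingVariant("tx", pos, cds[pos - 1], alt)
    width = 1 if kind == "del1" else 2
    return cds, CodingVariant("tx", pos, cds[pos - 1:pos - 1 + width], "")


class TestHgvsProteinConsistency:
    """The p. string must describe exactly what mutate-and-translate produces."""

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(_cds_and_indel())
    def test_p_string_matches_direct_translation(self, case):
        cds, cv = case
        from recessmap.iomodel import TranscriptModel
        tm = TranscriptModel("tx", cds)
        try:
            tm.validate()
        except DomainError:
            return                          # random fillers formed no valid ORF
        call = annotate(tm, cv)
        cv_norm = normalize_3prime(cds, cv)
        mut_prot = translate(apply_coding_variant(cds, cv_norm))
        wt_prot = translate(cds)
        assert call.wt_orf_codons == len(wt_prot)
        assert call.mut_orf_codons == len(mut_prot)
        fs = re.fullmatch(r"p\.([A-Z*])(\d+)([A-Z])fs\*(\d+|\?)", call.hgvs_p)
        if call.effect == "frameshift" and fs:
            pos1, new_aa = int(fs.group(2)), fs.group(3)
            assert mut_prot[:pos1 - 1] == wt_prot[:pos1 - 1]
            assert mut_prot[pos1 - 1] == new_aa
            assert wt_prot[pos1 - 1] != new_aa
            if fs.group(4) != "?":
                # stop at relative position n: internal-consistency identity
                assert call.mut_orf_codons + 1 == pos1 + int(fs.group(4)) - 1
        elif call.effect == "nonsense":
            m = re.fullmatch(r"p\.([A-Z])(\d+)\*", call.hgvs_p)
            assert m and len(mut_prot) == int(m.group(2)) - 1
        elif call.effect == "missense":
            m = re.fullmatch(r"p\.([A-Z])(\d+)([A-Z])", call.hgvs_p)
            assert m
            idx = int(m.group(2)) - 1
            assert wt_prot[idx] == m.group(1) and mut_prot[idx] == m.group(3)
        elif call.effect == "synonymous":
            assert mut_prot == wt_prot

    def test_frameshift_effect_iff_fs_pattern(self):
        # spot-check the biconditional on the two planted calls
        for builder in (synthetic_cubn_like_transcript, synthetic_mrc1_like_transcript):
            tm, cv = builder()
            call = annotate(tm, cv)
            is_fs_name = bool(re.fullmatch(r"p\.[A-Z*]\d+[A-Z]fs\*(\d+|\?)", call.hgvs_p))
            assert (call.effect == "frameshift") == is_fs_name
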