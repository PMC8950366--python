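"""MSA ingestion, position mapping, conservation and motif scanning."""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemedist import (
    MSA,
    column_conservation,
    map_position,
    read_msa,
    relaxed_motif_scan,
    scan_heme_motif,
    simulate_msa,
)
from hemedist.errors import MSAError

ALIGNED_FASTA = """>ref
MK-LV
>hom1
MKALV
>hom2
MR-LV
"""

ALIGNED_CLUSTAL = """CLUSTAL O(1.2.4) multiple sequence alignment

ref       MK-LV
hom1      MKALV
hom2      MR-LV
"""


class TestReadMSA:
    def test_aligned_fasta(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(ALIGNED_FASTA)
        msa = read_msa(p)
        assert msa.n_sequences == 3
        assert msa.length == 5
        assert msa.records[0] == ("ref", "MK-LV")

    def test_clustal_equals_fasta(self, tmp_path):
        pf, pc = tmp_path / "a.fasta", tmp_path / "a.aln"
        pf.write_text(ALIGNED_FASTA)
        pc.write_text(ALIGNED_CLUSTAL)
        assert read_msa(pf, "fasta").records == read_msa(pc, "clustal").records

    def test_ragged_alignment_names_record(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">ref\nMKLV\n>short\nMK\n")
        with pytest.raises(MSAError, match="short"):
            read_msa(p)

    def test_single_record_rejected(self, tmp_path):
        p = tmp_path / "one.fasta"
        p.write_text(">only\nMKLV\n")
        with pytest.raises(MSAError):
            read_msa(p)


class TestMapPosition:
    def _msa(self, ref_seq, others=("AAAA",)):
        records = [("ref", ref_seq)] + [
            (f"s{i}", o) for i, o in enumerate(others)
        ]
        return MSA(records=records, ref_id="ref")

    def test_gapped_reference_example(self):
        msa = self._msa("A-CD")
        assert map_position(msa, 2) == 3

    def test_gapless_reference_is_identity(self):
        msa = self._msa("ACDE")
        for pos in range(1, 5):
            assert map_position(msa, pos) == pos

    def test_beyond_reference_is_an_error(self):
        with pytest.raises(MSAError, match="beyond"):
            map_position(self._msa("A-CD"), 4)

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10**6))
    def test_matches_linear_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        chars = rng.choice(list("ACDEFG-"), size=30)
        ref = "".join(chars)
        n_res = sum(c != "-" for c in ref)
        if n_res == 0:
            return
        msa = self._msa(ref, others=["A" * 30])
        pos = int(rng.integers(1, n_res + 1))
        col = map_position(msa, pos)
        # Oracle: the returned column holds the pos-th non-gap residue.
        assert ref[col - 1] != "-"
        assert sum(c != "-" for c in ref[:col]) == pos


class TestColumnConservation:
    def test_nineteen_of_twenty(self):
        records = [("ref", "G")] + [(f"s{i}", "G") for i in range(18)] + [("sub", "A")]
        msa = MSA(records=records, ref_id="ref")
        rep = column_conservation(msa, 1)
        assert rep.conserved_fraction == pytest.approx(0.95)
        assert rep.conserved_percent == 95
        assert rep.substitution_counts == {"A": 1}

    def test_synthetic_counts_reproduce_reported_fraction(self):
        ref = "".join(np.random.default_rng(0).choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
        ref = ref[:29] + "G" + ref[30:]
        msa = simulate_msa(1635, 80, ref, 30, {"A", "S", "Y", "F", "D", "L"}, seed=4)
        rep = column_conservation(msa, map_position(msa, 30))
        assert rep.n_conserved == 1555
        assert rep.conserved_fraction == pytest.approx(1555 / 1635)
        assert rep.conserved_percent == 95
        assert set(rep.substitution_counts) <= {"A", "S", "Y", "F", "D", "L"}
        assert sum(rep.substitution_counts.values()) == 80

    def test_all_gap_column_is_an_error(self):
        msa = MSA(records=[("ref", "A-"), ("s1", "A-"), ("s2", "A-")], ref_id="ref")
        with pytest.raises(MSAError, match="gap"):
            column_conservation(msa, 2)

    def test_gap_handling_flag(self):
        records = [("ref", "G"), ("s1", "G"), ("s2", "-"), ("s3", "A")]
        msa = MSA(records=records, ref_id="ref")
        excl = column_conservation(msa, 1)
        incl = column_conservation(msa, 1, count_gaps=True)
        assert excl.conserved_fraction == pytest.approx(2 / 3)
        assert incl.conserved_fraction == pytest.approx(2 / 4)

    def test_invariant_under_record_reordering(self):
        rng = np.random.default_rng(8)
        msa = simulate_msa(40, 7, "ACDEFGHIKLMNPQRSTVWY", 5, {"W"}, seed=3)
        perm = rng.permutation(len(msa.records))
        shuffled = MSA(records=[msa.records[i] for i in perm], ref_id="REF")
        col = map_position(msa, 5)
        a = column_conservation(msa, col)
        b = column_conservation(shuffled, col)
        assert a.conserved_fraction == b.conserved_fraction
        assert a.substitution_counts == b.substitution_counts


STRICT_RE = re.compile(r"(?=(G.[HR].C[PLAV]G))")


class TestMotifScan:
    def test_canonical_motif(self):
        hits = scan_heme_motif("GRHPCLG")
        assert len(hits) == 1
        hit = hits[0]
        assert (hit.start, hit.cys_pos, hit.plus_two_pos) == (1, 5, 7)
        assert hit.span == "GRHPCLG"

    def test_no_cysteine_no_hits(self):
        assert scan_heme_motif("GRHPGLGAAAA") == []

    def test_tandem_overlapping_hits(self):
        seq = "GRHPCLGRHPCLG"
        hits = scan_heme_motif(seq)
        assert [h.start for h in hits] == [1, 7]
        assert all(h.plus_two_pos == h.start + 6 for h in hits)

    def test_matches_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(17)
        alphabet = list("GRHCPLAVSKXYWT")
        for _ in range(200):
            seq = "".join(rng.choice(alphabet, size=40))
            expected = [m.start() + 1 for m in STRICT_RE.finditer(seq)]
            assert [h.start for h in scan_heme_motif(seq)] == expected

    def test_relaxed_admits_plus_two_variants(self):
        assert scan_heme_motif("GRHPCLA") == []
        hits = relaxed_motif_scan("GRHPCLA", {"A", "S", "K"})
        assert len(hits) == 1 and hits[0].span == "GRHPCLA"

    def test_empty_allowed_set_falls_back_to_strict(self):
        assert relaxed_motif_scan("GRHPCLA", set()) == []
        assert len(relaxed_motif_scan("GRHPCLG", set())) == 1

    @settings(derandomize=True, max_examples=50)
    @given(seq=st.text(alphabet="GRHCPLAVSKYW", min_size=7, max_size=30))
    def test_strict_hits_subset_of_relaxed(self, seq):
        strict = {h.start for h in scan_heme_motif(seq)}
        relaxed = {h.start for h in relaxed_motif_scan(seq, {"A", "S", "K"})}
        assert strict <= relaxed

    def test_planted_plus_two_variants_counted(self):
        rng = np.random.default_rng(23)
        filler = "".join(rng.choice(list("DETQNMFYWI"), size=10))
        seq = filler + "GRHPCLS" + filler + "GAHVCVK" + filler + "GRHPCLG" + filler
        relaxed = relaxed_motif_scan(seq, {"A", "S", "K"})
        strict = scan_heme_motif(seq)
        assert len(strict) == 1 and len(relaxed) == 3


class TestSimulateMSA:
    def test_exact_substitution_counts(self):
        msa = simulate_msa(20, 1, "ACDEFGHIKLMNPQRSTVWY", 6, {"A", "S"}, seed=1)
        rep = column_conservation(msa, 6)
        assert rep.conserved_fraction == pytest.approx(0.95)

    def test_zero_substitutions_fully_conserved(self):
        msa = simulate_msa(25, 0, "ACDEFGHIKLMNPQRSTVWY", 3, {"W"}, seed=2)
        rep = column_conservation(msa, 3)
        assert rep.conserved_fraction == 1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            simulate_msa(10, 10, "ACDEFG", 2, {"W"}, seed=0)

    def test_alphabet_equal_to_reference_residue_rejected(self):
        with pytest.raises(ValueError):
            simulate_msa(10, 3, "AAAA", 2, {"A"}, seed=0)

    def test_reference_is_first_record_and_untouched(self):
        msa = simulate_msa(12, 4, "ACDEFGHIKL", 5, {"W", "Y"},
                           background_identity=0.7, seed=6)
        assert msa.records[0] == ("REF", "ACDEFGHIKL")
        assert msa.ref_id == "REF"
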