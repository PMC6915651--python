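"""Translation QC under the vertebrate mitochondrial code, identity search, mislabeling."""

import random

import pytest

from coibar.barcode import (
    best_match,
    builtin_survey_rows,
    check_coding,
    mislabeling_report,
    qc_table,
)
from coibar.seqio import SeqRecord

# vertebrate mitochondrial code: TGA = Trp, AGA/AGG/TAA/TAG = stop
MITO_STOPS = {"TAA", "TAG", "AGA", "AGG"}
NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in MITO_STOPS
]


def _record(seq, rec_id="q"):
    return SeqRecord(id=rec_id, sequence=seq)


class TestCheckCoding:
    def test_clean_frame_zero(self):
        check = check_coding(_record("ATGGCTGCT"), numt_length_threshold=0)
        assert check.best_frame == 0 and check.passed

    def test_tga_is_tryptophan_in_mito_code(self):
        # TGA would be a stop under the standard code but not in mtDNA
        check = check_coding(_record("ATGTGATTT"), numt_length_threshold=0)
        assert check.passed and check.best_frame == 0
        assert "W" in check.protein
        standard = check_coding(_record("ATGTGATTT"), genetic_code=1, numt_length_threshold=0)
        assert standard.n_internal_stops > 0 or standard.best_frame != 0

    def test_aga_is_stop_in_mito_code(self):
        # frame 0 reads ATG AGA GCT: AGA is a mitochondrial stop
        seq = "ATGAGAGCT"
        frames = {}
        for f in range(3):
            sub = seq[f : f + 3 * ((len(seq) - f) // 3)]
            frames[f] = sub
        assert frames[0][3:6] == "AGA"
        check = check_coding(_record(seq), numt_length_threshold=0)
        # best frame avoids the frame-0 stop if it can
        if check.best_frame == 0:
            assert check.has_internal_stop

    def test_short_sequence_flagged_as_numt_suspect(self):
        rng = random.Random(0)
        seq = "".join(rng.choice(NON_STOP_CODONS) for _ in range(150))  # 450 b
        check = check_coding(_record(seq))
        assert check.length_flag

    def test_sub_codon_input_is_error(self):
        with pytest.raises(ValueError):
            check_coding(_record("AT"))

    def test_codonwise_coding_sequences_always_pass(self):
        rng = random.Random(1)
        for _ in range(20):
            seq = "".join(rng.choice(NON_STOP_CODONS) for _ in range(220))
            assert check_coding(_record(seq)).passed

    def test_stop_in_every_frame_always_fails(self):
        rng = random.Random(2)
        for _ in range(20):
            codons = [rng.choice(NON_STOP_CODONS) for _ in range(220)]
            seq = list("".join(codons))
            # overwrite a mid-sequence stop into each of the three frames
            for frame, at in ((0, 90), (1, 301), (2, 512)):
                assert at % 3 == frame
                seq[at : at + 3] = "TAA"
            check = check_coding(_record("".join(seq)))
            assert not check.passed


class TestBestMatch:
    def _refs(self):
        rng = random.Random(3)
        base = "".join(rng.choice("ACGT") for _ in range(652))
        other = "".join(rng.choice("ACGT") for _ in range(652))
        return base, other

    def test_identical_is_hundred(self):
        base, other = self._refs()
        refs = [
            SeqRecord(id="refA", sequence=base, declared_species="spA"),
            SeqRecord(id="refB", sequence=other, declared_species="spB"),
        ]
        hit = best_match(_record(base), refs)
        assert hit.subject_id == "refA" and hit.identity_pct == 100.0

    def test_one_substitution_in_652(self):
        base, other = self._refs()
        query = base[:300] + ("A" if base[300] != "A" else "C") + base[301:]
        refs = [SeqRecord(id="refA", sequence=base, declared_species="spA")]
        hit = best_match(_record(query), refs)
        assert hit.identity_pct == 99.85  # 651/652, round half up to 2 dp
        assert hit.aligned_columns == 652

    def test_prefers_closer_reference(self):
        base, _ = self._refs()

        def mutate(seq, n, seed):
            rng = random.Random(seed)
            s = list(seq)
            for pos in rng.sample(range(len(s)), n):
                s[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]]
            return "".join(s)

        refs = [
            SeqRecord(id="near", sequence=mutate(base, 1, 5), declared_species="spA"),
            SeqRecord(id="far", sequence=mutate(base, 5, 6), declared_species="spB"),
        ]
        hit = best_match(_record(base), refs)
        assert hit.subject_id == "near" and hit.subject_species == "spA"

    def test_terminal_gaps_excluded_from_identity(self):
        base, _ = self._refs()
        refs = [SeqRecord(id="refA", sequence=base, declared_species="spA")]
        hit = best_match(_record(base[25:-25]), refs)  # truncated query
        assert hit.identity_pct == 100.0
        assert hit.aligned_columns == len(base) - 50

    def test_empty_reference_set_error(self):
        with pytest.raises(ValueError):
            best_match(_record("ACGT"), [])


class TestMislabelingReport:
    def test_bundled_survey_rates(self):
        rep = mislabeling_report(builtin_survey_rows())
        assert rep.groups["2018"] == (20, 3, 15.0)
        assert rep.groups["2010"] == (15, 1, 6.7)
        assert rep.groups["reference"] == (10, 0, 0.0)
        assert rep.substitutions[("Xiphias gladius", "Prionace glauca")] == 2

    def test_all_concordant(self):
        rows = [(f"s{i}", "spA", "spa ", "g") for i in range(8)]  # case/space-insensitive
        rep = mislabeling_report(rows)
        assert rep.groups["g"] == (8, 0, 0.0)
        assert not rep.substitutions

    def test_percent_recomputed_from_counts(self):
        rows = [("a", "x", "y", "g"), ("b", "x", "x", "g"), ("c", "x", "x", "g")]
        rep = mislabeling_report(rows)
        total, mism, pct = rep.groups["g"]
        assert pct == round(100 * mism / total, 1) == 33.3

    def test_empty_input_empty_report(self):
        rep = mislabeling_report([])
        assert rep.groups == {} and rep.total == 0


def test_qc_table_format():
    checks = [
        check_coding(_record("ATGGCTGCTATGGCTGCT", rec_id="ok"), numt_length_threshold=600)
    ]
    text = qc_table(checks)
    assert text.splitlines()[0].startswith("record_id\t")
    assert "ok\t0\t0\tyes\tpass-short" in text
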