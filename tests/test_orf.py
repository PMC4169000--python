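"""Six-frame ORF prediction against a brute-force position scanner."""

import numpy as np
import pytest

from dgescreen.orf import (
    STOP_CODONS,
    OrfPolicy,
    best_orf,
    reverse_complement,
    six_frame_orfs,
    translate,
    trim_to_best_orf,
)

# independent codon table for the translation oracle
_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_ORACLE_CODE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def oracle_translate(seq, offset=0):
    out = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append("X" if "N" in codon else _ORACLE_CODE[codon])
    return "".join(out)


def brute_force_orfs(seq, min_nt=3, kinds="partial"):
    """Position-by-position scan for starts/stops in every frame."""
    seq = seq.upper()
    n = len(seq)
    found = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for f in range(3):
            positions = list(range(f, n - 2, 3))
            stops = [p for p in positions if s[p : p + 3] in STOP_CODONS]
            starts = [p for p in positions if s[p : p + 3] == "ATG"]
            segments = []  # (segment_begin, orf_end, closed_by_stop)
            prev = None
            for p in stops:
                segments.append((f if prev is None else prev + 3, p + 3, True))
                prev = p
            tail_begin = f if prev is None else prev + 3
            tail_end = f + 3 * len(positions)
            segments.append((tail_begin, tail_end, False))
            for si, (begin, end, closed) in enumerate(segments):
                # 5'-open means no stop precedes the segment: only the first
                # segment of the frame qualifies; it contributes the open ORF
                # plus, when distinct, the one from its first ATG
                cands = [p for p in starts if begin <= p < (end - 3 if closed else end)]
                orf_starts = []
                if si == 0:
                    orf_starts.append(begin)
                if cands and cands[0] not in orf_starts:
                    orf_starts.append(cands[0])
                for orf_start in orf_starts:
                    if end - orf_start < 3:
                        continue
                    c5 = s[orf_start : orf_start + 3] == "ATG"
                    if end - orf_start < min_nt:
                        continue
                    if kinds == "complete" and not (c5 and closed):
                        continue
                    if strand == "+":
                        start_fwd, end_fwd = orf_start, end
                    else:
                        start_fwd, end_fwd = n - end, n - orf_start
                    pep = oracle_translate(s[orf_start:end])
                    if closed:
                        pep = pep[:-1]
                    found.append((strand, f, start_fwd, end_fwd, c5, closed, pep))
    return sorted(found)


def _as_tuples(records):
    return sorted(
        (r.strand, r.frame, r.start, r.end, r.complete5, r.complete3, r.peptide)
        for r in records
    )


class TestTranslate:
    @pytest.mark.parametrize(
        "seq, offset, pep",
        [("ATGTTTTAA", 0, "MF*"), ("NATG", 1, "M"), ("ATGA", 0, "M"), ("NNNAAA", 0, "XK")],
    )
    def test_examples(self, seq, offset, pep):
        assert translate(seq, offset) == pep

    def test_illegal_characters_rejected(self):
        with pytest.raises(ValueError):
            translate("ATGQ")
        with pytest.raises(ValueError):
            translate("")

    def test_against_codon_table_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGTN"), size=999))
        for offset in (0, 1, 2):
            assert translate(seq, offset) == oracle_translate(seq, offset)


class TestSixFrameOrfs:
    def test_single_complete_orf(self):
        recs = [r for r in six_frame_orfs("ATGAAATAA") if r.complete]
        assert len(recs) == 1
        rec = recs[0]
        assert (rec.strand, rec.frame, rec.nt_length, rec.peptide) == ("+", 0, 9, "MK")

    def test_no_start_no_stop_complete_policy_empty(self):
        assert six_frame_orfs("CCCCCC", OrfPolicy(kinds="complete")) == []

    def test_illegal_input(self):
        with pytest.raises(ValueError):
            six_frame_orfs("AC")
        with pytest.raises(ValueError):
            six_frame_orfs("ATXG")

    def test_oracle_equivalence_random_sequences(self, rng):
        for _ in range(60):
            length = int(rng.integers(30, 400))
            seq = "".join(rng.choice(list("ACGTN"), size=length, p=[0.245] * 4 + [0.02]))
            for kinds in ("partial", "complete"):
                mine = _as_tuples(six_frame_orfs(seq, OrfPolicy(kinds=kinds)))
                assert mine == brute_force_orfs(seq, kinds=kinds), seq

    def test_complete_orfs_reextract_correctly(self, rng):
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            for rec in six_frame_orfs(seq):
                sub = seq[rec.start : rec.end]
                if rec.strand == "-":
                    sub = reverse_complement(sub)
                if rec.complete5:
                    assert sub[:3] == "ATG"
                if rec.complete3:
                    assert sub[-3:] in STOP_CODONS
                assert len(sub) % 3 == 0 and len(sub) == rec.nt_length


class TestBestOrf:
    def test_single_orf_sequence(self):
        rec = best_orf("ATGAAATAA", OrfPolicy(kinds="complete"))
        assert rec.peptide == "MK"

    def test_longer_complete_orf_wins(self):
        seq = "ATG" + "GCA" * 10 + "TAA" + "ATG" + "GCA" * 2 + "TAA"
        rec = best_orf(seq, OrfPolicy(kinds="complete"))
        assert rec.nt_length == 36
        assert rec.start == 0

    def test_strand_symmetry(self, rng):
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(60, 500))))
            fwd = best_orf(seq)
            rev = best_orf(reverse_complement(seq))
            assert fwd.nt_length == rev.nt_length

    def test_length_multiset_invariant_under_revcomp(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        lengths = sorted(r.nt_length for r in six_frame_orfs(seq))
        lengths_rc = sorted(r.nt_length for r in six_frame_orfs(reverse_complement(seq)))
        assert lengths == lengths_rc

    def test_none_when_policy_admits_nothing(self):
        assert best_orf("CCCCCCCCC", OrfPolicy(kinds="complete")) is None

    def test_min_length_filter(self):
        seq = "ATGAAATAA"
        assert best_orf(seq, OrfPolicy(kinds="complete", min_nt=12)) is None


class TestTrim:
    def test_utr_removed_upstream_of_start(self):
        seq = "CCCCC" + "ATG" + "GCA" * 20 + "TAA"
        trimmed = trim_to_best_orf(seq, OrfPolicy(kinds="complete"))
        assert trimmed.startswith("ATG")
        assert len(trimmed) == len(seq) - 5

    def test_no_complete_orf_returns_input(self):
        assert trim_to_best_orf("CCCCCCCCC", OrfPolicy(kinds="complete")) == "CCCCCCCCC"
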