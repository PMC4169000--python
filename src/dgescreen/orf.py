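"""Six-reading-frame ORF prediction for assembled transcripts.

Each transcript is scanned in all six reading frames (three per strand).  A
frame's codons are split at stop codons; every inter-stop segment yields the
maximal ORF of each admissible kind:

* **complete** — first ATG of the segment through the stop codon;
* **5'-partial** — frame start through the first stop, when no stop precedes
  the segment (the coding region may begin upstream of the assembled
  sequence);
* **3'-partial** — first ATG through the trimmed frame end, when no stop
  follows (the coding region may run off the assembly); a frame with no stop
  at all also yields a doubly-open ORF spanning the whole frame.

A 5'-open segment can therefore contribute two records: the open ORF from
the frame start and, when a later ATG exists, the embedded ATG-initiated
ORF (the usual complete ORF of a transcript with a 5' UTR).

``N`` bases make a codon ambiguous: it translates to ``X`` and never counts
as a start or a stop.  Coordinates are 0-based half-open on the forward
strand regardless of ORF strand.  The "best" ORF of a transcript is the
longest one, with a deterministic tie-break chain (complete beats partial,
forward beats reverse, lower frame, smaller start).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "START_CODON",
    "STOP_CODONS",
    "OrfPolicy",
    "OrfRecord",
    "translate",
    "reverse_complement",
    "six_frame_orfs",
    "best_orf",
    "trim_to_best_orf",
]

START_CODON = "ATG"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA
_CODON_TABLE = dict(standard_dna_table.forward_table)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class OrfPolicy:
    """What counts as an ORF.

    ``kinds='complete'`` keeps only ATG..stop ORFs; ``'partial'`` (default)
    additionally admits 5'- and 3'-partial ORFs.  ``min_nt`` filters short
    predictions (0 keeps everything; a screen for plausible proteins would
    typically use 150 nt = 50 aa).
    """

    kinds: str = "partial"
    min_nt: int = 3

    def __post_init__(self):
        if self.kinds not in ("partial", "complete"):
            raise ValueError("kinds must be 'partial' or 'complete'")
        if self.min_nt < 3:
            raise ValueError("min_nt must be >= 3")


@dataclass(frozen=True)
class OrfRecord:
    """One predicted open reading frame."""

    seq_id: str
    strand: str  # '+' or '-'
    frame: int  # 0, 1, 2 on that strand
    start: int  # forward-strand, 0-based half-open
    end: int
    complete5: bool  # begins with ATG
    complete3: bool  # ends with a stop codon
    peptide: str

    @property
    def nt_length(self) -> int:
        return self.end - self.start

    @property
    def complete(self) -> bool:
        return self.complete5 and self.complete3


def _clean(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    if not s:
        raise ValueError("empty sequence")
    bad = set(s) - _ALPHABET
    if bad:
        raise ValueError(f"illegal characters in sequence: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    return _clean(seq).translate(_COMPLEMENT)[::-1]


def translate(seq: str, offset: int = 0) -> str:
    """Standard-code translation of the complete codons from ``offset``.

    Stops render as ``*``; codons containing ``N`` render as ``X``.
    """
    if offset not in (0, 1, 2):
        raise ValueError("offset must be 0, 1 or 2")
    s = _clean(seq)
    out = []
    for i in range(offset, len(s) - 2, 3):
        codon = s[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in STOP_CODONS:
            out.append("*")
        else:
            out.append(_CODON_TABLE[codon])
    return "".join(out)


def _segment_orfs(frame_seq: str):
    """Yield (start_codon_idx, end_codon_idx_exclusive, complete5, complete3)
    for the maximal ORFs of each inter-stop segment of one frame.

    Codon indices are relative to the frame; ``end`` includes the stop codon
    when present.  A 5'-open segment (no stop before it, including the
    no-stop-at-all case) yields an ORF from the frame start plus, when
    distinct, one from its first ATG; segments after a stop yield only the
    first-ATG ORF.
    """
    codons = [frame_seq[i : i + 3] for i in range(0, len(frame_seq) - 2, 3)]
    seg_start = 0
    open5 = True  # no stop seen yet before this segment
    for idx, codon in enumerate(codons + [None]):
        at_end = codon is None
        is_stop = (not at_end) and ("N" not in codon) and (codon in STOP_CODONS)
        if not (is_stop or at_end):
            continue
        # segment codons: seg_start .. idx-1, optionally closed by stop at idx
        end = idx + 1 if not at_end else idx
        starts = [seg_start] if open5 else []
        first_atg = next(
            (i for i in range(seg_start, idx) if codons[i] == START_CODON), None
        )
        if first_atg is not None and first_atg not in starts:
            starts.append(first_atg)
        for start in starts:
            if end > start:
                yield start, end, codons[start] == START_CODON, not at_end
        seg_start = idx + 1
        open5 = False


def six_frame_orfs(seq: str, policy: OrfPolicy = OrfPolicy(), seq_id: str = "") -> list[OrfRecord]:
    """All maximal ORFs of ``seq`` in the six reading frames under ``policy``."""
    fwd = _clean(seq)
    if len(fwd) < 3:
        raise ValueError("sequence shorter than one codon")
    n = len(fwd)
    records: list[OrfRecord] = []
    for strand, s in (("+", fwd), ("-", reverse_complement(fwd))):
        for frame in range(3):
            frame_seq = s[frame:]
            for c_start, c_end, c5, c3 in _segment_orfs(frame_seq):
                nt_start = frame + 3 * c_start  # on this strand
                nt_end = frame + 3 * c_end
                if strand == "+":
                    start, end = nt_start, nt_end
                else:
                    start, end = n - nt_end, n - nt_start
                nt_len = nt_end - nt_start
                if nt_len < policy.min_nt:
                    continue
                if policy.kinds == "complete" and not (c5 and c3):
                    continue
                orf_seq = s[nt_start:nt_end]
                pep = translate(orf_seq)
                if c3:
                    pep = pep[:-1]  # drop the stop
                records.append(
                    OrfRecord(
                        seq_id=seq_id,
                        strand=strand,
                        frame=frame,
                        start=start,
                        end=end,
                        complete5=c5,
                        complete3=c3,
                        peptide=pep,
                    )
                )
    return records


def _best_key(rec: OrfRecord):
    # longest first; then complete > partial, + strand > -, low frame, low start
    return (
        -rec.nt_length,
        not rec.complete,
        rec.strand != "+",
        rec.frame,
        rec.start,
    )


def best_orf(seq: str, policy: OrfPolicy = OrfPolicy(), seq_id: str = "") -> OrfRecord | None:
    """The single best ORF of a transcript, or None if the policy admits none."""
    records = six_frame_orfs(seq, policy, seq_id)
    if not records:
        return None
    return min(records, key=_best_key)


def trim_to_best_orf(seq: str, policy: OrfPolicy = OrfPolicy()) -> str:
    """Remove the 5' UTR upstream of the best complete ORF's first ATG.

    Returns the sequence from the ORF's ATG onward (on the ORF's strand); the
    input unchanged when no complete best ORF exists.
    """
    rec = best_orf(seq, policy)
    if rec is None or not rec.complete5:
        return seq
    s = _clean(seq)
    if rec.strand == "+":
        return s[rec.start :]
    return reverse_complement(s)[len(s) - rec.end :]
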