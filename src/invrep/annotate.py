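"""Hit annotation: mismatch/gap decomposition and dot-bracket structures.

The detectors count a single *total* mismatch number per window: every
non-complementary pair contributes 2 nucleotides and the unpaired centre of
an odd window contributes 1.  For reporting, that total is split into a
central *spacer* (the loop of a hairpin) and *stem mismatches*: walking
outward from the centre, the maximal run of consecutive non-pairing pairs
— plus the centre base itself when the length is odd — is the spacer
(``gap_count`` nucleotides); every non-pairing pair beyond the first
pairing pair is a stem mismatch (``mismatch_stem`` nucleotides).  The two
always sum to the total.

Records are rendered in a combined dot-bracket/FASTA format::

    >start|length|mismatch_stem|gap_count
    AACAACTTTCTT
    ((.((..)).))

with 1-based, closed genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import FormatError
from .seqmap import DnaSequence, bases_pair

__all__ = [
    "InvertedRepeat",
    "decompose",
    "dot_bracket",
    "annotate_hit",
    "format_record",
    "parse_record",
]


@dataclass(frozen=True)
class InvertedRepeat:
    """A reported inverted repeat on one sequence record.

    ``start`` is 1-based; the hit covers ``start .. start + length - 1``
    inclusive.  ``mismatch_total = mismatch_stem + gap_count`` counts
    nucleotides (a failed pair contributes 2).  ``structure`` is the
    dot-bracket string of length ``length``.
    """

    sequence_id: str
    start: int
    length: int
    mismatch_total: int
    mismatch_stem: int
    gap_count: int
    sequence: str
    structure: str

    @property
    def end(self) -> int:
        """1-based inclusive end coordinate."""
        return self.start + self.length - 1

    @property
    def perfect(self) -> bool:
        return self.mismatch_total == 0


def _pair_ok_flags(window: str) -> list[bool]:
    """Pairing flags for pairs (i, h-1-i), i = 0 .. h//2 - 1 (outermost first)."""
    h = len(window)
    return [bases_pair(window[i], window[h - 1 - i]) for i in range(h // 2)]


def decompose(seq: DnaSequence, start: int, length: int) -> tuple[int, int]:
    """Split a window's total mismatch count into (stem mismatches, spacer gaps).

    Both numbers are nucleotide counts.  The spacer is the maximal
    centre-anchored run of non-pairing pairs (2 nt each) plus the unpaired
    centre base of an odd window (1 nt); all other non-pairing pairs are
    stem mismatches.
    """
    flags = _pair_ok_flags(seq.window(start, length))
    total_failed = sum(1 for ok in flags if not ok)
    run = 0
    for ok in reversed(flags):  # innermost pair first
        if ok:
            break
        run += 1
    gap = 2 * run + (length % 2)
    stem = 2 * (total_failed - run)
    return stem, gap


def dot_bracket(seq: DnaSequence, start: int, length: int) -> str:
    """Dot-bracket structure: brackets for pairing pairs, dots for the rest."""
    flags = _pair_ok_flags(seq.window(start, length))
    left = "".join("(" if ok else "." for ok in flags)
    right = "".join(")" if ok else "." for ok in reversed(flags))
    centre = "." if length % 2 else ""
    return left + centre + right


def annotate_hit(seq: DnaSequence, start: int, length: int) -> InvertedRepeat:
    """Build the full report record for a hit window."""
    stem, gap = decompose(seq, start, length)
    return InvertedRepeat(
        sequence_id=seq.id,
        start=start,
        length=length,
        mismatch_total=stem + gap,
        mismatch_stem=stem,
        gap_count=gap,
        sequence=seq.window(start, length),
        structure=dot_bracket(seq, start, length),
    )


def format_record(ir: InvertedRepeat) -> str:
    """Three-line combined dot-bracket/FASTA record (no trailing newline)."""
    return f">{ir.start}|{ir.length}|{ir.mismatch_stem}|{ir.gap_count}\n{ir.sequence}\n{ir.structure}"


def parse_record(block: str, sequence_id: str = "") -> InvertedRepeat:
    """Inverse of :func:`format_record`."""
    lines = block.strip().splitlines()
    if len(lines) != 3 or not lines[0].startswith(">"):
        raise FormatError(f"malformed record: {block!r}")
    fields = lines[0][1:].split("|")
    if len(fields) != 4:
        raise FormatError(f"malformed record header: {lines[0]!r}")
    try:
        start, length, stem, gap = (int(f) for f in fields)
    except ValueError as exc:
        raise FormatError(f"non-numeric record header: {lines[0]!r}") from exc
    sequence, structure = lines[1], lines[2]
    if len(sequence) != length or len(structure) != length:
        raise FormatError(f"record body lengths disagree with header: {lines[0]!r}")
    return InvertedRepeat(
        sequence_id=sequence_id,
        start=start,
        length=length,
        mismatch_total=stem + gap,
        mismatch_stem=stem,
        gap_count=gap,
        sequence=sequence,
        structure=structure,
    )
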