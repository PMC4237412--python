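"""Reading sequences and writing hit reports.

FASTA input (plain or gzip, wrapped, CRLF-tolerant, multi-record) is read
through Biopython.  Hits are written in three interchangeable formats:

``dotbracket``
    The combined dot-bracket/FASTA record format: a ``>start|length|
    mismatch|gap`` header, the window sequence, and the structure string.
    Records from different input records are grouped under a
    ``# sequence: <id>`` section line.
``tsv``
    One row per hit with explicit 1-based closed coordinates.
``bed``
    BED6 with 0-based half-open intervals and name ``length|mismatch|gap``.
"""

from __future__ import annotations

import gzip
import io
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .annotate import InvertedRepeat, format_record, parse_record
from .errors import FormatError
from .seqmap import DnaSequence

__all__ = ["read_fasta", "write_hits", "parse_hits", "hits_to_table", "TABLE_COLUMNS"]

TABLE_COLUMNS = [
    "sequence_id",
    "start",
    "end",
    "length",
    "mismatch_stem",
    "gap_count",
    "mismatch_total",
    "sequence",
    "structure",
]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, *, mask_lowercase: bool = False) -> list[DnaSequence]:
    """Read a (possibly gzipped) FASTA file into a list of sequences.

    Residues are uppercased, whitespace/gap characters removed and U
    converted to T; record order is preserved.  Raises
    :class:`~invrep.errors.FormatError` for empty or malformed files,
    reporting the offending line number.
    """
    with _open_text(path) as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith((">", ";")):
            raise FormatError(f"{path}: line {lineno}: expected a '>' header before sequence data")
        break
    else:
        raise FormatError(f"{path}: empty FASTA file")
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has no sequence")
        out.append(DnaSequence.from_raw(rec.id, str(rec.seq), mask_lowercase=mask_lowercase))
    return out


def hits_to_table(hits: Iterable[InvertedRepeat]) -> pd.DataFrame:
    """Hits as a DataFrame with 1-based closed coordinates, one row per hit."""
    rows = [
        (h.sequence_id, h.start, h.end, h.length, h.mismatch_stem, h.gap_count,
         h.mismatch_total, h.sequence, h.structure)
        for h in hits
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_hits(hits: Iterable[InvertedRepeat], fmt: str, path: str | Path) -> None:
    """Write hits to `path` in one of 'dotbracket', 'tsv' or 'bed'."""
    hits = list(hits)
    if fmt == "dotbracket":
        blocks = []
        current_id = None
        for h in hits:
            if h.sequence_id != current_id:
                current_id = h.sequence_id
                blocks.append(f"# sequence: {current_id}")
            blocks.append(format_record(h))
        Path(path).write_text("\n".join(blocks) + ("\n" if blocks else ""))
    elif fmt == "tsv":
        hits_to_table(hits).to_csv(path, sep="\t", index=False)
    elif fmt == "bed":
        lines = [
            f"{h.sequence_id}\t{h.start - 1}\t{h.end}\t"
            f"{h.length}|{h.mismatch_stem}|{h.gap_count}\t{h.mismatch_total}\t+"
            for h in hits
        ]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise FormatError(f"unknown output format {fmt!r}")


def parse_hits(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a file written by :func:`write_hits` back into a hit table.

    The format is inferred from the content when `fmt` is None.  BED input
    yields the coordinate and count columns only (sequence and structure
    are not stored in BED).
    """
    text = Path(path).read_text()
    if fmt is None:
        fmt = _sniff_format(text)
    if fmt == "dotbracket":
        return _parse_dotbracket(text)
    if fmt == "tsv":
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype={"sequence_id": str})
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: tsv report missing columns {missing}")
        return df[TABLE_COLUMNS]
    if fmt == "bed":
        return _parse_bed(text)
    raise FormatError(f"unknown report format {fmt!r}")


def _sniff_format(text: str) -> str:
    head = text.lstrip().splitlines()[0] if text.strip() else ""
    if head.startswith(("#", ">")):
        return "dotbracket"
    if head.startswith("sequence_id\t") or head == "sequence_id":
        return "tsv"
    return "bed"


def _parse_dotbracket(text: str) -> pd.DataFrame:
    hits: list[InvertedRepeat] = []
    current_id = ""
    lines = [l for l in text.splitlines() if l.strip()]
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("# sequence:"):
            current_id = line.split(":", 1)[1].strip()
            i += 1
            continue
        if not line.startswith(">"):
            raise FormatError(f"unexpected line in dotbracket report: {line!r}")
        if i + 2 >= len(lines):
            raise FormatError(f"truncated record at {line!r}")
        hits.append(parse_record("\n".join(lines[i : i + 3]), sequence_id=current_id))
        i += 3
    return hits_to_table(hits)


def _parse_bed(text: str) -> pd.DataFrame:
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise FormatError(f"line {lineno}: BED6 record needs 6 fields")
        chrom, start0, end = fields[0], int(fields[1]), int(fields[2])
        length, stem, gap = (int(x) for x in fields[3].split("|"))
        if end - start0 != length:
            raise FormatError(f"line {lineno}: interval span disagrees with name field")
        rows.append((chrom, start0 + 1, end, length, stem, gap, stem + gap))
    return pd.DataFrame(
        rows,
        columns=["sequence_id", "start", "end", "length", "mismatch_stem",
                 "gap_count", "mismatch_total"],
    )
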