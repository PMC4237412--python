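"""Complex-number encoding of DNA sequences.

The detectors in this package never compare strings.  Each base is mapped
to a complex score

    A -> +1      T -> -1      C -> +j      G -> -j

so that a base and its reverse complement always sum to zero.  The score of
a window (the sum of its base scores) is therefore 0 for every perfect
palindrome, and more generally ``|Re| + |Im|`` of the window score is a
lower bound on the window's mismatch count: a complementary pair contributes
0, a non-complementary pair at most 2 (and always exactly 2 to the true
count), and the unpaired centre of an odd window at most 1.  Window scores
for *every* start position of a given length come from one vectorised
difference of the cumulative-score vector, which is what makes genome-scale
scans cheap.

Ambiguity codes (N and the other IUPAC letters) are scored 0 and flagged
invalid; windows containing them are rejected by the detectors so that runs
of N can never masquerade as self-pairing sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "DnaSequence",
    "ComplexMapping",
    "ScoreVectors",
    "map_bases",
    "cumulative_score",
    "window_scores",
    "reverse_complement",
    "bases_pair",
    "COMPLEMENT",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_RC_TABLE = str.maketrans("ACGT", "TGCA")

# Integer base codes used internally: A=0, C=1, G=2, T=3, anything else 4.
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

# Complex score per base code; invalid bases score 0.
_SCORE_BY_CODE = np.array([1.0, 1.0j, -1.0j, -1.0, 0.0], dtype=np.complex128)

# PAIR_OK[a, b] is True iff codes a and b are reverse-complementary.
PAIR_OK = np.zeros((5, 5), dtype=bool)
PAIR_OK[0, 3] = PAIR_OK[3, 0] = True  # A/T
PAIR_OK[1, 2] = PAIR_OK[2, 1] = True  # C/G


def bases_pair(a: str, b: str) -> bool:
    """True iff single bases `a` and `b` are reverse-complementary (A/T or C/G)."""
    return COMPLEMENT.get(a) == b


def reverse_complement(s: str) -> str:
    """Reverse complement of an ACGT string (other letters pass through unchanged)."""
    return s.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class DnaSequence:
    """A named DNA sequence with 1-based, closed coordinates.

    ``residues`` is uppercase and free of whitespace and gap characters;
    use :meth:`from_raw` to ingest arbitrary text (soft-masked genomes,
    RNA with U, line-wrapped records).
    """

    id: str
    residues: str

    @classmethod
    def from_raw(cls, id: str, raw: str, *, mask_lowercase: bool = False) -> "DnaSequence":
        """Build a sequence from raw text.

        Whitespace and ``-``/``.`` gap characters are removed, ``U`` becomes
        ``T``, and the result is uppercased.  With ``mask_lowercase=True``
        soft-masked (lowercase) bases are converted to ``N`` instead, so
        they can never participate in a reported repeat.
        """
        cleaned = "".join(raw.split()).replace("-", "").replace(".", "")
        if mask_lowercase:
            cleaned = "".join("N" if c.islower() else c for c in cleaned)
        cleaned = cleaned.upper().replace("U", "T")
        if not cleaned:
            raise InvalidParameterError(f"sequence {id!r} is empty after ingest")
        return cls(id=id, residues=cleaned)

    def __len__(self) -> int:
        return len(self.residues)

    def window(self, start: int, length: int) -> str:
        """The subsequence of `length` bases starting at 1-based `start`."""
        if start < 1 or start + length - 1 > len(self):
            raise InvalidParameterError(
                f"window {start}..{start + length - 1} outside sequence of length {len(self)}"
            )
        return self.residues[start - 1 : start - 1 + length]


@dataclass
class ComplexMapping:
    """Per-base complex scores plus a validity mask.

    ``valid[i]`` is True iff residue i is one of A, C, G, T.  Invalid
    positions carry score 0 so they never perturb window sums, but any
    window covering one is rejected at the candidate stage.
    """

    scores: np.ndarray  # complex128, length N
    valid: np.ndarray  # bool, length N
    codes: np.ndarray = field(repr=False, default=None)  # int8 base codes, internal


@dataclass
class ScoreVectors:
    """Cumulative window-scoring vectors derived from a :class:`ComplexMapping`.

    ``cumulative[k]`` is the sum of the first k base scores (``cumulative[0]``
    is 0), so the score of the length-h window starting at 1-based position i
    is ``cumulative[i + h - 1] - cumulative[i - 1]``.  ``invalid_cumulative``
    counts non-ACGT bases the same way and lets the detectors reject windows
    containing any of them in O(1).
    """

    cumulative: np.ndarray  # complex128, length N+1
    invalid_cumulative: np.ndarray  # int64, length N+1
    window_length: int | None = None
    window_scores: np.ndarray | None = None


def map_bases(seq: DnaSequence) -> ComplexMapping:
    """Map a sequence to its complex score vector (A:+1, T:-1, C:+j, G:-j)."""
    if len(seq) == 0:
        raise InvalidParameterError("cannot map an empty sequence")
    codes = _CODE[np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)]
    return ComplexMapping(scores=_SCORE_BY_CODE[codes], valid=codes < 4, codes=codes)


def cumulative_score(mapping: ComplexMapping) -> ScoreVectors:
    """Running sums of the score vector and of the invalid-base indicator."""
    n = len(mapping.scores)
    cum = np.empty(n + 1, dtype=np.complex128)
    cum[0] = 0
    np.cumsum(mapping.scores, out=cum[1:])
    bad = np.empty(n + 1, dtype=np.int64)
    bad[0] = 0
    np.cumsum(~mapping.valid, out=bad[1:])
    return ScoreVectors(cumulative=cum, invalid_cumulative=bad)


def window_scores(vectors: ScoreVectors, h: int) -> np.ndarray:
    """Scores of all length-`h` windows; entry i is the 1-based start i+1 window.

    Raises
    ------
    InvalidParameterError
        If ``h`` is not in ``[1, N]``.
    """
    n = len(vectors.cumulative) - 1
    if not 1 <= h <= n:
        raise InvalidParameterError(f"window length {h} outside [1, {n}]")
    out = vectors.cumulative[h:] - vectors.cumulative[:-h]
    vectors.window_length = h
    vectors.window_scores = out
    return out


def window_invalid_counts(vectors: ScoreVectors, h: int) -> np.ndarray:
    """Number of non-ACGT bases in each length-`h` window."""
    n = len(vectors.invalid_cumulative) - 1
    if not 1 <= h <= n:
        raise InvalidParameterError(f"window length {h} outside [1, {n}]")
    return vectors.invalid_cumulative[h:] - vectors.invalid_cumulative[:-h]


def encode_codes(seq: DnaSequence) -> np.ndarray:
    """Integer base codes (A=0, C=1, G=2, T=3, other=4) for internal pairing tests."""
    return _CODE[np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)]
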