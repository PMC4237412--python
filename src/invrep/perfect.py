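"""Perfect inverted repeat (palindrome) detection.

A perfect inverted repeat of even length h is a window whose first half is
the reverse complement of its second half.  Every such window of length
h > 4 contains a perfect inverted repeat of length h-2 sharing its centre,
so the scan proceeds bottom-up: find all validated palindromes of the
minimum length l by a vectorised zero-score test followed by explicit
pairing validation, then repeatedly extend each survivor one base at both
ends, keeping exactly the extensions whose new terminal bases pair.  The
interior is never re-examined after the first validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import seqmap
from .annotate import InvertedRepeat, annotate_hit
from .errors import InvalidParameterError
from .seqmap import DnaSequence, PAIR_OK

__all__ = [
    "SearchParams",
    "perfect_candidates",
    "validate_perfect",
    "extend_perfect",
    "detect_perfect",
    "filter_maximal",
]


@dataclass(frozen=True)
class SearchParams:
    """Search window bounds and mismatch allowance.

    min_length/max_length bound the reported repeat length inclusively.
    In perfect mode both must be even (palindromes have even length) and
    max_mismatch is ignored; in imperfect mode max_mismatch must be >= 1,
    because a reported imperfect repeat has at least one mismatch by
    definition.  ``maximal_only`` suppresses hits wholly nested, with the
    same centre, inside a longer reported hit.
    """

    min_length: int = 10
    max_length: int = 1000
    max_mismatch: int = 6
    mode: str = "perfect"
    maximal_only: bool = False

    def validate(self, n: int) -> "SearchParams":
        """Check constraints against a sequence of length `n`; returns self.

        ``max_length`` larger than the sequence is allowed and simply capped
        by ``n`` during the scan; everything else raises.
        """
        l, L = self.min_length, self.max_length
        if self.mode not in ("perfect", "imperfect"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if l < 2:
            raise InvalidParameterError(f"min_length must be >= 2, got {l}")
        if l > L:
            raise InvalidParameterError(f"min_length {l} exceeds max_length {L}")
        if l > n:
            raise InvalidParameterError(f"min_length {l} exceeds sequence length {n}")
        if self.mode == "perfect" and (l % 2 or L % 2):
            raise InvalidParameterError(
                f"perfect mode requires even min/max lengths, got {l}/{L}"
            )
        if self.mode == "imperfect" and self.max_mismatch < 1:
            raise InvalidParameterError(
                "imperfect mode requires max_mismatch >= 1: a window with zero "
                "mismatches is a perfect palindrome and is never reported here"
            )
        return self


def perfect_candidates(
    window_scores: np.ndarray, valid_counts: np.ndarray, h: int
) -> np.ndarray:
    """1-based starts of length-`h` windows with score exactly 0 and no invalid base.

    A zero score is necessary but not sufficient for a palindrome (e.g.
    'TACG' scores 0), so candidates still require :func:`validate_perfect`.
    `valid_counts` is the per-window invalid-base count from
    :func:`seqmap.window_invalid_counts`.
    """
    mask = (window_scores == 0) & (valid_counts == 0)
    return np.flatnonzero(mask).astype(np.int64) + 1


def validate_perfect(seq: DnaSequence, starts: np.ndarray, h: int) -> np.ndarray:
    """Keep the 1-based `starts` whose length-`h` window fully self-pairs."""
    starts = np.asarray(starts, dtype=np.int64)
    if starts.size == 0:
        return starts
    codes = seqmap.encode_codes(seq)
    s0 = starts - 1
    keep = np.ones(starts.shape, dtype=bool)
    for k in range(h // 2):
        keep &= PAIR_OK[codes[s0 + k], codes[s0 + h - 1 - k]]
    return starts[keep]


def extend_perfect(seq: DnaSequence, starts_at_h: np.ndarray, h: int) -> np.ndarray:
    """Extend validated length-`h` palindromes to length h+2.

    Returns the 1-based starts s-1 of the extensions whose two new terminal
    bases are reverse-complementary; hits flush against either sequence end
    are dropped (they cannot be extended).
    """
    starts = np.asarray(starts_at_h, dtype=np.int64)
    if starts.size == 0:
        return starts
    n = len(seq)
    codes = seqmap.encode_codes(seq)
    inside = (starts > 1) & (starts + h - 1 < n)
    starts = starts[inside]
    if starts.size == 0:
        return starts
    s0 = starts - 1
    keep = PAIR_OK[codes[s0 - 1], codes[s0 + h]]
    return starts[keep] - 1


def detect_perfect(seq: DnaSequence, params: SearchParams | None = None) -> list[InvertedRepeat]:
    """All perfect inverted repeats of even length in [min_length, max_length].

    Nested palindromes sharing a centre are reported at every qualifying
    length unless ``params.maximal_only``.  Output is sorted by start, then
    by descending length.
    """
    params = (params or SearchParams(mode="perfect")).validate(len(seq))
    if params.mode != "perfect":
        raise InvalidParameterError("detect_perfect requires mode='perfect'")
    n = len(seq)
    l = params.min_length
    cap = min(params.max_length, n)
    cap -= cap % 2

    mapping = seqmap.map_bases(seq)
    vectors = seqmap.cumulative_score(mapping)
    codes = seqmap.encode_codes(seq)

    hits: list[tuple[int, int]] = []
    h = l
    scores = seqmap.window_scores(vectors, h)
    bad = seqmap.window_invalid_counts(vectors, h)
    starts = validate_perfect(seq, perfect_candidates(scores, bad, h), h)
    hits.extend((int(s), h) for s in starts)
    while h + 2 <= cap and starts.size:
        starts = _extend_codes(codes, starts, h, n)
        h += 2
        hits.extend((int(s), h) for s in starts)

    if params.maximal_only:
        hits = filter_maximal(hits)
    hits.sort(key=lambda sh: (sh[0], -sh[1]))
    return [annotate_hit(seq, s, h) for s, h in hits]


def _extend_codes(codes: np.ndarray, starts: np.ndarray, h: int, n: int) -> np.ndarray:
    # extend_perfect without re-encoding the sequence each round
    inside = (starts > 1) & (starts + h - 1 < n)
    starts = starts[inside]
    if starts.size == 0:
        return starts
    s0 = starts - 1
    keep = PAIR_OK[codes[s0 - 1], codes[s0 + h]]
    return starts[keep] - 1


def filter_maximal(hits: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Drop (start, length) hits nested in a reported (start-1, length+2) hit."""
    present = set(hits)
    return [(s, h) for s, h in hits if (s - 1, h + 2) not in present]
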