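"""Imperfect inverted repeat (quasipalindrome) detection.

An imperfect inverted repeat is a window whose two halves pair except for
up to ``m`` mismatch nucleotides: each non-complementary pair contributes 2
to the count and the unpaired centre of an odd-length window contributes 1
(so odd lengths have odd totals and even lengths even totals).  A reported
hit must additionally have reverse-complementary terminal bases and at
least one mismatch — windows with zero mismatches are perfect palindromes
and belong to :mod:`invrep.perfect`.

The scan mirrors the perfect detector but keeps a *carry set* per length:
every all-valid window whose score bound ``|Re| + |Im|`` does not exceed
``m`` has its exact mismatch count computed once; windows with count <= m
are carried to the next round regardless of their terminal bases (a longer
hit may well have a non-pairing pair just inside its ends).  Extension by
one base per end updates the count incrementally: +0 if the new ends pair,
+2 otherwise; carries whose count exceeds m, or that run off the sequence
or onto an ambiguous base, are dropped.  Because one pass only ever visits
lengths of one parity, the search runs twice, seeded at min_length and
min_length + 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from . import seqmap
from .annotate import InvertedRepeat, annotate_hit
from .errors import InvalidParameterError
from .perfect import SearchParams, filter_maximal
from .seqmap import DnaSequence, PAIR_OK, bases_pair

__all__ = [
    "CandidateCarry",
    "CarrySet",
    "mismatch_count",
    "imperfect_candidates",
    "classify_candidates",
    "extend_imperfect",
    "detect_imperfect",
]


@dataclass(frozen=True)
class CandidateCarry:
    """One carried window: 1-based start, current length, exact mismatch count."""

    start: int
    length: int
    mismatches: int


@dataclass
class CarrySet:
    """A batch of carried windows of one length, stored as flat arrays."""

    starts: np.ndarray  # int64, 1-based
    mismatches: np.ndarray  # int64
    length: int

    def __len__(self) -> int:
        return int(self.starts.size)

    def __iter__(self) -> Iterator[CandidateCarry]:
        for s, a in zip(self.starts, self.mismatches):
            yield CandidateCarry(int(s), self.length, int(a))


def mismatch_count(seq: DnaSequence, start: int, length: int) -> int:
    """Total mismatch nucleotides of one window.

    Each non-complementary pair (i, length+1-i) contributes 2; for odd
    lengths the unpaired centre contributes 1.  Perfect palindromes score 0.
    """
    window = seq.window(start, length)
    failed = sum(
        1
        for i in range(length // 2)
        if not bases_pair(window[i], window[length - 1 - i])
    )
    return 2 * failed + (length % 2)


def imperfect_candidates(
    window_scores: np.ndarray, valid_counts: np.ndarray, h: int, m: int
) -> np.ndarray:
    """1-based starts of all-valid windows with score bound |Re|+|Im| <= m.

    The bound never exceeds the true mismatch count, so no window with
    count <= m is lost here; the exact count is computed afterwards.
    """
    bound = np.abs(window_scores.real) + np.abs(window_scores.imag)
    return np.flatnonzero((bound <= m) & (valid_counts == 0)).astype(np.int64) + 1


def _exact_counts(codes: np.ndarray, starts: np.ndarray, h: int) -> np.ndarray:
    s0 = starts - 1
    failed = np.zeros(starts.shape, dtype=np.int64)
    for k in range(h // 2):
        failed += ~PAIR_OK[codes[s0 + k], codes[s0 + h - 1 - k]]
    return 2 * failed + (h % 2)


def _terminal_pairs(codes: np.ndarray, starts: np.ndarray, h: int) -> np.ndarray:
    s0 = starts - 1
    return PAIR_OK[codes[s0], codes[s0 + h - 1]]


def classify_candidates(
    seq: DnaSequence, candidates: np.ndarray, h: int, m: int
) -> tuple[list[CandidateCarry], CarrySet]:
    """Split score-bound candidates into reported hits and the carry set.

    A candidate is *reported* when its exact mismatch count is in [1, m]
    and its terminal bases pair; it is *carried* (kept for extension)
    whenever its count is <= m, terminal pairing and zero counts included.
    """
    candidates = np.asarray(candidates, dtype=np.int64)
    codes = seqmap.encode_codes(seq)
    alpha = _exact_counts(codes, candidates, h)
    keep = alpha <= m
    carry = CarrySet(starts=candidates[keep], mismatches=alpha[keep], length=h)
    reported_mask = keep & (alpha >= 1) & _terminal_pairs(codes, candidates, h)
    reported = [
        CandidateCarry(int(s), h, int(a))
        for s, a in zip(candidates[reported_mask], alpha[reported_mask])
    ]
    return reported, carry


def extend_imperfect(
    seq: DnaSequence, carry: CarrySet, m: int
) -> tuple[list[CandidateCarry], CarrySet]:
    """Grow every carried window one base at each end, to length + 2.

    The mismatch count is unchanged when the two new terminal bases pair
    and increases by 2 otherwise.  Windows flush against a sequence end are
    not extendable and are dropped, as are extensions onto an ambiguous
    base or past the mismatch budget.  Returns (reported hits at the new
    length, carry set at the new length).
    """
    n = len(seq)
    codes = seqmap.encode_codes(seq)
    return _extend_arrays(codes, n, carry, m)


def _extend_arrays(
    codes: np.ndarray, n: int, carry: CarrySet, m: int
) -> tuple[list[CandidateCarry], CarrySet]:
    h = carry.length + 2
    inside = (carry.starts > 1) & (carry.starts + carry.length - 1 < n)
    starts = carry.starts[inside] - 1
    alpha = carry.mismatches[inside].copy()
    if starts.size:
        s0 = starts - 1
        left, right = codes[s0], codes[s0 + h - 1]
        ends_valid = (left < 4) & (right < 4)
        starts, alpha = starts[ends_valid], alpha[ends_valid]
        ends_pair = PAIR_OK[codes[starts - 1], codes[starts - 1 + h - 1]]
        alpha = alpha + 2 * (~ends_pair)
        keep = alpha <= m
        starts, alpha, ends_pair = starts[keep], alpha[keep], ends_pair[keep]
    else:
        ends_pair = np.zeros(0, dtype=bool)
    new_carry = CarrySet(starts=starts, mismatches=alpha, length=h)
    reported_mask = ends_pair & (alpha >= 1)
    reported = [
        CandidateCarry(int(s), h, int(a))
        for s, a in zip(starts[reported_mask], alpha[reported_mask])
    ]
    return reported, new_carry


def detect_imperfect(
    seq: DnaSequence, params: SearchParams | None = None
) -> list[InvertedRepeat]:
    """All imperfect inverted repeats with 1 <= mismatch total <= max_mismatch.

    Two passes, seeded at min_length and min_length + 1, cover both length
    parities up to max_length (capped by the sequence length).  Output is
    sorted by start, then by descending length.
    """
    params = (params or SearchParams(min_length=20, mode="imperfect")).validate(len(seq))
    if params.mode != "imperfect":
        raise InvalidParameterError("detect_imperfect requires mode='imperfect'")
    n = len(seq)
    m = params.max_mismatch
    cap = min(params.max_length, n)

    mapping = seqmap.map_bases(seq)
    vectors = seqmap.cumulative_score(mapping)
    codes = mapping.codes

    found: list[tuple[int, int]] = []
    for seed in (params.min_length, params.min_length + 1):
        if seed > cap:
            continue
        scores = seqmap.window_scores(vectors, seed)
        bad = seqmap.window_invalid_counts(vectors, seed)
        candidates = imperfect_candidates(scores, bad, seed, m)
        reported, carry = classify_candidates(seq, candidates, seed, m)
        found.extend((r.start, r.length) for r in reported)
        h = seed
        while h + 2 <= cap and len(carry):
            reported, carry = _extend_arrays(codes, n, carry, m)
            h += 2
            found.extend((r.start, r.length) for r in reported)

    if params.maximal_only:
        found = filter_maximal(found)
    found.sort(key=lambda sh: (sh[0], -sh[1]))
    return [annotate_hit(seq, s, h) for s, h in found]
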