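"""Brute-force reference detectors and synthetic sequence generation.

The reference detectors here check every window of every length by direct
base pairing — no complex scores, no cumulative sums, no extension — so
exact agreement with the vectorised detectors is meaningful evidence, not
a tautology.  The generators produce uniform-random backgrounds at a
chosen GC content and splice in inverted repeats with controlled stem
length, spacer length and stem-mismatch count, returning the ground-truth
annotation for the planted window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotate import InvertedRepeat, annotate_hit
from .errors import InvalidParameterError
from .seqmap import COMPLEMENT, DnaSequence, reverse_complement

__all__ = [
    "brute_force_perfect",
    "brute_force_imperfect",
    "random_sequence",
    "PlantSpec",
    "plant_ir",
]

_BASES = "ACGT"

# Byte-indexed lookups local to the oracle (independent of seqmap's tables).
_IDX = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _IDX[ord(_b)] = _i
_IS_PAIR = np.zeros((5, 5), dtype=bool)
for _a, _b in (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")):
    _IS_PAIR[_IDX[ord(_a)], _IDX[ord(_b)]] = True


def brute_force_perfect(seq: DnaSequence, l: int, L: int) -> set[tuple[int, int]]:
    """All (1-based start, even length) windows equal to their own reverse complement.

    Every window of every even length in [l, L] is compared against its
    reverse complement as a string; windows containing non-ACGT letters
    never qualify (their reverse complement differs at those letters only
    if... they simply cannot pair, so they are excluded explicitly).
    """
    s = seq.residues
    n = len(s)
    hits: set[tuple[int, int]] = set()
    lo = l + (l % 2)
    for h in range(lo, min(L, n) + 1, 2):
        for i in range(n - h + 1):
            w = s[i : i + h]
            if any(c not in _BASES for c in w):
                continue
            if w == reverse_complement(w):
                hits.add((i + 1, h))
    return hits


def brute_force_imperfect(
    seq: DnaSequence, l: int, L: int, m: int
) -> set[tuple[int, int, int]]:
    """All (start, length, mismatch total) windows with 1 <= total <= m and pairing ends.

    Direct per-length evaluation: for each window every pair (i, h+1-i) is
    tested for reverse complementarity, failures count 2 nucleotides each
    and an odd centre counts 1.  Windows with ambiguous bases are excluded.
    """
    if m < 1:
        raise InvalidParameterError("imperfect search needs m >= 1")
    codes = _IDX[np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)]
    n = codes.size
    ok = codes < 4
    bad_cum = np.concatenate(([0], np.cumsum(~ok)))
    hits: set[tuple[int, int, int]] = set()
    for h in range(l, min(L, n) + 1):
        nwin = n - h + 1
        failed = np.zeros(nwin, dtype=np.int64)
        for k in range(h // 2):
            failed += ~_IS_PAIR[codes[k : k + nwin], codes[h - 1 - k : h - 1 - k + nwin]]
        total = 2 * failed + (h % 2)
        clean = (bad_cum[h:] - bad_cum[:-h]) == 0
        ends = _IS_PAIR[codes[:nwin], codes[h - 1 : h - 1 + nwin]]
        keep = clean & ends & (total >= 1) & (total <= m)
        for i in np.flatnonzero(keep):
            hits.add((int(i) + 1, h, int(total[i])))
    return hits


def random_sequence(
    n: int, gc_fraction: float = 0.5, seed: int | np.random.Generator = 0, id: str = "random"
) -> DnaSequence:
    """Uniform-random DNA of length `n` with expected GC content `gc_fraction`."""
    if n < 1:
        raise InvalidParameterError("sequence length must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise InvalidParameterError("gc_fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    draws = rng.choice(4, size=n, p=[at, gc, gc, at])
    residues = "".join(_BASES[i] for i in draws)
    return DnaSequence(id=id, residues=residues)


@dataclass(frozen=True)
class PlantSpec:
    """Blueprint of an inverted repeat to splice into a background sequence.

    ``stem_length`` counts pairs per arm, ``spacer_length`` nucleotides in
    the central non-pairing loop, ``stem_mismatches`` non-complementary
    stem pairs.  The planted window has total length
    ``2 * stem_length + spacer_length`` and mismatch total
    ``2 * stem_mismatches + spacer_length``.  ``insert_position`` is the
    1-based coordinate where the window overwrites the background.
    """

    stem_length: int
    spacer_length: int = 0
    stem_mismatches: int = 0
    insert_position: int = 1

    @property
    def window_length(self) -> int:
        return 2 * self.stem_length + self.spacer_length

    @property
    def mismatch_total(self) -> int:
        return 2 * self.stem_mismatches + self.spacer_length


def plant_ir(
    seq: DnaSequence, spec: PlantSpec, seed: int | np.random.Generator = 0
) -> tuple[DnaSequence, InvertedRepeat]:
    """Overwrite part of `seq` with a constructed inverted repeat.

    Returns the modified sequence and the ground-truth annotation of the
    planted window.  The outermost and innermost stem pairs always pair
    (so the hit is reportable and its spacer decomposition is exactly the
    planted spacer), mismatch pairs are drawn from the interior stem
    positions, and spacer bases are chosen to be non-complementary across
    the centre.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stem, spacer, mm = spec.stem_length, spec.spacer_length, spec.stem_mismatches
    if stem < 1:
        raise InvalidParameterError("stem_length must be >= 1")
    if mm < 0 or spacer < 0:
        raise InvalidParameterError("spacer_length and stem_mismatches must be >= 0")
    reserved = 2 if stem >= 2 else 1  # outermost pair, plus innermost when distinct
    if mm > stem - reserved:
        raise InvalidParameterError(
            f"{mm} stem mismatches do not fit in a stem of {stem} pairs "
            "(the outermost and innermost pairs must pair)"
        )
    end = spec.insert_position + spec.window_length - 1
    if spec.insert_position < 1 or end > len(seq):
        raise InvalidParameterError(
            f"planted window {spec.insert_position}..{end} exceeds sequence of length {len(seq)}"
        )

    left = [_BASES[i] for i in rng.choice(4, size=stem)]
    right = [COMPLEMENT[b] for b in reversed(left)]
    # stem pair k pairs left[k] with right[stem-1-k]; pair 0 is outermost
    mismatch_pairs = rng.choice(np.arange(1, stem - 1), size=mm, replace=False) if mm else []
    for k in mismatch_pairs:
        good = COMPLEMENT[left[k]]
        right[stem - 1 - k] = rng.choice([b for b in _BASES if b != good])
    loop = []
    for i in range(spacer // 2):
        a = _BASES[rng.choice(4)]
        loop.append(a)
    # mirror half chosen so that pair (i, spacer-1-i) never pairs
    mirror = [rng.choice([b for b in _BASES if b != COMPLEMENT[a]]) for a in reversed(loop)]
    centre = [_BASES[rng.choice(4)]] if spacer % 2 else []
    window = "".join(left + loop + centre + mirror + right)
    assert len(window) == spec.window_length

    res = seq.residues
    pos0 = spec.insert_position - 1
    planted = DnaSequence(
        id=seq.id, residues=res[:pos0] + window + res[pos0 + len(window):]
    )
    truth = annotate_hit(planted, spec.insert_position, spec.window_length)
    return planted, truth
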