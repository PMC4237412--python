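"""Imperfect inverted repeat detection: counting, candidacy, extension, full scan."""

import numpy as np
import pytest

from invrep import DnaSequence, InvalidParameterError, SearchParams, brute_force_imperfect, detect_imperfect, detect_perfect, mismatch_count, random_sequence
from invrep.imperfect import classify_candidates, extend_imperfect, imperfect_candidates
from invrep.seqmap import cumulative_score, map_bases, window_invalid_counts, window_scores


def _candidates(text: str, h: int, m: int) -> list[int]:
    seq = DnaSequence("x", text)
    v = cumulative_score(map_bases(seq))
    return imperfect_candidates(window_scores(v, h), window_invalid_counts(v, h), h, m).tolist()


class TestMismatchCount:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("AACAACTTTCTT", 4),  # two failed pairs, 2 nt each
            ("CAAAAATTTTG", 1),  # five pairing pairs plus the unpaired centre
            ("ATCAGATGCTAAAGCATATGAT", 4),  # pairs (5,18) and (11,12) fail
            ("GAATTC", 0),  # perfect palindrome
            ("AAAAATTTCT", 2),
            ("AAAATTTC", 2),
        ],
    )
    def test_examples(self, text, expected):
        seq = DnaSequence("x", text)
        assert mismatch_count(seq, 1, len(text)) == expected


class TestCandidates:
    def test_bound_keeps_window_within_budget(self):
        assert _candidates("AACAACTTTCTT", 12, 4) == [1]  # score -1+3j, bound 4

    def test_bound_rejects_window_over_budget(self):
        assert _candidates("AACAACTTTCTT", 12, 2) == []

    def test_perfect_palindrome_always_a_candidate(self):
        assert 1 in _candidates("GAATTC", 6, 1)

    def test_ambiguous_windows_excluded(self):
        assert _candidates("AANTT", 5, 6) == []


class TestClassification:
    def test_pairing_ends_reported_and_carried(self):
        seq = DnaSequence("x", "AAAAATTTCT")
        reported, carry = classify_candidates(seq, np.array([1]), 10, 6)
        assert [(r.start, r.mismatches) for r in reported] == [(1, 2)]
        assert carry.starts.tolist() == [1]

    def test_non_pairing_ends_carried_but_not_reported(self):
        seq = DnaSequence("x", "AAAATTTC")
        reported, carry = classify_candidates(seq, np.array([1]), 8, 6)
        assert reported == []
        assert carry.starts.tolist() == [1] and carry.mismatches.tolist() == [2]

    def test_perfect_palindrome_carried_but_not_reported(self):
        seq = DnaSequence("x", "GAATTC")
        reported, carry = classify_candidates(seq, np.array([1]), 6, 6)
        assert reported == []
        assert carry.mismatches.tolist() == [0]

    def test_over_budget_candidate_dropped_entirely(self):
        seq = DnaSequence("x", "AACAACTTTCTT")
        reported, carry = classify_candidates(seq, np.array([1]), 12, 2)
        assert reported == [] and len(carry) == 0


class TestExtension:
    def test_pairing_extension_keeps_count_and_reports(self):
        # AAAATTTC (count 2, A/C ends) sits at 2 inside this sequence; its
        # extension AAAAATTTCT gains pairing A/T ends and is reported with count 2
        seq = DnaSequence("x", "AAAAATTTCTGG")
        _, carry = classify_candidates(seq, np.array([2]), 8, 6)
        reported, new_carry = extend_imperfect(seq, carry, 6)
        assert [(r.start, r.length, r.mismatches) for r in reported] == [(1, 10, 2)]

    def test_non_pairing_extension_adds_two(self):
        seq = DnaSequence("x", "CCGAATTCAA")
        _, carry = classify_candidates(seq, np.array([4]), 4, 6)  # AATT, count 0
        reported, new_carry = extend_imperfect(seq, carry, 6)
        # G/C ends pair: count stays 0, not reported; next round adds C/A ends
        assert reported == [] and new_carry.mismatches.tolist() == [0]
        reported, new_carry = extend_imperfect(seq, new_carry, 6)
        assert new_carry.mismatches.tolist() == [2]
        assert [(r.start, r.length) for r in reported] == []  # C/A ends do not pair

    def test_carry_flush_against_sequence_end_dropped(self):
        seq = DnaSequence("x", "ATCGAATT")
        _, carry = classify_candidates(seq, np.array([1]), 6, 6)  # flush left
        reported, new_carry = extend_imperfect(seq, carry, 6)
        assert reported == [] and len(new_carry) == 0

    def test_extension_onto_ambiguous_base_dropped(self):
        seq = DnaSequence("x", "NAATTA")
        _, carry = classify_candidates(seq, np.array([2]), 4, 6)
        _, new_carry = extend_imperfect(seq, carry, 6)
        assert len(new_carry) == 0

    def test_over_budget_extension_dropped(self):
        seq = DnaSequence("x", "CCGAATTCAA")
        _, carry = classify_candidates(seq, np.array([4]), 4, 1)
        _, carry = extend_imperfect(seq, carry, 1)  # count 0 at length 6
        _, carry = extend_imperfect(seq, carry, 1)  # would reach count 2
        assert len(carry) == 0


class TestDetect:
    def test_worked_12mer_found_with_budget_four(self):
        seq = DnaSequence("x", "AACAACTTTCTT")
        hits = detect_imperfect(seq, SearchParams(12, 12, 4, mode="imperfect"))
        assert [(h.start, h.length, h.mismatch_total) for h in hits] == [(1, 12, 4)]

    def test_worked_12mer_missed_with_budget_three(self):
        seq = DnaSequence("x", "AACAACTTTCTT")
        assert detect_imperfect(seq, SearchParams(12, 12, 3, mode="imperfect")) == []

    def test_zero_budget_is_a_parameter_error(self, toy_seq):
        with pytest.raises(InvalidParameterError):
            detect_imperfect(toy_seq, SearchParams(4, 20, 0, mode="imperfect"))

    def test_oracle_equivalence_on_random_sequences(self, rng):
        for _ in range(30):
            n = int(rng.integers(40, 400))
            seq = random_sequence(n, float(rng.uniform(0.2, 0.8)), rng)
            l = int(rng.choice([4, 6, 10]))
            L = min(n, 50)
            m = int(rng.choice([2, 4, 6, 7]))
            got = {(h.start, h.length, h.mismatch_total)
                   for h in detect_imperfect(seq, SearchParams(l, L, m, mode="imperfect"))}
            assert got == brute_force_imperfect(seq, l, L, m)

    def test_oracle_equivalence_with_ambiguous_bases(self, rng):
        seq = random_sequence(300, 0.5, rng)
        res = list(seq.residues)
        for p in rng.integers(0, 300, size=8):
            res[p] = "N"
        seq = DnaSequence("n", "".join(res))
        got = {(h.start, h.length, h.mismatch_total)
               for h in detect_imperfect(seq, SearchParams(6, 40, 4, mode="imperfect"))}
        assert got == brute_force_imperfect(seq, 6, 40, 4)


class TestProperties:
    def test_parity_law_and_count_consistency(self, rng):
        seq = random_sequence(1200, 0.5, rng)
        hits = detect_imperfect(seq, SearchParams(6, 60, 7, mode="imperfect"))
        assert hits, "a 1.2 kb random sequence should contain quasipalindromes"
        odd = even = 0
        for h in hits:
            assert h.mismatch_total % 2 == h.length % 2  # odd centre forces odd totals
            assert h.mismatch_total == mismatch_count(seq, h.start, h.length)
            assert 1 <= h.mismatch_total <= 7
            odd += h.length % 2
            even += 1 - h.length % 2
        assert odd and even  # an odd budget admits both parities

    def test_disjoint_from_perfect_detector(self, rng):
        seq = random_sequence(600, 0.5, rng)
        perfect = {(h.start, h.length)
                   for h in detect_perfect(seq, SearchParams(4, 60, mode="perfect"))}
        imperfect = {(h.start, h.length)
                     for h in detect_imperfect(seq, SearchParams(4, 60, 6, mode="imperfect"))}
        assert perfect
        assert not perfect & imperfect
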