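# Methods

## Problem and model

An inverted repeat (IR) is a DNA segment whose first half is approximately
the reverse complement of its second half. Perfect IRs (palindromes, always
even length) pair completely; imperfect IRs (quasipalindromes) tolerate
non-complementary stem pairs and a central non-palindromic spacer, and are
the substrate for cruciform extrusion in duplex DNA and hairpin formation in
single strands. `invrep` scans arbitrary FASTA input for both classes.

The *mismatch number* of a window of length *h* starting at *i* is a
nucleotide count: every non-complementary pair (i+k, i+h−1−k) contributes 2,
and for odd *h* the unpaired centre always contributes 1 (an odd window
necessarily has a spacer). Consequently even-length windows have even
totals and odd-length windows odd totals — the parity law the test suite
asserts. A reported imperfect IR must have total in [1, m] and
reverse-complementary terminal bases; total 0 is by definition a perfect IR
and is reported only by the perfect detector, so the two outputs are
disjoint by construction.

## Complex scoring and the candidate bound

Each base maps to a complex score — A: +1, T: −1, C: +j, G: −j — so a base
and its reverse complement cancel exactly. With the cumulative vector
V (V[0] = 0, V[k] = Σ score), the score of every length-h window is one
vectorised difference C[i] = V[i+h−1] − V[i−1]. Two facts drive the scan:

* a perfect palindrome's window score is exactly 0 (each pair cancels), and
* |Re(C)| + |Im(C)| ≤ mismatch number: a complementary pair contributes 0 to
  both sides; a non-complementary pair contributes at most 2 to the bound
  and exactly 2 to the count; an odd centre contributes at most 1 to each.

Neither condition is sufficient (e.g. TACG scores 0 without pairing), so
score filtering only prunes; exact pairing or exact counting always follows.
All arithmetic is on sums of {0, ±1, ±j} in complex doubles, which is exact
far beyond genome scale, so the zero test and the integer bound involve no
floating-point tolerance.

## Scan structure

**Perfect.** Every palindrome of length h > 4 contains a palindrome of
length h−2 with the same centre. The scan therefore validates the zero-score
candidates at the minimum length l by explicit half-against-half pairing,
then repeatedly extends each survivor one base per end, keeping exactly the
extensions whose two new terminal bases pair — interior bases are never
re-examined. Iteration stops at the maximum length L (capped by the
sequence length; there is no other cap on L).

**Imperfect.** The same bottom-up structure with a *carry set* per length:
all-valid windows passing the score bound get their exact mismatch count
computed once; every window with count ≤ m is carried — including perfect
cores and windows whose ends do not pair, since a longer repeat may enclose
either — while only windows with count in [1, m] and pairing ends are
reported. Extension updates the count incrementally (+0 if the new ends
pair, else +2) and drops carries that exceed the budget, run off the
sequence, or land on an ambiguous base. One pass visits a single length
parity, so the search runs twice, seeded at l and l+1, covering every
length in [l, L].

Windows flush against either sequence end are never extended (they have no
flanking bases), but are still reported at their current length if they
qualify.

## Mismatch/spacer decomposition and output

Reports split the total into `gap_count` (the spacer) and `mismatch_stem`:
walking outward from the centre, the maximal run of consecutive non-pairing
pairs — plus the centre base itself for odd lengths — is the spacer; any
non-pairing pair beyond the first pairing pair is a stem mismatch. The two
always sum to the total, and the dot-bracket string marks exactly the
mismatch nucleotides with dots. This centre-anchored rule is the natural
reading of the three hairpin cases (mismatch only, mismatch + spacer,
spacer only) and reproduces the published example decompositions
(AACAACTTTCTT → 2 stem + 2 spacer nucleotides); it is re-derived for every
hit from the sequence, never carried through the scan.

Records are written as `>start|length|mismatch_stem|gap_count`, window
sequence, structure — plus TSV (1-based closed coordinates) and BED6
(0-based half-open) for interoperability.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `min_length` (l) | shortest reported IR, nt | 10 perfect / 20 imperfect | even required in perfect mode |
| `max_length` (L) | longest reported IR, nt | 1000 | capped by sequence length, otherwise unlimited |
| `max_mismatch` (m) | mismatch-nucleotide budget | 6 | imperfect mode only; must be ≥ 1 |
| `maximal_only` | drop same-centre nested hits | off | default reports every qualifying length |
| `mask_lowercase` | treat soft-masked bases as ambiguous | off | lowercase is otherwise uppercased |

Defaults are the standard genome-survey settings for each mode. Nested
same-centre hits are reported at every qualifying length by default because
the per-length enumeration is the detector's native output; `maximal_only`
exposes the deduplicated view.

## Ambiguity handling

N and all other IUPAC ambiguity letters score 0 and are flagged invalid. A
window containing any invalid position is rejected at the candidate stage
and a carry extending onto one is dropped, so runs of N can never be
reported as self-pairing — a documented false-positive mode of older
string-based scanners. U is accepted and treated as T; `-`/`.` gap
characters and whitespace are stripped at ingest.

## Synthetic data and validation design

`simulate.random_sequence` draws i.i.d. bases at a target GC fraction —
deliberately the simplest null model, matching how detection tools are
exercised on random sequence. `simulate.plant_ir` splices in an IR with
controlled stem length, spacer length and stem-mismatch count; the
outermost and innermost stem pairs always pair and spacer bases are chosen
non-complementary across the centre, so the planted window has exactly the
intended mismatch total (2·mismatches + spacer) and decomposition.

Uniform backgrounds contain no repeat families, GC isochores, masked runs
or chromosome-scale length structure, so passing tests demonstrate
algorithmic correctness (exact agreement with an exhaustive reference), not
biological realism of hit densities.

The reference implementations in the same module share nothing with the
detectors — no complex mapping, no prefix sums, no extension; every window
of every length is checked by direct base pairing. The master validation
property is exact hit-set equality between detector and reference over a
seeded campaign of 102 random sequences (mostly 60–600 nt with L ≤ 80, six
at 2 kb with L = 120) crossing l ∈ {4, 10, 20} with m ∈ {2, 4, 6, 7},
plus sequences salted with N. These sizes keep the exhaustive reference
cheap while still exercising kilobase inputs and deep extension chains;
the vectorised detectors themselves run at chromosome scale.

## Numerical and determinism choices

* Coordinates are 1-based and closed everywhere except BED output.
* Output ordering is start ascending, then length descending; all ties are
  resolved by this total order, so identical inputs give byte-identical
  reports.
* All randomness flows through `numpy.random.Generator` seeds.
* Memory is dominated by the complex cumulative vector (16 bytes/base plus
  the carry sets), linear in sequence length.

## Known limitations

* No indels within the pairing stem: a bulged hairpin is reported, if at
  all, as a shifted window with extra mismatches.
* No G·U wobble or other non-Watson-Crick pairing; no thermodynamic
  scoring — hits are combinatorial, not free-energy-ranked.
* Hit lists grow quadratically in dense tandem-palindromic regions when
  every nested length is reported; use `maximal_only` to deduplicate.
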