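# invrep

Genome-scale detection of perfect and imperfect DNA inverted repeats.

Inverted repeats — segments whose first half is (approximately) the reverse
complement of their second half — can extrude cruciforms in duplex DNA and
fold into hairpins in single strands, structures involved in replication
stalling, recombination hotspots, transcription-factor binding and
transposon boundaries. `invrep` scans FASTA input of any size for both
**perfect** inverted repeats (palindromes, fully paired, even length) and
**imperfect** ones (quasipalindromes with up to *m* mismatch nucleotides in
the stem and/or a central spacer), and reports each hit with coordinates, a
mismatch/spacer decomposition and a dot-bracket structure string. It is
aimed at anyone doing genome-wide surveys of cruciform/hairpin-forming
motifs.

## The algorithm

String comparison is replaced by vector arithmetic. Each base maps to a
complex score

    A → +1    T → −1    C → +j    G → −j

so reverse-complementary bases cancel exactly. With the cumulative vector
*V* of these scores, the score of every window of length *h* is obtained in
one vectorised pass, *C(i) = V(i+h−1) − V(i−1)*. A perfect palindrome has
*C = 0*, and for any window

    |Re C| + |Im C|  ≤  mismatch number

where the mismatch number counts 2 nucleotides per non-complementary pair
(i+k, i+h−1−k) plus 1 for the unpaired centre of an odd window. Zero-score
(resp. within-bound) windows at the minimum length are validated by exact
pairing (resp. exact counting), then grown one base per end and re-checked
only at their new termini, up to the maximum length. A reported imperfect
repeat has mismatch number in [1, m] and reverse-complementary terminal
bases; windows containing N or other ambiguity codes are never reported.

## Worked example

The 20-mer `ATCGAACGAATTCGTTAACC` maps to the score vector
`[1, −1, j, −j, 1, 1, j, −j, 1, 1, −1, −1, j, −j, −1, −1, 1, 1, j, j]`.
Scanning it for palindromes of length 4–20:

```sh
$ printf '>toy\nATCGAACGAATTCGTTAACC\n' > toy.fa
$ invrep detect -i toy.fa -o toy.out --mode perfect -l 4 -L 20
INFO toy: 20 nt, 8 hit(s) [mode=perfect l=4 L=20 m=6]
INFO wrote 8 hit(s) to toy.out
```

`toy.out` holds eight records in the combined dot-bracket/FASTA format,
including the nested family of lengths 4–12 that share one centre —
each header is `>start|length|mismatch|gap` with 1-based coordinates:

```
>5|12|0|0
AACGAATTCGTT
(((((())))))
>6|10|0|0
ACGAATTCGT
((((()))))
>7|8|0|0
CGAATTCG
(((())))
```

Imperfect mode reports quasipalindromes with their mismatch decomposition.
The 12-mer `AACAACTTTCTT` carries 4 mismatch nucleotides — one failed stem
pair (2 nt) and a 2 nt central spacer — and is found as soon as the budget
allows it:

```sh
$ invrep detect -i ex.fa -o ex.out --mode imperfect -l 12 -L 12 -m 4
$ cat ex.out
# sequence: ex
>3|12|2|2
AACAACTTTCTT
((.((..)).))
```

Dots mark the four mismatch nucleotides; brackets mark the four pairing
pairs. Output is also available as TSV (`-f tsv`) or BED6 (`-f bed`), and
the same functionality is exposed as a library:

```python
from invrep import DnaSequence, SearchParams, detect_imperfect, mismatch_count

seq = DnaSequence.from_raw("ex", "AACAACTTTCTT")
mismatch_count(seq, 1, 12)           # 4
detect_imperfect(seq, SearchParams(12, 12, 4, mode="imperfect"))
```

Two further subcommands support validation work: `invrep synth` generates
random sequence with inverted repeats planted at controlled stem length,
spacer length and mismatch count (plus a ground-truth table), and
`invrep oracle` runs an exhaustive brute-force scan for cross-checking the
fast detector on small inputs.

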