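# rapdscan

Selecting RAPD primers at the bench is expensive guesswork: a random
decamer either happens to prime at two nearby genomic sites and gives a
band, or it does not. `rapdscan` moves that screen in silico. Given a
list of short arbitrary primers and a set of target nucleotide
sequences (ESTs, contigs, any plain FASTA), it locates every
mismatch-tolerant priming site on both strands, predicts which primers
would yield PCR products of amplifiable size, shortlists them, and
converts qualifying amplicons into locus-specific **iSCAR**
(in-silico Sequence Characterized Amplified Region) primer pairs ready
for synthesis. It is aimed at molecular-marker developers working on
species with limited sequence resources.

## Method

- **Priming sites.** A primer *p* of length *k* primes a target *T* at
  position *s* (1-based) when the Hamming distance
  d(p, T[s..s+k−1]) ≤ m, with the mismatch ceiling m ∈ {0,…,3}
  (default 3, the tolerance of short-arbitrary-primer annealing).
  Both the given primer and its reverse complement are searched, so
  each site carries an orientation (`given`/`complement`) and its
  mismatch count. `N` in a target always counts as a mismatch.
- **Amplicons.** Two sites of the same primer in one sequence with
  non-overlapping footprints delimit a potential product of size
  `right.end − left.start + 1` (both primer footprints included). A
  product is amplifiable when it falls inside the inclusive window
  [200, 2000] bp. Primers with at least one in-window product are
  shortlisted; a primer priming only once in a sequence cannot give a
  band from it.
- **iSCAR design.** Each in-window amplicon yields a primer pair by
  extending both priming-site footprints 10 template bases into the
  amplicon: forward = the left footprint plus its right flank, reverse
  = the reverse complement of the right footprint plus its left flank
  (decamer sites become 20-mers). Extensions are read from the
  template, not the arbitrary primer, so the designed pair matches its
  locus exactly; every pair is verified by exact in-silico PCR against
  its source sequence.
- **QC and reports.** Primers are flagged (advisory, never excluded)
  on the classic criteria — GC content ≥ 40% and absence of a
  reverse-complement palindrome — and each run emits base composition,
  per-(primer, sequence) site frequencies, optional per-library
  tallies, and a JSON manifest of configuration, input digests and row
  counts.

## Worked example

Generate a small synthetic target set with planted priming sites, then
scan it:

```sh
printf 'OPR-11\tGTAGCCGTCT\nOPY-20\tAGCCGTGGAA\n' > primers.tsv
rapdscan fixtures --primers primers.tsv --n-sequences 4 --length 1500 \
    --seed 42 --out-dir fixture
rapdscan scan --primers primers.tsv --targets fixture/targets.fasta \
    --out-dir out
```

```
INFO wrote fixture/targets.fasta and fixture/truth_sites.tsv (8 planted sites)
INFO scan complete: 84 sites, 440 amplicons, 2 shortlisted primers, 334 iSCAR pairs
```

The fixture plants one convergent site pair per sequence at a 510 bp
product size; at the default ceiling of 3 mismatches the scan also
picks up 3-mismatch background windows, which is why 8 planted sites
grow to 84 reported ones — each row records its own mismatch count so
stricter views need no rescan:

```
$ head -3 out/sites.tsv
primer_name	sequence_id	start	end	orientation	mismatches
OPR-11	SYN_0001	101	110	given	0
OPR-11	SYN_0001	245	254	given	3
```

Both primers end up shortlisted, with their tightest in-window product
listed as evidence:

```
$ cat out/shortlist.tsv
primer_name	n_in_window_pairs	best_sequence_id	best_product_size
OPR-11	162	SYN_0001	202
OPY-20	172	SYN_0002	203
```

and each qualifying amplicon becomes a 20-mer iSCAR pair with its
expected product size:

```
$ head -2 out/iscar.tsv
primer_name	sequence_id	forward_primer	reverse_primer	expected_product
OPR-11	SYN_0001	AGACGGCTACGGTTCGGCAA	AGACGGAAAGCTGGGACTCA	550
```

`out/primer_qc.tsv` shows both primers passing the GC/palindrome
screen (60% GC, not self-complementary). Rerunning either command with
the same inputs and seed reproduces every file byte for byte.

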