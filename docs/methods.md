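# Methods

## Model

`rapdscan` treats RAPD priming as approximate string matching: a primer
*p* (length *k*, alphabet A/C/G/T) primes target *T* at 1-based
position *s* when the Hamming distance between *p* and the window
`T[s..s+k−1]` is at most a ceiling *m*. Substitutions only — the model
has no insertions or deletions, matching the physics of a short
annealing oligo — and no thermodynamics: every tolerated window counts
equally, regardless of where the mismatches fall (a 3'-terminal
mismatch, which real polymerases penalize heavily, is not treated
specially). Both the primer and its reverse complement are scanned, so
annealing to either strand is represented; orientation is recorded per
site rather than in separate files (a `--split-orientation` CLI flag
restores a two-file layout).

An amplicon is any ordered pair of same-primer sites in one sequence
with non-overlapping footprints; its size spans both footprints,
`right.end − left.start + 1`. The amplifiable window is inclusive on
both boundaries. SCAR primers are the two footprints extended into the
amplicon by `extension` template bases, the right one
reverse-complemented; extensions are copied from the template rather
than the (possibly mismatched) arbitrary primer, because a SCAR primer
is only useful if it matches its locus exactly.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `max_mismatches` | 3 | bases | upper end of the tolerance a decamer shows in practice; sites store their own mismatch count so stricter views are a filter, not a rescan |
| `min_product` | 200 | bp | shorter products are hard to separate from primer artefacts on a gel |
| `max_product` | 2000 | bp | longer templates amplify poorly under standard RAPD cycling |
| `extension` | 10 | bases | turns a decamer site into a 20-mer, the conventional SCAR primer length |
| `pairing_mode` | `paper` | — | see below |

`pairing_mode="paper"` pairs all sites of a primer within a sequence
regardless of orientation; `"convergent"` keeps only
(given-left, complement-right) pairs — the only geometry an actual PCR
amplifies exponentially. The permissive mode is the default because
the orientation-agnostic pairing is the more complete contract (the
convergent subset is recoverable by filtering; the converse is not),
but `"convergent"` is the right choice when the output feeds primer
synthesis directly. All eligible pairs are enumerated, not only
adjacent ones, for the same recoverability reason.

## Algorithmic choices

- The scan is an exhaustive sliding-window comparison, vectorised over
  windows with numpy (`sliding_window_view` + per-window mismatch
  sums). No index or seed-and-extend structure: targets are short
  (EST-scale) and exhaustiveness is the contract. The test suite holds
  the scanner to exact agreement with an independent, deliberately
  naive per-window Python loop.
- `N` in a target is a forced mismatch at that position. Input letters
  outside A/C/G/T/N are collapsed to N at load time (counted and
  logged); primers must be unambiguous A/C/G/T.
- Coordinates are 0-based half-open internally (numpy indexing) and
  1-based inclusive in every emitted file and public type.
- "Palindrome" in primer QC means reverse-complement palindrome — the
  self-annealing-prone property — not literal string reversal, which is
  meaningless for an oligo. QC is advisory: failing primers are
  scanned and flagged, never dropped, since the GC/palindrome criteria
  belong to primer purchase, not to the search.
- Overlapping and self-overlapping sites are all reported; site pairs
  whose footprints overlap are excluded from amplicon prediction. A
  palindromic primer yields coincident sites under both orientations
  and both records are kept, so downstream pairing semantics stay
  uniform.
- SCAR design skips (with a logged warning) any pair whose extension
  would cross the opposite footprint's outer edge or run off the
  sequence, and any pair whose footprint contains N — emitting a
  degenerate primer would be worse than emitting none. Identical
  (sequence, forward, reverse) pairs are deduplicated. In-silico PCR
  verification requires exact matches of both footprints in the
  correct order and returns the smallest product when several
  placements exist, mirroring PCR's bias toward short templates.
- Reports are tab-separated with fixed column orders and fixed sort
  keys (primer name, sequence id, start, …), so identical inputs
  serialize to identical bytes. The run manifest echoes the
  configuration, SHA-256 digests of the inputs and per-report row
  counts; it deliberately carries no wall-clock timestamp so that two
  identical runs produce identical manifests.
- Library tallies append one `total` row per primer; `total` and
  `unassigned` are reserved library labels.

## Synthetic data

The fixture generator produces i.i.d. per-base backgrounds at a
configurable GC fraction and plants primer footprints (the primer or
its reverse complement, carrying an exact number of substitutions at
distinct positions) at requested coordinates and orientations.
Generation is fully deterministic in the seed. Ground truth lists only
the planted sites; the background can legitimately contain additional
tolerated windows, so tests compare scans to truth with "exact on
planted, superset allowed on background" semantics.

What this emulates: the positional/orientational/mismatch structure
the scanner must resolve. What it does not: real transcript data —
no repeat families, no expression-level redundancy, no UTR structure,
no sequencing error model, no compositional heterogeneity. Passing
tests therefore demonstrate algorithmic correctness, not biological
performance; on real EST collections the background hit density and
the multiplicity of per-primer sites will differ.

Default study sizes were chosen to exercise the pipeline well inside a
desk-scale run: the oracle comparison uses 100 random sequences of
1–2 kb against 20 random decamers at all four mismatch ceilings;
recall uses 200 planted sites across both orientations and loads 0–3;
the SCAR round trip covers ≥100 amplicons; the end-to-end tally runs
120 sequences of 2 kb. These complete in seconds.

## Limitations

- No thermodynamic model (melting temperature, 3'-end stability,
  dimers/hairpins): a reported site is a sequence-similarity statement
  only, and designed SCAR pairs are not Tm-matched.
- Hamming matching cannot represent indel-containing priming events.
- `paper` pairing mode can predict products a real PCR cannot make
  (e.g. two same-orientation sites); use `convergent` when that
  matters.
- Whether a site count should pool mismatch levels 0–3 or fix one
  level is a reporting choice; the default pools (ceiling 3) and the
  per-site mismatch column supports re-filtering.
- The multi-site threshold (2 sites) is fixed, not configurable, to
  keep the shortlist semantics unambiguous.
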