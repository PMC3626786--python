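# Methods

## Model and procedure

`duplexscan` treats secondary-structure space, not primary sequence, as the
object of the search: instead of looking for inverted repeats, it folds many
overlapping sub-sequences and asks which duplex elements recur across the
predicted structures. The working assumption is that a duplex appearing in a
large fraction of the folded windows that could contain it — regardless of
what else flanks it — is more likely to be a real, locally determined folding
unit than a duplex appearing in a single whole-molecule fold.

The pipeline is: sequence pool → window plan → per-window folding (pluggable
backend) → pair-table parsing → helix enumeration → criterion filtering →
global mapping and deduplication → region assignment and frequency tables.

### Coordinates

All positions are 1-based and intervals closed, matching the CT file
convention; window offsets are 0-based internally and converted at the
reporting boundary. The folding-potential profile indexes windows by their
1-based start position.

### Window plan

For transcript length *L*, window *W* and step *S*, the plan holds
⌊(*L*−*W*)/*S*⌋ windows at offsets 0, *S*, 2*S*, … when *L* > *W*. This
convention leaves up to *S*−1 trailing nucleotides of the transcript outside
every window; `trailing_window=True` (CLI `--trailing-window`) appends one
extra window ending exactly at position *L* for users who want full 3′
coverage. Degenerate cases are resolved in favour of never silently skipping
a transcript: *L* ≤ *W* gives a single whole-sequence window, and
*W* < *L* < *W*+*S* gives one window at offset 0 rather than an empty plan.

### Backends

A backend maps `(window sequence, k, transcript id, offset)` to up to *k*
ranked structures with optional free energies. The transcript id and offset
are part of the contract because two of the shipped backends are lookups
(precomputed `<transcript>__<offset>.ct` / `.db` directories) and the fixture
backend is keyed by transcript; live engines ignore them. A failed fold of
one window is logged and skipped — a long batch must survive sporadic engine
errors — while a missing backend aborts before any fold. Pair tables may
contain crossing (pseudoknotted) pairs; only the dot-bracket *writer* is
limited to nested structures, since a single bracket family cannot express
crossings.

The ViennaRNA adapter returns the MFE structure for *k* = 1; for *k* > 1 it
enumerates suboptimal structures within a growing energy band above the MFE
(doubling from 1 kcal/mol, capped at 3 kcal/mol) and keeps the *k* lowest.
The cap bounds memory on strongly folding windows, so fewer than *k*
structures may be returned; energy ties are broken by structure string so the
ranking is deterministic.

## Selection criteria

Defaults (all thresholds are ≥ comparisons and CLI-configurable):

| parameter            | default | unit | meaning |
|----------------------|---------|------|---------|
| `min_len_bp`         | 8       | bp   | minimal uninterrupted duplex length |
| `min_strand_distance`| 40      | nt   | nucleotides strictly between the innermost pair |
| `min_linker_paired`  | 16      | nt   | paired nucleotides inside that linker |
| window / step / k    | 800 / 20 / 10 | nt / nt / structures | fold batch geometry |
| profile window       | 60      | nt   | folding-potential window, step 1 |

Interpretation choices a reader should know:

* **Linker pairing counts nucleotides, not base pairs.** The operational
  definition attached to every reported motif is "≥ 16 nt in the linker
  involved in base pairing"; a paired linker position counts whether its
  partner lies inside or outside the linker. Users preferring the stricter
  16-*bp* reading can pass `--min-linker-paired 32`.
* **Composition runs are literal.** A GC-helix is an *uninterrupted* run of
  G·C pairs: a single A·U (or wobble G·U) pair splits the run into two
  sub-runs, each tested separately. A sub-run's strand distance and linker
  statistics are computed from its *own* innermost pair, since the sub-run is
  the reported motif with its own strand coordinates.
* **GC-stems.** `hairpin_mode` inverts the distance test (< 40 nt) to count
  classical GC-rich stem-loops. The linker-pairing test is dropped in this
  mode: its purpose is to demand structure where a hairpin has its loop, which
  would contradict the very thing being counted.
* **Non-canonical pairs** other than G·U are treated as corrupt structure
  input and rejected with coordinates, not silently dropped — energy-based
  folders do not emit them, so their presence signals a damaged file.

## Aggregation

Motif identity is exact: (class, 5′-strand interval, 3′-strand interval) in
transcript coordinates. Near-duplicate variants from suboptimal structures
are kept distinct by default because exactness is auditable;
`--collapse-contained` optionally drops motifs whose both strands lie within
a longer same-class motif's strands. Support is the number of distinct
structures containing the motif; the eligible denominator counts structures
whose window spans both strands, and `support_fraction` = support/eligible is
reported as a separate column from the per-100-nt frequency (they normalise
different things). A motif straddling a region boundary is labelled by its
5′-most nucleotide, which keeps per-region counts summing to the
whole-transcript count. Distance from the start codon is
`strand5_start − (utr5_len + 1)`: 0 at the A of AUG, negative upstream.
Summaries use the arithmetic mean and sample (n−1) standard deviation;
single-member groups report SD 0 with a `single_member` flag.

The analysis partition (5′-region = 5′-UTR + 200 nt of CDS, capped at the
CDS end for short CDSs so the three intervals always partition the
transcript) is deliberately distinct from the annotation partition
(5′-UTR/CDS/3′-UTR) used by the shuffler.

## Synthetic data

The fixture generator plants one exactly reverse-complementary duplex of a
requested length, class, and strand distance into a background drawn from
{A, C} — an alphabet that admits no canonical or wobble pair, so the
background contributes no structure. The requested linker pairing is realised
by a small internal hairpin of alternating G·C/A·U pairs (alternation keeps
the hairpin from forming a uniform composition run of its own); an odd count
adds one linker position paired to a site downstream of the 3′ strand.
Defaults (length 9 bp, distance 100 nt, 20 paired linker nt, GC class,
1000-nt background) mirror the geometry at which the selection thresholds are
comfortably cleared, with boundary fixtures at 39/40 nt and 15/16 nt probing
the exact threshold semantics.

The deterministic fixture backend "folds" a window by returning each planted
helical element — duplex, linker hairpin, singleton pair — whose pairs all
fall inside the window, and nothing else, at −2 kcal/mol per pair (an
arbitrary fixed convention so profiles are computable). Elements are included
all-or-none: a window that clips one edge pair of a planted duplex omits the
whole element rather than reporting a truncated variant, so planted truth is
recovered exactly. What fixtures do **not** emulate is folding energetics:
passing tests show the scanning, filtering, mapping, deduplication and
reporting machinery is correct, not that any particular folding engine will
predict a given duplex in real sequence.

Shuffled controls permute nucleotides independently within the annotated
5′-UTR, CDS and 3′-UTR, conserving each region's mononucleotide counts
exactly (the generator's stated conservation level; dinucleotide shuffling
would be a possible extension, not the default). Replicate streams derive
from one master seed via `SeedSequence([seed, transcript_index, replicate])`.
Shuffling breaks the phase relationship between complementary strands, so a
planted 9-bp duplex survives a shuffle only with vanishing probability —
the suite measures ≥ 95 destroyed in 100 seeded shuffles.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: window-arithmetic checks
at 3500/9000 nt with a counting backend, scanner-vs-oracle equivalence on
500 random pair tables of up to 200 nt, planted-recovery grids on 1000–1200-nt
fixtures, 20-transcript pools for the region-enrichment pattern, and
100-replicate shuffle experiments — sizes chosen so the full pipeline
logic, including the published window counts (135 and 410), is exercised
end-to-end in seconds. Frequencies per 100 nt are exact rationals scaled by
100 and compared without tolerance except where floating-point summaries
(means, SDs) warrant `pytest.approx`. Report TSVs are written with fixed
column order and a stable mergesort, making reruns byte-identical.

## Known limitations

* Published absolute motif frequencies for real mRNA libraries depend on the
  curated sequence set and the specific folding engine and are not
  reproduced here; the package reproduces the method, its arithmetic, and
  its qualitative behaviour on controlled inputs.
* Whether linker pairing should be restricted to partners *within* the
  linker is an open interpretation; the implementation counts any paired
  linker position and exposes the threshold as a parameter.
* Strict stacking is enforced: a composition run never spans a bulge, even a
  one-nucleotide one.
* The dot-bracket writer cannot express pseudoknots (use CT for those); no
  statistical test for region enrichment is provided — the report is
  descriptive, as the frequencies themselves are the quantity of interest.
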