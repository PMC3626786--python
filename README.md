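# duplexscan

Sliding-window scan for **long-range, non-hairpin duplex elements** — notably
GC-rich helices — in mRNA secondary structure.

Perfect double helices in RNA are usually parts of hairpins: the two strands
sit a loop apart. But consecutive Watson–Crick pairing can also form between
*distant* segments of one long transcript, and such long-range duplexes (for
example in the 5′-region of Argonaute-family mRNAs) are candidate
cis-regulatory elements. `duplexscan` finds them: it cuts a transcript into
overlapping windows, folds each window with a pluggable secondary-structure
backend, scans every predicted structure for maximal stacked helices, and
keeps those that are *not* hairpins.

## Method

For a transcript of length *L*, windows of size *W* (default 800 nt, intended
range 500–1200) advance by step *S* (default 20 nt); the plan holds
⌊(*L*−*W*)/*S*⌋ windows (135 for a 3500-nt mRNA, 410 for 9000 nt), and each
window is folded into up to *k* = 10 ranked (sub)optimal structures. Within a
structure, a **helix** is a maximal run of stacked pairs
(i, j), (i+1, j−1), …; a helix of ≥ 8 bp counts as **non-hairpin** when, at
its innermost pair (i_k, j_k):

* strand distance j_k − i_k − 1 ≥ 40 nt (hairpin loops are short), and
* ≥ 16 of those intervening "linker" nucleotides are themselves base-paired
  (a hairpin has a loop where a long-range duplex has structure).

A **GC-helix** is an uninterrupted run of ≥ 8 G·C pairs satisfying both
criteria (AU-helices analogously); a **GC-stem** is the same composition run
in hairpin context (distance < 40). Motifs are mapped to transcript
coordinates, deduplicated across overlapping windows and suboptimal
structures (support = number of structures containing the motif, next to the
number of eligible structures whose window spans both strands), assigned to
one of three regions — 5′-region (5′-UTR + first 200 nt of CDS), remaining
CDS (rCDS), 3′-UTR — and reported as counts and frequencies per 100 nt.
Composition-preserving per-region shuffles provide the negative control, and
a 60-nt/step-1 minimum-free-energy profile (the *local folding potential*)
flags stably folded domains.

Folding itself is delegated to a backend: precomputed CT or dot-bracket
directories, the ViennaRNA engine (if its Python bindings are installed), or
a deterministic fixture backend for synthetic ground-truth data.

## Worked example

Generate a synthetic pool of two 1000-nt transcripts, each carrying one
planted 9-bp GC duplex at strand distance 100 in its 5′-region, rendered as a
CT directory; then scan it:

```bash
duplexscan make-fixture --transcripts 2 --seed 11 -o demo_fx
duplexscan scan demo_fx/transcripts.fasta demo_fx/annotation.tsv \
    --backend ct-dir --structures-dir demo_fx/ct --structures 1 \
    --class GC -o demo_out
# 20 structures scanned, 2 motifs -> demo_out/motifs.tsv
```

`demo_out/motifs.tsv` (abridged):

```
transcript_id           class  strand5_seq  strand5_start  strand5_end  strand3_start  strand3_end  length_bp  strand_distance  linker_paired  support  eligible  support_fraction  region      distance_from_start
fixture_five_prime_000  GC     CGCCGCGGG    20             28           129            137          9          100              20             1        1         1.0               five_prime  -181
fixture_five_prime_001  GC     GGGCCCCGC    20             28           129            137          9          100              20             1        1         1.0               five_prime  -181
```

Each row is one deduplicated GC-helix: a 9-bp duplex whose strands sit
100 nt apart with 20 paired linker nucleotides, found in every structure
whose window spans it (support_fraction 1.0), located in the 5′-region
181 nt upstream of the start codon. `demo_out/regions.tsv` gives the
per-region frequencies (here 0.25 per 100 nt in the 400-nt 5′-region, 0
elsewhere), with pooled rows under transcript id `ALL`.

Other subcommands: `duplexscan shuffle` (composition-preserving controls),
`duplexscan profile` (folding-potential profile with local minima).

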