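"""Synthetic transcripts, shuffled controls, and a deterministic backend.

Two kinds of control material make the whole pipeline testable offline:

* **Shuffled controls** — nucleotides permuted independently within the
  annotated 5'-UTR, CDS, and 3'-UTR, conserving each region's mononucleotide
  counts exactly.  Shuffling destroys the phased complementarity a duplex
  needs, so planted motifs vanish from shuffled pools.

* **Planted fixtures** — synthetic transcripts whose background alphabet is
  {A, C} (which admits no canonical base pair, so the background folds to
  nothing) carrying one exactly reverse-complementary duplex at a requested
  length, strand distance, and linker pairing.  The linker pairing is
  supplied by a small internal hairpin (plus, for odd counts, one linker
  position paired to a site downstream of the 3' strand).  A deterministic
  :class:`PlantedBackend` "folds" any window by pairing exactly the planted
  pairs it fully contains, so every downstream stage sees ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .structure_io import PairTable, StructureRecord, write_ct
from .transcripts import AnnotatedTranscript, write_annotation, write_fasta
from .windows import WindowPlan, enumerate_windows

__all__ = [
    "PlantedTruth",
    "shuffle_regions",
    "build_shuffled_pool",
    "plant_duplex_sequence",
    "PlantedBackend",
    "planted_backend",
    "make_fixture_pool",
    "render_ct_dir",
    "write_fixture",
]

_COMPLEMENT = str.maketrans("ACGU", "UGCA")
#: background alphabet: A·C cannot form a canonical or wobble pair
_BACKGROUND = np.array(list("AC"))
_HAIRPIN_LOOP = 3


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one planted duplex fixture.

    ``duplex_pairs`` are the pairs of the planted long-range duplex itself;
    ``all_pairs`` additionally includes the linker hairpin (and the odd-count
    singleton pair) and is what the fixture backend folds.
    """

    transcript_id: str
    motif_class: str
    strand5: tuple[int, int]
    strand3: tuple[int, int]
    duplex_pairs: tuple[tuple[int, int], ...]
    all_pairs: tuple[tuple[int, int], ...]
    strand_distance: int
    linker_paired: int
    background: Mapping[str, int | str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Shuffled controls

def _region_slices(t: AnnotatedTranscript) -> list[slice]:
    # annotation regions (5'-UTR / CDS / 3'-UTR), not the analysis partition
    return [slice(0, t.utr5_len), slice(t.utr5_len, t.cds_end),
            slice(t.cds_end, len(t))]


def shuffle_regions(
    t: AnnotatedTranscript,
    seed: int | np.random.Generator,
    suffix: str = "_shuffled",
) -> AnnotatedTranscript:
    """Permute nucleotides independently within 5'-UTR, CDS, and 3'-UTR.

    Per-region mononucleotide counts are conserved exactly; the annotation is
    carried over unchanged.  A seeded generator makes the shuffle
    reproducible.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    chars = np.array(list(t.sequence))
    for sl in _region_slices(t):
        region = chars[sl]
        if len(region):
            chars[sl] = rng.permutation(region)
    return AnnotatedTranscript(
        id=t.id + suffix, sequence="".join(chars),
        utr5_len=t.utr5_len, cds_end=t.cds_end, metadata=dict(t.metadata),
    )


def build_shuffled_pool(
    pool: Sequence[AnnotatedTranscript],
    n_replicates: int,
    seed: int,
) -> list[AnnotatedTranscript]:
    """Independent per-region shuffles of every transcript in *pool*.

    Replicate streams derive from one master seed through
    ``SeedSequence([seed, transcript_index, replicate])``, so the whole pool
    is reproducible and replicates are statistically independent.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    out = []
    for ti, t in enumerate(pool):
        for rep in range(1, n_replicates + 1):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, ti, rep]))
            out.append(shuffle_regions(t, rng, suffix=f"_shuf{rep}"))
    return out


# ---------------------------------------------------------------------------
# Planted duplex fixtures

_CLASS_ALPHABET = {"GC": "GC", "AU": "AU", "mixed": "ACGU"}


def plant_duplex_sequence(
    length_bp: int,
    strand_dist: int,
    linker_paired: int,
    duplex_class: str = "GC",
    background_length: int = 1000,
    seed: int = 0,
    *,
    duplex_start: int | None = None,
    utr5_len: int | None = None,
    cds_end: int | None = None,
    transcript_id: str | None = None,
) -> tuple[AnnotatedTranscript, PlantedTruth]:
    """Build a synthetic transcript with one planted long-range duplex.

    The duplex has exactly ``length_bp`` reverse-complementary pairs of the
    requested class, ``strand_dist`` nt between its strands, and exactly
    ``linker_paired`` paired nucleotides inside that linker (an internal
    hairpin with mixed composition, plus one out-of-linker partner when the
    count is odd).  Geometry that does not fit ``background_length`` is
    rejected.
    """
    if duplex_class not in _CLASS_ALPHABET:
        raise ValueError(f"duplex class must be one of {list(_CLASS_ALPHABET)}")
    rng = np.random.default_rng(seed)
    L = background_length
    k = length_bp

    stem = linker_paired // 2
    extra = linker_paired % 2
    hairpin_span = (2 * stem + _HAIRPIN_LOOP) if stem else 0
    if hairpin_span + extra > strand_dist:
        raise ValueError(
            f"linker of {strand_dist} nt cannot hold {linker_paired} paired "
            "positions"
        )
    span = 2 * k + strand_dist
    tail_needed = 12 if extra else 0
    if duplex_start is None:
        duplex_start = max(1, (L - span - tail_needed) // 2 + 1)
    a = duplex_start
    b = a + k + strand_dist  # strand3 start
    if a < 1 or b + k - 1 + tail_needed > L:
        raise ValueError(
            f"duplex geometry (start {a}, span {span}) does not fit a "
            f"{L}-nt background"
        )

    chars = list(rng.choice(_BACKGROUND, size=L))
    alphabet = list(_CLASS_ALPHABET[duplex_class])
    strand5_seq = "".join(rng.choice(alphabet, size=k))
    strand3_seq = _revcomp(strand5_seq)
    chars[a - 1 : a - 1 + k] = list(strand5_seq)
    chars[b - 1 : b - 1 + k] = list(strand3_seq)
    duplex_pairs = tuple((a + m, b + k - 1 - m) for m in range(k))

    all_pairs = list(duplex_pairs)
    linker_start = a + k  # first linker position
    if stem:
        pad = (strand_dist - hairpin_span) // 2
        h5 = linker_start + pad
        # mixed-composition stem (alternating G/A vs U/C) so the hairpin
        # never forms a uniform GC or AU run of its own
        stem5 = "".join("GA"[m % 2] for m in range(stem))
        stem3 = _revcomp(stem5)
        h3 = h5 + stem + _HAIRPIN_LOOP
        chars[h5 - 1 : h5 - 1 + stem] = list(stem5)
        chars[h3 - 1 : h3 - 1 + stem] = list(stem3)
        all_pairs += [(h5 + m, h3 + stem - 1 - m) for m in range(stem)]
    if extra:
        # one more paired linker position, partnered outside the linker
        paired = {p for pr in all_pairs for p in pr}
        free = next(p for p in range(linker_start, linker_start + strand_dist)
                    if p not in paired)
        target = b + k - 1 + 8
        chars[free - 1] = "A"
        chars[target - 1] = "U"
        all_pairs.append((free, target))

    sequence = "".join(chars)
    if utr5_len is None:
        utr5_len = min(100, max(0, L // 4 - 1))
    if cds_end is None:
        cds_end = max(utr5_len + 1, L - min(100, L // 4))
    tid = transcript_id or f"planted_{duplex_class}{k}_d{strand_dist}_s{seed}"
    t = AnnotatedTranscript(tid, sequence, utr5_len, cds_end)
    truth = PlantedTruth(
        transcript_id=tid,
        motif_class=duplex_class if duplex_class != "mixed" else "general",
        strand5=(a, a + k - 1),
        strand3=(b, b + k - 1),
        duplex_pairs=duplex_pairs,
        all_pairs=tuple(sorted(all_pairs)),
        strand_distance=strand_dist,
        linker_paired=linker_paired,
        background={"length": L, "seed": int(seed), "alphabet": "AC"},
    )
    return t, truth


def _stacked_runs(
    pairs: Iterable[tuple[int, int]]
) -> list[tuple[tuple[int, int], ...]]:
    """Group pairs into maximal stacked runs (constant i+j, consecutive i)."""
    by_sum: dict[int, list[tuple[int, int]]] = {}
    for i, j in pairs:
        by_sum.setdefault(i + j, []).append((i, j))
    runs = []
    for total in by_sum:
        chunk = sorted(by_sum[total])
        run = [chunk[0]]
        for p in chunk[1:]:
            if p[0] == run[-1][0] + 1:
                run.append(p)
            else:
                runs.append(tuple(run))
                run = [p]
        runs.append(tuple(run))
    return sorted(runs)


class PlantedBackend:
    """Deterministic fixture backend that folds exactly the planted pairs.

    For any window it returns one structure containing each planted helical
    element (long-range duplex, linker hairpin, singleton pair) whose pairs
    all fall inside the window — an element a window clips at its edge is
    omitted whole, so windows never report truncated variants of a planted
    duplex — and nothing else, in window-local coordinates.  The energy is
    −2 · (number of pairs) kcal/mol, an arbitrary but fixed convention that
    makes profiles computable.  Unknown transcripts fold to the empty
    structure.
    """

    name = "fixture"

    def __init__(self, truths: Iterable[PlantedTruth]):
        pairs_by_id: dict[str, set[tuple[int, int]]] = {}
        for truth in truths:
            pairs_by_id.setdefault(truth.transcript_id, set()).update(
                truth.all_pairs)
        self._runs = {tid: _stacked_runs(pairs)
                      for tid, pairs in pairs_by_id.items()}

    def fold(self, sequence: str, max_structures: int, *,
             transcript_id: str = "", offset: int = 0) -> list[StructureRecord]:
        n = len(sequence)
        local = [
            (i - offset, j - offset)
            for run in self._runs.get(transcript_id, ())
            if all(offset < i and j <= offset + n for i, j in run)
            for i, j in run
        ]
        pt = PairTable.from_pairs(n, local)
        return [StructureRecord(
            pair_table=pt, transcript_id=transcript_id, window_offset=offset,
            rank=1, free_energy=-2.0 * len(local),
        )]


def planted_backend(truths: Iterable[PlantedTruth]) -> PlantedBackend:
    return PlantedBackend(truths)


def make_fixture_pool(
    n_transcripts: int,
    seed: int,
    *,
    region: str = "five_prime",
    length: int = 1000,
    length_bp: int = 9,
    strand_dist: int = 100,
    linker_paired: int = 20,
    duplex_class: str = "GC",
) -> tuple[list[AnnotatedTranscript], list[PlantedTruth]]:
    """A pool of planted-duplex transcripts, the duplex in a chosen region.

    Annotation is fixed at utr5_len = length/5 and cds_end = length − length/5
    and the duplex start placed so its 5' strand falls inside the requested
    analysis region (``five_prime``, ``rcds``, or ``utr3``).
    """
    utr5 = length // 5
    cds_end = length - length // 5
    span = 2 * length_bp + strand_dist
    starts = {
        "five_prime": 20,
        "rcds": utr5 + 220,
        "utr3": cds_end + 10,
    }
    if region not in starts:
        raise ValueError(f"unknown region {region!r}")
    start = starts[region]
    if start + span - 1 > length:
        raise ValueError("duplex does not fit the requested region")
    pool, truths = [], []
    for i in range(n_transcripts):
        t, truth = plant_duplex_sequence(
            length_bp, strand_dist, linker_paired, duplex_class, length,
            seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0]
                     % 2**31),
            duplex_start=start, utr5_len=utr5, cds_end=cds_end,
            transcript_id=f"fixture_{region}_{i:03d}",
        )
        pool.append(t)
        truths.append(truth)
    return pool, truths


# ---------------------------------------------------------------------------
# Fixture rendering (exercises the precomputed-structure reader paths)

def render_ct_dir(
    pool: Sequence[AnnotatedTranscript],
    truths: Sequence[PlantedTruth],
    outdir: str | Path,
    window_size: int = 800,
    step: int = 20,
) -> list[WindowPlan]:
    """Write each planned window's planted structure as a CT file.

    Files follow the ``<transcript>__<offset>.ct`` naming convention of the
    CT-directory backend, so a scan over the rendered directory reproduces
    the fixture-backend scan exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    backend = PlantedBackend(truths)
    plans = []
    for t in pool:
        plan = enumerate_windows(len(t), window_size, step, transcript_id=t.id)
        for offset in plan.offsets:
            wlen = min(window_size, len(t) - offset)
            seq = t.sequence[offset : offset + wlen]
            records = backend.fold(seq, 1, transcript_id=t.id, offset=offset)
            write_ct(records, seq, outdir / f"{t.id}__{offset}.ct")
        plans.append(plan)
    return plans


def write_fixture(
    outdir: str | Path,
    n_transcripts: int = 3,
    seed: int = 0,
    *,
    region: str = "five_prime",
    window_size: int = 800,
    step: int = 20,
    **pool_kwargs,
) -> None:
    """Emit a complete offline fixture: FASTA, annotation, truth JSON, CT dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pool, truths = make_fixture_pool(n_transcripts, seed, region=region,
                                     **pool_kwargs)
    write_fasta(pool, outdir / "transcripts.fasta")
    write_annotation(pool, outdir / "annotation.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump([
            {
                "transcript_id": tr.transcript_id,
                "class": tr.motif_class,
                "strand5": list(tr.strand5),
                "strand3": list(tr.strand3),
                "duplex_pairs": [list(p) for p in tr.duplex_pairs],
                "all_pairs": [list(p) for p in tr.all_pairs],
                "strand_distance": tr.strand_distance,
                "linker_paired": tr.linker_paired,
            }
            for tr in truths
        ], fh, indent=2)
    render_ct_dir(pool, truths, outdir / "ct", window_size, step)
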