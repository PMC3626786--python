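"""Transcripts with functional region annotation.

An mRNA is described by its sequence plus two annotation numbers: the length
of the 5'-UTR and the 1-based position of the last CDS nucleotide.  For the
duplex analysis the transcript is partitioned into three *analysis* regions:

* ``five_prime`` — the 5'-UTR plus the first 200 nt of coding sequence
  (capped at the CDS end when the CDS is shorter than 200 nt),
* ``rcds``       — the remaining coding sequence,
* ``utr3``       — everything downstream of the CDS.

All coordinates are 1-based and intervals are closed, matching the CT file
convention.  Sequences are normalised to the RNA alphabet {A, C, G, U};
ambiguity codes are rejected rather than randomised, mirroring the input
curation rule that only complete, unambiguous mRNAs enter the analysis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "AnnotatedTranscript",
    "RegionScheme",
    "Region",
    "normalize_sequence",
    "define_regions",
    "assign_region",
    "region_composition",
    "read_fasta",
    "read_annotation",
    "load_pool",
    "write_fasta",
    "write_annotation",
]

#: analysis region labels, 5' to 3'
REGION_LABELS = ("five_prime", "rcds", "utr3")

#: nt of coding sequence absorbed into the 5' analysis region
FIVE_PRIME_CDS_EXTENSION = 200

_VALID = set("ACGU")
_TRANS = str.maketrans("acgtuT", "ACGUUU")


def normalize_sequence(raw: str) -> str:
    """Uppercase *raw* and convert DNA T to RNA U.

    Raises
    ------
    ValueError
        If *raw* is empty or contains a character outside {A,C,G,T,U}
        (case-insensitive); the message names the 1-based offending position.
    """
    if not raw:
        raise ValueError("empty sequence")
    seq = raw.translate(_TRANS)
    for pos, ch in enumerate(seq, start=1):
        if ch not in _VALID:
            raise ValueError(
                f"invalid character {raw[pos - 1]!r} at position {pos}: "
                "sequence must contain only A, C, G, T, U"
            )
    return seq


@dataclass(frozen=True)
class Region:
    """Closed 1-based interval [start, end]; empty iff start > end."""

    start: int
    end: int

    def __len__(self) -> int:
        return max(0, self.end - self.start + 1)

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class AnnotatedTranscript:
    """A transcript sequence with 5'-UTR / CDS boundary annotation.

    ``utr5_len`` is the number of 5'-UTR nucleotides (0 allowed) and
    ``cds_end`` the 1-based position of the last coding nucleotide.
    """

    id: str
    sequence: str
    utr5_len: int
    cds_end: int
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        n = len(self.sequence)
        if not (0 <= self.utr5_len < self.cds_end <= n):
            raise ValueError(
                f"{self.id}: annotation must satisfy "
                f"0 <= utr5_len ({self.utr5_len}) < cds_end ({self.cds_end}) "
                f"<= length ({n})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RegionScheme:
    """The three-interval analysis partition of one transcript."""

    five_prime: Region
    rcds: Region
    utr3: Region

    def __getitem__(self, label: str) -> Region:
        if label not in REGION_LABELS:
            raise KeyError(label)
        return getattr(self, label)

    @property
    def length(self) -> int:
        return self.utr3.end

    def lengths(self) -> dict[str, int]:
        return {label: len(self[label]) for label in REGION_LABELS}


def define_regions(t: AnnotatedTranscript) -> RegionScheme:
    """Partition *t* into five_prime / rcds / utr3 analysis regions.

    The 5' region runs from position 1 to ``utr5_len + 200``, capped at the
    CDS end so the partition never overlaps when the CDS is short.
    """
    n = len(t)
    fp_end = min(t.utr5_len + FIVE_PRIME_CDS_EXTENSION, t.cds_end)
    return RegionScheme(
        five_prime=Region(1, fp_end),
        rcds=Region(fp_end + 1, t.cds_end),
        utr3=Region(t.cds_end + 1, n),
    )


def assign_region(pos: int, scheme: RegionScheme) -> str:
    """Return the label of the region containing 1-based position *pos*."""
    if not 1 <= pos <= scheme.length:
        raise ValueError(f"position {pos} outside transcript [1, {scheme.length}]")
    for label in REGION_LABELS:
        if pos in scheme[label]:
            return label
    raise AssertionError("unreachable: partition covers every position")


def region_composition(
    t: AnnotatedTranscript, scheme: RegionScheme | None = None
) -> dict[str, dict[str, float] | None]:
    """Per-region mononucleotide fractions of A, C, G, U.

    Empty regions map to ``None``; for non-empty regions the four fractions
    sum to 1.
    """
    scheme = scheme or define_regions(t)
    out: dict[str, dict[str, float] | None] = {}
    for label in REGION_LABELS:
        region = scheme[label]
        if len(region) == 0:
            out[label] = None
            continue
        sub = t.sequence[region.start - 1 : region.end]
        out[label] = {b: sub.count(b) / len(sub) for b in "ACGU"}
    return out


# ---------------------------------------------------------------------------
# I/O: FASTA + annotation TSV (id <TAB> utr5_len <TAB> cds_end)

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (multi-record, possibly line-wrapped) FASTA into id → sequence."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_annotation(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read the annotation table: header ``id<TAB>utr5_len<TAB>cds_end``."""
    out: dict[str, tuple[int, int]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "utr5_len", "cds_end"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: annotation header must contain columns {sorted(required)}"
            )
        for row in reader:
            out[row["id"]] = (int(row["utr5_len"]), int(row["cds_end"]))
    return out


def load_pool(
    fasta_path: str | Path, annotation_path: str | Path
) -> list[AnnotatedTranscript]:
    """Join a FASTA file with its annotation table into transcripts.

    Every FASTA record must have an annotation row; extra annotation rows are
    ignored (the FASTA defines the pool).
    """
    seqs = read_fasta(fasta_path)
    ann = read_annotation(annotation_path)
    pool = []
    for tid, seq in seqs.items():
        if tid not in ann:
            raise ValueError(f"transcript {tid!r} missing from annotation table")
        utr5_len, cds_end = ann[tid]
        pool.append(AnnotatedTranscript(tid, seq, utr5_len, cds_end))
    return pool


def write_fasta(transcripts: Iterable[AnnotatedTranscript], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.sequence), width):
                fh.write(t.sequence[i : i + width] + "\n")


def write_annotation(transcripts: Iterable[AnnotatedTranscript],
                     path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tutr5_len\tcds_end\n")
        for t in transcripts:
            fh.write(f"{t.id}\t{t.utr5_len}\t{t.cds_end}\n")
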