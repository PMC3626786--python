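"""Global motif records, deduplication, region statistics, and report tables.

Motifs found in individual windows are mapped back to transcript coordinates
and deduplicated across overlapping windows and suboptimal structures by
exact identity (class, 5' strand interval, 3' strand interval).  Each record
carries its *support* (number of predicted structures containing the motif)
next to the number of *eligible* structures — those whose window spans both
strands — so that a support fraction can be reported.

Frequencies are normalised per 100 nt of region length, per transcript and
pooled over a sequence set; strand-distance and duplex-length summaries use
the arithmetic mean and sample (n−1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .helices import CandidateMotif
from .structure_io import StructureRecord
from .transcripts import (REGION_LABELS, AnnotatedTranscript, RegionScheme,
                          assign_region, define_regions)

__all__ = [
    "MotifRecord",
    "map_to_global",
    "deduplicate_motifs",
    "assign_motif_region",
    "distance_from_start_codon",
    "frequency_per_100nt",
    "strand_distance_stats",
    "write_motif_table",
    "write_region_table",
    "read_motif_table",
    "POOLED_ID",
    "MOTIF_COLUMNS",
    "REGION_COLUMNS",
]

POOLED_ID = "ALL"

MOTIF_COLUMNS = [
    "transcript_id", "class", "strand5_seq", "strand5_start", "strand5_end",
    "strand3_seq", "strand3_start", "strand3_end", "length_bp",
    "strand_distance", "linker_paired", "support", "eligible",
    "support_fraction", "region", "distance_from_start",
]

REGION_COLUMNS = [
    "transcript_id", "region", "region_length", "class", "count",
    "freq_per_100nt",
]


@dataclass(frozen=True)
class MotifRecord:
    """A deduplicated duplex motif in global 1-based transcript coordinates."""

    transcript_id: str
    motif_class: str
    strand5: tuple[int, int]
    strand3: tuple[int, int]
    length_bp: int
    strand_distance: int
    linker_paired: int
    support: int
    eligible_structures: int
    region: str = ""
    distance_from_start: int = 0

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")
        if self.eligible_structures < self.support:
            raise ValueError("support cannot exceed eligible structures")
        if not self.strand5[1] < self.strand3[0]:
            raise ValueError("5' strand must precede 3' strand")

    @property
    def key(self) -> tuple[str, tuple[int, int], tuple[int, int]]:
        return (self.motif_class, self.strand5, self.strand3)

    @property
    def support_fraction(self) -> float:
        return self.support / self.eligible_structures


def map_to_global(motif: CandidateMotif, window_offset: int,
                  transcript_length: int | None = None) -> CandidateMotif:
    """Shift a window-local motif into transcript coordinates (reversible)."""
    if window_offset < 0:
        raise ValueError("window offset must be >= 0")
    shifted = replace(
        motif,
        pairs=tuple((i + window_offset, j + window_offset)
                    for i, j in motif.pairs),
        strand5=(motif.strand5[0] + window_offset,
                 motif.strand5[1] + window_offset),
        strand3=(motif.strand3[0] + window_offset,
                 motif.strand3[1] + window_offset),
    )
    if transcript_length is not None and shifted.strand3[1] > transcript_length:
        raise ValueError(
            f"motif end {shifted.strand3[1]} exceeds transcript length "
            f"{transcript_length}: inconsistent record"
        )
    return shifted


def _spans(structure: StructureRecord, window_size_of: Mapping[int, int],
           strand5: tuple[int, int], strand3: tuple[int, int]) -> bool:
    start = structure.window_offset + 1
    end = structure.window_offset + window_size_of[structure.window_offset]
    return start <= strand5[0] and strand3[1] <= end


def deduplicate_motifs(
    candidates: Sequence[tuple[CandidateMotif, StructureRecord]],
    structures: Sequence[StructureRecord],
    transcript_id: str,
) -> list[MotifRecord]:
    """Collapse per-structure candidates into one record per motif identity.

    ``candidates`` pairs each *global-coordinate* candidate with the
    structure it was found in; ``structures`` is the full list of structures
    of the run, used to count, per motif, how many structures' windows span
    both strands (the eligible denominator).
    """
    window_size_of = {s.window_offset: s.pair_table.n for s in structures}
    by_key: dict[tuple, dict] = {}
    for cand, struct in candidates:
        key = (cand.motif_class, cand.strand5, cand.strand3)
        entry = by_key.setdefault(key, {"cand": cand, "structs": set()})
        entry["structs"].add(struct.key)
    records = []
    for key in sorted(by_key, key=lambda k: (k[1], k[2], k[0])):
        cand = by_key[key]["cand"]
        support = len(by_key[key]["structs"])
        eligible = sum(
            1 for s in structures
            if _spans(s, window_size_of, cand.strand5, cand.strand3)
        )
        records.append(MotifRecord(
            transcript_id=transcript_id,
            motif_class=cand.motif_class,
            strand5=cand.strand5,
            strand3=cand.strand3,
            length_bp=cand.length_bp,
            strand_distance=cand.strand_distance,
            linker_paired=cand.linker_paired,
            support=support,
            eligible_structures=max(eligible, support),
        ))
    return records


def assign_motif_region(m: MotifRecord, scheme: RegionScheme) -> str:
    """Region of the motif's 5'-most nucleotide (single label per motif)."""
    return assign_region(m.strand5[0], scheme)


def distance_from_start_codon(m: MotifRecord, utr5_len: int) -> int:
    """nt from the 5' strand start to the A of the start codon (0 = at AUG,
    negative = upstream)."""
    return m.strand5[0] - (utr5_len + 1)


def annotate_motifs(
    motifs: Iterable[MotifRecord], t: AnnotatedTranscript
) -> list[MotifRecord]:
    """Fill in region label and start-codon distance for each motif."""
    scheme = define_regions(t)
    return [
        replace(m, region=assign_motif_region(m, scheme),
                distance_from_start=distance_from_start_codon(m, t.utr5_len))
        for m in motifs
    ]


def frequency_per_100nt(
    motifs: Sequence[MotifRecord],
    transcripts: Sequence[AnnotatedTranscript],
) -> pd.DataFrame:
    """Per-region motif counts and frequencies per 100 nt.

    One row per (transcript, region, class) plus a ``whole`` row per
    transcript and pooled rows (transcript id ``ALL``) aggregating the set:
    pooled frequency = 100 · Σ counts / Σ region lengths.  Regions of length
    zero are omitted.
    """
    classes = sorted({m.motif_class for m in motifs}) or ["general"]
    by_tr: dict[str, list[MotifRecord]] = {t.id: [] for t in transcripts}
    for m in motifs:
        if m.transcript_id not in by_tr:
            raise ValueError(f"motif for unknown transcript {m.transcript_id!r}")
        by_tr[m.transcript_id].append(m)

    rows = []
    region_len_sum = {label: 0 for label in (*REGION_LABELS, "whole")}
    count_sum = {(label, c): 0 for label in (*REGION_LABELS, "whole")
                 for c in classes}
    for t in transcripts:
        scheme = define_regions(t)
        lengths = {**scheme.lengths(), "whole": len(t)}
        for label in (*REGION_LABELS, "whole"):
            region_len_sum[label] += lengths[label]
            if lengths[label] == 0:
                continue
            for c in classes:
                count = sum(
                    1 for m in by_tr[t.id]
                    if m.motif_class == c and (label == "whole"
                                               or m.region == label)
                )
                count_sum[(label, c)] += count
                rows.append({
                    "transcript_id": t.id, "region": label,
                    "region_length": lengths[label], "class": c,
                    "count": count,
                    "freq_per_100nt": 100.0 * count / lengths[label],
                })
    for label in (*REGION_LABELS, "whole"):
        if region_len_sum[label] == 0:
            continue
        for c in classes:
            rows.append({
                "transcript_id": POOLED_ID, "region": label,
                "region_length": region_len_sum[label], "class": c,
                "count": count_sum[(label, c)],
                "freq_per_100nt":
                    100.0 * count_sum[(label, c)] / region_len_sum[label],
            })
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def strand_distance_stats(motifs: Sequence[MotifRecord]) -> pd.DataFrame:
    """Mean ± sample SD of strand distance and duplex length, per class.

    Single-motif groups report SD = 0 and are flagged in ``single_member``.
    """
    rows = []
    by_class: dict[str, list[MotifRecord]] = {}
    for m in motifs:
        by_class.setdefault(m.motif_class, []).append(m)
    for cls in sorted(by_class):
        group = by_class[cls]
        dists = np.array([m.strand_distance for m in group], dtype=float)
        lens = np.array([m.length_bp for m in group], dtype=float)
        single = len(group) == 1
        rows.append({
            "class": cls, "n": len(group),
            "distance_mean": dists.mean(),
            "distance_sd": 0.0 if single else dists.std(ddof=1),
            "length_mean": lens.mean(),
            "length_sd": 0.0 if single else lens.std(ddof=1),
            "single_member": single,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Table output

def _motif_row(m: MotifRecord, sequence: str) -> dict:
    return {
        "transcript_id": m.transcript_id,
        "class": m.motif_class,
        "strand5_seq": sequence[m.strand5[0] - 1 : m.strand5[1]],
        "strand5_start": m.strand5[0],
        "strand5_end": m.strand5[1],
        "strand3_seq": sequence[m.strand3[0] - 1 : m.strand3[1]],
        "strand3_start": m.strand3[0],
        "strand3_end": m.strand3[1],
        "length_bp": m.length_bp,
        "strand_distance": m.strand_distance,
        "linker_paired": m.linker_paired,
        "support": m.support,
        "eligible": m.eligible_structures,
        "support_fraction": round(m.support_fraction, 6),
        "region": m.region,
        "distance_from_start": m.distance_from_start,
    }


def write_motif_table(
    motifs: Sequence[MotifRecord],
    transcripts: Sequence[AnnotatedTranscript],
    path: str | Path,
) -> pd.DataFrame:
    """Write the per-motif TSV (deterministic row order, byte-stable)."""
    seqs = {t.id: t.sequence for t in transcripts}
    rows = [_motif_row(m, seqs[m.transcript_id]) for m in motifs]
    df = pd.DataFrame(rows, columns=MOTIF_COLUMNS)
    df = df.sort_values(
        ["transcript_id", "strand5_start", "class", "strand3_start"],
        kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)
    return df


def write_region_table(freqs: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Write the per-region frequency TSV (deterministic row order)."""
    order = {label: k for k, label in enumerate((*REGION_LABELS, "whole"))}
    df = freqs.copy()
    df["_r"] = df["region"].map(order)
    df["_pooled"] = (df["transcript_id"] == POOLED_ID).astype(int)
    df = df.sort_values(["_pooled", "transcript_id", "_r", "class"],
                        kind="mergesort").drop(columns=["_r", "_pooled"])
    df = df.reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df


def read_motif_table(path: str | Path) -> list[MotifRecord]:
    """Read a motif TSV back into records (round-trip of write_motif_table)."""
    df = pd.read_csv(path, sep="\t")
    return [
        MotifRecord(
            transcript_id=row["transcript_id"],
            motif_class=row["class"],
            strand5=(int(row["strand5_start"]), int(row["strand5_end"])),
            strand3=(int(row["strand3_start"]), int(row["strand3_end"])),
            length_bp=int(row["length_bp"]),
            strand_distance=int(row["strand_distance"]),
            linker_paired=int(row["linker_paired"]),
            support=int(row["support"]),
            eligible_structures=int(row["eligible"]),
            region=row["region"],
            distance_from_start=int(row["distance_from_start"]),
        )
        for _, row in df.iterrows()
    ]
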