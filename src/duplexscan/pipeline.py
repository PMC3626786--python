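"""End-to-end scan: windows → fold → parse → filter → aggregate.

``scan_transcript`` runs the full motif search for one transcript under one
or more criteria sets and returns annotated, deduplicated motif records;
``scan_pool`` repeats this over a sequence pool and also builds the
per-region frequency table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .helices import HelixCriteria, select_motifs
from .report import (MotifRecord, annotate_motifs, deduplicate_motifs,
                     frequency_per_100nt, map_to_global)
from .transcripts import AnnotatedTranscript
from .windows import (DEFAULT_STEP, DEFAULT_STRUCTURES, DEFAULT_WINDOW,
                      FoldingBackend, enumerate_windows, fold_windows)

__all__ = ["ScanStats", "standard_criteria", "scan_transcript", "scan_pool",
           "collapse_contained"]

logger = logging.getLogger(__name__)


def standard_criteria(
    min_len_bp: int = 8,
    min_strand_distance: int = 40,
    min_linker_paired: int = 16,
) -> list[HelixCriteria]:
    """The four motif classes of the standard report: general helices,
    GC-helices, AU-helices, and GC-stems (hairpin-context GC runs)."""
    common = dict(min_len_bp=min_len_bp,
                  min_strand_distance=min_strand_distance,
                  min_linker_paired=min_linker_paired)
    return [
        HelixCriteria(composition_class="any", **common),
        HelixCriteria(composition_class="GC", **common),
        HelixCriteria(composition_class="AU", **common),
        HelixCriteria(composition_class="GC", hairpin_mode=True, **common),
    ]


@dataclass
class ScanStats:
    """Per-stage counters of one scan (for the structured log)."""

    transcripts: int = 0
    windows_planned: int = 0
    structures: int = 0
    candidates: int = 0
    motifs: int = 0

    def log(self) -> None:
        logger.info(
            "scan: %d transcripts, %d windows, %d structures, "
            "%d candidate hits, %d deduplicated motifs",
            self.transcripts, self.windows_planned, self.structures,
            self.candidates, self.motifs,
        )


def scan_transcript(
    t: AnnotatedTranscript,
    backend: FoldingBackend,
    criteria: Sequence[HelixCriteria] | None = None,
    *,
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    structures_per_fold: int = DEFAULT_STRUCTURES,
    trailing_window: bool = False,
    stats: ScanStats | None = None,
) -> list[MotifRecord]:
    """Scan one transcript for duplex motifs under the given criteria sets."""
    criteria = list(criteria) if criteria is not None else standard_criteria()
    plan = enumerate_windows(
        len(t), window_size, step, transcript_id=t.id,
        structures_per_fold=structures_per_fold,
        trailing_window=trailing_window,
    )
    structures = fold_windows(t, plan, backend)
    candidates = []
    for struct in structures:
        wlen = struct.pair_table.n
        window_seq = t.sequence[struct.window_offset:
                                struct.window_offset + wlen]
        for crit in criteria:
            for cand in select_motifs(struct, window_seq, crit):
                candidates.append(
                    (map_to_global(cand, struct.window_offset, len(t)), struct))
    motifs = deduplicate_motifs(candidates, structures, t.id)
    motifs = annotate_motifs(motifs, t)
    if stats is not None:
        stats.transcripts += 1
        stats.windows_planned += plan.n_windows
        stats.structures += len(structures)
        stats.candidates += len(candidates)
        stats.motifs += len(motifs)
    return motifs


def scan_pool(
    pool: Sequence[AnnotatedTranscript],
    backend: FoldingBackend,
    criteria: Sequence[HelixCriteria] | None = None,
    **scan_kwargs,
) -> tuple[list[MotifRecord], pd.DataFrame, ScanStats]:
    """Scan a sequence pool; returns motifs, the frequency table, and stats."""
    stats = ScanStats()
    motifs: list[MotifRecord] = []
    for t in pool:
        motifs.extend(scan_transcript(t, backend, criteria, stats=stats,
                                      **scan_kwargs))
    stats.log()
    freqs = frequency_per_100nt(motifs, pool)
    return motifs, freqs, stats


def collapse_contained(motifs: Sequence[MotifRecord]) -> list[MotifRecord]:
    """Optionally fold near-duplicates: drop any motif whose both strands lie
    within another same-class motif's strands on the same transcript."""
    def contains(outer: MotifRecord, inner: MotifRecord) -> bool:
        return (outer.strand5[0] <= inner.strand5[0]
                and inner.strand5[1] <= outer.strand5[1]
                and outer.strand3[0] <= inner.strand3[0]
                and inner.strand3[1] <= outer.strand3[1])

    kept = []
    for m in motifs:
        shadowed = any(
            o is not m and o.transcript_id == m.transcript_id
            and o.motif_class == m.motif_class and contains(o, m)
            and (o.length_bp, o.key) > (m.length_bp, m.key)
            for o in motifs
        )
        if not shadowed:
            kept.append(m)
    return kept
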