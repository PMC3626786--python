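"""Sliding-window planning, batch folding, and the local folding potential.

A transcript of length L is cut into overlapping windows of size W advanced
by a constant step S; each window is folded independently by a pluggable
backend that returns up to k ranked structures.  The window count for L > W
is floor((L − W) / S) with offsets 0, S, 2S, …  — e.g. a 3500-nt transcript
at W=800, S=20 yields 135 windows (1350 structures at k=10) and a 9000-nt
transcript yields 410.  The trailing < S nt a plan leaves uncovered can be
picked up with ``trailing_window=True``, which appends one extra window
ending exactly at position L.

The *folding potential* profile slides a short window (default 60 nt) at
step 1 and records the minimum free energy of each window's optimal
structure; local minima of the profile flag stably folded domains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

from .structure_io import PairTable, StructureRecord
from .transcripts import AnnotatedTranscript

__all__ = [
    "WindowPlan",
    "FoldingBackend",
    "BackendCapabilityError",
    "FoldingProfile",
    "enumerate_windows",
    "fold_windows",
    "folding_profile",
    "profile_minima",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 800
DEFAULT_STEP = 20
DEFAULT_STRUCTURES = 10
PROFILE_WINDOW = 60


@runtime_checkable
class FoldingBackend(Protocol):
    """Contract every folding engine adapter satisfies.

    ``fold`` returns 1..max_structures ranked :class:`StructureRecord`s for a
    window sequence; the returned pair tables must have n equal to the window
    length.  ``transcript_id`` and ``offset`` identify the window so that
    precomputed-structure and fixture backends can look it up; live engines
    may ignore them.  Energies are optional unless the caller needs a
    folding-potential profile.
    """

    name: str

    def fold(self, sequence: str, max_structures: int, *,
             transcript_id: str = "", offset: int = 0) -> list[StructureRecord]:
        ...


class BackendCapabilityError(RuntimeError):
    """Raised when an operation needs a capability the backend lacks."""


@dataclass(frozen=True)
class WindowPlan:
    transcript_id: str
    window_size: int
    step: int
    offsets: tuple[int, ...]
    structures_per_fold: int = DEFAULT_STRUCTURES
    transcript_length: int = 0

    @property
    def n_windows(self) -> int:
        return len(self.offsets)

    def window_length(self, offset: int) -> int:
        return min(self.window_size, self.transcript_length - offset)


def enumerate_windows(
    length: int,
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    *,
    transcript_id: str = "",
    structures_per_fold: int = DEFAULT_STRUCTURES,
    trailing_window: bool = False,
) -> WindowPlan:
    """Plan the sliding windows over a transcript of the given length.

    For length > window_size the plan holds floor((L − W) / S) windows at
    offsets 0, S, 2S, …  (at least one window is always planned); for
    length <= window_size a single whole-sequence window is used.  With
    ``trailing_window`` one extra window ending at position L is appended
    when the regular plan stops short of the 3' end.
    """
    if length <= 0:
        raise ValueError("transcript length must be positive")
    if window_size < 1 or step < 1:
        raise ValueError("window size and step must be >= 1")
    if length <= window_size:
        return WindowPlan(transcript_id, min(window_size, length), step, (0,),
                          structures_per_fold, length)
    count = max(1, (length - window_size) // step)
    offsets = [i * step for i in range(count)]
    if trailing_window and offsets[-1] + window_size < length:
        offsets.append(length - window_size)
    return WindowPlan(transcript_id, window_size, step, tuple(offsets),
                      structures_per_fold, length)


def fold_windows(
    t: AnnotatedTranscript,
    plan: WindowPlan,
    backend: FoldingBackend,
) -> list[StructureRecord]:
    """Fold every planned window of *t*, collecting ranked structures.

    A failure of one window's fold is logged and skipped — long batch runs
    must survive sporadic engine errors — but a backend that is missing
    entirely aborts before any fold.
    """
    if backend is None or not hasattr(backend, "fold"):
        raise ValueError("no folding backend available")
    if plan.transcript_id and plan.transcript_id != t.id:
        raise ValueError(f"plan for {plan.transcript_id!r} applied to {t.id!r}")
    records: list[StructureRecord] = []
    skipped = []
    for offset in plan.offsets:
        wlen = min(plan.window_size, len(t) - offset)
        window_seq = t.sequence[offset : offset + wlen]
        try:
            structs = backend.fold(
                window_seq, plan.structures_per_fold,
                transcript_id=t.id, offset=offset,
            )
        except Exception as exc:  # noqa: BLE001 - skip contract
            logger.warning("fold failed for %s offset %d: %s", t.id, offset, exc)
            skipped.append(offset)
            continue
        for rank, rec in enumerate(structs[: plan.structures_per_fold], start=1):
            if rec.pair_table.n != wlen:
                raise ValueError(
                    f"backend {backend.name!r} returned a structure of length "
                    f"{rec.pair_table.n} for a {wlen}-nt window"
                )
            records.append(StructureRecord(
                pair_table=rec.pair_table,
                transcript_id=t.id,
                window_offset=offset,
                rank=rank,
                free_energy=rec.free_energy,
                bases=rec.bases,
            ))
    if skipped:
        logger.warning("%s: %d of %d windows skipped after fold failures",
                       t.id, len(skipped), plan.n_windows)
    return records


@dataclass(frozen=True)
class FoldingProfile:
    """Minimum free energy per window start (1-based), at fixed window/step."""

    transcript_id: str
    window_size: int
    step: int
    positions: tuple[int, ...]  # 1-based window start positions
    energies: tuple[float, ...]  # kcal/mol, one per position

    def __len__(self) -> int:
        return len(self.positions)


def folding_profile(
    t: AnnotatedTranscript,
    backend: FoldingBackend,
    window_size: int = PROFILE_WINDOW,
    step: int = 1,
) -> FoldingProfile:
    """Local folding potential: optimal-structure MFE of each short window.

    Requires an energy-reporting backend; a window with no possible pairing
    scores 0.
    """
    if window_size > len(t):
        raise ValueError(
            f"profile window ({window_size}) exceeds transcript length ({len(t)})"
        )
    plan = enumerate_windows(len(t), window_size, step, transcript_id=t.id,
                             structures_per_fold=1)
    positions, energies = [], []
    for offset in plan.offsets:
        window_seq = t.sequence[offset : offset + plan.window_length(offset)]
        structs = backend.fold(window_seq, 1, transcript_id=t.id, offset=offset)
        if not structs:
            continue
        best = structs[0]
        if best.free_energy is None:
            if best.pair_table.n_paired == 0:
                energy = 0.0
            else:
                raise BackendCapabilityError(
                    f"backend {backend.name!r} reports no energies; "
                    "folding profile unavailable"
                )
        else:
            energy = best.free_energy
        positions.append(offset + 1)
        energies.append(energy)
    return FoldingProfile(t.id, window_size, step, tuple(positions),
                          tuple(energies))


def profile_minima(p: FoldingProfile) -> list[int]:
    """1-based window-start positions that are local minima of the profile.

    A position qualifies when its energy is strictly lower than the nearest
    differing value on both sides; a flat plateau that dips below both flanks
    is reported once, at its leftmost position.  Profile endpoints are never
    minima.
    """
    if len(p) == 0:
        raise ValueError("empty profile")
    e = p.energies
    minima = []
    i = 0
    while i < len(e):
        j = i
        while j + 1 < len(e) and e[j + 1] == e[i]:
            j += 1
        interior = i > 0 and j < len(e) - 1
        if interior and e[i - 1] > e[i] and e[j + 1] > e[i]:
            minima.append(p.positions[i])
        i = j + 1
    return minima
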