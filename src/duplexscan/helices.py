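"""Helix enumeration, composition classification, and motif selection.

A *helix* is a maximal run of stacked base pairs: consecutive pairs
(i, j), (i+1, j−1), …  Long-range (non-hairpin) duplexes are separated from
ordinary hairpin stems by two criteria applied at the innermost pair:

* strand distance — the number of nucleotides strictly between the two
  strands must be at least 40 (a hairpin loop is short), and
* linker pairing — at least 16 of those intervening nucleotides must be
  base-paired themselves (a hairpin presents a loop where a long-range
  duplex presents structure).

Composition classes partition a helix into maximal uniform sub-runs:
GC = {G·C, C·G}, AU = {A·U, U·A}, GU = {G·U, U·G}.  A *GC-helix* is a
uniform GC sub-run of ≥ 8 pairs meeting both non-hairpin criteria; a
*GC-stem* is the same composition run in a hairpin context (strand distance
below the threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

from .structure_io import PairTable, StructureRecord

__all__ = [
    "Helix",
    "HelixCriteria",
    "CandidateMotif",
    "enumerate_helices",
    "composition_subruns",
    "strand_distance",
    "linker_paired_count",
    "select_motifs",
    "pair_class",
]

_PAIR_CLASS = {
    ("G", "C"): "GC", ("C", "G"): "GC",
    ("A", "U"): "AU", ("U", "A"): "AU",
    ("G", "U"): "GU", ("U", "G"): "GU",
}


def pair_class(b5: str, b3: str) -> str:
    """Composition class of one base pair; raises on non-canonical pairs."""
    try:
        return _PAIR_CLASS[(b5, b3)]
    except KeyError:
        raise ValueError(f"non-complementary pair {b5}·{b3}") from None


@dataclass(frozen=True)
class Helix:
    """A maximal run of stacked pairs, window-local 1-based coordinates.

    ``pairs[m] = (i1+m, j1−m)``; the 5' strand is [i1, ik], the 3' strand
    [jk, j1], and ik < jk always holds.
    """

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("helix must contain at least one pair")
        i1, j1 = self.pairs[0]
        for m, (i, j) in enumerate(self.pairs):
            if (i, j) != (i1 + m, j1 - m):
                raise ValueError(f"pairs not stacked at index {m}")
        if self.pairs[-1][0] >= self.pairs[-1][1]:
            raise ValueError("helix strands overlap")

    @property
    def length_bp(self) -> int:
        return len(self.pairs)

    @property
    def strand5(self) -> tuple[int, int]:
        return (self.pairs[0][0], self.pairs[-1][0])

    @property
    def strand3(self) -> tuple[int, int]:
        return (self.pairs[-1][1], self.pairs[0][1])

    @property
    def innermost(self) -> tuple[int, int]:
        return self.pairs[-1]


@dataclass(frozen=True)
class HelixCriteria:
    """Selection thresholds for duplex motifs (all comparisons are >=).

    ``composition_class`` "any" selects whole maximal helices regardless of
    base composition; "GC" or "AU" selects uniform sub-runs of that class.
    ``hairpin_mode`` flips the strand-distance test to < threshold (and drops
    the linker test, whose purpose is to demand structure where a hairpin
    has its loop) so that classical GC-rich stem-loops can be counted.
    """

    min_len_bp: int = 8
    min_strand_distance: int = 40
    min_linker_paired: int = 16
    composition_class: str = "any"  # any | GC | AU
    hairpin_mode: bool = False

    def __post_init__(self) -> None:
        if self.min_len_bp < 1:
            raise ValueError("min_len_bp must be >= 1")
        if self.min_strand_distance < 0 or self.min_linker_paired < 0:
            raise ValueError("distance/linker thresholds must be >= 0")
        if self.composition_class not in ("any", "GC", "AU"):
            raise ValueError(f"unknown composition class "
                             f"{self.composition_class!r}")

    @property
    def motif_class(self) -> str:
        """Label attached to selected motifs."""
        if self.composition_class == "any":
            return "general"
        if self.hairpin_mode:
            return f"{self.composition_class}_stem"
        return self.composition_class


@dataclass(frozen=True)
class CandidateMotif:
    """A selected helix or sub-run, still in window-local coordinates."""

    motif_class: str
    pairs: tuple[tuple[int, int], ...]
    length_bp: int
    strand5: tuple[int, int]
    strand3: tuple[int, int]
    strand_distance: int
    linker_paired: int


def enumerate_helices(pt: PairTable) -> list[Helix]:
    """All maximal stacked helices of a pair table, ascending by 5' start.

    Every paired position belongs to exactly one maximal helix; maximality
    means the run cannot be extended by another stacked pair on either side.
    """
    helices = []
    for i, j in pt.pairs():
        # start of a run iff (i-1, j+1) is not also a pair
        if i > 1 and j < pt.n and pt.partner[i - 1] == j + 1:
            continue
        run = [(i, j)]
        while True:
            ni, nj = run[-1][0] + 1, run[-1][1] - 1
            if ni < nj and ni <= pt.n and pt.partner[ni] == nj:
                run.append((ni, nj))
            else:
                break
        helices.append(Helix(tuple(run)))
    helices.sort(key=lambda h: h.pairs[0])
    return helices


def composition_subruns(h: Helix, window_seq: str) -> list[tuple[str, Helix]]:
    """Split a helix into maximal sub-runs of uniform composition class.

    Returns (class, sub-helix) tuples in 5'→3' order; sub-run lengths sum to
    the helix length.  A non-canonical pair signals a corrupt structure file
    and is rejected with its coordinates.
    """
    classes = []
    for i, j in h.pairs:
        if j > len(window_seq):
            raise ValueError("helix extends beyond window sequence")
        try:
            classes.append(pair_class(window_seq[i - 1], window_seq[j - 1]))
        except ValueError:
            raise ValueError(
                f"non-complementary pair {window_seq[i-1]}·{window_seq[j-1]} "
                f"at ({i},{j}): corrupt structure input"
            ) from None
    subruns = []
    start = 0
    for m in range(1, h.length_bp + 1):
        if m == h.length_bp or classes[m] != classes[start]:
            subruns.append((classes[start], Helix(h.pairs[start:m])))
            start = m
    return subruns


def strand_distance(h: Helix) -> int:
    """Nucleotides strictly between the innermost pair (the linker length)."""
    ik, jk = h.innermost
    return jk - ik - 1


def linker_paired_count(h: Helix, pt: PairTable) -> int:
    """Paired positions strictly between the innermost pair.

    Partners may lie inside or outside the linker; any paired linker
    position counts.
    """
    ik, jk = h.innermost
    return sum(1 for p in range(ik + 1, jk) if pt.partner[p] != 0)


def _passes(h: Helix, pt: PairTable, criteria: HelixCriteria) -> bool:
    if h.length_bp < criteria.min_len_bp:
        return False
    dist = strand_distance(h)
    if criteria.hairpin_mode:
        return dist < criteria.min_strand_distance
    if dist < criteria.min_strand_distance:
        return False
    return linker_paired_count(h, pt) >= criteria.min_linker_paired


def select_motifs(
    structure: StructureRecord,
    window_seq: str,
    criteria: HelixCriteria = HelixCriteria(),
) -> list[CandidateMotif]:
    """Apply the selection criteria to one predicted structure.

    With ``composition_class="any"`` whole maximal helices are tested; with
    "GC"/"AU" each uniform sub-run of that class is tested against the
    thresholds using its *own* innermost pair (the sub-run is the reported
    motif, with its own strand coordinates).
    """
    pt = structure.pair_table
    if pt.n != len(window_seq):
        raise ValueError(
            f"structure length {pt.n} != sequence length {len(window_seq)}"
        )
    out = []
    for helix in enumerate_helices(pt):
        if criteria.composition_class == "any":
            candidates = [helix]
        else:
            candidates = [sub for cls, sub in composition_subruns(helix, window_seq)
                          if cls == criteria.composition_class]
        for cand in candidates:
            if _passes(cand, pt, criteria):
                out.append(CandidateMotif(
                    motif_class=criteria.motif_class,
                    pairs=cand.pairs,
                    length_bp=cand.length_bp,
                    strand5=cand.strand5,
                    strand3=cand.strand3,
                    strand_distance=strand_distance(cand),
                    linker_paired=linker_paired_count(cand, pt),
                ))
    return out
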