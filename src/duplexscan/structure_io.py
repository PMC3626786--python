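"""Secondary-structure representations and their file formats.

The canonical in-memory form of one predicted structure is the *pair table*:
``partner[i]`` gives the 1-based pairing partner of position ``i``, or 0 when
``i`` is unpaired.  Pair tables are involutive (``partner[partner[i]] == i``)
and may contain crossing (pseudoknotted) pairs; only the dot-bracket *writer*
is restricted to nested structures.

Two interchange formats are supported: Vienna-style dot-bracket lines and the
Mfold connect-table (CT) dialect, including concatenated multi-structure CT
files ranked in file order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


__all__ = [
    "PairTable",
    "StructureRecord",
    "parse_dot_bracket",
    "write_dot_bracket",
    "parse_ct",
    "parse_ct_file",
    "write_ct",
    "validate_pair_table",
]

_OPEN = {"(": ")", "[": "]", "{": "}"}
_CLOSE = {v: k for k, v in _OPEN.items()}


@dataclass(frozen=True)
class PairTable:
    """Base-pairing map of one structure; ``partner`` is indexed 1..n."""

    n: int
    partner: tuple[int, ...]  # length n+1; slot 0 unused (=0)

    @classmethod
    def from_pairs(cls, n: int, pairs: Iterable[tuple[int, int]]) -> "PairTable":
        partner = [0] * (n + 1)
        for i, j in pairs:
            if not (1 <= i <= n and 1 <= j <= n) or i == j:
                raise ValueError(f"invalid pair ({i},{j}) for length {n}")
            if partner[i] or partner[j]:
                raise ValueError(f"position reused in pair ({i},{j})")
            partner[i], partner[j] = j, i
        return cls(n, tuple(partner))

    def pairs(self) -> list[tuple[int, int]]:
        """All pairs (i, j) with i < j, ascending in i."""
        return [(i, self.partner[i]) for i in range(1, self.n + 1)
                if self.partner[i] > i]

    def __getitem__(self, i: int) -> int:
        if not 1 <= i <= self.n:
            raise IndexError(i)
        return self.partner[i]

    @property
    def n_paired(self) -> int:
        return sum(1 for i in range(1, self.n + 1) if self.partner[i])


@dataclass(frozen=True)
class StructureRecord:
    """One folded window: a pair table plus its provenance.

    ``window_offset`` is the 0-based start of the folded window within its
    transcript; ``rank`` orders the (sub)optimal structures of one fold,
    1 = optimal.
    """

    pair_table: PairTable
    transcript_id: str = ""
    window_offset: int = 0
    rank: int = 1
    free_energy: float | None = None
    bases: str | None = None  # window sequence as recorded in the file, if any

    @property
    def key(self) -> tuple[str, int, int]:
        """Identity of the structure within a run."""
        return (self.transcript_id, self.window_offset, self.rank)


def parse_dot_bracket(line: str) -> PairTable:
    """Parse one dot-bracket string into a pair table.

    Round brackets are standard; ``[]`` and ``{}`` are accepted so that
    pseudoknotted input can be represented.  Unbalanced brackets are rejected
    with the 1-based position of the first violation.
    """
    line = line.strip()
    stacks: dict[str, list[int]] = {k: [] for k in _OPEN}
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(line, start=1):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks[ch].append(pos)
        elif ch in _CLOSE:
            stack = stacks[_CLOSE[ch]]
            if not stack:
                raise ValueError(f"unmatched {ch!r} at position {pos}")
            pairs.append((stack.pop(), pos))
        else:
            raise ValueError(f"invalid character {ch!r} at position {pos}")
    for opener, stack in stacks.items():
        if stack:
            raise ValueError(f"unmatched {opener!r} at position {stack[-1]}")
    return PairTable.from_pairs(len(line), pairs)


def write_dot_bracket(pt: PairTable) -> str:
    """Render a nested pair table as a dot-bracket string.

    Crossing pairs cannot be written with a single bracket family and are
    rejected.
    """
    chars = ["."] * pt.n
    open_pairs: list[tuple[int, int]] = []
    for i, j in pt.pairs():
        while open_pairs and open_pairs[-1][1] < i:
            open_pairs.pop()
        if open_pairs and not (i > open_pairs[-1][0] and j < open_pairs[-1][1]):
            raise ValueError(
                f"crossing pairs {open_pairs[-1]} and ({i},{j}): "
                "dot-bracket writer supports nested structures only"
            )
        open_pairs.append((i, j))
        chars[i - 1], chars[j - 1] = "(", ")"
    return "".join(chars)


def validate_pair_table(pt: PairTable) -> list[str]:
    """Return human-readable invariant violations (empty list = valid)."""
    issues = []
    if len(pt.partner) != pt.n + 1:
        issues.append(f"partner array length {len(pt.partner)} != n+1 ({pt.n + 1})")
        return issues
    for i in range(1, pt.n + 1):
        j = pt.partner[i]
        if not 0 <= j <= pt.n:
            issues.append(f"partner[{i}]={j} out of range 0..{pt.n}")
        elif j == i:
            issues.append(f"self-pair at position {i}")
        elif j and pt.partner[j] != i:
            issues.append(
                f"asymmetric pair: partner[{i}]={j} but partner[{j}]={pt.partner[j]}"
            )
    return issues


# ---------------------------------------------------------------------------
# CT format (Mfold connect-table dialect)

_ENERGY_RE = re.compile(r"dG\s*=?\s*(-?\d+\.?\d*)", re.IGNORECASE)


def _parse_ct_record(lines: Sequence[str], start: int,
                     lineno0: int) -> tuple[StructureRecord, int]:
    header = lines[start]
    fields = header.split()
    try:
        n = int(fields[0])
    except (IndexError, ValueError):
        raise ValueError(
            f"line {lineno0 + 1}: CT header must start with the nucleotide count"
        ) from None
    m = _ENERGY_RE.search(header)
    energy = float(m.group(1)) if m else None

    if len(lines) - start - 1 < n:
        raise ValueError(
            f"line {lineno0 + 1}: CT record announces {n} nucleotides but only "
            f"{len(lines) - start - 1} lines follow"
        )
    partner = [0] * (n + 1)
    bases = []
    for k in range(1, n + 1):
        lineno = lineno0 + 1 + k
        cols = lines[start + k].split()
        if len(cols) < 6:
            raise ValueError(f"line {lineno}: expected >= 6 CT columns")
        idx, base, p, idx2 = int(cols[0]), cols[1], int(cols[4]), int(cols[5])
        if idx != k or idx2 != k:
            raise ValueError(f"line {lineno}: index {idx}/{idx2} out of order "
                             f"(expected {k})")
        if not 0 <= p <= n:
            raise ValueError(f"line {lineno}: partner {p} out of range")
        partner[k] = p
        bases.append(base.upper().replace("T", "U"))
    pt = PairTable(n, tuple(partner))
    bad = validate_pair_table(pt)
    if bad:
        raise ValueError(f"CT record at line {lineno0 + 1}: " + "; ".join(bad))
    rec = StructureRecord(pair_table=pt, free_energy=energy, bases="".join(bases))
    return rec, start + n + 1


def parse_ct(text: str) -> list[StructureRecord]:
    """Parse CT text, possibly several concatenated records.

    Records are ranked in file order (rank 1 = first).  Each per-nucleotide
    line is ``index base prev next partner index``; the header carries the
    count and, optionally, a ``dG = x`` energy token.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    records: list[StructureRecord] = []
    pos = 0
    while pos < len(lines):
        rec, pos = _parse_ct_record(lines, pos, pos)
        records.append(rec)
    if not records:
        raise ValueError("empty CT input")
    return [
        StructureRecord(pair_table=r.pair_table, free_energy=r.free_energy,
                        bases=r.bases, rank=k)
        for k, r in enumerate(records, start=1)
    ]


def parse_ct_file(path: str | Path) -> list[StructureRecord]:
    return parse_ct(Path(path).read_text())


def write_ct(records: Sequence[StructureRecord], sequence: str,
             path: str | Path | None = None) -> str:
    """Render structures of one window as (concatenated) CT records."""
    out = []
    for rec in records:
        pt = rec.pair_table
        if pt.n != len(sequence):
            raise ValueError(
                f"pair table length {pt.n} != sequence length {len(sequence)}"
            )
        energy = "" if rec.free_energy is None else f"  dG = {rec.free_energy:.2f}"
        out.append(f"{pt.n}{energy}")
        for i in range(1, pt.n + 1):
            nxt = i + 1 if i < pt.n else 0
            out.append(
                f"{i} {sequence[i - 1]} {i - 1} {nxt} {pt.partner[i]} {i}"
            )
    text = "\n".join(out) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
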